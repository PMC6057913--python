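"""Pairwise similarity search and reciprocal-best-hit orthology calls.

The decision layer (ranking, the order-of-magnitude margin rule, and the
bidirectional positive/negative/ambiguous classification) is backend
agnostic: it consumes :class:`~exomertrace.io.SearchHit` lists that can come
from the built-in Smith-Waterman searcher, from BLAST tabular files, or from
HMMER tabular files, as long as they rank identically.

The built-in backend scores with affine-gap Smith-Waterman under a standard
substitution matrix and calibrates E-values by fitting a Gumbel
(extreme-value) distribution to scores of the query against shuffled
database sequences — the same statistical family BLAST's internal statistics
assume.

Decision rules: a family-specific inclusion E-value cutoff on the forward
search (stringent 1e-40 for the core protein, inclusive 0.05 for the
paralogous family); a candidate is *positive* only if a reverse search into
at least one reference database retrieves a member of the established
orthologue set as top hit AND beats the best non-redundant non-member hit by
at least ``margin_orders`` orders of magnitude of E-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .io import SearchHit, SequenceRecord

__all__ = [
    "SearchConfig",
    "OrthologyCall",
    "EValueModel",
    "local_align",
    "calibrate_evalue",
    "best_hits",
    "rank_hits",
    "margin_ok",
    "rbh_classify",
    "classify_family",
    "apply_domain_filter",
]

# reported-zero E-values from external tools are floored here so the
# order-of-magnitude margin stays defined
EVALUE_FLOOR = 1e-180


@dataclass
class SearchConfig:
    """Search and classification parameters.

    ``evalue_cutoff_chs5``/``evalue_cutoff_chap`` are the forward inclusion
    cutoffs for the core-protein and paralogous-family searches;
    ``margin_orders`` is the required E-value separation (in orders of
    magnitude) between the best in-set reverse hit and the best
    non-redundant non-member.
    """

    evalue_cutoff_chs5: float = 1e-40
    evalue_cutoff_chap: float = 0.05
    margin_orders: float = 2.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    null_shuffles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_cutoff_chs5 <= 0 or self.evalue_cutoff_chap <= 0:
            raise ValueError("E-value cutoffs must be > 0")
        if self.margin_orders < 0:
            raise ValueError("margin_orders must be >= 0")

    def cutoff_for(self, family: str) -> float:
        if family == "chs5":
            return self.evalue_cutoff_chs5
        if family == "chap":
            return self.evalue_cutoff_chap
        raise ValueError(f"unknown family {family!r} (expected 'chs5' or 'chap')")


@dataclass
class OrthologyCall:
    """Classification of one candidate under the bidirectional rules."""

    candidate_id: str
    status: str  # positive | negative | ambiguous
    forward_evalue: float | None = None
    reverse_db: str | None = None
    reverse_top: str | None = None
    reverse_evalue: float | None = None
    margin: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("positive", "negative", "ambiguous"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "positive" and (
            self.reverse_db is None or self.margin is None
        ):
            raise ValueError("positive call must record reverse evidence")


def _make_aligner(config: SearchConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix_name)
    # gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _sanitize(residues: str, alphabet: str) -> str:
    bad = set(residues) - set(alphabet)
    if bad:
        warnings.warn(
            f"unknown residue letter(s) {sorted(bad)} treated as X",
            stacklevel=3,
        )
        residues = "".join(c if c in alphabet else "X" for c in residues)
    return residues


def local_align(
    a: SequenceRecord,
    b: SequenceRecord,
    config: SearchConfig | None = None,
    with_span: bool = False,
) -> float | tuple[float, tuple[int, int, int, int]]:
    """Affine-gap Smith-Waterman score of ``a`` vs ``b`` (symmetric, >= 0).

    With ``with_span=True`` also returns the (qstart, qend, tstart, tend)
    coordinates of one optimal local alignment (half-open).
    """
    config = config or SearchConfig()
    aligner = _make_aligner(config)
    alphabet = str(aligner.substitution_matrix.alphabet)
    sa = _sanitize(a.residues, alphabet)
    sb = _sanitize(b.residues, alphabet)
    if not with_span:
        return max(0.0, float(aligner.score(sa, sb)))
    alns = aligner.align(sa, sb)
    if len(alns) == 0:
        return 0.0, (0, 0, 0, 0)
    best = alns[0]
    (qs, qe) = (int(best.aligned[0][0][0]), int(best.aligned[0][-1][1]))
    (ts, te) = (int(best.aligned[1][0][0]), int(best.aligned[1][-1][1]))
    return max(0.0, float(best.score)), (qs, qe, ts, te)


@dataclass
class EValueModel:
    """Gumbel null model for Smith-Waterman scores of one query.

    ``evalue(score)`` = database size x P(null score >= score) under the
    fitted extreme-value distribution; monotone non-increasing in the score.
    """

    loc: float
    scale: float
    database_size: int

    def evalue(self, score: float) -> float:
        p = float(stats.gumbel_r.sf(score, loc=self.loc, scale=self.scale))
        return max(self.database_size * p, 0.0)


def _shuffled(residues: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(residues.encode(), dtype="S1").copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


def calibrate_evalue(
    query: SequenceRecord,
    database: Sequence[SequenceRecord],
    config: SearchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> EValueModel:
    """Fit the Gumbel null by scoring ``query`` against shuffled database
    sequences (``config.null_shuffles`` of them, cycling over the database).
    """
    config = config or SearchConfig()
    if config.null_shuffles < 100:
        raise ValueError("null_shuffles must be >= 100 for a stable fit")
    if not database:
        raise ValueError("empty database")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    aligner = _make_aligner(config)
    alphabet = str(aligner.substitution_matrix.alphabet)
    q = _sanitize(query.residues, alphabet)
    scores = np.empty(config.null_shuffles)
    for i in range(config.null_shuffles):
        target = database[i % len(database)]
        t = _sanitize(_shuffled(target.residues, rng), alphabet)
        scores[i] = max(0.0, float(aligner.score(q, t)))
    if np.ptp(scores) == 0:
        raise ValueError(
            "degenerate null distribution (all shuffle scores equal); "
            "increase null_shuffles or check the database"
        )
    loc, scale = stats.gumbel_r.fit(scores)
    return EValueModel(loc=loc, scale=scale, database_size=len(database))


def rank_hits(hits: Iterable[SearchHit]) -> list[SearchHit]:
    """Ascending E-value; ties by descending score then lexical target id."""
    return sorted(hits, key=lambda h: (h.evalue, -h.raw_score, h.target_id))


def best_hits(
    query: SequenceRecord,
    database: Sequence[SequenceRecord],
    config: SearchConfig | None = None,
    model: EValueModel | None = None,
    rng: np.random.Generator | None = None,
) -> list[SearchHit]:
    """Score ``query`` against every database sequence with the built-in
    aligner and return ranked hits with calibrated E-values.
    """
    config = config or SearchConfig()
    if not database:
        raise ValueError("empty database")
    if model is None:
        model = calibrate_evalue(query, database, config, rng=rng)
    aligner = _make_aligner(config)
    alphabet = str(aligner.substitution_matrix.alphabet)
    q = _sanitize(query.residues, alphabet)
    hits = []
    for target in database:
        s = max(0.0, float(aligner.score(q, _sanitize(target.residues, alphabet))))
        hits.append(
            SearchHit(
                query_id=query.id,
                target_id=target.id,
                raw_score=s,
                evalue=model.evalue(s),
                source="builtin",
            )
        )
    return rank_hits(hits)


def margin_ok(
    hits: Sequence[SearchHit],
    orthoset: set[str],
    margin_orders: float = 2.0,
    redundant_ids: set[str] | None = None,
) -> tuple[bool, float]:
    """The non-redundant-hit margin rule.

    True iff the best hit is in ``orthoset`` and its E-value is at least
    ``margin_orders`` orders of magnitude below the best hit that is neither
    in the set nor an identical-sequence duplicate of a member
    (``redundant_ids``). With no non-member hit at all the margin is
    +infinity. E-values are floored at ``EVALUE_FLOOR`` first.
    """
    if not hits:
        return False, float("nan")
    member = orthoset | (redundant_ids or set())
    best = hits[0]
    if best.target_id not in orthoset:
        return False, 0.0
    e_in = max(best.evalue, EVALUE_FLOOR)
    out = [h for h in hits if h.target_id not in member]
    if not out:
        return True, float("inf")
    e_out = max(out[0].evalue, EVALUE_FLOOR)
    margin = np.log10(e_out) - np.log10(e_in)
    return bool(margin >= margin_orders), float(margin)


ReverseSearch = Callable[[SequenceRecord, Sequence[SequenceRecord]], list[SearchHit]]


def rbh_classify(
    candidate: SequenceRecord,
    forward_evalue: float,
    reverse_databases: Mapping[str, Sequence[SequenceRecord]],
    orthoset: set[str],
    config: SearchConfig | None = None,
    nonmember_ids: set[str] | None = None,
    redundant_ids: set[str] | None = None,
    reverse_search: ReverseSearch | None = None,
    rng: np.random.Generator | None = None,
) -> OrthologyCall:
    """Classify one forward-retrieved candidate by reverse search.

    Positive iff a reverse search into at least one reference database
    retrieves an ``orthoset`` member as top hit and the margin rule holds;
    negative if every informative reverse top hit is a robustly annotated
    non-member (``nonmember_ids``); ambiguous otherwise. Databases are
    examined in sorted-name order for determinism, and the first database
    satisfying the criterion is recorded.
    """
    config = config or SearchConfig()
    if not reverse_databases:
        raise ValueError("no reverse databases supplied")
    if reverse_search is None:
        reverse_search = lambda q, db: best_hits(q, db, config, rng=rng)
    saw_nonmember_top = False
    best_fail: OrthologyCall | None = None
    for name in sorted(reverse_databases):
        db = reverse_databases[name]
        if not db:
            continue
        hits = reverse_search(candidate, db)
        if not hits:
            continue
        top = hits[0]
        ok, margin = margin_ok(hits, orthoset, config.margin_orders, redundant_ids)
        if ok:
            return OrthologyCall(
                candidate_id=candidate.id,
                status="positive",
                forward_evalue=forward_evalue,
                reverse_db=name,
                reverse_top=top.target_id,
                reverse_evalue=top.evalue,
                margin=margin,
            )
        if nonmember_ids and top.target_id in nonmember_ids:
            saw_nonmember_top = True
        if best_fail is None:
            best_fail = OrthologyCall(
                candidate_id=candidate.id,
                status="ambiguous",
                forward_evalue=forward_evalue,
                reverse_db=name,
                reverse_top=top.target_id,
                reverse_evalue=top.evalue,
                margin=margin,
                note="reverse criterion not met",
            )
    if saw_nonmember_top:
        call = best_fail or OrthologyCall(candidate.id, "ambiguous")
        call.status = "negative"
        call.note = "reverse top hit is an annotated non-member"
        return call
    return best_fail or OrthologyCall(
        candidate_id=candidate.id,
        status="ambiguous",
        forward_evalue=forward_evalue,
        note="no informative reverse hit",
    )


def classify_family(
    reference_queries: Sequence[SequenceRecord],
    proteome: Sequence[SequenceRecord],
    reverse_databases: Mapping[str, Sequence[SequenceRecord]],
    orthoset: set[str],
    family: str = "chap",
    config: SearchConfig | None = None,
    nonmember_ids: set[str] | None = None,
    seed: int | None = None,
) -> list[OrthologyCall]:
    """Forward-search each reference query into ``proteome``, keep hits at or
    below the family cutoff, and classify each candidate bidirectionally.

    Candidates retrieved by several queries are classified once (best
    forward E-value kept). Returns calls sorted by candidate id.
    """
    config = config or SearchConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cutoff = config.cutoff_for(family)
    forward_e: dict[str, float] = {}
    for query in sorted(reference_queries, key=lambda r: r.id):
        for hit in best_hits(query, proteome, config, rng=rng):
            if hit.evalue <= cutoff:
                prev = forward_e.get(hit.target_id)
                if prev is None or hit.evalue < prev:
                    forward_e[hit.target_id] = hit.evalue
    by_id = {r.id: r for r in proteome}
    redundant = _identical_duplicates(reverse_databases, orthoset)
    calls = []
    for cand_id in sorted(forward_e):
        calls.append(
            rbh_classify(
                by_id[cand_id],
                forward_e[cand_id],
                reverse_databases,
                orthoset,
                config,
                nonmember_ids=nonmember_ids,
                redundant_ids=redundant,
                rng=rng,
            )
        )
    return calls


def _identical_duplicates(
    reverse_databases: Mapping[str, Sequence[SequenceRecord]], orthoset: set[str]
) -> set[str]:
    """Ids outside the orthologue set whose residues equal a member's."""
    member_seqs = set()
    for db in reverse_databases.values():
        for rec in db:
            if rec.id in orthoset:
                member_seqs.add(rec.residues)
    dup = set()
    for db in reverse_databases.values():
        for rec in db:
            if rec.id not in orthoset and rec.residues in member_seqs:
                dup.add(rec.id)
    return dup


def apply_domain_filter(
    calls: Sequence[OrthologyCall],
    domain_table: Sequence[tuple[str, str, int, int]],
    required_domain: str,
) -> list[OrthologyCall]:
    """Demote positive calls lacking an external domain annotation.

    ``domain_table`` rows are (candidate_id, domain, start, end) from an
    external scan; a positive candidate with no row naming
    ``required_domain`` becomes negative.
    """
    annotated = {cid for cid, dom, *_ in domain_table if dom == required_domain}
    out = []
    for call in calls:
        if call.status == "positive" and call.candidate_id not in annotated:
            demoted = OrthologyCall(
                candidate_id=call.candidate_id,
                status="negative",
                forward_evalue=call.forward_evalue,
                reverse_db=call.reverse_db,
                reverse_top=call.reverse_top,
                reverse_evalue=call.reverse_evalue,
                margin=call.margin,
                note=f"lacks required domain {required_domain}",
            )
            out.append(demoted)
        else:
            out.append(call)
    return out
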