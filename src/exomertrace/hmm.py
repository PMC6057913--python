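"""Profile hidden Markov models and the iterative enrichment search.

A profile HMM is built from a fixed-width alignment: columns with gap
fraction < 0.5 become match states; match emissions are pseudocount-
smoothed residue counts; transitions among match/insert/delete states are
estimated from the observed state paths with Laplace smoothing. Sequences
are scored by the forward algorithm in log space, reported as log-odds bits
against the background model (``log2 P(seq|hmm) / P(seq|background)``); the
model is global over its match states, so unrelated or mis-sized sequences
pay insert/delete penalties.

The enrichment loop mirrors iterative homology searching: build the HMM
from the seed alignment, search the proteomes, reverse-validate each new
hit against a reference proteome, insert validated hits into the alignment
along their Viterbi path, rebuild, and repeat until an iteration adds no
new validated homologue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import AMINO_ACIDS, GAP, Alignment, SearchHit, SequenceRecord
from .search import SearchConfig, best_hits

__all__ = [
    "ProfileHMM",
    "IterationState",
    "build_hmm",
    "forward_score",
    "viterbi_path",
    "hmm_search",
    "validate_hit",
    "iterate_search",
    "default_bit_threshold",
]

_N_AA = len(AMINO_ACIDS)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG_INF = -np.inf


@dataclass
class ProfileHMM:
    """Match/insert/delete profile architecture, probabilities in linear space.

    Arrays are indexed by match state k = 1..M with index 0 standing for the
    begin state; transitions are M->{M,I,D}, I->{M,I}, D->{M,D}. Insert
    states emit the background distribution.
    """

    match_emissions: np.ndarray      # (M+1, 20); row 0 unused
    background: np.ndarray           # (20,)
    t_mm: np.ndarray                 # (M+1,) M_k -> M_{k+1} (k=M: -> end)
    t_mi: np.ndarray                 # (M+1,) M_k -> I_k
    t_md: np.ndarray                 # (M+1,) M_k -> D_{k+1}
    t_im: np.ndarray                 # (M+1,) I_k -> M_{k+1} (k=M: -> end)
    t_ii: np.ndarray                 # (M+1,) I_k -> I_k
    t_dm: np.ndarray                 # (M+1,) D_k -> M_{k+1} (k=M: -> end)
    t_dd: np.ndarray                 # (M+1,) D_k -> D_{k+1}
    match_columns: list[int] = field(default_factory=list)

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0] - 1

    def validate(self) -> None:
        M = self.n_match_states
        if M < 1:
            raise ValueError("profile needs >= 1 match state")
        if not np.allclose(self.match_emissions[1:].sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        for name, total in (
            ("M", self.t_mm + self.t_mi + self.t_md),
            ("I", self.t_im + self.t_ii),
            ("D", self.t_dm + self.t_dd),
        ):
            if not np.allclose(total, 1.0, atol=1e-9):
                raise ValueError(f"outgoing {name}-state transitions must sum to 1")

    # -- plain-text serialization -------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# profile-hmm\tM={self.n_match_states}"]
        lines.append("background\t" + "\t".join(f"{x:.10g}" for x in self.background))
        lines.append(
            "match_columns\t" + "\t".join(str(c) for c in self.match_columns)
        )
        for k in range(self.n_match_states + 1):
            em = "\t".join(f"{x:.10g}" for x in self.match_emissions[k])
            tr = "\t".join(
                f"{arr[k]:.10g}"
                for arr in (self.t_mm, self.t_mi, self.t_md,
                            self.t_im, self.t_ii, self.t_dm, self.t_dd)
            )
            lines.append(f"state\t{k}\t{em}\t{tr}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileHMM":
        lines = Path(path).read_text().splitlines()
        M = int(lines[0].split("M=")[1])
        background = np.array([float(x) for x in lines[1].split("\t")[1:]])
        cols_f = lines[2].split("\t")[1:]
        match_columns = [int(c) for c in cols_f if c]
        em = np.zeros((M + 1, _N_AA))
        trs = [np.zeros(M + 1) for _ in range(7)]
        for line in lines[3:]:
            parts = line.split("\t")
            k = int(parts[1])
            em[k] = [float(x) for x in parts[2:2 + _N_AA]]
            for i, arr in enumerate(trs):
                arr[k] = float(parts[2 + _N_AA + i])
        hmm = cls(em, background, *trs, match_columns=match_columns)
        hmm.validate()
        return hmm


def _encode(residues: str) -> np.ndarray:
    # X and other unknowns get index -1 and emit the background
    return np.array([_AA_INDEX.get(c, -1) for c in residues], dtype=int)


def build_hmm(
    alignment: Alignment,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    match_gap_fraction: float = 0.5,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with gap fraction strictly below ``match_gap_fraction`` become
    match states. Emissions are ``(counts + w * background) / (n + w)``;
    transitions are Laplace-smoothed counts of the observed per-row state
    paths.
    """
    if background is None:
        background = np.full(_N_AA, 1.0 / _N_AA)
    n_rows = len(alignment)
    cols = [
        j
        for j in range(alignment.n_columns)
        if sum(r.residues[j] == GAP for r in alignment.records) / n_rows
        < match_gap_fraction
    ]
    if not cols:
        raise ValueError("alignment yields zero match columns")
    M = len(cols)
    col_set = set(cols)

    counts = np.zeros((M + 1, _N_AA))
    # transition counts per source state, Laplace-smoothed at the end
    c_m = np.zeros((M + 1, 3))  # -> M, I, D
    c_i = np.zeros((M + 1, 2))  # -> M, I
    c_d = np.zeros((M + 1, 2))  # -> M, D

    for row in alignment.records:
        path: list[tuple[str, int]] = [("M", 0)]  # begin acts as M_0
        k = 0
        for j in range(alignment.n_columns):
            ch = row.residues[j]
            if j in col_set:
                k += 1
                if ch == GAP:
                    path.append(("D", k))
                else:
                    path.append(("M", k))
                    idx = _AA_INDEX.get(ch, -1)
                    if idx >= 0:
                        counts[k, idx] += 1
            elif ch != GAP:
                path.append(("I", k))
        path.append(("M", M + 1))  # end treated as a match for counting
        for (s1, k1), (s2, _k2) in zip(path, path[1:]):
            col = {"M": 0, "I": 1, "D": 2}[s2] if s2 != "M" else 0
            if s1 == "M":
                c_m[k1, col] += 1
            elif s1 == "I":
                c_i[k1, min(col, 1)] += 1
            else:
                c_d[k1, min(col, 1)] += 1

    w = pseudocount_weight
    denom = counts[1:].sum(axis=1, keepdims=True) + w
    em = np.zeros((M + 1, _N_AA))
    em[1:] = (counts[1:] + w * background) / denom

    lap = 1.0
    m_tot = c_m + lap
    i_tot = c_i + lap
    d_tot = c_d + lap
    t_mm, t_mi, t_md = (m_tot / m_tot.sum(axis=1, keepdims=True)).T
    t_im, t_ii = (i_tot / i_tot.sum(axis=1, keepdims=True)).T
    t_dm, t_dd = (d_tot / d_tot.sum(axis=1, keepdims=True)).T

    hmm = ProfileHMM(
        match_emissions=em,
        background=background.copy(),
        t_mm=np.ascontiguousarray(t_mm), t_mi=np.ascontiguousarray(t_mi),
        t_md=np.ascontiguousarray(t_md), t_im=np.ascontiguousarray(t_im),
        t_ii=np.ascontiguousarray(t_ii), t_dm=np.ascontiguousarray(t_dm),
        t_dd=np.ascontiguousarray(t_dd), match_columns=cols,
    )
    hmm.validate()
    return hmm


def _log(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(a)


def forward_score(hmm: ProfileHMM, seq: SequenceRecord | str) -> float:
    """Log-odds forward score in bits: ``log2 P(seq|hmm)/P(seq|background)``.

    The DP runs in odds space (emissions divided by background), so insert
    states and the null model cancel exactly; the returned value is finite
    for every non-empty sequence.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise ValueError("empty sequence")
    x = _encode(residues)
    L = x.size
    M = hmm.n_match_states
    bg = hmm.background
    # log odds emissions per position (M+1, ), row k for match state k
    lem = _log(hmm.match_emissions[1:]) - _log(bg)[None, :]  # (M,20)
    l_mm, l_mi, l_md = _log(hmm.t_mm), _log(hmm.t_mi), _log(hmm.t_md)
    l_im, l_ii = _log(hmm.t_im), _log(hmm.t_ii)
    l_dm, l_dd = _log(hmm.t_dm), _log(hmm.t_dd)

    # fM[k], fI[k], fD[k] for current sequence position; k = 0..M
    fM = np.full(M + 1, _NEG_INF)
    fI = np.full(M + 1, _NEG_INF)
    fD = np.full(M + 1, _NEG_INF)
    # position 0 (nothing emitted): begin, then delete chain
    fM[0] = 0.0
    # position 0: begin, then the pure-deletion chain B->D1->...->Dk
    prev = fM[0] + l_md[0]
    for k in range(1, M + 1):
        fD[k] = prev
        prev = fD[k] + l_dd[k]

    for i in range(L):
        e = lem[:, x[i]] if x[i] >= 0 else np.zeros(M)  # unknown emits background
        nM = np.full(M + 1, _NEG_INF)
        nI = np.full(M + 1, _NEG_INF)
        # M_k (k>=1) entered from M_{k-1}, I_{k-1}, D_{k-1} at previous position
        entry = np.logaddexp(
            np.logaddexp(fM[:M] + l_mm[:M], fI[:M] + l_im[:M]),
            fD[:M] + l_dm[:M],
        )
        nM[1:] = entry + e
        # I_k from M_k, I_k at previous position (insert emits background; odds 0)
        nI = np.logaddexp(fM + l_mi, fI + l_ii)
        # D_k from M_{k-1} or D_{k-1} at the SAME position: sequential scan
        nD = np.full(M + 1, _NEG_INF)
        for k in range(1, M + 1):
            nD[k] = (
                np.logaddexp(nM[k - 1] + l_md[k - 1], nD[k - 1] + l_dd[k - 1])
                if k > 1
                else nM[0] + l_md[0]
            )
        fM, fI, fD = nM, nI, nD

    total = np.logaddexp(
        np.logaddexp(fM[M] + l_mm[M], fI[M] + l_im[M]), fD[M] + l_dm[M]
    )
    return float(total / np.log(2.0))


def viterbi_path(hmm: ProfileHMM, seq: SequenceRecord | str) -> list[tuple[str, int]]:
    """Best state path (global over match states) as (state, k) tuples."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    x = _encode(residues)
    L, M = x.size, hmm.n_match_states
    bg = hmm.background
    lem = _log(hmm.match_emissions[1:]) - _log(bg)[None, :]
    l_mm, l_mi, l_md = _log(hmm.t_mm), _log(hmm.t_mi), _log(hmm.t_md)
    l_im, l_ii = _log(hmm.t_im), _log(hmm.t_ii)
    l_dm, l_dd = _log(hmm.t_dm), _log(hmm.t_dd)

    vM = np.full((L + 1, M + 1), _NEG_INF)
    vI = np.full((L + 1, M + 1), _NEG_INF)
    vD = np.full((L + 1, M + 1), _NEG_INF)
    ptr: dict[tuple[str, int, int], tuple[str, int, int]] = {}
    vM[0, 0] = 0.0
    for k in range(1, M + 1):
        src = ("M", 0, 0) if k == 1 else ("D", 0, k - 1)
        vD[0, k] = (vM[0, 0] + l_md[0]) if k == 1 else vD[0, k - 1] + l_dd[k - 1]
        ptr[("D", 0, k)] = src
    for i in range(1, L + 1):
        e = lem[:, x[i - 1]] if x[i - 1] >= 0 else np.zeros(M)
        for k in range(1, M + 1):
            cands = [
                (vM[i - 1, k - 1] + l_mm[k - 1], ("M", i - 1, k - 1)),
                (vI[i - 1, k - 1] + l_im[k - 1], ("I", i - 1, k - 1)),
                (vD[i - 1, k - 1] + l_dm[k - 1], ("D", i - 1, k - 1)),
            ]
            best, src = max(cands, key=lambda c: c[0])
            vM[i, k] = best + e[k - 1]
            ptr[("M", i, k)] = src
        for k in range(0, M + 1):
            cands = [
                (vM[i - 1, k] + l_mi[k], ("M", i - 1, k)),
                (vI[i - 1, k] + l_ii[k], ("I", i - 1, k)),
            ]
            best, src = max(cands, key=lambda c: c[0])
            vI[i, k] = best
            ptr[("I", i, k)] = src
        for k in range(1, M + 1):
            cands = [(vM[i, k - 1] + l_md[k - 1], ("M", i, k - 1))]
            if k > 1:
                cands.append((vD[i, k - 1] + l_dd[k - 1], ("D", i, k - 1)))
            best, src = max(cands, key=lambda c: c[0])
            vD[i, k] = best
            ptr[("D", i, k)] = src
    ends = [
        (vM[L, M] + l_mm[M], ("M", L, M)),
        (vI[L, M] + l_im[M], ("I", L, M)),
        (vD[L, M] + l_dm[M], ("D", L, M)),
    ]
    _, cur = max(ends, key=lambda c: c[0])
    path = []
    while cur != ("M", 0, 0):
        state, i, k = cur
        path.append((state, k))
        cur = ptr[cur]
    return list(reversed(path))


def align_to_match_states(hmm: ProfileHMM, seq: SequenceRecord) -> SequenceRecord:
    """Project a sequence onto the HMM's match states via its Viterbi path.

    Match states receive the emitted residue, deletions a gap; insert-state
    residues are dropped (profile insertion keeps the alignment width fixed).
    """
    path = viterbi_path(hmm, seq)
    row = [GAP] * hmm.n_match_states
    i = 0
    for state, k in path:
        if state == "M":
            row[k - 1] = seq.residues[i]
            i += 1
        elif state == "I":
            i += 1
    return SequenceRecord(
        id=seq.id, residues="".join(row), taxon=seq.taxon, annotation=seq.annotation
    )


def hmm_search(
    hmm: ProfileHMM,
    proteomes: Sequence[SequenceRecord],
    bit_threshold: float,
) -> list[SearchHit]:
    """All sequences scoring at or above ``bit_threshold``, best first."""
    hits = []
    for rec in proteomes:
        bits = forward_score(hmm, rec)
        if bits >= bit_threshold:
            hits.append(
                SearchHit(
                    query_id="profile", target_id=rec.id, raw_score=bits,
                    evalue=np.inf, source="builtin",
                    metadata={"taxon": rec.taxon},
                )
            )
    return sorted(hits, key=lambda h: (-h.raw_score, h.target_id))


def default_bit_threshold(
    hmm: ProfileHMM,
    proteomes: Sequence[SequenceRecord],
    rng: np.random.Generator,
    decoy_quantile: float = 0.99,
    n_shuffles: int = 100,
) -> float:
    """Calibrate the acceptance threshold on shuffled sequences so that the
    decoy acceptance rate is at most ``1 - decoy_quantile``.
    """
    pool = sorted(proteomes, key=lambda r: r.id)
    scores = []
    for i in range(n_shuffles):
        rec = pool[i % len(pool)]
        arr = np.frombuffer(rec.residues.encode(), dtype="S1").copy()
        rng.shuffle(arr)
        scores.append(forward_score(hmm, arr.tobytes().decode()))
    return float(np.quantile(scores, decoy_quantile))


def validate_hit(
    hit: SequenceRecord,
    reference_proteome: Sequence[SequenceRecord],
    orthoset: set[str],
    config: SearchConfig | None = None,
    rng: np.random.Generator | None = None,
) -> bool:
    """Reverse pairwise search; True iff the top hit is an orthoset member."""
    hits = best_hits(hit, reference_proteome, config or SearchConfig(), rng=rng)
    return bool(hits) and hits[0].target_id in orthoset


@dataclass
class IterationState:
    """State of the iterative enrichment loop after its final round."""

    alignment: Alignment
    hmm: ProfileHMM
    accepted: set[str]
    iteration: int
    converged: bool
    log: list[dict] = field(default_factory=list)


def iterate_search(
    seed_alignment: Alignment,
    proteomes: Sequence[SequenceRecord],
    reference_proteome: Sequence[SequenceRecord],
    orthoset: set[str] | None = None,
    config: SearchConfig | None = None,
    bit_threshold: float | None = None,
    pseudocount_weight: float = 1.0,
    max_iterations: int = 10,
    seed: int = 0,
) -> IterationState:
    """Iterative HMM enrichment with reverse validation.

    Each round builds the HMM, searches the proteomes, reverse-validates
    every new hit against ``reference_proteome`` (top hit must belong to the
    accepted set), inserts validated hits along their Viterbi path, and
    rebuilds; terminates when a round adds nothing or at ``max_iterations``
    (then flagged non-converged). The accepted id set grows monotonically.
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs >= 2 rows")
    config = config or SearchConfig()
    rng = np.random.default_rng(seed)
    accepted = set(seed_alignment.ids) if orthoset is None else set(orthoset)
    accepted |= set(seed_alignment.ids)
    aln = seed_alignment
    hmm = build_hmm(aln, pseudocount_weight)
    if bit_threshold is None:
        bit_threshold = default_bit_threshold(hmm, proteomes, rng)
    log: list[dict] = []
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        hits = hmm_search(hmm, proteomes, bit_threshold)
        new = [h for h in hits if h.target_id not in accepted]
        validated = []
        by_id = {r.id: r for r in proteomes}
        for h in new:
            rec = by_id[h.target_id]
            if validate_hit(rec, reference_proteome, accepted, config, rng=rng):
                validated.append(rec)
        log.append(
            {
                "iteration": it,
                "n_hits": len(hits),
                "n_new": len(new),
                "n_validated": len(validated),
                "bit_threshold": bit_threshold,
            }
        )
        if not validated:
            converged = True
            break
        rows = list(aln.records)
        for rec in sorted(validated, key=lambda r: r.id):
            rows.append(align_to_match_states(hmm, rec))
            accepted.add(rec.id)
        # re-projected rows all have current match-state width
        width = hmm.n_match_states
        rows = [
            r if len(r.residues) == width else align_to_match_states(hmm, r.ungapped())
            for r in rows
        ]
        aln = Alignment(rows)
        hmm = build_hmm(aln, pseudocount_weight)
    return IterationState(
        alignment=aln, hmm=hmm, accepted=accepted, iteration=it,
        converged=converged, log=log,
    )
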