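"""Paralogue divergence statistics for the neofunctionalization analysis.

Distances are uncorrected p-distances with pairwise deletion (a column
counts for a pair only when both rows have a non-gap residue), converted to
percent identity as ``(1 - p) x 100``. Taxon-set comparisons report the
mean and sample standard deviation of percent identity over all cross
pairs; two comparisons are called *diverged* only when their +/-1 SD
intervals do not overlap.

The genus-balancing correction removes over-representation of congeneric
sequences from a duplicated paralogue clade before averaging: duplicated-
clade members outside the kept genus are dropped, while preduplicate
members are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import GAP, Alignment

__all__ = [
    "DistanceMatrix",
    "TaxonSet",
    "SetComparison",
    "p_distance",
    "percent_identity",
    "distance_matrix",
    "compare_sets",
    "balance_by_genus",
    "neofunctionalization_report",
    "count_complex_variants",
]


def p_distance(row_a: str, row_b: str, id_a: str = "a", id_b: str = "b") -> float:
    """Uncorrected p-distance between two aligned rows, pairwise deletion."""
    if len(row_a) != len(row_b):
        raise ValueError(
            f"rows {id_a!r} ({len(row_a)}) and {id_b!r} ({len(row_b)}) differ in length"
        )
    compared = mismatches = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError(f"no comparable columns between {id_a!r} and {id_b!r}")
    return mismatches / compared


def percent_identity(p: float) -> float:
    """Convert a p-distance to percent identity: ``(1 - p) x 100``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1]")
    return (1.0 - p) * 100.0


@dataclass
class DistanceMatrix:
    """Symmetric matrix of uncorrected p-distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("p-distances must lie in [0, 1]")
        self._index = {x: i for i, x in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def __contains__(self, x: str) -> bool:
        return x in self._index


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All pairwise p-distances of an alignment (pairwise deletion)."""
    ids = alignment.ids
    n = len(ids)
    vals = np.zeros((n, n))
    rows = [r.residues for r in alignment.records]
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(rows[i], rows[j], ids[i], ids[j])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids=list(ids), values=vals)


@dataclass(frozen=True)
class TaxonSet:
    """A named set of sequence ids (annotation labels)."""

    name: str
    members: frozenset[str]

    @classmethod
    def of(cls, name: str, members: Sequence[str]) -> "TaxonSet":
        return cls(name=name, members=frozenset(members))


@dataclass
class SetComparison:
    """Mean +/- SD percent identity over all cross pairs of two sets."""

    set_a: str
    set_b: str
    mean_pct_id: float
    sd: float | None
    n_pairs: int
    dropped: list[str] = field(default_factory=list)

    def interval(self) -> tuple[float, float]:
        s = self.sd or 0.0
        return (self.mean_pct_id - s, self.mean_pct_id + s)

    def overlaps(self, other: "SetComparison") -> bool:
        lo1, hi1 = self.interval()
        lo2, hi2 = other.interval()
        return not (hi1 < lo2 or hi2 < lo1)


def compare_sets(
    matrix: DistanceMatrix, set_a: TaxonSet, set_b: TaxonSet
) -> SetComparison:
    """Mean and sample SD of percent identities over all cross pairs.

    Ids absent from the matrix are dropped (and reported); identical-id
    pairs are excluded. Symmetric in its arguments.
    """
    dropped = sorted(
        [x for x in set_a.members | set_b.members if x not in matrix]
    )
    a = sorted(x for x in set_a.members if x in matrix)
    b = sorted(x for x in set_b.members if x in matrix)
    if not a or not b:
        raise ValueError(
            f"empty set after dropping missing ids ({set_a.name} vs {set_b.name})"
        )
    vals = [
        percent_identity(matrix.get(x, y)) for x in a for y in b if x != y
    ]
    if not vals:
        raise ValueError(f"no valid pairs between {set_a.name} and {set_b.name}")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return SetComparison(
        set_a=set_a.name, set_b=set_b.name, mean_pct_id=mean, sd=sd,
        n_pairs=len(vals), dropped=dropped,
    )


def balance_by_genus(
    taxon_set: TaxonSet,
    keep_genus: str,
    duplicated_members: frozenset[str] | set[str],
    genus_map: Mapping[str, str] | None = None,
) -> TaxonSet:
    """Drop congeneric over-representation from the duplicated clades.

    Members in ``duplicated_members`` are kept only when their genus equals
    ``keep_genus``; preduplicate members (everything else) are retained
    unchanged. The genus of a member id is taken from ``genus_map`` when
    given, else from the id's trailing genus tag (e.g. ``Bud7Scer`` ->
    ``Scer``), else from the first token of its taxon label.
    """
    def genus(member: str) -> str:
        if genus_map and member in genus_map:
            return genus_map[member]
        # annotation-label convention: family prefix + 4-letter genus tag
        return member[-4:] if len(member) > 4 else member

    kept = {
        m
        for m in taxon_set.members
        if m not in duplicated_members or genus(m) == keep_genus
    }
    return TaxonSet(name=f"{taxon_set.name}-B", members=frozenset(kept))


def neofunctionalization_report(
    matrix: DistanceMatrix,
    comparisons: Sequence[tuple[TaxonSet, TaxonSet]],
) -> list[tuple[SetComparison, SetComparison, str]]:
    """Run pairs of set comparisons and call divergence verdicts.

    ``comparisons`` is consumed two at a time (the two clades against the
    same reference set); each pair yields (comparison_1, comparison_2,
    verdict), where verdict is ``"diverged"`` only when the +/-1 SD
    intervals do not overlap, else ``"overlapping"``.
    """
    if len(comparisons) % 2 != 0:
        raise ValueError("comparisons must come in pairs")
    out = []
    for (a1, b1), (a2, b2) in zip(comparisons[::2], comparisons[1::2]):
        c1 = compare_sets(matrix, a1, b1)
        c2 = compare_sets(matrix, a2, b2)
        verdict = "overlapping" if c1.overlaps(c2) else "diverged"
        out.append((c1, c2, verdict))
    return out


def count_complex_variants(n_chaps: int) -> int:
    """Distinct heterotetramer variants: unordered pairs with repetition.

    The adaptor core binds any two family members, so with ``n`` paralogues
    there are n(n+1)/2 distinct complexes.
    """
    if n_chaps < 0:
        raise ValueError("n_chaps must be >= 0")
    return n_chaps * (n_chaps + 1) // 2
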