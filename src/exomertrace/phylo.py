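"""Desk-scale tree inference and Dollo gain-loss mapping.

Neighbor joining (Saitou-Nei) with deterministic lexical tie-breaking
serves for duplication-order and monophyly checks; bootstrap support is the
percentage of column-resampled replicates containing each internal
bipartition. Presence/absence columns are mapped onto a fixed rooted
species tree under Dollo parsimony: a single gain at the MRCA of the
present tips, and losses on the maximal absent subtrees below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np

from .divergence import DistanceMatrix, distance_matrix
from .io import Alignment, PresenceAbsenceMatrix

__all__ = [
    "GainLossMap",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "is_monophyletic",
    "duplication_order",
    "dollo_map",
    "group_presence",
]


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(matrix: DistanceMatrix, collapse_zero: bool = True) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is joined each round; ties are
    broken by the lexically smallest (id_a, id_b) pair. Negative branch
    lengths are clamped to zero (annotated ``clamped``); zero-length
    internal edges are collapsed into polytomies unless ``collapse_zero``
    is false. The result is an unrooted tree (arbitrarily displayed from
    its last join).
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 ids")
    tns = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for x in matrix.ids:
        node = dendropy.Node(taxon=tns.new_taxon(x))
        nodes[x] = node
    # working copy of distances keyed by label
    labels = sorted(matrix.ids)
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d[(a, b)] = matrix.get(a, b)

    def dist(a: str, b: str) -> float:
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    active = list(labels)
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        parent = dendropy.Node()
        counter += 1
        new_label = f"_nj{counter}"
        for child, length in ((nodes[a], la), (nodes[b], lb)):
            child.edge.length = max(0.0, length)
            if length < 0:
                child.edge.annotations.add_new("clamped", "true")
            parent.add_child(child)
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(new_label, c)] = max(0.0, dc)
        nodes[new_label] = parent
        active = sorted([c for c in active if c not in (a, b)] + [new_label])

    # terminal star join of the last three
    a, b, c = active
    root = dendropy.Node()
    for x, (y, z) in ((a, (b, c)), (b, (a, c)), (c, (a, b))):
        lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
        nodes[x].edge.length = max(0.0, lx)
        if lx < 0:
            nodes[x].edge.annotations.add_new("clamped", "true")
        root.add_child(nodes[x])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    if collapse_zero:
        _collapse_zero_internal_edges(tree)
    return tree


def _collapse_zero_internal_edges(tree: dendropy.Tree) -> None:
    for node in list(tree.postorder_internal_node_iter()):
        if node is tree.seed_node:
            continue
        if node.edge.length is not None and node.edge.length <= 0:
            parent = node.parent_node
            for child in list(node.child_nodes()):
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)


# ---------------------------------------------------------------------------
# bootstrap


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical frozensets of tip labels.

    Each internal edge splits the tips in two; the side not containing the
    alphabetically first tip is the canonical representative. Trivial
    splits (single tip or all-but-one) are excluded.
    """
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = tips[0]
    total = set(tips)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = below if ref not in below else total - below
        if 2 <= len(side) <= len(tips) - 2:
            out.add(frozenset(side))
    return out


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 100,
    seed: int = 0,
    matrix_fn: Callable[[Alignment], DistanceMatrix] = distance_matrix,
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports on edges.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate trees containing the edge's bipartition,
    attached to internal edges as the node label (and a ``support``
    annotation).
    """
    rng = np.random.default_rng(seed)
    point = nj_tree(matrix_fn(alignment))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(point)}
    ncol = alignment.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = [
            type(r)(
                id=r.id,
                residues="".join(r.residues[j] for j in cols),
                taxon=r.taxon,
                annotation=r.annotation,
            )
            for r in alignment.records
        ]
        rep_tree = nj_tree(matrix_fn(Alignment(rows)))
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    tips = sorted(leaf.taxon.label for leaf in point.leaf_node_iter())
    ref, total = tips[0], set(tips)
    for node in point.preorder_internal_node_iter():
        if node is point.seed_node:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        side = frozenset(below if ref not in below else total - below)
        if side in counts:
            support = 100.0 * counts[side] / n_replicates
            node.label = f"{support:g}"
            node.annotations.add_new("support", f"{support:g}")
            node.edge.annotations.add_new("support", f"{support:g}")
    return point


def _reroot_on_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    taxa = [clone.taxon_namespace.get_taxon(x) for x in outgroup]
    if any(t is None for t in taxa):
        missing = [x for x, t in zip(outgroup, taxa) if t is None]
        raise ValueError(f"outgroup tips not in tree: {missing}")
    if len(taxa) == 1:
        node = clone.find_node_with_taxon_label(outgroup[0])
    else:
        node = clone.mrca(taxa=taxa)
    clone.reroot_at_edge(node.edge, update_bipartitions=False)
    clone.is_rooted = True
    return clone


def is_monophyletic(
    tree: dendropy.Tree, tip_set: Sequence[str], outgroup: Sequence[str]
) -> tuple[bool, float | None]:
    """Root by the outgroup and test whether ``tip_set`` forms a clade.

    Returns (monophyletic, support of the defining edge) — support is None
    when the tree carries no bootstrap annotations on that edge.
    """
    rooted = _reroot_on_outgroup(tree, list(outgroup))
    want = set(tip_set)
    taxa = [rooted.taxon_namespace.get_taxon(x) for x in sorted(want)]
    if any(t is None for t in taxa):
        missing = sorted(x for x, t in zip(sorted(want), taxa) if t is None)
        raise ValueError(f"tips not in tree: {missing}")
    mrca = rooted.mrca(taxa=taxa)
    got = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if got != want:
        return False, None
    sup = mrca.annotations.get_value("support") if mrca.annotations else None
    if sup is None and mrca.label:
        try:
            sup = float(mrca.label)
        except ValueError:
            sup = None
    return True, float(sup) if sup is not None else None


def duplication_order(
    tree: dendropy.Tree,
    paralogue_sets: Mapping[str, Sequence[str]],
    species_of: Callable[[str], str] = lambda tip: tip.split("|")[0],
) -> list[dict]:
    """Place each paralogue clade's founding duplication against speciations.

    For each (monophyletic) paralogue clade the founding node is its MRCA's
    parent; the species represented in BOTH daughter clades of that node
    diverged after the duplication, so the most recent species divergence
    preceding it separates those from the species found on only one side.
    Non-monophyletic sets are reported as ``order undetermined``. Results
    are ordered root-ward first (by founding-node depth).
    """
    events = []
    for name in sorted(paralogue_sets):
        tips = set(paralogue_sets[name])
        taxa = [tree.taxon_namespace.get_taxon(x) for x in sorted(tips)]
        if any(t is None for t in taxa):
            events.append({"set": name, "status": "order undetermined",
                           "reason": "tips missing from tree"})
            continue
        mrca = tree.mrca(taxa=taxa)
        got = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if got != tips:
            events.append({"set": name, "status": "order undetermined",
                           "reason": "set not monophyletic"})
            continue
        founding = mrca.parent_node
        if founding is None:
            events.append({"set": name, "status": "order undetermined",
                           "reason": "clade spans the root"})
            continue
        daughters = founding.child_nodes()
        per_side = [
            {species_of(leaf.taxon.label) for leaf in ch.leaf_iter()}
            for ch in daughters
        ]
        shared = set.intersection(*per_side) if per_side else set()
        one_side = set.union(*per_side) - shared if per_side else set()
        depth = 0
        node = founding
        while node.parent_node is not None:
            depth += 1
            node = node.parent_node
        events.append({
            "set": name,
            "status": "ok",
            "depth": depth,
            "species_after_duplication": sorted(shared),
            "species_before_duplication": sorted(one_side),
        })
    return sorted(events, key=lambda e: (e.get("depth", -1), e["set"]))


# ---------------------------------------------------------------------------
# Dollo mapping


@dataclass
class GainLossMap:
    """Single-gain, multiple-loss history of one component on a species tree.

    Nodes are recorded as sorted tuples of the tip labels below them (the
    root of the gained subtree for the gain; the pruned subtree's root for
    each loss).
    """

    component: str
    gain: tuple[str, ...] | None
    losses: list[tuple[str, ...]] = field(default_factory=list)
    many_losses_flag: bool = False  # single-gain forced >= 5 losses

    @property
    def n_losses(self) -> int:
        return len(self.losses)

    def replay(self, tree: dendropy.Tree) -> dict[str, bool]:
        """Play the history forward; returns the implied presence column."""
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if self.gain is None:
            return {t: False for t in tips}
        present = set(self.gain)
        for loss in self.losses:
            present -= set(loss)
        return {t: t in present for t in tips}


def dollo_map(
    tree: dendropy.Tree, component_column: Mapping[str, bool],
    component: str = "component",
) -> GainLossMap:
    """Map one presence/absence column under Dollo parsimony.

    The gain sits at the MRCA of all present tips; each loss edge is the
    root of a maximal subtree below the gain containing no present tip.
    An all-absent column yields an empty map with no gain.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(component_column) - tips
    if unknown:
        raise ValueError(f"presence column names unknown tips: {sorted(unknown)}")
    present = {t for t in tips if component_column.get(t, False)}
    if not present:
        import warnings

        warnings.warn(f"component {component!r} absent everywhere; no gain placed",
                      stacklevel=2)
        return GainLossMap(component=component, gain=None)
    taxa = [tree.taxon_namespace.get_taxon(t) for t in sorted(present)]
    gain_node = tree.mrca(taxa=taxa) if len(taxa) > 1 else \
        tree.find_node_with_taxon_label(next(iter(present)))
    gain_tips = tuple(sorted(leaf.taxon.label for leaf in gain_node.leaf_iter()))

    losses: list[tuple[str, ...]] = []

    def walk(node: dendropy.Node) -> bool:
        """Returns True iff the subtree contains a present tip; collects
        maximal absent subtrees as losses."""
        if node.is_leaf():
            return node.taxon.label in present
        child_flags = [(ch, walk(ch)) for ch in node.child_nodes()]
        if any(flag for _, flag in child_flags):
            for ch, flag in child_flags:
                if not flag:
                    losses.append(
                        tuple(sorted(leaf.taxon.label for leaf in ch.leaf_iter()))
                    )
            return True
        return False

    walk(gain_node)
    losses.sort()
    return GainLossMap(
        component=component, gain=gain_tips, losses=losses,
        many_losses_flag=len(losses) >= 5,
    )


def group_presence(
    matrix: PresenceAbsenceMatrix,
    group_definitions: Mapping[str, Sequence[str]],
    k_min: int = 2,
) -> tuple[PresenceAbsenceMatrix, list[tuple[str, str, str]]]:
    """Collapse taxa into taxonomic groups by the k-of-group rule.

    A group is scored present for a component iff at least ``k_min`` member
    taxa are present. Single-representative cases (exactly one member
    present when ``k_min`` > 1) are returned separately as
    (group, component, taxon) exceptions rather than silently merged.
    """
    cells: dict[str, dict[str, bool]] = {}
    exceptions: list[tuple[str, str, str]] = []
    for group in group_definitions:
        members = [t for t in group_definitions[group] if t in matrix.taxa]
        cells[group] = {}
        for comp in matrix.components:
            present = [t for t in members if matrix.present(t, comp)]
            cells[group][comp] = len(present) >= k_min
            if k_min > 1 and len(present) == 1:
                exceptions.append((group, comp, present[0]))
    collapsed = PresenceAbsenceMatrix.from_dict(
        cells, taxa=list(group_definitions), components=matrix.components
    )
    return collapsed, sorted(exceptions)
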