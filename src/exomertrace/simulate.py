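"""Gene-family birth-death simulation on a fixed species tree.

Generates protein families with known ground truth: gene lineages descend
through a rooted species tree, duplicating and dying as a Poisson process
along branches, while accumulating substitutions under an equal-
exchangeability 20-letter model (per-site substitution events are Poisson
with mean equal to the branch length in substitutions/site; each event
redraws the residue from the stationary frequencies).

The neofunctionalization scenario mirrors a single ancient duplication
followed by asymmetric divergence: a forced duplication is planted on the
stem edge of a designated clade, and every lineage descending from the
accelerated daughter copy evolves with its branch lengths multiplied by
``neo_multiplier``. The truth outputs (orthogroup label per sequence, the
flagged gene tree, and the presence/absence matrix) are the recovery
targets for the orthology and divergence machinery downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .io import AMINO_ACIDS, PresenceAbsenceMatrix, SequenceRecord

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_family",
    "simulate_decoys",
    "truth_table",
    "default_species_tree",
    "DEFAULT_NEO_CLADE",
]

#: 12-taxon study tree: clade A (the duplication-bearing, yeast-like clade),
#: sister clade B, and outgroup clade C; branch lengths in subst/site.
_DEFAULT_TREE_NEWICK = (
    "(((A1:0.08,A2:0.08):0.06,(A3:0.1,A4:0.1):0.04):0.12,"
    "((B1:0.09,B2:0.09):0.07,(B3:0.11,B4:0.11):0.05):0.1,"
    "((C1:0.12,C2:0.12):0.08,(C3:0.14,C4:0.14):0.06):0.15);"
)

DEFAULT_NEO_CLADE = frozenset({"A1", "A2", "A3", "A4"})


def default_species_tree(depth_scale: float = 1.0) -> dendropy.Tree:
    """The packaged 12-taxon species tree, branch lengths scaled by
    ``depth_scale`` (1.0 gives a root-to-tip depth of ~0.26 subst/site).
    """
    from .io import read_newick

    tree = read_newick(_DEFAULT_TREE_NEWICK)
    if depth_scale != 1.0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= depth_scale
    return tree

_N_AA = len(AMINO_ACIDS)


@dataclass
class SimulationConfig:
    """Parameters of one simulated gene-family history.

    Rates are events per unit branch length (substitutions/site); the
    species tree's branch lengths set the clock. ``neo_clade`` is a set of
    tip labels whose MRCA's stem edge receives the forced founding
    duplication; ``neo_multiplier`` (>= 1) accelerates the neo daughter's
    descendants.
    """

    species_tree: dendropy.Tree
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    root_length: int = 200
    stationary_freqs: np.ndarray | None = None
    neo_clade: frozenset[str] | set[str] | None = None
    neo_multiplier: float = 1.0
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dup_rate) and self.dup_rate >= 0):
            raise ValueError("dup_rate must be finite and >= 0")
        if not (np.isfinite(self.loss_rate) and self.loss_rate >= 0):
            raise ValueError("loss_rate must be finite and >= 0")
        if self.neo_multiplier < 1:
            raise ValueError("neo_multiplier must be >= 1")
        if self.root_length < 10:
            raise ValueError("root_length must be >= 10")
        if self.stationary_freqs is None:
            self.stationary_freqs = np.full(_N_AA, 1.0 / _N_AA)
        else:
            self.stationary_freqs = np.asarray(self.stationary_freqs, float)
            if self.stationary_freqs.shape != (_N_AA,) or not np.isclose(
                self.stationary_freqs.sum(), 1.0
            ):
                raise ValueError("stationary_freqs must be 20 probabilities summing to 1")


@dataclass
class SimulatedFamily:
    """One simulated family plus its ground truth."""

    sequences: list[SequenceRecord]
    gene_tree: dendropy.Tree | None
    orthogroups: dict[str, str]  # sequence id -> paralogue-group label
    config: SimulationConfig
    extinct: bool = False
    taxa: list[str] = field(default_factory=list)

    def sequences_for(self, taxon: str) -> list[SequenceRecord]:
        return [s for s in self.sequences if s.taxon == taxon]


class _Lineage:
    __slots__ = ("seq", "label", "neo", "node")

    def __init__(self, seq: np.ndarray, label: str, neo: bool, node: dendropy.Node):
        self.seq = seq
        self.label = label
        self.neo = neo
        self.node = node


def _mutate(seq: np.ndarray, t: float, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply expected ``t`` substitutions/site; events redraw from ``freqs``."""
    if t <= 0:
        return seq.copy()
    hit = rng.poisson(t, size=seq.size) > 0
    out = seq.copy()
    n = int(hit.sum())
    if n:
        out[hit] = rng.choice(_N_AA, size=n, p=freqs)
    return out


def _stem_node_of_clade(tree: dendropy.Tree, tips: Sequence[str]) -> dendropy.Node:
    taxa = [tree.taxon_namespace.get_taxon(t) for t in tips]
    missing = [t for t, x in zip(tips, taxa) if x is None]
    if missing:
        raise ValueError(f"neo_clade tips not in species tree: {missing}")
    return tree.mrca(taxa=taxa)


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Evolve one gene family down ``config.species_tree``.

    Deterministic under a fixed seed. If every lineage is lost before
    reaching a tip, an empty family with ``extinct=True`` is returned.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.species_tree
    freqs = config.stationary_freqs
    neo_node = (
        _stem_node_of_clade(tree, sorted(config.neo_clade))
        if config.neo_clade
        else None
    )

    gene_tns = dendropy.TaxonNamespace()
    root_seq = rng.choice(_N_AA, size=config.root_length, p=freqs)
    gene_root = dendropy.Node()
    gene_root.annotations.add_new("event", "root")
    tip_records: list[SequenceRecord] = []
    orthogroups: dict[str, str] = {}
    counters: dict[str, int] = {}

    total_rate = config.dup_rate + config.loss_rate

    def evolve_branch(lin: _Lineage, length: float) -> list[_Lineage]:
        """Walk one lineage along a species-tree branch; may split or die."""
        mult = config.neo_multiplier if lin.neo else 1.0
        pos = 0.0
        active = [(lin, pos)]
        survivors: list[_Lineage] = []
        while active:
            cur, at = active.pop()
            remaining = length - at
            wait = (
                rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            )
            if wait >= remaining:
                cur.seq = _mutate(cur.seq, remaining * mult, freqs, rng)
                cur.node.edge.length = (cur.node.edge.length or 0.0) + remaining * mult
                survivors.append(cur)
                continue
            cur.seq = _mutate(cur.seq, wait * mult, freqs, rng)
            cur.node.edge.length = (cur.node.edge.length or 0.0) + wait * mult
            if rng.random() < config.dup_rate / total_rate:
                kids = []
                for suffix in ("1", "2"):
                    child = dendropy.Node()
                    child.edge.length = 0.0
                    cur.node.add_child(child)
                    kids.append(
                        _Lineage(cur.seq.copy(), f"{cur.label}.{suffix}", cur.neo, child)
                    )
                cur.node.annotations.add_new("event", "duplication")
                active.extend((k, at + wait) for k in kids)
            else:
                cur.node.annotations.add_new("event", "loss")
        return survivors

    def descend(sp_node: dendropy.Node, lineages: list[_Lineage]) -> None:
        if not lineages:
            return
        if sp_node.is_leaf():
            taxon = sp_node.taxon.label
            for lin in sorted(lineages, key=lambda l: l.label):
                counters[taxon] = counters.get(taxon, 0) + 1
                seq_id = f"{taxon}|{lin.label}|{counters[taxon]}"
                residues = "".join(AMINO_ACIDS[i] for i in lin.seq)
                tip_records.append(
                    SequenceRecord(id=seq_id, residues=residues, taxon=taxon,
                                   annotation=lin.label)
                )
                orthogroups[seq_id] = lin.label
                tx = gene_tns.new_taxon(seq_id)
                lin.node.taxon = tx
                lin.node.annotations.add_new("event", "tip")
            return
        for child in sp_node.child_nodes():
            # independent copies of each lineage enter each daughter branch
            entering = []
            for lin in lineages:
                node = dendropy.Node()
                node.edge.length = 0.0
                lin.node.add_child(node)
                entering.append(_Lineage(lin.seq.copy(), lin.label, lin.neo, node))
            if neo_node is not None and child is neo_node:
                # forced founding duplication on the clade's stem edge
                forced = []
                for lin in entering:
                    lin.node.annotations.add_new("event", "duplication")
                    for suffix, is_neo in (("bb", False), ("bc", True)):
                        sub = dendropy.Node()
                        sub.edge.length = 0.0
                        lin.node.add_child(sub)
                        forced.append(
                            _Lineage(lin.seq.copy(), f"{lin.label}.{suffix}", is_neo, sub)
                        )
                entering = forced
            out = []
            for lin in entering:
                out.extend(evolve_branch(lin, child.edge.length or 0.0))
            descend(child, out)

    root_lineage = _Lineage(root_seq, "fam", False, gene_root)
    descend(tree.seed_node, [root_lineage])

    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if not tip_records:
        warnings.warn("family went extinct before reaching any tip", stacklevel=2)
        return SimulatedFamily([], None, {}, config, extinct=True, taxa=taxa)

    gene_tree = dendropy.Tree(taxon_namespace=gene_tns, seed_node=gene_root)
    gene_tree.is_rooted = True
    _suppress_unifurcations(gene_tree)
    return SimulatedFamily(tip_records, gene_tree, orthogroups, config, taxa=taxa)


def _suppress_unifurcations(tree: dendropy.Tree) -> None:
    # drop dead-end internal nodes, then collapse pass-through nodes
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder_node_iter()):
            if node.is_leaf() and node.taxon is None and node is not tree.seed_node:
                node.parent_node.remove_child(node)
                changed = True
    tree.suppress_unifurcations()


def simulate_decoys(config: SimulationConfig, lengths: tuple[int, int] | None = None
                    ) -> list[SequenceRecord]:
    """Per-taxon unrelated decoy sequences drawn from the stationary
    frequencies, to exercise the non-redundant-hit margin rule.

    Lengths are uniform over ``lengths`` (default 0.8-1.2x the family root
    length). Deterministic under the config seed (offset so decoys are
    independent of the family draw).
    """
    rng = np.random.default_rng((config.seed + 1_000_003) % (2**31))
    freqs = config.stationary_freqs
    lo, hi = lengths or (
        max(10, int(0.8 * config.root_length)),
        int(1.2 * config.root_length),
    )
    records: list[SequenceRecord] = []
    taxa = sorted(
        leaf.taxon.label for leaf in config.species_tree.leaf_node_iter()
    )
    for taxon in taxa:
        for k in range(config.n_decoys):
            n = int(rng.integers(lo, hi + 1))
            seq = rng.choice(_N_AA, size=n, p=freqs)
            residues = "".join(AMINO_ACIDS[i] for i in seq)
            records.append(
                SequenceRecord(
                    id=f"{taxon}|decoy|{k + 1}", residues=residues,
                    taxon=taxon, annotation="decoy",
                )
            )
    return records


def truth_table(family: SimulatedFamily) -> PresenceAbsenceMatrix:
    """Presence/absence truth: one column per surviving paralogue group."""
    groups = sorted(set(family.orthogroups.values()))
    cells: dict[str, dict[str, bool]] = {t: {} for t in family.taxa}
    for seq in family.sequences:
        cells[seq.taxon][family.orthogroups[seq.id]] = True
    return PresenceAbsenceMatrix.from_dict(
        cells, taxa=family.taxa, components=groups
    )
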