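import itertools

import dendropy
import numpy as np
import pytest

from exomertrace.divergence import DistanceMatrix
from exomertrace.io import Alignment, PresenceAbsenceMatrix, SequenceRecord, read_newick
from exomertrace.phylo import (
    bipartitions,
    bootstrap_support,
    dollo_map,
    duplication_order,
    group_presence,
    is_monophyletic,
    nj_tree,
)

from conftest import random_tree


def additive_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (patristic) distances — additive by construction."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    vals = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.patristic_distance(
                    tree.taxon_namespace.get_taxon(a),
                    tree.taxon_namespace.get_taxon(b),
                )
                vals[i, j] = vals[j, i] = d
    # p-distances live in [0,1]; scale down to stay in range
    scale = max(1.0, vals.max() * 1.01)
    return DistanceMatrix(ids=labels, values=vals / scale), scale


class TestNeighborJoining:
    def test_recovers_four_taxon_tree_with_exact_lengths(self):
        # dAB=3, dAC=5, dAD=6, dBC=6, dBD=7, dCD=7
        ids = ["A", "B", "C", "D"]
        vals = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ], dtype=float)
        vals[2, 3] = vals[3, 2] = 7.0
        vals = vals / 10.0
        m = DistanceMatrix(ids=ids, values=vals)
        tree = nj_tree(m)
        assert frozenset({"A", "B"}) in bipartitions(tree) or \
            frozenset({"C", "D"}) in bipartitions(tree)
        # reconstructed path lengths reproduce the input matrix (additivity)
        pdm = tree.phylogenetic_distance_matrix()
        for a, b in itertools.combinations(ids, 2):
            d = pdm.patristic_distance(
                tree.taxon_namespace.get_taxon(a),
                tree.taxon_namespace.get_taxon(b),
            )
            assert d == pytest.approx(m.get(a, b), abs=1e-9)

    def test_three_taxon_star_with_correct_lengths(self):
        vals = np.array([[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]])
        m = DistanceMatrix(ids=["A", "B", "C"], values=vals)
        tree = nj_tree(m)
        assert len(tree.seed_node.child_nodes()) == 3
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.1)

    def test_too_few_ids(self):
        m = DistanceMatrix(ids=["A", "B"], values=np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError, match=">= 3"):
            nj_tree(m)

    def test_additive_matrices_recover_topology(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 11))
            tree = random_tree(rng, n)
            m, _scale = additive_matrix(tree)
            rebuilt = nj_tree(m)
            assert bipartitions(rebuilt) == bipartitions(tree)

    def test_permuting_input_order_gives_same_tree(self, rng):
        tree = random_tree(rng, 7)
        m, _ = additive_matrix(tree)
        perm = list(rng.permutation(len(m.ids)))
        m2 = DistanceMatrix(
            ids=[m.ids[i] for i in perm],
            values=m.values[np.ix_(perm, perm)],
        )
        assert bipartitions(nj_tree(m)) == bipartitions(nj_tree(m2))

    def test_negative_lengths_clamped(self):
        # strongly non-additive matrix can force negative NJ estimates
        vals = np.array([
            [0.0, 0.9, 0.05, 0.9],
            [0.9, 0.0, 0.9, 0.05],
            [0.05, 0.9, 0.0, 0.9],
            [0.9, 0.05, 0.9, 0.0],
        ])
        m = DistanceMatrix(ids=["A", "B", "C", "D"], values=vals)
        tree = nj_tree(m, collapse_zero=False)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0.0


class TestBootstrap:
    def _alignment(self, seqs):
        return Alignment([
            SequenceRecord(id=k, residues=v) for k, v in seqs.items()
        ])

    def test_identical_sequences_no_resolved_bipartitions(self):
        aln = self._alignment({x: "MKVWMKVW" for x in "ABCD"})
        tree = bootstrap_support(aln, n_replicates=10, seed=0)
        assert bipartitions(tree) == set()

    def test_two_clans_high_support(self, rng):
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            left = "".join(rng.choice(list("ACDE"), size=60))
            right = "".join(rng.choice(list("WYFH"), size=60))
            def noisy(base):
                out = list(base)
                for k in range(3):
                    j = int(rng.integers(len(out)))
                    out[j] = str(rng.choice(list("ACDEWYFH")))
                return "".join(out)
            aln = self._alignment({
                "L1": noisy(left), "L2": noisy(left), "L3": noisy(left),
                "R1": noisy(right), "R2": noisy(right), "R3": noisy(right),
            })
            tree = bootstrap_support(aln, n_replicates=50, seed=seed)
            split = frozenset({"R1", "R2", "R3"})
            for node in tree.preorder_internal_node_iter():
                if node is tree.seed_node:
                    continue
                below = frozenset(l.taxon.label for l in node.leaf_iter())
                if below in (split, frozenset({"L1", "L2", "L3"})):
                    sup = node.annotations.get_value("support")
                    if sup is not None and float(sup) >= 95:
                        hits += 1
                        break
        assert hits >= 0.9 * n_runs

    def test_same_seed_identical_supports(self, rng):
        rows = {
            f"s{i}": "".join(rng.choice(list("ACDEFGHIKL"), size=40))
            for i in range(6)
        }
        aln = self._alignment(rows)
        t1 = bootstrap_support(aln, n_replicates=30, seed=5)
        t2 = bootstrap_support(aln, n_replicates=30, seed=5)
        s1 = {frozenset(l.taxon.label for l in n.leaf_iter()):
              n.annotations.get_value("support")
              for n in t1.preorder_internal_node_iter() if n is not t1.seed_node}
        s2 = {frozenset(l.taxon.label for l in n.leaf_iter()):
              n.annotations.get_value("support")
              for n in t2.preorder_internal_node_iter() if n is not t2.seed_node}
        assert s1 == s2


class TestMonophyly:
    def test_clade_detected_with_outgroup_rooting(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:2);")
        tree.is_rooted = False
        mono, _ = is_monophyletic(tree, ["A", "B"], ["E"])
        assert mono
        mono2, _ = is_monophyletic(tree, ["A", "C"], ["E"])
        assert not mono2

    def test_support_reported_from_labels(self):
        tree = read_newick("((A:1,B:1)98:1,(C:1,D:1)77:1);")
        mono, support = is_monophyletic(tree, ["A", "B"], ["C", "D"])
        assert mono and support == pytest.approx(98.0)


class TestDuplicationOrder:
    def _gene_tree(self):
        # duplication after the split of species Y from (S, K): paralogue
        # clades p1 and p2 each contain S and K but Y has a single
        # pre-duplication gene
        text = ("((Y|pre|1:1,((S|p1|1:1,K|p1|1:1):1,(S|p2|1:1,K|p2|1:1):1):1)"
                ":1,O|out|1:3);")
        return read_newick(text)

    def test_species_shared_by_both_daughters(self):
        tree = self._gene_tree()
        sets = {
            "p1": ["S|p1|1", "K|p1|1"],
            "p2": ["S|p2|1", "K|p2|1"],
        }
        events = duplication_order(tree, sets)
        for ev in events:
            assert ev["status"] == "ok"
            assert ev["species_after_duplication"] == ["K", "S"]
            assert "Y" not in ev["species_after_duplication"]

    def test_non_monophyletic_set_reported_undetermined(self):
        tree = self._gene_tree()
        events = duplication_order(tree, {"bad": ["S|p1|1", "S|p2|1"]})
        assert events[0]["status"] == "order undetermined"


def presence(tree, present):
    return {l.taxon.label: (l.taxon.label in present)
            for l in tree.leaf_node_iter()}


class TestDollo:
    def test_gain_at_mrca_no_losses(self, four_tip_tree):
        gl = dollo_map(four_tip_tree, presence(four_tip_tree, {"A", "B"}))
        assert gl.gain == ("A", "B")
        assert gl.losses == [] and gl.n_losses == 0

    def test_patchy_presence_two_terminal_losses(self, four_tip_tree):
        gl = dollo_map(four_tip_tree, presence(four_tip_tree, {"A", "C"}))
        assert set(gl.gain) == {"A", "B", "C", "D"}
        assert gl.losses == [("B",), ("D",)]

    def test_all_present_no_losses(self, four_tip_tree):
        gl = dollo_map(four_tip_tree, presence(four_tip_tree, {"A", "B", "C", "D"}))
        assert set(gl.gain) == {"A", "B", "C", "D"} and gl.n_losses == 0

    def test_all_absent_warns_no_gain(self, four_tip_tree):
        with pytest.warns(UserWarning, match="absent everywhere"):
            gl = dollo_map(four_tip_tree, presence(four_tip_tree, set()))
        assert gl.gain is None and gl.replay(four_tip_tree) == {
            "A": False, "B": False, "C": False, "D": False
        }

    def test_replay_round_trip_random_columns(self, rng):
        # forward replay of gain+losses reproduces the input column
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(4, 13)))
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            col = {t: bool(rng.random() < 0.5) for t in tips}
            if not any(col.values()):
                col[tips[0]] = True
            gl = dollo_map(tree, col)
            assert gl.replay(tree) == col

    def test_loss_count_minimal_over_gain_placements(self, rng):
        # brute force: for every possible gain node, count the losses its
        # subtree forces; the MRCA placement must be minimal
        for _ in range(30):
            tree = random_tree(rng, int(rng.integers(4, 13)))
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            col = {t: bool(rng.random() < 0.6) for t in tips}
            if not any(col.values()):
                col[tips[0]] = True
            present = {t for t, v in col.items() if v}
            gl = dollo_map(tree, col)

            def losses_for_gain(node):
                below = {l.taxon.label for l in node.leaf_iter()}
                if not present <= below:
                    return None  # cannot explain tips outside the subtree
                count = [0]

                def walk(nd):
                    if nd.is_leaf():
                        return nd.taxon.label in present
                    flags = [(ch, walk(ch)) for ch in nd.child_nodes()]
                    if any(f for _, f in flags):
                        count[0] += sum(1 for _, f in flags if not f)
                        return True
                    return False

                walk(node)
                return count[0]

            candidates = [
                losses_for_gain(nd) for nd in tree.preorder_node_iter()
            ]
            feasible = [c for c in candidates if c is not None]
            assert gl.n_losses == min(feasible)

    def test_many_losses_flagged(self):
        tree = read_newick("(((((((A:1,B:1):1,C:1):1,D:1):1,E:1):1,F:1):1,G:1):1,H:1);")
        col = presence(tree, {"A", "H"})
        gl = dollo_map(tree, col)
        assert gl.n_losses >= 5 and gl.many_losses_flag


class TestGroupPresence:
    def test_k_of_group_rule_and_exceptions(self):
        matrix = PresenceAbsenceMatrix.from_dict(
            {
                "a1": {"X": True, "Y": True},
                "a2": {"X": True, "Y": False},
                "b1": {"X": False, "Y": True},
                "b2": {"X": False, "Y": False},
            },
            taxa=["a1", "a2", "b1", "b2"], components=["X", "Y"],
        )
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        collapsed, exceptions = group_presence(matrix, groups, k_min=2)
        assert collapsed.present("A", "X")
        assert not collapsed.present("A", "Y")
        assert not collapsed.present("B", "Y")
        # single-representative cases surface instead of silently merging
        assert ("A", "Y", "a1") in exceptions
        assert ("B", "Y", "b1") in exceptions
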