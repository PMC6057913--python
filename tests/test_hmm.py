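import math

import numpy as np
import pytest

from exomertrace.hmm import (
    IterationState,
    ProfileHMM,
    align_to_match_states,
    build_hmm,
    default_bit_threshold,
    forward_score,
    hmm_search,
    iterate_search,
    validate_hit,
    viterbi_path,
)
from exomertrace.io import AMINO_ACIDS, Alignment, SequenceRecord
from exomertrace.search import SearchConfig
from exomertrace.simulate import (
    SimulationConfig,
    default_species_tree,
    simulate_decoys,
    simulate_family,
)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def aln(rows):
    return Alignment([
        SequenceRecord(id=f"r{i}", residues=s) for i, s in enumerate(rows)
    ])


def forced_hmm(residue_sequence: str) -> ProfileHMM:
    """Hand-built HMM with one match state per residue and forced M-path."""
    M = len(residue_sequence)
    em = np.zeros((M + 1, 20))
    for k, ch in enumerate(residue_sequence, start=1):
        em[k, AA_INDEX[ch]] = 1.0
    ones = np.ones(M + 1)
    zeros = np.zeros(M + 1)
    return ProfileHMM(
        match_emissions=em, background=np.full(20, 0.05),
        t_mm=ones.copy(), t_mi=zeros.copy(), t_md=zeros.copy(),
        t_im=ones.copy(), t_ii=zeros.copy(),
        t_dm=ones.copy(), t_dd=zeros.copy(),
    )


def brute_force_log_odds(hmm: ProfileHMM, seq: str) -> float:
    """Exhaustive sum over all state paths; independent of the DP.

    Enumerates paths through the M/I/D lattice that consume the whole
    sequence and traverse all match/delete positions, multiplying
    transition and emission probabilities; inserts emit the background.
    Returns log2(P(seq|hmm) / P(seq|background)).
    """
    M = hmm.n_match_states
    x = [AA_INDEX[c] for c in seq]
    L = len(x)
    bg = hmm.background
    total = [0.0]

    def walk(state, k, i, prob):
        # state in {"M","I","D"}; k = model position of `state`; i = residues emitted
        if prob == 0.0:
            return
        if k == M and state in ("M", "I", "D"):
            # may exit to end
            exit_p = {"M": hmm.t_mm[M], "I": hmm.t_im[M], "D": hmm.t_dm[M]}[state]
            if i == L:
                total[0] += prob * exit_p
        # transitions onward
        if state == "M":
            trans = [("M", k + 1, hmm.t_mm[k]), ("I", k, hmm.t_mi[k]),
                     ("D", k + 1, hmm.t_md[k])]
        elif state == "I":
            trans = [("M", k + 1, hmm.t_im[k]), ("I", k, hmm.t_ii[k])]
        else:
            trans = [("M", k + 1, hmm.t_dm[k]), ("D", k + 1, hmm.t_dd[k])]
        for nstate, nk, tp in trans:
            if nk > M:
                continue
            if nstate == "M":
                if i < L:
                    walk("M", nk, i + 1, prob * tp * hmm.match_emissions[nk, x[i]])
            elif nstate == "I":
                if i < L:
                    walk("I", nk, i + 1, prob * tp * bg[x[i]])
            else:
                walk("D", nk, i, prob * tp)

    walk("M", 0, 0, 1.0)  # begin state acts as M_0
    null = float(np.prod([bg[c] for c in x]))
    return math.log2(total[0] / null)


class TestBuild:
    def test_single_row_three_match_states(self):
        hmm = build_hmm(aln(["MKV"]), pseudocount_weight=1.0)
        assert hmm.n_match_states == 3
        for k, ch in enumerate("MKV", start=1):
            assert np.argmax(hmm.match_emissions[k]) == AA_INDEX[ch]

    def test_identical_rows_small_pseudocount_indicator(self):
        hmm = build_hmm(aln(["MKV"] * 10), pseudocount_weight=1e-6)
        for k, ch in enumerate("MKV", start=1):
            assert hmm.match_emissions[k, AA_INDEX[ch]] == pytest.approx(1.0, abs=1e-5)

    def test_gap_fraction_threshold(self):
        # column 1: 6/10 gaps -> insert; column 2: 4/10 gaps -> match
        rows = ["M-V"] * 4 + ["MAV"] * 2 + ["MA-"] * 4
        # col0: 0 gaps; col1: 4/10 gaps -> match; col2: 4/10 gaps -> match
        hmm = build_hmm(aln(rows))
        assert hmm.n_match_states == 3
        rows2 = ["M-V"] * 6 + ["MAV"] * 4
        hmm2 = build_hmm(aln(rows2))  # col1 has 6/10 gaps
        assert hmm2.n_match_states == 2
        assert hmm2.match_columns == [0, 2]

    def test_all_gap_rejected(self):
        rows = ["--", "--", "AA"]  # both columns >= 2/3 gaps
        with pytest.raises(ValueError, match="zero match columns"):
            build_hmm(aln(rows))

    def test_probabilities_normalized(self):
        hmm = build_hmm(aln(["MKVW", "M-VW", "MKV-"]))
        hmm.validate()  # raises if any vector is off


class TestForward:
    def test_forced_path_closed_form(self):
        hmm = forced_hmm("A")
        assert forward_score(hmm, "A") == pytest.approx(math.log2(1 / 0.05))

    def test_forced_path_longer(self):
        hmm = forced_hmm("ACD")
        assert forward_score(hmm, "ACD") == pytest.approx(3 * math.log2(1 / 0.05))

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(12):
            m = int(rng.integers(1, 5))
            n_rows = int(rng.integers(2, 5))
            rows = [
                "".join(rng.choice(list(AMINO_ACIDS), size=m))
                for _ in range(n_rows)
            ]
            hmm = build_hmm(aln(rows))
            L = int(rng.integers(1, 6))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
            got = forward_score(hmm, seq)
            want = brute_force_log_odds(hmm, seq)
            assert got == pytest.approx(want, abs=1e-9), (rows, seq)

    def test_invariant_to_sequence_id(self):
        hmm = forced_hmm("ACDE")
        a = SequenceRecord(id="x", residues="ACDE")
        b = SequenceRecord(id="completely-different", residues="ACDE")
        assert forward_score(hmm, a) == forward_score(hmm, b)

    def test_consensus_beats_shuffled(self, rng):
        wins = 0
        n = 20
        for seed in range(n):
            cfg = SimulationConfig(
                species_tree=default_species_tree(1.0), root_length=80, seed=seed,
            )
            fam = simulate_family(cfg)
            rows = sorted(fam.sequences, key=lambda r: r.id)[:8]
            hmm = build_hmm(Alignment(rows))
            consensus = "".join(
                AMINO_ACIDS[int(np.argmax(hmm.match_emissions[k]))]
                for k in range(1, hmm.n_match_states + 1)
            )
            shuffled = "".join(
                rng.permutation(list(consensus))
            )
            if forward_score(hmm, consensus) > forward_score(hmm, shuffled):
                wins += 1
        assert wins >= 0.95 * n

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            forward_score(forced_hmm("A"), "")


class TestViterbiProjection:
    def test_exact_member_projects_onto_match_states(self):
        hmm = build_hmm(aln(["MKVW", "MKVW", "MKVW"]))
        rec = SequenceRecord(id="new", residues="MKVW")
        row = align_to_match_states(hmm, rec)
        assert row.residues == "MKVW"

    def test_deletion_becomes_gap(self):
        hmm = build_hmm(aln(["MKVW"] * 6))
        rec = SequenceRecord(id="new", residues="MKW")
        row = align_to_match_states(hmm, rec)
        assert len(row.residues) == 4
        assert row.residues.count("-") == 1


class TestSearchAndIterate:
    def _family_setup(self, depth=1.0, seed=0, n_decoys=5):
        cfg = SimulationConfig(
            species_tree=default_species_tree(depth), root_length=80,
            n_decoys=n_decoys, seed=seed,
        )
        fam = simulate_family(cfg)
        decoys = simulate_decoys(cfg)
        return fam, decoys

    def test_hmm_search_ranks_by_score(self):
        fam, decoys = self._family_setup()
        rows = sorted(fam.sequences, key=lambda r: r.id)[:6]
        hmm = build_hmm(Alignment(rows))
        hits = hmm_search(hmm, sorted(fam.sequences + decoys, key=lambda r: r.id),
                          bit_threshold=0.0)
        scores = [h.raw_score for h in hits]
        assert scores == sorted(scores, reverse=True)
        assert all(h.raw_score >= 0.0 for h in hits)

    def test_threshold_excludes_decoys(self, rng):
        fam, decoys = self._family_setup(depth=0.5)
        rows = sorted(fam.sequences, key=lambda r: r.id)
        hmm = build_hmm(Alignment(rows))
        thr = default_bit_threshold(hmm, rows, rng)
        hits = hmm_search(hmm, sorted(decoys, key=lambda r: r.id), thr)
        assert len(hits) <= 0.05 * len(decoys)

    def test_validate_hit_reverse_top(self, zero_divergence_family):
        fam, cfg = zero_divergence_family
        ref = fam.taxa[0]
        ref_proteome = sorted(
            (s for s in fam.sequences if s.taxon == ref), key=lambda r: r.id
        )
        member = next(s for s in fam.sequences if s.taxon == fam.taxa[1])
        assert validate_hit(
            member, ref_proteome, {r.id for r in ref_proteome},
            SearchConfig(null_shuffles=100), rng=np.random.default_rng(0),
        )

    def test_fixpoint_when_nothing_above_threshold(self):
        fam, _ = self._family_setup()
        rows = sorted(fam.sequences, key=lambda r: r.id)[:4]
        seed_aln = Alignment(rows)
        state = iterate_search(
            seed_aln, rows, rows, bit_threshold=1e9, max_iterations=5, seed=0,
        )
        assert state.converged
        assert state.iteration == 1
        assert state.accepted == set(seed_aln.ids)

    def test_accepted_grows_monotonically_and_deterministic(self):
        fam, decoys = self._family_setup(depth=0.5, seed=4)
        pool = sorted(fam.sequences + decoys, key=lambda r: r.id)
        ref = fam.taxa[0]
        ref_proteome = [r for r in pool if r.taxon == ref]
        seed_rows = sorted(
            (s for s in fam.sequences if s.taxon in fam.taxa[:2]),
            key=lambda r: r.id,
        )
        kw = dict(bit_threshold=10.0, max_iterations=6, seed=3)
        s1 = iterate_search(Alignment(seed_rows), pool, ref_proteome, **kw)
        s2 = iterate_search(Alignment(seed_rows), pool, ref_proteome, **kw)
        assert s1.accepted == s2.accepted
        assert set(Alignment(seed_rows).ids) <= s1.accepted
        sizes = [len(seed_rows)] + [
            len(seed_rows) + sum(e["n_validated"] for e in s1.log[:i + 1])
            for i in range(len(s1.log))
        ]
        assert sizes == sorted(sizes)

    def test_distant_member_recovered_by_iteration(self):
        # clade A+B seeds the model; the distant outgroup-clade members are
        # picked up once the enrichment loop broadens the alignment
        fam, decoys = self._family_setup(depth=1.2, seed=6, n_decoys=5)
        pool = sorted(fam.sequences + decoys, key=lambda r: r.id)
        ref = fam.taxa[0]
        ref_proteome = [r for r in pool if r.taxon == ref]
        near = sorted(
            (s for s in fam.sequences if s.taxon.startswith(("A", "B"))),
            key=lambda r: r.id,
        )
        state = iterate_search(
            Alignment(near), pool, ref_proteome,
            bit_threshold=15.0, max_iterations=8, seed=1,
        )
        distant = {s.id for s in fam.sequences if s.taxon.startswith("C")}
        assert state.converged
        assert distant & state.accepted

    def test_seed_alignment_too_small(self):
        with pytest.raises(ValueError, match=">= 2"):
            iterate_search(aln(["MKV"]), [], [], seed=0)


def test_serialization_round_trip(tmp_path):
    hmm = build_hmm(aln(["MKVW", "M-VW", "MKVA"]))
    p = tmp_path / "model.tsv"
    hmm.to_tsv(p)
    back = ProfileHMM.from_tsv(p)
    assert back.n_match_states == hmm.n_match_states
    assert np.allclose(back.match_emissions, hmm.match_emissions)
    assert np.allclose(back.t_mm, hmm.t_mm)
    assert back.match_columns == hmm.match_columns
    s = SequenceRecord(id="x", residues="MKVW")
    assert forward_score(back, s) == pytest.approx(forward_score(hmm, s))
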