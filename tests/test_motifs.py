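"""Confusion matrices, similarity, thresholds, subgroups, and motifs.

The confusion and sequence-distinguishability operations are checked
against direct summation oracles over all sequences on small ensembles.
"""

import itertools

import numpy as np
import pytest

from progspace.evaluation import ALPHABET, sequence_distribution
from progspace.motifs import (
    behavioral_similarity,
    candidate_motifs,
    canonical_rotation,
    cluster_subgroups,
    confusion_matrix,
    decompose_sequence,
    distinguishability_thresholds,
    motif_statistics,
    program_motifs,
    sequence_distinguishability,
    top_mass_codes,
    MotifSet,
)
from progspace.programs import WSLG, expand_to_size


@pytest.fixture(scope="module")
def toy_dists(m3_ensemble, params):
    progs = list(m3_ensemble)[:3]
    return progs, [sequence_distribution(p, params, 3) for p in progs]


def brute_confusion(dists):
    """Direct summation over every sequence of the ensemble support."""
    supports = [d.as_dict() for d in dists]
    seqs = set().union(*supports)
    n = len(dists)
    c = np.zeros((n, n))
    for seq in seqs:
        ps = np.array([s.get(seq, 0.0) for s in supports])
        tot = ps.sum()
        if tot > 0:
            c += np.outer(ps, ps) / tot
    return c


class TestConfusionMatrix:
    def test_single_program_diagonal_is_one(self, toy_dists):
        _, dists = toy_dists
        cm = confusion_matrix(dists[:1])
        assert np.isclose(cm.matrix[0, 0], 1.0)

    def test_columns_sum_to_one(self, m3_ensemble, params):
        dists = [
            sequence_distribution(p, params, 4) for p in list(m3_ensemble)[:12]
        ]
        cm = confusion_matrix(dists)
        assert np.allclose(cm.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_agrees_with_direct_summation(self, toy_dists):
        _, dists = toy_dists
        cm = confusion_matrix(dists)
        assert np.allclose(cm.matrix, brute_confusion(dists), atol=1e-12)

    def test_duplicated_program_shares_confusability(self, toy_dists):
        _, dists = toy_dists
        cm = confusion_matrix([dists[0], dists[0], dists[1]])
        brute = brute_confusion([dists[0], dists[0], dists[1]])
        assert np.allclose(cm.matrix, brute, atol=1e-12)
        assert np.isclose(cm.matrix[0, 0], cm.matrix[1, 0])


@pytest.fixture(scope="module")
def small_by_ell(m3_ensemble, params):
    progs = list(m3_ensemble)[:10]
    d10 = [sequence_distribution(p, params, 10) for p in progs]
    by_ell = {10: d10}
    cur = d10
    for ell in range(9, 0, -1):
        cur = [d.marginalize() for d in cur]
        by_ell[ell] = cur
    return progs, by_ell


class TestBehavioralSimilarity:
    def test_bounded_by_max_length(self, small_by_ell):
        _, by_ell = small_by_ell
        b = behavioral_similarity(by_ell)
        assert b.max() <= 10 and b.min() >= 0

    def test_merger_expansion_is_maximally_similar(self, params):
        twin = next(iter(expand_to_size(WSLG, 3)))
        d10 = [sequence_distribution(p, params, 10) for p in (WSLG, twin)]
        by_ell = {10: d10}
        cur = d10
        for ell in range(9, 0, -1):
            cur = [d.marginalize() for d in cur]
            by_ell[ell] = cur
        b = behavioral_similarity(by_ell)
        assert b[0, 1] == 10 and b[1, 0] == 10

    def test_matches_brute_force_top_n(self, small_by_ell):
        _, by_ell = small_by_ell
        b = behavioral_similarity(by_ell)
        expect = np.zeros_like(b)
        for ell, dists in by_ell.items():
            c = brute_confusion(dists)
            for i in range(len(dists)):
                n_i = int(np.round(1.0 / c[i, i]))
                others = [j for j in range(len(dists)) if j != i]
                top = sorted(others, key=lambda j: -c[i, j])[: min(n_i, len(others))]
                for j in top:
                    expect[i, j] += 1
        assert np.array_equal(b, expect)


class TestThresholdsAndSubgroups:
    def test_half_mass_threshold_property(self, m3_ensemble, params):
        dists = [sequence_distribution(p, params, 10) for p in m3_ensemble]
        sb_mask = np.zeros(len(dists), dtype=bool)
        sb_mask[:5] = True
        lab = distinguishability_thresholds(dists, sb_mask)
        vals = np.sort(lab.diag_gpn)[::-1]
        picked = lab.diag_gpn[lab.globally_distinguishable]
        assert picked.sum() >= vals.sum() / 2 - 1e-12
        assert (picked.min() >= lab.c_star_gpn) and lab.c_star_gpn > 0
        assert 0 < lab.c_star_sb <= 1.0
        assert len(lab.excluded_outliers) == 2

    def test_block_diagonal_gives_three_communities(self):
        block = np.ones((4, 4))
        c = np.zeros((12, 12))
        for k in range(3):
            c[4 * k : 4 * k + 4, 4 * k : 4 * k + 4] = block
        labels = cluster_subgroups(c, seed=0)
        assert len(np.unique(labels)) == 3

    def test_partition_invariant_to_permutation(self):
        rng = np.random.default_rng(0)
        c = np.zeros((9, 9))
        for k in range(3):
            c[3 * k : 3 * k + 3, 3 * k : 3 * k + 3] = 1.0
        perm = rng.permutation(9)
        labels = cluster_subgroups(c, seed=1)
        labels_p = cluster_subgroups(c[np.ix_(perm, perm)], seed=1)
        # same partition up to relabeling
        mapping = {}
        for orig, permuted in zip(labels[perm], labels_p):
            mapping.setdefault(orig, permuted)
            assert mapping[orig] == permuted


class TestSequenceDistinguishability:
    def test_unique_sequence_reduces_to_probability(self, toy_dists):
        _, dists = toy_dists
        vals = sequence_distinguishability(dists)
        supports = [d.as_dict() for d in dists]
        for i, d in enumerate(dists):
            for code, v in vals[i].items():
                seq = d.decode(code)
                p_i = supports[i][seq]
                assert v <= p_i + 1e-15
                if all(seq not in s for j, s in enumerate(supports) if j != i):
                    assert np.isclose(v, p_i)

    def test_agrees_with_direct_summation(self, toy_dists):
        _, dists = toy_dists
        vals = sequence_distinguishability(dists)
        supports = [d.as_dict() for d in dists]
        seqs = sorted(set().union(*supports))
        for i in range(len(dists)):
            for seq in seqs:
                p = supports[i].get(seq, 0.0)
                denom = sum(s.get(seq, 0.0) for s in supports)
                expect = p**2 / denom if denom > 0 else 0.0
                got = vals[i].get(dists[i].encode(seq), 0.0)
                assert np.isclose(got, expect, atol=1e-14)

    def test_top_mass_codes(self):
        vals = {0: 0.5, 1: 0.3, 2: 0.2}
        assert top_mass_codes(vals, 0.5) == {0}
        assert top_mass_codes(vals, 0.8) == {0, 1}
        assert top_mass_codes(vals, 1.0) == {0, 1, 2}


class TestMotifs:
    def test_rotations_of_wlw(self):
        from progspace.motifs import _rotations

        assert set(_rotations("Wlw")) == {"Wlw", "lwW", "wWl"}
        assert canonical_rotation("lwW") == canonical_rotation("Wlw")

    def test_wslg_candidates_are_win_stay_and_lose_go(self, params):
        sd = sequence_distribution(WSLG, params, 10)
        dist = sequence_distinguishability([sd])[0]
        cands = candidate_motifs(WSLG, sd, dist)
        singles = [c for c in cands if len(c) == 1]
        assert set(singles) == {"W", "l"}
        for c in cands:
            assert "L" not in c and "w" not in c

    def test_candidate_tilings_have_support(self, params):
        from progspace.motifs import _tile

        sd = sequence_distribution(WSLG, params, 10)
        dist = sequence_distinguishability([sd])[0]
        for c in candidate_motifs(WSLG, sd, dist):
            assert sd.prob(_tile(c, 10)) > 0

    def test_worked_decomposition_example(self):
        cands = ["W", "lw", "Lll", "Wlw", "LWll", "LlWl", "Lllwl"]
        out = decompose_sequence("lLWllwlLl", cands)
        assert [m for m, _ in out] == ["W", "lw", "Lll", "LWll"]
        fracs = [f for _, f in out]
        assert np.allclose(fracs, [1 / 9, 3 / 9, 2 / 9, 3 / 9])
        assert sum(fracs) <= 1.0 + 1e-12

    def test_single_tiled_motif_fully_explained(self):
        out = decompose_sequence("WlWlWlWlWl", ["Wl"])
        assert out == [("Wl", 1.0)]

    def test_decomposition_deterministic(self):
        cands = ["W", "lw", "Lll", "LWll"]
        a = decompose_sequence("lLWllwlLl", cands)
        b = decompose_sequence("lLWllwlLl", list(cands))
        assert a == b

    def test_merger_expansion_shares_motif_set(self, params):
        twin = next(iter(expand_to_size(WSLG, 3)))
        out = []
        for prog in (WSLG, twin):
            sd = sequence_distribution(prog, params, 10)
            dist = sequence_distinguishability([sd])[0]
            out.append(sorted(program_motifs(prog, sd, dist).motifs))
        assert out[0] == out[1]

    def test_motif_statistics_specificity_extremes(self):
        sets = [
            MotifSet("a", ["X"], []),
            MotifSet("b", ["X", "Y"], []),
            MotifSet("c", ["Y"], []),
            MotifSet("d", ["Y"], []),
        ]
        stats = motif_statistics(sets, np.array([0, 0, 1, 1]))
        assert stats["X"]["group"] == 0
        assert np.isclose(stats["X"]["specificity"], 1.0)
        assert np.isclose(stats["Y"]["prevalence"][1], 1.0)
        uniform = motif_statistics(
            [MotifSet(i, ["Z"], []) for i in "abcd"], np.array([0, 0, 1, 1])
        )
        assert np.isclose(uniform["Z"]["specificity"], 0.0)

    def test_pipeline_invariant_under_global_inversion(self, m3_ensemble, params):
        progs = list(m3_ensemble)[:6]
        d_a = [sequence_distribution(p, params, 6) for p in progs]
        d_b = [sequence_distribution(p.invert(), params, 6) for p in progs]
        ca, cb = confusion_matrix(d_a), confusion_matrix(d_b)
        assert np.allclose(ca.matrix, cb.matrix, atol=1e-12)
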