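"""Structural algebra: canonical forms, validity rules, minimization,
merger expansion, mutations, distances, wiring length."""

import itertools

import networkx as nx
import numpy as np
import pytest

from progspace.evaluation import reward_rate, sequence_distribution
from progspace.programs import (
    WIN_GO_LOSE_STAY,
    WSLG,
    Program,
    canonicalize,
    expand_to_size,
    minimize,
    neighbors,
    structural_distance,
    validate,
    wiring_length,
)
from tests.conftest import random_valid_programs


class TestCanonicalize:
    def test_invariant_under_swap_and_inversion(self):
        swapped = WSLG.permute((1, 0)).invert()
        assert canonicalize(WSLG) == canonicalize(swapped)

    def test_idempotent(self):
        for p in random_valid_programs(3, 10, seed=3):
            assert canonicalize(canonicalize(p)) == canonicalize(p)

    def test_m2_brute_force_count(self, params):
        ids = set()
        for tl in itertools.product(range(2), repeat=2):
            for tw in itertools.product(range(2), repeat=2):
                for labels in [(-1, 1), (1, -1), (-1, -1), (1, 1)]:
                    p = Program(labels, tl, tw)
                    if validate(p, params):
                        ids.add(p.canonical_id)
        assert len(ids) == 5


class TestValidate:
    def test_wslg_valid(self, params):
        assert validate(WSLG, params)

    def test_identity_maps_are_sink_drain(self, params):
        p = Program((-1, 1), (0, 1), (0, 1))
        v = validate(p, params)
        assert not v and v.failed_rule == "sink_drain"

    def test_duplicate_states_are_merger(self, params):
        # states 1 and 2 share label and outgoing transitions
        p = Program((-1, 1, 1), (1, 0, 0), (2, 1, 1))
        v = validate(p, params)
        assert not v and v.failed_rule == "merger"

    def test_pure_alternator_is_periodic(self, params):
        p = Program((-1, 1), (1, 0), (1, 0))
        v = validate(p, params)
        assert not v and v.failed_rule == "periodic"

    def test_exactly_one_failed_rule(self, params):
        verdicts = [
            validate(Program(lab, tl, tw), params)
            for lab in [(-1, 1)]
            for tl in itertools.product(range(2), repeat=2)
            for tw in itertools.product(range(2), repeat=2)
        ]
        for v in verdicts:
            assert v.is_valid == (v.failed_rule is None)


class TestMinimize:
    def test_wslg_already_minimal(self):
        assert minimize(WSLG) == WSLG

    def test_projection(self):
        for p in random_valid_programs(4, 10, seed=4):
            assert minimize(minimize(p)) == minimize(p)

    def test_expansion_inverts_to_wslg(self):
        for q in expand_to_size(WSLG, 3):
            assert canonicalize(minimize(q)) == canonicalize(WSLG)

    def test_minimization_preserves_sequences(self, params):
        for q in list(expand_to_size(WSLG, 3))[:3]:
            d_full = sequence_distribution(q, params, 6).as_dict()
            d_min = sequence_distribution(minimize(q), params, 6).as_dict()
            assert set(d_full) == set(d_min)
            for k in d_full:
                assert abs(d_full[k] - d_min[k]) < 1e-10


class TestExpandToSize:
    def test_expansions_preserve_reward_rate(self, params):
        base = reward_rate(WSLG, params)
        for q in expand_to_size(WSLG, 3):
            assert abs(reward_rate(q, params) - base) < 1e-10

    def test_two_step_expansion_consistency(self):
        via_one = expand_to_size(WSLG, 4)
        # every 4-state expansion minimizes to WSLG
        for q in via_one:
            assert canonicalize(minimize(q)) == canonicalize(WSLG)
        assert len(via_one) > len(expand_to_size(WSLG, 3))

    def test_cross_size_distance_via_expansion(self):
        # a 3-state expansion of WSLG is at distance 0 from none, but some
        # valid 3-state program sits one mutation from an expansion
        exp = expand_to_size(WSLG, 3)
        assert exp  # the reverse of a merger always exists for WSLG
        some = next(iter(exp))
        for q in neighbors(some):
            assert structural_distance(WSLG, q) <= 2


class TestNeighbors:
    def test_self_excluded(self):
        assert canonicalize(WSLG) not in neighbors(WSLG)

    def test_distance_one_round_trip(self):
        for p in random_valid_programs(3, 5, seed=5):
            for q in neighbors(p):
                assert structural_distance(p, q) == 1

    def test_wslg_chain_neighbor(self, m2_ensemble):
        nb_ids = {q.canonical_id for q in neighbors(WSLG)}
        # the second-best two-state program is WSLG's single mutation partner
        assert m2_ensemble[1].canonical_id in nb_ids


class TestStructuralDistance:
    def test_zero_iff_canonically_equal(self):
        assert structural_distance(WSLG, WSLG.permute((1, 0)).invert()) == 0

    def test_wslg_to_win_go_lose_stay_is_four(self):
        assert structural_distance(WSLG, WIN_GO_LOSE_STAY) == 4

    def test_agrees_with_bfs_on_m2(self, m2_ensemble):
        g = nx.Graph()
        for p in m2_ensemble:
            for q in neighbors(p):
                if q in m2_ensemble:
                    g.add_edge(p.canonical_id, q.canonical_id)
        for p, q in itertools.combinations(list(m2_ensemble), 2):
            bfs = nx.shortest_path_length(g, p.canonical_id, q.canonical_id)
            assert structural_distance(p, q) == bfs

    def test_triangle_inequality_m2(self, m2_ensemble):
        progs = list(m2_ensemble)
        for a, b, c in itertools.permutations(progs, 3):
            assert structural_distance(a, c) <= structural_distance(
                a, b
            ) + structural_distance(b, c)

    def test_symmetry(self):
        ps = random_valid_programs(3, 4, seed=6)
        for a, b in itertools.combinations(ps, 2):
            assert structural_distance(a, b) == structural_distance(b, a)


class TestWiringLength:
    def test_all_self_loops_is_zero(self):
        p = Program((-1, 1), (0, 1), (0, 1))  # fails validity; metric defined
        assert wiring_length(p) == 0

    def test_wslg_is_two(self):
        assert wiring_length(WSLG) == 2

    def test_invariant_under_canonicalization(self):
        for p in random_valid_programs(4, 8, seed=7):
            assert wiring_length(p) == wiring_length(canonicalize(p))

    def test_one_mutation_changes_by_at_most_four(self):
        for p in random_valid_programs(4, 4, seed=8):
            wl = wiring_length(p)
            for q in list(neighbors(p))[:6]:
                assert abs(wiring_length(q) - wl) <= 4
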