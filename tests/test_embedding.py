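"""Mutation graph, tree embeddings, GPN construction, smoothness."""

import numpy as np
import pytest

from progspace.embedding import (
    GPN,
    build_gpn,
    behavioral_tree,
    mutation_graph,
    performance_tree,
    smoothness_z,
    tree_to_networkx,
    write_gexf,
)
from progspace.evaluation import sequence_distribution
from progspace.motifs import behavioral_similarity
from progspace.programs import WSLG, canonicalize, structural_distance, wiring_length


@pytest.fixture(scope="module")
def m3_graph(m3_ensemble):
    return mutation_graph(m3_ensemble)


@pytest.fixture(scope="module")
def m3_tree(m3_ensemble, m3_graph):
    return performance_tree(m3_ensemble, m3_graph)


class TestMutationGraph:
    def test_every_edge_is_one_mutation(self, m3_ensemble, m3_graph):
        idx = {pid: i for i, pid in enumerate(m3_ensemble.ids)}
        for u, v in list(m3_graph.edges())[:80]:
            assert structural_distance(m3_ensemble[idx[u]], m3_ensemble[idx[v]]) == 1

    def test_m2_is_the_performance_chain(self, m2_ensemble):
        g = mutation_graph(m2_ensemble)
        ids = m2_ensemble.ids  # performance order
        assert set(g.edges()) == {
            tuple(sorted((ids[i], ids[i + 1]))) for i in range(4)
        } | set() or all(
            g.has_edge(ids[i], ids[i + 1]) for i in range(4)
        )
        assert g.number_of_edges() == 4


class TestPerformanceTree:
    def test_root_is_wslg(self, m3_tree):
        assert m3_tree.roots[0] == canonicalize(WSLG).canonical_id

    def test_edges_are_single_mutations(self, m3_ensemble, m3_tree):
        idx = {pid: i for i, pid in enumerate(m3_ensemble.ids)}
        for child, parent in list(m3_tree.parent.items())[:60]:
            if parent is None:
                continue
            assert (
                structural_distance(m3_ensemble[idx[child]], m3_ensemble[idx[parent]])
                == 1
            )

    def test_m2_tree_is_sorted_chain(self, m2_ensemble):
        tree = performance_tree(m2_ensemble)
        ids = m2_ensemble.ids
        assert tree.parent[ids[0]] is None
        for i in range(1, 5):
            assert tree.parent[ids[i]] == ids[i - 1]

    def test_deterministic_after_shuffle(self, m3_ensemble, m3_graph):
        shuffled = m3_ensemble.subset(
            np.random.default_rng(0).permutation(len(m3_ensemble))
        )
        tree_a = performance_tree(m3_ensemble, m3_graph)
        tree_b = performance_tree(shuffled, mutation_graph(shuffled))
        assert tree_a.parent == tree_b.parent

    def test_good_programs_form_few_components(self, m3_ensemble, m3_graph):
        import networkx as nx

        good_ids = [
            p.canonical_id
            for p, g in zip(m3_ensemble, m3_ensemble.flags["good"])
            if g
        ]
        comps = list(nx.connected_components(m3_graph.subgraph(good_ids)))
        largest = max(len(c) for c in comps)
        assert largest / len(good_ids) > 0.9


class TestGPN:
    def test_connected_and_counted(self, m3_ensemble, m3_graph):
        import networkx as nx

        gpn = build_gpn(m3_ensemble, m3_graph)
        assert nx.is_connected(gpn.graph)
        assert len(gpn.ensemble) == gpn.n_good + gpn.n_connection
        assert gpn.n_low_performing <= gpn.n_connection
        assert gpn.unconnected_components == 0

    def test_connection_programs_are_subthreshold(self, m3_ensemble, m3_graph):
        gpn = build_gpn(m3_ensemble, m3_graph)
        conn = gpn.ensemble.flags["connection"]
        good = gpn.ensemble.flags["good"]
        assert not np.any(conn & good)


@pytest.fixture(scope="module")
def full_gpn(m3_ensemble, m3_graph):
    """The whole evaluated M<=3 ensemble treated as one network, for a
    richer behavioral embedding than the tiny true GPN."""
    ens = m3_ensemble
    return GPN(
        ensemble=ens,
        graph=m3_graph,
        n_good=int(ens.flags["good"].sum()),
        n_connection=0,
        n_low_performing=int(ens.flags["low_performing"].sum()),
    )


@pytest.fixture(scope="module")
def similarity(m3_ensemble, params):
    dist10 = [sequence_distribution(p, params, 10) for p in m3_ensemble]
    by_ell = {10: dist10}
    cur = dist10
    for ell in range(9, 0, -1):
        cur = [d.marginalize() for d in cur]
        by_ell[ell] = cur
    return behavioral_similarity(by_ell, m3_ensemble.ids)


class TestBehavioralTree:
    def test_edge_kinds_partition_by_similarity(self, full_gpn, similarity):
        tree = behavioral_tree(full_gpn, similarity)
        idx = {pid: i for i, pid in enumerate(full_gpn.ensemble.ids)}
        for child, parent in tree.parent.items():
            if parent is None:
                continue
            b = similarity[idx[parent], idx[child]]
            kind = tree.edge_kind[child]
            assert (kind == "sloppy") == (b == 10)

    def test_constant_similarity_reduces_to_performance_rule(
        self, full_gpn, m3_ensemble
    ):
        const = np.ones((len(m3_ensemble), len(m3_ensemble)))
        tree_b = behavioral_tree(full_gpn, const)
        tree_p = performance_tree(m3_ensemble, full_gpn.graph)
        assert tree_b.parent == tree_p.parent


class TestSmoothness:
    def test_zero_for_constant_attribute(self, m3_tree, m3_ensemble):
        z = smoothness_z(m3_tree, {pid: 1.0 for pid in m3_ensemble.ids})
        assert all(v == 0.0 for v in z.values())

    def test_shift_invariance(self, m3_tree, m3_ensemble):
        attr = {
            pid: float(r)
            for pid, r in zip(m3_ensemble.ids, m3_ensemble.reward_rates)
        }
        z1 = smoothness_z(m3_tree, attr)
        z2 = smoothness_z(m3_tree, {k: v + 5.0 for k, v in attr.items()})
        assert np.isclose(sum(z1.values()), sum(z2.values()))

    def test_performance_embedding_smoother_than_wiring(
        self, m3_tree, m3_ensemble
    ):
        perf = {
            pid: float(r)
            for pid, r in zip(m3_ensemble.ids, m3_ensemble.reward_rates)
        }
        wl = {p.canonical_id: float(wiring_length(p)) for p in m3_ensemble}
        z_perf = np.array(list(smoothness_z(m3_tree, perf).values()))
        z_wl = np.array(list(smoothness_z(m3_tree, wl).values()))
        assert np.var(z_perf) < np.var(z_wl)


def test_gexf_round_trip(tmp_path, m3_ensemble, m3_tree):
    import networkx as nx

    path = tmp_path / "tree.gexf"
    write_gexf(m3_tree, path)
    g = nx.read_gexf(path)
    assert g.number_of_nodes() == len(m3_ensemble)
    d = tree_to_networkx(m3_tree)
    assert g.number_of_edges() == d.number_of_edges()
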