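"""Tree embeddings over the mutation graph and the good program network.

Programs are related by single algorithmic mutations (one relabeled state
or one redirected transition; across sizes, one mutation applied to a
merger expansion of the smaller program).  The embeddings here compress
that mutation graph to a tree that exposes how structure relates to
performance or behavior:

* ``performance_tree`` — children attach to the smallest, then
  highest-performing parent within one mutation; the root is WSLG.
* ``build_gpn`` — the good programs plus a greedy minimal set of
  subthreshold "connection" programs that stitch them into a single
  mutation-connected component (the good program network).
* ``behavioral_tree`` — children attach to the most behaviorally
  similar, then highest-performing parent; edges at maximal similarity
  are "sloppy" mutations, the rest are "key" mutations that change the
  behavioral repertoire.

Trees are deterministic given the canonical ensemble order; ties beyond
the stated criteria break by canonical id.  Export to GEXF carries all
node and edge attributes for external layout; no layout is computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enumeration import Ensemble
from .programs import Program, expand_to_size, neighbors
from .task import TaskParams

__all__ = [
    "TreeEmbedding",
    "GPN",
    "mutation_graph",
    "performance_tree",
    "build_gpn",
    "behavioral_tree",
    "smoothness_z",
    "tree_to_networkx",
    "write_gexf",
]


def mutation_graph(ensemble: Ensemble, params: TaskParams | None = None) -> nx.Graph:
    """Undirected graph over ensemble members with edges at structural
    distance 1, including cross-size edges through merger expansions."""
    params = params or ensemble.params
    g = nx.Graph()
    ids = set(ensemble.ids)
    g.add_nodes_from(ensemble.ids)
    max_size = max((p.size for p in ensemble), default=0)
    for p in ensemble:
        pid = p.canonical_id
        partners: set[str] = set()
        for q in neighbors(p, params):
            partners.add(q.canonical_id)
        if p.size + 1 <= max_size:
            for e in expand_to_size(p, p.size + 1):
                for q in neighbors(e, params):
                    partners.add(q.canonical_id)
        partners.discard(pid)
        for qid in partners & ids:
            g.add_edge(pid, qid)
    return g


@dataclass
class TreeEmbedding:
    """Parent map over an ensemble; every edge is one structural mutation.

    ``roots`` lists the primary root (WSLG in the canonical builds)
    followed by any programs that could not be attached; ``edge_kind``
    holds key/sloppy labels for behavioral trees.
    """

    ensemble: Ensemble
    parent: dict[str, str | None]
    roots: list[str]
    edge_kind: dict[str, str] = field(default_factory=dict)  # child id -> key|sloppy
    node_attrs: dict[str, dict] = field(default_factory=dict)

    @property
    def n_unattached(self) -> int:
        return len(self.roots) - 1

    def children(self, pid: str) -> list[str]:
        return [c for c, par in self.parent.items() if par == pid]

    def edges(self) -> list[tuple[str, str]]:
        return [(par, c) for c, par in self.parent.items() if par is not None]


def _attach(
    ensemble: Ensemble,
    graph: nx.Graph,
    preference,
) -> TreeEmbedding:
    """Shared attachment loop: walk the sorted ensemble, linking each
    program to the best already-placed candidate within one mutation."""
    if ensemble.reward_rates is None:
        raise ValueError("ensemble must be evaluated before embedding")
    order = ensemble.ids
    placed: set[str] = set()
    parent: dict[str, str | None] = {}
    roots: list[str] = []
    for pid in order:
        cands = [c for c in graph.neighbors(pid) if c in placed] if pid in graph else []
        if not cands:
            parent[pid] = None
            roots.append(pid)
        else:
            parent[pid] = min(cands, key=lambda c: preference(c, pid))
        placed.add(pid)
    return TreeEmbedding(ensemble=ensemble, parent=parent, roots=roots)


def performance_tree(
    ensemble: Ensemble, graph: nx.Graph | None = None
) -> TreeEmbedding:
    """Tree embedding by performance: each child attaches to the smallest,
    then highest-performing, placed program within a single mutation."""
    ensemble.sort()
    graph = graph if graph is not None else mutation_graph(ensemble)

    def pref(cand: str, _child: str):
        i = ensemble.index_of(cand)
        return (ensemble[i].size, -ensemble.reward_rates[i], cand)

    return _attach(ensemble, graph, pref)


@dataclass
class GPN:
    """The good program network: good programs plus connection programs.

    ``ensemble`` holds the members with flags good / connection /
    low_performing; ``graph`` is the mutation graph restricted to members
    (connected by construction when connection succeeds).
    """

    ensemble: Ensemble
    graph: nx.Graph
    n_good: int
    n_connection: int
    n_low_performing: int
    unconnected_components: int = 0


def build_gpn(ensemble: Ensemble, graph: nx.Graph | None = None) -> GPN:
    """Augment the good set with a minimal greedy set of subthreshold
    connectors until one mutation-connected component remains.

    Repeatedly adds the highest-performing non-member that merges at
    least two current components; when no single program bridges, the
    shortest bridging path through the full mutation graph is added.  The
    selection rule is a reconstruction (the reference procedure is not
    fully specified) and is isolated here so alternates can be swapped in.
    """
    if ensemble.reward_rates is None or "good" not in ensemble.flags:
        raise ValueError("ensemble must be evaluated (good flags) first")
    ensemble.sort()
    graph = graph if graph is not None else mutation_graph(ensemble)
    good_ids = [
        p.canonical_id for p, g in zip(ensemble, ensemble.flags["good"]) if g
    ]
    members = set(good_ids)
    rate = {
        p.canonical_id: float(r) for p, r in zip(ensemble, ensemble.reward_rates)
    }

    def components() -> list[set[str]]:
        return [set(c) for c in nx.connected_components(graph.subgraph(members))]

    comps = components()
    while len(comps) > 1:
        comp_of = {}
        for k, c in enumerate(comps):
            for pid in c:
                comp_of[pid] = k
        # single-program bridges first
        best = None
        for pid in graph.nodes:
            if pid in members:
                continue
            touched = {comp_of[q] for q in graph.neighbors(pid) if q in comp_of}
            if len(touched) >= 2:
                key = (-rate[pid], pid)
                if best is None or key < best[0]:
                    best = (key, pid)
        if best is not None:
            members.add(best[1])
        else:
            # multi-hop: shortest path between two components through
            # non-members, preferring high-performing interior nodes
            path = _shortest_bridge(graph, comps, rate)
            if path is None:
                break  # cannot connect; report remaining components
            members.update(path)
        comps = components()

    mask = np.array([pid in members for pid in ensemble.ids])
    sub = ensemble.subset(mask)
    goodset = set(good_ids)
    good_flag = np.array([pid in goodset for pid in sub.ids])
    conn_flag = ~good_flag
    low_flag = sub.flags["low_performing"] & conn_flag
    sub.flags["good"] = good_flag
    sub.flags["connection"] = conn_flag
    sub.flags["low_performing"] = low_flag
    return GPN(
        ensemble=sub,
        graph=graph.subgraph(sub.ids).copy(),
        n_good=int(good_flag.sum()),
        n_connection=int(conn_flag.sum()),
        n_low_performing=int(low_flag.sum()),
        unconnected_components=max(0, len(comps) - 1),
    )


def _shortest_bridge(graph: nx.Graph, comps: list[set[str]], rate: dict):
    base = comps[0]
    other = set().union(*comps[1:])
    try:
        # uniform edge weight: fewest added programs
        paths = nx.multi_source_dijkstra_path(graph, base)
    except nx.NetworkXNoPath:
        return None
    best = None
    for tgt in other:
        if tgt not in paths:
            continue
        interior = [p for p in paths[tgt] if p not in base and p != tgt]
        key = (len(interior), -min((rate[p] for p in interior), default=0.0))
        if best is None or key < best[0]:
            best = (key, interior)
    return best[1] if best is not None else None


def behavioral_tree(
    gpn: GPN,
    similarity: np.ndarray,
    b_max: int = 10,
    graph: nx.Graph | None = None,
) -> TreeEmbedding:
    """Tree embedding by behavior over the GPN.

    ``similarity`` is the total behavioral similarity matrix B (rows =
    candidate parents, columns = children) indexed like the GPN ensemble.
    Children attach to the most behaviorally similar, then
    highest-performing placed parent of size <= their own within one
    mutation.  Edges with B < ``b_max`` are key mutations; edges at
    ``b_max`` are sloppy.
    """
    ens = gpn.ensemble
    ens.sort()
    graph = graph if graph is not None else gpn.graph
    idx = {pid: i for i, pid in enumerate(ens.ids)}

    def pref(cand: str, child: str):
        i, j = idx[cand], idx[child]
        return (-similarity[i, j], ens[i].size, -ens.reward_rates[i], cand)

    # restrict candidate parents to size <= child size
    restricted = nx.Graph()
    restricted.add_nodes_from(graph.nodes)
    sizes = {pid: ens[idx[pid]].size for pid in ens.ids}
    restricted.add_edges_from(graph.edges)
    tree = _attach_sized(ens, restricted, pref, sizes)
    for child, par in tree.parent.items():
        if par is None:
            continue
        b = similarity[idx[par], idx[child]]
        tree.edge_kind[child] = "sloppy" if b >= b_max else "key"
    return tree


def _attach_sized(ensemble, graph, preference, sizes):
    placed: set[str] = set()
    parent: dict[str, str | None] = {}
    roots: list[str] = []
    for pid in ensemble.ids:
        cands = [
            c
            for c in (graph.neighbors(pid) if pid in graph else [])
            if c in placed and sizes[c] <= sizes[pid]
        ]
        if not cands:
            parent[pid] = None
            roots.append(pid)
        else:
            parent[pid] = min(cands, key=lambda c: preference(c, pid))
        placed.add(pid)
    return TreeEmbedding(ensemble=ensemble, parent=parent, roots=roots)


def smoothness_z(tree: TreeEmbedding, attribute: dict[str, float]) -> dict[str, float]:
    """Per-node embedding smoothness: the parent-child attribute change in
    units of the ensemble-wide standard deviation.  Roots carry no score."""
    vals = np.array([attribute[pid] for pid in tree.ensemble.ids], dtype=float)
    std = float(vals.std())
    if std == 0.0:
        std = 1.0
    out: dict[str, float] = {}
    for child, par in tree.parent.items():
        if par is None:
            continue
        out[child] = (attribute[child] - attribute[par]) / std
    return out


def tree_to_networkx(tree: TreeEmbedding) -> nx.DiGraph:
    """Directed parent -> child graph with node and edge attributes."""
    ens = tree.ensemble
    g = nx.DiGraph()
    for i, pid in enumerate(ens.ids):
        attrs = {
            "size": int(ens[i].size),
            "reward_rate": float(ens.reward_rates[i])
            if ens.reward_rates is not None
            else float("nan"),
        }
        for name, arr in ens.flags.items():
            attrs[name] = bool(arr[i])
        attrs.update(tree.node_attrs.get(pid, {}))
        g.add_node(pid, **attrs)
    for child, par in tree.parent.items():
        if par is None:
            continue
        g.add_edge(par, child, kind=tree.edge_kind.get(child, "mutation"))
    return g


def write_gexf(tree: TreeEmbedding, path) -> None:
    """Export a tree with its attributes as GEXF for external layout."""
    nx.write_gexf(tree_to_networkx(tree), path)
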