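"""Deterministic behavioral programs and their structural algebra.

A program is a deterministic Moore machine: ``M`` internal states, each
labeled by an action in {-1, +1}, and for each outcome o in {-1, +1} a
total transition map states -> states.  A program is a generative model of
trial-by-trial behavior: the current state emits its action, the world
returns an outcome, and the outcome selects the next state.

Two programs are "the same" when they coincide up to a relabeling of
states combined, optionally, with a global inversion of actions (the task
is symmetric under exchanging the two ports).  ``canonicalize`` computes a
unique representative over those symmetries; the five rule-out rules that
define a *valid* program (no sinks/drains, aperiodic occupancy, no merger
states, no permutation/inversion duplicates) live in ``validate`` and the
enumeration pipeline.

Structural edits — relabeling one state or redirecting one transition —
are the "mutations" that organize the program space; ``neighbors``,
``structural_distance`` and ``expand_to_size`` (reverse merger-state
splitting) implement that geometry.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .task import DEFAULT_PARAMS, PM, TaskParams, outcome_probability

__all__ = [
    "Program",
    "ValidityVerdict",
    "WSLG",
    "WIN_GO_LOSE_STAY",
    "canonicalize",
    "validate",
    "minimize",
    "expand_to_size",
    "neighbors",
    "structural_distance",
    "wiring_length",
]


@dataclass(frozen=True)
class Program:
    """A deterministic finite-state behavioral program.

    Attributes
    ----------
    labels : tuple of int
        Action (+-1) emitted by each state; length M.
    t_lose, t_win : tuple of int
        Transition targets per state for outcome o = -1 (loss) and
        o = +1 (win); 0-based state indices.
    """

    labels: tuple[int, ...]
    t_lose: tuple[int, ...]
    t_win: tuple[int, ...]

    def __post_init__(self) -> None:
        m = len(self.labels)
        if m < 1:
            raise ValueError("a program needs at least one state")
        if len(self.t_lose) != m or len(self.t_win) != m:
            raise ValueError("transition maps must cover every state exactly once")
        if any(l not in (-1, 1) for l in self.labels):
            raise ValueError("state labels must be -1 or +1")
        for t in (self.t_lose, self.t_win):
            if any(not (0 <= x < m) for x in t):
                raise ValueError("transition target out of range")

    @property
    def size(self) -> int:
        return len(self.labels)

    def transition(self, state: int, outcome: int) -> int:
        return self.t_win[state] if outcome == +1 else self.t_lose[state]

    @property
    def canonical_id(self) -> str:
        return _canonical_key(self.labels, self.t_lose, self.t_win)[1]

    def invert(self) -> "Program":
        """Globally exchange the two actions (port symmetry)."""
        return Program(
            tuple(-l for l in self.labels), self.t_lose, self.t_win
        )

    def permute(self, perm: tuple[int, ...]) -> "Program":
        """Relabel states: state i becomes perm[i]."""
        m = self.size
        inv = [0] * m
        for i, pi in enumerate(perm):
            inv[pi] = i
        return Program(
            tuple(self.labels[inv[j]] for j in range(m)),
            tuple(perm[self.t_lose[inv[j]]] for j in range(m)),
            tuple(perm[self.t_win[inv[j]]] for j in range(m)),
        )

    def to_record(self) -> dict:
        return {
            "M": self.size,
            "labels": list(self.labels),
            "t_lose": list(self.t_lose),
            "t_win": list(self.t_win),
            "id": self.canonical_id,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Program":
        p = cls(
            tuple(int(x) for x in rec["labels"]),
            tuple(int(x) for x in rec["t_lose"]),
            tuple(int(x) for x in rec["t_win"]),
        )
        return p

    def __repr__(self) -> str:  # compact, e.g. P[-+|10|01] for WSLG
        lab = "".join("+" if l > 0 else "-" for l in self.labels)
        tl = "".join(str(x) for x in self.t_lose)
        tw = "".join(str(x) for x in self.t_win)
        return f"P[{lab}|{tl}|{tw}]"


#: Win-stay, lose-go: repeat the action after a reward, switch after an
#: omission.  The benchmark program that defines "good" performance.
WSLG = Program((-1, 1), (1, 0), (0, 1))

#: Its performance-reversed cousin: switch after a reward, repeat after a loss.
WIN_GO_LOSE_STAY = Program((-1, 1), (0, 1), (1, 0))


@dataclass(frozen=True)
class ValidityVerdict:
    """Outcome of the rule-out checks; exactly one failed rule when invalid."""

    is_valid: bool
    failed_rule: str | None = None  # sink_drain | periodic | merger | duplicate
    detail: str = ""

    def __bool__(self) -> bool:
        return self.is_valid


# ---------------------------------------------------------------------------
# canonical form


@lru_cache(maxsize=None)
def _perms(m: int) -> tuple[tuple[int, ...], ...]:
    return tuple(itertools.permutations(range(m)))


def _apply(labels, t_lose, t_win, perm, inv):
    m = len(labels)
    inv_perm = [0] * m
    for i, pi in enumerate(perm):
        inv_perm[pi] = i
    sign = -1 if inv else 1
    lab = tuple(sign * labels[inv_perm[j]] for j in range(m))
    tl = tuple(perm[t_lose[inv_perm[j]]] for j in range(m))
    tw = tuple(perm[t_win[inv_perm[j]]] for j in range(m))
    return lab, tl, tw


def _encode(lab, tl, tw) -> str:
    return (
        "".join("+" if l > 0 else "-" for l in lab)
        + ":"
        + "".join(str(x) for x in tl)
        + ":"
        + "".join(str(x) for x in tw)
    )


@lru_cache(maxsize=1_000_000)
def _canonical_key(labels, t_lose, t_win):
    """Lexicographically minimal (labels, t_lose, t_win) over all state
    permutations x {identity, global action inversion}; returns the minimal
    triple and its string id."""
    best = None
    for perm in _perms(len(labels)):
        for inv in (False, True):
            cand = _apply(labels, t_lose, t_win, perm, inv)
            if best is None or cand < best:
                best = cand
    return best, _encode(*best)


def canonicalize(p: Program) -> Program:
    """Canonical representative of ``p`` under state permutation and
    global action inversion.  Idempotent; two programs are identical
    (rules 1 and 4) iff their canonical forms coincide."""
    (lab, tl, tw), _ = _canonical_key(p.labels, p.t_lose, p.t_win)
    return Program(lab, tl, tw)


# ---------------------------------------------------------------------------
# graph utilities (strong connectivity, period) on the tiny program graphs


def _union_adjacency(p: Program) -> list[set[int]]:
    return [{p.t_lose[m], p.t_win[m]} for m in range(p.size)]


def _strongly_connected(adj: list[set[int]]) -> bool:
    n = len(adj)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) < n:
        return False
    radj = [set() for _ in range(n)]
    for u in range(n):
        for v in adj[u]:
            radj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in radj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


def _period(adj: list[set[int]]) -> int:
    """Period (gcd of cycle lengths) of a strongly connected digraph via
    BFS levels: g = gcd over edges (u, v) of level(u) + 1 - level(v)."""
    n = len(adj)
    level = [-1] * n
    level[0] = 0
    queue = [0]
    g = 0
    while queue:
        nxt = []
        for u in queue:
            for v in adj[u]:
                if level[v] < 0:
                    level[v] = level[u] + 1
                    nxt.append(v)
                else:
                    g = math.gcd(g, level[u] + 1 - level[v])
        queue = nxt
    # A second pass catches tree edges whose defect was recorded before the
    # child level was final; with BFS levels this single pass is sufficient
    # for the gcd, but recompute defects once for safety.
    for u in range(n):
        for v in adj[u]:
            g = math.gcd(g, level[u] + 1 - level[v])
    return abs(g) if g != 0 else 0


def _joint_support_adjacency(p: Program, params: TaskParams) -> list[set[int]]:
    """Support digraph of the joint (world state, program state) chain.

    Node index = s_idx * M + m with s_idx 0 for s=-1, 1 for s=+1.  An edge
    exists when the corresponding world transition and outcome both have
    positive probability.  The occupancy of this chain is what must
    converge for a program to be evaluable (rule 3).
    """
    m_states = p.size
    h = params.hazard
    adj: list[set[int]] = [set() for _ in range(2 * m_states)]
    for si, s in enumerate(PM):
        for m in range(m_states):
            a = p.labels[m]
            for o in PM:
                if outcome_probability(params, s, a, o) <= 0.0:
                    continue
                m2 = p.transition(m, o)
                for sj, s2 in enumerate(PM):
                    w = 1.0 - h if s2 == s else h
                    if w > 0.0:
                        adj[si * m_states + m].add(sj * m_states + m2)
    return adj


# ---------------------------------------------------------------------------
# minimization (merger states) and validation


def _partition_refinement(p: Program) -> list[int]:
    """Coarsest behavior-preserving partition (Moore minimization).

    Initial blocks by action label; refine by the blocks of the two
    outcome successors until stable.  Returns block index per state.
    """
    m = p.size
    block = [0 if p.labels[i] < 0 else 1 for i in range(m)]
    # normalize block ids
    while True:
        sigs = [
            (block[i], block[p.t_lose[i]], block[p.t_win[i]]) for i in range(m)
        ]
        mapping: dict[tuple, int] = {}
        new_block = []
        for sig in sigs:
            if sig not in mapping:
                mapping[sig] = len(mapping)
            new_block.append(mapping[sig])
        if new_block == block:
            return block
        block = new_block


def minimize(p: Program) -> Program:
    """Smallest program generating identical outcome-conditioned action
    sequences (merger states combined)."""
    block = _partition_refinement(p)
    n_blocks = max(block) + 1
    if n_blocks == p.size:
        return p
    rep = [None] * n_blocks
    for i, b in enumerate(block):
        if rep[b] is None:
            rep[b] = i
    labels = tuple(p.labels[rep[b]] for b in range(n_blocks))
    t_lose = tuple(block[p.t_lose[rep[b]]] for b in range(n_blocks))
    t_win = tuple(block[p.t_win[rep[b]]] for b in range(n_blocks))
    return Program(labels, t_lose, t_win)


def validate(p: Program, params: TaskParams = DEFAULT_PARAMS) -> ValidityVerdict:
    """Apply the structural rule-out rules to a single program.

    Checks, in order: sinks/drains (the union digraph over both outcome
    maps must be one strongly connected component), merger states (the
    program must be minimal), and periodicity (the joint (s, m) occupancy
    chain under ``params`` must be aperiodic).
    """
    if not _strongly_connected(_union_adjacency(p)):
        return ValidityVerdict(False, "sink_drain", "union digraph not strongly connected")
    block = _partition_refinement(p)
    if max(block) + 1 < p.size:
        return ValidityVerdict(
            False, "merger", f"minimizes to {max(block) + 1} states"
        )
    adj = _joint_support_adjacency(p, params)
    if not _strongly_connected(adj):
        return ValidityVerdict(
            False, "sink_drain", "joint (s, m) support chain not irreducible"
        )
    if _period(adj) != 1:
        return ValidityVerdict(
            False, "periodic", f"joint chain period {_period(adj)}"
        )
    return ValidityVerdict(True)


# ---------------------------------------------------------------------------
# merger expansion (rule 5 in reverse)


def _split_state(p: Program, m: int):
    """All ways to split state ``m`` into two copies with identical labels
    and out-behavior, distributing its in-edges between the copies.

    The new copy gets index M.  Out-transitions of both copies must land in
    the same merged class, so they equal the original target except where
    the original target was ``m`` itself, in which case either copy is
    allowed.  Yields raw (uncanonicalized) programs; callers filter by
    strong connectivity and behavioral equivalence.
    """
    m_states = p.size
    new = m_states
    in_edges = []  # (source state, outcome) excluding self-loops
    for src in range(m_states):
        for o, tmap in ((-1, p.t_lose), (+1, p.t_win)):
            if tmap[src] == m and src != m:
                in_edges.append((src, o))
    self_loops = [o for o, tmap in ((-1, p.t_lose), (+1, p.t_win)) if tmap[m] == m]

    labels = p.labels + (p.labels[m],)
    base_tl = list(p.t_lose) + [p.t_lose[m]]
    base_tw = list(p.t_win) + [p.t_win[m]]

    n_in = len(in_edges)
    n_self = len(self_loops)
    for in_assign in itertools.product((0, 1), repeat=n_in):
        for self_assign in itertools.product((0, 1), repeat=2 * n_self):
            tl = base_tl[:]
            tw = base_tw[:]
            for (src, o), bit in zip(in_edges, in_assign):
                tgt = new if bit else m
                (tl if o == -1 else tw)[src] = tgt
            for k, o in enumerate(self_loops):
                t_from_old = new if self_assign[2 * k] else m
                t_from_new = new if self_assign[2 * k + 1] else m
                if o == -1:
                    tl[m] = t_from_old
                    tl[new] = t_from_new
                else:
                    tw[m] = t_from_old
                    tw[new] = t_from_new
            yield Program(labels, tuple(tl), tuple(tw))


def expand_to_size(p: Program, m_target: int) -> set[Program]:
    """All canonical programs of ``m_target`` states that are merger
    expansions of ``p``: every returned program minimizes back to ``p``
    (up to canonical form) and therefore generates identical behavior.

    May be empty (splitting can fail to keep the union digraph strongly
    connected in every arrangement).
    """
    if m_target <= p.size:
        raise ValueError("m_target must exceed the program size")
    target_id = canonicalize(minimize(p)).canonical_id
    frontier = {canonicalize(p)}
    for _ in range(m_target - p.size):
        grown: set[Program] = set()
        for q in frontier:
            for m in range(q.size):
                for cand in _split_state(q, m):
                    if not _strongly_connected(_union_adjacency(cand)):
                        continue
                    if canonicalize(minimize(cand)).canonical_id != target_id:
                        continue
                    grown.add(canonicalize(cand))
        frontier = grown
    return frontier


# ---------------------------------------------------------------------------
# mutations and distances


def _raw_single_edits(p: Program):
    """All programs one structural edit away: flip one label or redirect
    one transition (self included never yielded)."""
    m = p.size
    for i in range(m):
        lab = list(p.labels)
        lab[i] = -lab[i]
        yield Program(tuple(lab), p.t_lose, p.t_win)
    for i in range(m):
        for o, tmap in ((-1, p.t_lose), (+1, p.t_win)):
            for tgt in range(m):
                if tgt == tmap[i]:
                    continue
                t = list(tmap)
                t[i] = tgt
                if o == -1:
                    yield Program(p.labels, tuple(t), p.t_win)
                else:
                    yield Program(p.labels, p.t_lose, tuple(t))


def neighbors(p: Program, params: TaskParams = DEFAULT_PARAMS) -> set[Program]:
    """Valid canonical programs exactly one mutation from ``p`` (same size)."""
    self_id = canonicalize(p).canonical_id
    out: set[Program] = set()
    for cand in _raw_single_edits(p):
        c = canonicalize(cand)
        if c.canonical_id == self_id:
            continue
        if c in out:
            continue
        if validate(c, params):
            out.add(c)
    return out


def _min_hamming(p: Program, q: Program) -> int:
    """Minimal edit mismatch between equal-size programs over the
    permutation x inversion symmetry group."""
    best = math.inf
    for perm in _perms(p.size):
        for inv in (False, True):
            lab, tl, tw = _apply(p.labels, p.t_lose, p.t_win, perm, inv)
            d = 0
            for x, y in zip(lab, q.labels):
                if x != y:
                    d += 1
            for x, y in zip(tl, q.t_lose):
                if x != y:
                    d += 1
            for x, y in zip(tw, q.t_win):
                if x != y:
                    d += 1
            if d < best:
                best = d
                if best == 0:
                    return 0
    return int(best)


def structural_distance(p: Program, q: Program) -> float:
    """Minimal number of single mutations relating two programs.

    Equal sizes: minimum mismatch over state permutations and global
    inversion.  Different sizes: the smaller program is expanded through
    merger splits to the larger size and the minimum over expansions is
    taken; ``math.inf`` if no expansion exists.
    """
    if p.size == q.size:
        return _min_hamming(p, q)
    small, large = (p, q) if p.size < q.size else (q, p)
    best = math.inf
    for e in expand_to_size(small, large.size):
        d = _min_hamming(e, large)
        if d < best:
            best = d
    return best


def wiring_length(p: Program) -> int:
    """Net transition distance under the best linear ordering of states.

    Each transition contributes |position(target) - position(source)|
    (self-loops contribute 0); the ordering minimizing the sum is taken.
    """
    m = p.size
    best = math.inf
    for perm in _perms(m):
        total = 0
        for i in range(m):
            total += abs(perm[p.t_lose[i]] - perm[i])
            total += abs(perm[p.t_win[i]] - perm[i])
        if total < best:
            best = total
    return int(best)
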