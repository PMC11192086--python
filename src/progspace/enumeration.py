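"""Exhaustive enumeration of unique valid programs, and evolutionary search.

The raw space of M-state programs — 2**M action labelings times M**(2M)
transition arrangements — collapses to a far smaller set of unique valid
programs once the rule-out rules are applied.  The pipeline applies them
in increasing order of cost:

1. transition-pair generation over M**(2M) arrangements (vectorized);
2. sink/drain filter: the union digraph over both outcome maps must be a
   single strongly connected component (label-independent, removes the
   bulk of the space);
3. attach the unique action-label sets for the size (global inversion
   symmetry halves the labelings; uniform labelings are merger-reducible);
4. merger filter: Moore-minimality via partition refinement;
5. permutation/inversion deduplication by canonical form;
6. periodicity filter on the task-coupled joint (s, m) chain (slowest,
   applied to the smallest surviving set).

``evolutionary_search`` discovers good programs without full enumeration:
a reservoir of programs carries one of three status labels (morph, frozen,
idle); each generation promotes the best ~log(N_idle) hibernating
programs, takes *all* single mutations of the morph set (including
mutations through merger expansions one size up), filters them by the
rule-out rules, and hibernates the new mutants.  The algorithm is fully
deterministic — no random number generator is involved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation
from .programs import (
    Program,
    _canonical_key,
    canonicalize,
    expand_to_size,
    neighbors,
    validate,
)
from .task import DEFAULT_PARAMS, TaskParams

__all__ = [
    "Ensemble",
    "Reservoir",
    "LABEL_SETS",
    "raw_space_size",
    "enumerate_unique",
    "enumerate_all_up_to",
    "evolutionary_search",
]

#: Unique action-label sets per size after inversion symmetry; uniform
#: labelings are absent because they minimize to a single state.
LABEL_SETS: dict[int, list[tuple[int, ...]]] = {
    2: [(-1, 1)],
    3: [(-1, 1, 1)],
    4: [(-1, 1, 1, 1), (-1, -1, 1, 1)],
    5: [(-1, 1, 1, 1, 1), (-1, -1, 1, 1, 1)],
}


def raw_space_size(m: int) -> int:
    """Unfiltered count of labeled programs: 2**M * M**(2M)."""
    return 2**m * m ** (2 * m)


@dataclass
class Ensemble:
    """An ordered collection of canonical programs with evaluation results.

    The stable order — size ascending, reward rate descending, canonical
    id ascending — defines program indices once rates are filled in.
    """

    programs: list[Program]
    params: TaskParams = DEFAULT_PARAMS
    reward_rates: np.ndarray | None = None
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = "enumerated"

    def __post_init__(self) -> None:
        ids = [p.canonical_id for p in self.programs]
        if len(set(ids)) != len(ids):
            raise ValueError("ensemble contains duplicate canonical ids")
        self._index = {pid: i for i, pid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.programs)

    def __iter__(self):
        return iter(self.programs)

    def __getitem__(self, i: int) -> Program:
        return self.programs[i]

    @property
    def ids(self) -> list[str]:
        return [p.canonical_id for p in self.programs]

    def index_of(self, p: Program | str) -> int:
        pid = p if isinstance(p, str) else p.canonical_id
        return self._index[pid]

    def __contains__(self, p) -> bool:
        pid = p if isinstance(p, str) else p.canonical_id
        return pid in self._index

    @property
    def sizes(self) -> np.ndarray:
        return np.array([p.size for p in self.programs])

    def size_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for p in self.programs:
            out[p.size] = out.get(p.size, 0) + 1
        return dict(sorted(out.items()))

    def evaluate(self, progress: bool = False) -> np.ndarray:
        """Fill steady-state reward rates for every member (BDP)."""
        rates = np.empty(len(self.programs))
        for i, p in enumerate(self.programs):
            rates[i] = evaluation.reward_rate(p, self.params)
        self.reward_rates = rates
        good, low = evaluation.classify_good(rates, self.params)
        self.flags["good"] = good
        self.flags["low_performing"] = low
        return rates

    def sort(self) -> "Ensemble":
        """Apply the canonical ensemble order in place (requires rates for
        the performance component; falls back to (size, id) without)."""
        if self.reward_rates is None:
            key = sorted(
                range(len(self.programs)),
                key=lambda i: (self.programs[i].size, self.programs[i].canonical_id),
            )
        else:
            key = sorted(
                range(len(self.programs)),
                key=lambda i: (
                    self.programs[i].size,
                    -self.reward_rates[i],
                    self.programs[i].canonical_id,
                ),
            )
        self.programs = [self.programs[i] for i in key]
        if self.reward_rates is not None:
            self.reward_rates = self.reward_rates[key]
        self.flags = {k: v[key] for k, v in self.flags.items()}
        self._index = {p.canonical_id: i for i, p in enumerate(self.programs)}
        return self

    def subset(self, mask) -> "Ensemble":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else mask
        return Ensemble(
            programs=[self.programs[i] for i in idx],
            params=self.params,
            reward_rates=None if self.reward_rates is None else self.reward_rates[idx],
            flags={k: v[idx] for k, v in self.flags.items()},
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# vectorized sink/drain pre-filter


def _transition_digits(m: int, start: int, stop: int) -> np.ndarray:
    """Rows ``start:stop`` of the base-M digit table of all M**(2M)
    transition arrangements; columns 0..M-1 are t_lose, M..2M-1 t_win."""
    idx = np.arange(start, stop, dtype=np.int64)
    digits = np.empty((len(idx), 2 * m), dtype=np.int8)
    for c in range(2 * m - 1, -1, -1):
        digits[:, c] = idx % m
        idx = idx // m
    return digits


def _sc_mask(digits: np.ndarray, m: int) -> np.ndarray:
    """Boolean mask of arrangements whose union digraph is strongly
    connected, computed by batched boolean matrix squaring."""
    b = len(digits)
    adj = np.zeros((b, m, m), dtype=np.uint8)
    rows = np.arange(b)[:, None]
    src = np.tile(np.arange(m), 2)[None, :]
    adj[rows, src, digits] = 1
    reach = adj | np.eye(m, dtype=np.uint8)[None, :, :]
    hops = 1
    while hops < m - 1:
        reach = (np.matmul(reach, reach) > 0).astype(np.uint8)
        hops *= 2
    return reach[:, 0, :].all(axis=1) & reach[:, :, 0].all(axis=1)


def _is_minimal(labels, t_lose, t_win) -> bool:
    """Moore-minimality on raw tuples (hot path of the merger filter)."""
    m = len(labels)
    block = [0 if labels[i] < 0 else 1 for i in range(m)]
    if max(block) == 0 or min(block) == 1:
        return m == 1
    while True:
        mapping: dict[tuple, int] = {}
        new_block = []
        for i in range(m):
            sig = (block[i], block[t_lose[i]], block[t_win[i]])
            if sig not in mapping:
                mapping[sig] = len(mapping)
            new_block.append(mapping[sig])
        if new_block == block:
            return len(mapping) == m
        block = new_block


def enumerate_unique(
    m: int,
    params: TaskParams = DEFAULT_PARAMS,
    batch_size: int = 1 << 20,
    checkpoint: str | Path | None = None,
    allow_large: bool = False,
) -> Ensemble:
    """All unique valid programs of exactly ``m`` states.

    Sizes 2-4 complete in seconds to minutes on one core; size 5 iterates
    9.8 million transition arrangements in batches (``checkpoint`` stores
    per-batch partial results so a long run can resume).  Sizes above 5
    are refused unless ``allow_large`` is set.
    """
    if m < 2:
        raise ValueError("enumeration starts at 2 states")
    if m > 5 and not allow_large:
        raise ValueError(
            f"enumeration at M={m} is combinatorially infeasible; "
            "pass allow_large=True to override"
        )
    label_sets = LABEL_SETS.get(m)
    if label_sets is None:
        raise ValueError(f"no action-label sets defined for M={m}")

    total = m ** (2 * m)
    seen: set[str] = set()
    candidates: list[Program] = []
    start_batch = 0
    if checkpoint is not None and Path(checkpoint).exists():
        state = json.loads(Path(checkpoint).read_text())
        if state["M"] == m and state["batch_size"] == batch_size:
            start_batch = state["next_batch"]
            for rec in state["candidates"]:
                p = Program.from_record(rec)
                candidates.append(p)
                seen.add(p.canonical_id)

    n_batches = (total + batch_size - 1) // batch_size
    for bi in range(start_batch, n_batches):
        lo, hi = bi * batch_size, min((bi + 1) * batch_size, total)
        digits = _transition_digits(m, lo, hi)
        digits = digits[_sc_mask(digits, m)]
        for row in digits:
            t_lose = tuple(int(x) for x in row[:m])
            t_win = tuple(int(x) for x in row[m:])
            for labels in label_sets:
                if not _is_minimal(labels, t_lose, t_win):
                    continue
                (clab, ctl, ctw), cid = _canonical_key(labels, t_lose, t_win)
                if cid in seen:
                    continue
                seen.add(cid)
                candidates.append(Program(clab, ctl, ctw))
        if checkpoint is not None:
            Path(checkpoint).write_text(
                json.dumps(
                    {
                        "M": m,
                        "batch_size": batch_size,
                        "next_batch": bi + 1,
                        "candidates": [p.to_record() for p in candidates],
                    }
                )
            )

    # Periodicity (and coupled sink/drain) on the small surviving set, last.
    programs = [p for p in candidates if validate(p, params)]
    ens = Ensemble(programs=programs, params=params, provenance="enumerated")
    return ens.sort()


def enumerate_all_up_to(
    m_max: int,
    params: TaskParams = DEFAULT_PARAMS,
    **kwargs,
) -> Ensemble:
    """Union of unique valid programs for sizes 2..``m_max``.

    Cross-size duplicates cannot occur: every member is minimal, and
    minimal programs of different sizes behave differently.
    """
    programs: list[Program] = []
    for m in range(2, m_max + 1):
        programs.extend(enumerate_unique(m, params, **kwargs).programs)
    return Ensemble(programs=programs, params=params, provenance="enumerated").sort()


# ---------------------------------------------------------------------------
# evolutionary search


@dataclass
class Reservoir:
    """Program reservoir of the evolutionary search.

    ``status`` maps canonical id to one of morph / frozen / idle; frozen
    programs have had all their mutants taken and are never re-mutated.
    """

    programs: dict[str, Program] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)
    generation: int = 0
    history: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.programs)

    def count(self, status: str) -> int:
        return sum(1 for s in self.status.values() if s == status)

    @property
    def n_idle(self) -> int:
        return self.count("idle")

    def good_ids(self, params: TaskParams) -> list[str]:
        thr = evaluation.wslg_reward_rate(params)
        return [pid for pid, r in self.rates.items() if r > thr]

    def to_ensemble(self, params: TaskParams) -> Ensemble:
        progs = list(self.programs.values())
        ens = Ensemble(progs, params=params, provenance="evolved")
        ens.reward_rates = np.array([self.rates[p.canonical_id] for p in progs])
        good, low = evaluation.classify_good(ens.reward_rates, params)
        ens.flags["good"] = good
        ens.flags["low_performing"] = low
        return ens.sort()


def _promotion_count(n_idle: int) -> int:
    """~log(N_idle) promotions per generation: natural log rounded to the
    nearest integer, at least 1."""
    if n_idle <= 0:
        return 0
    return max(1, round(math.log(n_idle)))


def _all_mutants(p: Program, params: TaskParams, max_size: int) -> set[Program]:
    """Every valid canonical program within one mutation of ``p``,
    including mutations taken through its merger expansions one size up."""
    out = set(neighbors(p, params))
    if p.size + 1 <= max_size:
        for e in expand_to_size(p, p.size + 1):
            out |= neighbors(e, params)
    out.discard(canonicalize(p))
    return out


def evolutionary_search(
    seeds: Ensemble | list[Program],
    generations: int = 16,
    params: TaskParams = DEFAULT_PARAMS,
    max_size: int = 5,
) -> Reservoir:
    """Deterministic evolutionary discovery of good programs.

    Each generation: promote the top-performing ~log(N_idle) hibernating
    programs to morph status, generate *all* single mutations of the morph
    set (rule-out filtered, deduplicated against the reservoir), evaluate
    the new mutants, hibernate them, and freeze their parents.  Stops
    early when nothing is left to morph.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    res = Reservoir()
    seed_list = list(seeds)
    if not seed_list:
        raise ValueError("need at least one seed program")
    for p in seed_list:
        c = canonicalize(p)
        if not validate(c, params):
            raise ValueError(f"seed {c!r} fails the rule-out rules")
        pid = c.canonical_id
        res.programs[pid] = c
        res.status[pid] = "idle"
        res.rates[pid] = evaluation.reward_rate(c, params)

    for gen in range(1, generations + 1):
        n_promote = _promotion_count(res.n_idle)
        idle_sorted = sorted(
            (pid for pid, s in res.status.items() if s == "idle"),
            key=lambda pid: (-res.rates[pid], pid),
        )
        for pid in idle_sorted[:n_promote]:
            res.status[pid] = "morph"
        morphs = [pid for pid, s in res.status.items() if s == "morph"]
        if not morphs:
            break
        new = 0
        for pid in morphs:
            for mut in _all_mutants(res.programs[pid], params, max_size):
                mid = mut.canonical_id
                if mid in res.programs:
                    continue
                res.programs[mid] = mut
                res.status[mid] = "idle"
                res.rates[mid] = evaluation.reward_rate(mut, params)
                new += 1
            res.status[pid] = "frozen"
        res.generation = gen
        res.history.append(
            {
                "generation": gen,
                "morphed": len(morphs),
                "new_mutants": new,
                "reservoir": len(res),
                "good": len(res.good_ids(params)),
            }
        )
    return res
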