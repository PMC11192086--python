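"""Structurally Bayesian programs: discretizations of the ideal observer.

A compact program is *structurally Bayesian* when its states and
transitions can be obtained by binning the ideal observer's belief and
rounding the belief update to the bin grid.  The belief axis is split
into M equal bins spanning [-alpha * u_ub, +alpha * u_ub], where u_ub is
the fixed-point belief under continual winning and alpha in (0, 1]
controls the range.  Each bin is labeled by the greedy action at its
center, and each (bin, outcome) transition targets the bin nearest to the
updated belief — or, in the next-nearest variants, the bin on the other
side of the update when it falls strictly between two centers.

The resulting machines are filtered by the same rule-out rules as the
enumeration; WSLG is the two-state member of this family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .enumeration import Ensemble
from .programs import Program, _perms, canonicalize, validate
from .task import (
    DEFAULT_PARAMS,
    PM,
    TaskParams,
    belief_upper_bound,
    greedy_action,
    update_belief,
)

__all__ = [
    "DiscretizationSpec",
    "discretize_bayes",
    "structurally_bayesian_set",
    "default_alpha_grid",
    "has_bayesian_order",
]


@dataclass(frozen=True)
class DiscretizationSpec:
    """One belief discretization: size, range parameter, and per-cell
    rounding choices.

    ``variant`` assigns, per (state, outcome) cell in row-major order
    (state-major, outcome -1 before +1), 0 for the nearest bin and 1 for
    the next-nearest; cells where only the nearest bin is defined ignore
    the entry.
    """

    size: int
    alpha: float
    variant: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("discretization needs at least 2 bins")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.variant is not None and len(self.variant) != 2 * self.size:
            raise ValueError("variant must have one entry per (state, outcome)")


def _bin_centers(m: int, alpha: float, u_ub: float) -> np.ndarray:
    width = 2.0 * alpha * u_ub / m
    return -alpha * u_ub + (np.arange(m) + 0.5) * width


def _target_options(centers: np.ndarray, u2: float) -> tuple[int, ...]:
    """Nearest bin first, then the next-nearest when the updated belief
    falls strictly between two centers; exact midpoints break toward the
    confidence-decreasing (smaller |center|) side, with no second option."""
    d = np.abs(centers - u2)
    order = np.argsort(d, kind="stable")
    i0, i1 = int(order[0]), int(order[1]) if len(centers) > 1 else (int(order[0]),) * 2
    if np.isclose(d[i0], d[i1]):
        mid = i0 if abs(centers[i0]) < abs(centers[i1]) else i1
        return (mid,)
    lo, hi = min(centers), max(centers)
    if u2 <= lo or u2 >= hi:  # outside the grid: only the edge bin
        return (i0,)
    return (i0, i1)


def _cells(params: TaskParams, m: int, alpha: float):
    """Labels and per-(state, outcome) target options of a discretization."""
    u_ub = belief_upper_bound(params)
    if u_ub == 0.0:
        raise ValueError("belief upper bound is 0; discretization undefined")
    centers = _bin_centers(m, alpha, u_ub)
    labels = tuple(greedy_action(params, float(u)) for u in centers)
    options: list[tuple[int, ...]] = []
    for k in range(m):
        a = labels[k]
        for o in PM:  # -1 then +1, state-major
            u2 = update_belief(params, float(centers[k]), a, o)
            options.append(_target_options(centers, u2))
    return labels, options


def discretize_bayes(
    params: TaskParams = DEFAULT_PARAMS,
    spec: DiscretizationSpec = DiscretizationSpec(2, 0.5),
    filter_rules: bool = True,
) -> Program | None:
    """Build the program of one discretization; ``None`` when the machine
    fails the rule-out rules (rejection is a value, not an error).

    ``filter_rules=False`` skips the validity filter: fine discretizations
    (tens of states) legitimately carry transient outer bins and
    merger-reducible interior bins yet evaluate fine through the
    steady-state machinery, which settles on the recurrent class.
    """
    labels, options = _cells(params, spec.size, spec.alpha)
    variant = spec.variant or (0,) * (2 * spec.size)
    t_lose = []
    t_win = []
    for k in range(spec.size):
        opts_lose = options[2 * k]
        opts_win = options[2 * k + 1]
        t_lose.append(opts_lose[min(variant[2 * k], len(opts_lose) - 1)])
        t_win.append(opts_win[min(variant[2 * k + 1], len(opts_win) - 1)])
    p = Program(labels, tuple(t_lose), tuple(t_win))
    if filter_rules and not validate(p, params):
        return None
    # canonical form is only tractable (and only needed) at ensemble sizes
    return canonicalize(p) if p.size <= 6 else p


def default_alpha_grid(step: float = 0.05) -> np.ndarray:
    """Range-parameter grid 0.05 .. 1.00; the deduplicated program set
    saturates well before this density."""
    n = round(1.0 / step)
    return np.arange(1, n + 1) * step


def structurally_bayesian_set(
    params: TaskParams = DEFAULT_PARAMS,
    m_max: int = 5,
    alpha_grid: np.ndarray | None = None,
) -> Ensemble:
    """All canonical valid programs obtainable as belief discretizations
    with sizes 2..``m_max``, range parameters in ``alpha_grid``, and every
    combination of nearest / next-nearest rounding."""
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    if len(alpha_grid) == 0:
        raise ValueError("alpha_grid must be nonempty")
    seen: dict[str, Program] = {}
    for m in range(2, m_max + 1):
        for alpha in alpha_grid:
            labels, options = _cells(params, m, float(alpha))
            for combo in itertools.product(*options):
                t_lose = tuple(combo[0::2])
                t_win = tuple(combo[1::2])
                p = Program(labels, t_lose, t_win)
                if not validate(p, params):
                    continue
                c = canonicalize(p)
                seen.setdefault(c.canonical_id, c)
    ens = Ensemble(
        programs=list(seen.values()), params=params, provenance="bayes-discretized"
    )
    ens.flags["structurally_bayesian"] = np.ones(len(ens), dtype=bool)
    return ens.sort()


def has_bayesian_order(p: Program) -> bool:
    """Whether some state ordering exhibits the two directions of belief
    integration: the two action blocks are contiguous and every win
    transition moves away from (or holds) the block boundary, i.e. never
    decreases confidence in the currently favored option."""
    m = p.size
    for perm in _perms(m):
        pos = list(perm)
        lab_seq = [p.labels[i] for i in sorted(range(m), key=lambda i: pos[i])]
        # contiguous action blocks
        flips = sum(1 for x, y in zip(lab_seq, lab_seq[1:]) if x != y)
        if flips != 1:
            continue
        left_action = lab_seq[0]
        ok = True
        for i in range(m):
            tw = p.t_win[i]
            if p.labels[i] == left_action:
                if pos[tw] > pos[i]:
                    ok = False
                    break
            else:
                if pos[tw] < pos[i]:
                    ok = False
                    break
        if ok:
            return True
    return False
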