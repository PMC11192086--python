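"""Dynamic two-armed-bandit environment and the ideal Bayesian observer.

The task is a nonstationary two-armed bandit: a hidden binary world state
``s`` in {-1, +1} identifies the currently better port and switches with a
fixed hazard rate ``h`` per step.  On each step the agent takes a binary
action ``a`` in {-1, +1} (left/right port) and receives a binary outcome
``o`` in {-1, +1} (unrewarded/rewarded) with probability

    p(o | s, a) = (1 + o * (s * a * dp + dpbar)) / 2

where ``dp`` is the reward contrast between the two ports and
``dpbar = 2 * pbar - 1`` is the reward gain at baseline rate ``pbar``.

An ideal observer that knows (pbar, dp, h) but not ``s`` tracks the belief
``u = p(s=+1|history) - p(s=-1|history)`` in [-1, 1], updated after each
(action, outcome) pair by a closed-form filter that folds in one step of
world dynamics.  Coupling that belief to the reward-maximizing (greedy)
policy gives the optimal unconstrained strategy, solved here by
running-average value iteration on a discretized belief grid.

All of s, a, o are carried as integers -1/+1; no 0/1 recoding is used in
the math.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskParams",
    "BeliefPolicy",
    "outcome_probability",
    "world_step",
    "update_belief",
    "belief_upper_bound",
    "solve_optimal_policy",
    "greedy_action",
]

PM = (-1, +1)


@dataclass(frozen=True)
class TaskParams:
    """Bandit environment parameterization.

    Parameters
    ----------
    mean_reward : float
        Baseline reward probability pbar = (p_high + p_low) / 2.
    contrast : float
        Reward contrast dp = p_high - p_low.  May be negative; the task is
        equivalent under a relabeling of the world state, and the sign is
        kept exactly as given.
    hazard : float
        Per-step probability h that the hidden world state switches.
    """

    mean_reward: float = 0.3
    contrast: float = -0.5
    hazard: float = 0.05
    allow_out_of_range_hazard: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.hazard >= 0.0 and self.hazard <= 0.5):
            raise ValueError(f"hazard must lie in [0, 0.5], got {self.hazard}")
        if not (0.05 <= self.hazard <= 0.5):
            if self.allow_out_of_range_hazard:
                warnings.warn(
                    f"hazard {self.hazard} outside the standard range [0.05, 0.5]",
                    stacklevel=2,
                )
            else:
                raise ValueError(
                    f"hazard {self.hazard} outside [0.05, 0.5]; "
                    "pass allow_out_of_range_hazard=True to override"
                )
        for s in PM:
            for a in PM:
                for o in PM:
                    p = 0.5 * (1 + o * (s * a * self.contrast + self.gain))
                    if p < -1e-12 or p > 1 + 1e-12:
                        raise ValueError(
                            "invalid parameters: outcome probability "
                            f"p(o={o}|s={s},a={a}) = {p} outside [0, 1]"
                        )

    @property
    def gain(self) -> float:
        """Reward gain dpbar = 2*pbar - 1."""
        return 2.0 * self.mean_reward - 1.0

    @property
    def p_high(self) -> float:
        return self.mean_reward + self.contrast / 2.0

    @property
    def p_low(self) -> float:
        return self.mean_reward - self.contrast / 2.0

    def to_dict(self) -> dict:
        return {
            "mean_reward": self.mean_reward,
            "contrast": self.contrast,
            "hazard": self.hazard,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskParams":
        return cls(
            mean_reward=float(d["mean_reward"]),
            contrast=float(d["contrast"]),
            hazard=float(d["hazard"]),
            allow_out_of_range_hazard=bool(d.get("allow_out_of_range_hazard", False)),
        )


DEFAULT_PARAMS = TaskParams()


def outcome_probability(params: TaskParams, s: int, a: int, o: int) -> float:
    """Probability of outcome ``o`` given world state ``s`` and action ``a``."""
    return 0.5 * (1.0 + o * (s * a * params.contrast + params.gain))


def world_step(params: TaskParams, s: int) -> dict[int, float]:
    """Distribution over the next world state given the current one."""
    return {s: 1.0 - params.hazard, -s: params.hazard}


def update_belief(params: TaskParams, u: float, a: int, o: int) -> float:
    """One step of the ideal observer's belief filter.

    Applies the exact posterior update for (a, o) followed by one step of
    hazard-rate mixing; the combined map is

        U(u, a, o) = (1 - 2h) * (a*o*dp + (1 + o*dpbar)*u)
                              / (a*o*dp*u + (1 + o*dpbar))

    and contracts [-1, 1] into [-(1-2h), 1-2h].
    """
    if abs(u) > 1 + 1e-12:
        raise ValueError(f"belief must lie in [-1, 1], got {u}")
    num = a * o * params.contrast + (1.0 + o * params.gain) * u
    den = a * o * params.contrast * u + (1.0 + o * params.gain)
    if abs(den) < 1e-300:
        raise ZeroDivisionError(
            f"degenerate belief-update denominator at u={u}, a={a}, o={o}"
        )
    return (1.0 - 2.0 * params.hazard) * num / den


def greedy_action(params: TaskParams, u: float) -> int:
    """Reward-maximizing action at belief u.

    The expected immediate reward is (1 + a*u*dp + dpbar)/2, so the greedy
    action is sgn(u * dp); for dp > 0 this is the familiar a* = sgn(u).
    Ties (u = 0) break to +1.
    """
    v = u * params.contrast
    return +1 if v >= 0 else -1


def belief_upper_bound(
    params: TaskParams, tol: float = 1e-12, max_iter: int = 100_000
) -> float:
    """Magnitude of the fixed-point belief reached under continual winning.

    Iterates the winning (o = +1) belief update under the greedy action
    from u = 0 with mild damping until the change falls below ``tol``.
    Returns 0 for h = 0.5 (beliefs collapse).  The result is the stable
    root of the quadratic fixed-point equation induced by the update.
    """
    if params.hazard >= 0.5:
        return 0.0
    if params.contrast == 0.0:
        return 0.0
    u = 0.0
    for _ in range(max_iter):
        a = greedy_action(params, u)
        u_new = update_belief(params, u, a, +1)
        # Damping guards against the transient sign flip out of u = 0.
        u_next = 0.5 * (u + u_new) if u == 0.0 else u_new
        if abs(u_next - u) < tol:
            return abs(u_next)
        u = u_next
    raise RuntimeError(
        f"belief_upper_bound did not converge within {max_iter} iterations"
    )


@dataclass
class BeliefPolicy:
    """Greedy policy over a discretized belief grid.

    Attributes
    ----------
    params : TaskParams
    centers : ndarray, shape (n_bins,)
        Uniform bin centers over [-1, 1]; bin k of n has center -1 + (2k+1)/n,
        so for even n no center is exactly 0 and the greedy sign is always
        defined.
    values : ndarray, shape (n_bins,)
        Converged running-average value per bin (approaches the long-run
        reward rate in every bin of a unichain policy).
    q_values : ndarray, shape (n_bins, 2)
        Action values, columns ordered (a=-1, a=+1).
    actions : ndarray, shape (n_bins,)
        Greedy action (+-1) per bin.
    reward_rate : float
        Long-run reward rate of the greedy policy, computed by exact
        steady-state propagation of the induced (s, bin) chain.
    iterations, residual : int, float
        Value-iteration diagnostics.
    """

    params: TaskParams
    centers: np.ndarray
    values: np.ndarray
    q_values: np.ndarray
    actions: np.ndarray
    reward_rate: float
    iterations: int
    residual: float

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    def to_chain(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Deterministic chain induced by the policy on the belief grid.

        Returns (labels, t_lose, t_win): the action per bin and, for each
        outcome, the nearest-bin image of the belief update taken under the
        bin's own greedy action.  This is the form consumed by the
        steady-state and sequence propagation machinery.
        """
        labels = self.actions.copy()
        maps = []
        for o in PM:
            tgt = np.empty(self.n_bins, dtype=np.int64)
            for k, u in enumerate(self.centers):
                u2 = update_belief(self.params, float(u), int(labels[k]), o)
                tgt[k] = int(np.argmin(np.abs(self.centers - u2)))
            maps.append(tgt)
        t_lose, t_win = maps
        return labels, t_lose, t_win


def _belief_outcome_prob(params: TaskParams, u: np.ndarray, a: int, o: int):
    """p(o | u, a) marginalizing the hidden state under belief u."""
    return 0.5 * (1.0 + o * (a * u * params.contrast + params.gain))


def solve_optimal_policy(
    params: TaskParams,
    n_bins: int = 200,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> BeliefPolicy:
    """Running-average value iteration over the discretized belief space.

    The value update per sweep t -> t+1 is

        v(u, t+1) = max_a sum_{o} p(o | u, a) * [ r(o)/(t+1) + t/(t+1) * v(u', t) ]

    with r(o) = 1 for reward and u' = U(u, a, o) snapped to the nearest
    grid center.  The running-average weighting makes every bin's value
    converge to the long-run reward rate; the greedy policy stabilizes far
    earlier.  Iteration stops when the sup-norm change falls below ``tol``
    or after ``max_iter`` sweeps — the latter is normal termination
    provided the greedy policy has stopped changing, otherwise an error is
    raised with the residual.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    centers = -1.0 + (2.0 * np.arange(n_bins) + 1.0) / n_bins

    # Precompute, per (action, outcome): outcome probability and next-bin index.
    probs = {}
    nxt = {}
    for a in PM:
        for o in PM:
            probs[a, o] = _belief_outcome_prob(params, centers, a, o)
            u2 = np.array([update_belief(params, float(u), a, o) for u in centers])
            nxt[a, o] = np.argmin(
                np.abs(u2[:, None] - centers[None, :]), axis=1
            )

    v = np.zeros(n_bins)
    q = np.zeros((n_bins, 2))
    residual = np.inf
    last_actions = None
    stable_since = 0
    it = 0
    for it in range(1, max_iter + 1):
        w_r = 1.0 / it
        w_v = (it - 1.0) / it
        for ai, a in enumerate(PM):
            acc = np.zeros(n_bins)
            for o in PM:
                r = 1.0 if o == +1 else 0.0
                acc += probs[a, o] * (w_r * r + w_v * v[nxt[a, o]])
            q[:, ai] = acc
        v_new = q.max(axis=1)
        residual = float(np.max(np.abs(v_new - v)))
        v = v_new
        actions = np.where(q[:, 1] >= q[:, 0], 1, -1)
        if last_actions is not None and np.array_equal(actions, last_actions):
            stable_since += 1
        else:
            stable_since = 0
        last_actions = actions
        if residual < tol:
            break
    else:
        if stable_since < 1000:
            raise RuntimeError(
                f"value iteration did not converge: residual {residual:.3e} "
                f"after {max_iter} sweeps and the greedy policy is not stable"
            )

    policy = BeliefPolicy(
        params=params,
        centers=centers,
        values=v,
        q_values=q.copy(),
        actions=last_actions.astype(np.int64),
        reward_rate=np.nan,
        iterations=it,
        residual=residual,
    )
    # Long-run reward rate via exact propagation of the induced joint chain.
    from .evaluation import steady_state  # local import: avoid cycle at import time

    policy.reward_rate = steady_state(policy, params).reward_rate
    return policy
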