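"""Monte Carlo trajectory simulator.

A generative rollout of the task dynamics coupled to a strategy, kept as
the independent oracle for the exact propagation algorithms: empirical
reward rates and sequence frequencies from long trajectories must agree
with the steady-state computations within sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import _as_chain
from .task import DEFAULT_PARAMS, TaskParams, outcome_probability

__all__ = ["Trajectory", "simulate", "empirical_sequence_frequencies"]


@dataclass
class Trajectory:
    """Per-step records of one simulated session."""

    params: TaskParams
    seed: int
    s: np.ndarray  # hidden world state, +-1
    m: np.ndarray  # internal state index
    a: np.ndarray  # action, +-1
    o: np.ndarray  # outcome, +-1
    reward: np.ndarray  # 0/1, reward == (o == +1)

    def __len__(self) -> int:
        return len(self.s)

    @property
    def reward_rate(self) -> float:
        return float(self.reward.mean())

    @property
    def switch_rate(self) -> float:
        return float((self.s[1:] != self.s[:-1]).mean())

    def symbols(self) -> str:
        """Behavioral string: symbol t pairs outcome t with the stay/go
        relation between actions t and t+1 (length T - 1)."""
        stay = self.a[1:] == self.a[:-1]
        win = self.o[:-1] == 1
        chars = np.where(
            win & stay, "W", np.where(~win & stay, "L", np.where(win, "w", "l"))
        )
        return "".join(chars)


def simulate(
    strategy,
    params: TaskParams = DEFAULT_PARAMS,
    steps: int = 10_000,
    seed: int = 0,
    init_state: int = 0,
) -> Trajectory:
    """Exact generative rollout: reward delivery given (s, a), internal
    transition on the outcome, hazard-rate world switch.  Reproducible
    per seed."""
    if steps < 1:
        raise ValueError("need at least one step")
    labels, t_lose, t_win = _as_chain(strategy)
    k = len(labels)
    rng = np.random.default_rng(seed)
    u_out = rng.random(steps)
    u_sw = rng.random(steps)
    # outcome thresholds per (s index, state)
    p_win = np.empty((2, k))
    for si, s in enumerate((-1, +1)):
        for mm in range(k):
            p_win[si, mm] = outcome_probability(params, s, int(labels[mm]), +1)
    h = params.hazard
    s_arr = np.empty(steps, dtype=np.int8)
    m_arr = np.empty(steps, dtype=np.int64)
    a_arr = np.empty(steps, dtype=np.int8)
    o_arr = np.empty(steps, dtype=np.int8)
    s = -1 if rng.random() < 0.5 else 1
    m = init_state
    tl = t_lose.tolist()
    tw = t_win.tolist()
    lab = labels.tolist()
    pw = p_win.tolist()
    for t in range(steps):
        si = 0 if s == -1 else 1
        o = 1 if u_out[t] < pw[si][m] else -1
        s_arr[t] = s
        m_arr[t] = m
        a_arr[t] = lab[m]
        o_arr[t] = o
        m = tw[m] if o == 1 else tl[m]
        if u_sw[t] < h:
            s = -s
    return Trajectory(
        params=params,
        seed=seed,
        s=s_arr.astype(np.int64),
        m=m_arr,
        a=a_arr.astype(np.int64),
        o=o_arr.astype(np.int64),
        reward=(o_arr == 1).astype(np.int64),
    )


def empirical_sequence_frequencies(
    traj: Trajectory, ell: int, burn_in: int = 100
) -> dict[str, float]:
    """Sliding-window frequencies of length-``ell`` behavioral strings,
    after discarding an initial transient."""
    sym = traj.symbols()[burn_in:]
    counts: dict[str, int] = {}
    n = len(sym) - ell + 1
    for i in range(n):
        w = sym[i : i + ell]
        counts[w] = counts.get(w, 0) + 1
    return {k: v / n for k, v in counts.items()}
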