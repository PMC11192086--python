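"""Exact steady-state evaluation of strategies.

Monte Carlo rollouts converge slowly; instead the joint distribution over
(hidden world state s, internal state m) is propagated exactly under the
task dynamics — one step applies reward delivery given (s, action), the
deterministic internal transition on the outcome, and the hazard-rate
world switch.  We call this belief distribution propagation (BDP); its
fixed point is the leading eigenvector of the joint transition operator,
which is kept available as an independent cross-check.

The same operator, split by emitted behavioral symbol, yields sequence
distribution propagation (SDP): exact steady-state probabilities of
length-l strings over the alphabet

    W  win-stay    L  lose-stay    w  win-go    l  lose-go

where the symbol at position t pairs the outcome at t with the stay/go
relation between the actions at t and t+1.  Starting from stationarity
removes transients, and only strings of nonzero probability are ever
materialized (the support is at most M * 2**l, far below 4**l).

Both a :class:`~progspace.programs.Program` and a discretized
:class:`~progspace.task.BeliefPolicy` reduce to the same deterministic
chain form (labels, t_lose, t_win), so one code path evaluates both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import DEFAULT_PARAMS, PM, TaskParams, outcome_probability

__all__ = [
    "SteadyState",
    "SequenceDistribution",
    "ALPHABET",
    "steady_state",
    "reward_rate",
    "wslg_reward_rate",
    "random_policy_rate",
    "classify_good",
    "joint_transition",
    "sequence_distribution",
    "transient_length",
]

#: Symbol order used throughout: index -> character.
ALPHABET = "WLwl"
_SYMBOLS = {
    (+1, False): 0,  # W  win-stay
    (-1, False): 1,  # L  lose-stay
    (+1, True): 2,  # w  win-go
    (-1, True): 3,  # l  lose-go
}


def _as_chain(strategy):
    """Normalize a strategy to (labels, t_lose, t_win) integer arrays."""
    if hasattr(strategy, "to_chain"):  # BeliefPolicy
        labels, t_lose, t_win = strategy.to_chain()
    elif hasattr(strategy, "labels"):  # Program
        labels = np.asarray(strategy.labels, dtype=np.int64)
        t_lose = np.asarray(strategy.t_lose, dtype=np.int64)
        t_win = np.asarray(strategy.t_win, dtype=np.int64)
    else:
        labels, t_lose, t_win = strategy
        labels = np.asarray(labels, dtype=np.int64)
        t_lose = np.asarray(t_lose, dtype=np.int64)
        t_win = np.asarray(t_win, dtype=np.int64)
    return labels, t_lose, t_win


@dataclass
class SteadyState:
    """Joint stationary distribution over (world state, internal state).

    ``dist`` has shape (2, K): row 0 is s = -1, row 1 is s = +1; columns
    are internal states (or belief bins).  ``reward_rate`` is the
    steady-state probability of reward per step.
    """

    dist: np.ndarray
    reward_rate: float
    iterations: int
    residual: float

    @property
    def flat(self) -> np.ndarray:
        return self.dist.reshape(-1)


def joint_transition(strategy, params: TaskParams = DEFAULT_PARAMS) -> np.ndarray:
    """Column-stochastic joint transition operator T over (s, m).

    Index layout: j = s_idx * K + m with s_idx 0 for s = -1, 1 for s = +1.
    T[next, cur] sums reward delivery over outcomes consistent with the
    internal transition, times the world-switch kernel.
    """
    labels, t_lose, t_win = _as_chain(strategy)
    k = len(labels)
    h = params.hazard
    t = np.zeros((2 * k, 2 * k))
    for si, s in enumerate(PM):
        for m in range(k):
            a = int(labels[m])
            cur = si * k + m
            for o, tmap in ((-1, t_lose), (+1, t_win)):
                po = outcome_probability(params, s, a, o)
                if po <= 0.0:
                    continue
                m2 = int(tmap[m])
                for sj, s2 in enumerate(PM):
                    w = (1.0 - h) if s2 == s else h
                    t[sj * k + m2, cur] += w * po
    return t


def _reward_vector(labels: np.ndarray, params: TaskParams) -> np.ndarray:
    """p(o=+1 | s, a_m) laid out like the flat joint distribution."""
    k = len(labels)
    r = np.empty(2 * k)
    for si, s in enumerate(PM):
        for m in range(k):
            r[si * k + m] = outcome_probability(params, s, int(labels[m]), +1)
    return r


def steady_state(
    strategy,
    params: TaskParams = DEFAULT_PARAMS,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> SteadyState:
    """Propagate the joint (s, m) distribution to its stationary point.

    Starts from the uniform distribution and iterates the exact one-step
    operator until the L1 change drops below ``tol``.  Raises if the chain
    fails to converge (a periodic chain that escaped validation).
    """
    labels, _, _ = _as_chain(strategy)
    t = joint_transition(strategy, params)
    n = t.shape[0]
    p = np.full(n, 1.0 / n)
    residual = np.inf
    for it in range(1, max_iter + 1):
        p_new = t @ p
        residual = float(np.abs(p_new - p).sum())
        p = p_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"steady-state propagation did not converge: L1 residual "
            f"{residual:.3e} after {max_iter} iterations"
        )
    p = p / p.sum()
    rr = float(_reward_vector(labels, params) @ p)
    k = n // 2
    return SteadyState(
        dist=p.reshape(2, k), reward_rate=rr, iterations=it, residual=residual
    )


def reward_rate(strategy, params: TaskParams = DEFAULT_PARAMS) -> float:
    """Steady-state reward rate <R> of a strategy."""
    return steady_state(strategy, params).reward_rate


_WSLG_RATE_CACHE: dict[TaskParams, float] = {}


def wslg_reward_rate(params: TaskParams = DEFAULT_PARAMS) -> float:
    """Reward rate of win-stay, lose-go: the threshold defining "good"."""
    if params not in _WSLG_RATE_CACHE:
        from .programs import WSLG

        _WSLG_RATE_CACHE[params] = reward_rate(WSLG, params)
    return _WSLG_RATE_CACHE[params]


def random_policy_rate(params: TaskParams = DEFAULT_PARAMS) -> float:
    """Reward rate of the memoryless uniform-random policy.

    The world chain alone is stationary-uniform for h > 0, and the action
    is independent of s, so this evaluates to pbar; computed here from the
    stationary world distribution rather than assumed.
    """
    h = params.hazard
    # stationary distribution of the symmetric 2-state world chain
    pi_s = np.array([0.5, 0.5]) if h > 0 else np.array([0.5, 0.5])
    rate = 0.0
    for si, s in enumerate(PM):
        for a in PM:
            rate += pi_s[si] * 0.5 * outcome_probability(params, s, a, +1)
    return float(rate)


def classify_good(
    rates: np.ndarray, params: TaskParams = DEFAULT_PARAMS
) -> tuple[np.ndarray, np.ndarray]:
    """Flag programs as good (rate strictly above WSLG) and low-performing
    (rate strictly below the random baseline pbar)."""
    rates = np.asarray(rates, dtype=float)
    thr = wslg_reward_rate(params)
    base = random_policy_rate(params)
    return rates > thr, rates < base


# ---------------------------------------------------------------------------
# sequence distribution propagation


@dataclass
class SequenceDistribution:
    """Steady-state distribution of length-l behavioral strings.

    ``codes`` are base-4 encodings (most significant digit = first symbol,
    digit order per :data:`ALPHABET`); ``probs`` the matching
    probabilities.  Only nonzero-probability strings are stored.
    """

    ell: int
    codes: np.ndarray
    probs: np.ndarray

    def decode(self, code: int) -> str:
        out = []
        for _ in range(self.ell):
            out.append(ALPHABET[code % 4])
            code //= 4
        return "".join(reversed(out))

    @staticmethod
    def encode(seq: str) -> int:
        code = 0
        for ch in seq:
            code = code * 4 + ALPHABET.index(ch)
        return code

    def as_dict(self) -> dict[str, float]:
        return {self.decode(int(c)): float(p) for c, p in zip(self.codes, self.probs)}

    def prob(self, seq: str) -> float:
        idx = np.searchsorted(self.codes, self.encode(seq))
        if idx < len(self.codes) and self.codes[idx] == self.encode(seq):
            return float(self.probs[idx])
        return 0.0

    def marginalize(self) -> "SequenceDistribution":
        """Drop the last symbol: the length-(l-1) prefix distribution."""
        if self.ell < 2:
            raise ValueError("cannot marginalize a length-1 distribution")
        pref = self.codes // 4
        uniq, inv = np.unique(pref, return_inverse=True)
        probs = np.zeros(len(uniq))
        np.add.at(probs, inv, self.probs)
        return SequenceDistribution(self.ell - 1, uniq, probs)


def _symbol_operators(strategy, params: TaskParams) -> list[np.ndarray]:
    """Split the joint transition operator by emitted behavioral symbol.

    A_sym[next, cur] carries the probability flow of steps whose outcome
    and stay/go relation produce that symbol; the four operators sum to
    the full transition operator.
    """
    labels, t_lose, t_win = _as_chain(strategy)
    k = len(labels)
    h = params.hazard
    ops = [np.zeros((2 * k, 2 * k)) for _ in range(4)]
    for si, s in enumerate(PM):
        for m in range(k):
            a = int(labels[m])
            cur = si * k + m
            for o, tmap in ((-1, t_lose), (+1, t_win)):
                po = outcome_probability(params, s, a, o)
                if po <= 0.0:
                    continue
                m2 = int(tmap[m])
                go = int(labels[m2]) != a
                sym = _SYMBOLS[(o, go)]
                for sj, s2 in enumerate(PM):
                    w = (1.0 - h) if s2 == s else h
                    ops[sym][sj * k + m2, cur] += w * po
    return ops


def sequence_distribution(
    strategy,
    params: TaskParams = DEFAULT_PARAMS,
    ell: int = 10,
    max_support: int = 5_000_000,
) -> SequenceDistribution:
    """Exact steady-state probabilities of length-``ell`` behavioral strings.

    Starts from the stationary joint distribution and branches the
    conditional (s, m) vector over the four symbol operators, merging
    prefixes level by level; zero-probability branches are pruned exactly.
    """
    if not (1 <= ell <= 10):
        raise ValueError("sequence length must lie in [1, 10]")
    ops = _symbol_operators(strategy, params)
    ss = steady_state(strategy, params)
    codes = np.zeros(1, dtype=np.int64)
    vecs = ss.flat[None, :]
    for _ in range(ell):
        new_codes = []
        new_vecs = []
        for sym, op in enumerate(ops):
            v = vecs @ op.T
            mass = v.sum(axis=1)
            keep = mass > 0.0
            if not keep.any():
                continue
            new_codes.append(codes[keep] * 4 + sym)
            new_vecs.append(v[keep])
        codes = np.concatenate(new_codes)
        vecs = np.vstack(new_vecs)
        if len(codes) > max_support:
            raise MemoryError(
                f"sequence support exceeded {max_support} at length step"
            )
        uniq, inv = np.unique(codes, return_inverse=True)
        if len(uniq) < len(codes):
            merged = np.zeros((len(uniq), vecs.shape[1]))
            np.add.at(merged, inv, vecs)
            codes, vecs = uniq, merged
        else:
            order = np.argsort(codes)
            codes, vecs = codes[order], vecs[order]
    return SequenceDistribution(ell=ell, codes=codes, probs=vecs.sum(axis=1))


def transient_length(
    strategy,
    params: TaskParams = DEFAULT_PARAMS,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> int:
    """Steps until the worst-case point initialization reaches the steady
    state within L1 distance ``tol``; the scale is ~1/h."""
    t = joint_transition(strategy, params)
    target = steady_state(strategy, params).flat
    n = t.shape[0]
    worst = 0
    for j in range(n):
        p = np.zeros(n)
        p[j] = 1.0
        steps = 0
        while float(np.abs(p - target).sum()) >= tol:
            p = t @ p
            steps += 1
            if steps > max_iter:
                raise RuntimeError("transient did not dissipate")
        worst = max(worst, steps)
    return worst
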