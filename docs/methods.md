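# Methods

## Task model

The environment is a nonstationary two-armed bandit. A hidden binary
world state s ∈ {−1, +1} identifies the better port and flips with
hazard rate h per step (units: probability per step). Action a ∈ {−1, +1}
earns reward o = +1 with probability p(o|s,a) = ½(1 + o(s·a·Δp + Δp̄)).
The three parameters, with defaults:

| parameter | meaning | default | note |
|---|---|---|---|
| p̄ (`mean_reward`) | baseline reward probability (p_high + p_low)/2 | 0.3 | random-policy reward rate |
| Δp (`contrast`) | p_high − p_low | −0.5 | sign kept literally; see below |
| h (`hazard`) | world switch probability per step | 0.05 | accepted range [0.05, 0.5]; outside values need an explicit override |

These defaults produce effective per-arm reward probabilities
{0.05, 0.55} and a wide gap between the 2-state benchmark (WSLG, reward
rate 0.3827) and the unconstrained Bayesian bound (0.4511), which is
what makes a rich space of intermediate strategies possible; at h = 0.5
every strategy collapses to the baseline rate p̄.

**Sign convention.** With Δp < 0 the *anti-aligned* action is the
rewarding one, so the greedy policy on the belief u is
a* = sgn(u·Δp), not sgn(u); the task is identical to the Δp > 0 task
under a relabeling of s, and every ensemble-level result is invariant to
the choice. We keep Δp = −0.5 literally, let value iteration produce the
argmax policy, and check the familiar a* = sgn(u) identity at a Δp > 0
parameterization in the tests.

## Ideal observer and optimal policy

The belief u = p(s=+1|·) − p(s=−1|·) follows the closed-form filter
U(u,a,o) that composes the Bayes posterior update with one hazard-mixing
step; it contracts [−1,1] into [−(1−2h), 1−2h] and agrees with an
explicitly written two-state HMM predict-update to 1e−12 (tested).

The optimal policy is solved by value iteration over a uniform belief
grid (default 200 bins; bin k of n has center −1 + (2k+1)/n, so even n
leaves no center at exactly 0 and the greedy sign is always defined).
The sweep uses a running-average weighting r/(t+1) + t·v/(t+1), which
makes every bin's value converge to the long-run reward rate. The value
residual decays like 1/t²; we stop at sup-norm change < 1e−10 (reached
in ~5×10⁴ sweeps at the defaults) or at the sweep cap, which counts as
normal termination only if the greedy policy has been stable for a long
tail, and raises otherwise. The reported reward rate is *not* read off
v: it is recomputed exactly by steady-state propagation of the chain the
greedy policy induces on the grid.

The fixed-point belief under continual winning, u_ub, is found by
damped fixed-point iteration of the winning update from u = 0 at 1e−12
tolerance; the closed-form root of the induced quadratic serves as a
test oracle, not as the primary path.

## Programs and the rule-out rules

A program is a deterministic Moore machine: M states labeled by action,
one total transition map per outcome. Canonical identity is the
lexicographically minimal (labels, t_lose, t_win) encoding over all M!
state permutations × optional global action inversion (≤ 2·M! candidate
encodings; cheap at M ≤ 5, cached).

Validity applies the remaining rules in increasing order of cost:

* **sinks/drains** — the union digraph over both outcome maps must be
  one strongly connected component. This subsumes both absorbing subsets
  and transient states and guarantees a unique stationary support.
* **merger states** — the machine must be Moore-minimal (partition
  refinement from the action-label partition). Non-minimal machines
  replicate a smaller program's behavior exactly.
* **periodicity** — the joint (s, m) chain built with the task
  parameters must be aperiodic. We compute the period as the gcd of BFS
  level defects on the support digraph of that chain. For any h ∈
  (0, 0.5] and generic reward probabilities the support is the full
  product of the s- and m-supports, so this verdict coincides with the
  period of the union digraph; we nevertheless check the task-coupled
  chain, since its occupancy is what must converge.

Enumeration order: all M^(2M) transition arrangements are generated in
batches and pre-filtered for strong connectivity with vectorized boolean
matrix squaring (label-independent, removes most of the space); the
unique label sets per size — (−+), (−++), (−+++), (−−++), (−++++),
(−−+++) — are then attached (inversion symmetry halves the labelings;
uniform labelings are merger-reducible); then the merger filter, the
canonical dedup, and last the periodicity filter on the small survivor
set. Counts: 5 (M=2), 124 (M=3), 4979 (M=4), each in seconds to tens of
seconds on one core; M = 5 streams 9.8M arrangements in batches with an
optional resume checkpoint (hours on one core) and is not exercised in
the test suite.

**Merger expansion** (the merger rule in reverse) generates all
size-(M+1) machines that minimize back to a given program, by splitting
one state at a time: the copy inherits label and out-behavior (self-loop
targets may go to either copy), in-edges distribute over the copies in
all 2^k ways, and candidates are kept when strongly connected and
behavior-equivalent. Structural distance across sizes is the minimum
same-size distance over these expansions; same-size distance is the
minimum label+transition mismatch over the symmetry group. A mutation is
one unit of this distance: one relabeled state or one redirected
transition.

## Exact evaluation

**Steady state (BDP).** The joint distribution over (s, m) — 2M points —
is propagated by the exact one-step operator (reward delivery given
(s, a), deterministic internal transition on o, hazard switch of s) from
uniform initialization until the L1 change is below 1e−12. The fixed
point equals the leading eigenvector of the joint operator; the
eigendecomposition is kept as an independent oracle and the two agree to
1e−9 on 100 random programs per size in the tests. Reward rate:
⟨R⟩ = Σ p(o=+1|s,a_m)·p(s,m). "Good" means a rate strictly above WSLG's;
ties at machine precision resolve to not-good. "Low-performing" means
strictly below p̄.

**Sequence distributions (SDP).** Behavioral strings use the alphabet
W/L/w/l; the symbol at position t pairs the outcome at t with the
stay/go relation between the actions at t and t+1 (the other alignment
convention would shift all results consistently and leaves every
classification invariant). Starting from the stationary joint
distribution, the conditional (s, m) vector branches over the four
symbol-resolved operators level by level, merging equal prefixes; only
nonzero branches are materialized, so the support is at most M·2^ℓ
rather than 4^ℓ, and prefix marginalization consistency holds by
construction. Merger expansions and globally inverted programs produce
identical distributions to 1e−10 (tested).

**Monte Carlo.** The trajectory simulator is the generative counterpart
used as an oracle: empirical reward rates and sequence frequencies from
10⁶-step rollouts agree with BDP/SDP within three batch-means standard
errors. It emulates exactly the binary-world, binary-outcome dynamics
above — no reward magnitude, no action noise, no parameter drift — so
agreement validates the propagation algebra, not any claim about richer
real-world foraging data.

## Structurally Bayesian programs

Discretizations split [−α·u_ub, +α·u_ub] into M equal bins (α ∈ (0,1]),
label each bin with the greedy action at its center, and round the
belief update to the nearest bin; when the update falls strictly between
two centers, next-nearest variants are enumerated per (state, outcome)
cell, and exact midpoints break toward the confidence-decreasing bin.
All combinations over M = 2..M_max, an α grid (default 0.05..1.00 step
0.05; the deduplicated set is checked to saturate under grid doubling),
and the rounding variants are rule-out filtered and canonically
deduplicated. At the defaults the 2-state nearest-rounding
discretization is WSLG for α below ≈0.8; for larger α the lose-update no
longer leaves the bin and the machine is rejected as never-transitioning.
Fine discretizations (e.g. 30 states) legitimately carry transient outer
bins and merger-reducible bins; they bypass the validity filter and
evaluate on their recurrent class, landing within 1% of the 200-bin
optimal rate.

## Embeddings, GPN, key/sloppy mutations

The mutation graph connects ensemble members at structural distance 1
(cross-size edges go through merger expansions). The performance tree
walks the canonical ensemble order (size ascending, rate descending, id
ascending — this order also defines program indices) and attaches each
program to the smallest, then highest-performing, already-placed
neighbor; WSLG is the root; unattachable programs become extra roots and
are counted, not dropped. Embedding smoothness is scored per edge as the
parent-child attribute difference over the ensemble-wide standard
deviation; on the M ≤ 3 ensemble the performance embedding is measurably
smoother in performance than in wiring length (the minimal summed
transition distance over state orderings), as expected.

The GPN augments the good set with subthreshold connectors until one
mutation-connected component remains. The selection rule here — greedily
add the highest-performing non-member that merges two or more
components, falling back to shortest bridging paths — is this package's
reconstruction; the reference connector set is not derivable from a
stated rule, so connector counts are procedure-sensitive and the
procedure is isolated behind `build_gpn` for replacement.

The behavioral tree uses total similarity B_ij = Σ_ℓ B^ℓ_ij over
ℓ = 1..10, where B^ℓ marks, per program i, the top round(1/C^ℓ_ii) most
confusable partners (self excluded — including self would saturate the
score; the empirical minimum of B is reported rather than assumed ≥ 1).
Children attach to the most similar, then smallest, then
highest-performing placed parent of size ≤ their own; edges at the
maximal B are sloppy mutations, the rest key. With a constant similarity
matrix the construction reduces exactly to the performance rule
(tested).

## Distinguishability, subgroups, motifs

C*_GPN is the half-mass split of descending-sorted self-confusability at
ℓ = 10 (low-performing connectors excluded from the threshold
computation but kept in the normalization); C*_SB is the maximal
self-confusability of structurally Bayesian programs against their own
ensemble after dropping the most extreme member under each of the two
diagnostics (the reference excludes two named outliers whose identities
are not portable across sorts). A non-member scored against a reference
ensemble is normalized within reference-plus-itself, keeping the
diagonal in (0, 1]. Subgroups: Louvain communities on the symmetrized
confusion graph, resolution 1.0, ten seeded restarts, best modularity
kept.

Motif candidates of a program are subsequences (length < 10) all of
whose cyclic rotations tile (truncated to exactly length 10 — printed
9-symbol tilings elsewhere are treated as a typo) into sequences inside
the program's top-95% distinguishability mass, and which traverse a
stable action-outcome loop (the one-pass state map has a cycle). The
greedy decomposition processes candidates shortest-first (ties: tiled
probability descending, then lexicographic in W<L<w<l), admits a motif
only when windows of its cyclic tiling (length ≥ the motif) cover
not-yet-explained positions, and reports incremental explained
fractions; a program's motif set is the union over the sequences
carrying half of its total distinguishability. Motif prevalence,
argmax-group assignment, and specificity 1 + Σ p log p / log n_groups
follow directly.

## Evolutionary search

Deterministic by design — the reference procedure has no stochastic
step: each generation promotes the top max(1, round(ln N_idle)) idle
programs (ties: rate descending, then id) to morph at the *start* of the
generation (so a zero-generation run leaves all seeds idle), takes all
single mutations of the morph set including mutations through merger
expansions one size up, rule-out filters and deduplicates them against
the reservoir, evaluates the newcomers, hibernates them, and freezes the
parents. Seeded with the two best 2-state programs and capped at
4 states, 16 generations recover all 78 good M ≤ 4 programs while
evaluating 15.5% of the 5108-program space.

## Scales exercised

The test suite and the acceptance script run desk-scale configurations
chosen to exercise every code path exactly as the full-scale analyses
do: enumeration through M = 4, behavioral analyses (similarity, trees,
thresholds, subgroups, motifs) on the M ≤ 3 ensemble of 129 programs,
search at M ≤ 4. The M = 5 census and the full-ensemble behavioral
statistics use the identical entry points with larger arguments and
multi-hour runtimes on one core.

## Known limitations

* Two actions, two outcomes, symmetric hazard only; no stochastic
  (probabilistic-transition) programs; no discounted or finite-horizon
  objectives.
* Connector selection in the GPN and the outlier rule in C*_SB are
  reconstructions of under-specified procedures; counts that depend on
  them are reported alongside the procedure rather than asserted.
* Sequence lengths are capped at 10; enumeration beyond M = 5 is
  combinatorially out of reach and refused by default.
* Louvain subgroup counts are seed-dependent within a small range; the
  partition with the best modularity over ten restarts is kept and the
  seed recorded.
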