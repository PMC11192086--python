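"""Behavioral distinguishability, subgroups, and functional motifs.

The behavioral repertoire of a program is its steady-state distribution
over length-l strings of outcome-action symbols (W win-stay, L lose-stay,
w win-go, l lose-go).  Within a reference ensemble {P}, the confusion
matrix

    C_ij = sum_seq  p(seq|i) p(seq|j) / sum_{i'} p(seq|i')

gives the probability of mistaking program j for program i from one
sequence; its diagonal measures how *distinguishable* each program is.
From the confusion matrices at l = 1..10 a binary similarity score
B_ij in [0, 10] is accumulated, which drives the behavioral tree
embedding and the key/sloppy classification of mutations.

Motifs are short subsequences that tile (with all their cyclic rotations)
into high-distinguishability sequences and traverse a stable
action-outcome loop through the program; a greedy shortest-first
decomposition expresses each distinguishable sequence as a combination of
motifs.  Motif prevalence across behavioral subgroups, the subgroup
assignment, and a categorical-entropy specificity summarize how motifs
mark out lineages of programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

from .evaluation import ALPHABET, SequenceDistribution

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "confusion_diag_wrt",
    "behavioral_similarity",
    "distinguishability_thresholds",
    "cluster_subgroups",
    "sequence_distinguishability",
    "top_mass_codes",
    "candidate_motifs",
    "decompose_sequence",
    "program_motifs",
    "MotifSet",
    "motif_statistics",
    "canonical_rotation",
]


def _stack(dists: list[SequenceDistribution]) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse matrix S[i, k] = p(seq k | program i) over the union support."""
    all_codes = np.unique(np.concatenate([d.codes for d in dists]))
    rows, cols, vals = [], [], []
    for i, d in enumerate(dists):
        pos = np.searchsorted(all_codes, d.codes)
        rows.append(np.full(len(d.codes), i))
        cols.append(pos)
        vals.append(d.probs)
    s = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(dists), len(all_codes)),
    )
    return s, all_codes


@dataclass
class ConfusionMatrix:
    """Pairwise confusability within an ensemble at one sequence length.

    Columns sum to 1; ``top_counts`` gives n_i = round(1 / C_ii), the
    number of programs one would plausibly confuse with program i.
    """

    ell: int
    ids: list[str]
    matrix: np.ndarray

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def top_counts(self) -> np.ndarray:
        return np.round(1.0 / self.diagonal).astype(int)


def confusion_matrix(
    dists: list[SequenceDistribution], ids: list[str] | None = None
) -> ConfusionMatrix:
    """C_ij = p(prog i | prog j) from the length-l sequence distributions
    of an ensemble; sequences unsupported by every program contribute 0."""
    ell = dists[0].ell
    if any(d.ell != ell for d in dists):
        raise ValueError("all distributions must share one length")
    s, _ = _stack(dists)
    denom = np.asarray(s.sum(axis=0)).ravel()
    denom[denom == 0.0] = np.inf
    weighted = s.multiply(1.0 / denom)
    c = np.asarray((s @ weighted.T).todense())
    if ids is None:
        ids = [str(i) for i in range(len(dists))]
    return ConfusionMatrix(ell=ell, ids=list(ids), matrix=c)


def confusion_diag_wrt(
    dists: list[SequenceDistribution],
    ref_mask: np.ndarray,
) -> np.ndarray:
    """Self-confusability C_ii of every program measured against the
    reference subensemble ``ref_mask``.

    For members of the reference the normalization is the reference
    ensemble itself; a non-member is scored within reference + itself
    (keeping C_ii in (0, 1]).
    """
    s, _ = _stack(dists)
    ref = np.flatnonzero(np.asarray(ref_mask))
    denom_ref = np.asarray(s[ref].sum(axis=0)).ravel()
    out = np.empty(s.shape[0])
    for i in range(s.shape[0]):
        row = s.getrow(i)
        idx = row.indices
        p = row.data
        den = denom_ref[idx] + (0.0 if ref_mask[i] else p)
        good = den > 0
        out[i] = float(np.sum(p[good] ** 2 / den[good]))
    return out


def behavioral_similarity(
    dists_by_ell: dict[int, list[SequenceDistribution]],
    ids: list[str] | None = None,
) -> np.ndarray:
    """Total behavioral similarity B_ij = sum over lengths of the binary
    top-confusability indicators.

    For each length l, program j scores a point toward B_ij when j is
    among the top n_i = round(1/C_ii) programs most easily confused with
    i (self excluded; ties by index order).  B_ij is in [0, max length].
    """
    lengths = sorted(dists_by_ell)
    n = len(dists_by_ell[lengths[0]])
    b = np.zeros((n, n), dtype=int)
    for ell in lengths:
        cm = confusion_matrix(dists_by_ell[ell], ids)
        c = cm.matrix.copy()
        np.fill_diagonal(c, -np.inf)
        counts = cm.top_counts
        for i in range(n):
            k = min(max(int(counts[i]), 0), n - 1)
            if k <= 0:
                continue
            top = np.argsort(-c[i], kind="stable")[:k]
            b[i, top] += 1
    return b


@dataclass
class DistinguishabilityLabels:
    c_star_gpn: float
    c_star_sb: float
    diag_gpn: np.ndarray
    diag_sb: np.ndarray
    globally_distinguishable: np.ndarray
    behaviorally_bayesian: np.ndarray
    excluded_outliers: list[int]


def distinguishability_thresholds(
    dists: list[SequenceDistribution],
    sb_mask: np.ndarray,
    exclude_mask: np.ndarray | None = None,
    n_outliers: int = 2,
) -> DistinguishabilityLabels:
    """Distinguishability thresholds and behavioral labels for a GPN.

    ``C*_GPN`` is the half-mass split of the descending-sorted
    self-confusability within the full ensemble (programs in
    ``exclude_mask`` — the low-performing connectors — are left out of
    the threshold computation, though they stay in the normalization).
    ``C*_SB`` is the largest structurally-Bayesian self-confusability
    against the SB subensemble after dropping the most extreme SB program
    under each of the two diagnostics.
    """
    n = len(dists)
    sb_mask = np.asarray(sb_mask, dtype=bool)
    exclude_mask = (
        np.zeros(n, dtype=bool) if exclude_mask is None else np.asarray(exclude_mask)
    )
    diag_gpn = confusion_diag_wrt(dists, np.ones(n, dtype=bool))
    diag_sb = confusion_diag_wrt(dists, sb_mask)

    considered = np.flatnonzero(~exclude_mask)
    vals = diag_gpn[considered]
    order = np.argsort(-vals, kind="stable")
    cum = np.cumsum(vals[order])
    half = cum[-1] / 2.0
    cut = int(np.searchsorted(cum, half))
    c_star_gpn = float(vals[order[min(cut, len(order) - 1)]])

    sb_idx = np.flatnonzero(sb_mask)
    outliers: list[int] = []
    if len(sb_idx) > n_outliers:
        o1 = int(sb_idx[np.argmax(diag_gpn[sb_idx])])
        outliers.append(o1)
        rest = np.array([i for i in sb_idx if i not in outliers])
        o2 = int(rest[np.argmax(diag_sb[rest])])
        if o2 not in outliers:
            outliers.append(o2)
        keep = np.array([i for i in sb_idx if i not in outliers])
    else:
        keep = sb_idx
    c_star_sb = float(diag_sb[keep].max()) if len(keep) else float("nan")

    return DistinguishabilityLabels(
        c_star_gpn=c_star_gpn,
        c_star_sb=c_star_sb,
        diag_gpn=diag_gpn,
        diag_sb=diag_sb,
        globally_distinguishable=diag_gpn >= c_star_gpn,
        behaviorally_bayesian=diag_sb < c_star_sb,
        excluded_outliers=outliers,
    )


def cluster_subgroups(
    confusion: np.ndarray,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 10,
) -> np.ndarray:
    """Louvain communities on the symmetrized confusion-similarity graph.

    Runs several seeded restarts and keeps the partition with the best
    modularity; returns a community label per program.
    """
    w = (confusion + confusion.T) / 2.0
    np.fill_diagonal(w, 0.0)
    g = nx.from_numpy_array(w)
    best = None
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed + r
        )
        q = nx.community.modularity(g, comms, weight="weight")
        if best is None or q > best[0]:
            best = (q, comms)
    labels = np.empty(len(w), dtype=int)
    for k, comm in enumerate(sorted(best[1], key=lambda c: (-len(c), min(c)))):
        for i in comm:
            labels[i] = k
    return labels


# ---------------------------------------------------------------------------
# sequence distinguishability and motifs


def sequence_distinguishability(
    dists: list[SequenceDistribution],
) -> list[dict[int, float]]:
    """Per (program, sequence) distinguishability
    C_ii^{seq k} = p(seq k | i)^2 / sum_{i'} p(seq k | i'),
    returned as one {code: value} map per program."""
    s, codes = _stack(dists)
    denom = np.asarray(s.sum(axis=0)).ravel()
    out = []
    for i in range(s.shape[0]):
        row = s.getrow(i)
        vals = row.data**2 / denom[row.indices]
        out.append({int(codes[j]): float(v) for j, v in zip(row.indices, vals)})
    return out


def top_mass_codes(values: dict[int, float], frac: float) -> set[int]:
    """Codes in descending value order until ``frac`` of the summed value
    is accounted for (the half- and 95%-mass constructions)."""
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(v for _, v in items)
    if total <= 0:
        return set()
    out: set[int] = set()
    acc = 0.0
    for code, v in items:
        out.add(code)
        acc += v
        if acc >= frac * total:
            break
    return out


def _tile(motif: str, length: int) -> str:
    reps = -(-length // len(motif))
    return (motif * reps)[:length]


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def canonical_rotation(motif: str) -> str:
    """Representative of a motif's rotation class: the rotation minimal
    under the symbol order W < L < w < l."""
    key = {ch: i for i, ch in enumerate(ALPHABET)}
    return min(_rotations(motif), key=lambda r: [key[ch] for ch in r])


def _stable_loop(program, motif: str) -> bool:
    """A motif must, repeated in succession, traverse a closed
    action-outcome loop: the one-pass state map must contain a cycle."""
    m = program.size
    sym_o = {"W": +1, "L": -1, "w": +1, "l": -1}
    sym_go = {"W": False, "L": False, "w": True, "l": True}

    def one_pass(state: int) -> int | None:
        for ch in motif:
            nxt = program.transition(state, sym_o[ch])
            go = program.labels[nxt] != program.labels[state]
            if go != sym_go[ch]:
                return None
            state = nxt
        return state

    for start in range(m):
        seen = []
        state = start
        while state is not None and state not in seen:
            seen.append(state)
            state = one_pass(state)
        if state is not None:  # revisited: a cycle exists
            return True
    return False


def candidate_motifs(
    program,
    seq_dist: SequenceDistribution,
    distinguishability: dict[int, float],
    mass: float = 0.95,
    ell: int = 10,
) -> list[str]:
    """Candidate motifs of a program: subsequences (length < ell) whose
    every cyclic rotation tiles into a sequence inside the program's top
    ``mass`` distinguishability set, and which traverse a stable loop.

    Returned sorted for the greedy decomposition: length ascending, then
    tiled steady-state probability descending, then lexicographic (symbol
    order W < L < w < l).
    """
    top = top_mass_codes(distinguishability, mass)
    top_strings = {seq_dist.decode(c) for c in top}
    found: dict[str, float] = {}
    for seq in top_strings:
        for k in range(1, ell):
            motif = seq[:k]
            if _tile(motif, ell) != seq:
                continue
            rep = canonical_rotation(motif)
            if rep in found:
                continue
            rots = _rotations(motif)
            if not all(_tile(r, ell) in top_strings for r in rots):
                continue
            if not _stable_loop(program, motif):
                continue
            freq = sum(seq_dist.prob(_tile(r, ell)) for r in set(rots))
            found[rep] = freq
    key = {ch: i for i, ch in enumerate(ALPHABET)}
    return sorted(
        found, key=lambda mo: (len(mo), -found[mo], [key[ch] for ch in mo])
    )


def _coverage(seq: str, motif: str) -> set[int]:
    """Positions of ``seq`` covered by substrings (length >= the motif
    length) that occur as windows of the motif's cyclic tiling."""
    n, k = len(seq), len(motif)
    window_src = _tile(motif, n + 2 * k)
    covered: set[int] = set()
    for i in range(n):
        run = 0
        for j in range(i, n):
            if seq[i : j + 1] in window_src:
                run = j - i + 1
            else:
                break
        if run >= k:
            covered.update(range(i, i + run))
    return covered


def decompose_sequence(
    seq: str, candidates: list[str]
) -> list[tuple[str, float]]:
    """Greedy decomposition of a behavioral sequence into motifs.

    Candidates are taken in the given order (shortest first by
    convention); each is admitted only if it explains positions not yet
    covered, and contributes its incremental explained fraction.  Any
    unexplained residue simply leaves the fractions summing below 1.
    """
    explained: set[int] = set()
    out: list[tuple[str, float]] = []
    for motif in candidates:
        cover = _coverage(seq, motif)
        new = cover - explained
        if new:
            out.append((motif, len(new) / len(seq)))
            explained |= cover
    return out


@dataclass
class MotifSet:
    """Minimal motif description of one program's distinguishable behavior."""

    program_id: str
    motifs: list[str]
    candidates: list[str]
    explained: dict[str, float] = field(default_factory=dict)  # seq -> fraction


def program_motifs(
    program,
    seq_dist: SequenceDistribution,
    distinguishability: dict[int, float],
    ell: int = 10,
) -> MotifSet:
    """The smallest greedy motif set accounting for the sequences that
    carry half of the program's total distinguishability."""
    cands = candidate_motifs(program, seq_dist, distinguishability, ell=ell)
    half = top_mass_codes(distinguishability, 0.5)
    used: list[str] = []
    explained: dict[str, float] = {}
    for code in sorted(half, key=lambda c: -distinguishability[c]):
        seq = seq_dist.decode(code)
        parts = decompose_sequence(seq, cands)
        explained[seq] = sum(f for _, f in parts)
        for motif, _ in parts:
            if motif not in used:
                used.append(motif)
    return MotifSet(
        program_id=getattr(program, "canonical_id", ""),
        motifs=used,
        candidates=cands,
        explained=explained,
    )


def motif_statistics(
    motif_sets: list[MotifSet], subgroups: np.ndarray
) -> dict[str, dict]:
    """Prevalence, subgroup assignment, and specificity per motif.

    prevalence(motif, group) is the fraction of the group's programs
    expressing the motif; the motif is assigned to its argmax group; and
    specificity = 1 + sum_k p_k log p_k / log n_groups maps uniform
    prevalence to 0 and single-group motifs to 1.
    """
    subgroups = np.asarray(subgroups)
    groups = np.unique(subgroups)
    n_groups = len(groups)
    all_motifs = sorted({m for ms in motif_sets for m in ms.motifs})
    stats: dict[str, dict] = {}
    for motif in all_motifs:
        prev = {}
        for g in groups:
            members = [ms for ms, sg in zip(motif_sets, subgroups) if sg == g]
            prev[int(g)] = (
                sum(1 for ms in members if motif in ms.motifs) / len(members)
                if members
                else 0.0
            )
        total = sum(prev.values())
        if total > 0 and n_groups > 1:
            p = np.array([v / total for v in prev.values()])
            nz = p[p > 0]
            specificity = 1.0 + float(np.sum(nz * np.log(nz))) / np.log(n_groups)
        else:
            specificity = 1.0
        assigned = max(prev, key=lambda g: (prev[g], -g))
        stats[motif] = {
            "prevalence": prev,
            "group": assigned,
            "specificity": specificity,
        }
    return stats
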