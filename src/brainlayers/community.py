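"""Multilayer modularity and community detection.

The quality function is the standard multilayer modularity for layered
networks with diagonal interlayer coupling (Mucha-style):

    Q = (1/2μ) Σ_{ijlk} [ (Ã_{l,ij} − γ_l s_{il} s_{jl} / (2 m_l)) δ_{lk}
                          + δ_{ij} c ] δ(g_{il}, g_{jk})

with s_{il} the within-layer strength of node i in layer l, 2m_l the total
weight of layer l, and 2μ the total weight of the whole supra-adjacency
(within-layer plus interlayer coupling). Optimization is a generalized
Louvain: greedy single-node moves over the supra-modularity matrix with
randomized sweep order, followed by graph aggregation, iterated to a local
maximum; repeated runs differ only in sweep order.

Group-level structure is summarized through agreement (consensus) matrices —
the proportion of partitions in which two nodes share a community — and an
iterative consensus partition that re-clusters the agreement matrix until all
runs coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .mlnet import MultilayerNetwork

__all__ = [
    "Partition",
    "ModularityResult",
    "AgreementMatrix",
    "ConsensusError",
    "supra_modularity_matrix",
    "multilayer_modularity",
    "genlouvain",
    "louvain_single",
    "agreement_per_layer",
    "collapse_agreement",
    "consensus_partition",
    "module_frequency_across_c",
    "ModuleFrequencies",
]

_MIN_GAIN = 1e-10


@dataclass
class Partition:
    """Community assignment of every (node, layer) pair.

    ``assignment`` has shape (n_layers, n_nodes) with community indices
    contiguous from 1.
    """

    assignment: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim == 1:
            a = a[None, :]
        if a.ndim != 2:
            raise ValueError("assignment must be (n_layers, n_nodes)")
        labels = np.unique(a)
        if labels.size and (labels[0] != 1 or not np.array_equal(labels, np.arange(1, labels.size + 1))):
            raise ValueError("community indices must be contiguous from 1")
        self.assignment = a

    @property
    def n_layers(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.assignment.shape[1]

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max(initial=0))

    def flat(self) -> np.ndarray:
        """Labels in node-layer order (layer-major), 1-based."""
        return self.assignment.reshape(-1)


def relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary integer labels to 1..k in order of first appearance."""
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    lut = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([lut[lab] for lab in labels], dtype=int)


@dataclass
class ModularityResult:
    Q: float
    partition: Partition
    gamma: float
    c: float
    run_seed: int


@dataclass
class AgreementMatrix:
    """N×N co-assignment proportions over a set of partitions."""

    values: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("agreement matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("agreement matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("agreement entries must lie in [0, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, 0.0, 1.0)


class ConsensusError(RuntimeError):
    """Consensus clustering failed to stabilize within the iteration cap."""


# ---------------------------------------------------------------------------
# modularity matrix and evaluation
# ---------------------------------------------------------------------------

def supra_modularity_matrix(
    net: MultilayerNetwork, gamma: float = 1.0
) -> tuple[np.ndarray, float]:
    """The fN×fN supra-modularity matrix B and the normalization 2μ.

    Diagonal blocks are Ã_l − γ s_l s_lᵀ/(2m_l) (Newman–Girvan null per
    layer); off-diagonal blocks are the coupling c·I. 2μ is the total weight
    of the supra-adjacency: Σ_l 2m_l + N·f·(f−1)·c.
    """
    n, f, c = net.n_nodes, net.n_layers, net.coupling
    B = np.kron(c * (np.ones((f, f)) - np.eye(f)), np.eye(n))
    two_mu = n * f * (f - 1) * c
    for a, A in enumerate(net.layers):
        k = A.sum(axis=1)
        two_m = k.sum()
        null = np.outer(k, k) / two_m if two_m > 0 else 0.0
        B[a * n : (a + 1) * n, a * n : (a + 1) * n] = A - gamma * null
        two_mu += two_m
    if two_mu <= 0:
        raise ValueError("empty network: total weight is zero")
    return B, float(two_mu)


def _quality(B: np.ndarray, labels: np.ndarray) -> float:
    """Σ_{pq} B_pq δ(g_p, g_q), including the diagonal of B."""
    q = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        q += float(B[np.ix_(idx, idx)].sum())
    return q


def multilayer_modularity(
    net: MultilayerNetwork, partition: Partition, gamma: float = 1.0
) -> float:
    """Evaluate multilayer modularity Q for a given partition."""
    if partition.n_layers != net.n_layers or partition.n_nodes != net.n_nodes:
        raise ValueError(
            f"partition shape {partition.assignment.shape} does not match "
            f"network ({net.n_layers} layers × {net.n_nodes} nodes)"
        )
    B, two_mu = supra_modularity_matrix(net, gamma)
    return _quality(B, partition.flat()) / two_mu


# ---------------------------------------------------------------------------
# Louvain on a (supra-)modularity matrix
# ---------------------------------------------------------------------------

def _one_level(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy node moves on matrix B until no single move gains quality."""
    n = B.shape[0]
    comm = np.arange(n)
    Boff = B.copy()
    np.fill_diagonal(Boff, 0.0)
    improved = True
    while improved:
        improved = False
        for v in rng.permutation(n):
            gains = np.bincount(comm, weights=Boff[v], minlength=n)
            cur = comm[v]
            best = int(np.argmax(gains))
            best_gain = gains[best] - gains[cur]
            if -gains[cur] > best_gain:  # isolating v may beat every merge
                counts = np.bincount(comm, minlength=n)
                empty = np.where(counts == 0)[0]
                if empty.size:
                    best, best_gain = int(empty[0]), -gains[cur]
            if best != cur and best_gain > _MIN_GAIN:
                comm[v] = best
                improved = True
    return comm


def louvain_matrix(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Iterated Louvain (moves + aggregation) on modularity matrix B.

    Returns 0-based community labels for the rows of B. The achieved quality
    is non-decreasing across passes (asserted).
    """
    n0 = B.shape[0]
    mapping = np.arange(n0)
    Bcur = B
    q_prev = _quality(Bcur, np.arange(n0))  # singleton start
    while True:
        loc = _one_level(Bcur, rng)
        uniq, compact = np.unique(loc, return_inverse=True)
        k = uniq.size
        # the aggregated matrix carries lower-level contributions on its
        # diagonal, so qualities are directly comparable across levels
        q_now = _quality(Bcur, loc)
        assert q_now >= q_prev - 1e-9, "Louvain pass decreased quality"
        q_prev = q_now
        if k == Bcur.shape[0]:
            break
        mapping = compact[mapping]
        S = np.zeros((Bcur.shape[0], k))
        S[np.arange(Bcur.shape[0]), compact] = 1.0
        Bcur = S.T @ Bcur @ S
        q_prev = _quality(Bcur, np.arange(k))
    return mapping


def genlouvain(
    net: MultilayerNetwork,
    gamma: float = 1.0,
    n_runs: int = 100,
    seed: int | None = None,
) -> list[ModularityResult]:
    """Repeated generalized-Louvain optimization of multilayer modularity.

    Each run randomizes the node sweep order; results carry the achieved Q
    (consistent with :func:`multilayer_modularity` to machine precision) and
    the per-run seed. Runs are reproducible given *seed*.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n, f = net.n_nodes, net.n_layers
    B, two_mu = supra_modularity_matrix(net, gamma)
    run_seeds = [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n_runs)]
    results: list[ModularityResult] = []
    for rs in run_seeds:
        rng = np.random.default_rng(rs)
        labels = louvain_matrix(B, rng)
        labels = relabel_first_appearance(labels)
        part = Partition(labels.reshape(f, n))
        Q = _quality(B, labels) / two_mu
        results.append(
            ModularityResult(Q=float(Q), partition=part, gamma=gamma, c=net.coupling, run_seed=rs)
        )
    return results


def louvain_single(
    W: np.ndarray, gamma: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Single-layer Newman-modularity Louvain on weight matrix W.

    Returns 1-based, first-appearance-contiguous labels. The diagonal of W is
    ignored.
    """
    rng = np.random.default_rng() if rng is None else rng
    A = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        return np.arange(1, A.shape[0] + 1)
    B = A - gamma * np.outer(k, k) / two_m
    return relabel_first_appearance(louvain_matrix(B, rng))


# ---------------------------------------------------------------------------
# agreement and consensus
# ---------------------------------------------------------------------------

def agreement_per_layer(partitions: list[Partition]) -> list[AgreementMatrix]:
    """Per-layer co-assignment proportions across partitions.

    Entry (i, j) of layer l's matrix is the fraction of partitions in which
    nodes i and j share a community in layer l.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    f, n = partitions[0].n_layers, partitions[0].n_nodes
    for p in partitions:
        if (p.n_layers, p.n_nodes) != (f, n):
            raise ValueError("all partitions must share (n_layers, n_nodes)")
    out = []
    for l in range(f):
        acc = np.zeros((n, n))
        for p in partitions:
            lab = p.assignment[l]
            acc += (lab[:, None] == lab[None, :]).astype(float)
        out.append(AgreementMatrix(values=acc / len(partitions), n_samples=len(partitions)))
    return out


def collapse_agreement(per_layer: list[AgreementMatrix]) -> AgreementMatrix:
    """Element-wise mean of the per-layer agreement matrices."""
    if not per_layer:
        raise ValueError("need at least one agreement matrix")
    n = per_layer[0].values.shape[0]
    if any(m.values.shape[0] != n for m in per_layer):
        raise ValueError("agreement matrices must share N")
    mean = np.mean([m.values for m in per_layer], axis=0)
    return AgreementMatrix(values=mean, n_samples=per_layer[0].n_samples)


def consensus_partition(
    agreement: AgreementMatrix,
    n_runs: int = 100,
    seed: int | None = None,
    max_iter: int = 50,
    gamma: float = 1.0,
) -> Partition:
    """Iterative consensus clustering of an agreement matrix.

    Repeats: run single-layer Louvain *n_runs* times on the current matrix;
    if all runs return the identical partition (after canonical relabeling)
    stop, otherwise rebuild the agreement matrix from those runs and repeat.
    """
    W = agreement.values
    base = 0 if seed is None else int(seed)
    arr = np.empty((0, 0))
    for it in range(max_iter):
        seeds_iter = np.random.SeedSequence([base, it]).generate_state(n_runs)
        labels = [louvain_single(W, gamma, np.random.default_rng(int(s))) for s in seeds_iter]
        arr = np.vstack(labels)
        if np.all(arr == arr[0]):
            return Partition(arr[0][None, :])
        W = (arr[:, :, None] == arr[:, None, :]).mean(axis=0)
    n_distinct = len({tuple(row) for row in arr})
    raise ConsensusError(
        f"consensus did not stabilize in {max_iter} iterations "
        f"({n_distinct} distinct partitions in the last round of {n_runs} runs)"
    )


# ---------------------------------------------------------------------------
# module frequency across the coupling sweep
# ---------------------------------------------------------------------------

@dataclass
class ModuleFrequencies:
    """Per-node module frequencies across the interlayer-coupling sweep.

    ``frequencies[i, m]`` is the fraction of c values at which node i carried
    aligned module label m+1. ``final`` is the modal label per node;
    ``flagged`` marks nodes whose modal frequency does not exceed the chance
    level 1/(number of final modules).
    """

    labels: np.ndarray  # aligned module labels, 1..L
    frequencies: np.ndarray  # (n_nodes, L)
    final: np.ndarray  # (n_nodes,)
    flagged: np.ndarray  # (n_nodes,) bool
    chance_level: float
    c_values: np.ndarray = field(default_factory=lambda: np.array([]))


def _align_labels(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Relabel `other` to maximize overlap with `ref` (Hungarian matching)."""
    ref_labs = np.unique(ref)
    oth_labs = np.unique(other)
    M = np.zeros((oth_labs.size, ref_labs.size))
    for a, la in enumerate(oth_labs):
        for b, lb in enumerate(ref_labs):
            M[a, b] = np.sum((other == la) & (ref == lb))
    rows, cols = linear_sum_assignment(-M)
    lut = {}
    for r, ccol in zip(rows, cols):
        lut[oth_labs[r]] = ref_labs[ccol]
    nxt = int(ref_labs.max()) + 1
    for la in oth_labs:
        if la not in lut:
            lut[la] = nxt
            nxt += 1
    return np.array([lut[x] for x in other], dtype=int)


def module_frequency_across_c(
    consensus_by_c: dict[float, Partition]
) -> ModuleFrequencies:
    """Align consensus partitions across c and tabulate per-node frequencies.

    Labels are matched to the partition at the median c by maximum overlap;
    the final assignment is each node's modal aligned label, flagged when its
    frequency does not exceed 1/(final module count).
    """
    if not consensus_by_c:
        raise ValueError("need at least one c value")
    cs = np.array(sorted(consensus_by_c))
    parts = [consensus_by_c[c].assignment.reshape(-1) for c in cs]
    n = parts[0].size
    ref = parts[(len(cs) - 1) // 2]
    aligned = np.vstack([_align_labels(ref, p) for p in parts])
    labs = np.unique(aligned)
    freq = np.zeros((n, labs.size))
    for m, lab in enumerate(labs):
        freq[:, m] = (aligned == lab).mean(axis=0)
    final = labs[np.argmax(freq, axis=1)]
    chance = 1.0 / np.unique(final).size
    modal_freq = freq.max(axis=1)
    flagged = modal_freq <= chance + 1e-12
    return ModuleFrequencies(
        labels=labs,
        frequencies=freq,
        final=final,
        flagged=flagged,
        chance_level=chance,
        c_values=cs,
    )
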