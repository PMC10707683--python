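"""Consensus-weighted modularity maximization (two-round weight-matrix
filtering of the adjacency matrix) and the thresholded-association baseline.

Every stochastic stage draws from one root seed through
``numpy.random.SeedSequence.spawn`` so a full run is exactly reproducible:
child 0 seeds the pool runs, child 1 the subset selections, child 2 the
second-round runs, child 3 the final run (and, for the baseline, child 1
seeds the label-permutation null and child 2 the final run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Partition, PartitionEnsemble, WeightedNetwork
from .modularity import ModularityConfig, louvain_optimize

__all__ = [
    "WMMConfig",
    "association_matrix",
    "build_partition_pool",
    "mean_weight_matrix",
    "filtered_adjacency",
    "wmm",
    "robust_mm",
]


@dataclass
class WMMConfig:
    """Parameters of the two-round consensus filter.

    pool_size L, n_selected M and n_selections K default to the reference
    setting (L=100, M=K=50).
    """

    pool_size: int = 100
    n_selected: int = 50
    n_selections: int = 50
    gamma: float = 1.0
    seed: int | None = None
    max_passes: int = 100

    def __post_init__(self):
        if not (1 <= self.n_selected <= self.pool_size):
            raise ValueError("need 1 <= n_selected <= pool_size")
        if self.n_selections < 1:
            raise ValueError("n_selections must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def association_matrix(partition: Partition,
                       node_order=None) -> np.ndarray:
    """Binary co-assignment indicator T_ij = 1 iff sigma_i = sigma_j.

    Diagonal is 1 (a node is always co-assigned with itself).
    """
    nodes = partition.node_ids if node_order is None else node_order
    labels = partition.aligned_labels(nodes)
    return (labels[:, None] == labels[None, :]).astype(float)


def build_partition_pool(network: WeightedNetwork, pool_size: int,
                         config: ModularityConfig | None = None) -> PartitionEnsemble:
    """Pool of ``pool_size`` independently seeded greedy-optimizer runs."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if config is None:
        config = ModularityConfig()
    children = np.random.SeedSequence(config.seed).spawn(pool_size)
    parts = [
        louvain_optimize(network, ModularityConfig(
            gamma=config.gamma, max_passes=config.max_passes,
            seed=_seed_of(child)))
        for child in children
    ]
    return PartitionEnsemble(parts)


def mean_weight_matrix(ensemble: PartitionEnsemble,
                       indices=None,
                       node_order=None) -> np.ndarray:
    """Elementwise mean of selected binary association matrices.

    Entries are empirical co-assignment probabilities in [0, 1]; diagonal 1.
    """
    if indices is None:
        indices = range(ensemble.size)
    indices = list(indices)
    if not indices:
        raise ValueError("empty selection")
    nodes = ensemble.node_ids if node_order is None else node_order
    n = len(nodes)
    W = np.zeros((n, n))
    for m in indices:
        labels = ensemble[m].aligned_labels(nodes)
        W += labels[:, None] == labels[None, :]
    W /= len(indices)
    return W


def filtered_adjacency(network: WeightedNetwork, W: np.ndarray) -> WeightedNetwork:
    """Hadamard product A' = W * A (elementwise); never increases a weight
    since W <= 1. The null term downstream is recomputed from A' strengths."""
    W = np.asarray(W, dtype=float)
    if W.shape != network.weights.shape:
        raise ValueError(f"weight-matrix shape {W.shape} does not match "
                         f"network shape {network.weights.shape}")
    A = network.weights * W
    np.fill_diagonal(A, 0.0)
    return network.with_weights(A)


def _seed_of(ss: np.random.SeedSequence) -> int:
    # SeedSequence children carry a spawn_key; generate a plain integer seed
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def wmm(network: WeightedNetwork, config: WMMConfig | None = None,
        return_weight_matrix: bool = False):
    """Two-round consensus-filtered modularity maximization.

    Pipeline: pool of L optimizer runs -> K random M-subsets -> K first-round
    weight matrices W_i -> K optimizer runs on W_i * A -> final weight matrix
    W' (mean of those K association matrices) -> final run on A * W'.

    Returns the final Partition, or (Partition, W') when
    ``return_weight_matrix`` is set.
    """
    if config is None:
        config = WMMConfig()
    if network.total_weight <= 0:
        raise ValueError("consensus filtering undefined for an edgeless network")

    root = np.random.SeedSequence(config.seed)
    ss_pool, ss_select, ss_second, ss_final = root.spawn(4)
    L, M, K = config.pool_size, config.n_selected, config.n_selections

    # round 0: partition pool on the raw adjacency matrix
    pool_seeds = ss_pool.spawn(L)
    pool = PartitionEnsemble([
        louvain_optimize(network, ModularityConfig(
            gamma=config.gamma, max_passes=config.max_passes, seed=_seed_of(s)))
        for s in pool_seeds
    ])

    # round 1: K first-round weight matrices and filtered-run partitions
    select_rng = np.random.default_rng(_seed_of(ss_select))
    second_seeds = ss_second.spawn(K)
    nodes = network.node_ids
    n = network.n_nodes
    W_final = np.zeros((n, n))
    for i in range(K):
        chosen = select_rng.choice(L, size=M, replace=False)
        W_i = mean_weight_matrix(pool, chosen, node_order=nodes)
        A_i = filtered_adjacency(network, W_i)
        part_i = louvain_optimize(A_i, ModularityConfig(
            gamma=config.gamma, max_passes=config.max_passes,
            seed=_seed_of(second_seeds[i])))
        labels = part_i.aligned_labels(nodes)
        W_final += labels[:, None] == labels[None, :]
    W_final /= K

    # round 2: final run on the doubly filtered matrix
    A_final = filtered_adjacency(network, W_final)
    part = louvain_optimize(A_final, ModularityConfig(
        gamma=config.gamma, max_passes=config.max_passes,
        seed=_seed_of(ss_final)))
    if return_weight_matrix:
        return part, W_final
    return part


def robust_mm(network: WeightedNetwork, pool_size: int = 100,
              n_null: int = 1000, alpha: float = 0.05,
              config: ModularityConfig | None = None) -> Partition:
    """Optimizer applied to a permutation-thresholded mean association matrix.

    The null distribution permutes each pool partition's labels over nodes
    (community sizes preserved) ``n_null`` times; mean-association entries
    that do not strictly exceed the (1 - alpha) null quantile are zeroed.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if config is None:
        config = ModularityConfig()

    root = np.random.SeedSequence(config.seed)
    ss_pool, ss_null, ss_final = root.spawn(3)
    pool_seeds = ss_pool.spawn(pool_size)
    nodes = network.node_ids
    n = network.n_nodes
    label_mat = np.stack([
        louvain_optimize(network, ModularityConfig(
            gamma=config.gamma, max_passes=config.max_passes,
            seed=_seed_of(s))).aligned_labels(nodes)
        for s in pool_seeds
    ])
    if all(len(np.unique(row)) == n for row in label_mat):
        raise ValueError("degenerate pool: every partition is all-singletons")

    C = np.zeros((n, n))
    for row in label_mat:
        C += row[:, None] == row[None, :]
    C /= pool_size

    # Null: mean association of label-permuted partitions. Entries are
    # multiples of 1/pool_size, so pooled counts give the exact quantile.
    rng = np.random.default_rng(_seed_of(ss_null))
    iu = np.triu_indices(n, k=1)
    counts = np.zeros(pool_size + 1, dtype=np.int64)
    for _ in range(n_null):
        W0 = np.zeros((n, n))
        for row in label_mat:
            perm = rng.permutation(n)
            p = row[perm]
            W0 += p[:, None] == p[None, :]
        vals = np.rint(W0[iu]).astype(np.int64)
        counts += np.bincount(vals, minlength=pool_size + 1)
    total = counts.sum()
    # smallest level q with P(null <= q) >= 1 - alpha
    cum = np.cumsum(counts)
    q_level = int(np.searchsorted(cum, np.ceil((1 - alpha) * total)))
    threshold = q_level / pool_size

    Ct = np.where(C > threshold, C, 0.0)
    np.fill_diagonal(Ct, 0.0)
    thresholded = network.with_weights((Ct + Ct.T) / 2.0)
    if thresholded.total_weight <= 0:
        # nothing survives: no co-assignment beats chance
        return Partition(nodes, np.arange(1, n + 1))
    return louvain_optimize(thresholded, ModularityConfig(
        gamma=config.gamma, max_passes=config.max_passes,
        seed=_seed_of(ss_final)))
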