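"""Modularity objective, strength-preserving null model and a seeded
Louvain-style locally greedy optimizer.

The quality function is used on its unnormalized scale,

    Q = sum_ij [A_ij - gamma * k_i * k_j / 2U] * delta(sigma_i, sigma_j),

summed over all ordered pairs including i = j (A_ii = 0 for user-facing
networks, so only the null term contributes on the diagonal). Dividing by
2U never changes the argmax, so a normalized variant is provided for
display only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # optional JIT for the inner move loop; pure-NumPy fallback below
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False

from .core import Partition, WeightedNetwork

__all__ = [
    "ModularityConfig",
    "ng_null",
    "modularity",
    "normalized_modularity",
    "louvain_optimize",
]

_GAIN_TOL = 1e-12


@dataclass
class ModularityConfig:
    """Knobs for the greedy optimizer.

    gamma : resolution parameter scaling the null term (> 0).
    max_passes : cap on local-move sweeps per aggregation level.
    seed : seeds the node-visit shuffles; same seed => same partition.
    """

    gamma: float = 1.0
    max_passes: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")


def ng_null(network: WeightedNetwork) -> np.ndarray:
    """Expected weights P_ij = k_i k_j / 2U under the strength-preserving
    random null; conserves the total weight: sum_ij P_ij = 2U."""
    two_u = network.total_weight
    if two_u <= 0:
        raise ValueError("null model undefined for a network with no edges")
    k = network.strengths()
    return np.outer(k, k) / two_u


def modularity(network: WeightedNetwork, partition: Partition,
               gamma: float = 1.0) -> float:
    """Unnormalized Q of ``partition`` on ``network``.

    Computed community-wise: Q = sum_c [ A(c,c) - gamma * K_c^2 / 2U ],
    which equals the full double sum over ordered node pairs.
    """
    if set(partition.node_ids) != set(network.node_ids):
        raise ValueError("partition does not cover the network's node set")
    two_u = network.total_weight
    if two_u <= 0:
        raise ValueError("modularity undefined for a network with no edges")
    labels = partition.aligned_labels(network.node_ids)
    _, inv = np.unique(labels, return_inverse=True)
    k = network.strengths()
    n_comm = inv.max() + 1
    k_comm = np.bincount(inv, weights=k, minlength=n_comm)
    a_comm = np.zeros(n_comm)
    for c in range(n_comm):
        idx = np.nonzero(inv == c)[0]
        a_comm[c] = network.weights[np.ix_(idx, idx)].sum()
    return float((a_comm - gamma * k_comm**2 / two_u).sum())


def normalized_modularity(network: WeightedNetwork, partition: Partition,
                          gamma: float = 1.0) -> float:
    """Q / 2U — the conventional [-1, 1]-scale value, for display."""
    return modularity(network, partition, gamma) / network.total_weight


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

def _sweep_python(A, k, two_u, gamma, comm, sigma_tot, order):
    """One pass of greedy single-node moves; returns the move count.

    A node moves only when the best candidate community improves its
    contribution by more than _GAIN_TOL; on ties the current community is
    kept, otherwise the lowest candidate label wins.
    """
    n = len(k)
    n_moved = 0
    for i in order:
        ci = comm[i]
        row = A[i]
        nz = np.nonzero(row)[0]
        links = np.bincount(comm[nz], weights=row[nz], minlength=n)
        links[ci] -= row[i]  # exclude the node's own self-loop
        sigma_tot[ci] -= k[i]
        cand = np.unique(comm[nz])
        if ci not in cand:
            cand = np.append(cand, ci)
        scores = links[cand] - gamma * k[i] * sigma_tot[cand] / two_u
        best = scores.max()
        here = links[ci] - gamma * k[i] * sigma_tot[ci] / two_u
        if best - here > _GAIN_TOL:
            target = int(cand[scores >= best - _GAIN_TOL].min())
        else:
            target = ci
        comm[i] = target
        sigma_tot[target] += k[i]
        if target != ci:
            n_moved += 1
    return n_moved


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _sweep_jit(A, k, two_u, gamma, comm, sigma_tot, order,
                   links, touched):  # pragma: no cover - exercised via wrapper
        n = len(k)
        n_moved = 0
        tol = 1e-12
        for oi in range(n):
            i = order[oi]
            ci = comm[i]
            nt = 0
            for j in range(n):
                w = A[i, j]
                if w != 0.0:
                    c = comm[j]
                    if links[c] == 0.0:
                        touched[nt] = c
                        nt += 1
                    links[c] += w
            links[ci] -= A[i, i]
            sigma_tot[ci] -= k[i]
            here = links[ci] - gamma * k[i] * sigma_tot[ci] / two_u
            best = here
            target = ci
            for t in range(nt):
                c = touched[t]
                s = links[c] - gamma * k[i] * sigma_tot[c] / two_u
                if s - best > tol or (abs(s - best) <= tol and
                                      target != ci and c < target):
                    best = s
                    target = c
            comm[i] = target
            sigma_tot[target] += k[i]
            if target != ci:
                n_moved += 1
            for t in range(nt):
                links[touched[t]] = 0.0
            links[ci] = 0.0
        return n_moved


def _local_moves(A: np.ndarray, k: np.ndarray, two_u: float, gamma: float,
                 comm: np.ndarray, rng: np.random.Generator,
                 max_passes: int) -> bool:
    """Greedy single-node moves until a full sweep makes none.

    ``comm`` is modified in place (labels are indices into sigma_tot).
    """
    n = len(k)
    sigma_tot = np.bincount(comm, weights=k, minlength=n).astype(float)
    if _HAVE_NUMBA:
        links = np.zeros(n)
        touched = np.zeros(n, dtype=np.int64)
    improved = False
    for _ in range(max_passes):
        order = rng.permutation(n)
        if _HAVE_NUMBA:
            n_moved = _sweep_jit(A, k, two_u, gamma, comm, sigma_tot,
                                 order, links, touched)
        else:
            n_moved = _sweep_python(A, k, two_u, gamma, comm, sigma_tot, order)
        if n_moved == 0:
            break
        improved = True
    return improved


def _aggregate(A: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse communities to super-nodes; diagonal carries doubled
    internal weight so strengths and the total weight are preserved."""
    labels, inv = np.unique(comm, return_inverse=True)
    nc = len(labels)
    M = np.zeros((len(comm), nc))
    M[np.arange(len(comm)), inv] = 1.0
    return M.T @ A @ M, inv


def louvain_optimize(network: WeightedNetwork,
                     config: ModularityConfig | None = None) -> Partition:
    """Locally greedy modularity optimization (move phase + aggregation).

    Deterministic given ``config.seed``. Isolated nodes end as singleton
    communities; an edgeless network yields the all-singleton partition.
    """
    if config is None:
        config = ModularityConfig()
    n = network.n_nodes
    if n == 0:
        raise ValueError("empty network")
    if network.total_weight <= 0:
        return Partition(network.node_ids, np.arange(n))

    rng = np.random.default_rng(config.seed)
    A = network.weights.copy()
    two_u = float(A.sum())
    membership = np.arange(n)  # fine-level node -> current community

    while True:
        k = A.sum(axis=1)
        comm = np.arange(A.shape[0])
        _local_moves(A, k, two_u, config.gamma, comm, rng, config.max_passes)
        A, inv = _aggregate(A, comm)
        membership = inv[membership]
        if A.shape[0] == len(comm):  # no merge happened at this level
            break

    # relabel communities 1..n_comm in order of first appearance
    _, inv = np.unique(membership, return_inverse=True)
    order = {}
    final = np.empty(n, dtype=int)
    for i, c in enumerate(inv):
        if c not in order:
            order[c] = len(order) + 1
        final[i] = order[c]
    return Partition(network.node_ids, final)
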