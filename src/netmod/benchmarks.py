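"""Synthetic planted-partition benchmark generators.

The weighted generator emulates the statistical design of LFR-style
benchmarks: power-law degree and community-size sequences, a topological
mixing fraction mu_t (expected share of inter-community degree), node
strengths k^beta split (1 - mu_w) within / mu_w between communities. It is
an emulation targeting the same expected structure, not a port of the
original rewiring loop; wiring is degree-corrected (Chung-Lu style) with
per-community connectivity repair so the zero-mixing limit decomposes
exactly into the planted communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .core import NodeAttributes, Partition, WeightedNetwork

__all__ = [
    "BenchmarkSpec",
    "AttributedBenchmarkSpec",
    "generate_weighted_benchmark",
    "generate_attributed_benchmark",
    "generate_hierarchical_fixture",
    "experiment_grid",
    "DEFAULT_GRID",
]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of one weighted planted-partition network."""

    n_nodes: int
    mean_degree: float
    max_degree: int
    mu_topology: float
    mu_weight: float
    tau1: float = 2.0   # degree-sequence power-law exponent
    tau2: float = 1.0   # community-size power-law exponent
    beta: float = 1.5   # strength = degree ** beta
    seed: int | None = None

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (0 <= self.mu_topology < 1) or not (0 <= self.mu_weight < 1):
            raise ValueError("mixing coefficients must lie in [0, 1)")
        if not (1 <= self.mean_degree <= self.max_degree):
            raise ValueError("need 1 <= mean_degree <= max_degree")
        if self.max_degree >= self.n_nodes:
            raise ValueError("max_degree must be < n_nodes")


@dataclass(frozen=True)
class AttributedBenchmarkSpec(BenchmarkSpec):
    """Unweighted planted-partition network plus Gaussian node attributes."""

    n_attributes: int = 3
    attribute_sd: float = 0.2

    def __post_init__(self):
        super().__post_init__()
        if self.n_attributes < 1:
            raise ValueError("n_attributes must be >= 1")
        if self.attribute_sd <= 0:
            raise ValueError("attribute_sd must be > 0")


# ---------------------------------------------------------------------------
# power-law helpers
# ---------------------------------------------------------------------------

def _plaw_mean(exponent: float, lo: float, hi: float) -> float:
    """Mean of the continuous power law p(x) ~ x^-exponent on [lo, hi]."""
    if lo >= hi:
        return lo
    e = exponent
    if abs(e - 1.0) < 1e-12:
        z = np.log(hi / lo)
        return (hi - lo) / z
    if abs(e - 2.0) < 1e-12:
        z = lo**-1 - hi**-1
        return np.log(hi / lo) / z
    z = (hi**(1 - e) - lo**(1 - e)) / (1 - e)
    m1 = (hi**(2 - e) - lo**(2 - e)) / (2 - e)
    return m1 / z


def _plaw_sample(rng: np.random.Generator, exponent: float, lo: float,
                 hi: float, size: int) -> np.ndarray:
    """Inverse-CDF samples of the truncated continuous power law."""
    u = rng.random(size)
    e = exponent
    if lo >= hi:
        return np.full(size, float(lo))
    if abs(e - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a, b = lo**(1 - e), hi**(1 - e)
    return (a + u * (b - a)) ** (1.0 / (1 - e))


def _degree_sequence(rng: np.random.Generator, spec: BenchmarkSpec) -> np.ndarray:
    """Integer degrees from a truncated power law with the requested mean.

    The lower cutoff is solved by bisection so the continuous law matches
    ``mean_degree``; after rounding, single-unit corrections on random nodes
    pin the realized mean to the target.
    """
    n, hi = spec.n_nodes, float(spec.max_degree)
    target = float(spec.mean_degree)
    lo_a, lo_b = 1.0, hi
    if _plaw_mean(spec.tau1, lo_a, hi) >= target:
        lo = lo_a
    else:
        for _ in range(80):
            mid = 0.5 * (lo_a + lo_b)
            if _plaw_mean(spec.tau1, mid, hi) < target:
                lo_a = mid
            else:
                lo_b = mid
        lo = 0.5 * (lo_a + lo_b)
    deg = np.rint(_plaw_sample(rng, spec.tau1, lo, hi, n)).astype(int)
    deg = np.clip(deg, 1, spec.max_degree)
    # pin the realized total degree to n * target (within one unit)
    want = int(round(n * target))
    guard = 0
    while deg.sum() != want and guard < 10 * n:
        i = rng.integers(n)
        if deg.sum() > want and deg[i] > 1:
            deg[i] -= 1
        elif deg.sum() < want and deg[i] < spec.max_degree:
            deg[i] += 1
        guard += 1
    return deg


def _community_sizes(rng: np.random.Generator, spec: BenchmarkSpec,
                     degrees: np.ndarray) -> np.ndarray:
    """Power-law community sizes covering all nodes.

    Cutoffs sit near the degree-sequence extremes; sampled sizes are
    minimally adjusted so they sum to n and each stays >= the lower cutoff.
    """
    n = spec.n_nodes
    # cutoffs near the degree-sequence extremes; small communities host
    # low-degree nodes (assignment is feasibility-aware), which also
    # preserves the resolution-limit regime where plain optimization
    # merges small communities
    c_min = int(max(2, degrees.min() + 1))
    c_max = int(min(n, degrees.max() + 1))
    if c_max < c_min:
        c_max = c_min
    sizes: list[int] = []
    guard = 0
    while sum(sizes) < n:
        s = int(np.rint(_plaw_sample(rng, spec.tau2, c_min, c_max, 1)[0]))
        sizes.append(int(np.clip(s, c_min, c_max)))
        guard += 1
        if guard > 10 * n:
            raise ValueError("infeasible spec: community sizes do not converge")
    excess = sum(sizes) - n
    # shave the excess off the largest communities, never below c_min
    while excess > 0:
        i = int(np.argmax(sizes))
        take = min(excess, sizes[i] - c_min)
        if take == 0:
            # everything at c_min: drop one community, spread its nodes
            if len(sizes) == 1:
                raise ValueError("infeasible spec: cannot fit community sizes")
            drop = sizes.pop()
            excess -= drop
            if excess < 0:
                sizes[0] += -excess
                excess = 0
            continue
        sizes[i] -= take
        excess -= take
    return np.asarray(sizes, dtype=int)


def _assign_nodes(rng: np.random.Generator, degrees: np.ndarray,
                  d_in: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Community index per node; nodes with large internal degree go to
    communities large enough to host them when capacity allows."""
    n = len(degrees)
    remaining = sizes.copy()
    comm = np.full(n, -1, dtype=int)
    order = np.argsort(-(d_in + rng.random(n)))  # desc, random tie-break
    for i in order:
        ok = np.nonzero((remaining > 0) & (sizes - 1 >= d_in[i]))[0]
        if len(ok) == 0:
            ok = np.nonzero(remaining > 0)[0]
        probs = remaining[ok] / remaining[ok].sum()
        comm[i] = rng.choice(ok, p=probs)
        remaining[comm[i]] -= 1
    return comm


def _stub_match(rng: np.random.Generator, stubs: np.ndarray,
                allowed, max_rounds: int = 120) -> list[tuple[int, int]]:
    """Configuration-model pairing of node stubs with rejection rewiring.

    ``stubs`` holds one entry per half-edge (node index, repeated by
    degree). Invalid pairs (self, duplicate, or failing ``allowed``) are
    re-shuffled; after ``max_rounds`` a greedy completion pass pairs what
    it still can, so realized degrees fall short of the targets only where
    the remaining stubs admit no simple-graph pairing at all.
    """
    stubs = stubs.copy()
    edges: set[tuple[int, int]] = set()
    for _ in range(max_rounds):
        if len(stubs) < 2:
            break
        rng.shuffle(stubs)
        if len(stubs) % 2 == 1:
            stubs, odd = stubs[:-1], stubs[-1:]
        else:
            odd = stubs[:0]
        a, b = stubs[0::2], stubs[1::2]
        retry = []
        for i, j in zip(a, b):
            i, j = int(i), int(j)
            key = (i, j) if i < j else (j, i)
            if i == j or key in edges or not allowed(i, j):
                retry += [i, j]
            else:
                edges.add(key)
        stubs = np.concatenate([np.asarray(retry, dtype=stubs.dtype), odd])
        if not retry and len(odd) <= 1:
            break
    # greedy completion over whatever is left
    left = [int(s) for s in stubs]
    used = [False] * len(left)
    for a_pos in range(len(left)):
        if used[a_pos]:
            continue
        i = left[a_pos]
        for b_pos in range(a_pos + 1, len(left)):
            if used[b_pos]:
                continue
            j = left[b_pos]
            key = (i, j) if i < j else (j, i)
            if i != j and key not in edges and allowed(i, j):
                edges.add(key)
                used[a_pos] = used[b_pos] = True
                break
    return sorted(edges)


def _graphical_realize(rng: np.random.Generator, d: np.ndarray
                       ) -> list[tuple[int, int]]:
    """Simple graph with (local) degree sequence ~ d.

    Havel-Hakimi construction, then degree-preserving double-edge swaps to
    randomize. Non-graphical remainders are dropped, so heavy sequences
    (e.g. near-complete blocks) still realize almost all stubs.
    """
    m = len(d)
    remaining = d.astype(int).copy()
    adj: set[tuple[int, int]] = set()
    while True:
        order = np.argsort(-remaining)
        v = int(order[0])
        dv = int(remaining[v])
        if dv <= 0:
            break
        remaining[v] = 0
        attached = 0
        for u in order[1:]:
            if attached == dv:
                break
            u = int(u)
            if remaining[u] <= 0:
                continue
            key = (v, u) if v < u else (u, v)
            if key in adj:
                continue
            adj.add(key)
            remaining[u] -= 1
            attached += 1
        # if attached < dv the sequence was not graphical; stubs dropped
    edges = list(adj)
    # randomize while preserving degrees
    n_e = len(edges)
    for _ in range(10 * n_e):
        if n_e < 2:
            break
        x, y = rng.integers(n_e), rng.integers(n_e)
        if x == y:
            continue
        a, b = edges[x]
        c, e = edges[y]
        if rng.random() < 0.5:
            c, e = e, c
        if len({a, b, c, e}) < 4:
            continue
        k1 = (a, c) if a < c else (c, a)
        k2 = (b, e) if b < e else (e, b)
        if k1 in adj or k2 in adj:
            continue
        adj.discard(edges[x])
        adj.discard(edges[y])
        adj.add(k1)
        adj.add(k2)
        edges[x], edges[y] = k1, k2
    return sorted(adj)


def _connect_components(rng: np.random.Generator, A: np.ndarray) -> None:
    """Link the internal components of a community block with extra edges."""
    m = A.shape[0]
    if m < 2:
        return
    ncomp, lab = connected_components(csr_matrix(A), directed=False)
    while ncomp > 1:
        groups = [np.nonzero(lab == c)[0] for c in range(ncomp)]
        for a, b in zip(groups[:-1], groups[1:]):
            i = int(rng.choice(a))
            j = int(rng.choice(b))
            A[i, j] = A[j, i] = 1.0
        ncomp, lab = connected_components(csr_matrix(A), directed=False)


def _wire(rng: np.random.Generator, spec: BenchmarkSpec
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary adjacency, community index per node, and target degrees.

    Each node's degree is split into an internal part (randomized rounding
    of (1 - mu_t) * k, so the split is unbiased even at small degrees) and
    the external remainder; both parts are wired by stub matching.
    """
    degrees = _degree_sequence(rng, spec)
    sizes = _community_sizes(rng, spec, degrees)
    raw_in = (1.0 - spec.mu_topology) * degrees
    d_in = np.floor(raw_in).astype(int)
    d_in += rng.random(spec.n_nodes) < (raw_in - d_in)
    comm = _assign_nodes(rng, degrees, d_in, sizes)
    n = spec.n_nodes
    # cap internal degree by host community size
    for c in range(len(sizes)):
        members = np.nonzero(comm == c)[0]
        cap = len(members) - 1
        d_in[members] = np.minimum(d_in[members], cap)
    d_out = degrees - d_in

    A = np.zeros((n, n))
    for c in range(len(sizes)):
        members = np.nonzero(comm == c)[0]
        for li, lj in _graphical_realize(rng, d_in[members]):
            i, j = members[li], members[lj]
            A[i, j] = A[j, i] = 1.0
        if spec.mu_topology == 0:
            # zero-mixing limit: communities must equal connected components
            block = A[np.ix_(members, members)]
            _connect_components(rng, block)
            A[np.ix_(members, members)] = block

    if spec.mu_topology > 0 and d_out.sum() > 0:
        stubs = np.repeat(np.arange(n), d_out)
        for i, j in _stub_match(rng, stubs,
                                lambda i, j: comm[i] != comm[j]):
            A[i, j] = A[j, i] = 1.0
    return A, comm, degrees.astype(float)


def _balance_weights(W: np.ndarray, targets: np.ndarray,
                     n_iter: int = 60, tol: float = 1e-4) -> np.ndarray:
    """Symmetric diagonal scaling so row sums approach ``targets``.

    Nodes with no incident edges (or zero target) are left untouched.
    """
    W = W.copy()
    for _ in range(n_iter):
        u = W.sum(axis=1)
        active = (u > 0) & (targets > 0)
        if not np.any(active):
            break
        f = np.ones_like(u)
        f[active] = targets[active] / u[active]
        if np.max(np.abs(f[active] - 1.0)) < tol:
            break
        s = np.sqrt(f)
        W = W * np.outer(s, s)
    return W


def _weighted(rng: np.random.Generator, spec: BenchmarkSpec,
              A: np.ndarray, comm: np.ndarray, degrees: np.ndarray
              ) -> np.ndarray:
    """Edge weights realizing strength budgets k^beta split (1 - mu_w)
    within / mu_w between communities.

    Each node seeds its incident edges with equal shares of the class
    budget; symmetric scaling then balances realized internal and external
    strengths toward the targets (the split is exact only when every node
    can spend its budget, i.e. has edges of the class)."""
    n = len(degrees)
    strength = degrees ** spec.beta
    same = comm[:, None] == comm[None, :]
    internal = (A > 0) & same
    external = (A > 0) & ~same
    deg_int = internal.sum(axis=1)
    deg_ext = external.sum(axis=1)
    c_int = np.divide((1.0 - spec.mu_weight) * strength, deg_int,
                      out=np.zeros(n), where=deg_int > 0)
    c_ext = np.divide(spec.mu_weight * strength, deg_ext,
                      out=np.zeros(n), where=deg_ext > 0)
    W_int = np.zeros((n, n))
    W_ext = np.zeros((n, n))
    W_int[internal] = (c_int[:, None] + c_int[None, :])[internal] / 2.0
    W_ext[external] = (c_ext[:, None] + c_ext[None, :])[external] / 2.0
    W_int = _balance_weights(W_int, (1.0 - spec.mu_weight) * strength)
    if spec.mu_weight > 0:
        W_ext = _balance_weights(W_ext, spec.mu_weight * strength)
        return W_int + W_ext
    return W_int


def generate_weighted_benchmark(spec: BenchmarkSpec
                                ) -> tuple[WeightedNetwork, Partition]:
    """Weighted planted-partition network and its ground-truth partition.

    Node ids are "1".."N"; ground-truth labels are 1-based community ids.
    Same seed => bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    A, comm, degrees = _wire(rng, spec)
    W = _weighted(rng, spec, A, comm, degrees)
    ids = [str(i) for i in range(1, spec.n_nodes + 1)]
    return WeightedNetwork(ids, W), Partition(ids, comm + 1)


def _separated_centers(rng: np.random.Generator, n_centers: int,
                       n_dims: int) -> np.ndarray:
    """Random centers rescaled so the minimum pairwise distance is 1."""
    if n_centers == 1:
        return np.zeros((1, n_dims))
    while True:
        centers = rng.standard_normal((n_centers, n_dims))
        diffs = centers[:, None, :] - centers[None, :, :]
        dists = np.linalg.norm(diffs, axis=-1)
        dmin = dists[np.triu_indices(n_centers, k=1)].min()
        if dmin > 1e-9:  # redraw the (measure-zero) coincident case
            return centers / dmin


def generate_attributed_benchmark(spec: AttributedBenchmarkSpec
                                  ) -> tuple[WeightedNetwork, NodeAttributes,
                                             Partition]:
    """Unweighted planted-partition network with Gaussian node attributes.

    Each community draws a distinct center (pairwise separation >= 1);
    node attributes are center + N(0, attribute_sd^2) per dimension.
    """
    rng = np.random.default_rng(spec.seed)
    A, comm, _ = _wire(rng, spec)
    ids = [str(i) for i in range(1, spec.n_nodes + 1)]
    network = WeightedNetwork(ids, (A > 0).astype(float))
    n_comm = comm.max() + 1
    centers = _separated_centers(rng, n_comm, spec.n_attributes)
    values = centers[comm] + rng.normal(0.0, spec.attribute_sd,
                                        size=(spec.n_nodes, spec.n_attributes))
    attrs = NodeAttributes(ids, values)
    return network, attrs, Partition(ids, comm + 1)


def generate_hierarchical_fixture(n_super: int = 2, n_sub_per_super: int = 2,
                                  sub_size: int = 25, p_in_sub: float = 0.8,
                                  p_in_super: float = 0.3, p_out: float = 0.02,
                                  spatial_sep: float = 5.0, sigma: float = 0.5,
                                  n_dims: int = 3, seed: int | None = None
                                  ) -> tuple[WeightedNetwork, NodeAttributes,
                                             Partition, Partition]:
    """Nested stochastic-block fixture with spatially clustered sub-blocks.

    Sub-blocks inside a super-block sit at centers separated by
    ``spatial_sep`` with Gaussian spread ``sigma``; super-blocks are pushed
    far apart along the first axis. Returns both truth levels.
    """
    if not (p_in_sub > p_in_super >= p_out >= 0) or p_in_sub > 1:
        raise ValueError("need 1 >= p_in_sub > p_in_super >= p_out >= 0")
    rng = np.random.default_rng(seed)
    n = n_super * n_sub_per_super * sub_size
    sub_of = np.repeat(np.arange(n_super * n_sub_per_super), sub_size)
    super_of = sub_of // n_sub_per_super

    P = np.where(sub_of[:, None] == sub_of[None, :], p_in_sub,
                 np.where(super_of[:, None] == super_of[None, :],
                          p_in_super, p_out))
    np.fill_diagonal(P, 0.0)
    iu = np.triu_indices(n, k=1)
    A = np.zeros((n, n))
    A[iu] = rng.random(len(iu[0])) < P[iu]
    A = A + A.T

    offset = 10.0 * max(spatial_sep, 1.0)
    values = np.zeros((n, n_dims))
    for s in range(n_super):
        centers = _separated_centers(rng, n_sub_per_super, n_dims) * spatial_sep
        centers[:, 0] += offset * s
        for b in range(n_sub_per_super):
            g = s * n_sub_per_super + b
            members = np.nonzero(sub_of == g)[0]
            values[members] = centers[b] + rng.normal(
                0.0, sigma, size=(len(members), n_dims))

    ids = [str(i) for i in range(1, n + 1)]
    return (WeightedNetwork(ids, A), NodeAttributes(ids, values),
            Partition(ids, super_of + 1), Partition(ids, sub_of + 1))


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

# printed simulation design: per network size, the mixing-coefficient range
# (reduced to 0.7 for N=50), with tau1=2, tau2=1, beta=1.5 throughout
DEFAULT_GRID = (
    dict(n_nodes=50, mean_degree=3, max_degree=9, mu_min=0.2, mu_max=0.7),
    dict(n_nodes=100, mean_degree=5, max_degree=25, mu_min=0.2, mu_max=0.8),
    dict(n_nodes=300, mean_degree=15, max_degree=75, mu_min=0.4, mu_max=0.8),
    dict(n_nodes=500, mean_degree=25, max_degree=125, mu_min=0.4, mu_max=0.8),
    dict(n_nodes=1000, mean_degree=50, max_degree=250, mu_min=0.4, mu_max=0.8),
)
_MU_STEP = 0.1


def experiment_grid(grid=None, replicates: int = 1, base_seed: int = 0,
                    tau1: float = 2.0, tau2: float = 1.0, beta: float = 1.5
                    ) -> list[BenchmarkSpec]:
    """Enumerate the benchmark design into a deterministic spec list.

    Each grid row carries a mixing-coefficient range swept at step 0.1;
    every (row, mu) combination is replicated ``replicates`` times with
    per-spec seeds spawned from ``base_seed``.
    """
    if grid is None:
        grid = DEFAULT_GRID
    combos = []
    for row in grid:
        n_steps = int(round((row["mu_max"] - row["mu_min"]) / _MU_STEP)) + 1
        if n_steps < 1:
            raise ValueError(f"malformed grid row: {row}")
        for s in range(n_steps):
            mu = round(row["mu_min"] + s * _MU_STEP, 10)
            combos.append((row, mu))
    seeds = np.random.SeedSequence(base_seed).spawn(len(combos) * replicates)
    specs = []
    for ci, (row, mu) in enumerate(combos):
        for r in range(replicates):
            ss = seeds[ci * replicates + r]
            specs.append(BenchmarkSpec(
                n_nodes=row["n_nodes"], mean_degree=row["mean_degree"],
                max_degree=row["max_degree"], mu_topology=mu, mu_weight=mu,
                tau1=tau1, tau2=tau2, beta=beta,
                seed=int(ss.generate_state(1, dtype=np.uint64)[0])))
    return specs
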