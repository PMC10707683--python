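"""Two-level community detection: consensus detection followed by
per-community subdivision accepted only when the mean within-community
attribute distance drops significantly under a size-preserving
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .consensus import WMMConfig, wmm, _seed_of
from .core import NodeAttributes, Partition, WeightedNetwork

__all__ = [
    "TwoStepConfig",
    "SubdivisionTest",
    "HierarchicalPartition",
    "distance_matrix",
    "community_distance",
    "post_subdivision_distance",
    "permutation_test",
    "two_step_wmm",
]


@dataclass
class TwoStepConfig:
    n_permutations: int = 10_000
    alpha: float = 0.05
    min_subdivide_size: int = 6
    wmm_config: WMMConfig = field(default_factory=WMMConfig)

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_subdivide_size < 2:
            raise ValueError("min_subdivide_size must be >= 2")


@dataclass
class SubdivisionTest:
    """Decision record of one community's permutation test."""

    community: int
    size: int
    n_subcommunities: int
    d_before: float
    d_after: float
    null_quantile: float | None
    accepted: bool
    reason: str

    def to_dict(self) -> dict:
        return {
            "community": self.community,
            "size": self.size,
            "n_subcommunities": self.n_subcommunities,
            "d_before": self.d_before,
            "d_after": self.d_after,
            "null_quantile": self.null_quantile,
            "accepted": self.accepted,
            "reason": self.reason,
        }


@dataclass
class HierarchicalPartition:
    level1: Partition
    level2: Partition
    provenance: dict  # level-2 label -> parent level-1 label
    test_results: dict  # level-1 label -> SubdivisionTest

    def refines(self) -> bool:
        """True iff every level-2 community sits inside one level-1 community."""
        parent_of = {}
        for nid in self.level2.node_ids:
            l2 = self.level2.label_of(nid)
            l1 = self.level1.label_of(nid)
            if l2 in parent_of and parent_of[l2] != l1:
                return False
            parent_of[l2] = l1
        return True


def distance_matrix(attributes: NodeAttributes) -> np.ndarray:
    """Pairwise Euclidean distances between attribute rows; zero diagonal."""
    if attributes.n_attributes < 1:
        raise ValueError("need at least one attribute column")
    return squareform(pdist(attributes.values, metric="euclidean"))


def community_distance(indices, D: np.ndarray) -> float:
    """Mean of all N_c^2 entries of the community's distance block.

    The zero diagonal is included by the printed definition, so a singleton
    community has distance 0.
    """
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        raise ValueError("empty community")
    return float(D[np.ix_(idx, idx)].mean())


def post_subdivision_distance(sub_labels, D: np.ndarray) -> float:
    """Unweighted mean of community_distance over the sub-communities.

    ``sub_labels`` maps each node (row of D) to a sub-community label.
    """
    sub_labels = np.asarray(sub_labels)
    groups = np.unique(sub_labels)
    return float(np.mean([
        community_distance(np.nonzero(sub_labels == g)[0], D) for g in groups
    ]))


def _null_distances(sub_labels: np.ndarray, D: np.ndarray, T: int,
                    rng: np.random.Generator, chunk_elems: int = 4_000_000
                    ) -> np.ndarray:
    """T mean distances of size-preserving random reassignments.

    Each draw shuffles which nodes occupy each sub-community slot; computed
    in vectorized chunks to bound memory.
    """
    n = len(sub_labels)
    groups = np.unique(sub_labels)
    positions = [np.nonzero(sub_labels == g)[0] for g in groups]
    out = np.zeros(T)
    max_m2 = max(len(p) for p in positions) ** 2
    chunk = max(1, int(chunk_elems // max_m2))
    done = 0
    while done < T:
        c = min(chunk, T - done)
        perms = np.argsort(rng.random((c, n)), axis=1)  # c random permutations
        acc = np.zeros(c)
        for pos in positions:
            X = perms[:, pos]  # c x m node indices of this sub-community
            block = D[X[:, :, None], X[:, None, :]]
            acc += block.mean(axis=(1, 2))
        out[done:done + c] = acc / len(positions)
        done += c
    return out


def permutation_test(sub_labels, D: np.ndarray, d_before: float,
                     T: int = 10_000, alpha: float = 0.05,
                     seed: int | None = None,
                     community: int = -1) -> SubdivisionTest:
    """Accept the subdivision iff d_after < d_before and d_after is below
    the ceil(T * alpha)-th smallest of T size-preserving null distances.

    ``sub_labels`` and ``D`` are local to the community under test.
    """
    sub_labels = np.asarray(sub_labels)
    groups = np.unique(sub_labels)
    if len(groups) < 2:
        raise ValueError("permutation test requires >= 2 sub-communities")
    if T * alpha < 1:
        raise ValueError("T * alpha < 1: null quantile undefined")
    d_after = post_subdivision_distance(sub_labels, D)
    rng = np.random.default_rng(seed)
    null = np.sort(_null_distances(sub_labels, D, T, rng))
    q = float(null[ceil(T * alpha) - 1])
    accepted = (d_after < d_before) and (d_after < q)
    return SubdivisionTest(
        community=community, size=len(sub_labels),
        n_subcommunities=len(groups), d_before=d_before, d_after=d_after,
        null_quantile=q, accepted=accepted,
        reason="tested",
    )


def two_step_wmm(network: WeightedNetwork, attributes: NodeAttributes,
                 config: TwoStepConfig | None = None) -> HierarchicalPartition:
    """Consensus detection, then per-community subdivision with the
    attribute-distance permutation test.

    Communities smaller than ``min_subdivide_size`` pass through unchanged;
    a second-step result with a single sub-community is likewise retained.
    Final level-2 labels are globally unique, assigned in level-1 label
    order; unsplit communities keep their level-1 label identity through
    ``provenance``.
    """
    if config is None:
        config = TwoStepConfig()
    if set(attributes.node_ids) < set(network.node_ids):
        raise ValueError("attributes must cover every network node")

    root = np.random.SeedSequence(config.wmm_config.seed)
    ss_step1, ss_step2 = root.spawn(2)
    cfg1 = WMMConfig(
        pool_size=config.wmm_config.pool_size,
        n_selected=config.wmm_config.n_selected,
        n_selections=config.wmm_config.n_selections,
        gamma=config.wmm_config.gamma,
        max_passes=config.wmm_config.max_passes,
        seed=_seed_of(ss_step1),
    )
    level1 = wmm(network, cfg1)

    coords = attributes.aligned_values(network.node_ids)
    D_full = squareform(pdist(coords, metric="euclidean"))
    node_pos = {nid: i for i, nid in enumerate(network.node_ids)}

    level2_labels = {}
    provenance = {}
    test_results = {}
    next_label = 1
    comms = level1.communities()
    sub_seeds = ss_step2.spawn(2 * len(comms))

    for ci, (label, members) in enumerate(comms.items()):
        idx = np.asarray([node_pos[n] for n in members])
        d_before = community_distance(idx, D_full)
        record = None
        sub_of_member = None

        if len(members) < config.min_subdivide_size:
            record = SubdivisionTest(
                community=label, size=len(members), n_subcommunities=1,
                d_before=d_before, d_after=d_before, null_quantile=None,
                accepted=False, reason="below min_subdivide_size")
        else:
            sub_net = network.induced_subnetwork(members)
            if sub_net.total_weight <= 0:
                record = SubdivisionTest(
                    community=label, size=len(members), n_subcommunities=1,
                    d_before=d_before, d_after=d_before, null_quantile=None,
                    accepted=False, reason="edgeless subgraph")
            else:
                cfg2 = WMMConfig(
                    pool_size=config.wmm_config.pool_size,
                    n_selected=config.wmm_config.n_selected,
                    n_selections=config.wmm_config.n_selections,
                    gamma=config.wmm_config.gamma,
                    max_passes=config.wmm_config.max_passes,
                    seed=_seed_of(sub_seeds[2 * ci]),
                )
                sub_part = wmm(sub_net, cfg2)
                sub_labels = sub_part.aligned_labels(sub_net.node_ids)
                if len(np.unique(sub_labels)) < 2:
                    record = SubdivisionTest(
                        community=label, size=len(members), n_subcommunities=1,
                        d_before=d_before, d_after=d_before,
                        null_quantile=None, accepted=False,
                        reason="no split found")
                else:
                    D_local = D_full[np.ix_(idx, idx)]
                    # align: rows of D_local follow `members` order = sub_net order
                    record = permutation_test(
                        sub_labels, D_local, d_before,
                        T=config.n_permutations, alpha=config.alpha,
                        seed=_seed_of(sub_seeds[2 * ci + 1]), community=label)
                    if record.accepted:
                        sub_of_member = dict(zip(sub_net.node_ids, sub_labels))

        test_results[label] = record
        if sub_of_member is None:
            lab2 = next_label
            next_label += 1
            provenance[lab2] = label
            for n in members:
                level2_labels[n] = lab2
        else:
            local_map = {}
            for n in members:
                s = sub_of_member[n]
                if s not in local_map:
                    local_map[s] = next_label
                    provenance[next_label] = label
                    next_label += 1
                level2_labels[n] = local_map[s]

    level2 = Partition(network.node_ids,
                       [level2_labels[n] for n in network.node_ids])
    return HierarchicalPartition(level1=level1, level2=level2,
                                 provenance=provenance,
                                 test_results=test_results)
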