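"""Partition-quality (normalized mutual information) and partition-stability
(average node entropy with overlap-based label matching) measures.

Entropies are in bits (base 2); NMI is base-independent.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import Partition, PartitionEnsemble

__all__ = [
    "nmi",
    "match_labels",
    "average_node_entropy",
    "mean_average_node_entropy",
]


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(table, (xi, yi), 1.0)
    return table


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def nmi(x: Partition, y: Partition) -> float:
    """2 * MI(X, Y) / (H(X) + H(Y)); 1 for identical partitions (up to
    relabeling), 0 for statistically independent ones."""
    if set(x.node_ids) != set(y.node_ids):
        raise ValueError("partitions cover different node sets")
    if x.equivalent(y):  # identical up to relabeling: exactly 1 by definition
        return 1.0
    a = x.labels
    b = y.aligned_labels(x.node_ids)
    n = len(a)
    table = _contingency(a, b)
    pxy = table / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx, hy = _entropy(px), _entropy(py)
    if hx + hy == 0:
        # both single-community over the same node set: identical partitions
        return 1.0
    nz = pxy > 0
    mi = float((pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz])).sum())
    val = 2.0 * mi / (hx + hy)
    # clip tiny negative round-off
    return float(min(max(val, 0.0), 1.0))


def match_labels(partition: Partition, reference: Partition,
                 optimal: bool = False) -> Partition:
    """Relabel ``partition`` so its communities carry the reference labels
    they overlap most with.

    Greedy by default: community/reference pairs are matched in descending
    overlap size, ties broken by smallest reference label then smallest
    partition label. Unmatched communities get fresh labels above the
    reference's maximum. ``optimal=True`` uses a maximum-overlap assignment
    instead (sensitivity checks).
    """
    if set(partition.node_ids) != set(reference.node_ids):
        raise ValueError("partitions cover different node sets")
    p = partition.labels
    r = reference.aligned_labels(partition.node_ids)
    p_labels = np.unique(p)
    r_labels = np.unique(r)
    overlap = np.zeros((len(p_labels), len(r_labels)), dtype=int)
    pi = {l: i for i, l in enumerate(p_labels)}
    ri = {l: i for i, l in enumerate(r_labels)}
    for a, b in zip(p, r):
        overlap[pi[a], ri[b]] += 1

    mapping: dict[int, int] = {}
    if optimal:
        rows, cols = linear_sum_assignment(-overlap)
        for i, j in zip(rows, cols):
            if overlap[i, j] > 0:
                mapping[int(p_labels[i])] = int(r_labels[j])
    else:
        entries = [(-overlap[i, j], int(r_labels[j]), int(p_labels[i]), i, j)
                   for i in range(len(p_labels)) for j in range(len(r_labels))
                   if overlap[i, j] > 0]
        used_p: set[int] = set()
        used_r: set[int] = set()
        for negov, rl, pl, i, j in sorted(entries):
            if pl in used_p or rl in used_r:
                continue
            mapping[pl] = rl
            used_p.add(pl)
            used_r.add(rl)

    fresh = int(r_labels.max()) + 1 if len(r_labels) else 1
    for l in p_labels:
        if int(l) not in mapping:
            mapping[int(l)] = fresh
            fresh += 1
    return partition.relabeled(mapping)


def average_node_entropy(ensemble: PartitionEnsemble, reference_index: int = 0,
                         optimal_matching: bool = False) -> float:
    """Mean over nodes of the label-frequency Shannon entropy across the
    ensemble, after matching every member's labels to the reference member."""
    if ensemble.size < 2:
        raise ValueError("ensemble must contain at least 2 partitions")
    ref = ensemble[reference_index]
    nodes = ref.node_ids
    matched = np.stack([
        match_labels(p, ref, optimal=optimal_matching).aligned_labels(nodes)
        for p in ensemble
    ])  # size x N
    size, n = matched.shape
    total = 0.0
    for col in matched.T:
        counts = np.unique(col, return_counts=True)[1]
        total += _entropy(counts / size)
    return total / n


def mean_average_node_entropy(ensemble: PartitionEnsemble,
                              optimal_matching: bool = False) -> float:
    """Average of ``average_node_entropy`` over every choice of reference
    member — the per-network stability index (lower = more stable)."""
    if ensemble.size < 2:
        raise ValueError("ensemble must contain at least 2 partitions")
    return float(np.mean([
        average_node_entropy(ensemble, i, optimal_matching=optimal_matching)
        for i in range(ensemble.size)
    ]))
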