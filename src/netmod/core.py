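"""Network and partition data model plus text-format readers/writers.

Node ids are arbitrary strings mapped internally to dense 0-based indices;
every matrix in the package uses that internal order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "WeightedNetwork",
    "Partition",
    "PartitionEnsemble",
    "NodeAttributes",
    "read_edge_list",
    "write_edge_list",
    "read_partition",
    "write_partition",
    "read_attributes",
    "write_attributes",
]

_SYM_ATOL = 1e-12


class WeightedNetwork:
    """Undirected weighted network over N labeled nodes.

    Parameters
    ----------
    node_ids:
        Ordered node labels; coerced to ``str``.
    weights:
        N x N symmetric matrix of non-negative edge weights. The diagonal
        must be zero (no self-loops in user-facing networks).
    """

    __slots__ = ("node_ids", "weights", "_index")

    def __init__(self, node_ids: Sequence, weights: np.ndarray):
        node_ids = [str(n) for n in node_ids]
        weights = np.asarray(weights, dtype=float)
        n = len(node_ids)
        if weights.shape != (n, n):
            raise ValueError(f"weights shape {weights.shape} != ({n}, {n})")
        if len(set(node_ids)) != n:
            raise ValueError("duplicate node ids")
        if not np.allclose(weights, weights.T, atol=_SYM_ATOL, rtol=0):
            raise ValueError("weight matrix is not symmetric")
        if np.any(weights < 0):
            raise ValueError("negative edge weights are not allowed")
        if np.any(np.diagonal(weights) != 0):
            raise ValueError("self-loops are not allowed (non-zero diagonal)")
        # enforce exact symmetry so downstream sums are deterministic
        self.weights = (weights + weights.T) / 2.0
        self.node_ids = tuple(node_ids)
        self._index = {nid: i for i, nid in enumerate(node_ids)}

    # -- basic properties --------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id) -> int:
        return self._index[str(node_id)]

    def strengths(self) -> np.ndarray:
        """Node strengths k_i = sum_j A_ij; sums to twice the total weight."""
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """2U: the sum of all entries of the weight matrix."""
        return float(self.weights.sum())

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    # -- derived networks --------------------------------------------------
    def induced_subnetwork(self, nodes: Iterable) -> "WeightedNetwork":
        """Subnetwork on ``nodes`` keeping only within-subset edges.

        Node order of the subset follows this network's node order.
        """
        wanted = {str(n) for n in nodes}
        unknown = wanted - set(self.node_ids)
        if unknown:
            raise KeyError(f"unknown node ids: {sorted(unknown)}")
        keep = [i for i, nid in enumerate(self.node_ids) if nid in wanted]
        idx = np.asarray(keep, dtype=int)
        sub = self.weights[np.ix_(idx, idx)]
        return WeightedNetwork([self.node_ids[i] for i in keep], sub)

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        """Same node set with a replacement weight matrix."""
        return WeightedNetwork(self.node_ids, weights)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self.node_ids == other.node_ids and np.array_equal(
            self.weights, other.weights
        )

    def __repr__(self) -> str:
        return f"WeightedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges()})"


class Partition:
    """Assignment of each node to exactly one community label.

    Stored as an ordered node-id tuple plus an integer label array; labels
    are kept as given (no re-normalisation) so written files round-trip.
    """

    __slots__ = ("node_ids", "labels", "_index")

    def __init__(self, node_ids: Sequence, labels: Sequence[int]):
        node_ids = [str(n) for n in node_ids]
        labels = np.asarray(labels, dtype=int)
        if labels.ndim != 1 or len(labels) != len(node_ids):
            raise ValueError("labels must be a 1-D sequence matching node_ids")
        if len(node_ids) == 0:
            raise ValueError("empty partition")
        if len(set(node_ids)) != len(node_ids):
            raise ValueError("duplicate node ids")
        self.node_ids = tuple(node_ids)
        self.labels = labels.copy()
        self.labels.flags.writeable = False
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "Partition":
        nodes = list(mapping)
        return cls(nodes, [int(mapping[n]) for n in nodes])

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def label_of(self, node_id) -> int:
        return int(self.labels[self._index[str(node_id)]])

    def to_mapping(self) -> dict:
        return {nid: int(lab) for nid, lab in zip(self.node_ids, self.labels)}

    def communities(self) -> dict:
        """Map community label -> list of node ids, labels sorted ascending."""
        out: dict[int, list] = {}
        for nid, lab in zip(self.node_ids, self.labels):
            out.setdefault(int(lab), []).append(nid)
        return dict(sorted(out.items()))

    def aligned_labels(self, node_ids: Sequence) -> np.ndarray:
        """Label array re-ordered to match ``node_ids``."""
        return np.asarray([self.labels[self._index[str(n)]] for n in node_ids])

    def relabeled(self, mapping: Mapping[int, int]) -> "Partition":
        new = np.asarray([mapping[int(l)] for l in self.labels])
        return Partition(self.node_ids, new)

    def same_node_set(self, other: "Partition") -> bool:
        return set(self.node_ids) == set(other.node_ids)

    def __eq__(self, other) -> bool:
        """Exact equality: same node set and same literal labels."""
        if not isinstance(other, Partition):
            return NotImplemented
        if not self.same_node_set(other):
            return False
        return np.array_equal(self.labels, other.aligned_labels(self.node_ids))

    def equivalent(self, other: "Partition") -> bool:
        """Equality up to a relabeling of communities."""
        if not self.same_node_set(other):
            return False
        a = self.labels
        b = other.aligned_labels(self.node_ids)
        pairs = {(int(x), int(y)) for x, y in zip(a, b)}
        # a bijection between label sets exists iff the co-occurring label
        # pairs form a one-to-one correspondence
        return len(pairs) == len(np.unique(a)) == len(np.unique(b))

    def __repr__(self) -> str:
        return f"Partition(n_nodes={self.n_nodes}, n_communities={self.n_communities})"


@dataclass
class PartitionEnsemble:
    """Ordered collection of partitions over one shared node set."""

    partitions: list = field(default_factory=list)

    def __post_init__(self):
        if self.partitions:
            ref = set(self.partitions[0].node_ids)
            for p in self.partitions[1:]:
                if set(p.node_ids) != ref:
                    raise ValueError("ensemble members cover different node sets")

    @property
    def size(self) -> int:
        return len(self.partitions)

    @property
    def node_ids(self) -> tuple:
        return self.partitions[0].node_ids

    def label_matrix(self) -> np.ndarray:
        """size x N integer matrix, columns in the first member's node order."""
        nodes = self.node_ids
        return np.stack([p.aligned_labels(nodes) for p in self.partitions])

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self):
        return self.size

    def __getitem__(self, i):
        return self.partitions[i]


class NodeAttributes:
    """N x m table of continuous node attributes (e.g. spatial coordinates)."""

    __slots__ = ("node_ids", "values", "attribute_names", "_index")

    def __init__(self, node_ids: Sequence, values: np.ndarray,
                 attribute_names: Sequence[str] | None = None):
        node_ids = [str(n) for n in node_ids]
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] != len(node_ids):
            raise ValueError("values row count must match node_ids")
        if attribute_names is None:
            attribute_names = [f"a{j}" for j in range(values.shape[1])]
        if len(attribute_names) != values.shape[1]:
            raise ValueError("attribute_names length must match value columns")
        self.node_ids = tuple(node_ids)
        self.values = values
        self.attribute_names = tuple(attribute_names)
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def aligned_values(self, node_ids: Sequence) -> np.ndarray:
        idx = [self._index[str(n)] for n in node_ids]
        return self.values[np.asarray(idx, dtype=int)]

    def subset(self, node_ids: Sequence) -> "NodeAttributes":
        node_ids = [str(n) for n in node_ids]
        return NodeAttributes(node_ids, self.aligned_values(node_ids),
                              self.attribute_names)


# ---------------------------------------------------------------------------
# Readers / writers (all plain text, tab-delimited)
# ---------------------------------------------------------------------------

def read_edge_list(path, n_nodes: int | None = None,
                   node_ids: Sequence | None = None) -> WeightedNetwork:
    """Read a whitespace-delimited edge list "i j [weight]".

    Missing weights default to 1.0. Duplicate (i,j)/(j,i) entries must agree;
    self-loop lines are dropped with a warning. When ``n_nodes`` is given,
    unseen nodes labeled 1..n_nodes (integers) are included as isolated
    nodes; ``node_ids`` fixes the full node set and order explicitly.
    """
    edges: dict[tuple[str, str], float] = {}
    seen: list[str] = []
    seen_set: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{ln}: expected 'i j [weight]'")
            a, b = parts[0], parts[1]
            w = float(parts[2]) if len(parts) == 3 else 1.0
            if w < 0:
                raise ValueError(f"{path}:{ln}: negative weight {w}")
            if a == b:
                warnings.warn(f"{path}:{ln}: self-loop on node {a} dropped")
                continue
            for x in (a, b):
                if x not in seen_set:
                    seen_set.add(x)
                    seen.append(x)
            key = (a, b) if a <= b else (b, a)
            if key in edges and edges[key] != w:
                raise ValueError(
                    f"{path}:{ln}: conflicting duplicate edge {key}: "
                    f"{edges[key]} vs {w}")
            edges[key] = w

    if node_ids is not None:
        order = [str(n) for n in node_ids]
        missing = seen_set - set(order)
        if missing:
            raise ValueError(f"edge list references unknown nodes: {sorted(missing)}")
    elif n_nodes is not None:
        order = [str(i) for i in range(1, n_nodes + 1)]
        extra = [n for n in seen if n not in set(order)]
        if extra:
            raise ValueError(
                f"edge list references nodes outside 1..{n_nodes}: {extra}")
    else:
        # sort numerically when every id parses as an integer
        try:
            order = sorted(seen, key=lambda s: (0, int(s)))
        except ValueError:
            order = sorted(seen)

    index = {nid: i for i, nid in enumerate(order)}
    A = np.zeros((len(order), len(order)))
    for (a, b), w in edges.items():
        i, j = index[a], index[b]
        A[i, j] = A[j, i] = w
    return WeightedNetwork(order, A)


def write_edge_list(network: WeightedNetwork, path) -> None:
    """Write each undirected edge once, i before j in node order."""
    A = network.weights
    with open(path, "w") as fh:
        ii, jj = np.nonzero(np.triu(A, k=1))
        for i, j in zip(ii, jj):
            fh.write(f"{network.node_ids[i]}\t{network.node_ids[j]}\t{float(A[i, j])!r}\n")


def write_partition(partition: Partition, path) -> None:
    """Two-column TSV "node_id<TAB>label"; round-trips with read_partition."""
    with open(path, "w") as fh:
        for nid, lab in zip(partition.node_ids, partition.labels):
            fh.write(f"{nid}\t{int(lab)}\n")


def read_partition(path) -> Partition:
    nodes, labels = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'node_id label'")
            nodes.append(parts[0])
            labels.append(int(parts[1]))
    return Partition(nodes, labels)


def write_attributes(attrs: NodeAttributes, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\t" + "\t".join(attrs.attribute_names) + "\n")
        for nid, row in zip(attrs.node_ids, attrs.values):
            fh.write(nid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_attributes(path) -> NodeAttributes:
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "node_id":
            raise ValueError(f"{path}: first line must be a 'node_id ...' header")
        names = header[1:]
        nodes, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(names) + 1:
                raise ValueError(f"{path}:{ln}: expected {len(names)+1} columns")
            nodes.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return NodeAttributes(nodes, np.asarray(rows), names)
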