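import itertools

import numpy as np
import pytest

from netmod import Partition, WeightedNetwork


def network_from_edges(n, edges, node_ids=None):
    """Build a WeightedNetwork from (i, j, w) tuples over 0-based indices."""
    A = np.zeros((n, n))
    for e in edges:
        i, j = e[0], e[1]
        w = e[2] if len(e) == 3 else 1.0
        A[i, j] = A[j, i] = w
    ids = node_ids or [str(i + 1) for i in range(n)]
    return WeightedNetwork(ids, A)


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_from_blocks(node_ids, blocks):
    labels = {}
    for lab, block in enumerate(blocks, start=1):
        for n in block:
            labels[n] = lab
    return Partition(node_ids, [labels[n] for n in node_ids])


@pytest.fixture
def triangle():
    return network_from_edges(3, [(0, 1), (0, 2), (1, 2)],
                              node_ids=["a", "b", "c"])


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles on 6 nodes."""
    return network_from_edges(
        6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])


@pytest.fixture
def bridged_triangles():
    """Two unit-weight triangles joined by a single bridge edge (2-3)."""
    return network_from_edges(
        6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
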