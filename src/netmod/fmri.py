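"""Group-level density-thresholded correlation networks from ROI x time
matrices, plus a synthetic block-signal subject generator so the full
pipeline is testable without imaging data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Partition, WeightedNetwork

__all__ = [
    "RoiTimeSeries",
    "GroupNetworkConfig",
    "correlation_matrix",
    "fisher_z",
    "inverse_fisher",
    "group_average",
    "threshold_to_density",
    "generate_block_timeseries",
    "read_timeseries",
    "write_timeseries",
]

logger = logging.getLogger(__name__)


class RoiTimeSeries:
    """R x T matrix of ROI time courses."""

    __slots__ = ("roi_ids", "values")

    def __init__(self, roi_ids, values):
        values = np.asarray(values, dtype=float)
        roi_ids = [str(r) for r in roi_ids]
        if values.ndim != 2 or values.shape[0] != len(roi_ids):
            raise ValueError("values must be R x T with R == len(roi_ids)")
        if values.shape[1] < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contain non-finite values")
        self.roi_ids = tuple(roi_ids)
        self.values = values

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupNetworkConfig:
    density: float = 0.10
    subset_size: int = 90
    n_resamples: int = 100
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.density <= 1):
            raise ValueError("density must lie in (0, 1]")
        if self.subset_size < 1 or self.n_resamples < 1:
            raise ValueError("subset_size and n_resamples must be >= 1")


def correlation_matrix(ts: RoiTimeSeries) -> np.ndarray:
    """Pearson correlations between every pair of ROI time courses."""
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.roi_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance ROI(s): {bad}")
    r = np.corrcoef(ts.values)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh off-diagonal; the diagonal is excluded (set to 0)."""
    r = np.asarray(r, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("|r| >= 1 off-diagonal: z-transform undefined")
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return z


def inverse_fisher(z: np.ndarray) -> np.ndarray:
    """tanh elementwise; diagonal restored to 1."""
    r = np.tanh(np.asarray(z, dtype=float))
    np.fill_diagonal(r, 1.0)
    return r


def group_average(matrices, subset_size: int, n_resamples: int,
                  seed: int | None = None) -> list[np.ndarray]:
    """For each resample: mean of a random subject subset's z-matrices,
    then the inverse transform. Returns ``n_resamples`` correlation
    matrices; deterministic given the seed."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty matrix list")
    if subset_size > len(matrices):
        raise ValueError("subset_size exceeds the number of subjects")
    rng = np.random.default_rng(seed)
    stack = np.stack(matrices)
    out = []
    for _ in range(n_resamples):
        pick = rng.choice(len(matrices), size=subset_size, replace=False)
        out.append(inverse_fisher(stack[pick].mean(axis=0)))
    return out


def threshold_to_density(matrix: np.ndarray, density: float,
                         roi_ids=None) -> WeightedNetwork:
    """Keep the floor(R(R-1)/2 * density) largest positive off-diagonal
    entries as edge weights (fewer if not enough positive entries).

    Negative entries are zeroed first; surviving edges keep their values.
    Ties at the quota boundary break by lexicographic (i, j) order.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    M = np.asarray(matrix, dtype=float)
    R = M.shape[0]
    if roi_ids is None:
        roi_ids = [str(i) for i in range(1, R + 1)]
    M = (M + M.T) / 2.0
    ii, jj = np.triu_indices(R, k=1)
    w = M[ii, jj]
    pos = w > 0
    quota = int(np.floor(R * (R - 1) / 2 * density))
    n_keep = min(quota, int(pos.sum()))
    A = np.zeros((R, R))
    if n_keep > 0:
        order = np.lexsort((jj, ii, -w))  # weight desc, then (i, j) asc
        keep = order[:n_keep]
        A[ii[keep], jj[keep]] = w[keep]
        A = A + A.T
    net = WeightedNetwork(roi_ids, A)
    isolated = int((net.strengths() == 0).sum())
    if isolated:
        logger.info("density %.3f left %d isolated node(s)", density, isolated)
    return net


def generate_block_timeseries(block_labels, n_timepoints: int = 200,
                              signal_strength: float = 0.8,
                              seed: int | None = None
                              ) -> tuple[RoiTimeSeries, Partition]:
    """Synthetic subject: each ROI mixes its block's latent signal with
    white noise so within-block correlation ~= signal_strength^2."""
    labels = np.asarray(block_labels, dtype=int)
    if not (0 <= signal_strength < 1):
        raise ValueError("signal_strength must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    blocks = np.unique(labels)
    latent = {b: rng.standard_normal(n_timepoints) for b in blocks}
    noise = rng.standard_normal((len(labels), n_timepoints))
    values = np.stack([
        signal_strength * latent[b] + np.sqrt(1 - signal_strength**2) * e
        for b, e in zip(labels, noise)
    ])
    ids = [str(i) for i in range(1, len(labels) + 1)]
    return RoiTimeSeries(ids, values), Partition(ids, labels)


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(ts.roi_ids, ts.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_timeseries(path) -> RoiTimeSeries:
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return RoiTimeSeries(ids, np.asarray(rows))
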