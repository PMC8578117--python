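"""Registration-accuracy metrics.

Accuracy against a ground truth is quantified by the percent-error map

    E_P(x) = (P_r(x) - P(x)) / max_x{P(x)} * 100

whose median is the bias and whose 90% confidence-interval width (95th minus
5th percentile, linear interpolation) is the precision. Segmentation overlap
is summarised by the classical symmetric Hausdorff distance between mask
boundaries, in voxel units. Time-cut images (one spatial line stacked over
frames) support visual motion inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .kinetics import DynamicSeries

__all__ = [
    "ErrorMap",
    "BiasPrecision",
    "percent_error",
    "bias_precision",
    "hausdorff",
    "time_cut",
]


@dataclass
class ErrorMap:
    """Percent-error field and the mask of evaluated pixels."""

    values: np.ndarray
    mask: np.ndarray

    @property
    def masked(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class BiasPrecision:
    """bias: median percent error; precision: width of its 90% CI."""

    bias: float
    precision: float


def percent_error(recon: np.ndarray, truth: np.ndarray,
                  mask: np.ndarray | None = None) -> ErrorMap:
    """Percent error normalised by the maximum of the truth map over the
    whole field (not per-region)."""
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if recon.shape != truth.shape:
        raise ValueError("recon and truth shapes differ")
    denom = float(np.max(truth))
    if denom <= 0:
        raise ValueError("truth map has no positive values")
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    values = (recon - truth) / denom * 100.0
    return ErrorMap(values=values, mask=np.asarray(mask, dtype=bool))


def bias_precision(error_map) -> BiasPrecision:
    """Median and 90% CI width of a percent-error map (equal-tailed
    percentiles, linear interpolation)."""
    vals = error_map.masked if isinstance(error_map, ErrorMap) \
        else np.asarray(error_map, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty mask")
    p5, p50, p95 = np.percentile(vals, [5, 50, 95], method="linear")
    return BiasPrecision(bias=float(p50), precision=float(p95 - p5))


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: the mask minus its erosion."""
    er = binary_erosion(mask, border_value=0)
    b = mask & ~er
    if not b.any():
        b = mask
    return b


def hausdorff(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two binary masks, in voxels.

    Classical max-max-min definition over boundary voxels (Euclidean,
    isotropic voxel units); symmetric by construction.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    if not a.any() or not b.any():
        raise ValueError("empty mask")
    pa = np.argwhere(_boundary(a)).astype(float)
    pb = np.argwhere(_boundary(b)).astype(float)
    da = cKDTree(pb).query(pa)[0].max()
    db = cKDTree(pa).query(pb)[0].max()
    return float(max(da, db))


def time_cut(series: DynamicSeries | np.ndarray, axis: int, index: int) -> np.ndarray:
    """Extract a space x time image along one spatial line.

    `axis` is the spatial axis retained in the cut; `index` fixes every other
    spatial axis. For a 2D series, ``time_cut(s, 0, j)`` stacks column j of
    every frame, visualising superior-inferior motion.
    """
    data = series.data if isinstance(series, DynamicSeries) else np.asarray(series)
    nspatial = data.ndim - 1
    if not (0 <= axis < nspatial):
        raise IndexError("axis out of range")
    other = [ax for ax in range(nspatial) if ax != axis]
    idx = np.atleast_1d(index)
    if idx.size != len(other):
        raise IndexError("need one index per remaining spatial axis")
    sl = [slice(None)] * data.ndim
    for ax, i in zip(other, idx):
        if not (0 <= i < data.shape[ax]):
            raise IndexError("index out of range")
        sl[ax] = int(i)
    return data[tuple(sl)]
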