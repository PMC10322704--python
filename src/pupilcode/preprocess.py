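"""Fluorescence preprocessing for two-photon imaging and fiber photometry.

Imaging pipeline (fixed order): neuropil-correct each ROI against its halo,
merge ROIs that image the same cell on multiple Z-planes, smooth with a
three-sample moving average and z-score.  Photometry pipeline: detrend
against a monotonically decreasing convex-hull template (photobleaching
envelope), then z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZeroVarianceError",
    "neuropil_correct_dff",
    "merge_duplicate_cells",
    "smooth_and_zscore",
    "convex_hull_detrend",
    "lower_hull_template",
    "preprocess_imaging",
    "preprocess_photometry",
]

log = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """A trace has no variance where the pipeline requires some."""


def neuropil_correct_dff(cell_raw: np.ndarray, halo_raw: np.ndarray,
                         baseline_percentile: float = 10.0,
                         f0_floor_frac: float = 1e-6) -> np.ndarray:
    """Neuropil-corrected dF/F.

    The halo (neuropil) trace is subtracted sample-wise from the cell ROI
    trace; F0 is a low percentile of the corrected trace (default 10th) and
    dF/F = (F - F0)/|F0|.  A baseline within ``f0_floor_frac`` of the trace
    scale signals pathological cancellation and raises.
    """
    cell_raw = np.asarray(cell_raw, float)
    halo_raw = np.asarray(halo_raw, float)
    if cell_raw.shape != halo_raw.shape:
        raise ValueError("cell and halo traces must have equal length")
    if not (np.isfinite(cell_raw).all() and np.isfinite(halo_raw).all()):
        raise ValueError("traces must be finite")
    corrected = cell_raw - halo_raw
    scale = np.max(np.abs(corrected)) if corrected.size else 0.0
    f0 = np.percentile(corrected, baseline_percentile)
    if abs(f0) <= f0_floor_frac * max(scale, 1e-300) or scale == 0.0:
        raise ZeroVarianceError(
            f"pathological baseline: F0={f0:g} with trace scale {scale:g} "
            "(cell and halo cancel?)")
    return (corrected - f0) / abs(f0)


def merge_duplicate_cells(traces: np.ndarray,
                          duplicate_groups: list[list[int]],
                          ) -> tuple[np.ndarray, list[list[int]]]:
    """Average ROI traces that belong to the same cell.

    ``duplicate_groups`` lists ROI indices imaged on multiple planes; each
    group is replaced by the unweighted mean of its members, ungrouped ROIs
    pass through.  Returns (merged traces, per-output source indices).
    """
    traces = np.asarray(traces, float)
    seen: set[int] = set()
    for g in duplicate_groups:
        if seen & set(g):
            raise ValueError(f"overlapping duplicate groups at ROIs {sorted(seen & set(g))}")
        if not g:
            raise ValueError("empty duplicate group")
        seen |= set(g)
    grouped = [sorted(g) for g in duplicate_groups]
    singles = [[i] for i in range(traces.shape[0]) if i not in seen]
    mapping = sorted(grouped + singles, key=lambda g: g[0])
    merged = np.vstack([traces[g].mean(axis=0) for g in mapping])
    return merged, mapping


def smooth_and_zscore(trace: np.ndarray) -> np.ndarray:
    """Three-sample centered moving average, then z-score over the trace.

    Edges shrink the window to the available samples, preserving length.
    """
    x = np.asarray(trace, float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D trace of length >= 3")
    kernel = np.ones(3)
    sm = np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones(len(x)), kernel, mode="same")
    sd = sm.std()
    if sd == 0:
        raise ZeroVarianceError("trace has zero variance after smoothing")
    return (sm - sm.mean()) / sd


def lower_hull_template(trace: np.ndarray) -> np.ndarray:
    """Monotonically decreasing envelope from the lower convex hull.

    Computes the lower convex hull of (index, value), scans its vertices
    forward in time keeping the first and every vertex whose value strictly
    decreases, linearly interpolates between kept vertices and holds the
    last kept value to the end of the trace.
    """
    y = np.asarray(trace, float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    # Andrew monotone chain, lower hull only; indices are already sorted
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # cross product of (i2-i1) x (i-i1); <= 0 means i2 not below chord
            if (i2 - i1) * (y[i] - y[i1]) - (i - i1) * (y[i2] - y[i1]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    kept_i, kept_v = [hull[0]], [y[hull[0]]]
    for i in hull[1:]:
        if y[i] < kept_v[-1]:
            kept_i.append(i)
            kept_v.append(y[i])
    # np.interp holds the first/last kept value beyond the kept range
    return np.interp(np.arange(n), kept_i, kept_v)


def convex_hull_detrend(trace: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the decreasing convex-hull template and z-score the residual.

    Removes slow monotone decay (photobleaching) from a raw photometry
    trace.  Returns (z-scored residual, template).  A residual with no
    variance means the trace was pure trend and raises.
    """
    y = np.asarray(trace, float)
    if not np.isfinite(y).all():
        raise ValueError("trace must be finite")
    template = lower_hull_template(y)
    residual = y - template
    sd = residual.std()
    scale = max(np.max(np.abs(y)), 1e-300)
    if sd <= 1e-12 * scale:
        raise ZeroVarianceError("residual has zero variance: trace is pure trend")
    return (residual - residual.mean()) / sd, template


def preprocess_imaging(cell_raw: np.ndarray, halo_raw: np.ndarray,
                       duplicate_groups: list[list[int]] | None = None,
                       baseline_percentile: float = 10.0,
                       ) -> tuple[np.ndarray, list[list[int]]]:
    """Full imaging pipeline: correct -> merge -> smooth -> z-score."""
    cell_raw = np.atleast_2d(np.asarray(cell_raw, float))
    halo_raw = np.atleast_2d(np.asarray(halo_raw, float))
    dff = np.vstack([
        neuropil_correct_dff(c, h, baseline_percentile)
        for c, h in zip(cell_raw, halo_raw)
    ])
    merged, mapping = merge_duplicate_cells(dff, duplicate_groups or [])
    log.info("preprocessing %d ROIs -> %d cells (correct -> merge -> smooth -> z-score)",
             cell_raw.shape[0], merged.shape[0])
    return np.vstack([smooth_and_zscore(t) for t in merged]), mapping


def preprocess_photometry(trace: np.ndarray) -> np.ndarray:
    """Full photometry pipeline: convex-hull detrend -> z-score."""
    z, _ = convex_hull_detrend(trace)
    return z
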