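"""Pupil size extraction from edge-landmark tracking.

A video frame is reduced to eight landmark points on the pupil edge with
per-point confidence (the output format of markerless pose trackers such as
DeepLabCut).  A circle is fitted per frame by the algebraic least-squares
(Kasa) method; low-confidence points — blinks, occlusions — are linearly
interpolated from flanking frames before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircleFitError",
    "PupilTrace",
    "AlignedResponse",
    "fit_circle",
    "extract_pupil_trace",
    "align_to_events",
]

log = logging.getLogger(__name__)


class CircleFitError(ValueError):
    """Raised for degenerate geometry: <3 usable points or collinear points."""


@dataclass
class PupilTrace:
    """Pupil radius/area time series with an interpolation mask.

    ``interpolated`` marks frames where any landmark was replaced or where
    the radius itself was interpolated over a degenerate fit.
    """

    time_s: np.ndarray
    radius_px: np.ndarray
    area_px2: np.ndarray
    interpolated: np.ndarray
    center_x: np.ndarray | None = None
    center_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


@dataclass
class AlignedResponse:
    """Event-aligned windows of a trace with per-time mean and s.e.m."""

    matrix: np.ndarray               # (n_events, n_window)
    time_rel_s: np.ndarray
    window_s: tuple[float, float]
    mean: np.ndarray
    sem: np.ndarray
    baseline: np.ndarray             # per-event mean over baseline_window
    response: np.ndarray             # per-event mean over response_window
    event_times_s: np.ndarray        # retained events
    n_dropped: int = 0


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares (Kasa) circle fit.

    Minimizes sum((x^2 + y^2 + D x + E y + F)^2) in closed form; exact for
    points lying on a true circle.  Returns (center_x, center_y, radius).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CircleFitError(f"need >= 3 (x, y) points, got shape {pts.shape}")
    x, y = pts[:, 0], pts[:, 1]
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 3:
        raise CircleFitError("points are collinear or coincident")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if r2 <= 0:
        raise CircleFitError("degenerate fit: non-positive squared radius")
    return float(cx), float(cy), float(np.sqrt(r2))


def _interp_masked(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace ``bad`` entries by linear interpolation over good neighbours;
    leading/trailing gaps take the nearest good value."""
    good = ~bad
    if not good.any():
        raise ValueError("no valid samples to interpolate from")
    idx = np.arange(len(values))
    out = values.astype(float).copy()
    out[bad] = np.interp(idx[bad], idx[good], values[good])
    return out


def extract_pupil_trace(x: np.ndarray, y: np.ndarray, confidence: np.ndarray,
                        time_s: np.ndarray,
                        confidence_threshold: float = 0.9) -> PupilTrace:
    """Per-frame circle fit with confidence-gated landmark interpolation.

    Points with confidence below threshold are replaced, per landmark, by
    linear interpolation between the nearest flanking confident frames; the
    circle is then fitted frame by frame.  Frames where the fit itself is
    degenerate get their radius interpolated from neighbouring fits.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    confidence = np.asarray(confidence, float)
    time_s = np.asarray(time_s, float)
    if x.shape != y.shape or x.shape != confidence.shape:
        raise ValueError("x, y, confidence must share a (n_frames, 8) shape")
    if x.ndim != 2 or x.shape[1] != 8:
        raise ValueError(f"expected 8 landmarks per frame, got {x.shape}")
    n = x.shape[0]
    low = confidence < confidence_threshold
    if not (~low).any():
        raise ValueError("no landmark anywhere above the confidence threshold")
    for j in range(x.shape[1]):
        if not (~low[:, j]).any():
            raise ValueError(f"landmark {j} never exceeds the confidence threshold")
        if low[:, j].any():
            x[:, j] = _interp_masked(x[:, j], low[:, j])
            y[:, j] = _interp_masked(y[:, j], low[:, j])

    interpolated = low.any(axis=1)
    radius = np.full(n, np.nan)
    cx = np.full(n, np.nan)
    cy = np.full(n, np.nan)
    n_degenerate = 0
    for i in range(n):
        try:
            cx[i], cy[i], radius[i] = fit_circle(np.column_stack([x[i], y[i]]))
        except CircleFitError:
            n_degenerate += 1
    bad = np.isnan(radius)
    if bad.all():
        raise ValueError("circle fit failed on every frame")
    if bad.any():
        log.warning("interpolating radius over %d degenerate frames", n_degenerate)
        radius = _interp_masked(radius, bad)
        cx = _interp_masked(cx, bad)
        cy = _interp_masked(cy, bad)
        interpolated = interpolated | bad

    return PupilTrace(time_s=time_s, radius_px=radius,
                      area_px2=np.pi * radius ** 2,
                      interpolated=interpolated, center_x=cx, center_y=cy)


def align_to_events(time_s: np.ndarray, values: np.ndarray,
                    event_times_s: np.ndarray,
                    window_s: tuple[float, float],
                    baseline_window_s: tuple[float, float] | None = None,
                    response_window_s: tuple[float, float] | None = None,
                    ) -> AlignedResponse:
    """Slice per-event windows and summarize baseline/response values.

    ``window_s`` is (pre, post) relative to the event, pre typically
    negative.  Events whose full window falls outside the trace are dropped
    and counted.  Baseline and response are per-event means over the given
    sub-windows (defaults: first and last sample of the window).
    """
    time_s = np.asarray(time_s, float)
    values = np.asarray(values, float)
    dt = float(time_s[1] - time_s[0])
    pre, post = window_s
    if post <= pre:
        raise ValueError("window must satisfy post > pre")
    i_pre = int(round(pre / dt))
    i_post = int(round(post / dt))
    offsets = np.arange(i_pre, i_post + 1)
    rows, kept = [], []
    for t0 in np.asarray(event_times_s, float):
        i0 = int(round((t0 - time_s[0]) / dt))
        lo, hi = i0 + i_pre, i0 + i_post
        if lo < 0 or hi >= len(values):
            continue
        rows.append(values[lo:hi + 1])
        kept.append(t0)
    if not rows:
        raise ValueError("no events with a full window inside the trace")
    n_dropped = len(event_times_s) - len(rows)
    if n_dropped:
        log.info("dropped %d events with incomplete windows", n_dropped)
    matrix = np.asarray(rows)
    t_rel = offsets * dt

    def _window_mean(win: tuple[float, float] | None, default_idx: int) -> np.ndarray:
        if win is None:
            return matrix[:, default_idx]
        sel = (t_rel >= win[0]) & (t_rel <= win[1])
        if not sel.any():
            raise ValueError(f"sub-window {win} contains no samples")
        return matrix[:, sel].mean(axis=1)

    mean = matrix.mean(axis=0)
    sem = matrix.std(axis=0, ddof=1) / np.sqrt(matrix.shape[0]) \
        if matrix.shape[0] > 1 else np.zeros_like(mean)
    return AlignedResponse(
        matrix=matrix, time_rel_s=t_rel, window_s=window_s, mean=mean, sem=sem,
        baseline=_window_mean(baseline_window_s, 0),
        response=_window_mean(response_window_s, -1),
        event_times_s=np.asarray(kept), n_dropped=n_dropped,
    )
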