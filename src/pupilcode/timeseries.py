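"""Correlation, lagged cross-correlation and multitaper coherence.

Coherence is estimated with discrete prolate spheroidal sequence (DPSS)
tapers and Thomson adaptive weighting, using a single epoch spanning the
whole trace; per-subject spectra are averaged pointwise after clipping all
traces to a common length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

__all__ = [
    "CoherenceSpectrum",
    "correlate_and_classify",
    "cross_correlation",
    "multitaper_coherence",
    "average_coherence",
]

log = logging.getLogger(__name__)

CC_CONVENTION = "positive peak lag means the first argument leads the second"


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence on an explicit frequency axis."""

    frequency_hz: np.ndarray
    coherence: np.ndarray
    n_tapers: int
    bandwidth_hz: float              # half-bandwidth W = NW / (N dt)
    subject_spectra: np.ndarray | None = None  # (n_subjects, n_freqs)


def correlate_and_classify(cell_traces: np.ndarray, pupil: np.ndarray,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each cell with pupil size; ON if r > 0 else OFF.

    Apply to cells that survived the encoding-model r2 filter.
    """
    cells = np.atleast_2d(np.asarray(cell_traces, float))
    pupil = np.asarray(pupil, float)
    if pupil.std() == 0:
        raise ValueError("pupil trace has zero variance")
    if np.any(cells.std(axis=1) == 0):
        raise ValueError("a cell trace has zero variance")
    pz = (pupil - pupil.mean()) / pupil.std()
    cz = (cells - cells.mean(axis=1, keepdims=True)) / cells.std(axis=1, keepdims=True)
    r = cz @ pz / len(pupil)
    labels = np.where(r > 0, "ON", "OFF")
    return r, labels


def cross_correlation(x: np.ndarray, y: np.ndarray, max_lag_s: float,
                      rate_hz: float) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Normalized cross-correlation over +/- max_lag.

    cc(lag) = (1/n) * sum_t x[t] y[t + lag] / (sd_x sd_y) after mean
    removal (the biased estimator, stable at large lags).  A positive peak
    lag means x leads y.  Returns (lags_s, cc, peak_lag_s, metadata).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D traces")
    n = len(x)
    max_lag = int(round(max_lag_s * rate_hz))
    if max_lag >= n:
        raise ValueError(f"max_lag ({max_lag} samples) must be < trace length ({n})")
    xm = x - x.mean()
    ym = y - y.mean()
    denom = n * x.std() * y.std()
    if denom == 0:
        raise ValueError("zero-variance input")
    # full cross-correlation; index n-1+k holds sum_t x[t] y[t+k]
    full = np.correlate(ym, xm, mode="full")
    lags = np.arange(-max_lag, max_lag + 1)
    cc = full[n - 1 + lags] / denom
    peak_lag_s = float(lags[np.argmax(cc)] / rate_hz)
    meta = {"convention": CC_CONVENTION, "normalization": "biased (1/n)",
            "rate_hz": rate_hz}
    return lags / rate_hz, cc, peak_lag_s, meta


def _adaptive_weights(eigspectra: np.ndarray, eigvals: np.ndarray,
                      variance: float, n_iter: int = 30) -> np.ndarray:
    """Thomson adaptive taper weights d_k(f)^2 * lambda_k per frequency.

    Iterates d_k = S / (lambda_k S + (1 - lambda_k) sigma^2) with S the
    current weighted spectrum estimate.
    """
    lam = eigvals[:, None]
    s = eigspectra[:2].mean(axis=0)
    for _ in range(n_iter):
        d = s[None, :] / (lam * s[None, :] + (1.0 - lam) * variance)
        w = d * d * lam
        s_new = (w * eigspectra).sum(axis=0) / w.sum(axis=0)
        if np.allclose(s_new, s, rtol=1e-8, atol=0):
            s = s_new
            break
        s = s_new
    d = s[None, :] / (lam * s[None, :] + (1.0 - lam) * variance)
    return d * d * lam


def multitaper_coherence(x: np.ndarray, y: np.ndarray, rate_hz: float,
                         n_tapers: int = 7, nw: float = 4.0,
                         adaptive: bool = True) -> CoherenceSpectrum:
    """Magnitude-squared coherence via DPSS multitaper estimation.

    Uses the first ``n_tapers`` tapers at time-bandwidth product ``nw`` on a
    single whole-trace epoch, with per-signal adaptive eigenvalue weighting
    (Thomson's scheme) by default.  Coherence is bounded in [0, 1] and is
    exactly 1 when y is x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D traces")
    n = len(x)
    if n < 2 * n_tapers:
        raise ValueError(f"trace length {n} too short for {n_tapers} tapers")
    tapers, eigvals = dpss(n, nw, Kmax=n_tapers, return_ratios=True)
    xm = x - x.mean()
    ym = y - y.mean()
    jx = np.fft.rfft(tapers * xm[None, :], axis=1)
    jy = np.fft.rfft(tapers * ym[None, :], axis=1)
    px = np.abs(jx) ** 2
    py = np.abs(jy) ** 2
    if adaptive:
        wx = _adaptive_weights(px, eigvals, xm.var())
        wy = _adaptive_weights(py, eigvals, ym.var())
    else:
        wx = np.ones_like(px)
        wy = np.ones_like(py)
    sxx = (wx * px).sum(axis=0) / wx.sum(axis=0)
    syy = (wy * py).sum(axis=0) / wy.sum(axis=0)
    w_xy = np.sqrt(wx * wy)
    sxy = (w_xy * jx * np.conj(jy)).sum(axis=0) / np.sqrt(
        wx.sum(axis=0) * wy.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    coh = np.clip(np.nan_to_num(coh), 0.0, 1.0)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    return CoherenceSpectrum(frequency_hz=freqs, coherence=coh,
                             n_tapers=n_tapers,
                             bandwidth_hz=nw * rate_hz / n)


def average_coherence(pairs: list[tuple[np.ndarray, np.ndarray]], rate_hz: float,
                      n_tapers: int = 7, nw: float = 4.0,
                      adaptive: bool = True) -> CoherenceSpectrum:
    """Per-subject coherence averaged pointwise.

    All traces are clipped to the shortest length across subjects so the
    frequency axes coincide, then spectra are averaged.
    """
    if not pairs:
        raise ValueError("need at least one (x, y) pair")
    n_min = min(min(len(x), len(y)) for x, y in pairs)
    log.info("clipping %d subjects to %d samples before coherence", len(pairs), n_min)
    spectra = [
        multitaper_coherence(x[:n_min], y[:n_min], rate_hz,
                             n_tapers=n_tapers, nw=nw, adaptive=adaptive)
        for x, y in pairs
    ]
    stack = np.vstack([s.coherence for s in spectra])
    return CoherenceSpectrum(frequency_hz=spectra[0].frequency_hz,
                             coherence=stack.mean(axis=0),
                             n_tapers=n_tapers,
                             bandwidth_hz=spectra[0].bandwidth_hz,
                             subject_spectra=stack)
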