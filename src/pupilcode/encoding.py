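"""Per-cell encoding model and variance partitioning.

Each cell's activity is regressed (ordinary least squares, with intercept)
on z-scored pupil size, running speed and a reward-consumption regressor —
the lick square wave convolved with a causal spline kernel chosen from a
candidate basis by a cross-cell vote.  The unique contribution of predictor
v is 100 * (1 - r2_without_v / r2_full): the fraction of the full model's
explained variance lost when v is removed.  Cells whose full model explains
less than 5 % of variance are dropped before partitioning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplineBasis",
    "PredictorSet",
    "default_spline_basis",
    "build_reward_regressor",
    "build_predictor_set",
    "fit_full_model",
    "filter_cells",
    "variance_contributions",
    "classify_cells",
    "classify_one",
    "encode_session",
    "zscore",
]

log = logging.getLogger(__name__)

PREDICTORS = ("pupil", "locomotion", "reward")
R2_THRESHOLD = 0.05


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance trace")
    return (x - x.mean()) / sd


@dataclass
class SplineBasis:
    """Candidate set of causal reward kernels.

    Kernels are non-negative, finitely supported, unit-area raised-cosine
    bumps sampled at the cell rate; supports are log-spaced.
    """

    kernels: list[np.ndarray]
    supports_s: np.ndarray
    rate_hz: float

    def __len__(self) -> int:
        return len(self.kernels)


def default_spline_basis(rate_hz: float, n_kernels: int = 8,
                         support_min_s: float = 0.5,
                         support_max_s: float = 8.0) -> SplineBasis:
    supports = np.geomspace(support_min_s, support_max_s, n_kernels)
    kernels = []
    for sup in supports:
        n = max(int(round(sup * rate_hz)), 2)
        t = np.arange(n) / rate_hz
        k = 1.0 - np.cos(2 * np.pi * np.minimum(t / sup, 1.0))
        k /= k.sum() / rate_hz
        kernels.append(k)
    return SplineBasis(kernels=kernels, supports_s=supports, rate_hz=rate_hz)


@dataclass
class PredictorSet:
    """Z-scored predictors on the cell clock, as a design matrix."""

    time_s: np.ndarray
    pupil: np.ndarray
    locomotion: np.ndarray
    reward: np.ndarray | None        # None when the lick wave is degenerate
    chosen_kernel_index: int | None = None
    names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.names = tuple(
            n for n, v in zip(PREDICTORS, (self.pupil, self.locomotion, self.reward))
            if v is not None)

    @property
    def matrix(self) -> np.ndarray:
        cols = [v for v in (self.pupil, self.locomotion, self.reward) if v is not None]
        return np.column_stack(cols)


def fit_full_model(cell_trace: np.ndarray, predictors: np.ndarray,
                   names: tuple[str, ...] | None = None,
                   ) -> tuple[np.ndarray, float, float]:
    """OLS with intercept: returns (coefficients, intercept, r2)."""
    y = np.asarray(cell_trace, float)
    x = np.atleast_2d(np.asarray(predictors, float))
    if x.shape[0] != len(y):
        raise ValueError("cell trace and predictors must have equal length")
    n, p = x.shape
    if n < 10 * p:
        raise ValueError(f"need >= 10x more samples than predictors (n={n}, p={p})")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("inputs must be finite")
    design = np.column_stack([np.ones(n), x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (names[i] if names else i, names[j] if names else j)
            for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear predictors: {pairs}")
    resid = y - design @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("cell trace has zero variance")
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    return coef[1:], float(coef[0]), float(r2)


def build_reward_regressor(lick_wave: np.ndarray, basis: SplineBasis,
                           cell_traces: np.ndarray,
                           other_predictors: np.ndarray,
                           method: str = "vote",
                           ) -> tuple[int | None, np.ndarray | None, np.ndarray | None]:
    """Pick the reward kernel and return the convolved, z-scored regressor.

    Each candidate kernel is convolved with the lick square wave; the full
    model is fitted per cell for each candidate.  ``method='vote'`` (default)
    chooses the kernel with the best full-model r2 for the largest number of
    cells (ties -> earlier kernel); ``method='mean'`` maximizes mean r2.
    Returns (kernel index, kernel, regressor); all None when the lick wave
    has no variance (with a logged warning).
    """
    if len(basis) == 0:
        raise ValueError("empty spline basis")
    lick = np.asarray(lick_wave, float)
    cells = np.atleast_2d(np.asarray(cell_traces, float))
    if lick.std() == 0:
        warnings.warn("lick wave has zero variance; reward regressor excluded")
        log.warning("lick wave has zero variance; reward regressor excluded")
        return None, None, None
    n = len(lick)
    r2 = np.zeros((len(basis), cells.shape[0]))
    regs = []
    for ki, kernel in enumerate(basis.kernels):
        reg = zscore(np.convolve(lick, kernel)[:n])
        regs.append(reg)
        design = np.column_stack([other_predictors, reg])
        for ci, cell in enumerate(cells):
            _, _, r2[ki, ci] = fit_full_model(cell, design)
    if method == "vote":
        votes = np.bincount(np.argmax(r2, axis=0), minlength=len(basis))
        chosen = int(np.argmax(votes))
        log.info("reward kernel votes: %s -> kernel %d (support %.2f s)",
                 votes.tolist(), chosen, basis.supports_s[chosen])
    elif method == "mean":
        chosen = int(np.argmax(r2.mean(axis=1)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return chosen, basis.kernels[chosen], regs[chosen]


def build_predictor_set(time_s: np.ndarray, pupil: np.ndarray,
                        locomotion: np.ndarray, lick_wave: np.ndarray,
                        cell_traces: np.ndarray,
                        basis: SplineBasis | None = None,
                        method: str = "vote") -> PredictorSet:
    """Z-score raw predictors and attach the vote-chosen reward regressor."""
    if basis is None:
        basis = default_spline_basis(1.0 / float(time_s[1] - time_s[0]))
    pupil_z = zscore(pupil)
    loco_z = zscore(locomotion)
    others = np.column_stack([pupil_z, loco_z])
    idx, _, reward = build_reward_regressor(lick_wave, basis, cell_traces,
                                            others, method=method)
    return PredictorSet(time_s=np.asarray(time_s, float), pupil=pupil_z,
                        locomotion=loco_z, reward=reward,
                        chosen_kernel_index=idx)


def filter_cells(r2_full: np.ndarray, threshold: float = R2_THRESHOLD) -> np.ndarray:
    """Boolean mask of kept cells: full-model r2 >= threshold (boundary kept)."""
    r2_full = np.asarray(r2_full, float)
    kept = r2_full >= threshold
    log.info("r2 filter at %.2f: kept %d / %d cells", threshold,
             int(kept.sum()), len(kept))
    if not kept.any():
        warnings.warn("no cell passes the r2 filter")
    return kept


def variance_contributions(cell_trace: np.ndarray, predictors: np.ndarray,
                           ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-predictor-out partitioning of explained variance.

    Returns (r2_full, r2_reduced per predictor, contribution % floored at 0,
    raw contribution %).  contribution(v) = 100 * (1 - r2_without_v / r2_full);
    with correlated predictors the raw values need not sum to 100.
    """
    x = np.atleast_2d(np.asarray(predictors, float))
    _, _, r2_full = fit_full_model(cell_trace, x)
    if r2_full <= 0:
        raise ValueError("full-model r2 is zero; filter cells before partitioning")
    p = x.shape[1]
    r2_reduced = np.empty(p)
    for j in range(p):
        keep = [k for k in range(p) if k != j]
        if keep:
            _, _, r2_reduced[j] = fit_full_model(cell_trace, x[:, keep])
        else:
            r2_reduced[j] = 0.0
    raw = 100.0 * (1.0 - r2_reduced / r2_full)
    return float(r2_full), r2_reduced, np.maximum(raw, 0.0), raw


def classify_one(contrib: dict[str, float], major_cutoff: float = 20.0) -> str:
    """Label a cell from its pupil/reward contributions at the major cutoff."""
    p = contrib.get("pupil", 0.0) >= major_cutoff
    r = contrib.get("reward", 0.0) >= major_cutoff
    if p and r:
        return "both"
    if p:
        return "pupil"
    if r:
        return "reward"
    return "other"


def classify_cells(contrib: pd.DataFrame, major_cutoff: float = 20.0,
                   minor_cutoff: float = 10.0,
                   ) -> tuple[pd.Series, dict[str, int], dict[str, np.ndarray]]:
    """Label cells and tabulate the >minor_cutoff per-variable distributions.

    Returns (labels, category counts, per-variable contribution arrays for
    cells above the minor cutoff).
    """
    labels = contrib.apply(
        lambda row: classify_one(row.to_dict(), major_cutoff), axis=1)
    counts = {k: int((labels == k).sum()) for k in ("pupil", "reward", "both", "other")}
    above_minor = {
        col: contrib.loc[contrib[col] > minor_cutoff, col].to_numpy()
        for col in contrib.columns
    }
    return labels, counts, above_minor


def encode_session(cell_traces: np.ndarray, predictors: PredictorSet,
                   r2_threshold: float = R2_THRESHOLD,
                   major_cutoff: float = 20.0) -> pd.DataFrame:
    """Fit the full and reduced models for every cell; return a tidy table.

    Columns: r2_full, coef_*, r2_minus_*, contrib_* (floored),
    contrib_*_raw, kept, label.  Contributions and labels are only defined
    for kept cells (NaN / '' otherwise).
    """
    cells = np.atleast_2d(np.asarray(cell_traces, float))
    x = predictors.matrix
    names = predictors.names
    rows = []
    for ci, cell in enumerate(cells):
        coef, _, r2_full = fit_full_model(cell, x, names)
        row: dict[str, object] = {"cell_id": ci, "r2_full": r2_full}
        for j, nm in enumerate(names):
            row[f"coef_{nm}"] = coef[j]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("cell_id")
    table["kept"] = filter_cells(table["r2_full"].to_numpy(), r2_threshold)

    for nm in names:
        table[f"r2_minus_{nm}"] = np.nan
        table[f"contrib_{nm}"] = np.nan
        table[f"contrib_{nm}_raw"] = np.nan
    table["label"] = ""
    for ci in table.index[table["kept"]]:
        r2_full, r2_red, contrib, raw = variance_contributions(cells[ci], x)
        if np.any(r2_red > r2_full + 1e-12):
            raise AssertionError("nested-model monotonicity violated")
        for j, nm in enumerate(names):
            table.loc[ci, f"r2_minus_{nm}"] = r2_red[j]
            table.loc[ci, f"contrib_{nm}"] = contrib[j]
            table.loc[ci, f"contrib_{nm}_raw"] = raw[j]
        table.loc[ci, "label"] = classify_one(
            {nm: contrib[j] for j, nm in enumerate(names)}, major_cutoff)
    return table
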