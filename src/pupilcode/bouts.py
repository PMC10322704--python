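"""Running-bout detection, k-means bout matching and group comparisons.

Running bouts are contiguous epochs of wheel speed above a 1 cm/s binary
threshold.  To compare pupil dynamics across groups without locomotion
confounds, bouts from both groups are pooled, z-scored and clustered with
Lloyd's k-means (<= 1000 iterations); clusters in which both groups run
with indistinguishable mean speed profiles supply the matched bout sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "RunningBout",
    "GroupTestResult",
    "detect_bouts",
    "lloyd_kmeans",
    "cluster_bouts",
    "match_equivalent_bouts",
    "run_rest_partition",
    "compare_groups",
]

log = logging.getLogger(__name__)

RUN_THRESHOLD_CMPS = 1.0


@dataclass
class RunningBout:
    """One supra-threshold running epoch with a fixed peri-onset profile."""

    onset_s: float
    offset_s: float
    profile_cmps: np.ndarray         # raw speed over the peri-onset window
    profile_z: np.ndarray            # per-bout z-scored profile (k-means input)
    subject_id: str = ""
    group_id: str = ""

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("bout offset must exceed onset")


def detect_bouts(speed_cmps: np.ndarray, rate_hz: float,
                 run_threshold: float = RUN_THRESHOLD_CMPS,
                 min_duration_s: float = 1.0, merge_gap_s: float = 0.5,
                 window_s: tuple[float, float] = (-2.0, 8.0),
                 subject_id: str = "", group_id: str = "",
                 ) -> list[RunningBout]:
    """Threshold-crossing bout detection with gap merging.

    Epochs above ``run_threshold`` separated by gaps shorter than
    ``merge_gap_s`` are merged; epochs shorter than ``min_duration_s`` are
    dropped.  Each bout's speed profile is extracted over a fixed peri-onset
    window (default -2 to +8 s); bouts whose window leaves the trace are
    dropped from the profile set (logged).
    """
    speed = np.asarray(speed_cmps, float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    above = speed > run_threshold
    if not above.any():
        log.info("no samples above %.2f cm/s: no bouts", run_threshold)
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)   # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(speed))

    merged: list[list[int]] = []
    max_gap = int(round(merge_gap_s * rate_hz))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_len = int(round(min_duration_s * rate_hz))
    i_pre = int(round(window_s[0] * rate_hz))
    i_post = int(round(window_s[1] * rate_hz))
    bouts: list[RunningBout] = []
    n_edge = 0
    for s, e in merged:
        if e - s < min_len:
            continue
        lo, hi = s + i_pre, s + i_post
        if lo < 0 or hi >= len(speed):
            n_edge += 1
            continue
        profile = speed[lo:hi + 1]
        sd = profile.std()
        profile_z = (profile - profile.mean()) / sd if sd > 0 else np.zeros_like(profile)
        bouts.append(RunningBout(
            onset_s=s / rate_hz, offset_s=e / rate_hz,
            profile_cmps=profile, profile_z=profile_z,
            subject_id=subject_id, group_id=group_id))
    if n_edge:
        log.info("dropped %d bouts without a full peri-onset window", n_edge)
    return bouts


def lloyd_kmeans(points: np.ndarray, k: int, seed: int,
                 max_iter: int = 1000, tol: float = 1e-6,
                 ) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd's k-means with k-means++ initialization.

    Runs at most ``max_iter`` assignment/update sweeps or until the centroid
    shift falls below ``tol``.  Returns (labels, centroids, per-iteration
    within-cluster sum of squares), the latter non-increasing by
    construction.
    """
    x = np.asarray(points, float)
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.RandomState(seed)
    centroids, _ = kmeans_plusplus(x, n_clusters=k, random_state=rng)
    inertia_history: list[float] = []
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        inertia_history.append(float(d2[np.arange(n), labels].sum()))
        new_centroids = centroids.copy()
        for j in range(k):
            members = x[labels == j]
            if len(members):
                new_centroids[j] = members.mean(axis=0)
            else:                     # re-seed an empty cluster at the worst point
                new_centroids[j] = x[np.argmax(d2[np.arange(n), labels])]
        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    inertia_history.append(float(d2[np.arange(n), labels].sum()))
    return labels, centroids, inertia_history


def cluster_bouts(bouts: list[RunningBout], k: int, seed: int,
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd k-means on z-scored bout profiles; returns (labels, centroids,
    within-cluster SS)."""
    if len(bouts) < k:
        raise ValueError(f"need >= {k} bouts, got {len(bouts)}")
    x = np.vstack([b.profile_z for b in bouts])
    labels, centroids, history = lloyd_kmeans(x, k, seed)
    return labels, centroids, history[-1]


def match_equivalent_bouts(bouts_a: list[RunningBout], bouts_b: list[RunningBout],
                           k: int, seed: int,
                           tolerance_cmps: float = 0.5,
                           ) -> tuple[list[RunningBout], list[RunningBout], dict]:
    """Select clusters of equivalent running bouts across two groups.

    Pools and clusters all bouts; keeps clusters where both groups appear
    and their mean raw-speed profiles differ by less than
    ``tolerance_cmps`` at every time point.  Returns the per-group matched
    bout lists plus diagnostics; raises if no cluster qualifies.
    """
    if not bouts_a or not bouts_b:
        raise ValueError("both groups must contribute bouts")
    pooled = list(bouts_a) + list(bouts_b)
    is_a = np.array([True] * len(bouts_a) + [False] * len(bouts_b))
    labels, _, _ = cluster_bouts(pooled, k, seed)
    profiles = np.vstack([b.profile_cmps for b in pooled])
    diagnostics: dict = {"clusters": {}}
    matched_a: list[RunningBout] = []
    matched_b: list[RunningBout] = []
    qualifying = []
    for j in range(k):
        in_j = labels == j
        na, nb = int((in_j & is_a).sum()), int((in_j & ~is_a).sum())
        if na == 0 or nb == 0:
            diagnostics["clusters"][j] = {"n_a": na, "n_b": nb, "max_diff": None}
            continue
        diff = np.abs(profiles[in_j & is_a].mean(axis=0)
                      - profiles[in_j & ~is_a].mean(axis=0)).max()
        diagnostics["clusters"][j] = {"n_a": na, "n_b": nb, "max_diff": float(diff)}
        if diff < tolerance_cmps:
            qualifying.append(j)
            matched_a += [b for b, l, a in zip(pooled, labels, is_a) if l == j and a]
            matched_b += [b for b, l, a in zip(pooled, labels, is_a) if l == j and not a]
    diagnostics["qualifying"] = qualifying
    if not qualifying:
        raise ValueError(f"no cluster with matched speed profiles; diagnostics: {diagnostics}")
    return matched_a, matched_b, diagnostics


def run_rest_partition(speed_cmps: np.ndarray,
                       threshold: float = RUN_THRESHOLD_CMPS,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Complementary run/rest masks at the binary speed threshold."""
    speed = np.asarray(speed_cmps, float)
    run = speed > threshold
    return run, ~run


@dataclass
class GroupTestResult:
    test: str
    tail: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    paired: bool


def compare_groups(values_a: np.ndarray, values_b: np.ndarray,
                   test: str = "ttest", tail: str = "two-sided",
                   paired: bool = False) -> GroupTestResult:
    """Standard two-group tests (t-test / Mann-Whitney U) as thin wrappers.

    ``tail`` follows scipy ('two-sided', 'less', 'greater'; 'greater' means
    A > B).  A paired t-test on identical samples yields t = 0 and an
    undefined p (NaN, warned).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal-length samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if test == "ttest":
            if paired:
                if np.all(a - b == (a - b)[0]):
                    warnings.warn("zero-variance paired differences: p undefined",
                                  stacklevel=2)
                    res_stat, res_p = (0.0 if np.allclose(a, b) else np.inf), np.nan
                else:
                    r = stats.ttest_rel(a, b, alternative=tail)
                    res_stat, res_p = float(r.statistic), float(r.pvalue)
            else:
                r = stats.ttest_ind(a, b, alternative=tail)
                res_stat, res_p = float(r.statistic), float(r.pvalue)
        elif test == "mannwhitney":
            r = stats.mannwhitneyu(a, b, alternative=tail)
            res_stat, res_p = float(r.statistic), float(r.pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
    return GroupTestResult(test=test, tail=tail, statistic=res_stat,
                           p_value=res_p, n_a=len(a), n_b=len(b), paired=paired)
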