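# Methods

This note documents the models, estimators and numerical choices behind
`pupilcode`, and what the synthetic sessions used for testing do and do not
emulate.

## Pupil extraction

Each video frame is reduced to 8 landmark points on the pupil edge with a
per-point confidence, the output format of markerless trackers such as
DeepLabCut. The circle fit is the algebraic least-squares (Kåsa) fit: with
the circle written as x² + y² + Dx + Ey + F = 0, the coefficients solve a
3-column linear system in closed form, so the fit is deterministic, exact
for points on a true circle, and invariant to point order and rigid motion
(radius) — properties the test suite asserts. We chose the algebraic fit
over an iterative geometric fit because it has no initialization or
convergence behavior; on mildly jittered points the two agree to well
within the jitter scale (checked against a brute-force geometric grid
search).

Points whose confidence falls below a threshold (default **0.9**,
configurable; a conventional value for likelihood-gated landmark tracking)
are replaced, per landmark, by linear interpolation of that landmark's
coordinates between the nearest flanking confident frames; leading and
trailing gaps hold the nearest valid value. When a frame's fit itself is
degenerate (collinear or <3 usable points) the radius is interpolated
instead. Interpolating coordinates before fitting preserves information
when only some points are low-confidence; interpolation is linear because
nothing in the data argues for more structure, and it guarantees the
interpolated value lies between its anchors (no extrapolation).

Event-aligned responses slice fixed windows around event times, dropping
(and counting) events whose window leaves the trace; baseline and response
are means over configurable sub-windows, with s.e.m. computed over retained
events. The stimulation-train summary (mean over the last 10 s of a 30 s
train) and the run-onset probes at −2 s and +6 s are thin uses of this one
operation.

## Fluorescence preprocessing

Imaging pipeline, fixed order: **correct → merge → smooth → z-score**.

* Neuropil correction subtracts the halo ROI trace from the cell ROI trace
  sample-wise, with no scaling coefficient.
* ΔF/F baseline: F0 is the **10th percentile** (configurable) of the
  corrected trace, ΔF/F = (F − F0)/|F0|. A percentile baseline is standard
  practice for slow indicators; the floor check (|F0| ≤ 10⁻⁶ × trace
  scale) turns silent division blow-ups into an explicit error, which also
  catches the pathological cell≡halo case.
* Duplicate-plane merging averages (unweighted) the ΔF/F traces of ROIs
  that image the same cell on multiple Z-planes.
* Smoothing is a centered 3-sample moving average whose window shrinks at
  the edges (no phantom zeros, length preserved), followed by z-scoring
  over the whole trace.

Photometry pipeline: **detrend → z-score**. The detrending template is
built from the lower convex hull of (sample index, value): hull vertices
are scanned forward in time, keeping the first vertex and every vertex
whose value strictly decreases; the kept vertices are linearly interpolated
to full length, holding the last kept value to the end. This removes a
monotone photobleaching envelope while provably never rising (the template
is non-increasing by construction, asserted in tests). A residual with no
variance means the input was pure trend and raises rather than returning
a z-scored zero trace. An alternative reading of "decreasing hull" is a
running-minimum envelope; we implement the literal lower hull, which is
smoother and subsumes the running minimum at the kept vertices.

## Encoding model

Per cell: ordinary least squares with intercept of the (smoothed,
z-scored) activity trace on three z-scored predictors — pupil radius,
running speed, and reward consumption. No train/test split and no
regularization: the quantity of interest is in-sample explained variance.

The reward predictor is the lick square wave convolved with a causal
kernel from a candidate basis: **8 raised-cosine bumps with log-spaced
supports 0.5–8 s**, non-negative and unit-area. The basis is a documented
default (the historical spline set this stands in for is not published);
any basis can be supplied from file. The kernel is elected by a
cross-cell vote: for each candidate, the full model is fitted to every
cell, each cell votes for its argmax-r² kernel, and the kernel with most
votes wins (ties → earlier kernel). A mean-r² criterion is also
implemented (`method="mean"`); the vote is the default because it is
robust to a few high-r² outlier cells. A zero-variance lick wave excludes
the reward predictor with a warning rather than crashing the session.

Cells with full-model r² < 0.05 are removed (boundary value kept). For
each kept cell the model is refitted with one predictor left out, and the
contribution of predictor *v* is

  contribution(v) = 100 × (1 − r²₋ᵥ / r²_full),

the percentage of the full model's explained variance lost when *v* is
removed. With correlated predictors the raw values need not sum to 100 and
can be marginally negative; negatives are floored at 0 and raw values are
reported alongside. Nested-model monotonicity (r²₋ᵥ ≤ r²_full) holds
exactly for OLS with intercept and is asserted on every run. Cells are
labelled pupil / reward / both / other by comparing the pupil and reward
contributions to a **20 %** cutoff; per-variable histograms above a 10 %
cutoff are also emitted.

## Time-series statistics

* ON/OFF classing: sign of the Pearson correlation with pupil size,
  applied to cells surviving the r² filter.
* Cross-correlation: biased estimator, cc(ℓ) = (1/n)Σₜ x[t]y[t+ℓ]/(σₓσᵧ)
  after mean removal. The biased (1/n) normalization keeps large-lag values
  stable. Convention, stated in the output metadata: a positive peak lag
  means the **first** argument leads.
* Coherence: DPSS multitaper, **K = 7 tapers**, time–bandwidth product
  **NW = 4** (NW = 4 yields at least 7 well-concentrated tapers; the taper
  count is the specified quantity, NW is our choice), single epoch spanning
  the whole trace, Thomson adaptive weighting iterated per signal. The
  cross-spectrum combines per-signal weights as √(wₓwᵧ), which keeps
  coherence in [0, 1] by Cauchy–Schwarz and makes self-coherence exactly 1.
  Subject averaging clips all traces to the shortest length so frequency
  axes coincide, then averages spectra pointwise. For independent inputs
  the K-taper estimator has a known bias floor with mean 1/K (Beta(1, K−1)
  null); the tests check the Monte-Carlo floor against it.

## Bout analysis

Running bouts are epochs of speed > 1 cm/s (the same binary threshold
partitions whole sessions into run/rest). Defaults chosen where the
protocol leaves them open: minimum bout duration **1 s**, merge gap
**0.5 s**, peri-onset profile window **−2 to +8 s** (contains both probe
times, −2 s and +6 s). Clustering of z-scored bout profiles uses Lloyd's
algorithm (assignment/update sweeps, ≤ **1000 iterations**, centroid-shift
tolerance 10⁻⁶) with k-means++ initialization from a fixed seed; the
within-cluster sum of squares is recorded per iteration and is
non-increasing by construction. The implementation is in-package so this
invariant can be asserted per iteration; it is cross-checked against
scikit-learn's Lloyd solver in the tests. Default **k = 4**, configurable;
no k is canonical, and an elbow table can be produced from the returned
inertia.

Cross-group bout matching pools both groups' bouts, clusters them, and
keeps clusters where (a) both groups are represented and (b) the two
groups' mean raw-speed profiles differ by less than **0.5 cm/s** at every
time point (the equivalence tolerance is our operationalization of
"equivalent running bouts"; no numeric criterion exists to inherit).
Matched sets feed event-aligned pupil comparisons; group tests are thin
wrappers over scipy's t and Mann–Whitney implementations that make n,
tail and pairing explicit and handle the zero-variance paired case (t = 0,
p undefined) with a warning.

## Synthetic sessions and ground truth

The generator emulates the recording design end-to-end: 20 Hz pupil
camera, 5.15 Hz imaging clock, rewards at uniform random 60–90 s intervals
(50 per full session, hence a 75 min default duration), Bernoulli lick
bursts in a 0.1–2.1 s post-reward window, two-state running bouts with
rectangular speed envelopes (smoothed by a 3-sample moving average so the
1 cm/s crossing stays within one sample of the generative switch time),
and 30 s stimulation trains at 1/5/10/20 Hz every 2–2.5 min.

Latent arousal is a stationary Ornstein–Uhlenbeck process (correlation
time 20 s) — chosen for stationarity and a closed-form autocovariance, not
as a biological claim. Pupil radius is a first-order low-pass (τ = 1 s) of
arousal + locomotion coupling + post-reward transients, so neural signals
built from the same drive lead dilation, as the cross-correlation analyses
assume. Each cell is baseline + (weights · calcium-convolved z-scored
predictors) + white noise, with a GCaMP6s-like exponential kernel
(τ = 1.2 s); the halo carries shared slow contamination plus a 5 % leak of
the cell signal, which neuropil subtraction must remove. Landmarks are 8
equally spaced points on the true circle with 0.5 px Gaussian jitter;
blinks are confidence drops, not geometric occlusion, because the
extraction path only consumes confidence.

Ground truth is computed analytically from the realized predictor
covariance: the covariance decomposition wⱼ·Cov(qⱼ, s)/Var(total) gives
variance shares that sum with the noise share to exactly 1, and the
conditional-variance form wⱼ²·Var(qⱼ|q₋ⱼ)/Var(s) gives the leave-one-out
contributions the encoding model estimates; class labels apply the 20 %
rule to the latter. Designed sessions interleave four cell classes
(pupil-only, reward-only, mixed, locomotion) with major weights 0.6–1.4
and minor weights 0.1–0.3, producing a graded spread of true shares for
rank-recovery tests.

What the generator does **not** emulate: eye-lid geometry and corneal
reflections, imaging motion artifacts and ROI segmentation errors,
nonlinear indicator dynamics and saturation, non-stationary arousal
regimes, and correlated (shared-noise) variability across cells. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative assumptions, not robustness to these real-data
failure modes.

## Problem sizes and determinism

The recovery tests use a 30-minute, 60-cell session (20 rewards — a 30 min
session cannot hold 50 rewards at a ≥60 s spacing) at the native 5.15 Hz
cell clock; calibration tests use 1000 null cells of 2000 samples; the
two-group scenario uses 8 control and 7 ablated subjects, 3 min each, with
a designed 2 px (2 between-subject s.d.) resting-pupil deficit, over 100
seeds. Coherence constructions use 1024-sample epochs at 20 Hz averaged
over 60 synthetic subjects, giving a resolution half-bandwidth of
NW/T ≈ 0.078 Hz.

All randomness flows from explicit integer seeds (one per manifest, fanned
out per stage); identical configurations produce bit-identical arrays, and
the report stage writes canonical JSON (sorted keys, fixed separators) so
repeated runs are byte-identical.

## Known limitations

* The contribution percentages are unique contributions; strongly
  collinear predictors shrink everyone's unique share, and the floored
  values discard suppressor effects (raw values are reported for those).
* The Kåsa fit is biased toward smaller radii under large noise; at the
  landmark jitter levels of tracked video (≲1 px on a ≳20 px pupil) the
  bias is far below the jitter-propagated noise floor.
* Whole-trace single-epoch coherence has high per-frequency variance; the
  intended use averages across subjects, and conclusions at single
  frequencies of single subjects should not be drawn.
* `match_equivalent_bouts` guarantees speed equivalence only at the
  cluster-mean level; per-bout covariates (acceleration, bout history) are
  out of scope.
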