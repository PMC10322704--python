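"""Encoding model: OLS contracts, kernel vote, variance partitioning."""

import numpy as np
import pytest

from pupilcode import synthetic as syn
from pupilcode.encoding import (build_predictor_set, build_reward_regressor,
                                classify_one, default_spline_basis,
                                encode_session, filter_cells, fit_full_model,
                                variance_contributions, zscore)


@pytest.fixture(scope="module")
def ortho_predictors(rng_seed=99):
    """Three exactly orthonormal, zero-mean predictors (QR against a ones
    column so they are also orthogonal to the intercept)."""
    rng = np.random.default_rng(rng_seed)
    n = 2000
    q, _ = np.linalg.qr(np.column_stack([np.ones(n),
                                         rng.standard_normal((n, 3))]))
    return q[:, 1:] * np.sqrt(n)  # unit variance, zero mean, zero correlation


class TestFitFullModel:
    def test_identity_cell(self, ortho_predictors):
        x = ortho_predictors
        coef, intercept, r2 = fit_full_model(x[:, 0], x)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert coef == pytest.approx([1.0, 0.0, 0.0], abs=1e-9)

    def test_exact_linear_combination(self, ortho_predictors):
        x = ortho_predictors
        y = 0.6 * x[:, 0] + 0.8 * x[:, 1]
        coef, _, r2 = fit_full_model(y, x)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert coef == pytest.approx([0.6, 0.8, 0.0], abs=1e-9)

    def test_normal_equations_match_pinv_oracle(self, rng):
        """Independent solver: explicit pseudo-inverse on small instances."""
        for _ in range(5):
            x = rng.standard_normal((50, 3))
            y = rng.standard_normal(50)
            coef, intercept, _ = fit_full_model(y, x)
            design = np.column_stack([np.ones(50), x])
            beta = np.linalg.pinv(design) @ y
            assert intercept == pytest.approx(beta[0], abs=1e-9)
            assert coef == pytest.approx(beta[1:], abs=1e-9)

    def test_collinear_design_raises(self, rng):
        a = rng.standard_normal(100)
        with pytest.raises(ValueError, match="collinear"):
            fit_full_model(rng.standard_normal(100),
                           np.column_stack([a, a, rng.standard_normal(100)]))

    def test_too_few_samples_raises(self, rng):
        with pytest.raises(ValueError, match="10x"):
            fit_full_model(rng.standard_normal(20), rng.standard_normal((20, 3)))

    def test_null_r2_matches_analytic_expectation(self, rng):
        """Under the null, E[r2] = p/(n-1); check the mean over many noise
        cells against the Beta-distribution standard error."""
        n, p, n_cells = 500, 3, 400
        x = rng.standard_normal((n, p))
        r2s = np.array([fit_full_model(rng.standard_normal(n), x)[2]
                        for _ in range(n_cells)])
        expected = p / (n - 1)
        # r2 ~ Beta(p/2, (n-1-p)/2) under the null
        var = 2 * p * (n - 1 - p) / ((n - 1) ** 2 * (n + 1))
        assert abs(r2s.mean() - expected) < 3 * np.sqrt(var / n_cells)


class TestBuildRewardRegressor:
    def test_single_kernel_basis_is_chosen(self, rng):
        rate = 5.0
        basis = default_spline_basis(rate, n_kernels=1)
        lick = (rng.random(1000) < 0.05).astype(float)
        cells = rng.standard_normal((3, 1000))
        others = rng.standard_normal((1000, 2))
        idx, kernel, reg = build_reward_regressor(lick, basis, cells, others)
        assert idx == 0
        assert reg.std() == pytest.approx(1.0)

    def test_generative_kernel_wins_the_vote(self, rng):
        """Cells built from kernel index 1 of a 3-kernel basis must elect it."""
        rate = 5.0
        n = 3000
        basis = default_spline_basis(rate, n_kernels=3, support_min_s=0.5,
                                     support_max_s=8.0)
        lick = (rng.random(n) < 0.03).astype(float)
        true_reg = zscore(np.convolve(lick, basis.kernels[1])[:n])
        others = rng.standard_normal((n, 2))
        cells = np.vstack([
            1.0 * true_reg + 0.3 * rng.standard_normal(n) for _ in range(10)])
        idx, _, _ = build_reward_regressor(lick, basis, cells, others)
        assert idx == 1

    def test_zero_lick_wave_excluded_with_warning(self, rng):
        basis = default_spline_basis(5.0, n_kernels=2)
        with pytest.warns(UserWarning, match="zero variance"):
            idx, kernel, reg = build_reward_regressor(
                np.zeros(500), basis, rng.standard_normal((2, 500)),
                rng.standard_normal((500, 2)))
        assert idx is None and reg is None

    def test_empty_basis_raises(self, rng):
        from pupilcode.encoding import SplineBasis
        empty = SplineBasis(kernels=[], supports_s=np.array([]), rate_hz=5.0)
        with pytest.raises(ValueError, match="empty"):
            build_reward_regressor(np.ones(100), empty,
                                   rng.standard_normal((1, 100)),
                                   rng.standard_normal((100, 2)))

    def test_basis_kernels_are_normalized(self):
        basis = default_spline_basis(5.15)
        for k in basis.kernels:
            assert np.all(k >= 0)
            assert k.sum() / 5.15 == pytest.approx(1.0)


class TestFilterCells:
    def test_boundary_is_inclusive(self):
        kept = filter_cells(np.array([0.04, 0.05, 0.9]))
        assert kept.tolist() == [False, True, True]

    def test_all_below_warns_empty(self):
        with pytest.warns(UserWarning, match="no cell"):
            kept = filter_cells(np.array([0.01, 0.02]))
        assert not kept.any()

    def test_signal_vs_noise_cells(self, rng):
        """Signal cells always pass; noise-cell pass rate matches the
        simulated null tail."""
        n = 2000
        x = rng.standard_normal((n, 3))
        signal = np.vstack([x @ rng.uniform(0.5, 1, 3)
                            + 0.5 * rng.standard_normal(n) for _ in range(30)])
        noise = rng.standard_normal((30, n))
        r2 = np.array([fit_full_model(c, x)[2] for c in np.vstack([signal, noise])])
        kept = filter_cells(r2)
        assert kept[:30].all()
        # null tail: P(r2 >= 0.05) at n=2000 is ~1e-17; no noise cell passes
        assert not kept[30:].any()


class TestVarianceContributions:
    def test_single_predictor_cell_gets_100(self, ortho_predictors):
        x = ortho_predictors
        r2_full, r2_red, contrib, _ = variance_contributions(x[:, 0], x)
        assert contrib[0] == pytest.approx(100.0, abs=1e-9)
        assert contrib[1:] == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_orthogonal_shares_are_exact(self, ortho_predictors):
        """Variance shares 0.75/0.25 on orthonormal predictors partition
        exactly into 75% and 25% contributions."""
        x = ortho_predictors
        y = np.sqrt(0.75) * x[:, 0] + np.sqrt(0.25) * x[:, 1]
        _, _, contrib, _ = variance_contributions(y, x)
        assert contrib == pytest.approx([75.0, 25.0, 0.0], abs=1e-6)

    def test_irrelevant_predictor_contributes_nothing(self, ortho_predictors):
        x = ortho_predictors
        rng = np.random.default_rng(5)
        y = x[:, 0] + 0.1 * rng.standard_normal(len(x))
        _, _, contrib, _ = variance_contributions(y, x)
        assert contrib[2] < 0.5

    def test_nested_monotonicity(self, rng):
        x = rng.standard_normal((500, 3))
        x[:, 2] = 0.7 * x[:, 0] + 0.3 * rng.standard_normal(500)  # correlated
        for _ in range(20):
            y = x @ rng.uniform(-1, 1, 3) + rng.standard_normal(500)
            r2_full, r2_red, _, _ = variance_contributions(y, x)
            assert np.all(r2_red <= r2_full + 1e-12)


class TestClassify:
    @pytest.mark.parametrize("contrib,expected", [
        ({"pupil": 90.0, "reward": 5.0, "locomotion": 5.0}, "pupil"),
        ({"pupil": 25.0, "reward": 25.0, "locomotion": 50.0}, "both"),
        ({"pupil": 5.0, "reward": 80.0, "locomotion": 15.0}, "reward"),
        ({"pupil": 10.0, "reward": 10.0, "locomotion": 80.0}, "other"),
        ({"pupil": 20.0, "reward": 19.9, "locomotion": 0.0}, "pupil"),
    ])
    def test_rules(self, contrib, expected):
        assert classify_one(contrib, major_cutoff=20.0) == expected


class TestSessionRecovery:
    def test_contributions_and_labels_recovered(self, small_session):
        """Estimated contributions track analytic truth; labels match at the
        20% cutoff for a seeded session."""
        s = small_session
        from pupilcode.preprocess import preprocess_imaging
        dff, _ = preprocess_imaging(s.cell_raw, s.halo_raw)
        t_c = s.cell_time_s
        pred = build_predictor_set(
            t_c,
            np.interp(t_c, s.pupil.time_s, s.pupil.radius_px),
            np.interp(t_c, s.behavior.time_s, s.behavior.speed_cmps),
            np.interp(t_c, s.behavior.time_s, s.behavior.lick_wave),
            dff)
        table = encode_session(dff, pred)
        kept = table["kept"].to_numpy()
        assert kept.all()
        est = table.loc[:, ["contrib_pupil", "contrib_locomotion",
                            "contrib_reward"]].to_numpy()
        true = s.truth.unique_contrib_pct
        assert np.abs(est - true).max() < 15.0
        agree = (table["label"].to_numpy() == s.truth.labels).mean()
        assert agree >= 0.9
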