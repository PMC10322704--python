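"""Bout detection, Lloyd k-means, cross-group matching and group tests."""

import numpy as np
import pytest

from pupilcode import synthetic as syn
from pupilcode.bouts import (RunningBout, cluster_bouts, compare_groups,
                             detect_bouts, lloyd_kmeans, match_equivalent_bouts,
                             run_rest_partition)


def make_bout(profile, onset=10.0, subject="s", group="g"):
    profile = np.asarray(profile, float)
    sd = profile.std()
    z = (profile - profile.mean()) / sd if sd > 0 else np.zeros_like(profile)
    return RunningBout(onset_s=onset, offset_s=onset + 5.0,
                       profile_cmps=profile, profile_z=z,
                       subject_id=subject, group_id=group)


class TestDetectBouts:
    def test_zero_speed_no_bouts(self):
        assert detect_bouts(np.zeros(1000), 20.0) == []

    def test_single_rectangular_epoch(self):
        speed = np.zeros(2000)
        speed[500:600] = 10.0  # 5 s at 10 cm/s
        (bout,) = detect_bouts(speed, 20.0)
        assert bout.onset_s == pytest.approx(25.0)
        assert bout.offset_s == pytest.approx(30.0)
        assert len(bout.profile_cmps) == int(10.0 * 20.0) + 1

    def test_short_epochs_dropped_and_gaps_merged(self):
        speed = np.zeros(2000)
        speed[400:410] = 10.0            # 0.5 s: too short
        speed[800:850] = 10.0
        speed[855:905] = 10.0            # 0.25 s gap: merged
        bouts = detect_bouts(speed, 20.0, min_duration_s=1.0, merge_gap_s=0.5)
        assert len(bouts) == 1
        assert bouts[0].onset_s == pytest.approx(40.0)
        assert bouts[0].offset_s == pytest.approx(45.25)

    def test_onsets_match_generative_switch_times(self, small_session):
        """Detected onsets within one sample of the generator's bout-state
        switches."""
        beh = small_session.behavior
        rate = beh.rate_hz
        bouts = detect_bouts(beh.speed_cmps, rate)
        true_onsets = beh.bout_onsets_s
        # every detected onset pairs with a generative switch within 1 sample
        for b in bouts:
            assert np.min(np.abs(true_onsets - b.onset_s)) <= 1.0 / rate + 1e-9

    def test_bouts_lie_inside_run_mask(self, small_session):
        beh = small_session.behavior
        rate = beh.rate_hz
        run, _ = run_rest_partition(beh.speed_cmps)
        for b in detect_bouts(beh.speed_cmps, rate, merge_gap_s=0.0):
            mid = slice(int(b.onset_s * rate), int(b.offset_s * rate))
            assert run[mid].all()

    def test_negative_speed_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            detect_bouts(np.array([-1.0, 2.0]), 20.0)


class TestLloydKmeans:
    def test_k1_centroid_is_mean(self, rng):
        x = rng.standard_normal((30, 4))
        labels, centroids, history = lloyd_kmeans(x, 1, seed=0)
        assert np.allclose(centroids[0], x.mean(axis=0))
        assert np.all(labels == 0)

    def test_inertia_never_increases(self, rng):
        x = rng.standard_normal((200, 6))
        _, _, history = lloyd_kmeans(x, 5, seed=3)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_two_separated_shapes_perfectly_split(self, rng):
        a = np.tile([0.0, 5.0, 0.0], (20, 1)) + 0.05 * rng.standard_normal((20, 3))
        b = np.tile([5.0, 0.0, 5.0], (20, 1)) + 0.05 * rng.standard_normal((20, 3))
        labels, _, _ = lloyd_kmeans(np.vstack([a, b]), 2, seed=1)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicate_points_assigned_identically(self, rng):
        x = rng.standard_normal((10, 3))
        xx = np.vstack([x, x])
        labels, _, _ = lloyd_kmeans(xx, 3, seed=2)
        assert np.array_equal(labels[:10], labels[10:])

    def test_matches_sklearn_kmeans_inertia(self, rng):
        """Independent cross-check: final within-cluster SS agrees with
        sklearn's Lloyd implementation on well-separated data."""
        from sklearn.cluster import KMeans
        a = rng.standard_normal((40, 4)) + 10
        b = rng.standard_normal((40, 4)) - 10
        x = np.vstack([a, b])
        _, _, history = lloyd_kmeans(x, 2, seed=0)
        sk = KMeans(n_clusters=2, n_init=10, algorithm="lloyd",
                    random_state=0).fit(x)
        assert history[-1] == pytest.approx(sk.inertia_, rel=1e-6)

    def test_bad_k_raises(self, rng):
        with pytest.raises(ValueError, match="k must be"):
            lloyd_kmeans(rng.standard_normal((5, 2)), 6, seed=0)

    def test_seeded_reproducibility(self, rng):
        x = rng.standard_normal((50, 4))
        l1, c1, _ = lloyd_kmeans(x, 3, seed=11)
        l2, c2, _ = lloyd_kmeans(x, 3, seed=11)
        assert np.array_equal(l1, l2) and np.array_equal(c1, c2)


class TestMatchEquivalentBouts:
    def _group(self, rng, scale, n, group):
        base = np.concatenate([np.zeros(10), np.full(30, 10.0), np.zeros(10)])
        return [make_bout(scale * base + 0.1 * rng.standard_normal(50),
                          subject=f"{group}{i}", group=group)
                for i in range(n)]

    def test_exchangeable_groups_all_match(self, rng):
        a = self._group(rng, 1.0, 12, "A")
        b = self._group(rng, 1.0, 12, "B")
        ma, mb, diag = match_equivalent_bouts(a, b, k=2, seed=0)
        assert len(ma) == 12 and len(mb) == 12
        assert all(x.group_id == "A" for x in ma)
        assert all(x.group_id == "B" for x in mb)

    def test_disjoint_speed_scales_fail(self, rng):
        a = self._group(rng, 1.0, 10, "A")
        b = self._group(rng, 2.0, 10, "B")  # doubled speed: no equivalent bouts
        with pytest.raises(ValueError, match="no cluster"):
            match_equivalent_bouts(a, b, k=2, seed=0, tolerance_cmps=0.5)

    def test_never_returns_single_group(self, rng):
        a = self._group(rng, 1.0, 8, "A")
        b = self._group(rng, 1.0, 8, "B")
        ma, mb, _ = match_equivalent_bouts(a, b, k=3, seed=0)
        assert ma and mb

    def test_empty_group_raises(self, rng):
        with pytest.raises(ValueError, match="both groups"):
            match_equivalent_bouts([], self._group(rng, 1.0, 5, "B"), k=2, seed=0)


class TestRunRestPartition:
    @pytest.mark.parametrize("speed,run_frac", [
        (np.zeros(100), 0.0), (np.full(100, 5.0), 1.0)])
    def test_constant_speed(self, speed, run_frac):
        run, rest = run_rest_partition(speed)
        assert run.mean() == run_frac
        assert np.array_equal(run, ~rest)

    def test_alternating_samples(self):
        speed = np.tile([0.0, 5.0], 50)
        run, rest = run_rest_partition(speed)
        assert np.array_equal(run, np.tile([False, True], 50))


class TestCompareGroups:
    def test_identical_paired_samples(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                 test="ttest", paired=True)
        assert res.statistic == 0.0
        assert np.isnan(res.p_value)

    def test_complete_separation_mannwhitney(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], test="mannwhitney",
                             tail="two-sided")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # exact two-sided P for n=3,3

    def test_one_tailed_power_matches_analytic(self, rng):
        """Power of the one-tailed two-sample t-test at a designed shift
        agrees with the noncentral-t closed form."""
        from scipy import stats
        n, delta, n_sim = 10, 1.2, 400
        hits = 0
        for _ in range(n_sim):
            a = rng.standard_normal(n) + delta
            b = rng.standard_normal(n)
            if compare_groups(a, b, test="ttest", tail="greater").p_value < 0.05:
                hits += 1
        df = 2 * n - 2
        nc = delta / np.sqrt(2.0 / n)
        t_crit = stats.t.ppf(0.95, df)
        power = 1.0 - stats.nct.cdf(t_crit, df, nc)
        se = np.sqrt(power * (1 - power) / n_sim)
        assert abs(hits / n_sim - power) < 4 * se

    def test_small_samples_raise(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups([1.0], [2.0, 3.0])

    def test_paired_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="paired"):
            compare_groups([1, 2, 3], [1, 2], paired=True)


def test_cluster_bouts_requires_enough_bouts(rng):
    bouts = [make_bout(rng.random(50)) for _ in range(3)]
    with pytest.raises(ValueError, match="need >="):
        cluster_bouts(bouts, k=5, seed=0)
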