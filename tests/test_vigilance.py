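"""Staging building blocks: mixture fits, probability bands, the binary NREM
rule, the theta/delta threshold, REM flanking and activity reclassification."""

import numpy as np
import pytest

from lfprhythms import vigilance as vg

rng = np.random.default_rng(12345)


class TestFitTwoGaussians:
    def test_balanced_mixture_recovery(self):
        v = np.concatenate(
            [rng.normal(1.0, 0.1, 50_000), rng.normal(3.0, 0.3, 50_000)]
        )
        pair = vg.fit_two_gaussians(v)
        assert not pair.failed
        assert abs(pair.mean1 - 1.0) < 0.05
        assert abs(pair.mean2 - 3.0) < 0.05

    def test_unbalanced_weights_recovery(self):
        v = np.concatenate(
            [rng.normal(1.0, 0.1, 90_000), rng.normal(3.0, 0.3, 10_000)]
        )
        pair = vg.fit_two_gaussians(v)
        mass1 = pair.weight1 * pair.sd1
        mass2 = pair.weight2 * pair.sd2
        assert abs(mass1 / (mass1 + mass2) - 0.9) < 0.05

    def test_identical_components_flagged(self):
        v = rng.normal(2.0, 0.5, 20_000)
        pair = vg.fit_two_gaussians(v)
        assert pair.failed

    def test_requires_enough_values(self):
        with pytest.raises(ValueError):
            vg.fit_two_gaussians(np.ones(100))


class TestNremProbability:
    @pytest.mark.parametrize(
        "offset_sd,expected",
        [(0.5, 1.0), (1.5, 0.397), (2.5, 0.067), (3.5, 0.0)],
    )
    def test_published_bands(self, offset_sd, expected):
        assert vg.nrem_probability(1.0 + offset_sd * 0.2, mean=1.0, sd=0.2) == expected

    def test_non_increasing_step_function(self):
        x = np.linspace(0.0, 3.0, 400)
        p = vg.nrem_probability(x, mean=1.0, sd=0.3)
        assert np.all(np.diff(p) <= 0)
        assert set(np.unique(p)) <= {0.0, 0.067, 0.397, 1.0}

    def test_requires_positive_sd(self):
        with pytest.raises(ValueError):
            vg.nrem_probability(1.0, mean=1.0, sd=0.0)


class TestBinaryNrem:
    def test_all_ones(self):
        assert np.all(vg.binary_nrem(np.ones(50)) == 1)

    def test_isolated_one_removed(self):
        p = np.full(60, 0.067)
        p[30] = 1.0
        assert vg.binary_nrem(p)[30] == 0

    def test_run_oracle(self):
        # direct evaluation of the flanking rule on a 20 s run of ones
        p = np.zeros(80)
        p[30:50] = 1.0
        out = vg.binary_nrem(p)
        expected = np.zeros(80, int)
        for i in range(80):
            before = p[max(i - 8, 0) : i]
            after = p[i + 1 : i + 9]
            b = before.mean() if before.size else 0.0
            a = after.mean() if after.size else 0.0
            expected[i] = 1 if (b >= 0.5 or a >= 0.5) else 0
        assert np.array_equal(out, expected)
        assert np.all(out[32:48] == 1)


class TestThetaDeltaThreshold:
    def test_symmetric_midpoint(self):
        pair = vg.GaussianPair(1.0, 0.2, 5.0, 3.0, 0.2, 5.0)
        thr, flagged = vg.theta_delta_threshold(pair)
        assert not flagged
        assert abs(thr - 2.0) < 1e-9

    def test_quadratic_oracle(self):
        pair = vg.GaussianPair(1.0, 0.1, 4.0, 2.0, 0.4, 4.0)
        thr, flagged = vg.theta_delta_threshold(pair)

        def dens(x, a, mu, s):
            return a * np.exp(-0.5 * ((x - mu) / s) ** 2)

        # equal densities at the root, which lies between the means
        assert not flagged
        assert 1.0 < thr < 2.0
        assert np.isclose(dens(thr, 4.0, 1.0, 0.1), dens(thr, 4.0, 2.0, 0.4), rtol=1e-6)

    def test_failed_fit_raises(self):
        pair = vg.GaussianPair(1.0, 0.2, 1.0, 1.0, 0.2, 1.0, failed=True)
        with pytest.raises(ValueError):
            vg.theta_delta_threshold(pair)


class TestClassifyRemAwake:
    def test_flanked_by_nrem_becomes_rem(self):
        nrem = np.array([1, 1, 1, 0, 0, 0, 0])
        td = np.array([0.2, 0.2, 0.2, 3.0, 3.0, 0.5, 0.5])
        st = vg.classify_rem_awake(td, nrem, threshold=1.0)
        assert list(st) == ["NREM"] * 3 + ["REM"] * 2 + ["AWAKE"] * 2

    def test_awake_flanks_stay_awake(self):
        nrem = np.zeros(7, int)
        td = np.array([0.2, 0.2, 3.0, 3.0, 3.0, 0.2, 0.2])
        st = vg.classify_rem_awake(td, nrem, threshold=1.0)
        assert np.all(st != "REM")

    def test_exact_threshold_is_awake(self):
        nrem = np.array([1, 1, 0, 0])
        td = np.array([0.2, 0.2, 1.0, 1.0])
        st = vg.classify_rem_awake(td, nrem, threshold=1.0)
        assert list(st[2:]) == ["AWAKE", "AWAKE"]

    def test_small_transition_gap_bridged(self):
        nrem = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        td = np.array([0.2, 0.2, 0.2, 0.8, 3.0, 3.0, 0.5, 0.5])
        st = vg.classify_rem_awake(td, nrem, threshold=1.0, max_gap_s=2)
        assert list(st[3:6]) == ["REM", "REM", "REM"]


class TestReclassifyByActivity:
    def test_active_rem_becomes_awake(self):
        state = np.array(["NREM", "NREM", "REM", "AWAKE", "AWAKE"], dtype="U5")
        act = np.array([0.0, 0.0, 9.0, 1.0, 1.0])
        out = vg.reclassify_by_activity(state, act)
        assert out.state[2] == "AWAKE"

    def test_inactive_awake_becomes_rem(self):
        state = np.array(["NREM"] * 4 + ["AWAKE", "AWAKE"], dtype="U5")
        act = np.array([5.0, 5.0, 5.0, 5.0, 1.0, 50.0])
        out = vg.reclassify_by_activity(state, act)
        assert out.state[4] == "REM"
        assert out.state[5] == "AWAKE"

    def test_awake_to_rem_transition_removed(self):
        state = np.array(["AWAKE", "REM", "REM", "NREM"], dtype="U5")
        act = np.array([10.0, 0.0, 0.0, 0.0])
        out = vg.reclassify_by_activity(state, act)
        assert np.all(out.state[:3] == "AWAKE")

    def test_zero_activity_no_ops(self):
        state = np.array(["NREM", "REM", "AWAKE"], dtype="U5")
        out = vg.reclassify_by_activity(state, np.zeros(3))
        # strict inequalities: nothing moves in passes 1-2; pass 3 does not
        # apply (REM preceded by NREM)
        assert list(out.state) == ["NREM", "REM", "AWAKE"]

    def test_misaligned_activity(self):
        with pytest.raises(ValueError):
            vg.reclassify_by_activity(np.array(["AWAKE"], dtype="U5"), np.zeros(2))


class TestHourlyFractions:
    def test_all_nrem_hour(self):
        out = vg.hourly_fractions(np.full(3600, "NREM", dtype="U5"))
        assert np.allclose(out[0], [0.0, 100.0, 0.0])

    def test_counting_oracle_and_normalization(self, staging):
        truth = staging["rec"].truth["state"]
        out = vg.hourly_fractions(truth)
        assert np.allclose(out.sum(axis=1), 100.0)
        h0 = truth[:3600]
        expected = [100.0 * np.mean(h0 == s) for s in ("AWAKE", "NREM", "REM")]
        assert np.allclose(out[0], expected)
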