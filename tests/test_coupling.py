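"""Modulation index, FAC/PAC matrices by both methods, averaging/Z-scoring
and coordinate extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from lfprhythms import coupling as cp
from lfprhythms.filters import BANDS, FilterSpec, analytic_signal, bandpass

SR = 512.0


def phase_amp_from(epochs, gamma_band=(65.0, 85.0)):
    x = np.concatenate(epochs[:4])
    th = analytic_signal(bandpass(x, FilterSpec.for_band("theta", SR)), SR).phase
    gm = analytic_signal(bandpass(x, FilterSpec(*gamma_band, SR)), SR).amplitude
    return th, gm


class TestModulationIndex:
    def test_uniform_amplitude_is_zero(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 20_000)
        amp = np.ones(20_000)
        assert cp.modulation_index(phase, amp) < 1e-12

    def test_single_bin_mass_is_one(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, 20_000)
        amp = np.where((phase > 0) & (phase < np.pi / 9), 1.0, 0.0)
        assert np.isclose(cp.modulation_index(phase, amp), 1.0)

    def test_monotone_in_depth(self, pac_epochs):
        mis = {}
        for depth in (0.0, 0.2, 0.5):
            th, gm = phase_amp_from(pac_epochs[(0.0, depth)])
            mis[depth] = cp.modulation_index(th, gm)
        assert mis[0.0] < mis[0.2] < mis[0.5]

    def test_uncoupled_below_surrogates(self, pac_epochs):
        th, gm = phase_amp_from(pac_epochs[(0.0, 0.0)])
        mi = cp.modulation_index(th, gm)
        thr = cp.surrogate_mi_threshold(th, gm, n_surrogates=100, seed=2)
        assert mi <= max(thr, 1e-6)

    @given(hst.floats(min_value=0.1, max_value=10.0), hst.floats(min_value=-3.0, max_value=3.0))
    def test_scale_and_joint_offset_invariance(self, scale, offset):
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = 1.0 + 0.5 * np.cos(phase)
        base = cp.modulation_index(phase, amp)
        shifted = np.angle(np.exp(1j * (phase + offset)))
        assert np.isclose(cp.modulation_index(shifted, scale * amp), base, atol=5e-3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cp.modulation_index(np.zeros(10), np.zeros(11))


class TestPacMatrices:
    def test_methods_agree_on_preferred_phase(self, pac_epochs):
        for phase in (0.0, np.pi):
            eps = pac_epochs[(phase, 0.3)]
            p1 = cp.preferred_phase(cp.pac_matrix_cycles(eps, SR))
            p2 = cp.preferred_phase(cp.pac_matrix_hilbert(eps, SR))
            diff = abs(np.angle(np.exp(1j * (p1 - p2))))
            assert diff <= np.pi / 9

    def test_max_phase_bin_matches_configured(self, pac_epochs):
        eps = pac_epochs[(np.pi / 2, 0.3)]
        mat = cp.pac_matrix_hilbert(eps, SR)
        coords = cp.max_coupling_coordinates(mat)
        diff = abs(np.angle(np.exp(1j * (coords["phase_rad"] - np.pi / 2))))
        assert diff <= np.pi / 9

    def test_uncoupled_profile_flat(self, pac_epochs):
        mat = cp.pac_matrix_hilbert(pac_epochs[(0.0, 0.0)], SR)
        profile = mat.values.sum(axis=0)
        assert profile.std() / profile.mean() < 0.05

    def test_requires_min_epochs(self, pac_epochs):
        with pytest.raises(ValueError):
            cp.pac_matrix_cycles(pac_epochs[(0.0, 0.3)][:5], SR)

    def test_matrix_shape_and_metadata(self, pac_epochs):
        mat = cp.pac_matrix_cycles(pac_epochs[(0.0, 0.3)], SR)
        assert mat.values.shape == (9, 18)
        assert mat.col_kind == "phase"
        assert mat.scheme == "nonoverlap"
        assert np.all(mat.values >= 0)

    def test_overlap14_scheme(self):
        bins = cp.gamma_bins("overlap14")
        assert len(bins) == 14
        assert bins[0] == (30.0, 40.0)
        assert bins[-1] == (110.0, 120.0)


class TestFacMatrix:
    def test_driving_pair_located(self):
        import lfprhythms as m

        cfg = m.SimConfig(
            duration=112, seed=9, sample_rate=SR,
            state_dwell_means={"AWAKE": 1e9},
            circadian=m.sim.CircadianConfig(
                theta_mean=8.0, theta_amp=0.0, gamma_mean=70.0, gamma_amp=0.0
            ),
            pac=m.sim.PacConfig(0.0, 0.6),
            spwr=m.sim.SpwrConfig(rate=0),
            spindle=m.sim.SpindleConfig(rate=0, coupled_fraction=0),
        )
        rec = m.synthesize(cfg)
        wlen = int(8 * SR)
        eps = [rec.channels[0][k * wlen : (k + 1) * wlen] for k in range(12)]
        mat = cp.fac_matrix(eps, SR)
        coords = cp.max_coupling_coordinates(mat)
        assert abs(coords["theta_hz"] - 8.0) <= 1.0
        assert abs(coords["gamma_hz"] - 70.0) <= 10.0


class TestAverageZscoreSmooth:
    def _mat(self, values):
        return cp.CouplingMatrix(
            values=values, gamma_bands=cp.gamma_bins(), col_kind="phase",
            col_centers=cp.PHASE_CENTERS.copy(), n_epochs=10,
        )

    def test_identical_matrices_average(self):
        rng = np.random.default_rng(0)
        v = rng.random((9, 18))
        out = cp.average_zscore_smooth([self._mat(v)] * 10)
        assert np.allclose(out.raw_mean.values, v)

    def test_zscore_normalization(self):
        rng = np.random.default_rng(1)
        out = cp.average_zscore_smooth([self._mat(rng.random((9, 18)))])
        assert abs(out.zscored.mean()) < 1e-12
        assert np.isclose(out.zscored.std(), 1.0)

    def test_smoothing_preserves_argmax_within_one_bin(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            v = rng.random((9, 18))
            v[4, 9] = 3.0  # clear maximum
            out = cp.average_zscore_smooth([self._mat(v)], upsample=4)
            gi, ci = np.unravel_index(np.argmax(out.smoothed), out.smoothed.shape)
            assert abs(gi / 4 - 4) <= 1.0 and abs(ci / 4 - 9) <= 1.0

    def test_shape_mismatch(self):
        a = self._mat(np.zeros((9, 18)))
        b = cp.CouplingMatrix(
            values=np.zeros((9, 17)), gamma_bands=cp.gamma_bins(),
            col_kind="phase", col_centers=cp.PHASE_CENTERS[:17], n_epochs=10,
        )
        with pytest.raises(ValueError):
            cp.average_zscore_smooth([a, b])


class TestMaxCoordinates:
    def test_tie_resolution(self):
        mat = cp.CouplingMatrix(
            values=np.ones((9, 18)), gamma_bands=cp.gamma_bins(), col_kind="phase",
            col_centers=cp.PHASE_CENTERS.copy(), n_epochs=10,
        )
        coords = cp.max_coupling_coordinates(mat)
        assert coords["tied"]
        assert coords["gamma_hz"] == 35.0  # lowest gamma bin centre
        assert np.isclose(coords["phase_rad"], cp.PHASE_CENTERS[0])
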