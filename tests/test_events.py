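"""Event detection (ripples, spindles), sharp-wave baseline validation,
ripple-spindle coupling and IEI burstiness/memory statistics."""

import numpy as np
import pytest

import lfprhythms as m
from lfprhythms import events as ev
from conftest import match_onsets, match_overlap

SR = 512.0


class TestDetectSpwr:
    def test_recall_precision_on_inserted_templates(self, nrem_events):
        tp, n_truth, n_det = match_onsets(
            nrem_events["spwr"].onsets_s, nrem_events["rec"].truth["events"]["spwr"]
        )
        assert tp / n_truth >= 0.95
        assert tp / n_det >= 0.95

    def test_peak_ripple_frequency(self, nrem_events):
        assert abs(nrem_events["spwr"].peak_freq_hz.mean() - 180.0) <= 5.0

    def test_noise_only_rate_bounded(self):
        cfg = m.SimConfig(
            duration=600, seed=13, sample_rate=SR,
            state_dwell_means={"NREM": 1e9},
            spwr=m.sim.SpwrConfig(rate=0.0),
            spindle=m.sim.SpindleConfig(rate=0.0, coupled_fraction=0.0),
        )
        rec = m.synthesize(cfg)
        train = ev.detect_spwr(rec.channels[0], SR, rec.truth["state"] == "NREM")
        assert len(train) <= 12  # < 0.02 false events/s on pure background

    def test_no_nrem_gives_empty_train(self, nrem_events):
        train = ev.detect_spwr(
            nrem_events["rec"].channels[0], SR, np.zeros(600, dtype=bool)
        )
        assert len(train) == 0

    def test_scale_invariance(self, nrem_events):
        rec = nrem_events["rec"]
        a = ev.detect_spwr(rec.channels[0], SR, nrem_events["nrem"])
        b = ev.detect_spwr(7.0 * rec.channels[0], SR, nrem_events["nrem"])
        assert len(a) == len(b)
        assert np.allclose(a.onsets_s, b.onsets_s)

    def test_train_invariants(self, nrem_events):
        tr = nrem_events["spwr"]
        assert np.all(np.diff(tr.onsets_s) > 0)
        assert np.all(tr.offsets_s > tr.onsets_s)
        assert np.all(tr.offsets_s[:-1] <= tr.onsets_s[1:])  # no overlap
        assert np.all(tr.peak_z >= 3.0)


class TestDetectSpindles:
    def test_recall_precision_on_inserted_templates(self, nrem_events):
        recall, precision = match_overlap(
            nrem_events["spindles"], nrem_events["rec"].truth["events"]["spindle"]
        )
        assert recall >= 0.95
        assert precision >= 0.95

    def test_short_blip_rejected_by_duration_floor(self):
        # the 5 ms floor applies to the supra-threshold envelope excursion:
        # a 4 ms excursion is rejected, a sustained one kept
        z = np.zeros(int(10 * SR))
        z[100 : 100 + int(0.004 * SR)] = 8.0
        assert ev._find_events(z, SR, 5.0, 0.0, 0.005, 0.03) == []
        z2 = np.zeros(int(10 * SR))
        z2[100 : 100 + int(0.050 * SR)] = 8.0
        assert len(ev._find_events(z2, SR, 5.0, 0.0, 0.005, 0.03)) == 1

    def test_flat_input_no_events(self):
        x = np.zeros(int(120 * SR))
        train = ev.detect_spindles(x, SR, np.ones(120, dtype=bool))
        assert len(train) == 0


class TestValidateSpwBaseline:
    def test_matched_baseline_passes(self):
        rng = np.random.default_rng(1)
        x = 0.01 * rng.standard_normal(int(10 * SR))
        t = np.arange(int(0.05 * SR)) / SR
        tpl = 0.05 * np.hanning(t.size) * np.sin(2 * np.pi * 180 * t)
        tpl -= tpl.mean()
        x[2560 : 2560 + t.size] += tpl
        res = ev.validate_spw_baseline(5.0, 5.05, x, SR)
        assert res["passed"] and not res["single_flank"]

    def test_dc_step_fails(self):
        x = np.concatenate([np.zeros(int(5 * SR)), np.ones(int(5 * SR))])
        res = ev.validate_spw_baseline(5.0, 5.05, x + 1e-6 * np.random.default_rng(2).standard_normal(x.size), SR)
        assert not res["passed"]

    def test_edge_event_single_flank(self):
        rng = np.random.default_rng(3)
        x = 0.01 * rng.standard_normal(int(1 * SR))
        res = ev.validate_spw_baseline(0.0, 0.05, x, SR)
        assert res["single_flank"]

    def test_compliant_template_pass_rate(self):
        rng = np.random.default_rng(4)
        t = np.arange(int(0.05 * SR)) / SR
        tpl = 0.05 * np.hanning(t.size) * np.sin(2 * np.pi * 180 * t)
        tpl -= tpl.mean()
        passed = 0
        for k in range(40):
            x = 0.01 * rng.standard_normal(int(2 * SR))
            x[512 : 512 + t.size] += tpl
            passed += ev.validate_spw_baseline(1.0, 1.05, x, SR)["passed"]
        assert passed / 40 >= 0.95


class TestCoupleEvents:
    def _train(self, onsets, kind="spwr"):
        onsets = np.asarray(onsets, dtype=float)
        return ev.EventTrain(
            onsets_s=onsets, offsets_s=onsets + 0.05,
            peak_z=np.full(onsets.size, 5.0),
            peak_freq_hz=np.full(onsets.size, 180.0), kind=kind,
        )

    def test_fixed_lag_full_coupling(self):
        spwr = self._train(np.arange(0.0, 100.0, 10.0))
        spin = self._train(np.arange(1.0, 101.0, 10.0), "spindle")
        out = ev.couple_events(spwr, spin, window_s=5.0)
        assert out.fraction_followed_pct == 100.0
        assert np.allclose(out.latencies_s, 1.0)

    def test_count_ratio(self):
        spwr = self._train(np.linspace(0, 460, 47))
        spin = self._train(np.linspace(2, 462, 10), "spindle")
        out = ev.couple_events(spwr, spin)
        assert np.isclose(out.count_ratio, 4.7)

    def test_binomial_fraction_recovery(self):
        # sparse trains: the followed fraction estimates the configured
        # coupling probability without chance contamination
        cfg = m.SimConfig(
            duration=4000, seed=6, sample_rate=SR,
            state_dwell_means={"NREM": 1e9},
            spwr=m.sim.SpwrConfig(rate=0.05),
            spindle=m.sim.SpindleConfig(
                rate=0.0, coupled_fraction=0.14, latency_mean=1.0, latency_sd=0.5
            ),
        )
        rec = m.synthesize(cfg)
        nrem = rec.truth["state"] == "NREM"
        spwr = ev.detect_spwr(rec.channels[0], SR, nrem)
        spin = ev.detect_spindles(rec.channels[1], SR, nrem)
        out = ev.couple_events(spwr, spin, window_s=5.0)
        # binomial oracle: configured coupling plus the chance of an
        # unrelated spindle landing in the window
        bg_rate = out.n_spindle / 4000.0
        chance = 1.0 - np.exp(-bg_rate * 5.0)
        expected = 100.0 * (0.14 + (1 - 0.14) * chance)
        n = out.n_spwr
        tol = 100.0 * 3 * np.sqrt(0.14 * 0.86 / n)
        assert abs(out.fraction_followed_pct - expected) <= max(tol, 3.0)

    def test_empty_spindles(self):
        spwr = self._train([1.0, 2.0])
        out = ev.couple_events(spwr, self._train([], "spindle"))
        assert out.fraction_followed_pct == 0.0
        assert out.latencies_s.size == 0


class TestBurstinessMemory:
    def test_constant_ieis(self):
        ts = ev.burstiness_memory(np.ones(100))
        assert ts.burstiness == -1.0
        assert ts.memory == 0.0 and ts.memory_undefined

    def test_exponential_ieis(self):
        rng = np.random.default_rng(7)
        ts = ev.burstiness_memory(rng.exponential(1.0, 10_000))
        assert abs(ts.burstiness) <= 0.03
        assert abs(ts.memory) <= 0.03

    def test_alternating_negative_memory(self):
        ts = ev.burstiness_memory(np.tile([0.1, 1.0], 50))
        assert ts.memory < 0

    def test_burstiness_permutation_invariant_memory_not(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(1.0, 500) + np.repeat([0.0, 2.0], 250)  # trend
        perm = rng.permutation(x)
        a, b = ev.burstiness_memory(x), ev.burstiness_memory(perm)
        assert np.isclose(a.burstiness, b.burstiness)
        assert not np.isclose(a.memory, b.memory, atol=1e-3)

    def test_too_few(self):
        with pytest.raises(ValueError):
            ev.burstiness_memory(np.array([1.0]))
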