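"""Shared fixtures: synthetic recordings reused across the suite.

Heavy syntheses are session-scoped so the expensive study-scale fixtures
(the 2 h staging recording, the long NREM event recording) are built once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lfprhythms as m
from lfprhythms.sim import PacConfig, SpindleConfig, SpwrConfig

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SR = 512.0


@pytest.fixture(scope="session")
def sr() -> float:
    return SR


@pytest.fixture(scope="session")
def staging():
    """2 h default-condition recording plus ratio series and labels."""
    cfg = m.SimConfig(duration=7200, seed=3, sample_rate=SR)
    rec = m.synthesize(cfg)
    ratios = m.band_ratios(rec.channels[0], SR)
    labels = m.vigilance.classify(
        ratios["gamma_delta"], ratios["theta_delta"], rec.activity
    )
    return {"rec": rec, "ratios": ratios, "labels": labels}


@pytest.fixture(scope="session")
def nrem_events():
    """10 min all-NREM recording with inserted ripples/spindles and detections."""
    cfg = m.SimConfig(
        duration=600,
        seed=4,
        sample_rate=SR,
        state_dwell_means={"NREM": 1e9},
        spwr=SpwrConfig(rate=0.44),
        spindle=SpindleConfig(rate=0.035, coupled_fraction=0.14),
    )
    rec = m.synthesize(cfg)
    nrem = rec.truth["state"] == "NREM"
    spwr = m.events.detect_spwr(rec.channels[0], SR, nrem)
    spindles = m.events.detect_spindles(rec.channels[1], SR, nrem)
    return {"rec": rec, "nrem": nrem, "spwr": spwr, "spindles": spindles}


def pac_epoch_set(phase: float, depth: float, seed: int, n_epochs: int = 12):
    """8 s AWAKE epochs with theta-gamma coupling at the given phase/depth."""
    cfg = m.SimConfig(
        duration=8 * n_epochs + 16,
        seed=seed,
        sample_rate=SR,
        state_dwell_means={"AWAKE": 1e9},
        pac=PacConfig(preferred_phase=phase, coupling_depth=depth),
        spwr=SpwrConfig(rate=0.0),
        spindle=SpindleConfig(rate=0.0, coupled_fraction=0.0),
    )
    rec = m.synthesize(cfg)
    wlen = int(8 * SR)
    x = rec.channels[0]
    return [x[k * wlen : (k + 1) * wlen] for k in range(n_epochs)]


@pytest.fixture(scope="session")
def pac_epochs():
    """Coupled epoch sets keyed by (preferred phase, depth)."""
    out = {}
    for phase in (0.0, np.pi / 2, np.pi):
        out[(phase, 0.3)] = pac_epoch_set(phase, 0.3, seed=42)
    out[(0.0, 0.0)] = pac_epoch_set(0.0, 0.0, seed=5)
    out[(0.0, 0.5)] = pac_epoch_set(0.0, 0.5, seed=5)
    out[(0.0, 0.2)] = pac_epoch_set(0.0, 0.2, seed=5)
    return out


def match_onsets(detected_onsets, truth_events, tol_s: float = 0.025):
    """One-to-one onset matching; returns (tp, n_truth, n_detected)."""
    truth_on = np.array([a for a, _ in truth_events])
    hit = np.zeros(truth_on.size, dtype=bool)
    tp = 0
    for o in detected_onsets:
        if truth_on.size == 0:
            break
        d = np.abs(truth_on - o)
        j = int(np.argmin(d))
        if d[j] <= tol_s and not hit[j]:
            hit[j] = True
            tp += 1
    return tp, truth_on.size, len(detected_onsets)


def match_overlap(train, truth_events):
    """Interval-overlap matching; returns (recall, precision)."""
    ta = np.array([a for a, _ in truth_events])
    tb = np.array([b for _, b in truth_events])
    covered = np.zeros(ta.size, dtype=bool)
    good = 0
    for o, f in zip(train.onsets_s, train.offsets_s):
        ov = (ta < f) & (tb > o)
        covered |= ov
        good += bool(ov.any())
    recall = covered.mean() if ta.size else np.nan
    precision = good / len(train) if len(train) else np.nan
    return recall, precision
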