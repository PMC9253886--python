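"""End-to-end orchestration: filter -> vigilance -> peaks -> synchrony -> events.

:func:`band_ratios` produces the per-second RMS(gamma)/RMS(delta) and
RMS(theta)/RMS(delta) series the stager consumes; :func:`run_pipeline` runs
the full stage sequence on a two-channel recording plus activity trace and
returns a single nested report of per-hour state fractions, hourly spectral
peaks with circadian sine fits, delta-synchrony summaries over NREM
segments and the SPW-R / spindle event tables.
"""

from __future__ import annotations

import numpy as np

from . import coupling as _coupling
from . import events as _events
from . import spectral as _spectral
from . import synchrony as _synchrony
from . import vigilance as _vigilance
from .filters import BANDS, FilterSpec, analytic_signal, bandpass, rms_envelope
from .io import Recording, light_mask

__all__ = ["band_ratios", "nrem_segments", "run_pipeline"]

_EPS = 1e-12


def band_ratios(
    series: np.ndarray, sr: float, window_s: float = 8.0, step_s: float = 1.0
) -> dict:
    """Per-epoch G/D and theta/delta RMS ratios on a 1 s grid."""
    envs = {}
    for band in ("delta", "theta", "gamma"):
        filt = bandpass(series, FilterSpec.for_band(band, sr))
        envs[band] = rms_envelope(filt, sr, window_s, step_s).values
    return {
        "gamma_delta": envs["gamma"] / np.maximum(envs["delta"], _EPS),
        "theta_delta": envs["theta"] / np.maximum(envs["delta"], _EPS),
    }


def nrem_segments(state: np.ndarray, min_s: float = 20.0):
    """(start_s, stop_s) of NREM runs of at least ``min_s`` seconds."""
    mask = np.asarray(state) == "NREM"
    d = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    out = []
    for s0, s1 in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if s1 - s0 >= min_s:
            out.append((int(s0), int(s1)))
    return out


def run_pipeline(
    rec: Recording,
    activity: np.ndarray,
    compute_coupling: bool = False,
    seed: int = 0,
) -> dict:
    """Run all analysis stages on *rec* and assemble the report."""
    sr = rec.sample_rate
    hippo = rec.samples[0]
    cortex = rec.samples[1] if rec.n_channels > 1 else rec.samples[0]

    ratios = band_ratios(hippo, sr)
    labels = _vigilance.classify(ratios["gamma_delta"], ratios["theta_delta"], activity)
    fractions = _vigilance.hourly_fractions(labels.state)

    peaks = _spectral.sliding_peaks(hippo, sr)
    hourly = _spectral.hourly_state_peaks(peaks, labels.state)
    sine_fits = {}
    for band in ("theta", "gamma"):
        vals = hourly[band]["all"]
        if np.isfinite(vals).sum() >= 3:
            sine_fits[band] = _spectral.fit_circadian_sine(vals)

    # delta synchrony over long NREM segments
    spec_d = FilterSpec.for_band("delta", sr)
    sync_rows = []
    for s0, s1 in nrem_segments(labels.state, min_s=20.0)[:20]:
        a, b = int(s0 * sr), int(s1 * sr)
        if b - a <= spec_d.n_taps:
            continue
        d1 = bandpass(hippo[a:b], spec_d)
        d2 = bandpass(cortex[a:b], spec_d)
        p1, p2 = analytic_signal(d1, sr).phase, analytic_signal(d2, sr).phase
        summ = _synchrony.phase_diff_summary(p1, p2, sr)
        sync_rows.append(
            {
                "segment_start_s": s0,
                "segment_stop_s": s1,
                "ispc": _synchrony.ispc(p1, p2),
                "xcorr": _synchrony.segment_xcorr(d1, d2),
                "dphi_rad": summ.mean_rad,
                "compound_hz": summ.compound_hz,
                "lag_ms": summ.lag_ms,
            }
        )

    nrem_mask = labels.state == "NREM"
    spwr = _events.detect_spwr(hippo, sr, nrem_mask)
    spindles = _events.detect_spindles(cortex, sr, nrem_mask)
    coupling_summary = _events.couple_events(spwr, spindles)
    nrem_seconds = float(nrem_mask.sum())

    report = {
        "seed": seed,
        "sample_rate": sr,
        "duration_s": rec.duration,
        "labels": labels,
        "hourly_fractions_pct": fractions,
        "state_fractions_pct": {
            s: 100.0 * labels.fraction(s) for s in ("AWAKE", "NREM", "REM")
        },
        "hourly_peaks_hz": hourly,
        "circadian_fits": sine_fits,
        "delta_synchrony": sync_rows,
        "events": {
            "spwr": spwr,
            "spindle": spindles,
            "spwr_rate_per_s": spwr.rate_per_s(nrem_seconds),
            "spindle_rate_per_s": spindles.rate_per_s(nrem_seconds),
            "coupling": coupling_summary,
        },
        "light_mask": light_mask(rec),
    }

    if compute_coupling:
        # PAC on AWAKE/REM epochs with significant dual spectral peaks
        epochs = _dual_peak_epochs(hippo, sr, labels.state, peaks)
        if len(epochs) >= 10:
            pac = _coupling.pac_matrix_cycles(epochs[:20], sr)
            report["pac"] = {
                "matrix": pac,
                "preferred_phase_rad": _coupling.preferred_phase(pac),
                "max_coordinates": _coupling.max_coupling_coordinates(pac),
            }
    return report


def _dual_peak_epochs(
    series: np.ndarray, sr: float, state: np.ndarray, peaks: dict, window_s: float = 8.0
):
    """8 s epochs during AWAKE/REM where both theta and gamma peaks are present."""
    wlen = int(round(window_s * sr))
    starts = peaks["window_start_s"]
    good = np.isfinite(peaks["theta_hz"]) & np.isfinite(peaks["gamma_hz"])
    epochs = []
    last_end = -1.0
    for k in np.flatnonzero(good):
        s0 = starts[k]
        if s0 < last_end:  # non-overlapping epochs only
            continue
        sec0, sec1 = int(s0), min(int(np.ceil(s0 + window_s)), state.size)
        chunk = state[sec0:sec1]
        if np.all((chunk == "AWAKE") | (chunk == "REM")):
            a = int(s0 * sr)
            epochs.append(series[a : a + wlen])
            last_end = s0 + window_s
    return epochs
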