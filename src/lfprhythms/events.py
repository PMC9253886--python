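"""Sharp-wave-ripple and sleep-spindle detection during NREM, with
ripple-to-spindle coupling and inter-event-interval statistics.

Detection is envelope-based: the channel is FIR-bandpassed (ripples
120-250 Hz on the hippocampal channel, spindles 10-30 Hz on the cortical
channel), rectified (squared then square-rooted), smoothed into a short RMS
envelope and z-scored against the NREM baseline (mean/SD over NREM samples,
re-estimated once with detected events excluded).  Ripples are maximal runs
with z >= 3 whose boundaries extend outward to where z returns to 0;
spindles use a 5 SD threshold and a 5 ms minimum supra-threshold duration.
Events separated by less than a 30 ms gap merge into one.

Inter-event intervals are summarized by the Goh-Barabasi burstiness
``B = (sigma - mu) / (sigma + mu)`` (-1 for perfectly regular trains, 0 for
a Poisson process, -> 1 for strongly bursty trains) and the memory
coefficient ``M = corr(IEI_i, IEI_i+1)`` (positive when short intervals
follow short ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import FilterSpec, bandpass

__all__ = [
    "EventTrain",
    "CouplingSummary",
    "TemporalStats",
    "detection_envelope",
    "detect_spwr",
    "detect_spindles",
    "validate_spw_baseline",
    "couple_events",
    "burstiness_memory",
]

RIPPLE_BANDS = {"methods": (120.0, 250.0), "figure": (150.0, 250.0)}


@dataclass
class EventTrain:
    """Ordered detected events with per-event peak statistics."""

    onsets_s: np.ndarray
    offsets_s: np.ndarray
    peak_z: np.ndarray
    peak_freq_hz: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.offsets_s <= self.onsets_s):
            raise ValueError("offsets must exceed onsets")

    def __len__(self) -> int:
        return self.onsets_s.size

    @property
    def durations_ms(self) -> np.ndarray:
        return (self.offsets_s - self.onsets_s) * 1000.0

    @property
    def ieis_s(self) -> np.ndarray:
        return np.diff(self.onsets_s)

    def rate_per_s(self, nrem_seconds: float) -> float:
        return len(self) / nrem_seconds if nrem_seconds > 0 else np.nan


def _nrem_sample_mask(nrem_sec: np.ndarray, sr: float, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    step = int(round(sr))
    for sec in np.flatnonzero(np.asarray(nrem_sec).astype(bool)):
        mask[sec * step : (sec + 1) * step] = True
    return mask


def detection_envelope(
    series: np.ndarray, sr: float, band: tuple[float, float], smooth_s: float = 0.006
) -> np.ndarray:
    """Rectified, RMS-smoothed band envelope used for event detection."""
    filt = bandpass(series, FilterSpec(band[0], band[1], sr))
    rect = np.sqrt(filt**2)  # rectification
    w = max(1, int(round(smooth_s * sr)))
    kernel = np.ones(w) / w
    return np.sqrt(np.convolve(rect**2, kernel, mode="same"))


def _find_events(
    z: np.ndarray,
    sr: float,
    z_on: float,
    z_off: float,
    min_duration_s: float,
    min_gap_s: float,
) -> list[tuple[int, int]]:
    above = z >= z_on
    if not above.any():
        return []
    d = np.diff(np.concatenate(([0], above.astype(int), [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    min_len = min_duration_s * sr
    events: list[tuple[int, int]] = []
    below = z <= z_off
    for s0, s1 in zip(starts, stops):
        if s1 - s0 < min_len:
            continue
        # extend outward to where z returns to the off level
        left = s0
        while left > 0 and not below[left - 1]:
            left -= 1
        right = s1
        while right < z.size and not below[right]:
            right += 1
        events.append((left, right))
    if not events:
        return []
    merged = [events[0]]
    gap = min_gap_s * sr
    for s0, s1 in events[1:]:
        p0, p1 = merged[-1]
        if s0 - p1 < gap:
            merged[-1] = (p0, max(p1, s1))
        else:
            merged.append((s0, s1))
    return merged


def _peak_frequency(
    segment: np.ndarray, sr: float, band: tuple[float, float], n_fft: int = 8192
) -> float:
    spec = np.abs(np.fft.rfft(segment * np.hanning(segment.size), n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[sel][np.argmax(spec[sel])])


def _detect(
    series: np.ndarray,
    sr: float,
    nrem_sec: np.ndarray,
    band: tuple[float, float],
    z_on: float,
    z_off: float,
    min_duration_s: float,
    min_gap_s: float,
    kind: str,
    smooth_s: float = 0.006,
) -> EventTrain:
    x = np.asarray(series, dtype=float)
    env = detection_envelope(x, sr, band, smooth_s)
    nrem_mask = _nrem_sample_mask(nrem_sec, sr, x.size)
    empty = EventTrain(
        onsets_s=np.empty(0), offsets_s=np.empty(0), peak_z=np.empty(0),
        peak_freq_hz=np.empty(0), kind=kind,
        params={"band": band, "z_on": z_on, "z_off": z_off,
                "min_duration_s": min_duration_s, "min_gap_s": min_gap_s},
    )
    if not nrem_mask.any():
        return empty

    filt = bandpass(x, FilterSpec(band[0], band[1], sr))
    events: list[tuple[int, int]] = []
    baseline_mask = nrem_mask.copy()
    for _pass in range(2):  # second pass re-baselines with events excluded
        mu = env[baseline_mask].mean()
        sd = env[baseline_mask].std()
        if sd == 0:
            return empty
        z = (env - mu) / sd
        events = [
            (s0, s1)
            for s0, s1 in _find_events(z, sr, z_on, z_off, min_duration_s, min_gap_s)
            if nrem_mask[s0]
        ]
        baseline_mask = nrem_mask.copy()
        for s0, s1 in events:
            baseline_mask[s0:s1] = False
        if not baseline_mask.any():
            baseline_mask = nrem_mask.copy()
            break
    if not events:
        return empty
    onsets = np.array([s0 / sr for s0, _ in events])
    offsets = np.array([s1 / sr for _, s1 in events])
    peak_z = np.array([float(z[s0:s1].max()) for s0, s1 in events])
    peak_f = np.array([_peak_frequency(filt[s0:s1], sr, band) for s0, s1 in events])
    return EventTrain(
        onsets_s=onsets, offsets_s=offsets, peak_z=peak_z, peak_freq_hz=peak_f,
        kind=kind, params=empty.params,
    )


def detect_spwr(
    series: np.ndarray,
    sr: float,
    nrem_sec: np.ndarray,
    band: tuple[float, float] = RIPPLE_BANDS["methods"],
    z_on: float = 3.0,
    z_off: float = 0.0,
    min_core_s: float = 0.010,
    min_gap_s: float = 0.030,
    smooth_s: float = 0.006,
) -> EventTrain:
    """Sharp-wave-ripple train from the hippocampal channel during NREM.

    ``min_core_s`` is the minimum time the envelope must hold z >= ``z_on``
    for a crossing to count as an event (culls single-sample noise
    excursions); boundaries still extend to the z = 0 return points.
    """
    return _detect(
        series, sr, nrem_sec, band, z_on, z_off, min_core_s, min_gap_s, "spwr",
        smooth_s,
    )


def detect_spindles(
    series: np.ndarray,
    sr: float,
    nrem_sec: np.ndarray,
    band: tuple[float, float] = (10.0, 30.0),
    z_on: float = 5.0,
    z_off: float = 0.0,
    min_duration_s: float = 0.005,
    min_gap_s: float = 0.100,
    smooth_s: float = 0.030,
) -> EventTrain:
    """Sleep-spindle train from the cortical channel during NREM.

    The 5 ms duration floor applies to the supra-threshold core of the event.
    """
    return _detect(
        series, sr, nrem_sec, band, z_on, z_off, min_duration_s, min_gap_s,
        "spindle", smooth_s,
    )


def validate_spw_baseline(
    onset_s: float, offset_s: float, raw: np.ndarray, sr: float
) -> dict:
    """Check the sharp-wave placement criterion for one event.

    The mean of the raw trace over the event is compared with the means of
    the two flanking baseline windows of equal duration; the event passes
    when both differences stay within one SD of the corresponding flank.
    Events at a recording edge fall back to a single flank, flagged.
    """
    x = np.asarray(raw, dtype=float)
    s0, s1 = int(round(onset_s * sr)), int(round(offset_s * sr))
    dur = s1 - s0
    ev_mean = x[s0:s1].mean()
    checks = []
    edge = False
    if s0 - dur >= 0:
        flank = x[s0 - dur : s0]
        checks.append(abs(ev_mean - flank.mean()) < flank.std())
    else:
        edge = True
    if s1 + dur <= x.size:
        flank = x[s1 : s1 + dur]
        checks.append(abs(ev_mean - flank.mean()) < flank.std())
    else:
        edge = True
    if not checks:
        raise ValueError("event has no usable flanking baseline")
    return {"passed": all(checks), "single_flank": edge}


@dataclass
class CouplingSummary:
    """Ripple-to-spindle coupling: latencies, followed fraction, count ratio."""

    latencies_s: np.ndarray  # ripple onset -> next spindle onset, all ripples
    fraction_followed_pct: float
    count_ratio: float  # n_spwr / n_spindle
    window_s: float
    n_spwr: int
    n_spindle: int


def couple_events(
    spwr: EventTrain, spindles: EventTrain, window_s: float = 5.0
) -> CouplingSummary:
    """Latency from each ripple to the next spindle; fraction followed within the window."""
    n_r, n_s = len(spwr), len(spindles)
    if n_r == 0:
        return CouplingSummary(np.empty(0), 0.0, np.nan, window_s, 0, n_s)
    if n_s == 0:
        return CouplingSummary(np.empty(0), 0.0, np.inf, window_s, n_r, 0)
    idx = np.searchsorted(spindles.onsets_s, spwr.onsets_s, side="left")
    has_next = idx < n_s
    lat = np.full(n_r, np.inf)
    lat[has_next] = spindles.onsets_s[idx[has_next]] - spwr.onsets_s[has_next]
    followed = lat <= window_s
    return CouplingSummary(
        latencies_s=lat[np.isfinite(lat)],
        fraction_followed_pct=100.0 * followed.mean(),
        count_ratio=n_r / n_s,
        window_s=window_s,
        n_spwr=n_r,
        n_spindle=n_s,
    )


@dataclass
class TemporalStats:
    burstiness: float  # in [-1, 1)
    memory: float  # in [-1, 1]
    n_ieis: int
    memory_undefined: bool = False
    low_n_flag: bool = False


def burstiness_memory(ieis: np.ndarray) -> TemporalStats:
    """Burstiness and memory of an inter-event-interval sequence."""
    x = np.asarray(ieis, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 inter-event intervals")
    mu, sigma = x.mean(), x.std()
    b = (sigma - mu) / (sigma + mu)
    undef = False
    if x[:-1].std() == 0 or x[1:].std() == 0:
        m, undef = 0.0, True
    else:
        m = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    return TemporalStats(
        burstiness=float(b), memory=m, n_ieis=x.size,
        memory_undefined=undef, low_n_flag=x.size < 10,
    )
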