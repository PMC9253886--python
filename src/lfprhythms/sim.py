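"""Ground-truth-labelled synthetic two-channel LFP generator.

Emulates the statistical structure that every downstream analysis stage
assumes of a chronic two-site rodent recording (a ventral-hippocampal and a
prefrontal channel):

* an AWAKE / NREM / REM vigilance schedule with exponential dwell times,
  biased by a 12 h light/dark mask (NREM-dominant light phase,
  AWAKE-dominant dark phase; REM only entered from NREM);
* state-dependent amplitudes of delta (0.5-4 Hz), theta (5-12 Hz) and
  gamma (30-120 Hz) band oscillations;
* counterphase 24 h sinusoidal modulation of the theta and gamma carrier
  frequencies;
* theta-gamma phase-amplitude coupling with a configurable preferred phase
  (0 rad = theta peak) and depth, via the envelope
  ``(1 + depth*cos(phase - preferred)) / (1 + depth)``;
* sharp-wave ripples (a windowed ripple-frequency burst riding on a
  mean-balanced slow deflection) inserted during NREM on channel 1, and
  sleep spindles on channel 2, a configurable fraction of which follow
  ripples at a configurable latency distribution;
* channel-2 delta equal to channel-1 delta shifted by a phase lag plus
  smooth Gaussian phase jitter (sets the target inter-site phase
  clustering, ISPC = exp(-sd^2/2) for Gaussian jitter);
* 1/f^alpha pink background noise on both channels, synthesized by
  spectral shaping of white Gaussian noise;
* a per-second activity trace drawn from a high-mean lognormal during
  AWAKE and a low-mean lognormal during sleep.

Fixed seed => bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .filters import BANDS, FilterSpec, bandpass

__all__ = [
    "CircadianConfig",
    "PacConfig",
    "DeltaSyncConfig",
    "SpwrConfig",
    "SpindleConfig",
    "SimConfig",
    "SyntheticRecording",
    "make_state_schedule",
    "synthesize",
]

STATES = ("AWAKE", "NREM", "REM")


class ConfigError(ValueError):
    """Raised for invalid simulator configurations."""


@dataclass(frozen=True)
class CircadianConfig:
    theta_mean: float = 7.5  # Hz
    theta_amp: float = 0.4  # Hz
    gamma_mean: float = 80.0  # Hz
    gamma_amp: float = 5.0  # Hz
    period_h: float = 24.0
    phase_offset: float = 0.0  # rad; theta peaks mid-dark for offset 0


@dataclass(frozen=True)
class PacConfig:
    preferred_phase: float = 0.0  # rad, 0 = theta peak (control-like); pi = trough
    coupling_depth: float = 0.5  # 0..1


@dataclass(frozen=True)
class DeltaSyncConfig:
    phase_lag: float = 0.0  # rad, channel 2 lags channel 1
    phase_jitter_sd: float = 0.0  # rad
    delta_freq: float = 2.0  # Hz carrier


@dataclass(frozen=True)
class SpwrConfig:
    rate: float = 0.44  # events/s during NREM
    ripple_freq: float = 180.0  # Hz
    snr: float = 8.0  # ripple amplitude / in-band NREM background SD
    duration_s: float = 0.050


@dataclass(frozen=True)
class SpindleConfig:
    rate: float = 0.035  # independent events/s during NREM
    latency_mean: float = 2.0  # s after a coupled ripple
    latency_sd: float = 1.5
    coupled_fraction: float = 0.14  # fraction of ripples followed by a spindle
    freq: float = 15.0  # Hz
    duration_s: float = 0.5  # realistic multi-cycle spindle envelope
    snr: float = 10.0  # amplitude / in-band NREM background SD


def _default_dwells() -> dict:
    # (light, dark) mean dwell seconds; light phase NREM-dominant.
    return {
        "AWAKE": (240.0, 480.0),
        "NREM": (360.0, 180.0),
        "REM": (60.0, 60.0),
    }


def _default_band_amplitudes() -> dict:
    # mV, per state; chosen to land in the printed delta-amplitude range
    # (sleep delta ~0.1-0.14 mV peak-to-peak scale) with clear band-ratio
    # separation between states.
    return {
        "AWAKE": {"delta": 0.05, "theta": 0.07, "gamma": 0.09},
        "NREM": {"delta": 0.14, "theta": 0.03, "gamma": 0.03},
        "REM": {"delta": 0.02, "theta": 0.13, "gamma": 0.10},
    }


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one synthetic recording.

    ``state_dwell_means`` maps state -> mean dwell seconds, either a scalar
    (same in both photoperiods) or a ``(light, dark)`` pair; omitting a state
    removes it from the schedule entirely.  ``start_hour`` is the clock hour
    at sample 0 (lights on 06:00-18:00).
    """

    sample_rate: float = 512.0
    duration: float = 7200.0  # s
    start_hour: float = 12.0
    lights_on: float = 6.0
    lights_off: float = 18.0
    state_dwell_means: dict = field(default_factory=_default_dwells)
    rem_probability: float = 0.6  # NREM -> REM transition probability
    circadian: CircadianConfig = field(default_factory=CircadianConfig)
    pac: PacConfig = field(default_factory=PacConfig)
    band_amplitudes: dict = field(default_factory=_default_band_amplitudes)
    delta_sync: DeltaSyncConfig = field(default_factory=DeltaSyncConfig)
    spwr: SpwrConfig = field(default_factory=SpwrConfig)
    spindle: SpindleConfig = field(default_factory=SpindleConfig)
    pink_alpha: float = 1.0
    pink_rms: float = 0.02  # mV broadband RMS of the 1/f^alpha noise
    amplitude_jitter_sigma: float = 0.25  # log-SD of slow within-state band-power fluctuation
    channel2_scale: float = 0.7  # theta/gamma amplitude scale on channel 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.sample_rate < 256:
            raise ConfigError("sample_rate must be >= 256 Hz")
        if not 0.0 <= self.pac.coupling_depth <= 1.0:
            raise ConfigError("coupling_depth must lie in [0, 1]")
        if self.spwr.rate < 0 or self.spindle.rate < 0:
            raise ConfigError("event rates must be >= 0")
        for state, mean in self.state_dwell_means.items():
            pair = (mean, mean) if np.isscalar(mean) else tuple(mean)
            if min(pair) <= 0:
                raise ConfigError(f"non-positive dwell mean for {state}")
        for amps in self.band_amplitudes.values():
            if min(amps.values()) < 0:
                raise ConfigError("band amplitudes must be >= 0")
        nyq = self.sample_rate / 2
        top = max(
            self.circadian.gamma_mean + abs(self.circadian.gamma_amp),
            self.spwr.ripple_freq,
            self.spindle.freq,
        )
        if top >= nyq:
            raise ConfigError(f"requested band content {top} Hz >= Nyquist {nyq} Hz")

    def dwell_mean(self, state: str, light: bool) -> float:
        mean = self.state_dwell_means[state]
        if np.isscalar(mean):
            return float(mean)
        return float(mean[0] if light else mean[1])


@dataclass
class SyntheticRecording:
    """Two channels (mV), an activity trace and the generating truth."""

    channels: np.ndarray  # shape (2, n)
    sample_rate: float
    activity: np.ndarray  # per second, >= 0
    truth: dict
    start_hour: float = 0.0
    config: SimConfig | None = None

    @property
    def duration(self) -> float:
        return self.channels.shape[1] / self.sample_rate

    def light_mask_seconds(self) -> np.ndarray:
        """Boolean per-second mask: True where lights are on."""
        cfg = self.config
        on, off = (cfg.lights_on, cfg.lights_off) if cfg else (6.0, 18.0)
        hours = (self.start_hour + np.arange(self.activity.size) / 3600.0) % 24.0
        return (hours >= on) & (hours < off)


def _is_light(hour: float, cfg: SimConfig) -> bool:
    return cfg.lights_on <= (hour % 24.0) < cfg.lights_off


def make_state_schedule(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-second vigilance state sequence for *config*.

    Alternating-renewal construction: exponential dwell segments with
    photoperiod-dependent means; AWAKE -> NREM -> (REM with probability
    ``rem_probability``, else AWAKE) -> AWAKE, restricted to the states
    present in ``state_dwell_means``.
    """
    if config.duration < 60:
        raise ConfigError("schedule requires duration >= 60 s")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_sec = int(round(config.duration))
    avail = [s for s in STATES if s in config.state_dwell_means]
    if not avail:
        raise ConfigError("no states configured")
    out = np.empty(n_sec, dtype="U5")
    t = 0
    state = "AWAKE" if "AWAKE" in avail else avail[0]
    while t < n_sec:
        hour = config.start_hour + t / 3600.0
        mean = config.dwell_mean(state, _is_light(hour, config))
        dwell = max(1, int(round(rng.exponential(mean))))
        out[t : t + dwell] = state
        t += dwell
        if state == "NREM" and "REM" in avail and rng.random() < config.rem_probability:
            state = "REM"
        elif state != "AWAKE" and "AWAKE" in avail:
            state = "AWAKE"
        elif "NREM" in avail:
            state = "NREM"
    return out


def _pink_noise(n: int, alpha: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha noise via spectral shaping (magnitude ~ f^(-alpha/2))."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _smooth_jitter(n: int, sr: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow (sub-0.5 Hz) Gaussian phase jitter with the requested SD."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sr)
    spec[f > 0.5] = 0.0
    spec[0] = 0.0  # zero-mean jitter: a DC term would bias the configured lag
    x = np.fft.irfft(spec, n=n)
    x_sd = x.std()
    return x * (sd / x_sd) if x_sd > 0 else x


def _slow_modulator(n: int, sr: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian process with ~20 s correlation time (sub-0.05 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sr)
    spec[f > 0.05] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _state_amplitude(states_sec: np.ndarray, band: str, cfg: SimConfig, sr: float) -> np.ndarray:
    """Per-sample amplitude envelope for *band*, ramped over 0.25 s at state changes."""
    amps = np.array([cfg.band_amplitudes.get(s, {}).get(band, 0.0) for s in states_sec])
    per_sample = np.repeat(amps, int(round(sr)))
    w = max(3, int(0.25 * sr))
    kernel = np.hanning(w)
    kernel /= kernel.sum()
    return np.convolve(per_sample, kernel, mode="same")


def _insert_template(x: np.ndarray, start: int, template: np.ndarray) -> None:
    stop = min(start + template.size, x.size)
    x[start:stop] += template[: stop - start]


def _band_noise_sd(noise: np.ndarray, band: tuple[float, float], sr: float) -> float:
    spec = FilterSpec(band[0], band[1], sr)
    return float(bandpass(noise, spec).std())


def synthesize(config: SimConfig) -> SyntheticRecording:
    """Generate the synthetic recording described by *config*."""
    rng = np.random.default_rng(config.seed)
    sr = config.sample_rate
    n_sec = int(round(config.duration))
    n = int(round(n_sec * sr))
    t = np.arange(n) / sr
    clock_h = config.start_hour + t / 3600.0

    states = make_state_schedule(config, rng)

    # --- circadian carrier frequencies (counterphase theta vs gamma) -----
    circ = config.circadian
    ph24 = 2 * np.pi * clock_h / circ.period_h + circ.phase_offset
    f_theta = circ.theta_mean + circ.theta_amp * np.sin(ph24)
    f_gamma = circ.gamma_mean + circ.gamma_amp * np.sin(ph24 + np.pi)

    phi_theta = 2 * np.pi * np.cumsum(f_theta) / sr
    phi_gamma = 2 * np.pi * np.cumsum(f_gamma) / sr

    # state-dependent band amplitudes with slow within-state lognormal
    # fluctuation: real band power varies substantially within a state, and
    # the downstream ratio-histogram fits assume modes of finite width
    amp_d = _state_amplitude(states, "delta", config, sr)
    amp_t = _state_amplitude(states, "theta", config, sr)
    amp_g = _state_amplitude(states, "gamma", config, sr)
    if config.amplitude_jitter_sigma > 0:
        for arr in (amp_d, amp_t, amp_g):
            arr *= np.exp(
                config.amplitude_jitter_sigma * _slow_modulator(n, sr, rng)
            )

    depth = config.pac.coupling_depth
    pac_env = (1.0 + depth * np.cos(phi_theta - config.pac.preferred_phase)) / (1.0 + depth)

    theta = amp_t * np.cos(phi_theta)
    gamma = amp_g * pac_env * np.cos(phi_gamma)

    # --- two-site delta with configurable lag and jitter ------------------
    dsync = config.delta_sync
    phi_delta = 2 * np.pi * dsync.delta_freq * t
    jitter = _smooth_jitter(n, sr, dsync.phase_jitter_sd, rng)
    delta1 = amp_d * np.cos(phi_delta)
    delta2 = amp_d * np.cos(phi_delta - dsync.phase_lag - jitter)

    noise1 = _pink_noise(n, config.pink_alpha, config.pink_rms, rng)
    noise2 = _pink_noise(n, config.pink_alpha, config.pink_rms, rng)

    ch1 = delta1 + theta + gamma + noise1
    ch2 = delta2 + config.channel2_scale * (theta + gamma) + noise2

    # --- NREM transient events -------------------------------------------
    nrem_sec = np.flatnonzero(states == "NREM")
    spwr_events: list[tuple[float, float]] = []
    spindle_events: list[tuple[float, float]] = []

    # template amplitudes are SNR multiples of the composed in-band NREM
    # background (ongoing rhythms + pink noise), the reference a detector
    # actually competes against
    nrem_sample = np.repeat(states == "NREM", int(round(sr)))[:n]
    ref1 = ch1[nrem_sample] if nrem_sample.any() else ch1
    ref2 = ch2[nrem_sample] if nrem_sample.any() else ch2

    rip_len = int(round(config.spwr.duration_s * sr))
    rip_t = np.arange(rip_len) / sr
    rip_sd = (
        _band_noise_sd(ref1, BANDS["ripple"], sr)
        if config.spwr.rate > 0 and ref1.size > 2048
        else 0.0
    )
    rip_amp = config.spwr.snr * rip_sd
    ripple_tpl = rip_amp * np.hanning(rip_len) * np.sin(2 * np.pi * config.spwr.ripple_freq * rip_t)
    # slow deflection, mean-balanced so the event mean stays within the
    # flanking-baseline criterion
    sw = -2.0 * rip_amp * np.hanning(rip_len)
    sw -= sw.mean()
    ripple_tpl = ripple_tpl + sw

    spin_len = int(round(config.spindle.duration_s * sr))
    spin_t = np.arange(spin_len) / sr
    spin_sd = (
        _band_noise_sd(ref2, BANDS["spindle"], sr)
        if (config.spindle.rate > 0 or config.spindle.coupled_fraction > 0)
        and ref2.size > 2048
        else 0.0
    )
    spin_amp = config.spindle.snr * spin_sd
    spindle_tpl = spin_amp * np.hanning(spin_len) * np.sin(2 * np.pi * config.spindle.freq * spin_t)

    lat = config.spindle
    if lat.latency_sd > 0:
        shape = (lat.latency_mean / lat.latency_sd) ** 2
        scale = lat.latency_sd**2 / lat.latency_mean
    else:
        shape = scale = 0.0

    nrem_set = set(nrem_sec.tolist())
    if nrem_sec.size and config.spwr.rate > 0:
        for sec in nrem_sec:
            for _ in range(rng.poisson(config.spwr.rate)):
                onset = sec + rng.uniform(0.0, 1.0 - config.spwr.duration_s)
                start = int(round(onset * sr))
                if start + rip_len >= n:
                    continue
                _insert_template(ch1, start, ripple_tpl)
                spwr_events.append((onset, onset + config.spwr.duration_s))
                if rng.random() < config.spindle.coupled_fraction:
                    delay = rng.gamma(shape, scale) if scale > 0 else lat.latency_mean
                    s_on = onset + max(0.05, delay)
                    s_start = int(round(s_on * sr))
                    if s_start + spin_len < n and int(s_on) in nrem_set:
                        _insert_template(ch2, s_start, spindle_tpl)
                        spindle_events.append((s_on, s_on + config.spindle.duration_s))
    if nrem_sec.size and config.spindle.rate > 0:
        for sec in nrem_sec:
            for _ in range(rng.poisson(config.spindle.rate)):
                onset = sec + rng.uniform(0.0, 1.0 - config.spindle.duration_s)
                start = int(round(onset * sr))
                if start + spin_len >= n:
                    continue
                _insert_template(ch2, start, spindle_tpl)
                spindle_events.append((onset, onset + config.spindle.duration_s))
    spwr_events.sort()
    spindle_events.sort()

    # --- activity trace ----------------------------------------------------
    awake = states == "AWAKE"
    activity = np.where(
        awake,
        rng.lognormal(np.log(30.0), 0.5, n_sec),
        rng.lognormal(np.log(2.0), 0.5, n_sec),
    )

    sec_idx = (np.arange(n_sec) * sr + sr / 2).astype(int).clip(0, n - 1)
    truth = {
        "state": states,
        "events": {"spwr": spwr_events, "spindle": spindle_events},
        "theta_freq_hz": f_theta[sec_idx],
        "gamma_freq_hz": f_gamma[sec_idx],
        "pac_preferred_phase": config.pac.preferred_phase,
        "delta_phase_lag": dsync.phase_lag,
    }
    return SyntheticRecording(
        channels=np.vstack([ch1, ch2]),
        sample_rate=sr,
        activity=activity,
        truth=truth,
        start_hour=config.start_hour,
        config=config,
    )
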