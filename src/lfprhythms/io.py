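"""Recording container and on-disk formats.

The native interchange format is a flat little-endian float32 sample stream
(channel-major) with a JSON sidecar holding the sample rate, channel labels
and start time; it round-trips losslessly at float32 precision.  EDF files
are read through :mod:`mne` when it is installed.  Truth/label tables are
plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "write_recording",
    "read_recording",
    "states_to_csv",
    "events_to_csv",
    "light_mask",
]


@dataclass
class Recording:
    """Multi-channel sample stream (mV) with rate and schedule metadata."""

    samples: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    channel_labels: list = field(default_factory=lambda: ["vCA1", "mPFC"])
    start_hour: float = 0.0  # clock hour of sample 0
    lights_on: float = 6.0  # standard 12 h light cycle, lights on 06:00-18:00
    lights_off: float = 18.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


def light_mask(rec_or_start, n_seconds: int | None = None,
               lights_on: float = 6.0, lights_off: float = 18.0) -> np.ndarray:
    """Per-second boolean light-phase mask — pure function of start time and schedule."""
    if isinstance(rec_or_start, Recording):
        start = rec_or_start.start_hour
        n_seconds = int(rec_or_start.duration)
        lights_on, lights_off = rec_or_start.lights_on, rec_or_start.lights_off
    else:
        start = float(rec_or_start)
        if n_seconds is None:
            raise ValueError("n_seconds required")
    hours = (start + np.arange(n_seconds) / 3600.0) % 24.0
    return (hours >= lights_on) & (hours < lights_off)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write *rec* as ``<path>.dat`` (little-endian float32) + ``<path>.json``."""
    base = Path(path)
    dat = base.with_suffix(".dat")
    rec.samples.astype("<f4").tofile(dat)
    meta = {
        "format": "rawbin-f4le",
        "sample_rate": rec.sample_rate,
        "n_channels": rec.n_channels,
        "n_samples": int(rec.samples.shape[1]),
        "channel_labels": list(rec.channel_labels),
        "start_hour": rec.start_hour,
        "lights_on": rec.lights_on,
        "lights_off": rec.lights_off,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return dat


def read_recording(path: str | Path) -> Recording:
    """Read a recording from rawbin+sidecar (``.dat``/``.json``) or EDF."""
    p = Path(path)
    if p.suffix.lower() == ".edf":
        return _read_edf(p)
    base = p.with_suffix("")
    meta_path = base.with_suffix(".json")
    dat_path = base.with_suffix(".dat")
    if not meta_path.exists():
        raise FileNotFoundError(f"sidecar {meta_path} not found")
    meta = json.loads(meta_path.read_text())
    expected = meta["n_channels"] * meta["n_samples"] * 4
    actual = dat_path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"{dat_path}: truncated or inconsistent stream — expected {expected} "
            f"bytes, found {actual} (differs from byte offset {min(actual, expected)})"
        )
    raw = np.fromfile(dat_path, dtype="<f4").reshape(
        meta["n_channels"], meta["n_samples"]
    )
    return Recording(
        samples=raw.astype(float),
        sample_rate=meta["sample_rate"],
        channel_labels=meta["channel_labels"],
        start_hour=meta.get("start_hour", 0.0),
        lights_on=meta.get("lights_on", 6.0),
        lights_off=meta.get("lights_off", 18.0),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional mne dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e3  # mne returns volts; recordings are handled in mV
    return Recording(
        samples=data,
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def states_to_csv(state: np.ndarray, path: str | Path, **extra_columns) -> None:
    """Per-second vigilance states (plus optional aligned columns) as CSV."""
    df = pd.DataFrame({"second": np.arange(len(state)), "state": state})
    for name, col in extra_columns.items():
        df[name] = col
    df.to_csv(path, index=False)


def events_to_csv(trains, path: str | Path) -> None:
    """One or more EventTrains as a long CSV (type, onset_s, offset_s, ...)."""
    frames = []
    for train in np.atleast_1d(trains):
        frames.append(
            pd.DataFrame(
                {
                    "type": train.kind,
                    "onset_s": train.onsets_s,
                    "offset_s": train.offsets_s,
                    "duration_ms": train.durations_ms,
                    "peak_freq_hz": train.peak_freq_hz,
                    "peak_z": train.peak_z,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
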