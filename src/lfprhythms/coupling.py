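"""Theta-gamma cross-frequency coupling: FAC and PAC matrices.

Two couplings are quantified over 8 s epochs in which both theta and gamma
show significant whitened spectral peaks:

* FAC (frequency-amplitude coupling): for every (theta frequency bin, gamma
  frequency bin) pair, the Tort modulation index (MI) of the gamma-band
  amplitude against the theta-band phase — the Kullback-Leibler distance of
  the phase-conditioned amplitude distribution from uniform, normalized to
  [0, 1] by log(n_bins).
* PAC (phase-amplitude coupling): gamma amplitude as a function of theta
  phase (18 bins of pi/9 rad per cycle, 0 rad at the theta peak), by two
  methods that should agree — per-cycle peak-to-peak amplitude medians
  (cycles delimited trough-to-trough from the analytic theta phase), and
  continuous Hilbert amplitude histograms over the continuous theta phase.

Gamma rows are 10 Hz bins spanning 30-120 Hz.  The default scheme uses the
9 non-overlapping bins that exactly tile that range; a 14-bin overlapping
scheme (10 Hz wide windows, evenly spaced starts) is selectable and every
matrix records which scheme produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi

from .filters import BANDS, FilterSpec, analytic_signal, bandpass

__all__ = [
    "CouplingMatrix",
    "gamma_bins",
    "theta_bins",
    "modulation_index",
    "fac_matrix",
    "pac_matrix_cycles",
    "pac_matrix_hilbert",
    "average_zscore_smooth",
    "max_coupling_coordinates",
    "preferred_phase",
    "surrogate_mi_threshold",
]

N_PHASE_BINS = 18  # pi/9 rad each
PHASE_EDGES = np.linspace(-np.pi, np.pi, N_PHASE_BINS + 1)
PHASE_CENTERS = 0.5 * (PHASE_EDGES[:-1] + PHASE_EDGES[1:])


def gamma_bins(scheme: str = "nonoverlap") -> list[tuple[float, float]]:
    """10 Hz gamma bins spanning 30-120 Hz.

    ``nonoverlap``: the 9 bins 30-40, ..., 110-120.  ``overlap14``: 14 bins
    of width 10 Hz with evenly spaced starts from 30 to 110 Hz.
    """
    if scheme == "nonoverlap":
        starts = np.arange(30.0, 120.0, 10.0)
    elif scheme == "overlap14":
        starts = np.linspace(30.0, 110.0, 14)
    else:
        raise ValueError(f"unknown gamma bin scheme: {scheme}")
    return [(s, s + 10.0) for s in starts]


def theta_bins(width: float = 1.0) -> list[tuple[float, float]]:
    """Theta frequency bins of *width* Hz tiling 5-12 Hz."""
    lo, hi = BANDS["theta"]
    starts = np.arange(lo, hi, width)
    return [(s, min(s + width, hi)) for s in starts]


@dataclass
class CouplingMatrix:
    """Gamma-bin x (phase-bin | theta-bin) coupling values with bin metadata."""

    values: np.ndarray  # (n_gamma, n_cols)
    gamma_bands: list
    col_kind: str  # "phase" or "theta_freq"
    col_centers: np.ndarray
    n_epochs: int
    scheme: str = "nonoverlap"
    method: str = ""

    @property
    def gamma_centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.gamma_bands])


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_phase_bins: int = N_PHASE_BINS
) -> float:
    """Tort modulation index of *amplitude* over *phase*, in [0, 1].

    Mean amplitude per phase bin is normalized to a distribution P and
    MI = KL(P || uniform) / log(n_bins).  Empty phase bins are dropped
    (merged with their neighbours by renormalization over occupied bins).
    """
    ph = np.asarray(phase, dtype=float)
    am = np.asarray(amplitude, dtype=float)
    if ph.shape != am.shape:
        raise ValueError("phase and amplitude must have equal length")
    edges = np.linspace(-np.pi, np.pi, n_phase_bins + 1)
    idx = np.clip(np.digitize(ph, edges) - 1, 0, n_phase_bins - 1)
    sums = np.bincount(idx, weights=am, minlength=n_phase_bins)
    counts = np.bincount(idx, minlength=n_phase_bins)
    occupied = counts > 0
    means = sums[occupied] / counts[occupied]
    n_occ = int(occupied.sum())
    if n_occ < 2:
        return 0.0
    total = means.sum()
    if total <= 0:
        return 0.0
    p = means / total
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n_occ)))
    return kl / np.log(n_occ)


def _require_epochs(epochs, min_epochs: int) -> list:
    eps = [np.asarray(e, dtype=float) for e in epochs]
    if len(eps) < min_epochs:
        raise ValueError(
            f"coupling matrices require at least {min_epochs} epochs, got {len(eps)}"
        )
    return eps


def fac_matrix(
    epochs,
    sr: float,
    scheme: str = "nonoverlap",
    theta_width: float = 1.0,
    min_epochs: int = 10,
) -> CouplingMatrix:
    """MI matrix over (theta frequency bin, gamma frequency bin) pairs.

    For each epoch and each pair, the theta sub-band phase and the gamma
    sub-band Hilbert amplitude feed the modulation index; matrices are
    averaged over epochs.
    """
    eps = _require_epochs(epochs, min_epochs)
    tbins = theta_bins(theta_width)
    gbins = gamma_bins(scheme)
    acc = np.zeros((len(gbins), len(tbins)))
    for x in eps:
        phases = []
        for lo, hi in tbins:
            spec = FilterSpec(lo, hi, sr, n_taps=_epoch_taps(lo, hi, sr, x.size))
            phases.append(analytic_signal(bandpass(x, spec), sr).phase)
        for gi, (glo, ghi) in enumerate(gbins):
            spec = FilterSpec(glo, ghi, sr, n_taps=_epoch_taps(glo, ghi, sr, x.size))
            amp = analytic_signal(bandpass(x, spec), sr).amplitude
            for ti in range(len(tbins)):
                acc[gi, ti] += modulation_index(phases[ti], amp)
    acc /= len(eps)
    centers = np.array([(lo + hi) / 2 for lo, hi in tbins])
    return CouplingMatrix(
        values=acc, gamma_bands=gbins, col_kind="theta_freq",
        col_centers=centers, n_epochs=len(eps), scheme=scheme, method="fac",
    )


def _epoch_taps(lo: float, hi: float, sr: float, n_samples: int) -> int:
    """Tap count for sub-band filters, capped so short epochs stay filterable."""
    from .filters import fir_num_taps

    n = fir_num_taps(lo, hi, sr)
    cap = n_samples - 1
    if cap % 2 == 0:
        cap -= 1
    return min(n, cap) if cap >= 401 else cap


def _gamma_filtered(x: np.ndarray, sr: float, gbins) -> list[np.ndarray]:
    out = []
    for lo, hi in gbins:
        spec = FilterSpec(lo, hi, sr, n_taps=_epoch_taps(lo, hi, sr, x.size))
        out.append(bandpass(x, spec))
    return out


def _theta_phase(x: np.ndarray, sr: float) -> np.ndarray:
    lo, hi = BANDS["theta"]
    spec = FilterSpec(lo, hi, sr, n_taps=_epoch_taps(lo, hi, sr, x.size))
    return analytic_signal(bandpass(x, spec), sr).phase


def pac_matrix_cycles(
    epochs, sr: float, scheme: str = "nonoverlap", min_epochs: int = 10
) -> CouplingMatrix:
    """PAC by per-cycle peak-to-peak amplitudes (method 1).

    Theta cycles are delimited trough-to-trough from the analytic phase;
    each cycle is divided into 18 equal-phase segments (pi/9 rad) and the
    peak-to-peak amplitude of every 10 Hz gamma sub-band trace is measured
    per segment; the matrix holds the medians over all cycles.  Epochs
    without detectable cycles are skipped and counted.
    """
    eps = _require_epochs(epochs, min_epochs)
    gbins = gamma_bins(scheme)
    collected: list[list[list[float]]] = [
        [[] for _ in range(N_PHASE_BINS)] for _ in gbins
    ]
    skipped = 0
    for x in eps:
        phase = _theta_phase(x, sr)
        gtraces = _gamma_filtered(x, sr, gbins)
        wraps = np.flatnonzero(np.diff(phase) < -np.pi)
        if wraps.size < 2:
            skipped += 1
            continue
        bin_idx = np.clip(np.digitize(phase, PHASE_EDGES) - 1, 0, N_PHASE_BINS - 1)
        for c0, c1 in zip(wraps[:-1] + 1, wraps[1:] + 1):
            if c1 - c0 < N_PHASE_BINS:
                continue
            seg_bins = bin_idx[c0:c1]
            for gi, tr in enumerate(gtraces):
                seg = tr[c0:c1]
                for b in range(N_PHASE_BINS):
                    sel = seg_bins == b
                    if sel.any():
                        chunk = seg[sel]
                        collected[gi][b].append(float(chunk.max() - chunk.min()))
    values = np.zeros((len(gbins), N_PHASE_BINS))
    for gi in range(len(gbins)):
        for b in range(N_PHASE_BINS):
            vals = collected[gi][b]
            values[gi, b] = np.median(vals) if vals else 0.0
    return CouplingMatrix(
        values=values, gamma_bands=gbins, col_kind="phase",
        col_centers=PHASE_CENTERS.copy(), n_epochs=len(eps) - skipped,
        scheme=scheme, method="cycles",
    )


def pac_matrix_hilbert(
    epochs, sr: float, scheme: str = "nonoverlap", min_epochs: int = 10
) -> CouplingMatrix:
    """PAC from continuous theta phase and gamma Hilbert amplitude (method 2)."""
    eps = _require_epochs(epochs, min_epochs)
    gbins = gamma_bins(scheme)
    acc = np.zeros((len(gbins), N_PHASE_BINS))
    counts = np.zeros((len(gbins), N_PHASE_BINS))
    for x in eps:
        phase = _theta_phase(x, sr)
        bin_idx = np.clip(np.digitize(phase, PHASE_EDGES) - 1, 0, N_PHASE_BINS - 1)
        for gi, (glo, ghi) in enumerate(gamma_bins(scheme)):
            spec = FilterSpec(glo, ghi, sr, n_taps=_epoch_taps(glo, ghi, sr, x.size))
            amp = analytic_signal(bandpass(x, spec), sr).amplitude
            acc[gi] += np.bincount(bin_idx, weights=amp, minlength=N_PHASE_BINS)
            counts[gi] += np.bincount(bin_idx, minlength=N_PHASE_BINS)
    values = np.divide(acc, counts, out=np.zeros_like(acc), where=counts > 0)
    return CouplingMatrix(
        values=values, gamma_bands=gbins, col_kind="phase",
        col_centers=PHASE_CENTERS.copy(), n_epochs=len(eps),
        scheme=scheme, method="hilbert",
    )


@dataclass
class SmoothedCoupling:
    raw_mean: CouplingMatrix
    zscored: np.ndarray
    smoothed: np.ndarray
    upsample: int


def average_zscore_smooth(matrices, upsample: int = 4) -> SmoothedCoupling:
    """Element-wise average, Z-score over cells, and bicubic-spline upsampling.

    The raw averaged matrix is retained; the Z-scored matrix has cell mean 0
    and SD 1; the smoothed matrix is a display-resolution spline
    interpolation (order-3) of the Z-scored one.
    """
    mats = list(matrices)
    if len(mats) < 1:
        raise ValueError("need at least one matrix")
    shape = mats[0].values.shape
    if any(m.values.shape != shape for m in mats):
        raise ValueError("matrices must share a shape")
    mean = np.mean([m.values for m in mats], axis=0)
    sd = mean.std()
    z = (mean - mean.mean()) / sd if sd > 0 else np.zeros_like(mean)
    smoothed = _ndi.zoom(z, upsample, order=3, mode="nearest")
    raw = CouplingMatrix(
        values=mean, gamma_bands=mats[0].gamma_bands, col_kind=mats[0].col_kind,
        col_centers=mats[0].col_centers, n_epochs=sum(m.n_epochs for m in mats),
        scheme=mats[0].scheme, method=mats[0].method,
    )
    return SmoothedCoupling(raw_mean=raw, zscored=z, smoothed=smoothed, upsample=upsample)


def max_coupling_coordinates(matrix: CouplingMatrix) -> dict:
    """Bin-centre coordinates of the global maximum of a non-Z-scored matrix.

    Ties resolve to the lowest gamma bin and earliest column, flagged.
    """
    v = matrix.values
    best = v.max()
    ties = np.argwhere(v == best)
    gi, ci = ties[np.lexsort((ties[:, 1], ties[:, 0]))][0]
    return {
        "gamma_hz": float(matrix.gamma_centers[gi]),
        ("phase_rad" if matrix.col_kind == "phase" else "theta_hz"): float(
            matrix.col_centers[ci]
        ),
        "value": float(best),
        "tied": bool(len(ties) > 1),
    }


def preferred_phase(matrix: CouplingMatrix) -> float:
    """Amplitude-weighted circular mean phase of a PAC matrix, in (-pi, pi]."""
    if matrix.col_kind != "phase":
        raise ValueError("preferred_phase requires a PAC (phase-binned) matrix")
    profile = matrix.values.sum(axis=0)
    profile = profile - profile.min()
    if profile.sum() <= 0:
        return 0.0
    z = np.sum(profile * np.exp(1j * matrix.col_centers))
    return float(np.angle(z))


def surrogate_mi_threshold(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_surrogates: int = 200,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """MI quantile under circular time-shift shuffles of the amplitude series.

    Provides the objective zero for "significant" coupling: an observed MI
    at or below this threshold is indistinguishable from no coupling.
    """
    rng = np.random.default_rng(seed)
    n = len(amplitude)
    vals = np.empty(n_surrogates)
    for k in range(n_surrogates):
        shift = rng.integers(1, n - 1)
        vals[k] = modulation_index(phase, np.roll(amplitude, shift))
    return float(np.quantile(vals, quantile))
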