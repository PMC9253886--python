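"""Per-second vigilance staging (AWAKE / NREM / REM) from band-ratio mixtures.

The classifier follows a fixed sequence: the histogram of per-second
RMS(gamma)/RMS(delta) ratios is fit by a sum of two Gaussians; the
lower-mean component defines NREM membership probabilities through a step
function of its mean and SD (1 within 1 SD, 0.397 within 2 SD, 0.067
within 3 SD, 0 beyond); a second is NREM when either flanking 8 s window
averages a probability >= 0.5.  Seconds outside NREM are split into REM and
AWAKE at the intersection of a two-Gaussian fit to their RMS(theta)/RMS(delta)
ratios, REM additionally requiring adjacency to an NREM run, and are then
reclassified against the activity trace (active "REM" -> AWAKE, inactive
AWAKE -> REM, and REM immediately following AWAKE -> AWAKE).

The probability weights 0.397 and 0.067 are the published constants
((95.45-68.27)/68.27 and (99.73-95.45)/68.27) and are used verbatim rather
than recomputed from normal tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GaussianPair",
    "VigilanceLabels",
    "fit_two_gaussians",
    "nrem_probability",
    "binary_nrem",
    "theta_delta_threshold",
    "classify_rem_awake",
    "reclassify_by_activity",
    "hourly_fractions",
    "classify",
]

P_1SD = 1.0
P_2SD = 0.397  # (95.45 - 68.27) / 68.27, published constant
P_3SD = 0.067  # (99.73 - 95.45) / 68.27, published constant


@dataclass
class GaussianPair:
    """Two Gaussian components ordered by mean (component 1 = lower mean)."""

    mean1: float
    sd1: float
    weight1: float
    mean2: float
    sd2: float
    weight2: float
    residual_rms: float = np.nan
    failed: bool = False
    variance_crossed: bool = False  # lower-mean component has larger SD

    @property
    def lower(self) -> tuple[float, float, float]:
        return self.mean1, self.sd1, self.weight1


@dataclass
class VigilanceLabels:
    """Per-second state with the NREM probability track and provenance flags."""

    state: np.ndarray  # '<U5' in {AWAKE, NREM, REM}
    nrem_probability: np.ndarray
    reclassified: np.ndarray  # bool, touched by the activity passes

    def fraction(self, which: str) -> float:
        return float(np.mean(self.state == which))


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - m2) / s2) ** 2
    )


def fit_two_gaussians(values: np.ndarray, n_bins: int = 200) -> GaussianPair:
    """Least-squares two-Gaussian fit to the histogram of *values*.

    Binning spans the 0.1-99.9 percentile range in ``n_bins`` equal-width
    bins; the fit is initialized from the 25th/75th percentiles.  Degenerate
    (effectively single-mode) data raise the ``failed`` flag and return a
    single-Gaussian fallback duplicated into both slots.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 1000:
        raise ValueError("need at least 1000 values for a stable mixture fit")
    lo, hi = np.percentile(v, [0.1, 99.9])
    if hi <= lo:
        return _single_fallback(v)
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    bounds = ([0, lo, 1e-9, 0, lo, 1e-9], [np.inf, hi, hi - lo, np.inf, hi, hi - lo])
    # multi-start: quartile-based init handles balanced mixtures, the
    # tail-percentile inits handle strongly unbalanced ones (a minority
    # component of a few percent, as REM is among non-NREM seconds)
    starts = [(float(np.percentile(v, plo)), float(np.percentile(v, phi)))
              for plo, phi in ((25, 75), (10, 90), (50, 97.5), (2.5, 50))]
    # extra start at the two most prominent smoothed-histogram modes
    smooth = np.convolve(counts, np.ones(7) / 7.0, mode="same")
    order = np.argsort(smooth)[::-1]
    m_a = centers[order[0]]
    far = order[np.abs(centers[order] - m_a) > (hi - lo) / 10.0]
    if far.size:
        starts.append((min(m_a, centers[far[0]]), max(m_a, centers[far[0]])))
    starts.append(_kmeans_start(v))
    # candidates are scored by the data log-likelihood of their implied
    # mixture: a pure histogram-residual criterion happily models
    # substructure of the dominant mode while leaving a small second mode
    # unexplained, which the likelihood of the raw values heavily penalizes
    sub = v if v.size <= 20_000 else v[:: v.size // 20_000]
    best = None
    for qlo, qhi in starts:
        if qhi <= qlo:
            continue
        spread = max((qhi - qlo) / 4.0, (hi - lo) / n_bins)
        p0 = [counts.max(), qlo, spread, counts.max() / 10.0, qhi, spread]
        try:
            popt, _ = curve_fit(
                _two_gauss, centers, counts, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            continue
        ll = _mixture_loglik(sub, popt)
        if best is None or ll > best[0]:
            best = (ll, popt)
    if best is None:
        return _single_fallback(v)
    a1, m1, s1, a2, m2, s2 = best[1]
    if m1 > m2:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    resid = counts - _two_gauss(centers, a1, m1, s1, a2, m2, s2)
    rms = float(np.sqrt(np.mean(resid**2)))
    # unidentifiable: components essentially coincide, or one carries
    # negligible mass (a spurious second component fitted to a tail)
    sep = abs(m2 - m1) / max(s1, s2, 1e-12)
    mass1, mass2 = a1 * abs(s1), a2 * abs(s2)
    min_mass = min(mass1, mass2) / max(mass1 + mass2, 1e-300)
    failed = sep < 0.5 or min(a1, a2) <= 0 or min_mass < 0.02
    return GaussianPair(
        mean1=m1, sd1=abs(s1), weight1=a1,
        mean2=m2, sd2=abs(s2), weight2=a2,
        residual_rms=rms, failed=failed, variance_crossed=abs(s1) > abs(s2),
    )


def _kmeans_start(v: np.ndarray, iters: int = 25) -> tuple[float, float]:
    """Two-cluster Lloyd iteration on the values; returns the cluster means."""
    c1, c2 = np.percentile(v, [20, 80])
    for _ in range(iters):
        split = 0.5 * (c1 + c2)
        lo, hi_ = v[v <= split], v[v > split]
        if lo.size == 0 or hi_.size == 0:
            break
        n1, n2 = float(lo.mean()), float(hi_.mean())
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    return float(c1), float(c2)


def _mixture_loglik(values: np.ndarray, popt) -> float:
    """Mean log-likelihood of *values* under the mixture implied by a fit."""
    a1, m1, s1, a2, m2, s2 = popt
    w1, w2 = a1 * abs(s1), a2 * abs(s2)
    tot = w1 + w2
    if tot <= 0 or abs(s1) < 1e-12 or abs(s2) < 1e-12:
        return -np.inf
    w1, w2 = w1 / tot, w2 / tot
    d1 = w1 / abs(s1) * np.exp(-0.5 * ((values - m1) / s1) ** 2)
    d2 = w2 / abs(s2) * np.exp(-0.5 * ((values - m2) / s2) ** 2)
    return float(np.mean(np.log(np.maximum(d1 + d2, 1e-300))))


def _single_fallback(v: np.ndarray) -> GaussianPair:
    m, s = float(np.mean(v)), float(np.std(v))
    return GaussianPair(m, s, 1.0, m, s, 1.0, residual_rms=np.nan, failed=True)


def nrem_probability(ratio, mean: float, sd: float):
    """Step-function NREM membership probability of a G/D ratio.

    1 within mean+1*SD, 0.397 within mean+2*SD, 0.067 within mean+3*SD and 0
    beyond; the published weights, applied with the published boundaries.
    Vectorized over *ratio*.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    r = np.asarray(ratio, dtype=float)
    out = np.zeros_like(r)
    out[r <= mean + 3 * sd] = P_3SD
    out[r <= mean + 2 * sd] = P_2SD
    out[r <= mean + 1 * sd] = P_1SD
    return out if out.ndim else float(out)


def binary_nrem(prob: np.ndarray, flank_s: int = 8) -> np.ndarray:
    """Binary NREM track from the per-second probability series.

    A second is NREM (1) unless the probability averages below 0.5 over
    *both* the preceding and the following ``flank_s`` seconds — i.e. NREM
    iff at least one flank averages >= 0.5.  Flanks truncate at the block
    edges.
    """
    p = np.asarray(prob, dtype=float)
    n = p.size
    csum = np.concatenate(([0.0], np.cumsum(p)))
    idx = np.arange(n)
    lo = np.maximum(idx - flank_s, 0)
    before = np.where(idx > lo, (csum[idx] - csum[lo]) / np.maximum(idx - lo, 1), 0.0)
    hi = np.minimum(idx + 1 + flank_s, n)
    after = np.where(hi > idx + 1, (csum[hi] - csum[idx + 1]) / np.maximum(hi - idx - 1, 1), 0.0)
    return ((before >= 0.5) | (after >= 0.5)).astype(int)


def theta_delta_threshold(pair: GaussianPair) -> tuple[float, bool]:
    """Ratio value where the two fitted Gaussian densities are equal.

    Solves the quadratic equality of the two weighted log-densities and
    returns the root between the means.  When no root lies between the
    means the density-weighted midpoint is returned with a True flag.
    """
    if pair.failed:
        raise ValueError("mixture fit failed; no threshold defined")
    a1, m1, s1 = pair.weight1, pair.mean1, pair.sd1
    a2, m2, s2 = pair.weight2, pair.mean2, pair.sd2
    # a1 exp(-(x-m1)^2/2s1^2) = a2 exp(-(x-m2)^2/2s2^2)
    A = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    B = m1 / s1**2 - m2 / s2**2
    C = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log(a1 / a2)
    if abs(A) < 1e-14:
        if abs(B) < 1e-14:
            return 0.5 * (m1 + m2), True
        x = -C / B
        if m1 < x < m2:
            return float(x), False
        return 0.5 * (m1 + m2), True
    disc = B**2 - 4 * A * C
    if disc < 0:
        return 0.5 * (m1 + m2), True
    roots = (-B + np.array([1.0, -1.0]) * np.sqrt(disc)) / (2 * A)
    inside = [r for r in roots if m1 < r < m2]
    if not inside:
        w = (a1 * s1) / (a1 * s1 + a2 * s2)
        return float(m1 * (1 - w) + m2 * w), True
    return float(inside[0]), False


def _runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs (half-open)."""
    m = np.asarray(mask).astype(int)
    d = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return zip(starts, stops)


def classify_rem_awake(
    theta_delta: np.ndarray, nrem: np.ndarray, threshold: float, max_gap_s: int = 2
) -> np.ndarray:
    """Split non-NREM seconds into REM and AWAKE.

    A contiguous run of non-NREM seconds whose theta/delta ratio exceeds the
    threshold becomes REM only when the run touches an NREM period on at
    least one side; everything else outside NREM is AWAKE.  The comparison
    is strict, so a ratio exactly at the threshold stays AWAKE.

    The 8 s RMS epochs smear state transitions, so up to ``max_gap_s``
    sub-threshold transition seconds between an NREM run and a candidate
    run still count as adjacency and are absorbed into the REM run.
    """
    td = np.asarray(theta_delta, dtype=float)
    nrem = np.asarray(nrem).astype(bool)
    n = td.size
    state = np.where(nrem, "NREM", "AWAKE").astype("U5")
    candidate = (~nrem) & (td > threshold)
    for start, stop in _runs(candidate):
        left = start
        for g in range(max_gap_s + 1):
            if start - 1 - g < 0:
                break
            if nrem[start - 1 - g]:
                left = start - g
                break
        right = stop
        for g in range(max_gap_s + 1):
            if stop + g >= n:
                break
            if nrem[stop + g]:
                right = stop + g
                break
        if left < start or right > stop or (start > 0 and nrem[start - 1]) or (
            stop < n and nrem[stop]
        ):
            state[left:right] = "REM"
    return state


def reclassify_by_activity(state: np.ndarray, activity: np.ndarray) -> VigilanceLabels:
    """Refine REM/AWAKE labels with the per-second activity trace.

    Three ordered passes: (1) REM seconds with activity above the pooled
    median activity of REM and AWAKE seconds become AWAKE; (2) AWAKE seconds
    with activity below the median activity of NREM seconds become REM;
    (3) REM runs whose immediately preceding second is AWAKE become AWAKE.
    All comparisons are strict.  An empty NREM set skips pass 2.
    """
    st = np.asarray(state, dtype="U5").copy()
    act = np.asarray(activity, dtype=float)
    if act.size != st.size:
        raise ValueError("activity not aligned to labels")
    flags = np.zeros(st.size, dtype=bool)

    awake_rem = (st == "AWAKE") | (st == "REM")
    if awake_rem.any():
        med_ar = np.median(act[awake_rem])
        p1 = (st == "REM") & (act > med_ar)
        st[p1] = "AWAKE"
        flags |= p1

    nrem = st == "NREM"
    if nrem.any():
        med_n = np.median(act[nrem])
        p2 = (st == "AWAKE") & (act < med_n)
        st[p2] = "REM"
        flags |= p2

    for start, stop in _runs(st == "REM"):
        if start > 0 and st[start - 1] == "AWAKE":
            st[start:stop] = "AWAKE"
            flags[start:stop] = True

    return VigilanceLabels(state=st, nrem_probability=np.full(st.size, np.nan), reclassified=flags)


def hourly_fractions(state: np.ndarray) -> np.ndarray:
    """Per-hour percentages of AWAKE / NREM / REM (rows sum to 100).

    Returns an array of shape (n_hours, 3) in the order AWAKE, NREM, REM; a
    partial last hour is included and normalized over its own length.
    """
    st = np.asarray(state, dtype="U5")
    n_hours = int(np.ceil(st.size / 3600))
    out = np.zeros((n_hours, 3))
    for h in range(n_hours):
        chunk = st[h * 3600 : (h + 1) * 3600]
        for j, name in enumerate(("AWAKE", "NREM", "REM")):
            out[h, j] = 100.0 * np.mean(chunk == name)
    return out


def classify(
    gd_ratio: np.ndarray,
    td_ratio: np.ndarray,
    activity: np.ndarray,
) -> VigilanceLabels:
    """Full staging pipeline on aligned per-second ratio and activity series."""
    pair = fit_two_gaussians(gd_ratio)
    prob = nrem_probability(gd_ratio, pair.mean1, pair.sd1)
    nrem = binary_nrem(prob)
    outside = ~nrem.astype(bool)
    # too few non-NREM seconds (or a unimodal theta/delta histogram) leaves
    # the REM/AWAKE split undefined; everything outside NREM stays AWAKE
    thr = np.inf
    if outside.sum() >= 1000:
        td_pair = fit_two_gaussians(np.asarray(td_ratio)[outside])
        if not td_pair.failed:
            thr, _flag = theta_delta_threshold(td_pair)
    state = classify_rem_awake(td_ratio, nrem, thr)
    labels = reclassify_by_activity(state, activity)
    labels.nrem_probability = np.asarray(prob, dtype=float)
    return labels
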