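"""Effect sizes, rank tests and rank-based multiple comparisons.

Cohen's d is computed as ``|M1 - M2| / sqrt((SD1^2 + SD2^2) / 2)`` — the
root-mean of the two group variances in the denominator, not the pooled,
sample-size-weighted variance — with the anchor scale small (d <= 0.2),
medium (0.5), large (0.8), very large (d >= 1.2); interval labels use the
midpoints between anchors as boundaries.

Hypothesis tests are non-parametric: Wilcoxon-Mann-Whitney for unpaired
data, Wilcoxon signed-rank for paired data, Kruskal-Wallis across multiple
groups followed — only when significant — by Dunn-Holland-Wolfe joint-rank
multiple comparisons allowing unequal sample sizes, and two-sample
Kolmogorov-Smirnov for cumulative distributions (alpha 0.001; 0.05
elsewhere).  All p-values are two-tailed; exact distributions are used at
small sample sizes, normal approximations with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _stats

__all__ = [
    "GroupSummary",
    "EffectSize",
    "cohens_d",
    "cohens_d_from_samples",
    "fold_ratio",
    "rank_tests",
    "dunn_holland_wolfe",
]

EXACT_N_CUTOFF = 25

# anchor points of the effect-size scale; labels switch at the midpoints
_LABELS = [(0.35, "small"), (0.65, "medium"), (1.2, "large")]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD, SEM, n and 95% CI of one group."""

    mean: float
    sd: float
    n: int

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n)

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.96 * self.sem
        return (self.mean - half, self.mean + half)

    @classmethod
    def from_samples(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=x.size)


@dataclass(frozen=True)
class EffectSize:
    d: float
    label: str


def cohens_d(m1: float, sd1: float, m2: float, sd2: float) -> EffectSize:
    """Cohen's d from two group means and SDs.

    >>> round(cohens_d(0.589, 0.147, 0.365, 0.133).d, 2)
    1.6
    """
    if sd1 == 0 and sd2 == 0:
        raise ValueError("Cohen's d undefined when both SDs are zero")
    d = abs(m1 - m2) / np.sqrt((sd1**2 + sd2**2) / 2.0)
    for bound, label in _LABELS:
        if d < bound:
            return EffectSize(d=float(d), label=label)
    return EffectSize(d=float(d), label="very large")


def cohens_d_from_samples(x, y) -> EffectSize:
    a, b = GroupSummary.from_samples(x), GroupSummary.from_samples(y)
    return cohens_d(a.mean, a.sd, b.mean, b.sd)


def fold_ratio(a: float, b: float) -> float:
    """Ratio a/b (full precision; round to 2 decimals when reporting)."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return a / b


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return np.unique(pooled).size < pooled.size


def rank_tests(kind: str, *samples, alpha: float | None = None) -> dict:
    """Dispatch the study's rank tests: MWW, signed-rank, KW or KS.

    Exact null distributions are used for MWW when the combined sample size
    is at most 25 (and ties permit) and for the signed-rank test at up to 25
    pairs; otherwise the tie-corrected normal approximation applies.
    """
    kind = kind.upper()
    samples = tuple(np.asarray(s, dtype=float) for s in samples)
    if any(s.size == 0 for s in samples):
        raise ValueError("empty sample")
    if alpha is None:
        alpha = 0.001 if kind == "KS" else 0.05
    flag = None
    if kind == "MWW":
        x, y = samples
        exact = (x.size + y.size) <= EXACT_N_CUTOFF and not _has_ties(x, y)
        res = _stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
    elif kind in ("WILCOXON_SIGNED", "WILCOXON"):
        x, y = samples
        diffs = x - y
        if np.all(diffs == 0):
            return {
                "kind": kind, "statistic": np.nan, "p_value": np.nan,
                "alpha": alpha, "significant": False,
                "flag": "all paired differences zero; test undefined",
            }
        exact = x.size <= EXACT_N_CUTOFF and not _has_ties(np.abs(diffs[diffs != 0]))
        res = _stats.wilcoxon(x, y, method="exact" if exact else "approx")
    elif kind == "KW":
        res = _stats.kruskal(*samples)
    elif kind == "KS":
        x, y = samples
        res = _stats.ks_2samp(x, y)
    else:
        raise ValueError(f"unknown test kind: {kind}")
    return {
        "kind": kind,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "alpha": alpha,
        "significant": bool(res.pvalue < alpha),
        "flag": flag,
    }


def dunn_holland_wolfe(groups, alpha: float = 0.05, force: bool = False) -> dict:
    """Joint-rank pairwise comparisons after a significant Kruskal-Wallis.

    All observations are ranked jointly (midranks for ties); each pair of
    groups is compared via the mean-rank difference against its large-sample
    normal standard error ``sqrt((N(N+1)/12 - T/(12(N-1))) * (1/ni + 1/nj))``
    with the tie term ``T = sum(t^3 - t)``.  Family-wise adjusted p-values
    use a Bonferroni factor over the k(k-1)/2 pairs.  Calling without a
    significant KW result is refused unless ``force`` is set.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    kw = rank_tests("KW", *gs, alpha=alpha) if len(gs) > 2 else None
    if len(gs) == 2:
        kw = rank_tests("MWW", *gs, alpha=alpha)
    if not kw["significant"] and not force:
        raise ValueError(
            "omnibus test not significant "
            f"(p={kw['p_value']:.4g} >= {alpha}); pairwise comparisons refused"
        )
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = _stats.rankdata(pooled)
    sizes = [g.size for g in gs]
    mean_ranks = []
    pos = 0
    for sz in sizes:
        mean_ranks.append(ranks[pos : pos + sz].mean())
        pos += sz
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_pairs = len(gs) * (len(gs) - 1) // 2
    pairs = {}
    for i, j in combinations(range(len(gs)), 2):
        se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else np.inf
        p_unadj = 2.0 * _stats.norm.sf(z)
        p_adj = min(1.0, p_unadj * n_pairs)
        pairs[(i, j)] = {
            "z": float(z),
            "p_unadjusted": float(p_unadj),
            "p_adjusted": float(p_adj),
            "significant": bool(p_adj < alpha),
        }
    return {"omnibus": kw, "pairs": pairs, "alpha": alpha}
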