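"""Normality-gated group comparisons and correlations.

Workflow mirrors a standard small-animal imaging study: one value per animal
per region (repeated measurements pre-averaged), Kolmogorov-Smirnov normality
screening, ANOVA + Bonferroni-adjusted pairwise t-tests when every group
looks normal and Kruskal-Wallis + Bonferroni-adjusted Mann-Whitney otherwise,
Pearson or Spearman correlation with histology covariates, and the
conventional correlation-strength labels (|r| >= 0.7 strong, 0.4-0.699
moderate, below weak).

The Mann-Whitney test uses exact enumeration with midranks for combined
n <= 12 and the tie-corrected normal approximation otherwise.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult", "ThreeGroupResult", "CorrelationResult",
    "normality_gate", "bonferroni", "mann_whitney", "compare_three_groups",
    "correlate", "strength_label", "significance_tier",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ThreeGroupResult:
    path: str                       # "anova" | "kruskal"
    omnibus: TestResult
    pairwise: dict[tuple[str, str], TestResult] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    method: str                     # "pearson" | "spearman"
    r: float
    p: float
    label: str

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")


def normality_gate(values, alpha: float = 0.05) -> str:
    """Kolmogorov-Smirnov screen against a normal with the sample moments.

    Returns "normal" iff the KS p-value is >= alpha.  Note the parameters
    are estimated from the same sample (Lilliefors caveat: the nominal KS
    p-value is anti-conservative), used here as a routing rule, not as a
    calibrated test.  A degenerate (zero-variance) sample is "non_normal".
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("normality screening needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return "non_normal"
    p = sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue
    return "normal" if p >= alpha else "non_normal"


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


@lru_cache(maxsize=32)
def _exact_u_deviations(n1: int, n2: int) -> np.ndarray:
    """|U - mean| over every rank assignment, tie-free case (cached)."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    base = n1 * (n1 + 1) / 2.0
    return np.array([abs(sum(c) - base - mu)
                     for c in itertools.combinations(range(1, n + 1), n1)])


def mann_whitney(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For combined n <= 12, the p-value is computed by exhaustive enumeration
    of all rank assignments (midranks for ties): the two-sided p is the
    probability of a U at least as far from its null mean as observed.
    Larger samples use the normal approximation with tie correction.
    The reported statistic is U for the first sample.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= 12:
        dev_obs = abs(u_obs - mu)
        if len(np.unique(combined)) == n1 + n2:
            devs = _exact_u_deviations(n1, n2)      # tie-free: cached null
        else:
            base = n1 * (n1 + 1) / 2.0
            devs = np.array([abs(ranks[list(idx)].sum() - base - mu)
                             for idx in itertools.combinations(range(n1 + n2), n1)])
        p = float(np.mean(devs >= dev_obs - 1e-9))
        return TestResult(test="mann-whitney-exact", statistic=u_obs, p=p)
    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(test="mann-whitney-approx", statistic=u_obs, p=1.0)
    z = (u_obs - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(test="mann-whitney-approx", statistic=u_obs, p=min(p, 1.0))


def compare_three_groups(
    samples: dict[str, np.ndarray],
    path: str | None = None,
) -> ThreeGroupResult:
    """Omnibus comparison of three groups with Bonferroni-adjusted pairs.

    If all three groups pass the normality screen the parametric path is
    taken (one-way ANOVA, pairwise t-tests); otherwise Kruskal-Wallis with
    pairwise Mann-Whitney.  Pairwise p-values are Bonferroni-adjusted for
    the three comparisons.  ``path`` ("anova" or "kruskal") overrides the
    normality routing.
    """
    if len(samples) != 3:
        raise ValueError("exactly three groups are required")
    if path not in (None, "anova", "kruskal"):
        raise ValueError("path must be None, 'anova' or 'kruskal'")
    names = list(samples.keys())
    arrays = [np.asarray(samples[k], dtype=np.float64) for k in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    if path is None:
        all_normal = all(a.size >= 3 and normality_gate(a) == "normal"
                         for a in arrays)
    else:
        all_normal = path == "anova"
    pairs = list(itertools.combinations(range(3), 2))
    if all_normal:
        f, p = sps.f_oneway(*arrays)
        omnibus = TestResult(test="anova", statistic=float(f), p=float(p))
        pairwise = {}
        for i, j in pairs:
            t, pp = sps.ttest_ind(arrays[i], arrays[j])
            pairwise[(names[i], names[j])] = TestResult(
                test="t-test", statistic=float(t), p=float(pp),
                p_adjusted=bonferroni(float(pp), len(pairs)))
        return ThreeGroupResult(path="anova", omnibus=omnibus, pairwise=pairwise)
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        # identical groups: H = 0 by symmetry; scipy raises on all-tied input
        omnibus = TestResult(test="kruskal-wallis", statistic=0.0, p=1.0)
    else:
        h, p = sps.kruskal(*arrays)
        omnibus = TestResult(test="kruskal-wallis", statistic=float(h), p=float(p))
    pairwise = {}
    for i, j in pairs:
        res = mann_whitney(arrays[i], arrays[j])
        res.p_adjusted = bonferroni(res.p, len(pairs))
        pairwise[(names[i], names[j])] = res
    return ThreeGroupResult(path="kruskal", omnibus=omnibus, pairwise=pairwise)


def strength_label(r: float) -> str:
    """Conventional correlation-strength category for |r|."""
    a = abs(r)
    if a >= 0.700:
        return "strong"
    if a >= 0.400:
        return "moderate"
    return "weak"


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def correlate(x, y, method: str = "auto") -> CorrelationResult:
    """Pearson or Spearman correlation with a strength label.

    ``method="auto"`` uses Pearson iff both variables pass the normality
    screen, Spearman otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired samples with n >= 3 are required")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance variable: correlation undefined")
    if method == "auto":
        method = ("pearson"
                  if normality_gate(x) == "normal" and normality_gate(y) == "normal"
                  else "spearman")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    r, p = float(r), float(p)
    return CorrelationResult(method=method, r=r, p=p, label=strength_label(r))
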