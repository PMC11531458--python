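"""Method-comparison statistics.

Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 x SD of the
paired differences, sample SD with n-1), rank correlation, paired location
tests, mask-overlap indices (Jaccard, Dice), segmentation-grade summaries,
and a Monte-Carlo power simulation for agreement studies.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .image_io import GridError, LungMask

#: Conventional normal quantile for 95% limits of agreement.
LOA_MULTIPLIER = 1.96


@dataclass
class BlandAltmanResult:
    """Bias and limits of agreement between two paired measurement methods.

    Differences are ``x - y`` in the orientation the caller supplied (the
    pipeline's convention is TPTD minus CT).  Confidence intervals are
    normal-theory: Var(bias) = sd^2/n and Var(LoA) ~ sd^2 (1/n + z^2/(2(n-1))).
    """

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    orientation: str = "x-y"


def bland_altman(
    x: Sequence[float],
    y: Sequence[float],
    loa_multiplier: float = LOA_MULTIPLIER,
    ci_level: float = 0.95,
    orientation: str = "x-y",
) -> BlandAltmanResult:
    """Bland-Altman analysis of paired measurements ``x`` and ``y``.

    ``loa_multiplier`` is fixed at 1.96 by convention; pass a t-quantile
    for small samples if preferred.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")

    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance of differences; limits of agreement collapse", stacklevel=2)
    half = loa_multiplier * sd
    t = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    se_bias = sd / np.sqrt(n)
    # classic Bland-Altman large-sample variance for a limit of agreement
    se_loa = sd * np.sqrt(1.0 / n + loa_multiplier**2 / (2.0 * (n - 1)))
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - half,
        loa_upper=bias + half,
        ci_bias=(bias - t * se_bias, bias + t * se_bias),
        ci_loa_lower=(bias - half - t * se_loa, bias - half + t * se_loa),
        ci_loa_upper=(bias + half - t * se_loa, bias + half + t * se_loa),
        orientation=orientation,
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1D of equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class OverlapResult:
    """Set-overlap indices between two segmentations on one grid."""

    jaccard: float
    dice: float
    intersection_voxels: int
    union_voxels: int


def overlap_indices(a: LungMask, b: LungMask) -> OverlapResult:
    """Jaccard |A∩B|/|A∪B| and Dice 2|A∩B|/(|A|+|B|) of two masks.

    Two empty masks are defined as perfectly overlapping (1.0), with a
    warning, so the indices stay total.
    """
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-3, rtol=0.0):
        raise GridError("masks are not on compatible grids")
    inter = int(np.logical_and(a.data, b.data).sum())
    union = int(np.logical_or(a.data, b.data).sum())
    size_sum = a.n_voxels + b.n_voxels
    if union == 0:
        warnings.warn("both masks empty; overlap defined as 1", stacklevel=2)
        return OverlapResult(1.0, 1.0, 0, 0)
    jaccard = inter / union
    dice = 2.0 * inter / size_sum
    return OverlapResult(jaccard, dice, inter, union)


@dataclass
class GradeSummary:
    """Tallies of a three-point segmentation-quality score (1 good .. 3 poor)."""

    counts: dict[int, int]
    fractions: dict[int, float]
    percentages: dict[int, int]
    n_total: int


def summarize_grades(grades: Sequence[int], n_expected: Optional[int] = None) -> GradeSummary:
    """Counts, exact fractions and display percentages per grade."""
    grades = list(grades)
    if not grades:
        raise ValueError("no grades supplied")
    if any(g not in (1, 2, 3) for g in grades):
        bad = sorted({g for g in grades if g not in (1, 2, 3)})
        raise ValueError(f"grades must be in {{1,2,3}}; got {bad}")
    n = len(grades)
    if n_expected is not None and n != n_expected:
        raise ValueError(f"expected {n_expected} grades, got {n}")
    counts = Counter(grades)
    full = {g: counts.get(g, 0) for g in (1, 2, 3)}
    fractions = {g: c / n for g, c in full.items()}
    percentages = {g: int(round(100.0 * f)) for g, f in fractions.items()}
    return GradeSummary(counts=full, fractions=fractions, percentages=percentages, n_total=n)


def paired_location_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
) -> tuple[float, float]:
    """Two-sided paired t test or Wilcoxon signed-rank on (x, y).

    The t test on zero-variance differences is degenerate and raises;
    Wilcoxon falls back to scipy's zero-handling (all-zero differences give
    p = 1 via the zsplit rule).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    d = x - y
    if method == "t":
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                raise ValueError("zero-variance, zero-mean differences; paired t test degenerate")
            # constant nonzero shift: t statistic diverges, reject exactly
            return float(np.sign(d.mean()) * np.inf), 0.0
        res = stats.ttest_rel(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        if np.all(d == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(x, y, zero_method="zsplit")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}; use 't' or 'wilcoxon'")


def bland_altman_power(
    n: int,
    true_bias: float,
    true_sd: float,
    max_allowed_difference: float,
    reps: int = 1000,
    seed: Optional[int] = None,
    loa_multiplier: float = LOA_MULTIPLIER,
) -> float:
    """Monte-Carlo power of an agreement study of size ``n``.

    Simulates normal paired differences with the given bias and SD and
    estimates the probability that both 95% LoA confidence bounds fall
    inside +/- ``max_allowed_difference`` (the usual criterion for claiming
    acceptable agreement).  Deterministic given ``seed``.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if true_sd <= 0:
        raise ValueError("true_sd must be positive")
    if reps < 100:
        raise ValueError("reps must be >= 100 for a stable estimate")
    if max_allowed_difference <= abs(true_bias) + loa_multiplier * true_sd:
        warnings.warn(
            "allowed difference does not exceed the true limits of agreement; "
            "power will be near zero",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        d = rng.normal(true_bias, true_sd, size=n)
        ba = bland_altman(d, np.zeros(n), loa_multiplier=loa_multiplier)
        if ba.ci_loa_lower[0] > -max_allowed_difference and ba.ci_loa_upper[1] < max_allowed_difference:
            hits += 1
    return hits / reps


def bland_altman_plot(
    x: Sequence[float],
    y: Sequence[float],
    path: str,
    result: Optional[BlandAltmanResult] = None,
    xlabel: str = "mean of methods (ml)",
    ylabel: str = "difference (ml)",
) -> None:
    """Scatter of pairwise means vs differences with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if result is None:
        result = bland_altman(x, y)
    means = (x + y) / 2.0
    diffs = x - y
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=14, alpha=0.7)
    ax.axhline(result.bias, linestyle=":", color="k", label=f"bias {result.bias:.0f} ml")
    ax.axhline(result.loa_lower, linestyle="--", color="gray")
    ax.axhline(result.loa_upper, linestyle="--", color="gray", label="95% LoA")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
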