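"""Group summaries, t-tests, effect sizes and responder analysis.

Conventions, chosen to match how pre/post field-test studies in sport
science report their numbers:

* Confidence intervals are central two-sided t intervals (default level
  0.90, a common choice in this literature).
* The unpaired test defaults to Student's pooled-variance form; Welch is
  available behind a flag. Pooled (n-1)-weighted SDs are also what the
  between-group Cohen's d uses.
* Within-group (pre/post) Cohen's d divides the mean change by the
  root-mean-square of the two time-point SDs — the convention that lets d be
  recomputed from a summary table with no raw data.
* Effect-size bands are contiguous half-open intervals at 0.2 / 0.5 / 0.8 /
  1.2 / 2.0 on |d| (trivial, small, moderate, large, very large, huge), so
  every finite d gets exactly one label.
* Percent improvement exists in two inequivalent conventions — the ratio of
  group means, and the mean of per-subject percentages — and both are
  implemented and labelled, because summary reports routinely mix them.

Summary-statistic entry points (``ci_mean_t``, ``cohen_d_prepost``,
``cohen_d_independent``) accept printed mean/SD/n directly, so published
tables can be re-analysed without raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError
from .io import Subject

__all__ = [
    "GroupSummary",
    "TTestResult",
    "EffectSize",
    "group_summary",
    "ci_mean_t",
    "paired_t",
    "independent_t",
    "bonferroni_alpha",
    "cohen_d_prepost",
    "cohen_d_independent",
    "classify_effect",
    "percent_improvement_of_means",
    "mean_individual_percent_improvement",
    "responder_counts",
    "EFFECT_BANDS",
]

#: Upper |d| bound (exclusive, except the closed 2.0) per qualitative band.
EFFECT_BANDS: tuple[tuple[float, str], ...] = (
    (0.2, "trivial"),
    (0.5, "small"),
    (0.8, "moderate"),
    (1.2, "large"),
    (2.0, "very large"),
    (math.inf, "huge"),
)


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD and central-t CI for one group of distances (m)."""

    label: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.90


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p: float
    alpha_adjusted: float = 0.05
    degenerate_variance: bool = False

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha_adjusted


@dataclass(frozen=True)
class EffectSize:
    d: float
    band: str


def classify_effect(d: float) -> str:
    """Qualitative band for |d|: trivial <0.2 ... huge >2."""
    magnitude = abs(d)
    for upper, band in EFFECT_BANDS:
        if magnitude < upper or (upper == 2.0 and magnitude == 2.0):
            return band
    return "huge"  # pragma: no cover - inf band always matches


def ci_mean_t(mean: float, sd: float, n: int, conf_level: float = 0.90) -> tuple[float, float]:
    """Two-sided central-t CI for a mean from summary statistics.

    Callable directly on printed mean/SD/n, which is how published tables
    are reproduced without raw data.
    """
    if n < 2:
        raise UndefinedStatisticError(f"CI undefined for n={n} (need n >= 2)")
    if not 0.0 < conf_level < 1.0:
        raise ValidationError(f"conf_level must lie in (0, 1), got {conf_level}")
    if sd < 0:
        raise ValidationError(f"sd must be non-negative, got {sd}")
    half_width = sps.t.ppf(0.5 + conf_level / 2.0, n - 1) * sd / math.sqrt(n)
    return (mean - half_width, mean + half_width)


def group_summary(
    values: Sequence[float], conf_level: float = 0.90, label: str = "all"
) -> GroupSummary:
    """Mean, sample SD (n-1) and t CI for raw values."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise UndefinedStatisticError(f"group summary needs n >= 2, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    lo, hi = ci_mean_t(mean, sd, n, conf_level)
    return GroupSummary(
        label=label, n=n, mean=mean, sd=sd, ci_low=lo, ci_high=hi, conf_level=conf_level
    )


def _one_sample_t(diffs: np.ndarray, alpha_adjusted: float) -> TTestResult:
    n = diffs.size
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, df, 1.0, alpha_adjusted, degenerate_variance=True)
        return TTestResult(
            math.copysign(math.inf, mean), df, 0.0, alpha_adjusted, degenerate_variance=True
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t, df, p, alpha_adjusted)


def paired_t(
    pre: Sequence[float], post: Sequence[float], alpha_adjusted: float = 0.05
) -> TTestResult:
    """Paired t-test on post - pre differences, two-sided.

    Zero-variance differences are reported with a degenerate-variance flag:
    all-zero differences give statistic 0 / p 1, constant non-zero
    differences give an unbounded statistic / p 0.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.size != b.size:
        raise ValidationError(f"pre/post length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise UndefinedStatisticError("paired t-test needs at least 2 pairs")
    return _one_sample_t(b - a, alpha_adjusted)


def independent_t(
    a: Sequence[float],
    b: Sequence[float],
    alpha_adjusted: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test, Student's pooled-variance by default (Welch optional)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise UndefinedStatisticError("independent t-test needs n >= 2 in each group")
    diff = float(y.mean() - x.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    nx, ny = x.size, y.size
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0.0:
            return _degenerate_two_sample(diff, float(min(nx, ny) - 1), alpha_adjusted)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        se = math.sqrt(se2)
    else:
        df = nx + ny - 2
        pooled_var = ((nx - 1) * vx + (ny - 1) * vy) / df
        if pooled_var == 0.0:
            return _degenerate_two_sample(diff, df, alpha_adjusted)
        se = math.sqrt(pooled_var * (1.0 / nx + 1.0 / ny))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t, df, p, alpha_adjusted)


def _degenerate_two_sample(diff: float, df: float, alpha_adjusted: float) -> TTestResult:
    if diff == 0.0:
        return TTestResult(0.0, df, 1.0, alpha_adjusted, degenerate_variance=True)
    return TTestResult(
        math.copysign(math.inf, diff), df, 0.0, alpha_adjusted, degenerate_variance=True
    )


def bonferroni_alpha(alpha: float, k: int) -> float:
    """Family alpha divided by the number of tests."""
    if k < 1:
        raise ValidationError(f"number of tests must be >= 1, got {k}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / k


def cohen_d_prepost(
    mean_pre: float, sd_pre: float, mean_post: float, sd_post: float
) -> EffectSize:
    """Within-group effect size: mean change over the RMS of the two SDs.

    d = (mean_post - mean_pre) / sqrt((sd_pre^2 + sd_post^2) / 2). With equal
    SDs this reduces to the plain change-over-SD form.
    """
    if sd_pre < 0 or sd_post < 0:
        raise ValidationError("SDs must be non-negative")
    denom = math.sqrt((sd_pre**2 + sd_post**2) / 2.0)
    if denom == 0.0:
        raise UndefinedStatisticError("effect size undefined: both SDs are zero")
    d = (mean_post - mean_pre) / denom
    return EffectSize(d=d, band=classify_effect(d))


def cohen_d_independent(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> EffectSize:
    """Between-group effect size with the (n-1)-weighted pooled SD.

    d = |mean2 - mean1| / s_pooled, s_pooled^2 = ((n1-1)sd1^2 + (n2-1)sd2^2)
    / (n1+n2-2). Symmetric in the two groups.
    """
    if n1 < 2 or n2 < 2:
        raise UndefinedStatisticError("pooled effect size needs n >= 2 per group")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        raise UndefinedStatisticError("effect size undefined: pooled variance is zero")
    d = abs(mean2 - mean1) / math.sqrt(pooled_var)
    return EffectSize(d=d, band=classify_effect(d))


def percent_improvement_of_means(mean_improvement: float, mean_pre: float) -> float:
    """Group improvement as a percentage of the group's mean baseline."""
    if mean_pre <= 0:
        raise ValidationError(f"mean pre-training distance must be > 0, got {mean_pre}")
    return 100.0 * mean_improvement / mean_pre


def mean_individual_percent_improvement(subjects: Iterable[Subject]) -> float:
    """Mean over subjects of each subject's own percent improvement.

    Distinct from (and generally larger than) the ratio-of-means convention
    whenever low-baseline subjects improve proportionally more.
    """
    ratios = []
    for s in subjects:
        if s.pre_yoyo <= 0:
            raise ValidationError(f"subject {s.id}: percent improvement undefined for pre=0")
        ratios.append(100.0 * s.improvement / s.pre_yoyo)
    if not ratios:
        raise ValidationError("no subjects given")
    return float(np.mean(ratios))


def responder_counts(
    improvements: Sequence[float], thresholds: Sequence[float] = (120.0, 500.0)
) -> Mapping[float, int]:
    """Per threshold, the count of improvements strictly greater than it.

    Defaults to the 120 m (beyond test-retest noise) and 500 m (large
    responder) cut-offs.
    """
    if len(thresholds) == 0:
        raise ValidationError("at least one threshold is required")
    x = np.asarray(improvements, dtype=float)
    return {float(t): int((x > t).sum()) for t in thresholds}
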