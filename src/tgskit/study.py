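"""Published summary statistics of the original cohort, as analysis inputs.

The study this package re-implements reported a 42-player male youth-soccer
cohort stratified by five-SNP TGS into low / medium / high groups of
6 / 23 / 13, with pre/post Yo-Yo IR1 distances and improvements given only
as group means and SDs. Those printed numbers are sufficient inputs for the
summary-statistic entry points (t confidence intervals, within- and
between-group Cohen's d, ratio-of-means percentages, and the difference-
score time/interaction F), so the headline statistics can be recomputed
here without the raw per-player data file.
"""

from __future__ import annotations

from dataclasses import dataclass

from .anova import anova_from_summaries
from .stats import (
    bonferroni_alpha,
    ci_mean_t,
    cohen_d_independent,
    cohen_d_prepost,
    percent_improvement_of_means,
)

__all__ = ["PublishedGroup", "PUBLISHED_GROUPS", "PUBLISHED_WHOLE_COHORT", "reproduce_published_analysis"]


@dataclass(frozen=True)
class PublishedGroup:
    """Printed mean/SD summaries for one TGS stratum (distances in metres)."""

    label: str
    n: int
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    improvement_mean: float
    improvement_sd: float


PUBLISHED_GROUPS: tuple[PublishedGroup, ...] = (
    PublishedGroup("low", 6, 1006.0, 292.0, 1073.0, 281.0, 67.0, 33.0),
    PublishedGroup("medium", 23, 1045.0, 472.0, 1409.0, 453.0, 364.0, 248.0),
    PublishedGroup("high", 13, 969.0, 493.0, 1529.0, 508.0, 560.0, 225.0),
)

#: Whole-cohort improvement summary: mean, SD, n.
PUBLISHED_WHOLE_COHORT = (382.0, 270.0, 42)


def reproduce_published_analysis(conf_level: float = 0.90) -> dict[str, object]:
    """Recompute every statistic derivable from the printed summaries.

    Returns a dict with within-group effect sizes, all pairwise
    between-group effect sizes of the improvements, t confidence intervals,
    ratio-of-means percent improvements, the Bonferroni-adjusted alpha for
    the six follow-up t-tests, and the unweighted-means (Type III) time and
    interaction F from the difference-score summaries.
    """
    groups = {g.label: g for g in PUBLISHED_GROUPS}
    within = {
        label: cohen_d_prepost(g.pre_mean, g.pre_sd, g.post_mean, g.post_sd)
        for label, g in groups.items()
    }
    pairs = (("low", "medium"), ("medium", "high"), ("low", "high"))
    between = {
        f"{a}_vs_{b}": cohen_d_independent(
            groups[a].improvement_mean,
            groups[a].improvement_sd,
            groups[a].n,
            groups[b].improvement_mean,
            groups[b].improvement_sd,
            groups[b].n,
        )
        for a, b in pairs
    }
    cis = {
        "low_improvement": ci_mean_t(
            groups["low"].improvement_mean, groups["low"].improvement_sd, groups["low"].n, conf_level
        ),
        "high_improvement": ci_mean_t(
            groups["high"].improvement_mean, groups["high"].improvement_sd, groups["high"].n, conf_level
        ),
        "all_improvement": ci_mean_t(*PUBLISHED_WHOLE_COHORT, conf_level),
        "low_pre": ci_mean_t(
            groups["low"].pre_mean, groups["low"].pre_sd, groups["low"].n, conf_level
        ),
    }
    percents = {
        label: percent_improvement_of_means(g.improvement_mean, g.pre_mean)
        for label, g in groups.items()
    }
    summary_anova = anova_from_summaries(
        [g.improvement_mean for g in PUBLISHED_GROUPS],
        [g.improvement_sd for g in PUBLISHED_GROUPS],
        [g.n for g in PUBLISHED_GROUPS],
        type_iii=True,
    )
    return {
        "within_effect_sizes": within,
        "between_effect_sizes": between,
        "confidence_intervals": cis,
        "percent_improvement_of_means": percents,
        "bonferroni_alpha_six_tests": bonferroni_alpha(0.05, 6),
        "summary_anova": summary_anova,
    }
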