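"""3x2 split-plot (mixed) ANOVA and Tukey's HSD.

One between-subjects factor (trainability group) crossed with one
within-subjects factor (time: pre/post). With exactly two within-subject
levels the within-subject tests reduce exactly to analyses of per-subject
difference scores: the Group x Time interaction is a one-way ANOVA on the
differences, and the Time main effect tests the grand mean of the
differences; no sphericity question arises. The between-subjects (Group)
effect operates on subject means, tested against subjects-within-groups.

Unbalanced designs use the unweighted-means (Type III) analysis by default:
effects are built from the plain average of group means with the harmonic
mean of the group sizes as the effective n, which is what mainstream GLM
software reports for unbalanced mixed designs. A sums-over-observations
(weighted) variant is available behind a flag; the two coincide on balanced
designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "SummaryAnovaResult",
    "TukeyPair",
    "TukeyResult",
    "split_plot_anova",
    "anova_from_summaries",
    "tukey_hsd",
    "studentized_range_sf_mc",
]


@dataclass(frozen=True)
class AnovaEffect:
    """One row of the ANOVA table; F and p are None for error strata."""

    name: str
    ss: float
    df: float
    ms: float
    f: float | None = None
    p: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    """Full split-plot decomposition.

    Effects: group (vs subjects-within-groups), time and group x time
    (vs the within-subjects error). Degrees of freedom across the five
    strata sum to 2N - 1.
    """

    group: AnovaEffect
    subjects_within_groups: AnovaEffect
    time: AnovaEffect
    interaction: AnovaEffect
    within_error: AnovaEffect
    type_iii: bool

    @property
    def effects(self) -> tuple[AnovaEffect, ...]:
        return (
            self.group,
            self.subjects_within_groups,
            self.time,
            self.interaction,
            self.within_error,
        )

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {"effect": e.name, "SS": e.ss, "df": e.df, "MS": e.ms, "F": e.f, "p": e.p}
            for e in self.effects
        ]


@dataclass(frozen=True)
class SummaryAnovaResult:
    """Time and interaction tests recomputed from difference-score summaries.

    Partial by construction: the between-subjects (Group) effect needs the
    pre/post correlation structure, which summary statistics do not carry.
    """

    time_f: float
    time_df: tuple[float, float]
    time_p: float
    interaction_f: float | None
    interaction_df: tuple[float, float] | None
    interaction_p: float | None
    type_iii: bool
    partial: bool = True


def _f_effect(name: str, ss: float, df: float, ms_error: float, df_error: float) -> AnovaEffect:
    ms = ss / df
    if ms_error == 0.0:
        f = 0.0 if ms == 0.0 else math.inf
        p = 1.0 if ms == 0.0 else 0.0
    else:
        f = ms / ms_error
        p = float(sps.f.sf(f, df, df_error))
    return AnovaEffect(name=name, ss=ss, df=df, ms=ms, f=f, p=p)


def split_plot_anova(
    groups: Mapping[str, Sequence[tuple[float, float]]], type_iii: bool = True
) -> AnovaResult:
    """Split-plot ANOVA for (pre, post) pairs grouped by stratum.

    Parameters
    ----------
    groups
        Mapping from group label to that group's (pre, post) pairs.
    type_iii
        Unweighted-means analysis with harmonic effective group size
        (default); ``False`` selects the sums-over-observations variant.
    """
    if len(groups) < 2:
        raise ValidationError("split-plot ANOVA needs at least 2 groups")
    labels = list(groups)
    pre, post, sizes = [], [], []
    for label in labels:
        pairs = np.asarray(groups[label], dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValidationError(f"group {label!r}: each subject needs exactly two time points")
        if pairs.shape[0] < 2:
            raise ValidationError(f"group {label!r}: need at least 2 subjects, got {pairs.shape[0]}")
        pre.append(pairs[:, 0])
        post.append(pairs[:, 1])
        sizes.append(pairs.shape[0])

    k = len(labels)
    ns = np.asarray(sizes, dtype=float)
    n_total = float(ns.sum())
    # Within-subject half: difference scores. Between half: subject means.
    diffs = [b - a for a, b in zip(pre, post)]
    means = [(a + b) / 2.0 for a, b in zip(pre, post)]
    diff_group_means = np.array([d.mean() for d in diffs])
    mean_group_means = np.array([m.mean() for m in means])

    ss_subj = 2.0 * sum(float(((m - m.mean()) ** 2).sum()) for m in means)
    ss_werr = 0.5 * sum(float(((d - d.mean()) ** 2).sum()) for d in diffs)
    df_between_err = n_total - k
    df_within_err = n_total - k

    if type_iii:
        n_eff = k / float((1.0 / ns).sum())  # harmonic mean group size
        grand_diff = float(diff_group_means.mean())
        grand_mean = float(mean_group_means.mean())
        ss_group = 2.0 * n_eff * float(((mean_group_means - grand_mean) ** 2).sum())
        ss_time = k * n_eff * grand_diff**2 / 2.0
        ss_int = n_eff * float(((diff_group_means - grand_diff) ** 2).sum()) / 2.0
    else:
        grand_diff = float(np.concatenate(diffs).mean())
        grand_mean = float(np.concatenate(means).mean())
        ss_group = 2.0 * float((ns * (mean_group_means - grand_mean) ** 2).sum())
        ss_time = n_total * grand_diff**2 / 2.0
        ss_int = float((ns * (diff_group_means - grand_diff) ** 2).sum()) / 2.0

    ms_subj = ss_subj / df_between_err
    ms_werr = ss_werr / df_within_err
    return AnovaResult(
        group=_f_effect("group", ss_group, k - 1, ms_subj, df_between_err),
        subjects_within_groups=AnovaEffect(
            "subjects_within_groups", ss_subj, df_between_err, ms_subj
        ),
        time=_f_effect("time", ss_time, 1.0, ms_werr, df_within_err),
        interaction=_f_effect("group_x_time", ss_int, k - 1, ms_werr, df_within_err),
        within_error=AnovaEffect("within_error", ss_werr, df_within_err, ms_werr),
        type_iii=type_iii,
    )


def anova_from_summaries(
    diff_means: Sequence[float],
    diff_sds: Sequence[float],
    ns: Sequence[int],
    type_iii: bool = True,
) -> SummaryAnovaResult:
    """Time and interaction F from per-group difference-score summaries.

    With two within-subject levels these tests depend only on each group's
    mean, SD and n of (post - pre), so a published summary table is enough.
    With a single group the interaction is undefined and the time F equals
    the squared one-sample t of that group's differences.
    """
    dm = np.asarray(diff_means, dtype=float)
    sd = np.asarray(diff_sds, dtype=float)
    ns_arr = np.asarray(ns, dtype=float)
    if not (dm.size == sd.size == ns_arr.size):
        raise ValidationError("diff_means, diff_sds and ns must have equal length")
    if dm.size == 0:
        raise ValidationError("at least one group is required")
    if np.any(ns_arr < 2):
        raise ValidationError("every group needs n >= 2")
    k = dm.size
    n_total = float(ns_arr.sum())
    df_err = n_total - k
    ms_err = float(((ns_arr - 1) * sd**2).sum()) / df_err / 2.0

    if type_iii:
        n_eff = k / float((1.0 / ns_arr).sum())
        grand = float(dm.mean())
        ss_time = k * n_eff * grand**2 / 2.0
        ss_int = n_eff * float(((dm - grand) ** 2).sum()) / 2.0
    else:
        grand = float((ns_arr * dm).sum() / n_total)
        ss_time = n_total * grand**2 / 2.0
        ss_int = float((ns_arr * (dm - grand) ** 2).sum()) / 2.0

    def _f(ss: float, df: float) -> tuple[float, float]:
        if ms_err == 0.0:
            return (0.0 if ss == 0.0 else math.inf, 1.0 if ss == 0.0 else 0.0)
        f = (ss / df) / ms_err
        return (f, float(sps.f.sf(f, df, df_err)))

    time_f, time_p = _f(ss_time, 1.0)
    if k == 1:
        return SummaryAnovaResult(
            time_f=time_f,
            time_df=(1.0, df_err),
            time_p=time_p,
            interaction_f=None,
            interaction_df=None,
            interaction_p=None,
            type_iii=type_iii,
        )
    int_f, int_p = _f(ss_int, k - 1.0)
    return SummaryAnovaResult(
        time_f=time_f,
        time_df=(1.0, df_err),
        time_p=time_p,
        interaction_f=int_f,
        interaction_df=(k - 1.0, df_err),
        interaction_p=int_p,
        type_iii=type_iii,
    )


@dataclass(frozen=True)
class TukeyPair:
    label_a: str
    label_b: str
    mean_diff: float
    q: float
    p_adjusted: float


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[TukeyPair, ...]
    mse: float
    df_error: float
    k: int


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    mse: float | None = None,
    df_error: float | None = None,
) -> TukeyResult:
    """Tukey-Kramer all-pairwise comparison of group means.

    q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)); the adjusted p is
    the studentized-range tail probability with k groups and the error df.
    When ``mse``/``df_error`` are not supplied they come from the one-way
    pooled within-group variance of ``groups``.
    """
    if len(groups) < 2:
        raise ValidationError("Tukey's HSD needs at least 2 groups")
    labels = list(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    if mse is None or df_error is None:
        ns = np.array([arrays[g].size for g in labels], dtype=float)
        if np.any(ns < 2):
            raise ValidationError("need n >= 2 per group to estimate the error variance")
        ss_within = sum(float(((x - x.mean()) ** 2).sum()) for x in arrays.values())
        df_error = float(ns.sum()) - len(labels)
        mse = ss_within / df_error
    if mse <= 0:
        raise UndefinedStatisticError(f"Tukey's HSD requires MSE > 0, got {mse}")
    k = len(labels)
    pairs = []
    for a, b in itertools.combinations(labels, 2):
        xa, xb = arrays[a], arrays[b]
        diff = float(xb.mean() - xa.mean())
        se = math.sqrt(mse / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_error))
        pairs.append(TukeyPair(label_a=a, label_b=b, mean_diff=diff, q=q, p_adjusted=min(p, 1.0)))
    return TukeyResult(pairs=tuple(pairs), mse=float(mse), df_error=float(df_error), k=k)


def studentized_range_sf_mc(
    q: float, k: int, df: float, n_draws: int = 1_000_000, seed: int = 0
) -> float:
    """Monte-Carlo estimate of the studentized-range tail probability.

    Simulates the range of k standard-normal means over an independent
    chi-distributed scale with ``df`` degrees of freedom. Used to validate
    the closed-form adjusted p, not as the production path.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))
    ranges = z.max(axis=1) - z.min(axis=1)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    return float((ranges / s > q).mean())
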