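"""Cohort analysis orchestration and report rendering.

``run_analysis`` chains the full pipeline — score, stratify, summarise,
test, size effects, split-plot ANOVA, Tukey follow-up, responder counts —
into one :class:`AnalysisReport`. It computes nothing of its own: every
number comes from the module that owns it, so a report can always be
cross-checked operation by operation.

Inferential blocks degrade gracefully: a stratum with one subject keeps its
listing but its paired test is marked not-computable, and a single-stratum
cohort skips ANOVA, Tukey and the between-group tests while still emitting
summaries.

All rounding lives in the rendering layer (`render_report`): distances to
whole metres, d to 2 decimals, percentages to 1 decimal, p-values printed
as "<0.0001" below that threshold. Statistical code never rounds.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .anova import AnovaResult, TukeyResult, split_plot_anova, tukey_hsd
from .errors import ValidationError
from .io import Subject
from .panel import Panel
from .scoring import STRATA, TgsResult, score_subjects
from .stats import (
    EffectSize,
    GroupSummary,
    TTestResult,
    bonferroni_alpha,
    cohen_d_independent,
    cohen_d_prepost,
    group_summary,
    independent_t,
    mean_individual_percent_improvement,
    paired_t,
    percent_improvement_of_means,
    responder_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisOptions", "AnalysisReport", "run_analysis", "render_report"]

SMALL_STRATUM_N = 10


@dataclass(frozen=True)
class AnalysisOptions:
    conf_level: float = 0.90
    alpha: float = 0.05
    thresholds: tuple[float, ...] = (120.0, 500.0)
    anova_type_iii: bool = True
    welch: bool = False
    allow_missing_genotypes: bool = False


@dataclass(frozen=True)
class SubjectImprovement:
    subject_id: str
    stratum: str
    improvement: float
    percent_improvement: float | None


@dataclass(frozen=True)
class AnalysisReport:
    """Everything the pipeline computes for one cohort."""

    options: AnalysisOptions
    n_total: int
    strata_n: Mapping[str, int]
    tgs: tuple[TgsResult, ...]
    summaries: Mapping[str, Mapping[str, GroupSummary]]  # label -> period -> summary
    paired_tests: Mapping[str, TTestResult]
    between_tests: Mapping[str, TTestResult]
    alpha_adjusted: float
    n_tests: int
    within_effects: Mapping[str, EffectSize]
    between_effects: Mapping[str, EffectSize]
    anova: AnovaResult | None
    tukey: TukeyResult | None
    responders: Mapping[str, Mapping[float, int]]
    percent_of_means: Mapping[str, float]
    mean_individual_percent: Mapping[str, float]
    per_subject: tuple[SubjectImprovement, ...]
    not_computable: tuple[str, ...] = field(default_factory=tuple)


def run_analysis(
    subjects: Sequence[Subject], panel: Panel, options: AnalysisOptions | None = None
) -> AnalysisReport:
    """Score a cohort and compute the full stratified pre/post analysis."""
    options = options or AnalysisOptions()
    if not subjects:
        raise ValidationError("cannot analyse an empty cohort")

    tgs = score_subjects(subjects, panel, allow_missing=options.allow_missing_genotypes)
    stratum_of = {r.subject_id: r.stratum for r in tgs}
    by_stratum: dict[str, list[Subject]] = {
        s: [subj for subj in subjects if stratum_of[subj.id] == s] for s in STRATA
    }
    occupied = [s for s in STRATA if by_stratum[s]]
    strata_n = {s: len(by_stratum[s]) for s in occupied}
    logger.info(
        "cohort n=%d; strata %s; conventions: %s t-test, %s ANOVA, conf %.2f",
        len(subjects),
        ", ".join(f"{s}={n}" for s, n in strata_n.items()),
        "Welch" if options.welch else "pooled-variance",
        "Type III (unweighted means)" if options.anova_type_iii else "weighted",
        options.conf_level,
    )
    for s, n in strata_n.items():
        if n < SMALL_STRATUM_N:
            logger.warning("stratum %r has only n=%d subjects; interpret with caution", s, n)

    not_computable: list[str] = []

    def _periods(label: str, members: Sequence[Subject]) -> dict[str, GroupSummary] | None:
        if len(members) < 2:
            not_computable.append(f"summaries[{label}] (n < 2)")
            return None
        return {
            "pre": group_summary([m.pre_yoyo for m in members], options.conf_level, label),
            "post": group_summary([m.post_yoyo for m in members], options.conf_level, label),
            "improvement": group_summary(
                [m.improvement for m in members], options.conf_level, label
            ),
        }

    summaries: dict[str, dict[str, GroupSummary]] = {}
    for label in occupied:
        block = _periods(label, by_stratum[label])
        if block is not None:
            summaries[label] = block
    all_block = _periods("all", subjects)
    if all_block is not None:
        summaries["all"] = all_block

    # Six follow-up tests by design: 3 paired within-stratum + 3 unpaired
    # between-stratum comparisons of the improvements, alpha shared across them.
    n_tests = len(STRATA) + len(list(itertools.combinations(STRATA, 2)))
    alpha_adjusted = bonferroni_alpha(options.alpha, n_tests)

    paired_tests: dict[str, TTestResult] = {}
    within_effects: dict[str, EffectSize] = {}
    for label in occupied:
        members = by_stratum[label]
        if len(members) < 2:
            not_computable.append(f"paired_t[{label}] (n < 2)")
            continue
        paired_tests[label] = paired_t(
            [m.pre_yoyo for m in members], [m.post_yoyo for m in members], alpha_adjusted
        )
        s = summaries[label]
        try:
            within_effects[label] = cohen_d_prepost(
                s["pre"].mean, s["pre"].sd, s["post"].mean, s["post"].sd
            )
        except Exception:
            not_computable.append(f"within_effect[{label}] (zero variance)")

    between_tests: dict[str, TTestResult] = {}
    between_effects: dict[str, EffectSize] = {}
    for a, b in itertools.combinations(occupied, 2):
        key = f"{a}_vs_{b}"
        ga, gb = by_stratum[a], by_stratum[b]
        if len(ga) < 2 or len(gb) < 2:
            not_computable.append(f"between[{key}] (n < 2)")
            continue
        between_tests[key] = independent_t(
            [m.improvement for m in ga],
            [m.improvement for m in gb],
            alpha_adjusted,
            welch=options.welch,
        )
        sa, sb = summaries[a]["improvement"], summaries[b]["improvement"]
        try:
            between_effects[key] = cohen_d_independent(sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n)
        except Exception:
            not_computable.append(f"between_effect[{key}] (zero pooled variance)")

    anova = tukey = None
    anova_groups = {
        s: [(m.pre_yoyo, m.post_yoyo) for m in by_stratum[s]]
        for s in occupied
        if len(by_stratum[s]) >= 2
    }
    if len(anova_groups) >= 2:
        anova = split_plot_anova(anova_groups, type_iii=options.anova_type_iii)
        # Follow up the Group main effect: Tukey-Kramer on subject mean scores
        # against the between-subjects error of the split-plot model.
        subject_means = {
            s: [(m.pre_yoyo + m.post_yoyo) / 2.0 for m in by_stratum[s]] for s in anova_groups
        }
        try:
            tukey = tukey_hsd(
                subject_means,
                mse=anova.subjects_within_groups.ms / 2.0,
                df_error=anova.subjects_within_groups.df,
            )
        except Exception:
            not_computable.append("tukey (degenerate between-subjects variance)")
    else:
        not_computable.append("anova (need >= 2 strata with n >= 2)")
        not_computable.append("tukey (need >= 2 strata with n >= 2)")

    responders = {
        label: responder_counts([m.improvement for m in by_stratum[label]], options.thresholds)
        for label in occupied
    }
    responders["all"] = responder_counts([m.improvement for m in subjects], options.thresholds)

    percent_of_means: dict[str, float] = {}
    mean_individual: dict[str, float] = {}
    for label, members in [*((s, by_stratum[s]) for s in occupied), ("all", list(subjects))]:
        pre_values = [m.pre_yoyo for m in members]
        if len(members) >= 1 and sum(pre_values) > 0:
            mean_pre = sum(pre_values) / len(members)
            mean_impr = sum(m.improvement for m in members) / len(members)
            percent_of_means[label] = percent_improvement_of_means(mean_impr, mean_pre)
        if all(p > 0 for p in pre_values):
            mean_individual[label] = mean_individual_percent_improvement(members)
        else:
            not_computable.append(f"mean_individual_percent[{label}] (pre = 0 present)")

    per_subject = tuple(
        SubjectImprovement(
            subject_id=m.id,
            stratum=stratum_of[m.id],
            improvement=m.improvement,
            percent_improvement=(
                100.0 * m.improvement / m.pre_yoyo if m.pre_yoyo > 0 else None
            ),
        )
        for m in subjects
    )

    return AnalysisReport(
        options=options,
        n_total=len(subjects),
        strata_n=strata_n,
        tgs=tuple(tgs),
        summaries=summaries,
        paired_tests=paired_tests,
        between_tests=between_tests,
        alpha_adjusted=alpha_adjusted,
        n_tests=n_tests,
        within_effects=within_effects,
        between_effects=between_effects,
        anova=anova,
        tukey=tukey,
        responders=responders,
        percent_of_means=percent_of_means,
        mean_individual_percent=mean_individual,
        per_subject=per_subject,
        not_computable=tuple(not_computable),
    )


# ---------------------------------------------------------------- rendering


def _m(x: float) -> str:
    """Distances to whole metres."""
    return f"{x:.0f}"


def _d(x: float) -> str:
    return f"{x:.2f}"


def _pct(x: float) -> str:
    return f"{x:.1f}"


def _p(p: float) -> str:
    if p < 0.0001:
        return "<0.0001"
    return f"{p:.4f}"


def _cell(s: GroupSummary) -> str:
    return f"{_m(s.mean)} ({_m(s.sd)}; {_m(s.ci_low)} to {_m(s.ci_high)})"


def render_report(report: AnalysisReport, format: str = "text") -> str:
    """Render a report as 'text' (summary-table style), 'tsv' or 'json'."""
    if format == "json":
        return _render_json(report)
    if format == "tsv":
        return _render_tsv(report)
    if format == "text":
        return _render_text(report)
    raise ValidationError(f"unknown report format {format!r} (expected text, tsv or json)")


def _group_rows(report: AnalysisReport) -> list[dict[str, str]]:
    rows = []
    for label in report.summaries:
        s = report.summaries[label]
        row = {
            "group": label,
            "n": str(s["pre"].n),
            "pre": _cell(s["pre"]),
            "post": _cell(s["post"]),
            "improvement": _cell(s["improvement"]),
        }
        t = report.paired_tests.get(label)
        row["paired_p"] = _p(t.p) if t else "NA"
        e = report.within_effects.get(label)
        row["d"] = f'{_d(e.d)} "{e.band}"' if e else "NA"
        rows.append(row)
    return rows


def _render_text(report: AnalysisReport) -> str:
    conf = f"{100 * report.options.conf_level:.0f}%"
    lines = [
        f"Pre/post Yo-Yo analysis by TGS stratum (n = {report.n_total})",
        "",
        f"Group summaries [mean (SD; {conf} CI)], paired-test p, within-group d:",
    ]
    header = ["group", "n", "pre (m)", "post (m)", "improvement (m)", "paired p", "Cohen's d"]
    lines.append("  " + " | ".join(header))
    for row in _group_rows(report):
        lines.append(
            "  "
            + " | ".join(
                [
                    row["group"],
                    row["n"],
                    row["pre"],
                    row["post"],
                    row["improvement"],
                    row["paired_p"],
                    row["d"],
                ]
            )
        )
    lines.append("")
    lines.append(
        f"Six follow-up t-tests at Bonferroni-adjusted alpha = "
        f"{report.alpha_adjusted:.3f} ({report.options.alpha}/{report.n_tests})"
    )
    if report.between_tests:
        lines.append("Between-group improvement comparisons (unpaired t):")
        for key, t in report.between_tests.items():
            e = report.between_effects.get(key)
            extra = f', d = {_d(e.d)} "{e.band}"' if e else ""
            sig = "significant" if t.significant else "not significant"
            lines.append(f"  {key}: t = {t.statistic:.2f}, p = {_p(t.p)} ({sig}){extra}")
    if report.anova is not None:
        a = report.anova
        kind = "Type III (unweighted means)" if a.type_iii else "weighted"
        lines.append("")
        lines.append(f"3 x 2 (Group x Time) split-plot ANOVA [{kind}]:")
        for e in a.effects:
            if e.f is None:
                lines.append(f"  {e.name}: SS = {e.ss:.1f}, df = {e.df:.0f}, MS = {e.ms:.1f}")
            else:
                lines.append(
                    f"  {e.name}: F({e.df:.0f}, {a.within_error.df:.0f}) = {e.f:.1f}, p = {_p(e.p)}"
                )
    if report.tukey is not None:
        lines.append("Tukey HSD on subject mean scores (group follow-up):")
        for pair in report.tukey.pairs:
            lines.append(
                f"  {pair.label_a} vs {pair.label_b}: diff = {_m(pair.mean_diff)} m, "
                f"q = {pair.q:.2f}, adjusted p = {_p(pair.p_adjusted)}"
            )
    lines.append("")
    lines.append("Percent improvement:")
    for label in report.percent_of_means:
        parts = [f"ratio of means {_pct(report.percent_of_means[label])}%"]
        if label in report.mean_individual_percent:
            parts.append(f"mean of individual {_pct(report.mean_individual_percent[label])}%")
        lines.append(f"  {label}: " + ", ".join(parts))
    lines.append("Responders (improvement strictly greater than threshold):")
    for label, counts in report.responders.items():
        cells = ", ".join(f">{_m(t)} m: {c}" for t, c in counts.items())
        lines.append(f"  {label}: {cells}")
    lines.append("")
    lines.append("Individual improvements:")
    for item in report.per_subject:
        pct = f" ({_pct(item.percent_improvement)}%)" if item.percent_improvement is not None else ""
        lines.append(f"  {item.subject_id} [{item.stratum}]: {_m(item.improvement)} m{pct}")
    if report.not_computable:
        lines.append("")
        lines.append("Not computable: " + "; ".join(report.not_computable))
    return "\n".join(lines) + "\n"


def _render_tsv(report: AnalysisReport) -> str:
    lines = ["group\tn\tpre\tpost\timprovement\tpaired_p\td"]
    for row in _group_rows(report):
        lines.append(
            "\t".join(
                [
                    row["group"],
                    row["n"],
                    row["pre"],
                    row["post"],
                    row["improvement"],
                    row["paired_p"],
                    row["d"],
                ]
            )
        )
    if report.anova is not None:
        lines.append("")
        lines.append("effect\tSS\tdf\tMS\tF\tp")
        for e in report.anova.effects:
            f = f"{e.f:.4f}" if e.f is not None else ""
            p = _p(e.p) if e.p is not None else ""
            lines.append(f"{e.name}\t{e.ss:.4f}\t{e.df:.0f}\t{e.ms:.4f}\t{f}\t{p}")
    return "\n".join(lines) + "\n"


def _to_jsonable(obj):
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return str(obj)
    return obj


def _render_json(report: AnalysisReport) -> str:
    return json.dumps(_to_jsonable(report), indent=2, sort_keys=True) + "\n"
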