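"""Total genotype score (TGS) and trainability stratification.

The TGS sums per-SNP genotype points and expresses the sum as a percentage
of the panel maximum, so panels with different weight scales are directly
comparable. Subjects are stratified on the percent scale at 40 and 70:
<=40% "low", (40, 70] "medium", >70% "high". The boundaries are half-open on
purpose — the published anchors ("40% or less" low, "41-70%" medium, ">70%"
high) are stated on integers, but weighted percentages need not be integral,
and (40, 70] preserves all three anchors simultaneously.

Percent is carried at full floating precision; round only when reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from .errors import ConfigurationError, ValidationError
from .io import Subject
from .panel import Panel, SnpDefinition, normalize_genotype

__all__ = [
    "TgsResult",
    "score_snp",
    "total_genotype_score",
    "stratify",
    "score_subjects",
    "write_tgs_table",
    "STRATA",
]

STRATA = ("low", "medium", "high")
LOW_MAX_PERCENT = 40.0
MEDIUM_MAX_PERCENT = 70.0


@dataclass(frozen=True)
class TgsResult:
    subject_id: str
    raw_points: float
    percent: float
    stratum: str


def score_snp(genotype: str, snp: SnpDefinition) -> float:
    """Points earned by one genotype at one SNP."""
    g = normalize_genotype(genotype)
    try:
        return snp.genotype_points[g]
    except KeyError:
        raise ValidationError(
            f"{snp.rsid}: genotype {genotype!r} is not one of {sorted(snp.genotype_points)}"
        )


def stratify(percent: float) -> str:
    """Map a TGS percent to its trainability stratum (low / medium / high)."""
    if not 0.0 <= percent <= 100.0:
        raise ValidationError(f"TGS percent must lie in [0, 100], got {percent}")
    if percent <= LOW_MAX_PERCENT:
        return "low"
    if percent <= MEDIUM_MAX_PERCENT:
        return "medium"
    return "high"


def total_genotype_score(
    genotypes: Mapping[str, str],
    panel: Panel,
    subject_id: str = "",
    allow_missing: bool = False,
) -> TgsResult:
    """Weighted TGS for one subject's genotypes.

    In the default strict mode every panel rsid must be genotyped. With
    ``allow_missing=True`` the score is rescaled to the attainable maximum
    over the SNPs actually present (so a subject missing one SNP is scored
    out of the remaining panel), which keeps percent comparable but assumes
    missingness is unrelated to genotype.
    """
    if not panel.snps:
        raise ConfigurationError("cannot score against an empty panel")
    present = [s for s in panel.snps if s.rsid in genotypes]
    if not allow_missing and len(present) != len(panel.snps):
        missing = sorted(set(panel.rsids) - set(genotypes))
        raise ValidationError(
            f"subject {subject_id or '<unknown>'}: missing genotype(s) for {', '.join(missing)}"
        )
    if not present:
        raise ValidationError(f"subject {subject_id or '<unknown>'}: no panel genotypes present")
    raw = sum(score_snp(genotypes[s.rsid], s) for s in present)
    attainable = sum(s.max_points for s in present)
    percent = 100.0 * raw / attainable
    return TgsResult(subject_id=subject_id, raw_points=raw, percent=percent, stratum=stratify(percent))


def score_subjects(
    subjects: Iterable[Subject], panel: Panel, allow_missing: bool = False
) -> list[TgsResult]:
    """Score a cohort, one TgsResult per subject in input order."""
    return [
        total_genotype_score(s.genotypes, panel, subject_id=s.id, allow_missing=allow_missing)
        for s in subjects
    ]


def write_tgs_table(results: Iterable[TgsResult], dest: IO[str]) -> None:
    """Export TGS results as TSV: subject_id, raw_points, percent, stratum."""
    dest.write("subject_id\traw_points\tpercent\tstratum\n")
    for r in results:
        dest.write(f"{r.subject_id}\t{r.raw_points:g}\t{r.percent:.6g}\t{r.stratum}\n")
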