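"""Subject records and their readers/writers.

Subjects arrive either as a delimited table (one row per player: id, one
genotype column per panel rsid, pre/post Yo-Yo distances in metres) or as a
VCF whose records are matched by rsID. Genotypes are unordered allele pairs
normalized to uppercase alphabetical order. Strand handling is deliberately
strict: alleles must be reported on the forward strand as defined by the
panel, and strand-ambiguous SNPs (C/G such as rs2010963 and rs1042714) are
never silently flipped — a base outside the SNP's allele domain is an error.
"""

from __future__ import annotations

import logging
import math
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError
from .panel import Panel, normalize_genotype

logger = logging.getLogger(__name__)

__all__ = ["Subject", "read_subject_table", "write_subject_table", "read_vcf_genotypes"]

#: One Yo-Yo IR1 shuttle is 2 x 20 m; recorded distances are multiples of this.
SHUTTLE_METRES = 40.0


@dataclass(frozen=True)
class Subject:
    """One participant: genotypes plus pre/post Yo-Yo IR1 distance (metres)."""

    id: str
    genotypes: Mapping[str, str]
    pre_yoyo: float
    post_yoyo: float
    age: float | None = None
    height: float | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.pre_yoyo < 0 or self.post_yoyo < 0:
            raise ValidationError(
                f"subject {self.id}: distances must be non-negative "
                f"(pre={self.pre_yoyo}, post={self.post_yoyo})"
            )
        object.__setattr__(
            self, "genotypes", {k: normalize_genotype(v) for k, v in self.genotypes.items()}
        )

    @property
    def improvement(self) -> float:
        """Post minus pre distance in metres (may be negative)."""
        return self.post_yoyo - self.pre_yoyo


_REQUIRED = ("id", "pre_yoyo_m", "post_yoyo_m")


def _validate_genotype(subject_id: str, rsid: str, genotype: str, panel: Panel) -> str:
    g = normalize_genotype(genotype)
    snp = panel.snp(rsid)
    bad = set(g) - snp.alleles
    if bad:
        raise ValidationError(
            f"subject {subject_id}, {rsid}: genotype {genotype!r} contains base(s) "
            f"{sorted(bad)} outside the allele domain {{{snp.other_allele},{snp.effect_allele}}} "
            "(no automatic strand flipping)"
        )
    return g


def read_subject_table(source: str | Path | IO[str], panel: Panel) -> list[Subject]:
    """Read subjects from a CSV/TSV with columns id, <rsids...>, pre_yoyo_m, post_yoyo_m.

    Extra columns are preserved on read but ignored by analysis. Distances
    that are not multiples of the 40 m shuttle quantum trigger a lint
    warning, not an error.
    """
    try:
        frame = pd.read_csv(source, sep=None, engine="python", dtype=str, skipinitialspace=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse subject table: {exc}") from exc

    missing = [c for c in (*_REQUIRED, *panel.rsids) if c not in frame.columns]
    if missing:
        raise FormatError(f"subject table missing required column(s): {', '.join(missing)}")

    subjects: list[Subject] = []
    for _, row in frame.iterrows():
        sid = str(row["id"])
        genotypes = {
            rsid: _validate_genotype(sid, rsid, str(row[rsid]), panel) for rsid in panel.rsids
        }
        distances = {}
        for col in ("pre_yoyo_m", "post_yoyo_m"):
            raw = row[col]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"subject {sid}: non-numeric {col} value {raw!r}")
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"subject {sid}: {col} must be a non-negative number, got {raw!r}")
            if value % SHUTTLE_METRES != 0:
                warnings.warn(
                    f"subject {sid}: {col}={value} is not a multiple of the "
                    f"{SHUTTLE_METRES:.0f} m Yo-Yo shuttle",
                    UserWarning,
                    stacklevel=2,
                )
            distances[col] = value

        def _opt(col: str) -> float | None:
            if col in frame.columns and pd.notna(row[col]) and str(row[col]).strip():
                return float(row[col])
            return None

        subjects.append(
            Subject(
                id=sid,
                genotypes=genotypes,
                pre_yoyo=distances["pre_yoyo_m"],
                post_yoyo=distances["post_yoyo_m"],
                age=_opt("age"),
                height=_opt("height_cm"),
                mass=_opt("mass_kg"),
            )
        )
    return subjects


def write_subject_table(subjects: Iterable[Subject], dest: str | Path | IO[str], panel: Panel) -> None:
    """Write subjects in the same CSV layout read_subject_table consumes."""
    rows = []
    for s in subjects:
        row: dict[str, object] = {"id": s.id}
        for rsid in panel.rsids:
            row[rsid] = s.genotypes[rsid]
        row["pre_yoyo_m"] = s.pre_yoyo
        row["post_yoyo_m"] = s.post_yoyo
        if s.age is not None:
            row["age"] = s.age
        if s.height is not None:
            row["height_cm"] = s.height
        if s.mass is not None:
            row["mass_kg"] = s.mass
        rows.append(row)
    pd.DataFrame(rows).to_csv(dest, index=False)


def read_vcf_genotypes(source: str | Path | IO[str], panel: Panel) -> dict[str, dict[str, str]]:
    """Extract panel genotypes per sample from a VCF, matching on the ID field.

    Returns ``{sample_id: {rsid: allele_pair}}``. Records whose ID is not a
    panel rsid are ignored; a missing GT (``./.``) leaves that rsid absent
    for the sample. Panel rsids with no decodable genotype are reported per
    sample at info level. Alleles are taken as written (forward strand); a
    record whose REF/ALT set is not a subset of the SNP's allele domain is
    rejected.
    """
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    if isinstance(source, (str, Path)):
        return _read_vcf_path(str(source), panel)
    with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as tmp:
        tmp.write(source.read())
        path = tmp.name
    try:
        return _read_vcf_path(path, panel)
    finally:
        Path(path).unlink(missing_ok=True)


def _read_vcf_path(path: str, panel: Panel) -> dict[str, dict[str, str]]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    out: dict[str, dict[str, str]] = {s: {} for s in samples}
    wanted = set(panel.rsids)
    for variant in vcf:
        rsid = variant.ID
        if rsid not in wanted:
            continue
        snp = panel.snp(rsid)
        alleles = [variant.REF, *variant.ALT]
        bad = {a for a in alleles if a not in snp.alleles}
        if bad:
            raise ValidationError(
                f"{rsid}: VCF alleles {alleles} are not a subset of the panel domain "
                f"{{{snp.other_allele},{snp.effect_allele}}}"
            )
        for sample, gt in zip(samples, variant.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:  # ./. or half-missing
                continue
            out[sample][rsid] = normalize_genotype(alleles[a1] + alleles[a2])
    for sample in samples:
        unmatched = sorted(wanted - set(out[sample]))
        if unmatched:
            logger.info("sample %s: no genotype for panel rsid(s) %s", sample, ", ".join(unmatched))
    return out
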