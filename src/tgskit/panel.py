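"""SNP panel definitions and weight-table configuration.

A panel is an ordered set of SNPs, each carrying a per-genotype point map
(0-4 points for 0/1/2 copies of the effect allele). The shipped default is
the five-SNP aerobic-trainability panel (VEGF rs2010963, ADRB2 rs1042713 and
rs1042714, CRP rs1205, PPARGC1A rs8192678) with a 0/2/4 scheme per SNP; the
commercial per-allele weights behind the original algorithm are unpublished,
so every weight here is an overridable default, not an established fact.

Effect-allele defaults: rs2010963->C (the expression-increasing VEGF allele)
and rs8192678->G (higher post-training VO2max) are well supported; the
rs1042713->G, rs1042714->G and rs1205->C choices are configurable
assumptions drawn from the association literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import yaml

from .errors import ConfigurationError

VALID_BASES = frozenset("ACGT")

__all__ = [
    "SnpDefinition",
    "Panel",
    "default_panel",
    "load_weight_config",
    "normalize_genotype",
    "DEFAULT_POINTS_BY_COPIES",
]

#: Default points for 0 / 1 / 2 copies of the effect allele.
DEFAULT_POINTS_BY_COPIES: tuple[float, float, float] = (0.0, 2.0, 4.0)


def normalize_genotype(genotype: str) -> str:
    """Return the canonical (uppercased, alphabetically sorted) allele pair.

    ``"gc"`` and ``"CG"`` both normalize to ``"CG"``; genotypes are unordered.
    """
    g = genotype.strip().upper()
    if len(g) != 2:
        raise ConfigurationError(f"genotype must be two bases, got {genotype!r}")
    return "".join(sorted(g))


@dataclass(frozen=True)
class SnpDefinition:
    """One scored SNP: identity, allele domain, and per-genotype points.

    ``genotype_points`` maps the three normalized genotypes (other/other,
    other/effect, effect/effect) to points in [0, 4], non-decreasing in the
    number of effect alleles.
    """

    rsid: str
    gene: str
    effect_allele: str
    other_allele: str
    genotype_points: Mapping[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        eff, oth = self.effect_allele, self.other_allele
        if eff not in VALID_BASES or oth not in VALID_BASES:
            raise ConfigurationError(
                f"{self.rsid}: alleles must be single bases in A/C/G/T, got {eff!r}/{oth!r}"
            )
        if eff == oth:
            raise ConfigurationError(f"{self.rsid}: effect and other allele are identical")
        if self.genotype_points is None:
            object.__setattr__(
                self, "genotype_points", self.points_from_copies(DEFAULT_POINTS_BY_COPIES)
            )
        else:
            pts = {normalize_genotype(k): float(v) for k, v in self.genotype_points.items()}
            object.__setattr__(self, "genotype_points", pts)
        expected = {self.genotype_for_copies(c) for c in (0, 1, 2)}
        if set(self.genotype_points) != expected:
            raise ConfigurationError(
                f"{self.rsid}: genotype_points keys {sorted(self.genotype_points)} "
                f"!= expected {sorted(expected)}"
            )
        by_copies = [self.genotype_points[self.genotype_for_copies(c)] for c in (0, 1, 2)]
        if any(not (0.0 <= p <= 4.0) for p in by_copies):
            raise ConfigurationError(f"{self.rsid}: points must lie in [0, 4], got {by_copies}")
        if not (by_copies[0] <= by_copies[1] <= by_copies[2]):
            raise ConfigurationError(
                f"{self.rsid}: points must be non-decreasing in effect-allele count, got {by_copies}"
            )

    def genotype_for_copies(self, copies: int) -> str:
        """Normalized genotype string for 0, 1 or 2 effect-allele copies."""
        alleles = [self.effect_allele] * copies + [self.other_allele] * (2 - copies)
        return "".join(sorted(alleles))

    def points_from_copies(self, points: Sequence[float]) -> dict[str, float]:
        """Build a genotype_points map from (p0, p1, p2) per effect-allele count."""
        if len(points) != 3:
            raise ConfigurationError(f"{self.rsid}: need exactly three point values")
        return {self.genotype_for_copies(c): float(points[c]) for c in (0, 1, 2)}

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def max_points(self) -> float:
        return max(self.genotype_points.values())


@dataclass(frozen=True)
class Panel:
    """An ordered SNP panel with a positive attainable maximum score."""

    snps: tuple[SnpDefinition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ConfigurationError(f"duplicate rsid(s) in panel: {dupes}")
        if not self.snps:
            raise ConfigurationError("panel must contain at least one SNP")
        if self.max_points <= 0:
            raise ConfigurationError("panel max_points must be > 0")

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    @property
    def max_points(self) -> float:
        return sum(s.max_points for s in self.snps)

    def snp(self, rsid: str) -> SnpDefinition:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)


_DEFAULT_SNPS = (
    ("rs2010963", "VEGF", "C", "G"),
    ("rs1042713", "ADRB2", "G", "A"),
    ("rs1042714", "ADRB2", "G", "C"),
    ("rs1205", "CRP", "C", "T"),
    ("rs8192678", "PPARGC1A", "G", "A"),
)


def default_panel() -> Panel:
    """The five-SNP aerobic-trainability panel with the 0/2/4 default weights."""
    return Panel(
        snps=tuple(
            SnpDefinition(rsid=r, gene=g, effect_allele=e, other_allele=o)
            for r, g, e, o in _DEFAULT_SNPS
        )
    )


def load_weight_config(source: str | Path | IO[str]) -> Panel:
    """Build a :class:`Panel` from a JSON or YAML weight-table config.

    The config maps each rsid to gene, effect_allele, other_allele and an
    optional ``points`` triple for 0/1/2 effect-allele copies (default 0/2/4).
    Accepts either ``{"snps": [...]}`` or a bare list of SNP entries.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    try:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse weight config: {exc}") from exc
    if isinstance(data, Mapping) and "snps" in data:
        entries = data["snps"]
    elif isinstance(data, list):
        entries = data
    else:
        raise ConfigurationError("weight config must be a list of SNPs or a {'snps': [...]} map")

    snps = []
    seen: set[str] = set()
    for entry in entries:
        try:
            rsid = entry["rsid"]
        except (TypeError, KeyError):
            raise ConfigurationError(f"SNP entry missing 'rsid': {entry!r}")
        if rsid in seen:
            raise ConfigurationError(f"duplicate rsid in weight config: {rsid}")
        seen.add(rsid)
        points = [float(p) for p in entry.get("points", DEFAULT_POINTS_BY_COPIES)]
        if len(points) != 3:
            raise ConfigurationError(f"{rsid}: 'points' must be three values (0/1/2 copies)")
        eff, oth = entry["effect_allele"], entry["other_allele"]
        genotype_points = {
            "".join(sorted([eff] * c + [oth] * (2 - c))): points[c] for c in (0, 1, 2)
        }
        snps.append(
            SnpDefinition(
                rsid=rsid,
                gene=entry.get("gene", ""),
                effect_allele=eff,
                other_allele=oth,
                genotype_points=genotype_points,
            )
        )
    return Panel(snps=tuple(snps))


def panel_to_config(panel: Panel) -> str:
    """Serialize a panel back to its JSON weight-table form."""
    entries = []
    for s in panel.snps:
        entries.append(
            {
                "rsid": s.rsid,
                "gene": s.gene,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele,
                "points": [s.genotype_points[s.genotype_for_copies(c)] for c in (0, 1, 2)],
            }
        )
    return json.dumps({"snps": entries}, indent=2)
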