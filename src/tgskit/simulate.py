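"""Synthetic cohorts with the study's statistical structure.

Genotypes are drawn per SNP under Hardy-Weinberg equilibrium (genotype
probabilities p^2 / 2p(1-p) / (1-p)^2 for 2/1/0 effect-allele copies),
independently across SNPs and subjects (no linkage disequilibrium).
Baseline Yo-Yo distance is Normal(baseline_mean, baseline_sd) floored at
0 m, and the training response is linear in the TGS percent:

    improvement = intercept + slope * percent + Normal(0, noise_sd)

with post = max(0, pre + improvement); negative responses are allowed, as
observed cohorts contain them. The linear-response model is the simplest one
consistent with monotonically increasing stratum-mean improvements.

Default calibration (invented, chosen to echo the scale of a 42-player
youth-soccer cohort): baseline 1015 +/- 450 m; intercept -335 m, slope
11.5 m per TGS percent, noise SD 225 m; effect-allele frequency 0.65 per
SNP, which under the 0/2/4 weights puts ~64% of subjects in the medium
stratum (the calibration anchor: roughly 60% of scores between 40-70%) and
skews the remainder toward the high stratum. Optional 40 m shuttle
quantization is off by default so statistical oracles see continuous data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import statsmodels.api as sm

from .errors import ConfigurationError, ValidationError
from .io import Subject
from .panel import Panel, default_panel
from .scoring import total_genotype_score

__all__ = [
    "SimulationConfig",
    "default_simulation_config",
    "simulate_genotypes",
    "simulate_cohort",
    "recover_response_slope",
]

DEFAULT_EFFECT_ALLELE_FREQ = 0.65


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the cohort generator; identical config + seed give
    bitwise-identical cohorts."""

    seed: int = 0
    n_subjects: int = 42
    panel: Panel = field(default_factory=default_panel)
    effect_allele_freqs: Mapping[str, float] | None = None
    baseline_mean: float = 1015.0
    baseline_sd: float = 450.0
    response_intercept: float = -335.0
    response_slope: float = 11.5
    response_noise_sd: float = 225.0
    round_to_shuttle: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.baseline_sd < 0 or self.response_noise_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        freqs = dict(self.effect_allele_freqs or {})
        if not freqs:
            freqs = {rsid: DEFAULT_EFFECT_ALLELE_FREQ for rsid in self.panel.rsids}
        for rsid, p in freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{rsid}: allele frequency {p} outside [0, 1]")
        object.__setattr__(self, "effect_allele_freqs", freqs)


def default_simulation_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The shipped calibration, optionally overridden field-by-field."""
    return replace(SimulationConfig(seed=seed), **overrides) if overrides else SimulationConfig(seed=seed)


def simulate_genotypes(config: SimulationConfig) -> dict[str, dict[str, str]]:
    """Draw HWE genotypes for every subject and panel SNP.

    Effect-allele copies per subject/SNP are Binomial(2, p), equivalent to
    the p^2 / 2p(1-p) / (1-p)^2 genotype law.
    """
    missing = [r for r in config.panel.rsids if r not in config.effect_allele_freqs]
    if missing:
        raise ConfigurationError(f"no allele frequency for panel rsid(s): {', '.join(missing)}")
    rng = np.random.default_rng(config.seed)
    out: dict[str, dict[str, str]] = {}
    copies_by_snp = {
        snp.rsid: rng.binomial(2, config.effect_allele_freqs[snp.rsid], size=config.n_subjects)
        for snp in config.panel.snps
    }
    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        out[sid] = {
            snp.rsid: snp.genotype_for_copies(int(copies_by_snp[snp.rsid][i]))
            for snp in config.panel.snps
        }
    return out


def simulate_cohort(config: SimulationConfig) -> list[Subject]:
    """Generate a full cohort: genotypes, baseline and post-training distances."""
    genotypes = simulate_genotypes(config)
    # Separate stream so the genotype draw and the response draw stay
    # reproducible independently of each other.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_subjects
    baseline = np.maximum(0.0, rng.normal(config.baseline_mean, config.baseline_sd, size=n))
    noise = rng.normal(0.0, config.response_noise_sd, size=n) if config.response_noise_sd > 0 else np.zeros(n)
    subjects = []
    for i, (sid, gts) in enumerate(genotypes.items()):
        percent = total_genotype_score(gts, config.panel, subject_id=sid).percent
        improvement = config.response_intercept + config.response_slope * percent + noise[i]
        pre = float(baseline[i])
        post = max(0.0, pre + improvement)
        if config.round_to_shuttle:
            pre = round(pre / 40.0) * 40.0
            post = round(post / 40.0) * 40.0
        subjects.append(Subject(id=sid, genotypes=gts, pre_yoyo=pre, post_yoyo=post))
    return subjects


def recover_response_slope(subjects: list[Subject], panel: Panel) -> tuple[float, float]:
    """OLS estimate (and SE) of the improvement-per-TGS-percent slope.

    The parameter-recovery harness for the generator: regress each subject's
    improvement on their TGS percent and return (slope, standard error).
    """
    if len(subjects) < 3:
        raise ValidationError("slope recovery needs at least 3 subjects")
    percent = np.array(
        [total_genotype_score(s.genotypes, panel, subject_id=s.id).percent for s in subjects]
    )
    if np.ptp(percent) == 0.0:
        raise ValidationError("TGS percent has zero variance; slope is unidentifiable")
    improvement = np.array([s.improvement for s in subjects])
    model = sm.OLS(improvement, sm.add_constant(percent)).fit()
    return float(model.params[1]), float(model.bse[1])
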