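# Methods

## The total genotype score

Each panel SNP assigns points to its three genotypes, non-decreasing in the
number of effect-allele copies and bounded by [0, 4]. The TGS is the point
sum rescaled to percent of the panel maximum, so scores are comparable
across weight schemes; stratification cuts the percent scale at 40 and 70.

**Weights.** The commercial algorithm this score family descends from does
not publish its per-allele weights. The shipped default is 0/2/4 points per
SNP for 0/1/2 effect-allele copies — the simplest additive scheme spanning
the stated 0–4 range — and every weight can be overridden through a
JSON/YAML weight table (`load_weight_config`). Results that depend on the
exact weights (an individual's percent, stratum membership near a boundary)
should therefore be read as properties of the configured scheme, not of the
athletes.

**Effect alleles.** rs2010963→C (higher VEGF expression) and rs8192678→G
(higher post-training VO2max) are well supported; rs1042713→G, rs1042714→G
and rs1205→C are defaults drawn from the association literature and are
flagged as assumptions — override them in the panel config if your evidence
differs.

**Boundaries.** The strata are published as integer anchors ("40% or
less", "41–70%", ">70%"), but weighted percentages are generally not
integers. The implementation uses half-open intervals (40, 70]: ≤ 40 low,
> 70 high, medium otherwise, which preserves all three anchors
simultaneously. Percent is carried at full precision and rounded only at
report time.

**Missing genotypes** are a hard error by default. The permissive mode
rescales the denominator to the attainable maximum over the SNPs present;
this keeps percent on a 0–100 scale but silently assumes missingness is
independent of genotype, which is why it is opt-in.

**Strand policy.** Two panel SNPs (rs2010963, rs1042714) are C/G and hence
strand-ambiguous: a flipped report is undetectable after the fact. The
readers therefore never flip strands — any base outside a SNP's declared
allele domain is a validation error, for tables and VCFs alike.

## Statistical conventions

* **Confidence intervals** are central two-sided *t* intervals,
  mean ± t₍(1+γ)/2, n−1₎ · s/√n, default γ = 0.90. The summary-statistic
  entry point (`ci_mean_t`) takes printed mean/SD/n directly so published
  tables can be re-analysed without raw data.
* **Unpaired tests** default to Student's pooled-variance form with
  df = n₁+n₂−2. This matches the pooled-SD convention of the between-group
  effect sizes; Welch is available behind a flag for unequal variances.
* **Paired tests** are one-sample *t* on post−pre. Zero-variance
  differences are reported with a `degenerate_variance` flag (statistic 0 /
  p 1 when the mean difference is also zero; unbounded statistic / p 0
  otherwise) rather than NaN.
* **Within-group Cohen's d** divides the mean change by
  √((s_pre² + s_post²)/2), the RMS of the two time-point SDs — the unique
  simple convention computable from a pre/post summary table; with equal
  SDs it reduces to Δmean/s. **Between-group d** uses the (n−1)-weighted
  pooled SD and is reported as a magnitude.
* **Effect-size bands** are printed in the literature with gaps (e.g.
  "<0.2", "0.21–0.5"); implemented as contiguous half-open intervals on |d|
  at 0.2/0.5/0.8/1.2/2.0 (2.0 itself is "very large"), so every finite d
  gets exactly one label.
* **Multiplicity.** The canonical design runs six follow-up tests (three
  paired within-stratum, three unpaired between-stratum) at α/6; with
  α = 0.05 the threshold prints as 0.008 at three decimals.
* **Percent improvement** exists in two inequivalent conventions — the
  group mean improvement over the group mean baseline, and the mean of
  per-subject percentages. Both are implemented and labelled; they differ
  whenever low-baseline subjects improve proportionally more, so a single
  "percent improvement" number without its convention is ambiguous.
* **Responder counts** are strict: an improvement exactly at a threshold
  does not count. Defaults are 120 m (approximately the test-retest noise
  of the Yo-Yo IR1) and 500 m.

## The split-plot ANOVA

With exactly two within-subject levels the design decomposes exactly into
per-subject difference scores (time, interaction, within-subject error) and
per-subject means (group, subjects-within-groups): no sphericity correction
is needed or implemented, and two time points is a contract, not a
limitation to lift.

For unbalanced strata the default is the unweighted-means (Type III)
analysis: effects are built from the plain average of group means with the
harmonic mean of group sizes as effective n, which is what mainstream GLM
software reports for unbalanced mixed designs; a sums-over-observations
(weighted) variant sits behind a flag. The two coincide on balanced
designs (asserted to 1e-8 against an explicit design-matrix least-squares
oracle). `anova_from_summaries` recomputes the time and interaction tests
from per-group difference-score summaries alone; the group main effect is
not recoverable that way (it needs the pre/post correlations) and is
flagged partial.

Tukey follow-up uses the Kramer form for unequal n,
q = |Δmean| / √(MSE/2 · (1/nᵢ + 1/nⱼ)), with adjusted p from scipy's
studentized-range distribution; a seeded Monte-Carlo simulator of the range
of k normal means over a chi scale is included for validation. In the full
pipeline the HSD follows up the Group main effect on subject mean scores
against the between-subjects error.

## The synthetic cohort generator

The generator emulates the structure of a stratified training study:
genotypes per SNP under Hardy–Weinberg equilibrium (independent across SNPs
— no linkage disequilibrium), baseline Normal(1015, 450) m floored at 0,
and a response linear in TGS percent,

```
improvement = −335 + 11.5 · TGS% + Normal(0, 225) m,
```

with post = max(0, pre + improvement). Negative responses are allowed
(observed cohorts contain them); optional 40 m shuttle quantization is off
by default so statistical oracles see continuous data. The response
defaults are invented back-of-envelope fits chosen so that stratum-mean
improvements land on the scale of a real youth-soccer cohort (tens of
metres for low, several hundred for high); they are calibration constants,
not estimates.

The default effect-allele frequency is 0.65 per SNP. Under the 0/2/4
weights the raw score is 2·Binomial(10, 0.65), which puts ~64% of subjects
in the medium stratum — consistent with the design expectation that roughly
60% of scores fall between 40 and 70% — and skews the remainder toward the
high stratum, as observed stratifications do. Frequencies are config, not
code.

What the generator does *not* model: linkage disequilibrium, genotyping
error, age/maturation covariates, test-retest measurement error beyond the
single Gaussian noise term, or any nonlinearity in the genotype–response
relationship. Passing tests on synthetic cohorts therefore demonstrate that
the statistical machinery is correct under the stated model, not that the
linear TGS-response model is true of athletes.

Determinism: one integer seed fixes the whole cohort; genotype and response
draws use separate child streams of that seed so each is reproducible
independently.

## Problem sizes used in the test suite

Distribution-level properties use the smallest sizes at which their
tolerances are meaningful multiples of sampling error: HWE goodness-of-fit
and stratum-calibration checks at n = 20 000 subjects; CI coverage over
2 000 simulated samples (±0.02 band ≈ 3σ); slope recovery over 200
replicates of n = 2 000 (≥ 93% of estimates within 2 SE); Tukey's adjusted
p against 4×10⁶ Monte-Carlo draws at a 5×10⁻⁴ band (> 4σ of the MC error).

## Known limitations

* The five-SNP panel explains a small slice of trainability; the score
  stratifies expected response, it does not predict absolute performance —
  the published low/medium/high baselines are statistically
  indistinguishable, and this package makes no talent-identification
  claims.
* Reproduction from printed summaries inherits their rounding: one
  published CI endpoint (low-stratum pre-training upper bound) differs by
  1 m from what the rounded mean/SD imply, and the interaction and group F
  statistics and the mean-of-individual percentages require the raw
  per-subject data, which is not redistributed here.
* The analysis offers no nonparametric alternatives, equivalence testing
  or baseline-adjusted ANCOVA; the implemented toolbox mirrors the
  pre/post field-test literature it serves.
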