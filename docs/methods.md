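# Methods

This note records the statistical model behind `polyres`, the simulator's
generative assumptions, the defaults and why they were chosen, and what the
package's passing tests do and do not establish about real data.

## The resilience design

The design treats resilience as heritable variation that lowers the
penetrance of polygenic risk, orthogonal to risk itself. It is a
conditional contrast: among subjects whose polygenic risk score (PRS) is in
the upper tail of the control distribution, unaffected status is the
outcome and the genome outside risk-associated regions is the predictor
space. Three choices define the contrast:

* **Threshold.** Resilient controls are controls with standardized PRS at
  or above the control 90th percentile (`pct = 90`, configurable). The
  quantile uses linear interpolation between order statistics — the default
  convention of the major statistics environments; the threshold itself and
  both ends of the matched-case window are inclusive so ties land
  deterministically. Cases above the control maximum have no matching
  controls and are excluded as ultra-high-risk.
* **Orthogonality.** Any variant with risk-meta p < 0.05, or with
  r² > 0.2 to such a variant within 1 Mb, is removed before resilience
  scoring, together with MHC (chr6:25–34 Mb) and chr8-inversion
  (chr8:7–14 Mb) markers, INFO < 0.9, strand-ambiguous/indel markers,
  MAF < 0.05 and markers supported by 10 or fewer studies. Removals are
  attributed to the first rule that fires, in that fixed order, so filter
  reports always reconcile: removed + surviving = input.
* **Two-model variance attribution.** For each p-value bin, Nagelkerke's
  pseudo-R² of logistic(resilient ~ score + PCs) minus that of
  logistic(resilient ~ PCs) isolates the score's contribution. The
  observed-scale ΔR² is converted to the liability scale with the standard
  ascertainment correction R²_liab = R²_obs · K²(1−K)² / (z²·P(1−P)),
  where K is the population prevalence of resilience (0.10, matching the
  90th-percentile definition), P the proportion of resilient controls in
  the analyzed sample, and z the standard-normal density at Φ⁻¹(1−K).
  The choice of P as the analyzed-sample proportion is an assumption (the
  alternative — a fixed design proportion — is configurable through the
  function arguments).

Per-study GWAS are plain additive-dosage logistic regressions with Wald
tests; covariate principal components are screened by a Welch two-sample
t-test between resilient controls and matched cases (p < 0.1 in discovery,
p < 0.05 in replication). Welch's test is one defensible reading of
"significantly different PCs"; a univariate logistic screen would be the
obvious alternative. Meta-analysis is inverse-variance fixed-effect with
allele harmonization (sign flips for swapped alleles, complementing for
unambiguous strand flips, drop-with-record for irreconcilable pairs);
heterogeneity is summarized only by the per-variant study count.

## The simulator

`simulate_multistudy` draws genotypes haplotype-wise from a Gaussian copula:
within an LD block of `block_size` markers, each haplotype's latent vector
is √ρ·(shared factor) + √(1−ρ)·noise, thresholded at Φ⁻¹(p_j). Summing two
independent haplotypes gives Hardy–Weinberg marginals at exactly the target
frequency and exchangeable within-block LD (dosage r² ≈ 0.5–0.7 at
ρ = 0.85), which is all that the clumping and LD-exclusion machinery needs.
This is deliberately not a coalescent simulation: there is no recombination
gradient, no allele-frequency spectrum, and no population structure beyond
per-study frequency jitter (σ = 0.01), so the principal components computed
from these genotypes carry no real confounding — the PC machinery is
exercised, not stressed.

Phenotypes follow

    logit P(case) = α + R + c_s·S + b_int·(R − μ_R)(S − μ_S)

with R = Σβ_j g_j over risk loci, S = Σγ_k g_k over resilience loci
(γ_k ≥ 0: the counted allele of a resilience locus is protective), centered
at the population means μ so the main effects stay interpretable, and α
calibrated by bisection until the expected case rate matches `base_rate`
within 10⁻⁴. The resilience main effect c_s defaults to 0: resilience loci
then act *only* by moderating penetrance (b_int < 0), which is the model's
core postulate. Risk and resilience loci are placed in disjoint LD blocks.
All randomness descends from one integer seed through `SeedSequence`
spawning, so studies are independent streams and runs are bit-reproducible.

### Default study conditions, and why

| parameter | default | rationale |
|---|---|---|
| studies | 3 (2 discovery + 1 held-out) | smallest design with a genuine replication cohort |
| n per study | 5 000 cases / 5 000 controls | smallest size at which held-out direction recovery is reliable (pilot below) |
| markers | 400 in 50 blocks of 8 | enough null blocks to exercise every filter rule |
| ρ (within block) | 0.85 | dosage r² comfortably above the 0.2 clump/exclusion threshold |
| risk / resilience loci | 20 / 20 | desk-scale stand-in for a polygenic background |
| risk_effect_sd | 0.25 | see below |
| resilience_effect_sd | 0.5 | gives the interaction a detectable stratum contrast at n = 5 000 |
| b_int | −0.5 | penetrance-moderating interaction strength of the reference design |
| base_rate | 0.20 | desk-scale prevalence; keeps the simulation pool (n_cases/base_rate) tractable |
| maf_range | 0.05–0.5 | common variants only, matching the MAF filter |

The one subtle calibration is `risk_effect_sd`. In a case–control sample,
ascertainment induces a *marginal* association at resilience loci even when
their population-marginal effect is zero: cases are drawn from high-R
subjects, where the interaction makes low-S more likely, so S differs
between cases and controls. That induced association scales roughly with
SD(R)² (the ascertainment shift of R among cases), while the
resilient-vs-matched contrast the pipeline exploits scales with SD(R) (the
height of the selected stratum). A strong risk scale therefore makes the
risk-p/LD exclusion swallow the resilience loci themselves, contradicting
the orthogonality postulate the generator is supposed to embody. At
risk_effect_sd = 0.25 (SD(R) ≈ 0.54 on the logit scale) the median |z| of
resilience loci in the risk meta-analysis stays compatible with the null at
the default sample sizes, while the stratum contrast remains detectable.
These values were fixed after a design pilot and are not tuned per run.

The canned experiments in `polyres.experiments` freeze two designs: the
default architecture above for direction recovery, and a null design
(2 studies of 800/800, 160 markers, 15 risk loci, b_int = 0, no resilience
loci) for type-I calibration. In both, weights are always estimated on
discovery data and evaluated on a held-out cohort; in-sample evaluation of
a freshly fitted score is biased even under the null and is never used as
an error check.

### What passing tests do and do not show

The simulation demonstrates internal validity: the pipeline recovers the
direction of a true penetrance-moderating architecture (held-out OR > 1,
negative interaction, control-specific positive risk–resilience
correlation) in ≥ 90 % of replicates, and rejects at the nominal 5 % rate
when no such architecture exists. It does not demonstrate that any real
disorder has such an architecture, nor calibrate effect sizes for real
data: per-locus effects here are orders of magnitude larger than realistic
per-SNP effects so that 20 loci can stand in for thousands, LD is
idealized, and imputation noise is reduced to a scalar INFO. Quantities
like the discovery ΔR² are therefore not comparable in magnitude to
real-cohort values — only the qualitative pattern (broad bins carrying
replicated signal, the sharp discovery-to-replication drop, the
control-specific correlation) is.

## Numerical choices

* Per-SNP logistic fits use a Newton–Raphson maximizer with step-halving
  (tolerance 10⁻¹⁰ on the step, 40 iterations); non-convergent, separated
  (|β| > 15 or SE > 100) and monomorphic variants are flagged in a status
  column, never silently dropped, and flagged rows are excluded from
  pooling. Single-model fits (resilience, interaction, deciles) go through
  statsmodels.
* λ_GC = median(χ²)/0.4549364 (the χ²₁ median to seven digits); p-values
  are clipped away from 0 before the inverse-χ² transform.
* Missing dosages are mean-imputed at scoring and association time (an
  explicit strict mode fails instead); missingness is an I/O-level fact,
  never silently filled on read.
* Greedy clumping breaks ties deterministically by (p, chrom, pos, id)
  with a stable sort, so output is independent of input order.
* Cluster-robust gene-level SEs use the sandwich estimator with the
  G/(G−1)·(n−1)/(n−k) small-sample factor; the cluster unit is the
  chromosome (configurable) — a proxy for "LD between genes" since genes on
  different chromosomes are linkage-independent.
* The LD-vs-association diagnostic uses |z| as the association statistic
  by default (−log₁₀ p is available); variants with no risk SNP inside the
  window contribute r² = 0.
* The allelic power approximation anchors the given allele frequency in
  the reference group by default; case-group and pooled anchorings are
  selectable because a bare "allele frequency" is group-ambiguous.

## Degenerate inputs

Zero-variance scores raise instead of propagating NaNs; single-class
outcomes raise a design error; a constant resilience score drops the
interaction term with an explicit warning; empty p-value bins are carried
as flagged empty fits; rank-deficient gene-level designs raise naming the
collinear columns; strata that fail to produce any resilient control raise
a strata error.

## Known limitations

* The PLINK1 reader/writer handles SNP-major bed files only (the format's
  modern default); dosage-format (non-hard-call) genotypes can be carried
  in memory but not round-tripped through bed.
* Stratification pools standardized scores across discovery studies; a
  per-study percentile option would change which subjects are selected when
  study PRS distributions differ in shape, and is a worthwhile extension.
* The simulator's PCs are computed per study; pooled analyses stack them,
  which is adequate without real structure but would be wrong for real
  multi-ancestry data.
* Random-effects meta-analysis, LD-score-regression heritability,
  imputation, and trio-based pseudo-controls are out of scope.
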