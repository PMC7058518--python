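# polyres — polygenic resilience scores for case–control GWAS

Some people carry as much common-variant risk for a heritable disorder as
affected individuals do, yet never become ill. `polyres` implements a
genome-wide procedure for studying that phenomenon: it identifies unaffected
subjects whose polygenic risk score (PRS) is at least as high as that of
cases, matches them to cases of equal risk, and scans the *residual* genome
— everything not associated with, or in linkage disequilibrium (LD) with,
risk loci — for variants whose alleles separate the resilient controls from
the risk-matched cases. The weighted sum of those alleles is a **polygenic
resilience score**: an additive index of variation that lowers the
penetrance of risk loci rather than simply being the mirror image of risk.

The package is written for statistical geneticists who want to apply the
design to their own cohorts or study its operating characteristics in
simulation. It ships a multi-study case–control simulator with LD-block
genotype structure and a penetrance-moderating risk×resilience interaction,
so the entire pipeline is testable on a laptop.

## Method

For each study, per-variant logistic regressions of phenotype on additive
dosage (with principal-component covariates) are pooled across studies by
inverse-variance fixed-effect meta-analysis: with per-study weights
w<sub>i</sub> = 1/se<sub>i</sub>², the pooled log odds ratio is
β = Σw<sub>i</sub>β<sub>i</sub>/Σw<sub>i</sub> with se = (Σw<sub>i</sub>)^(−1/2).
The pipeline then:

1. **Scores risk.** PRS = Σ<sub>j</sub> ln(OR<sub>j</sub>)·g<sub>ij</sub>
   over LD-clumped variants below a p-value threshold, z-scaled within each
   study.
2. **Stratifies.** The 90th percentile of the control PRS distribution
   defines *resilient controls* (controls at or above it) and *risk-matched
   cases* (cases between it and the control maximum); cases above the
   control maximum are set aside as ultra-high-risk.
3. **Filters to the risk-orthogonal genome.** Candidate variants are
   discarded if they associate with risk (p < 0.05) or sit in LD
   (r² > 0.2 within 1 Mb) with such a variant, fall in the MHC
   (chr6:25–34 Mb) or chr8 inversion (chr8:7–14 Mb) regions, have
   imputation INFO < 0.9, are strand-ambiguous (A/T, C/G) or indels, have
   MAF < 0.05 or support from 10 or fewer studies; survivors are greedily
   LD-clumped (500 kb, r² 0.2).
4. **Scores resilience.** A resilient-vs-matched-case GWAS over the
   surviving variants yields ln(OR) weights, binned at ten p-value cutoffs
   (10⁻⁴ … 1.0).
5. **Fits and replicates.** `ResilienceModel.fit()` runs the two-model
   procedure — logistic(resilient ~ score + PCs) against
   logistic(resilient ~ PCs) — and reports the score's ln OR per SD, its
   Nagelkerke ΔR², and the liability-scale R² at resilience prevalence
   K = 0.10. Per-cohort replication fits are pooled with the same
   fixed-effect rule and BH-FDR-corrected across bins.
6. **Analyzes.** Risk–resilience correlations by case/control and
   risk stratum, the risk×resilience logistic interaction, risk-decile odds
   ratios, LD-vs-association diagnostics, allelic power, and gene-level
   risk/resilience enrichment with chromosome-cluster-robust errors.

## Worked example

```python
from polyres import SimConfig, PipelineConfig, run_simulated_study

sim = SimConfig(n_studies=3, n_cases=1000, n_controls=1000, seed=42)
cfg = PipelineConfig(min_studies=1)          # 3 simulated studies, not 51
result = run_simulated_study(sim, cfg, n_discovery=2)

print(result.strata_discovery.counts().to_dict())
fit = {f.cutoff: f for f in result.replication_fits["study3"]}[0.3]
print(fit.summary())
print(result.replication_meta[["cutoff", "or", "p", "fdr"]].round(4))
```

prints

```
{'below_threshold': 3206, 'matched_case': 593, 'resilient_control': 200, 'ultra_high_case': 1}
Resilience-score logistic fit (cohort=study3, p<0.3 bin, status=ok)
  resilient controls: 100   matched cases: 229
  ln OR per SD: +0.4139  (SE 0.1272, p = 0.00113)
  OR per SD:    1.5127
  Nagelkerke R^2: full 0.0882, covariates 0.0425, score Delta 0.0457
  liability-scale R^2: 0.05678
```

Reading this: of the 4 000 discovery subjects, 200 controls sit at or above
the control 90th PRS percentile and 593 cases fall inside the matched-risk
window. In the held-out third study, each standard deviation of resilience
score multiplies the odds of being a resilient control (rather than an
equally at-risk case) by 1.51, and the score explains 4.6 % of resilience
status on the observed scale beyond the principal components. The
replication table shows the pooled odds ratio per bin with BH-FDR across
the ten bins — the broad bins carry the signal, as expected when weights
are noisy per-SNP but informative in aggregate.

A command-line interface mirrors the stages
(`polyres simulate | gwas | meta | score | stratify | filter | resfit |
replicate | analyze | run`); `polyres run --config cfg.yaml --out dir`
executes everything and writes auditable stage TSVs plus a manifest of
config, seed and output hashes.

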