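# Methods

`summr` implements a summary-statistics Mendelian randomization (MR)
workflow of the kind used to probe causal links between environmental
exposures (air pollutants measured in a population biobank) and disease
outcomes (case-control GWAS of autoimmune diseases), together with the
downstream analyses that dissect such links: multivariable MR, protein
mediation, colocalization, and transcriptome-wide overlap.

## The identifying model

For instrument j, let γ_j be the SNP-exposure effect (SE σ_γj) and Γ_j the
SNP-outcome effect (SE σ_Γj), estimated in non-overlapping samples.  The
model is

    Γ_j = β·γ_j + α_j

where β is the causal effect of the exposure on the outcome (log odds
ratio per unit exposure for binary outcomes) and α_j a direct (pleiotropic)
effect of the variant on the outcome.  All estimators consume an
allele-harmonized set of (γ̂, σ_γ, Γ̂, σ_Γ) pairs.

### Instrument selection

Variants associated with the exposure at p < 5×10⁻⁶ are greedily pruned to
pairwise r² < 0.001 within 10 Mb (ascending p; ties broken lexicographically
by variant id for determinism; LD pairs absent from the matrix count as
r = 0 with a warning).  Per-instrument strength is summarized by the F
statistic F = (R²/K)/[(1−R²)/(N−K−1)] with K = 1; instruments with F < 10
are removed, as are instruments associated with the outcome at p < 5×10⁻⁸.

Two variance-explained formulas are provided.  The textbook per-SNP form
R² = 2·EAF·(1−EAF)·(β̂/σ̂)² has no sample-size normalization: at biobank
sample sizes it exceeds 1 for *every* genome-wide-significant SNP (e.g.
EAF 0.25, z 6 gives R² = 13.5), so rows where it does are flagged invalid
rather than silently clamped.  The normalized form
R² = z²/(z² + N − K − 1), which implies F ≈ z² and reproduces the
magnitude of F values reported for biobank exposure GWAS (≈ 20–67 at
z ≈ 4.5–8.2), is used by the pipeline and simulation studies.

### Estimators

- **IVW** (primary): weighted regression of Γ̂ on γ̂ through the origin
  with weights 1/σ_Γ².  Multiplicative random effects: the fixed-effect SE
  (Σwγ²)^(−1/2) is inflated by √(Q/(k−1)) when Cochran's Q exceeds its
  degrees of freedom; the inflation is floored at 1 by default
  (configurable).  Normal inference.
- **MR-Egger**: WLS with intercept after orienting all γ̂ ≥ 0; the
  intercept estimates the mean directional pleiotropic effect under the
  InSIDE assumption.  SEs scaled by max(1, residual scale); t inference
  with k−2 df.
- **Weighted median**: per-SNP Wald ratios Γ̂/γ̂ weighted ∝ γ̂²/σ_Γ²,
  linearly interpolated at percentile 0.5 (p_j = S_j − w_j/2); consistent
  when valid instruments carry ≥ 50% of weight.  SE from a seeded
  parametric bootstrap (default 1,000 resamples; the seed is mandatory).

Sensitivity analyses: Cochran's Q, the Egger intercept test, and
leave-one-out IVW with flags for sign or significance flips.  Multiple
testing uses Benjamini–Hochberg q-values with the family defined as one
exposure's tests across all outcomes; results are tiered *significant*
(q < 0.05), *suggestive* (p < 0.05 ≤ q), or null.  Statistical power for a
binary outcome uses the analytic approximation
Φ(|ln OR|·√(N·R²·K·(1−K)) − z_{0.975}) with K the case proportion.

### Meta-analysis, MVMR, mediation gap

Estimates of one exposure–outcome effect from independent cohorts are
pooled by fixed-effects inverse-variance weighting (single-true-effect
assumption) with Cochran's Q across cohorts.  Multivariable MR regresses
Γ̂ jointly on the per-exposure γ̂ matrix (weighted, no intercept) over the
union of per-exposure instruments, jointly re-clumped; the coefficients are
direct effects conditional on the other columns.  Collinear exposure sets
are reduced beforehand by a weighted lasso (sqrt-weight transform, 10-fold
seeded CV, 1-SE penalty; exactly duplicated columns are resolved
deterministically up front because the lasso solution is non-unique there;
at least one exposure is always retained).  The difference between an
exposure's total effect (univariable MR) and its direct effect (MVMR
conditioning on a candidate mediator) indicates mediation; its SE uses the
independence approximation √(se_total² + se_direct²), which is conservative
and labelled as such since both estimates share instruments.

### Two-step protein mediation

pQTLs are classified cis/trans by a ±1 Mb window (inclusive) around the
encoding gene.  Step 1 estimates each protein's effect on disease from its
cis instruments (selection at p < 1×10⁻⁵, clump 10,000 kb / r² 0.001);
proteins at BH-FDR < 0.05 within the panel are risk proteins.  Step 2
estimates the pollutant's effect on each risk protein (nominal p < 0.05
gate).  The mediated effect is β₁·β₂ with first-order delta-method SE
√(β₁²σ₂² + β₂²σ₁²) and normal inference.

### Colocalization

Per SNP and trait, the Wakefield log approximate Bayes factor is
labf = ½[ln(1−r) + r·z²] with r = W/(V+W), V the squared SE and W the
prior effect variance (0.04 for quantitative traits, 0.0225 for
case-control log-ORs).  Under a single causal variant per trait with priors
p1 = p2 = 10⁻⁴ (trait-specific) and p12 = 10⁻⁵ (shared), the unnormalized
hypothesis weights are (1, p1·S1, p2·S2, p1·p2·(S1·S2−S12), p12·S12) with
S1, S2, S12 the sums of exp(labf) terms, all evaluated via log-sum-exp so
|z| up to ~40 and beyond is safe.  A region colocalizes when PP(H4) > 0.8.
A single-SNP region has no distinct-variant configuration (S3 = 0, warned).

### TWAS overlap

A gene's association is z = (w·z_gwas)/√(wᵀRw) over its expression-model
weight variants with LD matrix R.  A gene overlaps a pollutant when the
disease and pollutant TWAS are both nominally significant (α = 0.05) with
equal z sign.  Evidence is combined by Fisher's method (−2Σln p ~ χ²_{2k}):
per pollutant over the disease/pollutant pair (4 df), and across pollutants
by combining the four pairwise combined values (8 df).  The 8-df
composition is the default because it reproduces published cross-pollutant
values exactly; combining the five raw p-values (10 df) is available by
option.  Ranks are dense, 1-based, ascending per column.

## Synthetic data

Generators work at the summary level: estimates are drawn from the normal
sampling distributions implied by sample size and allele frequency
(σ = 1/√(2·EAF·(1−EAF)·N)), never from genotypes — sufficient for every
estimator here and orders of magnitude faster.  Defaults encode the study
conditions the package is validated under:

| parameter | default | rationale |
|---|---|---|
| n_snp | 80 | instruments per exposure after QC |
| n_exposure_sample | 456,380 | biobank exposure GWAS |
| n_outcome_sample | 100,000 | autoimmune case-control GWAS scale |
| instrument z | U(4.5, 8.2) | implies F ≈ z² in ≈ [20, 67] |
| eaf_range | (0.05, 0.5) | common variants |
| true_beta | 0.3 | moderate causal effect |
| pleiotropy mean/sd | 0.05 / 0.02 | directional regime |
| coloc region | 200 SNPs, AR(1) ρ = 0.9, causal z 8, n 50,000 | per-trait power > 0.99 |
| proteome | 20 proteins, 5 cis-pQTL each, n 35,559 | proteome-panel scale |
| mediation chain | β₁ = 0.4, β₂ = 0.3 | planted indirect effect 0.12 |

Pleiotropy regimes: none, balanced (mean 0), directional, and
InSIDE-violating (α correlated with γ at r = 0.5).  An
`invalid_fraction` plants a subset of instruments with an added
directional effect to exercise the weighted median's breakdown behavior.
Exposure and outcome samples are non-overlapping by construction; sample
overlap, LD from real reference panels, population stratification, and
winner's-curse selection of discovery instruments are *not* modeled, so
passing recovery tests demonstrates estimator correctness under the stated
model, not robustness to those real-data complications.  Allele codings of
the outcome table are shuffled per SNP (seeded) so harmonization is
exercised end to end; identical seeds give byte-identical tables.

## Numerical and design choices

- Variants are matched by identifier only (rsID-keyed summary files), not
  by position.
- Palindromic (A/T, C/G) variants: strand inferred from EAF; dropped when
  either trait's EAF lies in (0.42, 0.58) (band configurable) or the
  outcome EAF is missing; otherwise aligned by minor-allele side.
- Reported 95% intervals use the conventional 1.96 multiplier.
- p-value selection thresholds are strict (<); the weak-instrument filter
  keeps F = 10 exactly; cis windows are inclusive at both boundaries.
- The one-SE lasso penalty path spans 3 decades below the data-derived
  maximum (50 points, 10 folds, seeded shuffle).
- Pipeline child seeds are the global seed plus fixed per-stage offsets, so
  adding a stage never perturbs earlier stages' randomness.

## Known estimator properties and limitations

At study-realistic instrument strength (|z| ∈ [4.5, 8.2]) the MR-Egger
intercept shows a small upward finite-sample bias under directional
pleiotropy with a nonzero causal effect — measured at +0.0019 for a planted
mean of 0.05 over 500 replicates — caused by measurement error in γ̂
attenuating the slope (the NOME/I²_GX phenomenon); it vanishes at β = 0 or
with very strong instruments.  IVW CI coverage under the same conditions is
≈ 93–95% rather than nominal, the usual behavior of the multiplicative
random-effects model with per-SNP weights treated as known.  The
independence approximation for the mediation-gap SE is conservative.  The
colocalization model assumes at most one causal variant per trait in a
region; multi-causal fine-mapping extensions are out of scope.

The replicate-study sizes (500 replicates for coverage and intercept
recovery, 2,000 for type-I error, 200 for weighted-median robustness and
per colocalization configuration, 10,000 Monte-Carlo draws for the delta
method, 100 instances for the clumping oracle) are the package's standing
validation conditions, chosen to make Monte-Carlo error small relative to
the margins being checked.
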