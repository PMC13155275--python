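# Methods

This note documents the statistical models implemented in `ironsmoke`,
the assumptions behind them, the synthetic-data generator that the
validation experiments run on, the numerical choices, and the known
limitations. Everything quantitative claimed here is computed by the
test suite or by `scripts/acceptance.py`.

## Phenotypic association stage

Pipeline order: impute missing covariates → exclude brain-trait
outliers → log-transform skewed variables → residualise on covariates →
rank-based inverse-normal transform → OLS battery → FDR.

* **Imputation** replaces missing covariate values by the column mean
  (continuous) or mode (categorical; ties broken by the first level in
  sorted order). The "group" is the whole analysis sample per column —
  no finer stratification is defined.
* **Outlier exclusion** keeps x iff |x − median| ≤ k·MAD with k = 5 and
  the *raw* MAD (no 1.4826 consistency factor): "five absolute median
  deviations" is taken literally. When MAD = 0 the rule degenerates to
  keeping exact-median values only. Filtering happens on the raw trait,
  before residualisation and transformation.
* **Log transforms** use y = ln(x + s): s = 1 for pack-years (zeros
  occur; the minimum maps to 0) and s = 1 − min(x) for variables with
  negative support such as the deprivation index.
* **De-confounding** regresses both the outcome (brain trait) and the
  predictor (smoking variable) on the same flat additive covariate set
  (demographics, socioeconomics, alcohol, blood pressure, BMI, opaque
  imaging covariates, plus age² and age × sex). Residuals become the
  analysis variables. By the Frisch–Waugh theorem the subsequent simple
  regression reproduces the covariate-adjusted coefficient.
* **INT** maps ranks through Φ⁻¹((r − 3/8)/(n + 1/4)) (Blom offsets,
  average ranks for ties) and z-scores the result. Blom is the most
  common convention where only "rank-based inverse normal
  transformation" is specified.
* **Battery**: six smoking variables × 12 brain traits, binary
  contrasts fitted on their defining subsets (e.g. current-vs-never
  drops former smokers), pack-years fitted among ever smokers;
  Benjamini–Hochberg FDR over the 72 main-effect p-values. Interaction
  models add a centred moderator and product term. The former-smoker
  model regresses each trait on INT cessation-years, INT pack-years and
  their product.
* **Asymmetry test**: z = (β_L − β_R)/√(se_L² + se_R²), one-sided upper
  tail. One-sided is the convention that reproduces the printed pair
  (z = 1.74, P = 0.04; the two-sided value would be ≈ 0.08). The L–R
  sampling covariance is ignored because separate per-hemisphere fits
  do not provide it; since the hemispheres correlate positively this
  makes the test conservative in the usual case. Documented limitation.
* **Robustness**: Pearson correlation of β across two aligned result
  sets and Jaccard index of their significant sets; the Jaccard is
  reported missing when both sets are empty.

## LD-score regression at desk scale

LD scores are ℓ_j = Σ_{|pos_k − pos_j| ≤ w} r²_adj with
r²_adj = r² − (1 − r²)/(n_panel − 2), so the self term contributes
exactly 1 and finite-panel inflation is removed in expectation. Fits are
weighted regressions of z² (univariate) or z1·z2 (bivariate) on ℓ:

* univariate weights: 1/max(ℓ,1) LD weights times the variance weight
  1/E[z²]², with the mean profile from a first 1/max(ℓ,1)-weighted pass
  (two-step re-weighting);
* cross-product weights use Var(z1z2) = E[z1²]E[z2²] + E[z1z2]², taking
  the univariate mean profiles from their own fits and the cross mean
  from a first pass;
* standard errors via a delete-one block jackknife over 20 contiguous
  equal-count SNP blocks — hundreds of blocks are impossible on toy
  genomes of a few thousand SNPs;
* r_g = gencov/√(h1²·h2²), reported missing when either heritability
  estimate is non-positive, and clipped to [−1.5, 1.5] against
  small-sample blow-ups.

Two desk-scale caveats, both visible in the experiments and accounted
for in their design. First, the intercept is identified by
extrapolating to ℓ = 0, so validation genomes mix AR coefficients
(0.1–0.95) across blocks to spread ℓ roughly over 1–7. Second, the
simulator conditions on the panel's *empirical* LD while the estimated
ℓ targets its population value; the resulting errors-in-variables
attenuation inflates intercepts by roughly (slope × a few %) — material
only when n·h²·ℓ/M is large. The overlap-recovery experiment therefore
uses a modest polygenic background (h² = 0.05), which keeps the
cross-intercept bias well under the 0.05 acceptance band while leaving
the quantity of interest (ρ_ov) untouched. r_g is a ratio of slopes and
cancels the attenuation to first order.

## Gene-level cross-GWAS tests

Signed scores: with u_i = (rank(p_i) − ½)/M over the genome-wide
MAF-filtered SNP set, z_i = sign(β_i)·Φ⁻¹(1 − u_i/2). Rank
normalisation makes the score magnitudes exactly uniform-quantile
distributed, trading power for type-I robustness; the sign carries the
direction needed for coherence. Alleles of the two studies are
harmonised before signs are taken.

Null model: the two score vectors within a gene window are jointly
Gaussian, each N(0, Σ) with Σ the regularised panel LD, and
cross-covariance ρ_ov·Σ, where ρ_ov comes from the bivariate LDSC cross
intercept (clipped to ±0.99). This is the minimal joint model consistent
with an LD-aware null and an overlap correction through the intercept.

* **Coherence**: D = Σ zA_i·zB_i. Writing Σ = QΛQᵀ and rotating, D is
  Σ_k λ_k a_k b_k with corr(a_k, b_k) = ρ_ov, and each product is
  ¼[(a+b)² − (a−b)²] with Var(a±b) = 2(1±ρ_ov), giving the weighted
  chi-square difference with weights λ_k(1 ± ρ_ov)/2. The
  anti-coherence p-value is the mirror tail of −D; negating one trait's
  scores (together with the sign of ρ_ov, which flips with the trait)
  swaps the two exactly. The T2\* direction flip (`trait_sign = −1`,
  lower T2\* = more iron) is implemented this way.
* **Ratio**: R = Σ zA_i·zB_i / Σ zB_i². P(R ≥ r_obs) equals
  P(wᵀA(r_obs)w ≥ 0) for the stacked scores w with
  A(r) = [[0, I/2], [I/2, −rI]] and Cov(w) = K ⊗ Σ,
  K = [[1, ρ_ov], [ρ_ov, 1]]. Since A(r) = B(r) ⊗ I, the eigenvalues of
  Ω^{1/2}A(r)Ω^{1/2} are the products of the eigenvalues of
  K^{1/2}B(r)K^{1/2} (2×2) with those of Σ — an exact and cheap
  reduction. Conditioning on the observed r makes the p-value an exact
  CDF transform, hence uniform under the null.
* **Numerics**: Σ is shrunk as (1−ε)Σ + εI with ε = 1e-3; eigenvalues
  below 1e-8 are truncated. Tail probabilities come from Imhof-type
  inversion (below); p-values are floored at 1e-300.
* **Multiplicity**: Bonferroni at α/(number of tested genes); candidate
  mode restricts the gene list and re-derives the threshold over the
  list size; significant genes whose ±50-kb windows overlap are merged
  into clusters (connected components of the overlap interval graph) —
  within a cluster the driving gene cannot be identified.
* Anti-coherence is implemented as the sign-flip mirror of coherence
  rather than a separate statistic; under this null the two
  formulations coincide.

### Weighted chi-square tail engine

P(Σ w⁺U − Σ w⁻V ≥ x) is computed from Imhof's inversion formula. Equal
same-sign weights dispatch to the exact scaled-chi-square form. The
general path integrates the oscillatory inversion integrand adaptively
on a finite core interval chosen from the integrand envelope, then
handles the slowly decaying tail — the hard regime when few weights are
present — either by summing half-period chunks with Wynn-epsilon
acceleration (x ≠ 0) or from a two-term asymptotic expansion (x = 0,
the ratio-test case, where the tail does not oscillate). Verified
against closed forms (chi-square, product-normal via the Bessel K₀
density) at ≤ 1e-9 absolute error and against Monte-Carlo oracles. If
the estimated error exceeds 1e-8 the engine falls back to Monte Carlo
(1e6 draws, p floored at 1/(draws+1)) and tags the result `mc`.

## Mendelian randomisation

Instrument selection sorts exposure SNPs by ascending p (ties broken by
id for order invariance) and keeps a SNP unless its panel r² with any
kept SNP exceeds 0.001; selection at 5e-8 falls back to 1e-5 when fewer
than five instruments survive, with the threshold recorded.
Harmonisation flips outcome betas for swapped allele pairs, drops
palindromic SNPs when min(eaf, 1−eaf) > 0.42 in either study, and
otherwise aligns palindromes by frequency. Estimators:

* **IVW**: origin-constrained WLS with weights 1/se_out², multiplicative
  random effects (se inflated by max(1, √(Q/(n−1)))) — the reference
  default where the choice is not specified;
* **MR-Egger**: WLS with intercept after orienting β_exp ≥ 0; the
  intercept and its p-value flag directional pleiotropy;
* **weighted median / weighted mode** of the Wald ratios (inverse
  ratio-variance weights; normal kernel with Silverman-type bandwidth
  for the mode), standard errors by seeded parametric bootstrap;
* Cochran's Q, per-instrument F = (β_exp/se_exp)², leave-one-out with
  sign/significance flags, and confounder-SNP exclusion.

FDR is applied to the IVW p-values of a run (both directions; in study
mode 12 traits × 2 directions); the sensitivity estimators are reported
at nominal p. First-order delta-method ratio standard errors
(se_out/|β_exp|) are used for weights, adequate for the strong
instruments the selection step enforces.

## Synthetic-data generator

What it emulates: block-structured LD (thresholded blockwise-AR latent
Gaussians; adjacent-SNP LD is the tetrachoric image of the latent
correlation), GWAS marginal statistics on the standardized-genotype
scale (z = √n·Σb + ε, ε ~ N(0, Σ), β = z/√n, se = 1/√n — closed-form,
n-independent recovery targets), participant overlap entering only
through the noise cross-covariance ρ_ov·Σ with
ρ_ov = overlap_n·ρ_e/√(n1n2) (exactly the quantity the LDSC cross
intercept estimates), per-gene shared architecture (null / coherent /
anti-coherent / causal in either direction / trait-private effects) plus
an optionally correlated polygenic background, and cohorts with the
study's smoking-status mix, demographic distributions, configurable
confounding of both smoking and brain traits, and injected missingness.

What it deliberately does not emulate: real human LD maps and
allele-frequency spectra, population stratification or relatedness,
genotyping error, cohort-specific field encodings, non-linear covariate
effects,
and selection effects in cohort assembly. Passing tests therefore
demonstrate the *statistical machinery* — calibration, recovery,
directionality, error control under the stated model — not robustness
to the full messiness of real cohort data.

All generators derive their streams from one master seed through
numpy `SeedSequence`-style spawning (`default_rng([seed, stream])`), so
each component is individually reproducible. Trait-private architecture
classes (`private_1`/`private_2`) exist so that both traits can carry
genuine instruments in null and reverse-causal MR experiments.

## Validation experiment design (problem sizes)

Sizes are fixed in `ironsmoke.experiments` as the package's reference
desk-scale conditions:

* tail engine vs Monte Carlo: 50 random ≤ 20-weight configurations,
  2×10⁶ oracle draws each; thresholds placed by pilot quantiles so the
  binomial standard error is informative; agreement demanded within 3
  oracle standard errors.
* calibration: 5 000 null genes (10-SNP AR(0.8) blocks, panel of 400
  haplotypes, n = 30 000 per GWAS), with ρ_ov ∈ {0, 0.3} (overlap
  simulated by shared participants, corrected with the true overlap
  term); empirical type-I in [0.04, 0.06] at α = 0.05.
* recovery: r_g = 0.5 over 20 GWAS seeds on the shared mixed-LD genome
  (±0.15); IVW γ = 0.1 over 50 seeds with ~10 strong instruments
  (±0.015 mean bias — winner's-curse attenuation is negligible at the
  instrument strength used); phenotypic β = 0.3 at n = 5 000 averaged
  over 8 cohorts (±0.1; a single cohort's contrast SE is ≈ 0.09 because
  current smokers are 3.3% of the sample).
* directionality: γ = 0.3 causal genes for the ratio test (10 seeds ×
  10 genes; median log₁₀ p_fwd/p_rev < −1) and γ = 0.2 for MR over 50
  seeds (forward IVW FDR-significant and reverse null in ≥ 80%).
* null FDR: 200 all-null cohorts (n = 1 500, confounding present) and
  200 null MR runs (both traits instrumented, no causal link);
  any-discovery rate ≤ 0.07.

## Known limitations

* The asymmetry z-test ignores the L–R error covariance (conservative
  for positively correlated hemispheres).
* Desk-scale LDSC carries the attenuation bias described above;
  heritability and intercept estimates on toy genomes are validated by
  parameter recovery, not by matching real-data magnitudes.
* The rank-normalised score null treats the transformed scores as
  exactly Gaussian with the panel LD; this is an approximation that the
  calibration experiments bound empirically.
* The MC fallback of the tail engine resolves p only to ~1/(draws+1);
  extremely small p-values are meaningful only on the analytic path.
* Candidate-gene and exclusion lists are taken as given inputs; no
  gene-set curation is performed.
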