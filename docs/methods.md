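# Methods

This note documents the statistical machinery, the defaults and the
numerical choices, in the package's own terms.

## Genotype container and filtering

Genotypes are biallelic diploid ALT-allele dosages (0/1/2) with an explicit
missing mask; all statistics use pairwise/groupwise-complete loci, never
imputation (the one exception is noted under Mantel inputs). The locus
filters reproduce the Stacks `populations` semantics: a locus is kept iff
its call rate reaches `min_samples_per_pop` in at least `min_populations`
populations **and** `min_samples_overall` overall, pooled minor-allele
frequency ≥ `min_maf`, minor-allele count ≥ `min_mac`, and observed
heterozygosity ≤ `max_obs_het` (defaults 0.7 / 1 / 0.3 / 0.05 / 1 / 0.5).
The minor allele is determined from pooled non-missing calls, which makes
the filter deterministic. Two grains of data (one-SNP-per-locus vs all
variant sites) are simply two input files; the package is agnostic.

## Diversity and F-statistics

Per-site nucleotide diversity uses the unbiased form
π_l = n_l/(n_l−1) · (1 − Σ p²) on n_l non-missing allele copies, averaged
over variant sites with SE = sd/√L. Expected heterozygosity is Nei's gene
diversity 1 − Σ p² without small-sample correction (matching the common
population-program convention for SNP panels); observed heterozygosity is
the called-genotype heterozygote fraction.

F-statistics are Weir & Cockerham (1984) variance components. Multi-locus
combining is ratio-of-sums (Σa / Σ(a+b+c)), not mean-of-ratios — the
estimator W&C recommend and what hierfstat-style software reports. The
inbreeding coefficient is f = 1 − Σc/Σ(b+c) with the r=1 reduction of the
same components; a plain 1 − Ho/He estimator is exposed for cross-checking
only. Confidence intervals are percentile bootstraps over loci (999
replicates by default) and the significance test permutes group labels
among individuals, p = (1 + #{θ* ≥ θ})/(B + 1). Negative θ estimates are
legitimate method-of-moments outcomes and are preserved.

**Per-individual-pair F_ST.** With one diploid per "population" the
among-individual component b is undefined, so pairs are scored with the
two-level (haplotype-frequency) reduction on each individual's two allele
copies: per locus MSP − MSG over MSP + MSG, summed over the loci called in
both individuals (n_c = 2, so the MSG weight in the denominator is one).
Identical homozygotes give θ ≤ 0, opposite homozygotes give θ = 1, and a
pair of heterozygotes gives −1; negative values are only clamped when the
pair table is built, because the quasi-binomial response must live in
[0, 1).

## Pair table

Geographic distance is the haversine great-circle distance on the WGS84
mean radius (6371.0088 km) — at a 150 km extent the difference from a
geodesic is far below the positional noise of colony coordinates. Distances
to the two reference points (primary and putative secondary introduction
sites; defaults are the published coordinates, overridable) enter as
|difference| between the pair's members, as do all environmental
covariates. Cluster pair type merges the small P3 sub-cluster into P1
before labelling (P1P1 / P2P2 / P1P2). Predictor screening removes, while
any |Pearson r| > 0.75 remains, the predictor with the highest mean
absolute correlation (ties broken by input order — deterministic).

## The shape-constrained additive model

The response is a proportion-like index, not a binomial count, so the model
is quasi-binomial: logit link, variance φμ(1−μ), unit weights, φ estimated
by Pearson χ²/df. Each constrained smooth is a cubic B-spline on
quantile-spaced knots whose coefficients enter through

    β₁ = 0,  β_j = Σ_{l≤j} exp(γ_l),

so the coefficient sequence — and therefore the spline — is nondecreasing
for every real γ and the inner optimisation is unconstrained
(SCOP-spline-style). Monotone smooths use a column-centred basis (the
intercept absorbs the level); "positive constraint" smooths use the
uncentred basis with f(min x) = 0, which pins the curve at zero at the left
edge and guarantees nonnegativity over the observed range. After every fit
the constraints are asserted on a 200-point grid per smooth.

Fitting is penalised quasi-likelihood: damped Gauss–Newton on the penalised
deviance (analytic Jacobian of the coefficient map), convergence when the
relative change drops below 1e−8, at most 200 iterations, with a 1e−7 ridge
in γ for numerical stability. Wiggliness is penalised by the second-order
difference penalty on β. Because the exponential map's Jacobian vanishes as
increments go to zero, a collapsed smooth contributes ≈ 0 effective degrees
of freedom — edf per term is the partial trace of
(JᵀWJ + H_pen)⁻¹ JᵀWJ at the solution.

**Smoothing selection.** Each smooth carries two hyperparameters: the
wiggliness λ and a null-space shrinkage λ₀ acting on the linear direction
the difference penalty cannot see (without it, a spurious trend survives
any λ). Both are chosen on a 21-point log₁₀ grid over [−4, 4] by cyclic
coordinate descent (up to 3 sweeps, early exit when stable), minimising
Pearson-based GCV, n·X²/(n − γ_c·edf)². The wiggliness scan uses the
customary mild inflation γ_c = 1.4. The null-space scan — and a final
"collapse the whole term" comparison — decide whether a term is in the
model at all, a selection decision for which plain GCV is known to be
anticonservative: monotone splines can buy a χ² of ~5 for half an edf from
pure noise. These scans therefore use γ_c = log n, i.e. a term keeps its
trend only when its Pearson improvement exceeds roughly 2·log(n) per edf —
an (E)BIC-grade bar. In simulations this removes a pure-noise monotone
smooth in ≥ 19/20 datasets while never dropping a genuine effect of the
magnitudes seen in these data. Smooths whose final edf falls below 0.1 are
deleted from the model and the fit is iterated to a fixed point — the same
"penalised to edf ≈ 0" behaviour that motivates dropping trivial terms.

Reported summaries: deviance explained = 100·(1 − D_res/D_null); adjusted
R² = 1 − (1 − R²_w)(n−1)/(n−edf_total) on the working-residual scale (no
standard definition exists for quasi models; this one is stated so it can
be compared); Wald tests per term (F = β̂ᵀV̂⁻β̂/edf on a smooth's block
against F(edf, df_res); t for parametric terms), with the usual caveat that
these are approximate for penalised, constrained fits.

A Gaussian/identity family is provided for the same estimator; it turns the
machinery into exact penalised least squares and is what allows the
partition to be verified against a closed-form R² decomposition.

## Hierarchical deviance partitioning

Predictors are grouped into genetic (cluster factor), spatial (geographic
distance, distances to introduction points) and environmental (climate and
moisture gradients) components. Seven models are fitted — full, three with
one component removed, three with a single component — and

    unique_i  = D_full − D_reduced(−i)
    shared_ij = D_simple(i) + D_simple(j) − D_(i∪j)

with the three-way term taken as the closure, so the identity
Σ unique + Σ shared + shared₃ = D_full holds algebraically (asserted each
run). Negative shared values are reported, not truncated — they are
ordinary collinearity artifacts. Sub-models reuse the smoothing parameters
selected on the full model, which keeps the seven deviances comparable (the
decomposition measures what the *same* smooths explain) and makes the
partition deterministic.

Significance: the component's predictor columns are shuffled **jointly**
across pair rows (preserving within-component correlation), the full model
is refitted at the observed smoothing parameters, and the unique
contribution is recomputed; p = (1 + #{unique* ≥ unique})/(B + 1), B = 1000
by default. Row-level shuffling mirrors the description of the original
analysis but ignores that pairs sharing a sample are dependent, so p-values
are calibrated under row exchangeability, not under sample-level nulls; a
Mantel-style sample-permutation mode (`permute="samples"`) is provided for
sensitivity analysis.

## Stand-alone tests

Mantel r is the Pearson correlation of lower-triangle entries, null by
simultaneous row/column permutation, one-sided upper p (the IBD
alternative); for n ≤ ~8 an exact enumeration over all n! permutations is
available and is what the tests check the sampled p against. Genetic
distances for Mantel are Euclidean on dosage vectors with per-locus mean
imputation (the only imputation in the package), geographic distances are
Euclidean on raw decimal degrees — deliberately different from the pair
table's haversine, mirroring the customary adegenet-style usage; both
conventions are documented so the difference is visible. The χ² concordance
test is plain Pearson without continuity correction (df = 1 for the 2×2
haplotype × cluster table). Kruskal–Wallis uses the tie-corrected H;
Dunn's Z uses pooled-rank variance with tie correction and Bonferroni over
the observed group pairs. The climate permutation test shuffles cluster
labels 10,000 times and reports the two-sided p for the observed mean
difference. Evanno's ΔK is |m(K+1) − 2m(K) + m(K−1)|/sd(K) over replicate
means, undefined at boundary K and wherever sd = 0.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with defaults
frozen at the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_per_cluster | (31, 16) | samples per founder lineage |
| n_loci | 2000 | biallelic SNPs |
| f_div | 0.15 | target between-lineage F_ST (Balding–Nichols) |
| f_deme | 0.02 | within-lineage drift scale of the spatial field |
| n_demes | 5 | demes per lineage |
| spatial_range_km | 30 | exponential GP correlation length |
| discordance_rate | 7/47 | mito-nuclear mismatch probability |
| missing_rate | 0.05 | per-genotype missingness |

Per locus the ancestral frequency is Uniform(0.05, 0.95) and each lineage
frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) — the Balding–Nichols F-model,
which makes the target θ directly recoverable (Weir–Cockerham estimates on
pure two-lineage draws recover F within ±0.02 at L = 2000, 24+24 diploids).
Within a lineage, deme frequencies add a logit-scale Gaussian process over
deme coordinates with exponential covariance; the marginal variance is
matched to `f_deme` by the delta method (σ² = F_deme/(p(1−p)), capped).
Genotypes are Binomial(2, deme frequency). Demes live in a 150 × 100 km
window with lineage-specific centroids (one widespread, one confined —
the dual-introduction geometry); coordinates are converted to pseudo
lat/lon around (−34, 19) so the downstream great-circle code runs
unchanged. Environmental covariates are baseline + lineage shift + a smooth
east–west gradient + noise, with magnitudes chosen to look like Western
Cape climate normals (e.g. lineage 0 ≈ 2.5 °C hotter summers, ≈ 200 mm
drier). Haplotypes equal the lineage label flipped with probability ε.
All draws flow from a single seed; identical seeds give byte-identical
VCF + metadata output.

Presets: `study-like` (defaults above), `null-panmixia` (F = 0, no
environmental linkage — calibration), `ibd-only`, `ibe-only`.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium between loci, allele-
frequency spectra from real ascertainment, colony kin structure and
assortative mating, genotyping error, and the dependence of pairs sharing a
sample beyond what the F-model induces. Calibration results for the
row-permutation tests are statements under row exchangeability (see above).

## Problem sizes used in the checks

The bundled checks run at desk scale: estimator-vs-oracle identities on
toy matrices; parameter recovery at L = 2000 with 24+24 diploids over 20
seeds; permutation-test calibration over 500 datasets (label and climate
permutations) and 200 datasets at B = 99 (component permutation);
study-condition end-to-end runs at 47 samples / 1081 pairs with 600–2000
loci; partition permutations at B = 199 in the reproduction script. These
sizes were chosen to keep each suite in the minutes range while leaving
Monte-Carlo error well inside the asserted bands.

## Known limitations

- Pairwise rows are not independent; the additive model's standard errors
  and the row-permutation p-values inherit that caveat (as in the original
  style of analysis). The sample-level permutation mode is the provided
  sensitivity check.
- The SCAM dialect (basis, penalty, smoothing criterion) is this package's
  own; exact effective degrees of freedom and F statistics will differ from
  other SCAM implementations even when fitted curves agree closely, so
  cross-package comparisons should be made on fitted means and deviance
  explained, not on edf decimals.
- Wald tests on penalised constrained fits are approximate; p-values very
  near a decision threshold deserve a permutation check.
- The Genepop reader supports the 2/3-digit diploid dialect only.
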