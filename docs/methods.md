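# Methods

## Statistical model

The core quantity is an inverse-variance-weighted multivariable regression of
one trait's per-variant GWAS effect estimates on two exposures' estimates,
with an intercept:

    β̂_out,k = θ₀ + θ₁ β̂_exp1,k + θ₂ β̂_exp2,k + ε_k,    w_k = se(β̂_out,k)⁻²

Weights come from the **outcome** standard errors only. The design is the
multivariable Egger-type regression used in summary-statistics MR, read here
associationally: exposures may be pleiotropic, slopes are aggregate polygenic
associations (outcome units per log-odds of liability when the exposures are
case-control disorders), and the intercept estimates directional pleiotropy
not carried by the exposures.

Inference: ordinary weighted least squares via the normal equations;
coefficient covariance `σ̂² (XᵀWX)⁻¹` with the multiplicative dispersion
estimator `σ̂² = Σ w_k r_k² / (n − p)`; two-sided P-values from the t
distribution with n − p degrees of freedom. Whether dispersion should be
fixed at 1 or estimated is a genuinely open modeling choice for this design;
the multiplicative estimator matches common weighted-least-squares and
MR-Egger practice and makes the test robust to an over- or under-dispersed
residual scale. The log-likelihood is the profiled Gaussian likelihood with
per-variant variances `σ²/w_k`, so nested univariable/multivariable
comparisons by likelihood-ratio test (χ², df = number of added exposures) are
internally consistent; the same convention is used by R's `logLik.lm` with
weights, so LRT values match that reference. Collinearity is reported as
VIF_j = 1/(1 − R²_j) with R²_j the weighted R² of exposure j on the other
exposure; exact collinearity is reported as +inf rather than an error, while
a singular full design (reciprocal condition number of the scaled normal
matrix below 1e-12) raises an error naming the offending columns. Both
weighted and unweighted R² are reported, since "variance explained" for this
design is convention-dependent.

Estimates are invariant to a positive rescaling of the weights and to a
global sign flip of all rows; they are *not* invariant to flipping a subset
of rows (the intercept breaks that symmetry), which is exactly why variants
are first oriented to the risk-increasing allele of the direction's primary
disorder. After that orientation the fit is independent of how alleles
happened to be reported.

## Variant selection

Discovery sets: P < threshold over an 11-point grid (5e-8 … 0.5), minor
allele frequency > 0.01, imputation INFO > 0.7, then greedy LD clumping —
visit by ascending P (ties: position, then id), retain unless an
already-retained same-chromosome variant within ±500 kb has r² ≥ 0.25.
Comparisons are strict so retained sets satisfy "r² < 0.25". The greedy
P-ordering and the deterministic tie-breaks follow the PLINK clumping
convention; windows are center-to-center and inclusive at the boundary.
Missing frequency or INFO fails the corresponding filter when that filter is
enabled (it can be disabled by setting the bound to None).

Conditional subsets: a member of one disorder's set qualifies at a
conditional threshold t if it — or its best LD proxy (r² ≥ 0.6, ±500 kb,
ties by distance then id) among the other disorder's variants passing the
MAF/INFO filters with P < t — exists. Six conditional thresholds (0.0015 …
0.5) give six nested subsets per direction. The candidate side is not
clumped: a proxy only establishes qualification, and the subset keeps the
primary variant's own estimates, so each direction's design stays
self-consistent. Bonferroni thresholds for the analysis plans: 0.05/22 =
0.0023 (discovery grid), 0.05/4 = 0.0125 (follow-up), 0.05/12 = 0.0042
(disorder specificity), 0.05/25 = 0.002 (correlation analyses); reported
rounded to four decimals.

Concordant subsets drop rows whose two disorder effects differ in sign; rows
with an exactly zero effect are dropped too, since a zero effect has no
risk-increasing allele.

## Harmonization

All traits are expressed for the reference trait's effect allele: swapped
allele pairs negate the effect and complement the frequency; strand-swapped
codings are matched after complementing. Palindromic variants (A/T, C/G)
cannot be disambiguated from alleles alone; they are resolved by frequency
agreement when both frequencies lie outside [0.4, 0.6] and dropped otherwise
(or always, under the `drop` policy). Odds ratios are converted to log-odds
at read time so every disorder effect lives on one additive scale. Every
drop is audited with a machine-readable reason, and counts are conserved:
input = aligned + dropped per trait.

## Permutation null

For a k-variant subset of a parent set, the observed statistic is the
absolute slope t per exposure; B draws of k variants without replacement
from the parent are refitted and the empirical P is (r + 1)/(B + 1), never
zero. Singular permuted fits count as non-exceeding and are audited. A
relative tie tolerance of 1e-9 on the comparison makes a re-draw of the
observed subset count as a tie regardless of floating-point summation order.
The statistic choice (|t| per slope, one-sided "larger than chance") is a
design decision: it is scale-free and targets the question of whether the
subset's association strength could arise from an arbitrary same-size draw.

## Overlap-aware meta-analysis and genetic correlation

Per variant, the two disorders' estimates are combined by generalized least
squares under covariance [[s₁², c s₁ s₂], [c s₁ s₂, s₂²]] (Lin–Sullivan
form). The overlap correlation c is estimated as the correlation of z-scores
over variants null in both traits (|z| < 1.96); with strong polygenic signal
this conflates true effect correlation with sample-overlap correlation, which
is acceptable for the purpose of demonstrating cancellation but is *not* a
substitute for the score-based meta-analysis software used on real data.
|c| is capped at 0.999 with a warning; non-positive-definite per-variant
systems are dropped and audited.

The genetic-correlation estimator is a deliberately simplified unconstrained
cross-trait LD-score regression: z₁z₂ on the LD score for the covariance
slope, z² on the LD score per trait for the heritability slopes, rg =
cov-slope / √(h₁h₂), intercepts free, standard error by delete-one block
jackknife over contiguous variant blocks (default 20). No iterative
weighting (optionally 1/ℓ weights) and no liability-scale conversion — rg is
scale-invariant, and the estimator is exercised only on simulator output
whose scale is controlled. Negative heritability slopes make rg undefined;
this is reported, not raised.

## Simulator

Markers live in AR1 LD blocks (signed r = ρ_LD^|i−j|, default ρ_LD = 0.8,
100 markers per block, 200 blocks) placed > 1 Mb apart so cross-block LD is
exactly zero; LD scores are within-block Σr². Causal disorder effects are
placed per scenario (disjoint low-LD/different-block sets; opposite-signed
shared or co-localised variants; same-signed co-localised variants; a shared
causal allele with different magnitudes), outcome causal effects follow the
generative identity b_out = θ₁ b_D1 + θ₂ b_D2 + N(0, σ_e²), true marginal
effects are the LD convolution R·b, and observed estimates add N(0, 1/N)
noise with se = 1/√N on the standardized-genotype scale. Disorder effects
are tagged log-odds for interface realism; no liability-scale conversion is
performed. Each marker's reported allele is flipped with probability 0.5 per
trait — the hook that forces harmonization correctness to matter everywhere —
and allele pairs are never palindromic, so the round trip is exact for every
marker (palindrome handling is tested on hand-built tables instead). An
optional replicate draw of the disorder statistics supports selecting
variants independently of estimating them (winner's-curse control). The
scenario of ascertainment bias during case recruitment is not generative and
is out of scope.

Scenario V encodes identical risk alleles: a shared random sign per causal
variant with folded-normal magnitudes. A shared sign alone already induces
an effect correlation of 2/π ≈ 0.64, so the magnitude correlation is solved
numerically so that the *realized* effect correlation equals the configured
`rho_disorders` (targets below the 2/π floor realize the floor; the default
0.6 realizes ≈ 0.64).

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| n_blocks × block_size | 200 × 100 (M = 20,000) | desk-scale genome; enough markers for stable fits, seconds per study |
| ρ_LD | 0.8 | strong local LD so clumping, proxies and tagging all matter |
| N per trait | 50,000 | mid-size consortium GWAS; se = 1/√N ≈ 0.0045 |
| θ (outcome per log-odds) | +0.1 / −0.1 | symmetric discordance with desk-scale power; real-data analogues are an order of magnitude smaller (a `consortium_scale` preset with θ = +0.009/−0.029, N = 500,000 is provided) |
| rho_disorders | 0.6 | positive disorder-effect correlation of comparable magnitude to reported ASD–ADHD genetic correlations |
| causal_fraction | 0.05 | sparse architecture: 5 causal variants per block |
| causal_scale | 0.4 | selected markers' true effects ≈ 50× estimation noise. The regression treats exposures as error-free (measurement-error correction is explicitly out of scope), so its inferential guarantees hold in the regime where selected effects dominate the 1/√N noise; smaller scales reintroduce regression-dilution bias that the model does not claim to handle |
| σ_e | 0.0005 | direct (non-mediated) pleiotropy at ~2% of the mediated effect. Because σ_e noise enters at causal variants and is LD-convolved, it produces residuals correlated across nearby markers, which the independent-residual WLS model does not capture; keeping it small keeps model-based standard errors honest. The near-zero empirical intercepts motivating this design justify a small value |

The `infinitesimal` preset (causal_fraction = 1, causal_scale = 0.04,
σ_e = 1.5e-4) is the polygenic regime that LD-score regression assumes;
correlation-level experiments (genetic correlation recovery, effect
cancellation) use it, with 600 blocks (M = 60,000) in the cancellation study
for adequate rg precision. Sparse-architecture defaults are used for the
variant-level machinery (selection, MVR recovery, permutation).

### What the simulator does and does not emulate

It reproduces the features this pipeline is sensitive to: block LD with
realistic tagging, correlated disorder architectures with scenario-specific
sign structure, discordant mediated outcome effects, per-study sampling noise
with the 1/√N scale, allele-reporting heterogeneity, and
selection/estimation sample splits. It does **not** emulate: liability-scale
case-control effects (log-odds labels are cosmetic), allele-frequency-
dependent effect sizes or LD (frequencies are decorative), population
stratification or uncontrolled confounding, genotyping/imputation artifacts
(INFO is constant 1), palindromic strand ambiguity, overlapping samples
between the emitted traits (the overlap machinery is validated on explicitly
shared noise instead), or real LD irregularity (AR1 blocks are homogeneous).
Passing tests therefore demonstrate the *statistical machinery* is correct
under controlled conditions, not that real consortium data meet those
conditions.

## Validation study sizes

The recovery study runs 200 end-to-end replicates at the defaults above
(selection on a replicate draw at P < 0.0015) and checks mean slope error,
95% CI coverage and discordance detection at the 0.0023 threshold. The
cancellation study runs 50 symmetric infinitesimal replicates; the
permutation calibration runs 200 repeats with B = 999 on parent sets of 300
markers (k = 50); clumping/proxy search are compared against brute-force
oracles on 1,000 randomized toys. These sizes give Monte-Carlo error well
inside the asserted bounds while keeping the full validation suite to a few
minutes on one CPU.

## Known limitations

- Exposure measurement error is ignored by design (no SIMEX/weighted-median
  variants); heterogeneity statistics (Q, I²) are not computed.
- The overlap-correlation estimator conflates polygenic correlation with
  sample overlap at null variants.
- The LD-score estimator is two-step and unweighted; its intercepts are not
  calibrated against a reference implementation.
- Matching is by variant id only; no positional matching, liftover,
  multi-allelic variants or VCF ingestion.
- The permutation statistic (per-slope |t|) is one reasonable choice among
  several (coefficient, model-level F); results for strongly non-exchangeable
  subsets depend on it.
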