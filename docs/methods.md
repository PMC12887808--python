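# Methods

This note documents the statistical machinery in `cisiv`: the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data generator does and does not emulate.

## Strength of correlated instruments from summary statistics

All methods consume marginal (univariable) GWAS estimates β̂ⱼ, SEⱼ, a sample
size N, and a signed LD correlation matrix R. The joint (multivariable)
system is reconstructed on the correlation scale:

1. zⱼ = β̂ⱼ/SEⱼ maps exactly to the sample correlation between variant j and
   the trait, bⱼ = zⱼ/√(zⱼ² + N − 2) (the t-to-r identity of simple OLS).
2. The standardized joint coefficients are a = R⁻¹b and the joint variance
   explained is the multiple-correlation identity R² = bᵀR⁻¹b.
3. Per-allele scale is restored via cⱼ = SEⱼ·√(N − 2)/√(1 − bⱼ²) (the
   sd(y)/sd(gⱼ) ratio implied by the marginal SE): γ̂ⱼ = cⱼaⱼ, and
   Σγ̂ = (1 − R²)/(N − J − 1) · C R⁻¹ C with C = diag(c).

The F-statistic is the joint Wald statistic per instrument,
F̂ = γ̂ᵀΣγ̂⁻¹γ̂/J, from which R² = J·F̂/(N − J − 1 + J·F̂) and
R²adj = 1 − (1 − R²)(N − 1)/(N − J − 1).

Two consequences motivate this construction:

* **J = 1 identities hold exactly**: γ̂ = β̂, Σγ̂ = SE², F̂ = z²,
  R² = z²/(N − 2 + z²).
* **In-sample exactness**: when the LD matrix and the marginal estimates
  come from the same sample, the chain reproduces the coefficient of
  determination of the individual-level multivariable regression to machine
  precision (the test suite asserts ±0.01 on every simulated replicate).

The covariance deliberately carries the *joint* residual variance (1 − R²).
A reconstruction that keeps the marginal SEs unscaled (Σγ̂ = S·R⁻¹·S) is
simpler but understates the joint F when individual variants explain a
non-trivial share of variance — at the 40%-heritability design point it
yields R² ≈ 0.36 for a true 0.40, which would defeat the purpose of an
exactness benchmark. This was a genuinely open design choice; the rescaled
chain was adopted because it is the one consistent with both the J = 1
identities and individual-level OLS.

**Singularity and stabilization.** A symmetric matrix is treated as singular
when λ_min < 10⁻⁸·max(1, λ_max) (relative tolerance; none is standard, this
one is scale-free). Wherever an inversion is required (joint reconstruction,
IVW weight matrix, PC score covariance), a singular matrix has its diagonal
shifted by ε = −λ_min + 10⁻⁸, which floors all eigenvalues at 10⁻⁸ and
leaves off-diagonal entries untouched; the operation is idempotent.

## Selection methods

Shared pre-processing: variants with marginal p ≥ 0.001 are removed before
pruning, the sum-of-single-effects fit, and PCA (strict inequality). PCA
additionally pre-prunes at pairwise r² > 0.95 to drop near-duplicates. The
stepwise conditional selector runs unfiltered — its p cutoff acts
internally. Selection order everywhere is |z| descending, which is the same
ordering as p ascending but immune to floating-point underflow of extreme
p-values (at the simulated sample sizes z ≈ 50 and p underflows to 0);
exact |z| ties are broken uniformly at random with the configured seed.

**Standard LD-pruning.** Iteratively select the remaining variant with the
largest |z|, exclude all remaining variants with r² above the threshold to
it, repeat. Guarantees max pairwise r² ≤ threshold in the output.

**Modified LD-pruning.** Same loop, but a candidate is permanently retained
only if (a) it strictly increases the adjusted R² of the selected set
(tolerance 10⁻¹², i.e. its partial F exceeds 1) and (b) the tentative LD
submatrix is non-singular. A rejected candidate is removed from
consideration but does *not* r²-exclude its neighbours — this maximizes the
chance of finding an acceptable variant within its LD block. The first pick
(the lead) is always retained. Note the adjusted-R² gate rejects a
conditionally-null candidate with probability P(χ²₁ < 1) ≈ 0.68, not with
near-certainty; the slight upward drift of R² from accepted noise variants
is visible in the simulation study (medians ~0.5 percentage points above
truth at r² = 0.4) and mirrors the known optimism of this strategy.

**Stepwise conditional selection.** Start from the lead variant if its
p < 0.001. Forward: for every remaining variant compute its collinearity
with the selected set, r_csᵀR_ss⁻¹r_cs (the LD-space R² of regressing the
candidate on the set; detects linear-combination collinearity that pairwise
r² misses); candidates above the threshold get conditional p = 1. The rest
get conditional p from the joint model on set ∪ {candidate}; the best
sub-cutoff candidate enters. Backward: recompute joint p-values of the set
and drop the weakest if ≥ cutoff. Iterate to a fixed point. A variant
removed twice is barred from re-entry (oscillation guard). The forward scan
is vectorized through the Schur complement of the selected block, making a
full scan O(J·|S|²) rather than J separate solves. Conditional p-values use
the standard-normal reference. One structural consequence worth knowing:
with two causal variants correlated at ρ = 0.5 (r² = 0.25), a collinearity
threshold of 0.1 gates out every good proxy of the second signal, so full
variance recovery requires thresholds above the causal-pair r².

**Sum-of-single-effects regression.** The standardized effect vector is
modelled as Σ_k b_k with each b_k having one non-zero entry (K = 10). The
fit operates on sufficient statistics on the correlation scale — XᵀX = N·R,
Xᵀy = N·b, yᵀy = N — rather than on raw z-scores: at large per-variant R²
the marginal SEs are heteroscedastic across variants, and z-scale residuals
are no longer N(0, R), which manufactures spurious effects; the
sufficient-statistic form avoids this and additionally lets the residual
variance σ² be re-estimated each sweep by its closed-form ELBO maximizer.
Each single-effect regression is exact given the other effects'
expectations, so the variational objective is monotone (asserted to 10⁻⁶).
The per-effect prior variance is optimized over a log₂ grid
{0} ∪ {2⁻²⁰ … 2²} (standardized-effect-variance scale) by exact SER marginal
likelihood; an effect is declared null unless its optimum beats the
zero-variance model by 0.1 log-units — genuine effects clear this margin by
orders of magnitude, while pure-noise effects otherwise linger at tiny
variances and stall convergence. Convergence is |ΔELBO| < 10⁻³ within 100
iterations (non-convergence is a warning, not an error; credible sets are
typically stable well before the objective settles). 95% credible sets are
the smallest per-effect prefix of variants (by within-effect inclusion
probability) reaching 0.95 cumulative probability; sets with purity
(minimum absolute pairwise |r|) below 0.5 are discarded, duplicate member
sets across effects are merged, and the max-PIP variant represents each
set. Zero surviving sets → empty selection; pipelines fall back to the
lead variant and flag it.

**PC instruments.** W = (zzᵀ)∘R is symmetric PSD (Schur product theorem);
eigendecompose, clip negative numerical eigenvalues to zero, and retain the
smallest k whose eigenvalue sum reaches the variance threshold (denominator
= trace of W after clipping — the natural choice; the fraction's
denominator is not otherwise pinned down). Eigenvector signs are fixed by
making each column's largest-magnitude loading positive. Strength in the
PC basis uses the multiple correlation of the trait with the k PC scores,
(Lᵀb)ᵀ(LᵀRL)⁻¹(Lᵀb); with all PCs retained this equals the full-variant R².

## MR

Fixed-effects correlated-instrument IVW: Ω = D_seY·ρ·D_seY,
θ̂ = (γᵀΩ⁻¹γ)⁻¹γᵀΩ⁻¹Γ, se(θ̂) = (γᵀΩ⁻¹γ)^(−1/2), normal CIs at ±1.959964.
Exposure and outcome samples are treated as independent (two-sample
framing, no cross-covariance), Ω uses outcome SEs only, and no
overdispersion is added. Ω is stabilized only when singular, and the result
carries a `stabilized` flag so reports can surface the recommended
lead-variant-only comparison. For PC instruments the same estimator runs on
the transformed system with Ω = LᵀS_Y R S_Y L. The comparison workflow
flags a row as "instability-suspect" when its MR SE is below half the
lead-only SE or its estimate moves more than two combined SEs from the
lead-only estimate (configurable operationalization of the qualitative
advice to distrust precision that arrives too cheaply).

## Synthetic data

`simulate_panel` draws a latent MVN with AR(1) correlation inside LD blocks
(default adjacent correlation 0.9, block sizes uniform 20–80), thresholds
at Hardy-Weinberg cut-points for per-variant MAF ~ U(0.05, 0.5) into
{0,1,2} dosages, and column-standardizes. A `gaussian` mode skips
thresholding for exact-correlation tests. This emulates a dense cis region
with strong local LD; it does *not* reproduce long-range haplotype
structure, allele-frequency-dependent LD, population stratification, or
imputation noise of real reference panels, so passing tests demonstrate
algorithmic correctness and calibration under block LD, not robustness to
reference mismatch.

Traits: with standardized genotypes and heritability h² = 0.40, the
one-causal model uses β = √h² ≈ 0.632 and residual variance 0.6; the
two-causal model picks a pair with empirical correlation within ±0.05 of
0.5 and uses β = √(h²/(2 + 2ρ)) ≈ 0.365 each, so the pair jointly explains
40% and each variant marginally explains h²(1+ρ)/2 = 30%. (The effect sizes
are calibrated analytically to these variance targets rather than fixed to
round numbers, since round per-allele effects cannot simultaneously satisfy
the 40%/30% joint/marginal targets under standardized genotypes.) Each
replicate records its in-sample `true_r2` by regressing the trait on the
causal set.

Marginal summary statistics are per-variant OLS (t-reference p-values,
floored at 10⁻³⁰⁰ to respect the p ∈ (0,1] contract), and LD is the exact
in-sample correlation matrix — so the strength chain's in-sample exactness
is testable replicate by replicate.

Scenario runners: `run_main_scenarios` (one-/two-causal medians of J and R²
per method/tuning, plus R² normalized by lead-only), `run_extended_I`
(causal variant and its r²-proxies removed before selection at thresholds
0.95/0.8/0.4), `run_extended_II` (two independent causal variants, one with
a direct pleiotropic outcome effect δ, independent outcome panel; reports
per-method mean estimate, bias, Monte-Carlo SE). Method failures within a
replicate are recorded as missing, not fatal.

## Problem sizes

The full-scale profile mirrors the motivating study: 1,620 variants,
n = 20,000, 100 replicates. The package also defines a reduced profile
(300 variants, n = 5,000, 50 replicates) used for the method-level
simulation summaries and most tests; at 40% heritability the causal signals
are overwhelming at either scale, so medians are indistinguishable between
profiles up to Monte-Carlo noise. `scripts/acceptance.py` runs the
truth-calibration targets at full scale and the method medians on the
reduced profile; the test suite asserts the same quantities at 12
replicates with correspondingly widened (±3 percentage point) windows.

## Known limitations

* R² is in-sample (selection and evaluation share the data), hence mildly
  optimistic; this matches the quantity the methods are compared on.
* The collinearity gate and conditional p-values assume a single cohort and
  constant N; no cross-cohort allele-frequency QC is performed.
* The sum-of-single-effects fit fixes the trait variance scale from the
  summary statistics; it does not implement refinement passes, and with
  heavily mismatched LD references its credible sets inherit the usual
  fragility of summary-statistic fine-mapping.
* Harmonization attempts match-or-flip only (no strand flips); palindromic
  variants with 0.42 < EAF < 0.58 are flagged, never dropped.
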