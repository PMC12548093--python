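# Methods

## Closed-system fractionation model

The package analyzes the reduction 2 NO → N₂O + H₂O in a sealed, well-mixed
vessel with a finite substrate pool. Under first-order kinetics in each
isotopologue, the instantaneous product delivered to nitrogen site
j ∈ {α, β} carries the isotope ratio R_s/KIE_j, where R_s is the current
substrate ¹⁵N/¹⁴N ratio, so each site has a constant fractionation factor
α_j = 1/KIE_j. The bulk instantaneous fractionation factor is the plain
average (α_α + α_β)/2 because every N₂O molecule draws one atom per site
from the common pool. Oxygen branches: one atom per molecule is retained in
N₂O with factor 1/KIE_O, the other leaves as water with a separate branch
enrichment factor; only the retained atom is observed.

Delta values are per mil versus atmospheric N₂ (¹⁵N/¹⁴N = 0.0036765) and
VSMOW (¹⁸O/¹⁶O = 0.0020052). These reference ratios are configurable; they
matter only where absolute ratios enter (atom accounting and the ρ fit), and
sensitivity there is weak.

## Estimation

**Bulk enrichment factor.** Ordinary least squares of measured bulk δ¹⁵N
against the Rayleigh abscissa x = −f ln f/(1 − f), where
f = (NO₀ − 2·N₂O_cum)/NO₀ from reaction stoichiometry. The slope estimates
ε_bulk, the intercept the initial substrate δ¹⁵N. The same machinery fits
the δ¹⁸O channel (reported strictly as a *slope*, since the water branch
makes it a composite quantity, not ε¹⁸O) and the SP trend line. Conventions:
R² = 1 − SSR/SST (defined as 0 with a flag when SST = 0); RMSE = √(SSR/n);
coefficient standard errors use the usual n−2 OLS degrees of freedom; the
slope p-value is a two-sided t test of slope = 0. f is computed from the
nominal initial NO amount and its uncertainty is not propagated (ordinary
rather than errors-in-variables regression); classical, not robust, SEs.

**Position-specific partition.** ρ is fit by trust-region nonlinear least
squares (SciPy `least_squares`, start 0.5, bounds (0, 1), xtol/ftol/gtol
10⁻¹², ≤200 evaluations — a one-parameter problem, so convergence is
robust) with measured bulk δ¹⁵N as the dependent variable: the predictor
re-expresses the observed product ¹⁵N inventory through the α-site ratio
implied by ρ and averages the resulting α delta with the observed β delta.
The ¹⁵N inventory uses exact isotope fractions R/(1+R) rather than the R ≈
fraction shortcut, removing a ~0.4 % systematic in ρ at no cost. SE(ρ) comes
from the Gauss–Newton curvature (JᵀJ)⁻¹·SSR/(n−1); the p-value is a
two-sided t test against ρ = 0.5 on n−1 df. τ is the per-observation mean of
¹⁴Nᵅ/¹⁴Nᵇᵘˡᵏ computed from the measured deltas (SE = SD/√n; one-sample
two-sided t against 0.5). At natural abundance τ sits within ~10⁻⁴ of 0.5
and moves by only ≈ −9×10⁻⁷ per ‰ of α–β asymmetry, so its test is
extremely sensitive to consistent site asymmetry despite the tiny effect
size. Per-site SEs propagate to first order treating (ρ, τ, α_bulk) as
independent; the bootstrap offers the empirical alternative. The outputs
satisfy τ·α_Nᵅ + (1−τ)·α_Nᵝ = α_bulk identically.

**Filters and QC.** Rows below 10 % conversion are excluded (the linearized
model is least accurate early in the reaction). The production plateau is
detected per replicate as the first observation whose cumulative-N₂O
increment over the previous retained sample is ≤ 1 % (configurable) of its
cumulative amount; it and all later rows are dropped — a reproducible proxy
for "production stopped increasing", which in practice is judged by
inspection. Replicates prepared identically are pooled with no random
effect. Grubbs' one-outlier test (two-sided, α = 0.05 default, critical
value from the t-quantile formula; n = 10 gives 2.290) screens the bulk-fit
residuals; at most one whole observation is removed, ties break to the first
index, and residual spreads at machine-rounding scale are treated as
zero-variance (no outlier). Whether the flagged row is removed or only
reported is a config policy (default: remove).

**Bootstrap.** Case resampling at the pooled-observation level: n rows drawn
with replacement, both models refit, KIEs/ε/RMSEs averaged over successful
resamples (a resample with a degenerate abscissa counts as a failed fit;
>10 % failures raises a warning). The RNG is counter-based (NumPy Philox)
with the resample index as the counter, so a given seed yields bit-identical
summaries regardless of execution order.

## The synthetic-data generator

`simulate_closed_system` discretizes substrate consumption into ≥1000 equal
N₂O increments (default 10 000) with exact atom bookkeeping, conserving ¹⁵N,
¹⁴N, ¹⁸O and ¹⁶O to <10⁻⁹ nmol at every step; halving the step count moves
sampled deltas by <0.005 ‰. In the equal-KIE limit it reproduces the exact
closed-form accumulated product R_p = R_s0(1−f^α)/(1−f) to <0.001 ‰.
`generate_study_like` is a preset of the study conditions: 10 300 nmol NO,
substrate δ¹⁵N −40.5 ‰, per-site enrichment factors −7.2 ‰ (α) and −9.9 ‰
(β), three replicates on staggered grids spanning 20–74 % conversion
(13 observations), timestamps from a 24 nmol min⁻¹ production rate, and
Gaussian noise only on the channels an IRMS measures: 0.5 ‰ on bulk δ¹⁵N
(m/z 45:44), 0.7 ‰ on δ¹⁵Nᵅ (NO⁺ fragment 31:30), 0.5 ‰ on δ¹⁸O. δ¹⁵Nᵝ is
derived as 2·bulk − α and therefore inherits correlated noise with an
empirical SD of √(4·0.5² + 0.7²) ≈ 1.2 ‰ — larger than the 0.7 ‰ a
standards-based figure suggests, but faithful to how per-sample β values are
actually obtained. Substrate δ¹⁸O defaults to 0 ‰ (no measured anchor
exists), so simulated δ¹⁸O magnitudes are arbitrary; only the slope is
meaningful. The two oxygen branch factors default to ε = −25 ‰ (retained)
and −14.8 ‰ (water), whose mean −19.9 ‰ equals the product-δ¹⁸O slope the
closed-form analysis predicts for the branched system. Optional f jitter is
off by default. Not emulated: enzyme kinetics and substrate inhibition,
headspace/liquid partitioning, O exchange with water, drift or non-Gaussian
IRMS error — so passing recovery tests demonstrate statistical correctness
of the estimators under the stated error model, not robustness to every
real-data pathology.

## Known limitations

**Delta-space linearization systematic.** The linearized model is fit, per
standard practice, in delta space against an international reference. For
exact closed-system data the fitted slope is not ε but ε·R_s0/R_std ≈
ε·(1 + δ_s0/1000) to first order — a −4 % scale shrink when δ¹⁵N_s0 =
−40.5 ‰ — plus a smaller (~+0.04 ‰) genuine linearization error. On the
study-like grid the zero-noise round trip returns ε_bulk −8.17 (truth
−8.55), ε_Nᵅ −6.81 (−7.2), ε_Nᵝ −9.52 (−9.9) while the intercept recovers
δ¹⁵N_s0 to 0.04 ‰ (computed by `analysis/05_parameter_recovery.py`). The
offset (≈0.3–0.4 ‰) is smaller than the 0.5–0.7 ‰ single-measurement noise
and well within the ≈1 ‰ standard errors, but it is a bias, not noise: it
depresses one-SE coverage of the true per-site ε from the nominal 68 % to
≈57–58 % over 200 noisy datasets, and reported ε/KIE magnitudes from this
workflow are systematically closer to zero than the underlying
rate-constant ratios whenever the substrate delta is far from the reference.
The package reports what the established workflow defines; it does not
rescale.

**Other limitations.** The dependent variable of the ρ fit (bulk δ¹⁵N) also
feeds the predictor through the ¹⁵N inventory — mirroring the published
estimator, documented rather than "fixed". SE propagation ignores (ρ, τ,
α_bulk) covariances. The δ¹⁸O slope cannot be converted to a KIE without an
independent constraint on the water branch. Mass-overlap (¹⁷O) corrections
are assumed applied upstream of the input CSV; derived β values can
therefore differ from lab-reported ones by a few hundredths ‰.

## Problem sizes

Defaults used throughout: 10 000 simulator steps, 13-observation datasets,
1000 bootstrap resamples, 200 recovery seeds — each stage runs in seconds on
one CPU.
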