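# Methods

## Scope

`poptk` implements a population pharmacokinetic analysis of single-dose
intravenous topiramate in adults on maintenance oral therapy, plus the
evaluation and simulation workflow around it. Because the underlying
trial's concentrations are not deposited, the package is organized around
a synthetic-study generator that reproduces the trial design; all
empirical claims in the test suite are statements about recovering a known
generating model, not about the original data.

## Structural model

A mammillary model with 1–3 compartments, linear elimination from the
central compartment and zero-order input (constant-rate infusion). With
micro constants k10 = CL/V1, k12 = Q2/V1, k21 = Q2/V2, k13 = Q3/V1,
k31 = Q3/V3, the disposition eigenvalues are the roots of the
characteristic cubic (all real and non-negative for a mammillary system);
they are computed in closed form by the trigonometric cubic method, and
the concentration under an infusion of rate R over [0, τ] is

    C(t) = R Σᵢ Aᵢ (1 − e^{−λᵢ·min(t,τ)}) e^{−λᵢ·max(t−τ,0)} / λᵢ,
    Aᵢ = Π(k_peripheral − λᵢ) / (V1 Π_{j≠i}(λⱼ − λᵢ)),

with superposition over dose events. The analytic route is used because
the realistic parameter region is stiff (Q2/V1 ≈ 20 h⁻¹ vs Q3/V3 ≈
0.07 h⁻¹); a Radau ODE integration at rtol 1e-11 is retained purely as a
verification oracle and agrees to better than 1e-6 relative on random
parameter sets spanning a 100-fold range. Numerically coincident
eigenvalues are separated by a 1e-9 relative nudge (the repeated-root set
has measure zero); the λ → 0 limit of the infusion primitive is taken
explicitly, and a singular rate matrix (CL = 0, the mass-balance check)
is handled by an augmented matrix exponential. Terminal half-life is
ln 2 over the smallest-magnitude nonzero disposition eigenvalue, which
reduces to ln2·V/CL in the one-compartment degenerate case. AUC is
integrated analytically term by term; AUC to infinity equals dose/CL.

## Covariates and random effects

Clearances scale as (WT/70)^0.75 and volumes as WT/70 with fixed
exponents. Enzyme-inducing comedication multiplies CL by a factor
θ_ind^IND. Interindividual variability is log-normal,
θᵢ = θ_TV·exp(ηᵢ), on CL, V1 and V2 only, with covariance Ω (free
off-diagonals for the three pairs), reported as %CV = 100·√(e^{ω²}−1).
Residual error is proportional, y = f·(1+ε), ε ~ N(0, σ²); additive and
combined variants are available for error-model comparison.

Two published values required interpretation. (1) The source's running
text gives a central volume of 15.6 L while its table and abstract give
9.84 L; the package uses 9.84 L. (2) The off-diagonal Ω rows (0.06,
0.03, 0.03, printed as "Correlation") cannot be covariances: 0.06 exceeds
√(ω²_CL·ω²_V1) = 0.0585, so the covariance reading implies |r| > 1 and a
non-PSD Ω. They are therefore read as correlations by default; a
`offdiag="covariance"` switch exists and raises on non-PSD input.
(3) The residual row "0.02" is taken as the proportional variance σ².

## Estimation

The marginal likelihood is approximated by the Laplace method with
interaction. Per subject,

    g(η) = Σⱼ [log 2πv_j + (y_j − f_j(η))²/v_j] + ηᵀΩ⁻¹η + log det 2πΩ,
    v_j = σ_add + σ_prop·f_j(η)²  (variance at the individual prediction),

is minimized over η by a damped Gauss–Newton Newton iteration with
backtracking (steps capped at norm 5, η clipped to ±15, per-subject ridge
on ill-scaled blocks), run batched across all subjects and across a batch
of models simultaneously. The objective is

    OFV = Σᵢ [g(η̂ᵢ) − d·log 2π + log det(Hᵢ/2)],

with H either the Gauss–Newton curvature (`laplace_hessian="gn"`, the
default, matching the first-order conditional flavor) or a full
central-difference Hessian (`"fd"`). On a two-subject toy with 1-D
quadrature as oracle both agree with the exact marginal −2 log L to
better than 0.1.

The outer problem optimizes log-transformed fixed effects, the Cholesky
factor of Ω (log diagonal, free off-diagonals) and log residual variances
with L-BFGS-B. Three design choices matter for robustness and are worth
recording:

* The inner problem is re-solved from the same deterministic start
  (η = 0) on every objective call, so OFV(x) is a deterministic,
  history-free function — a requirement of the quasi-Newton line search.
  (A second, NCA-informed inner start was evaluated during development
  and never improved the mode on realistic data, so it was removed.)
* The finite-difference outer gradient is computed in one batched engine
  pass (base model plus one perturbed model per parameter), and all
  perturbed models track the base model's posterior basin. Without basin
  tracking, a subject whose mode flips between adjacent columns corrupts
  a gradient component by (mode gap)/h and stalls the search.
* `ftol` is effectively disabled (1e-12) and convergence is judged by the
  projected gradient alone: an exit with projected gradient below a small
  noise floor (5 OFV units per log-parameter) counts as a successful
  minimization — the analogue of the convergence call in established NLME
  practice — while any exit above it, including the optimizer's own
  "success" after a stalled first line search, triggers up to two
  restarts with an explicit backtracking gradient-descent walk in
  between. The best visited point is always returned.

The batched concentration evaluation — the hot spot of the whole
estimator — has a compiled (numba) scalar kernel alongside the vectorized
numpy implementation; the two are asserted equal to machine precision in
the test suite and the numpy path runs automatically where no compiler is
available.

Initialization defaults are data-informed (median dose/AUC for CL,
dose/Cmax for V1, generic multiples for the peripheral parameters, Ω
diagonal 0.1, σ² 0.04); tests verify a cold start from these heuristics
reaches the same optimum as a start at the generating values. Standard
errors come from the inverse finite-difference Hessian of OFV/2 at the
optimum, delta-methoded to the natural scale; a non-PD Hessian yields a
warning and no SEs, never fabricated ones.

## Covariate selection

Stepwise search with forward inclusion at ΔOFV ≥ 3.84 (χ²₀.₀₅,₁) and
backward elimination at ΔOFV ≥ 6.63 (χ²₀.₀₁,₁). Continuous covariates
(age, CrCL) enter as power functions normalized to the population median;
binary covariates (sex, inducer) as multiplicative factors. Candidates
are screened on CL by default. Candidate fits are warm-started from the
current model; non-convergent candidates are skipped with a warning and
recorded. Ties break by larger ΔOFV, then input order.

## Evaluation

*Bootstrap*: subjects resampled with replacement to the original count,
unstratified; each replicate refit warm-started from the point estimates
(a standard runtime measure; a cold-start refit is a `fit_kwargs` away).
Medians and 2.5/97.5 percentiles are computed over converged replicates
only and the convergence rate is always reported.

*CWRES*: first-order expansion about the empirical Bayes mode η̂ with
interaction variance, V = JΩJᵀ + diag(σ(f̂)); CWRES = V^{−1/2}(y − f̂ + Jη̂).
Approximately N(0,1) under a correct model (verified on self-simulated
data); a tenfold clearance error pushes mean |CWRES| above 2.

*pcVPC*: replicates simulated under the original design; observed and
simulated values rescaled by bin-median population prediction
(pcY = Y·median(PRED_bin)/PRED, no variability correction); default one
bin per nominal sampling time (the design is nominal-time rich sampling),
quantile or explicit-edge binning optional; bins with fewer than two
observations merge into their nearest neighbor with a logged warning.
Bands are 95% CIs across replicates around the 5th/50th/95th percentiles;
stratification by the inducer flag is supported.

## Loading-dose simulation

Weight-based doses (0.5/1/1.5/3 mg/kg, 70 kg reference, 10-min infusion
by default — the duration the study drug was given over, configurable
since the published simulation does not state it). Typical mode is
deterministic (η = 0); Cmax is read at end of infusion, where the
continuous profile of a single zero-order input peaks; AUC is analytic.
Population mode draws η from Ω (and residual error on the output grid),
with per-draw summaries from the noise-free analytic profile. Linearity
gives exact dose-proportionality of Cmax and AUC; induction multiplies CL
only, so the induced:non-induced Cmax ratio is just under 1 (the deficit
is drug eliminated during the 10-minute infusion) while the AUC ratio is
exactly 1/θ_ind.

## Synthetic-study generator

The generator reproduces the trial design: 20 subjects (rich-recovery
variant: configurable N, no missingness), one 25 mg dose infused over
10 min, predose draw (MDV = 1 — the labeled IV analyte is absent before
dosing, so the draw cannot inform the likelihood) plus 12 post-dose
samples at 5/15/30 min and 1, 2, 4, 6, 12, 24, 48, 72, 96 h. Covariates:
7/20 on inducers and 13/20 female as design facts (deterministic counts,
random assignment); weight log-normal with median 85.2 kg and log-SD 0.25
truncated to [54.5, 150.3]; age normal 39.8 (SD 12.1) truncated to
[18, 80]; CrCL log-normal median 107.6, log-SD 0.30, truncated to
[46, 206]. Only medians/means, SDs and ranges are published, so the
log-SDs are emulation choices (picked so the published ranges are
plausible for n = 20), not source claims; no weight–CrCL correlation is
imposed because no joint information is available. Proportional-error
draws that would be negative are redrawn and counted. The study reported
246 analyzable concentrations, slightly more than the 240 the nominal
schedule can yield for 20 subjects, so the exact count is not
reproducible; the default missingness rate is 0 (closest attainable) with
an MCAR rate knob.

What the generator does not emulate: assay-specific noise structure
beyond proportional error, below-limit-of-quantification censoring,
unscheduled or duplicate draws, dropout, or covariate correlations.
Passing recovery tests therefore demonstrate estimator correctness under
the stated design and model, not robustness to those real-data features.

## Problem sizes used in tests and analyses

Recovery and covariate-selection checks use 50-subject rich studies
(better identified than the trial's n = 20, as appropriate for estimator
validation): 5 seeds for the CI-recovery check, 20 replicates for median
bias, 10 seeds for inducer-only selection, 20 replicates × 4 candidates
for the null inclusion rate. The bootstrap check runs 50 replicates on
the 20-subject study (the analysis driver defaults to 200; the study
itself used 1000), and the pcVPC check 200 replicates (1000 in the
driver). These are the package's chosen test scales; the drivers accept
larger counts on the command line.

## Known limitations

* The estimator is a Laplace/FOCE-interaction approximation; its exact
  linearization differs from any particular commercial implementation,
  so OFV values are comparable within this package only.
* Individual V1 is weakly identified under this design (very fast shallow
  distribution): its η shows large shrinkage (~50%) in simulated studies
  even where CL shrinkage is ~2%, and its IIV estimate is accordingly
  unstable. The source reports 1.5% shrinkage for V1 on the real data;
  that cannot be checked without the data.
* One dose series per subject (no steady-state or ADDL codes), no
  inter-occasion variability, no BLQ likelihood (M3), linear elimination
  only.
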