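# Methods

## Structural and statistical model

Teicoplanin disposition is modeled as a single well-stirred compartment
with first-order elimination and zero-order (constant-rate) infusion
input.  For a dose of amount D infused over T hours starting at time s,
the concentration contribution at elapsed time τ = t − s is

    C(τ) = (R/CL)·(1 − e^{−ke·te})·e^{−ke·(τ − te)},   R = D/T,
    te = min(τ, T),  ke = CL/V,

and profiles superpose linearly across doses.  Interval AUCs are exact
antiderivatives of this expression, split at infusion boundaries; no
quadrature is used in the production path.  Evaluation exactly at a dose
start time excludes that dose, so values at scheduled dose times are
pre-dose troughs (C72h, C168h denote the troughs at 72 h and 168 h after
the first dose).

Individual parameters are typical values scaled by covariate effects and
subject-level random effects η ~ N(0, ω²), diagonal across CL and V.
Categorical covariates (0/1) act as exp(θ·x); continuous covariates act
as median-normalized powers (x/median)^θ.  The default between-subject
model is exponential (log-normal parameters), matching the final
published model's form; an additive η model is available by
configuration (`bsv="additive"`) because the study's model-building
narrative describes the additive form.  Residual error is additive by
default (σ = 0.23 mg/L per the published estimate) with proportional,
mixed, and power alternatives implemented.  The additive magnitude is
strikingly small relative to observed troughs (~13 mg/L); we carry it
at face value, and the residual configuration allows reinterpreting the
value as a proportional fraction if desired.

## Estimation (FOCE-I)

For each subject the conditional mode η̂ of the joint density is found
by a damped Gauss–Newton iteration (start 0, gradient tolerance 1e−7
relative, vectorized across subjects); Jacobians of the prediction in η
come from complex-step differentiation of the closed-form kinetics and
are exact to machine precision.  The prediction is linearized at η̂ and
the subject's marginal contribution is

    OFV_i = n_i·log 2π + log|C_i| + r_i' C_i^{-1} r_i,
    C_i = G_i Ω G_i' + Σ_i(f_i(η̂)),   r_i = y_i − f_i(η̂) + G_i η̂,

with the residual variance Σ evaluated at the individual prediction
(the interaction term).  The determinant and quadratic form use the
matrix-determinant lemma and Woodbury identity so the per-subject cost
is O(m·k²) rather than O(m³).  The outer problem minimizes the total
OFV over typical values, covariate coefficients, ω² and σ, all positive
parameters on the log scale, by L-BFGS-B with finite-difference
gradients (relative tolerance 1e−8 on the objective, fallback
Nelder–Mead polish); warm-starting the inner modes across outer
iterations makes the objective smooth to the optimizer.  Exact zero
variances are handled by dropping the corresponding η dimension, never
by boundary estimation.  Standard errors come from the observed
information (central-difference Hessian of the OFV; covariance
2·H^{-1}), mapped to the natural scale by the delta method;
RSE% = 100·SE/|estimate|.

Correctness anchors: the no-BSV, zero-residual OFV reduces to the
Gaussian closed form; FOCE-I agrees with an adaptive Gauss–Hermite
quadrature oracle (32 nodes per η dimension, independent implementation
in `teicopk.reference`) to within 0.5 OFV units on small cohorts; and
CWRES — the Cholesky-decorrelated linearized residuals — are standard
normal under the generating model.

## Covariate search

Forward inclusion adds the candidate with the largest OFV drop among
those exceeding 3.84 (χ²₁, p < 0.05, strict inequality); backward
elimination removes, least-significant first, any retained effect whose
removal costs ≤ 6.63 (an effect must exceed 6.63 to stay, p < 0.01).
Each candidate carries one coefficient, so 1 df is hard-wired.  Ties
break alphabetically by covariate then parameter.  Continuous references
are dataset medians computed once from the base data.  Initial
coefficients are 0.1 (power) and 0.01 (exponential) — mild
perturbations that avoid sign lock-in.  Candidates are tested on both
CL and V.  Converged estimates are carried forward as initial values
through the search.

## Synthetic cohorts

The patient-level data behind the model are not publicly deposited, so
a generator emulates the study design.  Defaults: 86 septic adults,
40.70% female, 23.26% on CRRT, 4.65% on ECMO (ECMO is carried as a
cohort field only, never modeled); continuous covariates are log-normal
matched to the published median/IQR (age 62 y, weight 62 kg, height
165 cm, albumin 31.6 g/L, serum creatinine 109 µmol/L — the published
table's albumin/creatinine unit labels are internally inconsistent and
we follow the g/L and µmol/L reading supported by the text); ages are
truncated at 18 by resampling.  Stratum counts are exact:
round(n·fraction) with half rounding to the larger stratum, assignment
randomized.  Dosing: 400 mg q12h for three loading doses (t = 0, 12,
24 h) then 400 mg q24h from 48 h, 1-h infusions.  The default sampling
design is one trough per subject, placed exactly at the scheduled dose
time (pre-dose) on a uniformly drawn day 4–7 — the study reports
exactly one steady-state trough per patient, "within 30 min preceding a
dose"; we collapse that window to 0 for determinism.  Because one
sample per subject weakly identifies the variance components, a rich
design (8 samples at 1, 2, 6, 12, 24, 48, 96, 168 h) is provided for
estimation work; all estimation-oriented tests use it.

What the generator does not emulate: LOQ censoring (none reported),
missing covariates, assay-specific error beyond the residual model,
CRRT modality/intensity differences, or time-varying covariates.
Passing tests therefore demonstrate the correctness of the machinery on
data satisfying the model's assumptions, not the clinical adequacy of
the model for any real cohort.

## Dosing simulation and PTA

Virtual groups fix sex and CRRT status (male/noCRRT, male/CRRT,
female/noCRRT; female/CRRT was not simulated in the study).  Per
scenario, n = 1,000 subjects draw η from the BSV distribution; metrics
are individual-predicted (residual error excluded, standard PTA
practice).  The regimen grid covers loading 600–1,200 mg q12h for 3 or
5 doses with daily maintenance 200–1,000 mg in 200-mg steps (the study
states the ranges; the step is ours), plus continuation regimens
400–1,000 mg q12h and 1,000–1,800 mg qd.  Maintenance starts one
maintenance interval after the last loading dose (q12h×3 → first
maintenance at 48 h); the study never states the switch time, and the
convention is configurable.  Targets: trough ≥ 10 mg/L; AUC24/MIC ≥ 400
(default, used by the study's results narrative) with 345 also
supported; toxicity is flagged as troughs > 60 mg/L.  Scenario seeds
derive deterministically from a root seed, giving common random numbers
across regimens.  "Overall" PTA for male regimens pools the two male
strata with equal weight, the reading under which the published
70–80% band is reproduced.

## Numerical choices and degenerate inputs

Time is continuous in hours, zero-based at the first dose.  Complex-step
size 1e−100 (no subtractive cancellation).  Observations at a dose time
sort before the dose (pre-dose).  Negative simulated concentrations
truncate at 0.  Non-converged bootstrap resamples are dropped and
counted; fewer than 50% converged is a hard failure.  Empty VPC bins
merge via unique quantile edges.  A subject whose inner line search
cannot improve to double precision is treated as converged.  Datasets
with one observation per subject and ≥2 free variance components
trigger an identifiability warning; fitted variances below 1e−6 are
flagged as boundary collapses.

## Problem sizes in the test suite

The acceptance-style tests scale Monte Carlo sizes to keep the suite
fast while preserving each assertion: oracle agreement on 100 random
schedules; FOCE vs quadrature on 50 cohorts of ≤10 subjects; parameter
recovery on 20 cohorts of 200×8 (fixed effects within 10%, variances
within 30% on the median); covariate-structure recovery on 3 cohorts of
86×8 (majority retain exactly CRRT-on-V and sex-on-V) with the null
false-inclusion rate over 100 replicates of 40-subject cohorts;
PTA targets at n = 1,000 per scenario judged within 3 binomial standard
errors; bootstrap coverage with 100 resamples × 3 cohorts and pc-VPC
self-consistency over 10 fit+check replicates (4 bins, 200 simulation
replicates each).

## Known limitations

The FOCE linearization degrades when between-subject variability is
large and data are very sparse; with the study's own one-trough design
the three variance components are jointly weakly identified (the
package warns, and rich sampling is used for estimation tests).
Estimator bias for tvCL under the sparse 86×1 design is documented
behavior, not asserted.  Off-diagonal Ω, inter-occasion variability,
SAEM-type estimators, two-compartment structures, LOQ likelihoods and
MIC-distribution (CFR) weighting are out of scope.
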