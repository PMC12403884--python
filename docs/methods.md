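# Methods

## Data model and estimands

A panel holds n subjects over K treatment periods (default K = 3): binary
treatment A_t, binary instrument Z_t, numeric confounders L_t (p per period,
possibly none), and one continuous end-of-study outcome Y observed at
T = K + 1. Period indexing is 1-based. Estimation is complete-case by design:
rows with missing required values are rejected at read time with a reported
count, and no imputation is offered — constructing an instrument from imputed
values has little precedent and is deliberately unsupported.

The estimand is the average treatment effect of sustained treatment,
ATE = E[Y(1,…,1) − Y(0,…,0)]. Both estimators parameterise per-period effects
β_t whose sum is the ATE; this equivalence rests on a *no current treatment
interaction* assumption (the per-period shift is the same in treated and
untreated subjects), which holds when the outcome is linear in treatment
without interactions.

Instrument validity requires, beyond relevance: conditional exchangeability
of Z_t given the history M_t = (Ā_{t−1}, Z̄_{t−1}) (optionally augmented with
a chosen subset of confounder history L̄_t — the "adjusted" analysis), and the
exclusion restriction (Z_t reaches Y only through treatment). Only relevance
is testable; the diagnostics module addresses it.

## Nuisance models

All conditional probabilities are main-effects logistic regressions:
P(Z_t | M_t) for the instrument, P(A_t | Z_t, M_t, L̄_t) for the treatment,
plus the two stabiliser models (treatment on Ā_{t−1} alone, and on
(Z_t, Ā_{t−1})). At t = 1 with the minimal history the instrument model is
intercept-only and the fitted probability is the sample mean. Designs only
ever use variables with time index ≤ t (strictly < t for the instrument
model's history).

Fitting is by Newton–Raphson with a convergence tolerance of 1e−8 (max Newton
step) and a 100-iteration cap. The solver is a small vectorised routine
rather than a general GLM stack because the simulation studies and bootstrap
refit these models on the order of 10⁵–10⁶ times; its coefficients and fitted
probabilities are cross-checked against statsmodels GLM to 1e−6 in the test
suite. Constant responses, singular information matrices and (quasi-)
separation raise a degenerate-fit error naming the period — there is no
silent penalised fallback, so the estimand is never quietly changed. Note the
simulated treatment mechanism is a probit mixture, so the logistic treatment
model is an approximation even with the right covariates; empirically the
implied compliance differences average to the mechanism's constant Δ_t.

The compliance difference Δ_t = P_{A_t}(a_t | Z_t=1, ·) − P_{A_t}(a_t | Z_t=0, ·)
is computed from the fitted treatment model by predicting under both
instrument values and evaluating the pmf at the observed treatment, so its
sign flips with a_t. Three modes exist:

- `subject` (default): per-subject differences — appropriate for real data,
  where compliance varies with covariates;
- `constant`: the per-period average of P(A=1|Z=1) − P(A=1|Z=0), applied with
  the observed-treatment sign — the faithful operationalisation when the
  mechanism's compliance difference is a per-period constant, as in the
  simulation study (which uses this mode). At n = 10⁴ with a strong
  instrument, subject-mode weights carry a small finite-sample bias (≈ +0.03
  on an ATE of 5) that constant mode removes;
- a `known_delta` plug-in that bypasses Δ estimation entirely (sensitivity
  switch; also the only sound option when A ≡ Z, where the treatment model
  separates).

Subjects with |Δ_t| below 1e−6 trigger an instability warning carrying the
count; these feed the weighting estimator's non-convergence accounting.

## IV g-estimation (SNMM)

H₁ = Y − Σ_t β_t A_t estimates the counterfactual under no treatment; the
estimating equations Σ_i H₁ᵢ (Z_tᵢ − Ê[Z_tᵢ|M_tᵢ]) = 0 are solved exactly as
β̂ = (RᵀA)⁻¹ RᵀY with R = Z − Ê(Z). The solve is refused (weak/degenerate
instrument error naming the weakest periods) when cond(AᵀR) exceeds 1e12 —
an explicit failure is preferred to a silent pseudo-inverse. At the solution
the estimating-equation residuals are verified to vanish to 1e−8·‖Y‖. No
small-sample correction is applied; inference is bootstrap-only.

## IV weighting (MSM)

Per-period weights W_t = (−1)^{1−Z_t} P_{Z_t}(Z_t|M_t) Δ_t multiply into
subject weights W̄ᵢ; these are centred around zero and legitimately negative
(a subject treated "with" the instrument's push gets positive weight), so no
positivity check applies. With h(A) = (1, A) the estimating equations reduce
to WLS with per-subject weight 1/W̄ᵢ: β̂ = (A'ᵀDA')⁻¹A'ᵀDY, D = diag(1/W̄ᵢ).

Stabilisers divide W_t by either P(A_t | Ā_{t−1}) (standard) or the
history-only compliance difference Δ_t^Stab = P(A_t=1|Z_t=1,Ā_{t−1}) −
P(A_t=1|Z_t=0,Ā_{t−1}) (delta). The delta divisor is deliberately the
*unsigned* success-probability difference: dividing by an observed-treatment-
signed version would cancel the weights' sign structure and destroy the
estimating equations (verified numerically — the estimator collapses to ≈3
instead of 5 on strong-instrument data). With the unsigned divisor all three
stabilisation choices agree closely in large samples, as expected.

Trimming caps the **product** weights at the Tukey fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR]; the product is what enters estimation, so that
is the level trimmed by default (a per-period option exists). Quantiles use
linear interpolation between order statistics (the common "type 7" rule) —
fences depend on this convention, so it is fixed and tested against a
brute-force oracle. Trimming is idempotent.

Non-convergence is operational: a numerically zero product weight, a singular
weighted normal matrix (condition number > 1e12), or stabiliser values below
1e−6 in magnitude. Such fits raise; in the scenario runner they are counted
as failed replicates.

## Inference

Nonparametric bootstrap resamples **subjects** (whole trajectories), since
confounding and weights are subject-level; all nuisance models and the
estimator are refitted per resample. Failed resamples (separation, singular
solves at weak instruments) are excluded from the percentile computation but
counted and reported — more than 50% failures raises an inference error.
Percentile intervals take the 2.5th/97.5th type-7 percentiles of the ordered
draws. No BCa or studentised intervals.

## Simulation mechanism

Defaults (all configurable): per period t = 1..K with baseline Z₀ = A₀ = 0,

- logit P(Z_t=1|Z_{t−1},A_{t−1}) = σ₀ + σ₁Z_{t−1} + σ₂A_{t−1}, σ = (0, 0.5, 0);
- L_t = λ₀ + λ₁A_{t−1} + λ₂U_t, λ = (1, 1, 0.33), U_t iid N(0, 1) unobserved;
- P(A_t=1|·) = Φ(μ₀+μ₁L_t+μ₂U_t+μ₃A_{t−1}+μ₄Z_{t−1})(1−Δ_t) + Z_tΔ_t,
  μ = (−0.2, 0.2, 0.2, 0, 0), Δ_t = Φ(α_t);
- Y = Σβ_U,tU_t + Σβ_L,tL_t + Σβ_A,tA_t + ε, β_U = (⅓,⅓,⅓),
  β_L = β_A = (1,1,1), ε ~ N(0,1).

The mixture form makes the compliance difference exactly Δ_t in every
stratum, so α dials instrument strength directly: α ∈ {−1.2, −0.5, 0, 0.5}
gives Δ ≈ {0.1, 0.3, 0.5, 0.7}, and Δ approximates the Z_t–A_t correlation.
Treatment reaches the outcome directly and through the next period's
confounder only, so the per-period total effect is β_A,t + λ₁β_L,t+1 (last
period β_A,K): (2, 2, 1) under the defaults, ATE 5. Random draws are made in
a fixed order regardless of treatment forcing, so forced-regime contrasts
share common random numbers; because the outcome is linear, the
interventional contrast is then noiseless and equals the analytic path sum
exactly.

The distribution of U_t is not pinned down by the study the defaults emulate;
iid standard normal is the documented choice (scale configurable via
`u_scale`). This matters: reproduced estimator variances are internally
consistent across estimators and sample sizes but uniformly ≈ 27% smaller in
sd than the reference table values, a pattern consistent with the reference
simulation using heavier unobserved-confounder noise. The reproduced
RMSE at n = 1000 with a strong instrument is ≈ 0.225 against a reference
0.286; bias and coverage reproduce regardless. The defaults were not adjusted
to chase the table values.

What the generator does not emulate: missing data, informative dropout,
calendar-time effects, survival outcomes, continuous instruments, and
feedback from confounders into later confounders (the richer dependence
structure is representable only through the existing coefficients). Passing
tests therefore demonstrate correctness of the estimators under clean
complete-case conditions with a correctly chosen conditioning set, not
robustness to misspecification.

## Scenario runner

Each replicate r of a scenario derives a child seed from (master seed, r) via
`numpy.random.SeedSequence`, making results bit-reproducible under any
execution order. Per replicate: simulate, estimate, optionally bootstrap.
The per-dataset ATE summary is the mean over bootstrap draws when a bootstrap
is run (the reference tables' convention) or the plug-in estimate otherwise
(both are available as a flag; they differ negligibly — ≈ 0.002 at n = 10⁴).
Metrics: bias = mean − truth, RMSE, MCE = sd/√m (the convention that matches
the reference tables' own MCE entries, e.g. 0.122/√1000 ≈ 0.004), and
percentile-CI coverage. Replicates with extreme ATEs (outside the Tukey
fences of the replicate distribution) are filtered before summarising —
always for the weighting estimator, whose weak-instrument failure mode
produces exploding estimates, and only upon observed instability for
g-estimation ("auto" policy; both behaviours can be forced).

Problem sizes used by the reproduction suite: bias/RMSE scenarios run the
full m = 1000 replicates without bootstrap; coverage scenarios run at
m = 250/b = 250 (strong instrument) and m = 200/b = 200 (weak), with
binomially widened tolerances. The acceptance script's interventional truth
uses n = 10⁶.

## Preference-based instruments

From prescription records (prescriber, calendar phase, drug), three
dichotomisations of prescriber preference are built per patient-period, each
using the prescriber's whole history up to the phase by default (a
current-phase-only variant is a flag): proportion-above-median (strictly
above the median of prescribers' target-drug proportions in that phase;
exactly at the median gives 0), modal drug (ties resolve in favour of the
target drug), and last prescription (within a phase, the later record wins).
Prescribers with no prescriptions in the relevant history are excluded from
the phase median, and patient-periods without linked prescriber history are
excluded with a reported count — mirroring complete-case handling of subjects
lacking physician information. All tie-breaks are deterministic and tested.

## Known limitations

- Binary treatment and instrument only; continuous instruments would require
  a different weighting construction (g-estimation could accommodate them,
  but this implementation does not).
- The conditional F-statistic follows the Sanderson–Windmeijer construction
  (partial out the other treatment periods via their instrument-fitted
  values; joint F of the instruments on the residual; numerator df
  kz − kx + 1). Its weak-instrument threshold of 10 is reported as a flag,
  not enforced; substantially higher values may be needed in practice.
- Weight trimming is ad hoc: it tames a few extreme weights but is known to
  be ineffective under genuinely weak instruments, and introduces its own
  bias by distorting the pseudo-population.
- Bootstrap failure exclusion interacts with weak-instrument overcoverage:
  when many resamples fail, the reported interval is conditional on the
  converged subset, and the failure count should be read alongside it.
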