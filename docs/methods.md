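# Methods

## Scope

`pdmorph` analyses longitudinal regional brain morphometry — volumes
(cm³), planar areas (mm²) and cortical thickness (mm) — in a three-group
observational cohort: healthy controls (CTRL), Parkinson's disease with
normal cognition (PD-N) and PD with cognitive impairment (PD-CI, pooling
MCI and dementia).  It implements the tabular-data stages only: inputs
are already-extracted per-visit regional measurements in a long-format
TSV.  Image processing (segmentation, atlas masking, surface
reconstruction, vertex-wise statistics) is out of scope.

## Normalization and covariate correction

Regional volumes are reference-normalized to head size,

    V_norm = V / V_icv(subject) * mean(V_icv),

where the cohort mean intracranial volume is taken over the baseline
visits of the whole study population.  Regional cortical thickness is
normalized the same way with the subject's mean cortical thickness as
the reference.  A subject's reference is treated as time-constant:
follow-up visits reuse the baseline value.  (ICV genuinely is constant;
for thickness this is a modelling choice that keeps the subject
reference independent of follow-up noise.)  Mean cortical thickness
itself, when analysed as an outcome, cannot be normalized to itself and
is used on its native scale.

Normalized values are adjusted for age and education with per-region
slopes γ̂₁ (per year of age) and γ̂₂ (per year of education) estimated by
OLS **on baseline controls only**, then recentred at the baseline cohort
means:

    V_corr = V_norm − γ̂₁ (age − mean_age) − γ̂₂ (edu − mean_edu).

The slopes are never refitted on follow-up data.  Correction is linear,
so it commutes with hemisphere averaging; it is not idempotent, so
tables carry provenance flags (`normalized`, `corrected`) and a second
application raises.  Whether the visit-specific or the baseline age
enters the correction is not determined by the source analyses; both are
implemented, with visit age as default.  An optional male-indicator
covariate is available for the mean-thickness model only.

## Exploratory smoothing (LOWESS)

Cleveland's robust locally weighted regression with the settings used
throughout: window fraction f = 0.8 (q = ⌈f·n⌉ nearest neighbours, ties
included), local degree d = 1, tricube kernel scaled by the distance to
the farthest neighbour, and t = 2 bisquare robustness iterations with
the conventional 6×median-|residual| scale.  The description of the
window as "fixed width" conflicts with the fraction definition also
given; the fraction definition is followed.  Evaluation is at the
observed abscissae by default (a uniform grid is available for
plotting).  Replicated x with zero neighbourhood radius collapse to
uniform weights over the replicates; windows with too few distinct
points reduce the local degree to what is estimable.  No confidence
bands are produced — inference belongs to the mixed model.

## The linear mixed-effect model

Per region k the outcome of subject i across its m_i visits is

    y_i = X_i β + Z_i b_i + ε_i,   b_i ~ N(0, Ψ),   ε_i ~ N(0, σ² I),

with the eight fixed-effect columns in fixed order: intercept, time from
baseline t (years), PD-N indicator G1, t·G1, PD-CI indicator G2, t·G2,
piecewise age, education (years).  Controls are the reference group, so
β₁, β₁+β₃ and β₁+β₅ are the atrophy rates (units/year) of controls, PD-N
and PD-CI.  The random design Z_i = [1, t] has an unstructured 2×2
covariance Ψ (compound symmetry deliberately not assumed).  Group
membership is frozen at baseline; cognitive status per visit is kept
separately and used only for converter labelling.

The piecewise age term is max(age − knot, 0) with knot = 60 years,
encoding negligible cross-sectional aging effects below 60 and a linear
effect above.  By default the **enrollment** age is pushed through the
transform at every visit (the within-subject passage of time is already
carried by t); a time-varying-age option exists.

### Estimation

Estimation is REML (the standard unbiased-variance-component criterion;
ML is not offered).  The relative covariance G = Ψ/σ² is parametrized by
its Cholesky factor with non-negative diagonal — boundary fits (zero
variance components) are representable, reported via a `boundary` flag,
and never silently shifted.  σ² and β are profiled out analytically, and
the 3-parameter profiled objective is minimized by L-BFGS-B from a
method-of-moments start (per-subject OLS intercept/slope covariance
minus the average noise inflation, projected to PSD).  A derivative-free
simplex polish handles the rare abnormal terminations at the variance
boundary.  The fit is deterministic given the data; no seeds are
involved.

Subjects sharing a visit-time vector share V_i = σ²(I + Z G Zᵀ), so the
likelihood is evaluated per time-pattern with batched dense algebra.
With a fixed visit schedule and monotone drop-out there are at most as
many patterns as visits, and one fit costs milliseconds — which is what
makes the 2000-replicate calibration experiments below routine.

Numerical notes: noise-free data (zero residual after the GLS solve)
make the REML surface flat in the variance parameters; this degenerate
case is detected and the fit is returned at Ψ = 0 with an exact-fit tag
rather than letting the optimizer wander on a flat objective.
Rank-deficient fixed designs fall back to minimum-norm GLS.  A
"final gradient norm" criterion is not meaningful for a profiled
objective of magnitude O(10²–10³) under finite-difference derivatives;
convergence is instead asserted (and property-tested) as local
optimality: no perturbation of the variance parameters lowers the
objective.

### Hypothesis testing

Equality of atrophy rates across the three groups is H₀: β₃ = β₅ = 0,
tested with

    F = (Lβ̂)ᵀ (L Cov(β̂) Lᵀ)⁻¹ (Lβ̂) / rank(L),   DF₁ = rank(L) = 2.

The denominator df is the decisive design choice.  The residual rule
DF₂ = N_obs − 8 is offered but is **not** the default: a 2000-replicate
null calibration at 60 subjects under the study's attrition gave a 7.7%
type-I rate at α = .05 with residual df — the slope contrast draws its
information from the subset of subjects with ≥ 2 visits, so N_obs − 8 is
far too large.  The default is a Satterthwaite approximation
(Fai–Cornelius: spectral decomposition of L Cov(β̂) Lᵀ, per-component df
from the delta method against the observed REML information, computed by
finite differences), which calibrated to 6.0% (median DF₂ ≈ 29) in the
same experiment.  The report records which method produced each row.

## Cross-sectional battery

Welch's unequal-variance t (computable from printed summary statistics,
which is how the reported demographic t values are reproduced), Pearson
χ² **without** continuity correction (the uncorrected statistic is what
matches the reported categorical values exactly), two-sided Fisher's
exact for 2×2 tables (reported alongside χ², since the source tables
describe the test as Fisher's exact while printing χ² statistics — an
inconsistency we report rather than resolve), Kruskal–Wallis with
mid-rank ties and the χ² approximation, Spearman rank correlation, and
Bonferroni control (min(1, p·m), family = all p-values of one report
table unless overridden; m is logged).

The Lilliefors normality test uses the KS distance against a normal with
estimated mean/SD and a seeded Monte-Carlo null (default 10,000
simulated samples, vectorized) instead of lookup tables — reproducible
and free of interpolation error.  In the baseline report it acts as a
gate: regions failing normality in any group switch from Welch t to the
rank test for that region, and the switch is logged.  Note the test's
power is modest: against uniform data at n = 100 it rejects at the 1%
level only ~a third of the time (the table-based implementation in
statsmodels agrees), so the gate mostly catches gross departures.

## Synthetic cohort generator

The generator emulates the study conditions and is the test bed for
every downstream stage.  Defaults **are** those conditions: group sizes
85/80/92 (CTRL/PD-N/PD-CI), visit schedule 0, 1.1, 2.4, 3.2, 3.9 years,
per-group cumulative retention taken from the observed attrition schedule
(pooled PD: 75%, 31%, 20%, 5% at follow-ups 1–4), truncated-normal ages
(group means 65.1/65.9/68.9, bounds 45–80 y), education 16.1/13.8/13.0 y,
sex ratios from the baseline table, ICV ~ N(1459.3, 130²) cm³.  Regional
trajectories follow exactly the mixed model above; headline defaults
give mean-thickness thinning of 7.3 (controls), 28 (PD-N) and 2 (PD-CI)
μm/year and whole-brain volume loss ~5 cm³/year above age 60 — i.e. the
reported effect landscape, so "null" and "planted-effect" experiments
are departures from a realistic baseline.

Magnitudes the source never states — random-effect and residual SDs —
were fixed once at values that make trajectories look like the observed
spaghetti plots: volumes with between-subject SD ~3% of level, slope SD
~0.1–0.3% of level per year, residual ~0.3–0.5% of level.  Thickness
regions are generated on the **ratio-normalized** scale, where the
between-subject SD is much smaller than raw ROI thickness SDs because
the normalization removes global thickness variation; the default is
0.06 mm (~2.4% of a 2.55 mm level) with 0.03 mm residual.  Mean cortical
thickness, analysed unnormalized, keeps a raw-scale 0.10 mm SD.

Drop-out is monotone by construction (one uniform draw per subject
against the non-increasing cumulative retention), independent of the
outcomes — the missing-completely-at-random assumption implicit in the
mixed model.  An outcome-dependent mode (faster decliners leave earlier,
latent correlation 0.5) exists for sensitivity probes and is off by
default.  Visit-time jitter (uniform ±0.15 y) is likewise available and
off by default so exact-pattern tests stay exact.  One PRNG stream per
cohort, seeded explicitly; identical (config, seed) give byte-identical
tables.

The converter scenario splits cognitively normal PD subjects with
follow-up into future converters (cPD-N, default fraction 26/68) and
stable nonconverters (nPD-N), scales the converters' values in one
thickness region by (1 + δ) at every visit (δ = −3% by default), assigns
MCI status from the conversion visit onward so the labelling operation
recovers the planted arms exactly, and can couple a cognitive score to
the thinned region at a target Spearman correlation (default 0.4) via
the bivariate-normal rank-correlation identity ρ_P = 2 sin(πρ_S/6).

What the generator does **not** emulate: site effects and scanner
differences, outcome-dependent attrition (by default), measurement-error
heteroscedasticity, diagnostic misclassification, and any spatial
correlation across regions (regions are generated independently given
the covariates).  Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to these real-data
complications.

## Problem sizes in the validation suite

The simulation experiments run at the sizes that make their claims
meaningful: parameter recovery and Wald coverage over 200 cohorts of 200
subjects; null calibration of the contrast F-test over 2000 cohorts of
60 subjects; attrition over 100 cohorts of 172 patients; the converter
scenario over 100 full-size cohorts.  Coverage is pooled over the three
slope parameters (600 intervals) for a usefully tight Monte-Carlo SE.

## Known limitations

* The Satterthwaite df uses finite-difference derivatives of the REML
  objective; with near-singular information matrices it falls back to
  residual df.
* Welch post hocs after a Kruskal–Wallis omnibus mix a rank-based gate
  with mean-based pairwise tests; this mirrors the source procedure and
  is kept for comparability.
* The baseline Δ% summaries are computed from covariate-corrected group
  means; corrected values can in principle be negative for small
  structures, in which case percent deviations lose interpretability.
* Missing region cells are handled complete-case per region; no
  imputation is offered.
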