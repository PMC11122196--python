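# Methods

## Scope

`riftrace` models the time course of radiation-induced γ-H2AX + 53BP1 foci
(RIF) in peripheral blood mononuclear cells during radioiodine therapy, where
damage induction by the circulating and whole-body ¹³¹I activity competes
with DNA repair for days. It covers blood-based internal dosimetry, the
compartmental foci model, per-patient and pooled estimation, cohort
statistics, and a synthetic-cohort generator. Wet-lab concerns (cell
isolation, staining, microscopy scoring) and image-based measurement
acquisition are out of scope; focus counts and activity measurements are
inputs.

## Dosimetry

Measured time–activity curves are decay-inclusive. Bi-exponential fits
estimate decay-inclusive rates; the stored biological rates are those minus
the physical decay constant `l_phys` (default ln 2 / 8.02 d = 0.00360 h⁻¹ for
¹³¹I), which is composed back in at evaluation time. This keeps `l_phys` a
single configurable constant. A fitted decay-inclusive rate below `l_phys`
(apparent super-physical retention, possible with noisy data) is clamped to
zero biological clearance and logged, never silently accepted.

The absorbed dose rate to the blood is the sum of a β self-irradiation term
driven by the blood activity concentration (fraction of administered activity
per mL) and a γ term driven by the whole-body retention scaled by
`wt^(−2/3)`. The two coefficients `Dk_β` (Gy·mL·GBq⁻¹·h⁻¹) and `Dk_γ`
(Gy·kg^(2/3)·GBq⁻¹·h⁻¹) are **required configuration**: they belong to the
standard blood/bone-marrow dosimetry protocol for thyroid cancer, not to this
package, and the shipped `example_config.yaml` transcribes those standard
values (108 and 0.0188). Nothing in the test suite depends on these
constants. Internal arithmetic is Gy and hours with a single conversion
layer; reported doses are mGy, dose rates mGy/h, matching `c` in mGy⁻¹.

Cumulative dose uses the closed-form integral; the `λ → 0` degenerate term
switches to its analytic limit `a·t` when `|λ|·t < 10⁻⁸` for numerical
stability. Bi-exponential fitting uses a deterministic multi-start over a
log-spaced grid of rate pairs, so dosimetry is seed-free. Fits are
unweighted by default (measurement uncertainties for activity data are often
nominal); a weighted option exists.

Curves with renewed uptake cannot be described by one bi-exponential. The
piecewise evaluator fits bi-exponentially up to a chosen breakpoint and
completes the integral section by section: trapezoid integration of the
measured normalized values between samples and a pure physical-decay tail
beyond the last sample. The tail assumes no further biological clearance,
which is deliberately conservative (it can only overestimate the remaining
dose); on model-true data sampled out to 720 h the piecewise total agrees
with the closed form to about 1%.

## Foci kinetics

Induction is proportional to the absorbed dose rate with constant `c`
(foci·cell⁻¹·mGy⁻¹). Repair is first-order with two pools: a fraction `α` of
the induced damage enters a fast pool (rate `k₁`), the remainder a slow pool
(`k₂`), both starting empty:

    dN₁/dt = −k₁·N₁ + α·c·dD/dt
    dN₂/dt = −k₂·N₂ + (1−α)·c·dD/dt,     N(t) = N₁(t) + N₂(t) + N₀

The intercept `N₀` accounts for the uncertainty of the baseline-subtracted
count at t = 0; it is a pure offset, not an initial pool content. With a
bi-exponential dose rate each pool integrates to a weighted sum of terms
`(e^(−λt) − e^(−kt))/(k − λ)`; when `|k − λ| < 10⁻⁹` the analytic limit
`t·e^(−λt)` is used, so near-degenerate repair/clearance rates never divide
by ~0. The closed form is verified against high-accuracy numerical
integration of the ODE system (LSODA, rtol 10⁻¹⁰) to below 10⁻⁶ foci/cell
over random parameters including forced degeneracies. The ODE path also
serves as the evaluator for non-exponential dose-rate inputs (piecewise
dosimetry).

Labels are made unique by the convention `k₁ ≥ k₂`: a fitted parameter
vector violating it is relabelled by swapping `(k₁, α) ↔ (k₂, 1−α)`, which
leaves the model function unchanged.

A caution on `time_of_max`: with two pools the foci curve can be bimodal —
when fast repair strongly outpaces induction, the late slow-pool hump can
exceed the early fast peak. The maximizer brackets sign changes of the
analytic derivative on a dense grid over [0, 500 h] and refines each with
Brent's method, then takes the global maximum, so it reports the true peak
either way.

## Counting statistics

Focus counts are treated as Poisson. A RIF value is the difference of two
per-cell rates (sample minus pre-therapy baseline); its variance is the sum
of the two propagated count variances. A zero count contributes a floor
variance of one count so no data point acquires infinite weight. Negative
RIF values are legal data — late samples routinely fluctuate below the
baseline — and are never clipped.

## Fitting protocol

Per-patient estimation minimizes the weighted residual sum of squares
(weights 1/σ²) over `(c, α, k₁, k₂, N₀)` with bounds `c ≥ 0`, `α ∈ [0, 1]`,
`k₁, k₂ ≥ 0` and `N₀` within ± the baseline point's propagated uncertainty —
the intercept may not wander outside what the pre-therapy measurement allows.
The solver is scipy's bounded trust-region-reflective least squares run to a
χ² tolerance of 10⁻⁹ (the classic Levenberg–Marquardt implementation does
not accept bounds; at a common optimum in the interior the two coincide).
Starting values come from a fixed grid — `c ∈ {0.01, 0.03, 0.1}`,
`k₁ ∈ {0.2, 0.5, 1.5}`, `k₂ ∈ {0.001, 0.01, 0.05}`, `α ∈ {0.9, 0.99}`,
`N₀ = 0` — the best χ² wins and near-ties resolve to the smaller `k₁`, so
fitting is deterministic. Standard errors come from the inverse of the
weighted `JᵀJ` at the optimum scaled by the reduced χ²; `r²` is
`1 − SS_res/SS_tot` on weighted residuals.

The baseline point defines zero and is not a residual, but it counts toward
the data-point rule: a full schedule is 8 post-administration samples plus
the baseline, 9 points. Fitting requires at least 8 — one missing sample is
tolerated, two are not (`too-few-points`). After fitting, a standard error
exceeding twice the parameter's value for `c` or `k₁` excludes the patient
(`large-errors`); the set of checked parameters is configurable. Pooled
fits share one parameter vector across patients, every residual evaluated
with its own patient's dosimetry, and the simplified single-rate variant
freezes `α = 1` for model comparison. The robustness check refits from
perturbed starts (×/÷3) and on every drop-one-point subset, reporting the
effect of removing the final (168 h) sample separately because that point
effectively determines `k₂`.

Identifiability under study conditions deserves emphasis. With eight
Poisson-noised points from 100 scored cells, the weighted-Jacobian covariance
at typical cohort-scale truths yields relative standard errors around 50%
for `c` and `k₁` individually (the parameters trade off along a valley, a
dependence the model structure itself imposes). Published per-patient fits
of this design report standard errors of the same size. Monte-Carlo recovery
therefore plateaus near median relative errors of ~0.18 (`c`) and ~0.27–0.38
(`k₁`) regardless of optimizer quality — the estimator is exact (≲10⁻⁴) on
noise-free data. Rank ordering and the two-group structure survive the noise
far better than the individual values: group recovery by k-means reaches
adjusted Rand indices of ~0.5–0.9 and true-vs-fitted `k₁` rank correlations
of ~0.77–0.87 on 50-patient cohorts. Consumers of per-patient `k₁` values
should treat them as group-level, not individual-precision, estimates.

## Cohort statistics

Grouping thresholds (slow repair `k₁ < 0.6 h⁻¹`, fast `k₁ > 1.1 h⁻¹`, gap
values flagged unassigned) and the k-means cross-check operate on the raw,
unstandardized `(k₁, k₂, c)` triples. Unstandardized is intentional: the
cluster centroids are then exactly the within-group means of the physical
parameters (asserted on every run) even though `k₁` dominates the Euclidean
metric. Outlier screening uses a Tukey fence (any of the three parameters
above Q3 + 1.5·IQR); an explicit exclusion list can override the rule to
reproduce a published exclusion exactly.

Correlations route by Shapiro–Wilk at the 5% level: Pearson when both
variables pass, Spearman (tie-corrected average ranks) otherwise; Spearman
p-values use the t-approximation for n ≥ 10 and exact rank permutation below
that. Group contrasts route analogously to the t-test or the Mann–Whitney U
test. Routing on borderline data is knife-edge — a Shapiro p of 0.06 versus
0.04 flips the method — so the battery that reproduces the published panel
pins the reported method per pair (Spearman for the fit-parameter and
age–parameter pairs, Pearson for age versus the raw RIF values) while
automatic routing remains the default for new pairs; either way a Shapiro
rejection always implies the nonparametric choice. No multiple-testing
correction is applied by default, mirroring the published unadjusted 5%
screening; Benjamini–Hochberg is available as an opt-in flag, and each
result records its n because availability differs per pair.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: 18 patients by
default, ~3.43–3.91 GBq administered, nominal sampling at 0 (pre-therapy
baseline), 1, 2, 3, 4, 24, 48, 96, 168 h, 100 cells scored per sample,
Poisson counting noise, and occasional missing samples (the 96 h point most
often, as in clinical routine). Clearance parameters are drawn from ranges
tuned so the printed dose schedule is reproduced (median total blood dose
~300 mGy, dose rate ~15 mGy/h at 1 h, early RIF medians 0.3–0.7 per cell)
and rejection-sampled into a 200–600 mGy total-dose band. Kinetic truths are
bimodal in `k₁` — a slow mode (0.193–0.554 h⁻¹, `c` 0.012–0.028 mGy⁻¹) and a
fast mode (1.14–3.03 h⁻¹, `c` 0.044–0.109 mGy⁻¹), the per-group min–max of
the published per-patient fits — so grouping analyses have real structure.
Age skews older in the slow-repair group, mirroring the reported age
dependence of repair capacity. Baseline focus rates draw from
Uniform(0.05, 0.3) foci/cell; published cohorts do not print baselines, and
none of the quantitative checks depend on this choice. Truth `N₀` is 0 by
default (`N₀` is a fit nuisance); a nonzero-`N₀` stress mode exists, where a
Poisson expectation that would dip negative is floored at zero and logged.

What the generator does **not** emulate: deviations of actual sampling times
from nominal, the re-uptake physiology behind piecewise dosimetry (a
piecewise stress fixture stands in), inter-operator scoring variability, and
any correlation between clearance and kinetic parameters. Passing recovery
tests therefore demonstrate statistical behaviour under idealized sampling
and pure counting noise, not robustness to every clinical artifact.

Everything is reproducible from the seed; `truth.csv` is written alongside
the four pipeline input tables but never read by the pipeline.

## Pipeline

`run_pipeline` chains dosimetry → RIF preprocessing → per-patient fits →
grouping, pooled fits and k-means → linear early-dose and late-dose-rate
fits → the correlation battery, writing one CSV/JSON artifact per stage plus
a config snapshot and a log. Per-patient failures (unfittable dosimetry, too
few points) are recorded and skipped, not fatal; structural input problems
(missing columns) raise with a column-level message. CSV is the single
interchange format (UTF-8, dot decimal, mandatory header). Problem sizes in
the shipped tests are chosen to keep the whole suite in a few minutes:
cohorts of 8–50 patients, 25–50 Monte-Carlo replicates, 200 random draws for
the closed-form/ODE equivalence.

## Known limitations

- Per-patient `c` and `k₁` are weakly identified by design-sized data (see
  above); only noise-free data yield precise individual estimates.
- The model deliberately omits an uptake delay after oral administration,
  apoptotic cell clearance, and more than two repair classes.
- The piecewise dose evaluator's physical-decay tail overestimates when
  biological clearance actually continues beyond the last sample.
- The `N₀` bound and the Poisson variance floor are pragmatic conventions;
  alternatives (profile likelihood, variance-stabilizing transforms) are out
  of scope.
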