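# riftrace

Kinetics of radiation-induced DNA double-strand-break foci in patient blood
during radioiodine (¹³¹I) therapy: internal blood dosimetry, a compartmental
model of foci induction and biphasic repair, per-patient and pooled nonlinear
fitting with exclusion rules, cohort stratification and correlation analysis,
and a synthetic-cohort generator with stored ground truth.

## Who this is for

Radiation biodosimetry and nuclear-medicine dosimetry groups analyzing
γ-H2AX + 53BP1 focus counts ("RIF", radiation-induced foci per cell) sampled
from patient blood over the days following administration of a
radiopharmaceutical, together with blood-based dosimetry. Unlike external
irradiation, the source stays in the body for weeks: damage induction by the
residual activity competes with ongoing repair, so focus counts must be
modelled jointly with the patient-specific absorbed-dose history.

## The model

**Dosimetry.** Measured blood activity concentrations and whole-body
retention fractions are fitted by decay-inclusive bi-exponentials. The
absorbed dose rate to the blood is

```
dD/dt = A₀ · [ Dk_β · Σᵢ a_i,bl e^(−λᵢt)  +  Dk_γ · wt^(−2/3) · Σᵢ a_i,wb e^(−μᵢt) ]
```

with `λᵢ = l_i,bl + l_phys`, `μᵢ = l_i,wb + l_phys` (biological plus physical
decay, `l_phys = ln 2 / 8.02 d = 0.00360 h⁻¹`), `A₀` the administered
activity (GBq) and `wt` the body weight (kg). Cumulative and total dose
follow in closed form; a piecewise evaluator (bi-exponential up to a
breakpoint, trapezoid-integrated measurements after it) handles re-uptake
curves that defy a single bi-exponential.

**Foci kinetics.** Induction of foci is proportional to the dose rate
(constant `c`, mGy⁻¹); repair empties two first-order pools — a fraction `α`
of induced damage repairs fast (rate `k₁`, h⁻¹), the rest slowly (`k₂`):

```
dN₁/dt = −k₁N₁ + α·c·dD/dt        dN₂/dt = −k₂N₂ + (1−α)·c·dD/dt
N(t) = N₁ + N₂ + N₀
```

With a bi-exponential dose rate this integrates to a sum of exponential
differences, evaluated analytically (`model_N`) and cross-checked against
direct ODE integration (`model_N_ode`). The intercept `N₀` absorbs the
uncertainty of the baseline-subtracted count at t = 0.

**Estimation and cohort analysis.** Per-patient weighted least squares
(weights 1/σ², Poisson counting uncertainties with error propagation through
the baseline subtraction) over bounded parameters, run to a χ² tolerance of
10⁻⁹ from a deterministic multi-start grid. Patients with fewer than eight
valid data points, or with standard errors above twice the value of `c` or
`k₁`, are excluded. Cohorts are stratified by `k₁` (slow-repair group below
0.6 h⁻¹, fast-repair group above 1.1 h⁻¹), cross-validated by k-means on the
raw `(k₁, k₂, c)` triples, and screened with a Shapiro–Wilk-routed
correlation battery (Pearson/Spearman, t-test/Mann–Whitney U).

## Worked example

```python
from riftrace import *

co = DoseCoefficients(Dk_beta=108.0, Dk_gamma=0.0188)   # Gy·mL/(GBq·h), Gy·kg^(2/3)/(GBq·h)
patient = PatientDosimetry(
    A0=3.57, wt=70.0,                                    # GBq administered, kg
    blood=BiExpClearance(a=(3.0e-5, 4.0e-6), l=(0.07, 0.012)),   # per mL, h⁻¹
    wholebody=BiExpClearance(a=(0.85, 0.15), l=(0.06, 0.012)),
    coefficients=co)

print(f"dose rate at 1 h : {dose_rate(patient, 1.0):.1f} mGy/h")
print(f"dose by 24 h     : {cumulative_dose(patient, 24.0):.0f} mGy")
print(f"total blood dose : {total_dose(patient):.0f} mGy")

params = KineticParams(c=0.022, alpha=0.954, k1=0.362, k2=0.006)
t_max, n_max = time_of_max(params, patient)
print(f"foci peak        : {n_max:.2f} RIF/cell at t = {t_max:.1f} h")
print(f"RIF at 168 h     : {model_N(168.0, params, patient):.2f} per cell")
```

prints

```
dose rate at 1 h : 16.0 mGy/h
dose by 24 h     : 214 mGy
total blood dose : 347 mGy
foci peak        : 0.77 RIF/cell at t = 6.7 h
RIF at 168 h     : 0.16 per cell
```

A ~3.5 GBq administration with typical clearance delivers a few hundred
milligray to the blood, mostly within the first day. With slow-repair
kinetics (`k₁ ≈ 0.36 h⁻¹`) the focus count peaks below one focus per cell a
few hours after administration and decays over the following week without
quite reaching zero — the slow pool (`k₂`) keeps a residue at 168 h.

## Command line

```bash
riftrace simulate --seed 0 --n-patients 18 --out cohort/      # synthetic inputs + truth.csv
riftrace run --indir cohort/ --out results/                   # dosimetry → RIF → fits → stats
riftrace stats --fits results/fits.csv --out stats.json       # stats-only from a fit table
riftrace reproduce-tables                                     # fixture regression report
```

`run` writes `dosimetry.csv`, `rif_series.csv`, `fits.csv`, `pooled_fits.csv`,
`linear_fits.csv`, `groups.csv`, `cohort_stats.json`, `summary.json` and a
config snapshot. Dose coefficients are required configuration (see
`src/riftrace/data/example_config.yaml`); they are not baked into the code.

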