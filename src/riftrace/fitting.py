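"""Parameter estimation for the foci-kinetics model.

Per-patient fits minimize the uncertainty-weighted residual sum of squares

    chi2 = sum_i [ (N_i - N(t_i; c, alpha, k1, k2, N0)) / sigma_i ]^2

over bounded parameters (c >= 0, alpha in [0,1], k1,k2 >= 0, N0 within the
baseline uncertainty) with a bounded trust-region least-squares solver run to
a chi-square tolerance of 1e-9 from a deterministic multi-start grid, so
results are seed-free.  Exclusion rules: fewer than eight valid
post-administration points, or a standard error exceeding twice the parameter
value for c or k1.

Pooled fits share one parameter vector across patients, each residual
evaluated with its own patient's dosimetry.  Two auxiliary linear fits
describe the early-time dose dependence (t < 6 h) and the late-time
dose-rate dependence (t >= 20 h) of the pooled foci counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .dosimetry import PatientDosimetry
from .kinetics import KineticParams, RifPoint, model_N

_PARAM_NAMES = ("c", "alpha", "k1", "k2", "N0")


@dataclass
class FitOptions:
    """Knobs of the per-patient fitting protocol."""

    chi2_tol: float = 1e-9            # solver ftol on the weighted chi-square
    min_points: int = 8               # >=8 valid post-administration points
    se_factor: float = 2.0            # exclusion when SE > se_factor * |value|
    se_checked: tuple[str, ...] = ("c", "k1")
    weighted: bool = True
    # deterministic multi-start grid
    c_grid: tuple[float, ...] = (0.01, 0.03, 0.1)
    k1_grid: tuple[float, ...] = (0.2, 0.5, 1.5)
    k2_grid: tuple[float, ...] = (0.001, 0.01, 0.05)
    alpha_grid: tuple[float, ...] = (0.9, 0.99)


@dataclass
class FitResult:
    params: KineticParams | None
    se: dict[str, float] | None
    r2: float | None
    n_points: int
    converged: bool
    excluded: bool
    reason: str | None
    chi2: float | None

    def as_row(self) -> dict:
        row = {"n_points": self.n_points, "converged": self.converged,
               "excluded": self.excluded, "reason": self.reason or "",
               "chi2": self.chi2, "r2": self.r2}
        if self.params is not None:
            row.update(c=self.params.c, alpha=self.params.alpha, k1=self.params.k1,
                       k2=self.params.k2, n0=self.params.N0)
            row.update({f"se_{k.lower()}": v for k, v in (self.se or {}).items()})
        return row


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    n: int


def _prepare(rif: list[RifPoint]):
    t = np.array([p.t for p in rif], dtype=float)
    y = np.array([p.N for p in rif], dtype=float)
    s = np.array([p.sigma for p in rif], dtype=float)
    return t, y, s


def _weighted_r2(y, f, w):
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * (y - f) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def _se_from_jacobian(jac: np.ndarray, chi2: float, n: int, n_free: int) -> np.ndarray:
    """Standard errors from the weighted Jacobian, scaled by reduced chi-square."""
    dof = max(n - n_free, 1)
    cov = np.linalg.pinv(jac.T @ jac) * (chi2 / dof)
    return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))


def _solve_multistart(resid, starts, lower, upper, ftol):
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lower + 1e-12, upper - 1e-12 if np.all(np.isfinite(upper)) else upper)
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper),
                                ftol=ftol, xtol=1e-12, gtol=1e-12, method="trf")
        except Exception:
            continue
        chi2 = float(np.sum(sol.fun ** 2))
        if best is None:
            best = (chi2, sol)
            continue
        # best chi2 wins; near-ties broken by smaller k1 for determinism
        if chi2 < best[0] * (1 - 1e-9):
            best = (chi2, sol)
        elif abs(chi2 - best[0]) <= 1e-9 * max(best[0], 1e-30) and sol.x[2] < best[1].x[2]:
            best = (chi2, sol)
    return best


def _start_grid(opts: FitOptions):
    return [np.array([c, a, k1, k2, 0.0])
            for c, k1, k2, a in itertools.product(opts.c_grid, opts.k1_grid,
                                                  opts.k2_grid, opts.alpha_grid)]


def _canonicalize(params: KineticParams, se: dict[str, float]):
    """Enforce the k1 >= k2 labelling; swap SEs consistently with the relabel."""
    if params.k1 >= params.k2:
        return params, se
    se = dict(se)
    se["k1"], se["k2"] = se["k2"], se["k1"]
    return params.canonical(), se


def fit_patient(
    rif: list[RifPoint],
    pd: PatientDosimetry,
    opts: FitOptions | None = None,
    baseline_sigma: float | None = None,
    starts: list[np.ndarray] | None = None,
    count_baseline: bool = True,
) -> FitResult:
    """Fit the five-parameter model to one patient's RIF series.

    ``rif`` must not contain the baseline point (it defines zero by
    construction, so it is not a residual), but it does count toward the
    valid-data-point rule: a full nominal schedule has 8 post-administration
    samples plus the baseline, i.e. 9 points, and one missing sample (8
    points) still clears the >= 8 threshold while two (7 points) do not.
    ``baseline_sigma`` is the baseline point's propagated uncertainty,
    bounding N0; falls back to the largest series sigma when no baseline
    uncertainty is available.
    """
    opts = opts or FitOptions()
    n = len(rif) + (1 if count_baseline else 0)
    if n < opts.min_points:
        return FitResult(params=None, se=None, r2=None, n_points=n, converged=False,
                         excluded=True, reason="too-few-points", chi2=None)

    t, y, s = _prepare(rif)
    w = 1.0 / s if opts.weighted else np.ones_like(s)
    sigma0 = baseline_sigma if baseline_sigma is not None else float(np.max(s))

    def resid(x):
        p = KineticParams(c=x[0], alpha=x[1], k1=x[2], k2=x[3], N0=x[4])
        return w * (y - model_N(t, p, pd))

    lower = np.array([0.0, 0.0, 0.0, 0.0, -sigma0])
    upper = np.array([np.inf, 1.0, np.inf, np.inf, sigma0])
    best = _solve_multistart(resid, starts or _start_grid(opts), lower, upper, opts.chi2_tol)
    if best is None:
        return FitResult(params=None, se=None, r2=None, n_points=n, converged=False,
                         excluded=False, reason=None, chi2=None)
    chi2, sol = best
    se_vec = _se_from_jacobian(sol.jac, chi2, len(rif), 5)
    params = KineticParams(c=sol.x[0], alpha=sol.x[1], k1=sol.x[2], k2=sol.x[3], N0=sol.x[4])
    se = dict(zip(_PARAM_NAMES, se_vec))
    params, se = _canonicalize(params, se)
    r2 = _weighted_r2(y, model_N(t, params, pd), w ** 2)

    excluded, reason = False, None
    for name in opts.se_checked:
        value = getattr(params, name if name != "N0" else "N0")
        if se[name] > opts.se_factor * abs(value):
            excluded, reason = True, "large-errors"
            break
    return FitResult(params=params, se=se, r2=r2, n_points=n, converged=True,
                     excluded=excluded, reason=reason, chi2=chi2)


def fit_pooled(
    patients: list[tuple[list[RifPoint], PatientDosimetry]],
    opts: FitOptions | None = None,
    baseline_sigma: float | None = None,
) -> FitResult:
    """Fit a single shared parameter vector to pooled patient data.

    Every residual is evaluated with its own patient's dosimetry; one
    (c, alpha, k1, k2, N0) minimizes the combined weighted chi-square.
    """
    if len(patients) < 1:
        raise ValueError("pooled fit needs at least one patient")
    opts = opts or FitOptions()

    blocks = [(_prepare(rif), pd) for rif, pd in patients]
    n = sum(len(b[0][0]) for b in blocks)
    if n < opts.min_points:
        return FitResult(params=None, se=None, r2=None, n_points=n, converged=False,
                         excluded=True, reason="too-few-points", chi2=None)
    if baseline_sigma is None:
        baseline_sigma = float(max(np.max(s) for (t, y, s), _ in blocks))

    y_all = np.concatenate([y for (t, y, s), _ in blocks])
    w_all = np.concatenate([1.0 / s if opts.weighted else np.ones_like(s)
                            for (t, y, s), _ in blocks])

    def resid(x):
        p = KineticParams(c=x[0], alpha=x[1], k1=x[2], k2=x[3], N0=x[4])
        return np.concatenate([w * (y - model_N(t, p, pd))
                               for (t, y, s), pd in blocks
                               for w in [1.0 / s if opts.weighted else np.ones_like(s)]])

    lower = np.array([0.0, 0.0, 0.0, 0.0, -baseline_sigma])
    upper = np.array([np.inf, 1.0, np.inf, np.inf, baseline_sigma])
    best = _solve_multistart(resid, _start_grid(opts), lower, upper, opts.chi2_tol)
    if best is None:
        return FitResult(params=None, se=None, r2=None, n_points=n, converged=False,
                         excluded=False, reason=None, chi2=None)
    chi2, sol = best
    se_vec = _se_from_jacobian(sol.jac, chi2, n, 5)
    params = KineticParams(c=sol.x[0], alpha=sol.x[1], k1=sol.x[2], k2=sol.x[3], N0=sol.x[4])
    se = dict(zip(_PARAM_NAMES, se_vec))
    params, se = _canonicalize(params, se)
    f_all = np.concatenate([model_N(t, params, pd) for (t, y, s), pd in blocks])
    r2 = _weighted_r2(y_all, f_all, w_all ** 2)
    return FitResult(params=params, se=se, r2=r2, n_points=n, converged=True,
                     excluded=False, reason=None, chi2=chi2)


def fit_simplified(
    rif: list[RifPoint],
    pd: PatientDosimetry,
    opts: FitOptions | None = None,
    baseline_sigma: float | None = None,
) -> FitResult:
    """Single-repair-rate fit: alpha frozen at 1, k2 dropped (3 free parameters)."""
    opts = opts or FitOptions()
    n = len(rif)
    if n < 4:
        raise ValueError(f"too few points for the simplified fit ({n} < 4)")
    t, y, s = _prepare(rif)
    w = 1.0 / s if opts.weighted else np.ones_like(s)
    sigma0 = baseline_sigma if baseline_sigma is not None else float(np.max(s))

    def make_params(x):
        return KineticParams(c=x[0], alpha=1.0, k1=x[1], k2=0.0, N0=x[2])

    def resid(x):
        return w * (y - model_N(t, make_params(x), pd))

    starts = [np.array([c, k1, 0.0])
              for c, k1 in itertools.product(opts.c_grid, opts.k1_grid)]
    lower = np.array([0.0, 0.0, -sigma0])
    upper = np.array([np.inf, np.inf, sigma0])
    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper),
                                ftol=opts.chi2_tol, xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        chi2 = float(np.sum(sol.fun ** 2))
        if best is None or chi2 < best[0] * (1 - 1e-9):
            best = (chi2, sol)
    if best is None:
        return FitResult(params=None, se=None, r2=None, n_points=n, converged=False,
                         excluded=False, reason=None, chi2=None)
    chi2, sol = best
    se_vec = _se_from_jacobian(sol.jac, chi2, n, 3)
    params = make_params(sol.x)
    se = {"c": se_vec[0], "alpha": 0.0, "k1": se_vec[1], "k2": 0.0, "N0": se_vec[2]}
    r2 = _weighted_r2(y, model_N(t, params, pd), w ** 2)
    return FitResult(params=params, se=se, r2=r2, n_points=n, converged=True,
                     excluded=False, reason=None, chi2=chi2)


@dataclass
class RobustnessReport:
    max_rel_variation: dict[str, float]      # over perturbed starts + 1-point drops
    drop_last_variation: dict[str, float]    # effect of dropping the final time point
    n_refits: int


def robustness_check(
    rif: list[RifPoint],
    pd: PatientDosimetry,
    opts: FitOptions | None = None,
    baseline_sigma: float | None = None,
) -> RobustnessReport:
    """Stability of a converged fit under perturbed starts and point removal.

    Refits (a) from starting values multiplied/divided by 3 around the optimum
    and (b) on every subset obtained by dropping one post-administration point
    (the baseline is never part of ``rif``).  The effect of dropping the last
    point — the one anchoring the slow rate k2 — is reported separately.
    """
    opts = opts or FitOptions()
    ref = fit_patient(rif, pd, opts, baseline_sigma)
    if not ref.converged or ref.params is None:
        raise ValueError("robustness check requires a converged reference fit")
    ref_vec = np.array([ref.params.c, ref.params.alpha, ref.params.k1,
                        ref.params.k2, ref.params.N0])

    def rel_dev(res: FitResult) -> np.ndarray:
        v = np.array([res.params.c, res.params.alpha, res.params.k1,
                      res.params.k2, res.params.N0])
        denom = np.where(np.abs(ref_vec) > 1e-12, np.abs(ref_vec), 1.0)
        return np.abs(v - ref_vec) / denom

    n_refits = 0
    max_dev = np.zeros(5)
    # (a) perturbed starts around the optimum
    for factors in itertools.product((1 / 3, 1.0, 3.0), repeat=2):
        start = ref_vec.copy()
        start[0] *= factors[0]          # c
        start[2] *= factors[1]          # k1
        start[1] = min(start[1], 1.0)
        res = fit_patient(rif, pd, opts, baseline_sigma, starts=[start])
        if res.converged:
            max_dev = np.maximum(max_dev, rel_dev(res))
            n_refits += 1
    # (b) leave-one-out subsets, relaxing the point rule by one
    loo_opts = replace(opts, min_points=max(opts.min_points - 1, 4))
    drop_last = dict.fromkeys(_PARAM_NAMES, float("nan"))
    t_last = max(p.t for p in rif)
    for i in range(len(rif)):
        subset = rif[:i] + rif[i + 1:]
        res = fit_patient(subset, pd, loo_opts, baseline_sigma)
        if not res.converged:
            continue
        n_refits += 1
        dev = rel_dev(res)
        if rif[i].t == t_last:
            drop_last = dict(zip(_PARAM_NAMES, dev))
        else:
            max_dev = np.maximum(max_dev, dev)
    return RobustnessReport(max_rel_variation=dict(zip(_PARAM_NAMES, max_dev)),
                            drop_last_variation=drop_last, n_refits=n_refits)


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFitResult:
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = float(res.rsquared) if ss_tot > 0 else 0.0
    return LinearFitResult(slope=float(res.params[1]), intercept=float(res.params[0]),
                           slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
                           r2=r2, n=len(x))


def linear_fit_induction(dose: np.ndarray, rif: np.ndarray) -> LinearFitResult:
    """Early-time induction line N = slope * D + intercept (pooled, t < 6 h).

    ``dose`` is the absorbed dose to the blood at each sampling time (mGy);
    ordinary (unweighted) least squares, slope in mGy^-1.
    """
    if len(dose) < 3:
        raise ValueError("need at least 3 points for a linear fit")
    return _ols(dose, rif)


def linear_fit_doserate(dose_rate: np.ndarray, rif: np.ndarray) -> LinearFitResult:
    """Late-time dose-rate line N = slope * dD/dt + intercept (pooled, t >= 20 h);
    slope in h·mGy^-1."""
    if len(dose_rate) < 3:
        raise ValueError("need at least 3 points for a linear fit")
    return _ols(dose_rate, rif)
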