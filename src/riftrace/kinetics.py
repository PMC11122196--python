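"""One-compartment kinetics of radiation-induced foci (RIF).

Foci induction is proportional to the absorbed dose rate (constant c, mGy⁻¹);
repair removes foci in two first-order pools, a fast one (rate k1, fraction α
of the induced damage) and a slow one (rate k2, fraction 1−α):

    dN1/dt = -k1*N1 + α*c*dD/dt
    dN2/dt = -k2*N2 + (1-α)*c*dD/dt,      N(t) = N1 + N2 + N0

With a bi-exponential dose rate the solution is a sum of exponential
differences; ``model_N`` evaluates that closed form and ``model_N_ode``
integrates the ODE numerically (the reference oracle, also used for
non-exponential dose-rate inputs such as piecewise dosimetry).

The intercept N0 absorbs the uncertainty of the baseline-subtracted foci
count at t = 0; it is a fit nuisance, not an initial sub-pool content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .dosimetry import PatientDosimetry, _GY_TO_MGY

# below this separation the (e^{-λt} - e^{-kt})/(k-λ) term switches to its
# analytic k -> λ limit t·e^{-λt}
_DEGENERATE_GAP = 1e-9


@dataclass(frozen=True)
class FociCount:
    """Raw focus count: total co-localizing γ-H2AX+53BP1 foci in `cells` cells."""

    t: float
    foci_total: int
    cells: int

    def __post_init__(self) -> None:
        if self.cells < 1:
            raise ValueError("cells must be >= 1")
        if self.foci_total < 0 or self.foci_total != int(self.foci_total):
            raise ValueError("foci_total must be a non-negative integer")


@dataclass(frozen=True)
class RifPoint:
    """Baseline-subtracted foci per cell with propagated Poisson uncertainty."""

    t: float
    N: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class KineticParams:
    """Model parameters (c, α, k1, k2, N0); canonically k1 >= k2."""

    c: float
    alpha: float
    k1: float
    k2: float
    N0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("repair rates must be >= 0")
        if self.c < 0:
            raise ValueError("induction constant c must be >= 0")

    def canonical(self) -> "KineticParams":
        """Relabel so the fast pool is first: swap (k1,α) <-> (k2,1-α) if k1 < k2."""
        if self.k1 >= self.k2:
            return self
        return KineticParams(c=self.c, alpha=1.0 - self.alpha,
                             k1=self.k2, k2=self.k1, N0=self.N0)


def rif_from_counts(sample: FociCount, baseline: FociCount) -> RifPoint:
    """Baseline-subtract a focus count and propagate Poisson uncertainty.

    Each count contributes variance equal to the count itself (Poisson); a zero
    count contributes a floor variance of 1 count so no data point receives
    infinite weight.  Negative RIF values are legal and never clipped.
    """
    n = sample.foci_total / sample.cells - baseline.foci_total / baseline.cells
    var = (max(sample.foci_total, 1) / sample.cells ** 2
           + max(baseline.foci_total, 1) / baseline.cells ** 2)
    return RifPoint(t=sample.t, N=n, sigma=math.sqrt(var))


def _exp_diff(lam: float, k: float, t: np.ndarray) -> np.ndarray:
    """(e^{-λt} - e^{-kt}) / (k - λ), with the analytic k -> λ limit."""
    if abs(k - lam) < _DEGENERATE_GAP:
        return t * np.exp(-lam * t)
    return (np.exp(-lam * t) - np.exp(-k * t)) / (k - lam)


def _pool_response(k: float, t: np.ndarray, pd: PatientDosimetry) -> np.ndarray:
    """Response of a unit-induction pool with repair rate k to the dose rate.

    Returns the convolution  ∫_0^t e^{-k(t-s)} dD/ds ds  in mGy, i.e. the
    closed-form pool content divided by c.
    """
    co = pd.coefficients
    beta = sum(ai * _exp_diff(lam, k, t) for ai, lam in zip(pd.blood.a, pd.lam_bl))
    gamma = sum(ai * _exp_diff(lam, k, t) for ai, lam in zip(pd.wholebody.a, pd.lam_wb))
    return pd.A0 * (co.Dk_beta * beta + co.Dk_gamma * pd.wt ** (-2.0 / 3.0) * gamma) * _GY_TO_MGY


def model_N(t, p: KineticParams, pd: PatientDosimetry) -> np.ndarray | float:
    """Closed-form foci per cell at time t (h)."""
    t_arr = np.asarray(t, dtype=float)
    out = (p.alpha * p.c * _pool_response(p.k1, t_arr, pd)
           + (1.0 - p.alpha) * p.c * _pool_response(p.k2, t_arr, pd)
           + p.N0)
    return out if np.ndim(t) else float(out)


def model_N_deriv(t, p: KineticParams, pd: PatientDosimetry) -> np.ndarray | float:
    """Analytic time derivative of model_N (foci per cell per hour)."""
    t_arr = np.asarray(t, dtype=float)
    co = pd.coefficients

    def dpool(k):
        def dterm(a, lam):
            if abs(k - lam) < _DEGENERATE_GAP:
                return a * np.exp(-lam * t_arr) * (1.0 - lam * t_arr)
            return a * (-lam * np.exp(-lam * t_arr) + k * np.exp(-k * t_arr)) / (k - lam)

        beta = sum(dterm(ai, lam) for ai, lam in zip(pd.blood.a, pd.lam_bl))
        gamma = sum(dterm(ai, lam) for ai, lam in zip(pd.wholebody.a, pd.lam_wb))
        return pd.A0 * (co.Dk_beta * beta + co.Dk_gamma * pd.wt ** (-2.0 / 3.0) * gamma) * _GY_TO_MGY

    out = p.alpha * p.c * dpool(p.k1) + (1.0 - p.alpha) * p.c * dpool(p.k2)
    return out if np.ndim(t) else float(out)


def model_N_ode(
    t_grid,
    p: KineticParams,
    dose_rate_fn,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Numerically integrate the two-pool ODE along t_grid.

    ``dose_rate_fn(t)`` must return the dose rate in mGy/h.  Used as the test
    oracle for the closed form and as the evaluator for non-exponential dose
    rates (piecewise dosimetry).
    """
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(t, y):
        r = dose_rate_fn(t)
        return [-p.k1 * y[0] + p.alpha * p.c * r,
                -p.k2 * y[1] + (1.0 - p.alpha) * p.c * r]

    sol = solve_ivp(rhs, (0.0, float(t_grid[-1])), [0.0, 0.0],
                    t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0] + sol.y[1] + p.N0


def time_of_max(
    p: KineticParams,
    pd: PatientDosimetry,
    t_max_search: float = 500.0,
) -> tuple[float, float]:
    """Time and height of the foci maximum (above the intercept N0).

    Locates the global maximizer of ``model_N - N0`` on [0, t_max_search] by
    bracketing sign changes of the analytic derivative on a dense grid and
    refining each bracket with Brent's method.  Also returns values needed for
    end-of-observation reporting via ``model_N``.
    """
    if p.c <= 0:
        raise ValueError("no maximum: induction constant c must be > 0")
    if not (any(a > 0 for a in pd.blood.a) or any(a > 0 for a in pd.wholebody.a)):
        raise ValueError("no maximum: at least one positive clearance amplitude required")

    grid = np.linspace(0.0, t_max_search, 4001)
    d = model_N_deriv(grid, p, pd)
    candidates = [0.0, t_max_search]
    sign_change = np.where(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0]
    for i in sign_change:
        root = brentq(lambda tt: model_N_deriv(tt, p, pd), grid[i], grid[i + 1],
                      xtol=1e-12, rtol=1e-14)
        candidates.append(root)
    heights = [model_N(tc, p, pd) - p.N0 for tc in candidates]
    best = int(np.argmax(heights))
    return candidates[best], heights[best]
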