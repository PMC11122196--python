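"""Internal blood dosimetry for radioiodine therapy.

The absorbed dose rate to the blood is split into a beta self-irradiation
term driven by the blood activity concentration and a gamma cross-irradiation
term driven by the whole-body retention scaled by ``wt**(-2/3)``:

    dD/dt = A0 * [ Dk_beta * a_bl(t)  +  Dk_gamma * wt**(-2/3) * a_wb(t) ]

where ``a_bl`` (fraction of administered activity per mL of blood) and
``a_wb`` (dimensionless retention fraction) are decay-inclusive bi-exponential
clearance curves obtained by fitting measured time-activity data.  Internal
arithmetic is in Gy and hours; reported doses are mGy and dose rates mGy/h.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: physical decay constant of I-131 (h^-1), ln 2 / 8.02 d
L_PHYS_I131 = 0.00360

_GY_TO_MGY = 1e3
# series-expansion switch for the (1 - exp(-l t)) / l integral
_SMALL_RATE_PRODUCT = 1e-8


@dataclass(frozen=True)
class DoseCoefficients:
    """Absorbed dose coefficients coupling activity curves to blood dose.

    Dk_beta : Gy·mL·GBq⁻¹·h⁻¹, blood self-irradiation (beta component).
    Dk_gamma : Gy·kg^(2/3)·GBq⁻¹·h⁻¹, whole-body-to-blood photon component.
    l_phys : h⁻¹, physical decay constant of the radionuclide.
    """

    Dk_beta: float
    Dk_gamma: float
    l_phys: float = L_PHYS_I131

    def __post_init__(self) -> None:
        if not (self.Dk_beta > 0 and self.Dk_gamma > 0 and self.l_phys > 0):
            raise ValueError("dose coefficients and l_phys must be strictly positive")


@dataclass(frozen=True)
class BiExpClearance:
    """Two-component clearance curve with *biological* rate constants.

    The decay-inclusive curve is ``f(t) = sum_i a[i] * exp(-(l[i]+l_phys)*t)``;
    physical decay is composed in at evaluation time so that ``l_phys`` stays a
    single configurable constant.  A negative amplitude is allowed (uptake
    phase) as long as f(0) >= 0 and the curve is non-negative.
    """

    a: tuple[float, float]
    l: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.a) != 2 or len(self.l) != 2:
            raise ValueError("exactly two clearance components required")
        object.__setattr__(self, "a", (float(self.a[0]), float(self.a[1])))
        object.__setattr__(self, "l", (float(self.l[0]), float(self.l[1])))
        if any(li < 0 for li in self.l):
            raise ValueError("biological rate constants must be >= 0")
        if not any(ai > 0 for ai in self.a):
            raise ValueError("at least one amplitude must be positive")
        if sum(self.a) < 0:
            raise ValueError("f(0) = sum(a) must be >= 0")

    def value(self, t, l_phys: float = L_PHYS_I131):
        """Decay-inclusive curve value at time t (h)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for ai, li in zip(self.a, self.l):
            out = out + ai * np.exp(-(li + l_phys) * t)
        return out

    def check_nonnegative(self, l_phys: float = L_PHYS_I131, t_max: float = 2000.0) -> None:
        grid = np.linspace(0.0, t_max, 2001)
        vals = self.value(grid, l_phys)
        if not np.all(np.isfinite(vals)) or np.any(vals < -1e-15 * max(abs(v) for v in self.a)):
            raise ValueError("decay-inclusive clearance curve is negative or non-finite on [0, %g h]" % t_max)


@dataclass(frozen=True)
class PatientDosimetry:
    """Everything needed to evaluate blood dose and dose rate for one patient."""

    A0: float  # administered activity, GBq
    wt: float  # body weight, kg
    blood: BiExpClearance
    wholebody: BiExpClearance
    coefficients: DoseCoefficients
    allow_retention_outside_unity: bool = False

    def __post_init__(self) -> None:
        if not (self.A0 > 0 and self.wt > 0):
            raise ValueError("A0 and wt must be positive")
        f0 = sum(self.wholebody.a)
        if not self.allow_retention_outside_unity and not (0.9 <= f0 <= 1.1):
            raise ValueError(
                f"whole-body retention at t=0 is {f0:.3f}; expected within [0.9, 1.1] "
                "(the whole body initially holds all administered activity)"
            )

    # decay-inclusive effective rates
    @property
    def lam_bl(self) -> tuple[float, float]:
        lp = self.coefficients.l_phys
        return (self.blood.l[0] + lp, self.blood.l[1] + lp)

    @property
    def lam_wb(self) -> tuple[float, float]:
        lp = self.coefficients.l_phys
        return (self.wholebody.l[0] + lp, self.wholebody.l[1] + lp)


@dataclass(frozen=True)
class TimeActivitySeries:
    """Measured decay-inclusive time-activity samples for one patient.

    ``value`` holds GBq/mL for blood, retention fraction for whole body.
    """

    t: np.ndarray
    value: np.ndarray
    kind: Literal["blood", "wholebody"]
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("t and value must be 1-d arrays of equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be non-negative and strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("activity values must be finite")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != t.shape or np.any(s <= 0):
                raise ValueError("sigma must be positive and match t in length")
        if self.kind not in ("blood", "wholebody"):
            raise ValueError("kind must be 'blood' or 'wholebody'")


@dataclass
class BiExpFitDiagnostics:
    r2: float
    rss: float
    param_se: np.ndarray
    clamped: bool = False


def _biexp_model(t, a1, a2, r1, r2):
    return a1 * np.exp(-r1 * t) + a2 * np.exp(-r2 * t)


def fit_biexponential(
    series: TimeActivitySeries,
    coefficients: DoseCoefficients,
    A0: float,
    weighted: bool = False,
) -> tuple[BiExpClearance, BiExpFitDiagnostics]:
    """Fit a decay-inclusive bi-exponential to measured activity data.

    Values are normalized to fraction of administered activity (blood: per mL)
    before fitting.  Fitted decay-inclusive rates have ``l_phys`` subtracted to
    give biological rate constants; a fitted rate below ``l_phys`` is flagged as
    super-physical retention and the biological rate is clamped to zero.

    The fit is unweighted by default (a weighted option is available); starting
    values come from a deterministic log-spaced grid of rate pairs so the
    result is seed-free.
    """
    if len(series.t) < 5:
        raise ValueError(f"need at least 5 samples to fit a bi-exponential, got {len(series.t)}")
    if A0 <= 0:
        raise ValueError("administered activity must be positive")

    t = series.t
    y = series.value / A0
    if weighted and series.sigma is not None:
        w = A0 / series.sigma  # residual scale: (y - f) / sigma_norm
    else:
        w = np.ones_like(y)

    scale = float(np.max(np.abs(y)))
    if scale == 0:
        raise ValueError("all-zero activity series cannot be fitted")

    # deterministic multi-start over log-spaced decay-inclusive rate pairs
    rate_grid = np.geomspace(1e-3, 1.0, 6)
    best = None
    for r1 in rate_grid:
        for r2 in rate_grid:
            if r2 >= r1:
                continue

            def resid(p):
                return w * (y - _biexp_model(t, *p))

            p0 = [0.8 * scale, 0.2 * scale, r1, r2]
            try:
                sol = least_squares(
                    resid, p0,
                    bounds=([-np.inf, -np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf, np.inf]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:  # singular start
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0] - 1e-15 * abs(best[0]):
                best = (rss, sol)
    if best is None:
        raise RuntimeError("bi-exponential fit failed from every starting point")
    rss, sol = best
    a1, a2, r1, r2 = sol.x
    # canonical order: fast component first
    if r2 > r1:
        a1, a2, r1, r2 = a2, a1, r2, r1

    clamped = False
    ls = []
    for r in (r1, r2):
        lb = r - coefficients.l_phys
        if lb < 0:
            logger.warning(
                "super-physical retention: fitted decay-inclusive rate %.4g h^-1 below "
                "l_phys=%.4g h^-1; biological rate clamped to 0", r, coefficients.l_phys
            )
            clamped = True
            lb = 0.0
        ls.append(lb)

    # covariance from the Jacobian at the optimum, scaled by reduced chi^2
    dof = max(len(t) - 4, 1)
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(JTJ) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except Exception:
        se = np.full(4, np.nan)

    ss_tot = float(np.sum((w * (y - np.average(y, weights=w ** 2))) ** 2))
    r2_coef = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
    clear = BiExpClearance(a=(a1, a2), l=(ls[0], ls[1]))
    return clear, BiExpFitDiagnostics(r2=r2_coef, rss=rss, param_se=se, clamped=clamped)


def _integral_term(a: float, lam: float, t):
    """integral_0^t a*exp(-lam s) ds with the lam -> 0 analytic limit a*t."""
    t = np.asarray(t, dtype=float)
    small = np.abs(lam) * t < _SMALL_RATE_PRODUCT
    with np.errstate(divide="ignore", invalid="ignore"):
        full = a * (1.0 - np.exp(-lam * t)) / lam if lam != 0 else np.full_like(t, np.nan)
    return np.where(small, a * t, full)


def dose_rate(pd: PatientDosimetry, t) -> np.ndarray | float:
    """Absorbed dose rate to the blood at time t (h), in mGy/h."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    co = pd.coefficients
    beta = sum(ai * np.exp(-lam * t_arr) for ai, lam in zip(pd.blood.a, pd.lam_bl))
    gamma = sum(ai * np.exp(-lam * t_arr) for ai, lam in zip(pd.wholebody.a, pd.lam_wb))
    rate_gy = pd.A0 * (co.Dk_beta * beta + co.Dk_gamma * pd.wt ** (-2.0 / 3.0) * gamma)
    out = rate_gy * _GY_TO_MGY
    return out if np.ndim(t) else float(out)


def cumulative_dose(pd: PatientDosimetry, t) -> np.ndarray | float:
    """Absorbed dose to the blood accumulated on [0, t] (mGy); D(0)=0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    co = pd.coefficients
    beta = sum(_integral_term(ai, lam, t_arr) for ai, lam in zip(pd.blood.a, pd.lam_bl))
    gamma = sum(_integral_term(ai, lam, t_arr) for ai, lam in zip(pd.wholebody.a, pd.lam_wb))
    dose_gy = pd.A0 * (co.Dk_beta * beta + co.Dk_gamma * pd.wt ** (-2.0 / 3.0) * gamma)
    out = dose_gy * _GY_TO_MGY
    return out if np.ndim(t) else float(out)


def total_dose(pd: PatientDosimetry) -> float:
    """Total absorbed dose to the blood, the t -> infinity limit (mGy)."""
    if any(lam <= 0 for lam in pd.lam_bl) or any(lam <= 0 for lam in pd.lam_wb):
        raise ValueError("non-convergent TIAC: every decay-inclusive rate must be > 0")
    co = pd.coefficients
    tau_bl = sum(ai / lam for ai, lam in zip(pd.blood.a, pd.lam_bl))
    tau_wb = sum(ai / lam for ai, lam in zip(pd.wholebody.a, pd.lam_wb))
    return pd.A0 * (co.Dk_beta * tau_bl + co.Dk_gamma * pd.wt ** (-2.0 / 3.0) * tau_wb) * _GY_TO_MGY


def tiacs(pd: PatientDosimetry) -> tuple[float, float]:
    """Time-integrated activity coefficients (tau_bl in h/mL, tau_wb in h)."""
    tau_bl = sum(ai / lam for ai, lam in zip(pd.blood.a, pd.lam_bl))
    tau_wb = sum(ai / lam for ai, lam in zip(pd.wholebody.a, pd.lam_wb))
    return tau_bl, tau_wb


class PiecewiseDosimetry:
    """Dose evaluator for curves that defy a single bi-exponential fit.

    Handles re-uptake: the clearance curve is fitted bi-exponentially only up
    to ``breakpoint`` and completed section by section afterwards — linear
    interpolation of the measured (normalized, decay-inclusive) values between
    samples, integrated by the trapezoid rule, with a pure physical-decay tail
    beyond the last sample.  Cumulative dose is continuous at the breakpoint.
    The companion curve (usually the whole body) is taken from the template
    dosimetry unchanged.
    """

    def __init__(
        self,
        series: TimeActivitySeries,
        breakpoint: float,
        template: PatientDosimetry,
    ) -> None:
        t = series.t
        if breakpoint not in t:
            raise ValueError("breakpoint must be one of the sample times")
        if breakpoint >= t[-1]:
            raise ValueError("breakpoint beyond last sample")
        n_after = int(np.sum(t > breakpoint))
        if n_after < 2:
            raise ValueError("need at least 2 samples after the breakpoint")

        self.template = template
        self.breakpoint = float(breakpoint)
        self.kind = series.kind
        co = template.coefficients

        pre_mask = t <= breakpoint
        pre = TimeActivitySeries(t=t[pre_mask], value=series.value[pre_mask], kind=series.kind,
                                 sigma=None if series.sigma is None else series.sigma[pre_mask])
        self.pre_fit, _ = fit_biexponential(pre, co, template.A0)

        # normalized decay-inclusive samples from the breakpoint onwards;
        # trapezoid nodes use the measured values (the integrand may jump at
        # the breakpoint where fit and measurement disagree, the cumulative
        # dose stays continuous)
        post_mask = t >= breakpoint
        self.t_post = t[post_mask].copy()
        y_post = series.value[post_mask] / template.A0
        self.y_post = y_post
        # cumulative trapezoid integral of the normalized curve at the nodes
        self._cum_post = np.concatenate(
            [[0.0], np.cumsum(0.5 * np.diff(self.t_post) * (y_post[1:] + y_post[:-1]))]
        )

    # --- normalized piecewise curve and its running integral -----------------

    def _curve(self, t: float) -> float:
        lp = self.template.coefficients.l_phys
        if t <= self.breakpoint:
            return float(self.pre_fit.value(t, lp))
        if t <= self.t_post[-1]:
            return float(np.interp(t, self.t_post, self.y_post))
        return float(self.y_post[-1] * math.exp(-lp * (t - self.t_post[-1])))

    def _curve_integral(self, t: float) -> float:
        """integral_0^t of the normalized piecewise curve."""
        lp = self.template.coefficients.l_phys
        if t <= self.breakpoint:
            return float(sum(_integral_term(ai, li + lp, t)
                             for ai, li in zip(self.pre_fit.a, self.pre_fit.l)))
        base = self._curve_integral(self.breakpoint)
        if t <= self.t_post[-1]:
            i = int(np.searchsorted(self.t_post, t, side="right")) - 1
            partial = self._cum_post[i]
            y_t = float(np.interp(t, self.t_post, self.y_post))
            partial += 0.5 * (t - self.t_post[i]) * (self.y_post[i] + y_t)
            return base + float(partial)
        full = base + float(self._cum_post[-1])
        tail = self.y_post[-1] * (1.0 - math.exp(-lp * (t - self.t_post[-1]))) / lp
        return full + tail

    # --- public dose API ------------------------------------------------------

    def _other_terms(self, t, integrated: bool):
        """Beta or gamma contribution of the template's untouched curve."""
        tmpl = self.template
        if self.kind == "blood":
            pairs = zip(tmpl.wholebody.a, tmpl.lam_wb)
        else:
            pairs = zip(tmpl.blood.a, tmpl.lam_bl)
        if integrated:
            return sum(_integral_term(ai, lam, t) for ai, lam in pairs)
        return sum(ai * np.exp(-lam * np.asarray(t, float)) for ai, lam in pairs)

    def dose_rate(self, t: float) -> float:
        if t < 0:
            raise ValueError("t must be >= 0")
        co = self.template.coefficients
        own = self._curve(t)
        other = float(self._other_terms(t, integrated=False))
        if self.kind == "blood":
            gy = self.template.A0 * (co.Dk_beta * own
                                     + co.Dk_gamma * self.template.wt ** (-2 / 3) * other)
        else:
            gy = self.template.A0 * (co.Dk_beta * other
                                     + co.Dk_gamma * self.template.wt ** (-2 / 3) * own)
        return gy * _GY_TO_MGY

    def cumulative_dose(self, t: float) -> float:
        if t < 0:
            raise ValueError("t must be >= 0")
        co = self.template.coefficients
        own = self._curve_integral(t)
        other = float(self._other_terms(t, integrated=True))
        if self.kind == "blood":
            gy = self.template.A0 * (co.Dk_beta * own
                                     + co.Dk_gamma * self.template.wt ** (-2 / 3) * other)
        else:
            gy = self.template.A0 * (co.Dk_beta * other
                                     + co.Dk_gamma * self.template.wt ** (-2 / 3) * own)
        return gy * _GY_TO_MGY

    def total_dose(self, horizon: float = 1e5) -> float:
        return self.cumulative_dose(horizon)


def piecewise_tiac(
    series: TimeActivitySeries,
    breakpoint: float,
    template: PatientDosimetry,
) -> PiecewiseDosimetry:
    """Build a piecewise dose evaluator (bi-exponential before the breakpoint,
    trapezoid-integrated measurements after, physical-decay tail at the end)."""
    return PiecewiseDosimetry(series, breakpoint, template)
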