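"""Blood dosimetry: bi-exponential fitting, dose rate and cumulative dose."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from riftrace import (BiExpClearance, DoseCoefficients, PatientDosimetry,
                      TimeActivitySeries, cumulative_dose, dose_rate,
                      fit_biexponential, piecewise_tiac, tiacs, total_dose)
from riftrace.dosimetry import L_PHYS_I131

from .conftest import random_patient


class TestBiExpClearance:
    def test_requires_two_components(self):
        with pytest.raises(ValueError):
            BiExpClearance(a=(1.0,), l=(0.1,))

    def test_rejects_negative_rates_and_all_negative_amplitudes(self):
        with pytest.raises(ValueError):
            BiExpClearance(a=(1.0, 0.5), l=(-0.1, 0.01))
        with pytest.raises(ValueError):
            BiExpClearance(a=(-1.0, -0.5), l=(0.1, 0.01))

    def test_uptake_phase_allowed_when_curve_stays_nonnegative(self):
        c = BiExpClearance(a=(1.0, -0.5), l=(0.01, 0.1))
        c.check_nonnegative()

    def test_wholebody_retention_at_zero_must_be_near_unity(self, coefficients):
        bad_wb = BiExpClearance(a=(0.4, 0.1), l=(0.05, 0.01))
        with pytest.raises(ValueError, match="retention"):
            PatientDosimetry(A0=3.5, wt=70, blood=bad_wb, wholebody=bad_wb,
                             coefficients=coefficients)


class TestFitBiexponential:
    TIMES = np.array([1, 2, 3, 4, 24, 48, 96, 168], float)

    def test_exact_recovery_noise_free(self, coefficients):
        truth = BiExpClearance(a=(0.08e-3, 0.02e-3), l=(0.15, 0.01))
        y = 3.5 * truth.value(self.TIMES, coefficients.l_phys)
        fit, diag = fit_biexponential(
            TimeActivitySeries(t=self.TIMES, value=y, kind="blood"), coefficients, 3.5)
        for got, want in zip(fit.a + fit.l, truth.a + truth.l):
            assert got == pytest.approx(want, rel=1e-6)
        assert diag.rss < 1e-20

    def test_single_exponential_yields_degenerate_second_component(self, coefficients):
        truth = BiExpClearance(a=(0.05e-3, 0.0), l=(0.08, 0.0))
        y = 3.5 * truth.value(self.TIMES, coefficients.l_phys)
        fit, _ = fit_biexponential(
            TimeActivitySeries(t=self.TIMES, value=y, kind="blood"), coefficients, 3.5)
        # dose functions must match the generating single exponential
        wb = BiExpClearance(a=(0.85, 0.15), l=(0.06, 0.012))
        pd_fit = PatientDosimetry(A0=3.5, wt=70, blood=fit, wholebody=wb,
                                  coefficients=coefficients)
        pd_true = PatientDosimetry(A0=3.5, wt=70, blood=truth, wholebody=wb,
                                   coefficients=coefficients)
        for t in (1.0, 10.0, 100.0):
            assert cumulative_dose(pd_fit, t) == pytest.approx(
                cumulative_dose(pd_true, t), rel=1e-6)

    def test_noisy_tiac_recovery_median_under_2_percent(self, coefficients):
        truth = BiExpClearance(a=(3.0e-5, 4.0e-6), l=(0.07, 0.012))
        tau_true = sum(a / (l + coefficients.l_phys) for a, l in zip(truth.a, truth.l))
        y0 = 3.5 * truth.value(self.TIMES, coefficients.l_phys)
        errs = []
        rng = np.random.default_rng(42)
        for _ in range(50):
            y = y0 * (1 + 0.01 * rng.standard_normal(len(y0)))
            fit, _ = fit_biexponential(
                TimeActivitySeries(t=self.TIMES, value=y, kind="blood"),
                coefficients, 3.5)
            tau = sum(a / (l + coefficients.l_phys) for a, l in zip(fit.a, fit.l))
            errs.append(abs(tau / tau_true - 1))
        assert np.median(errs) < 0.02

    def test_refuses_fewer_than_five_points(self, coefficients):
        t = np.array([1, 2, 3, 4], float)
        with pytest.raises(ValueError, match="5 samples"):
            fit_biexponential(TimeActivitySeries(t=t, value=np.ones(4), kind="blood"),
                              coefficients, 3.5)

    def test_super_physical_retention_clamped(self, coefficients, caplog):
        # constant activity: decay-inclusive rate ~0 < l_phys
        y = np.full(len(self.TIMES), 1e-4)
        with caplog.at_level("WARNING"):
            fit, diag = fit_biexponential(
                TimeActivitySeries(t=self.TIMES, value=y, kind="blood"),
                coefficients, 3.5)
        assert diag.clamped
        assert min(fit.l) == 0.0


class TestDoseFunctions:
    def test_rejects_negative_time(self, patient):
        with pytest.raises(ValueError):
            dose_rate(patient, -1.0)
        with pytest.raises(ValueError):
            cumulative_dose(patient, -0.5)

    def test_dose_rate_is_derivative_of_cumulative_dose(self, patient):
        for t in (0.5, 2.0, 10.0, 50.0, 200.0):
            h = 1e-4 * max(t, 1.0)
            fd = (cumulative_dose(patient, t + h) - cumulative_dose(patient, t - h)) / (2 * h)
            assert dose_rate(patient, t) == pytest.approx(fd, rel=1e-6)

    def test_cumulative_matches_quadrature_on_random_patients(self, coefficients):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pd = random_patient(rng, coefficients)
            t_end = rng.uniform(10.0, 500.0)
            q, _ = quad(lambda t: dose_rate(pd, t), 0.0, t_end, limit=200)
            assert cumulative_dose(pd, t_end) == pytest.approx(q, rel=1e-8)

    def test_cumulative_dose_starts_at_zero_and_is_monotone(self, patient):
        assert cumulative_dose(patient, 0.0) == 0.0
        grid = np.linspace(0, 2000, 400)
        d = cumulative_dose(patient, grid)
        assert np.all(np.diff(d) >= 0)

    def test_total_dose_bounds_and_large_t_limit(self, patient):
        tot = total_dose(patient)
        for t in (1.0, 100.0, 1000.0):
            assert tot >= cumulative_dose(patient, t)
        assert tot == pytest.approx(cumulative_dose(patient, 1e5), rel=1e-6)

    def test_linearity_in_administered_activity(self, patient, coefficients):
        doubled = PatientDosimetry(A0=2 * patient.A0, wt=patient.wt,
                                   blood=patient.blood, wholebody=patient.wholebody,
                                   coefficients=coefficients)
        assert total_dose(doubled) == pytest.approx(2 * total_dose(patient), rel=1e-12)
        assert dose_rate(doubled, 5.0) == pytest.approx(2 * dose_rate(patient, 5.0),
                                                        rel=1e-12)

    def test_degenerate_zero_rate_uses_linear_limit(self, coefficients):
        # biological rate 0 + tiny l_phys: the a*t limit must kick in smoothly
        co = DoseCoefficients(Dk_beta=108.0, Dk_gamma=0.0188, l_phys=1e-12)
        pd = PatientDosimetry(
            A0=3.5, wt=70,
            blood=BiExpClearance(a=(3e-5, 0.0), l=(0.0, 0.1)),
            wholebody=BiExpClearance(a=(0.9, 0.1), l=(0.05, 0.01)),
            coefficients=co)
        t = 10.0
        beta_part = 3.5 * 108.0 * 3e-5 * t * 1e3
        gamma_part = cumulative_dose(
            PatientDosimetry(A0=3.5, wt=70,
                             blood=BiExpClearance(a=(1e-30, 0.0), l=(1.0, 1.0)),
                             wholebody=pd.wholebody, coefficients=co), t)
        assert cumulative_dose(pd, t) == pytest.approx(beta_part + gamma_part, rel=1e-6)


class TestPiecewiseTiac:
    TIMES = np.array([1, 2, 3, 4, 8, 16, 24, 36, 48, 72, 96, 120, 168,
                      240, 336, 480, 720], float)

    def _series(self, patient, scale=1.0, mutate=None):
        y = patient.A0 * patient.blood.value(self.TIMES,
                                             patient.coefficients.l_phys) * scale
        if mutate is not None:
            y = mutate(self.TIMES, y)
        return TimeActivitySeries(t=self.TIMES, value=y, kind="blood")

    def test_self_consistency_on_model_true_data(self, patient):
        for bp in (24.0, 48.0, 96.0):
            pw = piecewise_tiac(self._series(patient), bp, patient)
            assert pw.total_dose() == pytest.approx(total_dose(patient), rel=0.02)

    def test_cumulative_continuous_at_breakpoint(self, patient):
        pw = piecewise_tiac(self._series(patient), 48.0, patient)
        eps = 1e-6
        assert pw.cumulative_dose(48.0 - eps) == pytest.approx(
            pw.cumulative_dose(48.0 + eps), abs=1e-3)

    def test_reuptake_curve_adds_dose(self, patient):
        def reuptake(t, y):
            y = y.copy()
            y[t >= 96] *= 3.0
            return y

        pw_plain = piecewise_tiac(self._series(patient), 48.0, patient)
        pw_up = piecewise_tiac(self._series(patient, mutate=reuptake), 48.0, patient)
        assert pw_up.total_dose() > pw_plain.total_dose()

    def test_zero_activity_after_breakpoint_adds_nothing(self, coefficients):
        # gamma term switched off (negligible coefficient) to isolate the blood
        co = DoseCoefficients(Dk_beta=108.0, Dk_gamma=1e-30)
        pd = PatientDosimetry(A0=3.5, wt=70,
                              blood=BiExpClearance(a=(3e-5, 4e-6), l=(0.07, 0.012)),
                              wholebody=BiExpClearance(a=(0.85, 0.15), l=(0.06, 0.012)),
                              coefficients=co)
        y = pd.A0 * pd.blood.value(self.TIMES, co.l_phys)
        y[self.TIMES >= 48.0] = 0.0
        pw = piecewise_tiac(TimeActivitySeries(t=self.TIMES, value=y, kind="blood"),
                            48.0, pd)
        pd_refit = PatientDosimetry(A0=3.5, wt=70, blood=pw.pre_fit,
                                    wholebody=pd.wholebody, coefficients=co)
        assert pw.total_dose() == pytest.approx(cumulative_dose(pd_refit, 48.0),
                                                rel=1e-9)

    def test_breakpoint_validation(self, patient):
        with pytest.raises(ValueError, match="sample times"):
            piecewise_tiac(self._series(patient), 47.0, patient)
        with pytest.raises(ValueError):
            piecewise_tiac(self._series(patient), float(self.TIMES[-1]), patient)


def test_physical_decay_constant_matches_half_life():
    assert L_PHYS_I131 == pytest.approx(math.log(2) / (8.02 * 24), rel=5e-3)
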