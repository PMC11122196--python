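import math

import numpy as np
import pytest

from riftrace import (BiExpClearance, DoseCoefficients, GeneratorConfig,
                      PatientDosimetry, generate_cohort)
from riftrace.kinetics import rif_from_counts


@pytest.fixture(scope="session")
def coefficients() -> DoseCoefficients:
    return DoseCoefficients(Dk_beta=108.0, Dk_gamma=0.0188)


@pytest.fixture(scope="session")
def patient(coefficients) -> PatientDosimetry:
    """A cohort-scale reference patient (total blood dose ~350 mGy)."""
    return PatientDosimetry(
        A0=3.57, wt=70.0,
        blood=BiExpClearance(a=(3.0e-5, 4.0e-6), l=(0.07, 0.012)),
        wholebody=BiExpClearance(a=(0.85, 0.15), l=(0.06, 0.012)),
        coefficients=coefficients)


def random_patient(rng: np.random.Generator,
                   coefficients: DoseCoefficients) -> PatientDosimetry:
    """Draw a random valid patient dosimetry (used by property tests)."""
    return PatientDosimetry(
        A0=rng.uniform(3.4, 4.0), wt=rng.uniform(45.0, 115.0),
        blood=BiExpClearance(a=(rng.uniform(1e-5, 5e-5), rng.uniform(1e-6, 8e-6)),
                             l=(rng.uniform(0.03, 0.12), rng.uniform(0.003, 0.02))),
        wholebody=BiExpClearance(a=(0.8, 0.2),
                                 l=(rng.uniform(0.03, 0.09), rng.uniform(0.005, 0.02))),
        coefficients=coefficients)


def patient_rif(sp):
    """Baseline-subtracted RIF series and baseline sigma for a synthetic patient."""
    rif = [rif_from_counts(fc, sp.baseline) for fc in sp.samples]
    sigma0 = math.sqrt(max(sp.baseline.foci_total, 1)) / sp.baseline.cells
    return rif, sigma0


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve synthetic patients on the full nominal schedule."""
    return generate_cohort(GeneratorConfig(n_patients=12, seed=7, missing_prob={}))
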