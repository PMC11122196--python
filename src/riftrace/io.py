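"""CSV and config I/O.

CSV is the single interchange format: UTF-8, dot decimal, mandatory header.
Readers validate required columns and fail with a column-level message.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dosimetry import DoseCoefficients, TimeActivitySeries

REQUIRED_COLUMNS = {
    "patients": ("patient_id", "age_y", "weight_kg", "a0_gbq"),
    "blood_activity": ("patient_id", "t_h", "activity_gbq_per_ml"),
    "wholebody_retention": ("patient_id", "t_h", "retention_fraction"),
    "foci_counts": ("patient_id", "t_h", "foci_total", "cells", "is_baseline"),
}


class DataError(ValueError):
    """Malformed or incomplete input data."""


def _read_validated(path: str | Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing} for table '{table}'")
    return df


def read_patients(path: str | Path) -> pd.DataFrame:
    return _read_validated(path, "patients").set_index("patient_id")


def read_blood_activity(path: str | Path) -> pd.DataFrame:
    return _read_validated(path, "blood_activity")


def read_wholebody_retention(path: str | Path) -> pd.DataFrame:
    return _read_validated(path, "wholebody_retention")


def read_foci_counts(path: str | Path) -> pd.DataFrame:
    return _read_validated(path, "foci_counts")


def activity_series(df: pd.DataFrame, patient_id: str, kind: str) -> TimeActivitySeries:
    """Build a TimeActivitySeries from one patient's rows of an activity table."""
    value_col = "activity_gbq_per_ml" if kind == "blood" else "retention_fraction"
    sub = df[df["patient_id"] == patient_id].sort_values("t_h")
    if sub.empty:
        raise DataError(f"no {kind} activity rows for patient {patient_id}")
    sigma = sub["sigma"].to_numpy() if "sigma" in sub.columns else None
    return TimeActivitySeries(t=sub["t_h"].to_numpy(), value=sub[value_col].to_numpy(),
                              kind=kind, sigma=sigma)


def load_coefficients(path: str | Path | None = None) -> DoseCoefficients:
    """Load dose coefficients from a YAML/JSON config; the packaged example
    config transcribes the standard blood-dosimetry coefficients."""
    if path is None:
        with resources.files("riftrace.data").joinpath("example_config.yaml").open() as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = yaml.safe_load(Path(path).read_text())
    co = cfg["dose_coefficients"]
    return DoseCoefficients(Dk_beta=float(co["Dk_beta"]), Dk_gamma=float(co["Dk_gamma"]),
                            l_phys=float(co.get("l_phys", 0.00360)))


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged regression fixture (``table1`` or ``table3``)."""
    with resources.files("riftrace.data").joinpath(f"{name}.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("patient_id")
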