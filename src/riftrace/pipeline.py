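"""End-to-end orchestration: dosimetry -> RIF -> fits -> cohort statistics.

``run_pipeline`` ties the stages together for a directory of input CSVs and
writes all result tables plus a config snapshot; ``reproduce_tables`` reruns
the published cohort analysis from the packaged fixture tables and prints a
pass/fail comparison against the published values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cs
from .dosimetry import (DoseCoefficients, PatientDosimetry, cumulative_dose,
                        dose_rate, fit_biexponential, tiacs, total_dose)
from .fitting import (FitOptions, FitResult, fit_patient, fit_pooled,
                      linear_fit_doserate, linear_fit_induction)
from .io import (DataError, activity_series, load_fixture, read_blood_activity,
                 read_foci_counts, read_patients, read_wholebody_retention)
from .kinetics import FociCount, RifPoint, rif_from_counts

logger = logging.getLogger(__name__)

NOMINAL_REPORT_TIMES = (1.0, 2.0, 3.0, 4.0, 24.0, 48.0, 96.0, 168.0)


@dataclass
class PipelineConfig:
    indir: str
    outdir: str
    coefficients: DoseCoefficients = field(
        default_factory=lambda: DoseCoefficients(Dk_beta=108.0, Dk_gamma=0.0188))
    fit_options: FitOptions = field(default_factory=FitOptions)
    k1_low: float = 0.6
    k1_high: float = 1.1
    exclude: tuple[str, ...] = ()       # explicit outlier list for k-means
    seed: int = 0

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _build_dosimetry(patients: pd.DataFrame, blood: pd.DataFrame,
                     wb: pd.DataFrame, co: DoseCoefficients) -> dict[str, PatientDosimetry]:
    out: dict[str, PatientDosimetry] = {}
    for pid, row in patients.iterrows():
        try:
            bl_series = activity_series(blood, pid, "blood")
            wb_series = activity_series(wb, pid, "wholebody")
            bl_fit, _ = fit_biexponential(bl_series, co, row["a0_gbq"])
            wb_fit, _ = fit_biexponential(wb_series, co, 1.0)  # retention is already a fraction
            out[pid] = PatientDosimetry(
                A0=row["a0_gbq"], wt=row["weight_kg"], blood=bl_fit, wholebody=wb_fit,
                coefficients=co, allow_retention_outside_unity=True)
            f0 = sum(wb_fit.a)
            if not 0.9 <= f0 <= 1.1:
                logger.warning("patient %s: whole-body retention at t=0 is %.3f", pid, f0)
        except (DataError, ValueError, RuntimeError) as exc:
            logger.warning("patient %s: dosimetry failed (%s)", pid, exc)
    return out


def _rif_series(foci: pd.DataFrame) -> dict[str, tuple[list[RifPoint], float]]:
    """Per patient: baseline-subtracted RIF points and the baseline sigma."""
    out = {}
    for pid, sub in foci.groupby("patient_id"):
        base_rows = sub[sub["is_baseline"] == 1]
        if base_rows.empty:
            logger.warning("patient %s: no baseline sample, skipped", pid)
            continue
        b = base_rows.iloc[0]
        baseline = FociCount(t=float(b["t_h"]), foci_total=int(b["foci_total"]),
                             cells=int(b["cells"]))
        pts = []
        for _, r in sub[sub["is_baseline"] == 0].sort_values("t_h").iterrows():
            fc = FociCount(t=float(r["t_h"]), foci_total=int(r["foci_total"]),
                           cells=int(r["cells"]))
            pts.append(rif_from_counts(fc, baseline))
        sigma0 = math.sqrt(max(baseline.foci_total, 1)) / baseline.cells
        out[pid] = (pts, sigma0)
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages and write results under ``cfg.outdir``.

    Per-patient failures are recorded in the outputs, not fatal; only
    structural input errors raise.
    """
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    logging.getLogger().addHandler(fh)
    try:
        patients = read_patients(indir / "patients.csv")
        blood = read_blood_activity(indir / "blood_activity.csv")
        wb = read_wholebody_retention(indir / "wholebody_retention.csv")
        foci = read_foci_counts(indir / "foci_counts.csv")

        # --- dosimetry -------------------------------------------------------
        dosim = _build_dosimetry(patients, blood, wb, cfg.coefficients)
        rows = []
        for pid, pdm in dosim.items():
            tau_bl, tau_wb = tiacs(pdm)
            row = {"patient_id": pid,
                   "a1_bl": pdm.blood.a[0], "a2_bl": pdm.blood.a[1],
                   "l1_bl": pdm.blood.l[0], "l2_bl": pdm.blood.l[1],
                   "a1_wb": pdm.wholebody.a[0], "a2_wb": pdm.wholebody.a[1],
                   "l1_wb": pdm.wholebody.l[0], "l2_wb": pdm.wholebody.l[1],
                   "tau_bl_h_per_ml": tau_bl, "tau_wb_h": tau_wb}
            for t in NOMINAL_REPORT_TIMES:
                row[f"dose_{t:g}h_mgy"] = cumulative_dose(pdm, t)
            row["total_dose_mgy"] = total_dose(pdm)
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "dosimetry.csv", index=False)

        # --- RIF preprocessing ----------------------------------------------
        rifs = _rif_series(foci)
        rif_rows = [{"patient_id": pid, "t_h": p.t, "rif_per_cell": p.N, "sigma": p.sigma}
                    for pid, (pts, _) in rifs.items() for p in pts]
        pd.DataFrame(rif_rows).to_csv(outdir / "rif_series.csv", index=False)

        # --- per-patient fits -------------------------------------------------
        fits: dict[str, FitResult] = {}
        for pid in patients.index:
            if pid not in dosim or pid not in rifs:
                continue
            pts, sigma0 = rifs[pid]
            fits[pid] = fit_patient(pts, dosim[pid], cfg.fit_options, baseline_sigma=sigma0)
        fit_df = pd.DataFrame({pid: fr.as_row() for pid, fr in fits.items()}).T
        fit_df.index.name = "patient_id"
        fit_df.to_csv(outdir / "fits.csv")

        # --- grouping, pooled fits, k-means ----------------------------------
        ok = {pid: fr for pid, fr in fits.items() if fr.converged and not fr.excluded}
        k1_series = pd.Series({pid: fr.params.k1 for pid, fr in ok.items()})
        groups = cs.group_by_k1(k1_series, cfg.k1_low, cfg.k1_high)
        groups.rename("group").to_csv(outdir / "groups.csv", index_label="patient_id")

        pooled_rows = []
        for glabel in ("1", "2"):
            members = [pid for pid in ok if groups.get(pid) == glabel]
            if len(members) < 2:
                continue
            pooled = fit_pooled([(rifs[pid][0], dosim[pid]) for pid in members],
                                cfg.fit_options)
            row = pooled.as_row()
            row["group"] = glabel
            row["n_patients"] = len(members)
            pooled_rows.append(row)
        pd.DataFrame(pooled_rows).to_csv(outdir / "pooled_fits.csv", index=False)

        param_df = pd.DataFrame({pid: {"k1": fr.params.k1, "k2": fr.params.k2,
                                       "c": fr.params.c} for pid, fr in ok.items()}).T
        km_result = None
        if len(param_df.dropna()) >= 2:
            exclude = cfg.exclude or tuple(cs.detect_outlier(param_df))
            try:
                km_result = cs.kmeans_params(param_df, exclude=exclude,
                                             random_state=cfg.seed)
            except ValueError as exc:
                logger.warning("k-means skipped: %s", exc)

        # --- linear fits ------------------------------------------------------
        early, late = [], []
        for pid, (pts, _) in rifs.items():
            if pid not in dosim:
                continue
            for p in pts:
                if p.t < 6.0:
                    early.append((cumulative_dose(dosim[pid], p.t), p.N))
                if p.t >= 20.0:
                    late.append((dose_rate(dosim[pid], p.t), p.N))
        lin_rows = []
        if len(early) >= 3:
            lf = linear_fit_induction(np.array([d for d, _ in early]),
                                      np.array([n for _, n in early]))
            lin_rows.append({"fit": "induction_vs_dose", "slope": lf.slope,
                             "slope_se": lf.slope_se, "intercept": lf.intercept,
                             "intercept_se": lf.intercept_se, "r2": lf.r2, "n": lf.n})
        if len(late) >= 3:
            lf = linear_fit_doserate(np.array([d for d, _ in late]),
                                     np.array([n for _, n in late]))
            lin_rows.append({"fit": "rif_vs_doserate", "slope": lf.slope,
                             "slope_se": lf.slope_se, "intercept": lf.intercept,
                             "intercept_se": lf.intercept_se, "r2": lf.r2, "n": lf.n})
        pd.DataFrame(lin_rows).to_csv(outdir / "linear_fits.csv", index=False)

        # --- cohort statistics ------------------------------------------------
        cohort_df = patients.rename(columns={"age_y": "age", "weight_kg": "weight"}).copy()
        for pid, fr in ok.items():
            for name, v in (("c", fr.params.c), ("k1", fr.params.k1),
                            ("k2", fr.params.k2), ("alpha", fr.params.alpha),
                            ("n0", fr.params.N0)):
                cohort_df.loc[pid, name] = v
        for pid, (pts, _) in rifs.items():
            for p in pts:
                if p.t == 1.0:
                    cohort_df.loc[pid, "rif_1h"] = p.N
                if p.t == 48.0:
                    cohort_df.loc[pid, "rif_48h"] = p.N
        battery = cs.correlation_battery(cohort_df)

        summary_fits = pd.DataFrame(
            {pid: {"c": fr.params.c if fr.params else np.nan,
                   "k1": fr.params.k1 if fr.params else np.nan,
                   "k2": fr.params.k2 if fr.params else np.nan,
                   "alpha": fr.params.alpha if fr.params else np.nan,
                   "n0": fr.params.N0 if fr.params else np.nan,
                   "excluded": fr.excluded, "reason": fr.reason}
             for pid, fr in fits.items()}).T
        for col in ("c", "k1", "k2", "alpha", "n0"):
            summary_fits[col] = pd.to_numeric(summary_fits[col])
        summary = cs.summarize_cohort(summary_fits)
        if km_result is not None:
            summary["kmeans_centroids"] = {
                lab: dict(km_result.centroids.loc[lab])
                for lab in km_result.centroids.index}

        (outdir / "cohort_stats.json").write_text(
            json.dumps([r.as_dict() for r in battery], indent=2))
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        (outdir / "config_snapshot.yaml").write_text(yaml.safe_dump(cfg.snapshot()))
        return outdir
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()


def stats_only(fits: pd.DataFrame, patients: pd.DataFrame | None = None,
               exclude: tuple[str, ...] = (), seed: int = 0) -> dict:
    """Cohort statistics from an existing per-patient fit table.

    ``fits`` needs columns c, alpha, k1, k2, n0 (patient_id index); covariates
    (age, weight, ...) are joined from ``patients`` when given.  Returns the
    summary, the correlation battery and, when enough complete parameter sets
    exist, the k-means grouping.
    """
    cohort_df = fits.copy()
    if patients is not None:
        cohort_df = cohort_df.join(
            patients.rename(columns={"age_y": "age", "weight_kg": "weight"}),
            how="left")
    out: dict = {"summary": cs.summarize_cohort(fits)}
    out["battery"] = [r.as_dict() for r in cs.correlation_battery(cohort_df)]
    params = fits[["k1", "k2", "c"]].dropna()
    if len(params) >= 4:
        excl = exclude or tuple(cs.detect_outlier(params))
        try:
            km = cs.kmeans_params(params, exclude=excl, random_state=seed)
            out["kmeans"] = {
                "excluded": list(excl),
                "centroids": {lab: dict(km.centroids.loc[lab])
                              for lab in km.centroids.index},
                "assignments": dict(km.assignments),
            }
        except ValueError as exc:
            logger.warning("k-means skipped: %s", exc)
    return out


# published cohort statistics used by the fixture pass/fail report
_EXPECTED_FIXTURE_STATS = {
    "median_c": 0.026, "mean_alpha_percent": 96.0, "mean_n0": -0.018,
    "spearman_k1_c": 0.947, "spearman_k1_k2": 0.661, "spearman_k2_c": 0.616,
    "spearman_age_k1": -0.541, "spearman_age_k2": -0.615, "spearman_age_c": -0.624,
    "centroid1_k1": 0.37429, "centroid1_c": 0.02143, "centroid1_k2": 0.00657,
    "centroid2_k1": 1.3208, "centroid2_c": 0.052, "centroid2_k2": 0.0276,
}


def fixture_statistics(seed: int = 0) -> dict[str, float]:
    """Recompute the published cohort statistics from the fixture tables."""
    t3 = load_fixture("table3")
    t1 = load_fixture("table1")
    merged = t3.join(t1[["age_y"]]).rename(columns={"age_y": "age"})
    out: dict[str, float] = {}
    out["median_c"] = float(t3["c"].median())
    out["mean_alpha_percent"] = float(t3["alpha"].mean() * 100)
    out["mean_n0"] = float(t3["n0"].mean())
    for a, b, key in [("k1", "c", "spearman_k1_c"), ("k1", "k2", "spearman_k1_k2"),
                      ("k2", "c", "spearman_k2_c"), ("age", "k1", "spearman_age_k1"),
                      ("age", "k2", "spearman_age_k2"), ("age", "c", "spearman_age_c")]:
        sub = merged[[a, b]].dropna()
        out[key] = cs.correlate(sub[a], sub[b], method="spearman").statistic
    km = cs.kmeans_params(t3, exclude=("IP6", "IP18"), random_state=seed)
    for lab in ("1", "2"):
        for col in ("k1", "k2", "c"):
            out[f"centroid{lab}_{col}"] = float(km.centroids.loc[lab, col])
    return out


def reproduce_tables(seed: int = 0, rtol: float = 5e-3) -> tuple[pd.DataFrame, bool]:
    """Recompute every fixture statistic and compare with the published value."""
    got = fixture_statistics(seed)
    rows = []
    all_ok = True
    for key, expected in _EXPECTED_FIXTURE_STATS.items():
        value = got[key]
        ok = math.isclose(value, expected, rel_tol=rtol, abs_tol=5e-4)
        all_ok &= ok
        rows.append({"statistic": key, "computed": value, "published": expected,
                     "pass": ok})
    return pd.DataFrame(rows), all_ok
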