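"""Cohort-level analysis of fitted foci-kinetics parameters.

Patients are stratified by their fast repair rate k1 (a slow-repair group
below 0.6 h⁻¹ and a fast-repair group above 1.1 h⁻¹), cross-validated by
k-means clustering on the raw (k1, k2, c) triples, and screened with a
normality-routed correlation battery: Shapiro-Wilk at 5% decides between
Pearson and Spearman for correlations and between the t-test and the
Mann-Whitney U test for group contrasts.  No multiple-testing correction is
applied by default (unadjusted p at 5%); Benjamini-Hochberg is available as
an opt-in flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

PARAM_COLS = ("k1", "k2", "c")

#: clinical covariates screened against every fit parameter
CLINICAL_COVARIATES = ("weight", "tsh", "ft3", "ft4", "tg", "creatinine",
                       "platelets", "wbc")


@dataclass
class StatResult:
    pair: str
    method: str            # pearson | spearman | t-test | mann-whitney | shapiro-wilk
    statistic: float
    pvalue: float
    n: int
    normal_x: bool | None = None
    normal_y: bool | None = None

    def as_dict(self) -> dict:
        return {"pair": self.pair, "method": self.method,
                "statistic": self.statistic, "pvalue": self.pvalue, "n": self.n}


def group_by_k1(k1: pd.Series, low_threshold: float = 0.6,
                high_threshold: float = 1.1) -> pd.Series:
    """Label patients 1 (slow repair, k1 < low) or 2 (fast repair, k1 > high);
    values in the gap are 'unassigned'."""
    if not low_threshold < high_threshold:
        raise ValueError("low threshold must be below high threshold")
    k1 = pd.Series(k1)

    def label(v):
        if not np.isfinite(v):
            return "excluded"
        if v < low_threshold:
            return "1"
        if v > high_threshold:
            return "2"
        return "unassigned"

    return k1.map(label)


@dataclass
class KMeansResult:
    assignments: pd.Series          # cluster label "1"/"2" per patient id
    centroids: pd.DataFrame         # rows: cluster label; cols: k1, k2, c
    inertia: float


def kmeans_params(fits: pd.DataFrame, k: int = 2,
                  exclude: tuple[str, ...] = (),
                  n_restarts: int = 20, random_state: int = 0) -> KMeansResult:
    """k-means on the *unstandardized* (k1, k2, c) triples.

    Only patients with all three parameters enter; ``exclude`` removes known
    outliers first.  The cluster whose centroid has the smaller k1 is labelled
    1.  Unstandardized variables are intentional: the cluster centroids then
    equal the raw within-group parameter means even though k1 dominates the
    metric (asserted on every run).
    """
    sub = fits.loc[~fits.index.isin(exclude), list(PARAM_COLS)].dropna()
    if len(sub) < k:
        raise ValueError(f"need at least {k} complete patients, got {len(sub)}")
    X = sub.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=random_state).fit(X)

    order = np.argsort(km.cluster_centers_[:, 0])  # smaller k1 -> label 1
    relabel = {orig: str(i + 1) for i, orig in enumerate(order)}
    labels = pd.Series([relabel[c] for c in km.labels_], index=sub.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_[order], columns=list(PARAM_COLS),
                             index=[str(i + 1) for i in range(k)])
    # definitional invariant: centroids are within-cluster means of the raw data
    for lab in centroids.index:
        means = sub.loc[labels == lab].mean().to_numpy()
        assert np.allclose(means, centroids.loc[lab].to_numpy(), atol=1e-10), \
            "k-means centroid does not equal within-cluster mean"
    return KMeansResult(assignments=labels, centroids=centroids,
                        inertia=float(km.inertia_))


def detect_outlier(fits: pd.DataFrame, explicit: tuple[str, ...] | None = None,
                   iqr_factor: float = 1.5) -> list[str]:
    """Flag parameter outliers: any of (k1, k2, c) above Q3 + 1.5*IQR.

    An explicit patient list bypasses the rule for exact reproduction of a
    published exclusion.
    """
    if explicit is not None:
        return [p for p in explicit if p in fits.index]
    flagged: list[str] = []
    sub = fits[list(PARAM_COLS)]
    for col in PARAM_COLS:
        v = sub[col].dropna()
        q1, q3 = v.quantile([0.25, 0.75])
        fence = q3 + iqr_factor * (q3 - q1)
        flagged.extend(v.index[v > fence])
    return sorted(set(flagged), key=list(fits.index).index)


def _is_normal(v: np.ndarray, alpha: float = 0.05) -> bool:
    return bool(stats.shapiro(v).pvalue > alpha)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's r (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate(x, y, pair: str = "", method: str = "auto",
              alpha: float = 0.05) -> StatResult:
    """Correlation with normality routing.

    ``method='auto'`` runs Shapiro-Wilk on each variable: Pearson when both
    pass at the 5% level, Spearman (tie-corrected average ranks) otherwise.
    Spearman p-values use the t-approximation for n >= 10 and exact
    permutation for smaller samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 paired values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")

    nx = ny = None
    if method == "auto":
        nx, ny = _is_normal(x, alpha), _is_normal(y, alpha)
        method = "pearson" if (nx and ny) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
        if n < 10:
            p = _spearman_exact_p(x, y, r)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(pair=pair, method=method, statistic=float(r), pvalue=float(p),
                      n=n, normal_x=nx, normal_y=ny)


def compare_groups(values, labels, pair: str = "", method: str = "auto",
                   alpha: float = 0.05) -> StatResult:
    """Two-sample contrast with normality routing (t-test vs Mann-Whitney U).

    ``method='auto'`` runs Shapiro-Wilk per group at 5%: t-test when both
    pass, Mann-Whitney U otherwise; either test can also be requested
    explicitly.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [g for g in pd.unique(labels) if g is not None]
    if len(groups) != 2:
        raise ValueError("exactly two group labels required")
    a = values[(labels == groups[0]) & np.isfinite(values)]
    b = values[(labels == groups[1]) & np.isfinite(values)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 finite values")
    if method == "auto":
        both_normal = (np.ptp(a) > 0 and np.ptp(b) > 0
                       and _is_normal(a, alpha) and _is_normal(b, alpha))
        method = "t-test" if both_normal else "mann-whitney"
    if method == "t-test":
        s, p = stats.ttest_ind(a, b)
    elif method == "mann-whitney":
        s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(pair=pair, method=method, statistic=float(s), pvalue=float(p),
                      n=len(a) + len(b))


def summarize_cohort(fits: pd.DataFrame) -> dict:
    """Headline statistics of the fitted cohort.

    Median/min/max of c, k1, k2; mean ± SD of alpha (percent repaired fast)
    and N0; exclusion counts by reason.
    """
    excl_mask = (fits.get("excluded", pd.Series(False, index=fits.index))
                 .astype("boolean").fillna(False).astype(bool))
    ok = fits[~excl_mask]
    out: dict = {"n_total": int(len(fits)), "n_fitted": int(len(ok))}
    for col in ("c", "k1", "k2"):
        v = ok[col].dropna()
        out[col] = {"median": float(v.median()), "min": float(v.min()),
                    "max": float(v.max()), "n": int(len(v))}
    a = ok["alpha"].dropna()
    out["alpha_percent"] = {"mean": float(a.mean() * 100), "sd": float(a.std(ddof=1) * 100)}
    n0 = ok["n0"].dropna()
    out["n0"] = {"mean": float(n0.mean()), "sd": float(n0.std(ddof=1))}
    if "reason" in fits:
        reasons = fits.loc[excl_mask, "reason"]
        out["excluded"] = {str(k): int(v) for k, v in reasons.value_counts().items()}
    return out


#: the published analysis panel with the reporting method pinned per pair;
#: pairs not listed here are routed automatically by Shapiro-Wilk
_PINNED_PANEL = [
    ("k1", "k2", "spearman"), ("k1", "c", "spearman"), ("k2", "c", "spearman"),
    ("k1", "R", "spearman"), ("k2", "R", "spearman"), ("c", "R", "spearman"),
    ("age", "k1", "spearman"), ("age", "k2", "spearman"), ("age", "c", "spearman"),
    ("age", "rif_1h", "pearson"), ("age", "rif_48h", "pearson"),
    ("age", "R", "pearson"),
]


def correlation_battery(cohort: pd.DataFrame, adjust: bool = False) -> list[StatResult]:
    """Run the full cohort correlation panel.

    Fit-parameter and age pairs use the panel's pinned methods; every fit
    parameter is additionally screened against each available clinical
    covariate with automatic normality routing.  Each pair uses all patients
    with both values available (n recorded per pair).  ``adjust=True`` adds
    Benjamini-Hochberg adjusted p-values in place of the raw ones.
    """
    results: list[StatResult] = []
    for xcol, ycol, method in _PINNED_PANEL:
        if xcol not in cohort or ycol not in cohort:
            continue
        sub = cohort[[xcol, ycol]].dropna()
        if len(sub) < 4:
            continue
        results.append(correlate(sub[xcol], sub[ycol], pair=f"{xcol}~{ycol}",
                                 method=method))
    for param in ("c", "k1", "k2"):
        for cov in CLINICAL_COVARIATES:
            if param not in cohort or cov not in cohort:
                continue
            sub = cohort[[param, cov]].dropna()
            if len(sub) < 4:
                continue
            results.append(correlate(sub[param], sub[cov],
                                     pair=f"{param}~{cov}", method="auto"))
    if adjust:
        from statsmodels.stats.multitest import multipletests

        p = [r.pvalue for r in results]
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.pvalue = float(pa)
    return results
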