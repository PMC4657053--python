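"""Survival association of lineage similarity scores.

Per-cell-type univariate Cox proportional-hazards screens with
Benjamini-Hochberg adjustment, covariate-adjusted multivariate Cox models,
KDE-based score dichotomization, Kaplan-Meier / log-rank comparison and
nonparametric group tests. Cox, KM and log-rank fitting is delegated to
lifelines; ties use the Efron approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .containers import AssocResult, ClinicalTable, ValidationError

#: default reference levels for categorical clinical covariates
DEFAULT_REFERENCE_LEVELS = {
    "fab": "M1",
    "flt3": "wildtype",
    "cyto_risk": "favorable",
    "prior_malignancy": 0,
}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_cox(df: pd.DataFrame, covariate_cols: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df[["time", "event"] + covariate_cols],
            duration_col="time",
            event_col="event",
        )
    return cph


def _align(lss_col: pd.Series, clin: ClinicalTable) -> pd.DataFrame:
    shared = [s for s in clin.sample_ids if s in lss_col.index]
    if not shared:
        raise ValidationError("no samples shared between LSS matrix and clinical table")
    df = clin.data.loc[shared].copy()
    df["lss"] = lss_col.loc[shared].astype(float)
    return df


def cox_univariate(lss_col: pd.Series, clin: ClinicalTable, cell_type: str = "") -> AssocResult:
    """Univariate Cox PH fit of survival on one cell type's scores.

    A degenerate (constant) score column or a non-converging partial
    likelihood yields a flagged, NaN-valued result rather than an exception.
    """
    df = _align(lss_col, clin)
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValidationError(f"need >= 2 observed events, got {n_events}")
    if float(np.std(df["lss"])) == 0.0:
        return AssocResult(
            cell_type, np.nan, np.nan, np.nan, np.nan, np.nan,
            n=len(df), n_events=n_events, converged=False,
        )
    try:
        cph = _fit_cox(df, ["lss"])
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return AssocResult(
            cell_type, np.nan, np.nan, np.nan, np.nan, np.nan,
            n=len(df), n_events=n_events, converged=False,
        )
    s = cph.summary.loc["lss"]
    return AssocResult(
        cell_type=cell_type,
        coef=float(s["coef"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        wald_p=float(s["p"]),
        n=len(df),
        n_events=n_events,
    )


def cox_univariate_all(lss_wide: pd.DataFrame, clin: ClinicalTable) -> list[AssocResult]:
    """Univariate Cox screen over every cell-type column, BH-adjusted.

    The BH adjustment is applied once across all converged fits; flagged
    (non-converged) cell types keep adj_p = NaN.
    """
    results = [
        cox_univariate(lss_wide[ct], clin, cell_type=str(ct)) for ct in lss_wide.columns
    ]
    ok = [r for r in results if r.converged]
    if ok:
        adj = bh_adjust([r.wald_p for r in ok])
        for r, a in zip(ok, adj):
            r.adj_p = float(a)
    return results


def assoc_table(results: list[AssocResult]) -> pd.DataFrame:
    """Tabulate association results, sorted by adjusted p-value."""
    df = pd.DataFrame([vars(r) for r in results])
    return df.sort_values("adj_p", na_position="last").reset_index(drop=True)


def _encode_covariates(
    df: pd.DataFrame, covariates: list[str], reference_levels: dict
) -> tuple[pd.DataFrame, list[str]]:
    """Complete-case covariate encoding; categoricals dummy-coded against a
    stated reference level."""
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing covariate column(s): {missing}")
    out = df[["time", "event", "lss"]].copy()
    cols: list[str] = []
    for c in covariates:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 2:
            out[c] = col.astype(float)
            cols.append(c)
        else:
            ref = reference_levels.get(c)
            levels = sorted(col.dropna().astype(str).unique())
            if ref is not None and str(ref) in levels:
                levels.remove(str(ref))
            else:
                levels = levels[1:]  # first level is the reference
            for lv in levels:
                name = f"{c}[{lv}]"
                out[name] = (col.astype(str) == lv).astype(float)
                out.loc[col.isna(), name] = np.nan
                cols.append(name)
    out = out.dropna()
    return out, cols


def cox_multivariate(
    lss_col: pd.Series,
    clin: ClinicalTable,
    covariates: list[str] | None = None,
    reference_levels: dict | None = None,
    cell_type: str = "",
) -> AssocResult:
    """Cox PH fit of survival on LSS adjusted for clinical covariates.

    Complete-case analysis; warns when rows fall below 10x the parameter
    count. A singular design raises an error naming the aliased columns.
    """
    covariates = list(covariates or [])
    reference_levels = {**DEFAULT_REFERENCE_LEVELS, **(reference_levels or {})}
    df = _align(lss_col, clin)
    enc, cov_cols = _encode_covariates(df, covariates, reference_levels)
    n_params = 1 + len(cov_cols)
    if len(enc) < 10 * n_params:
        warnings.warn(
            f"only {len(enc)} complete-case rows for {n_params} parameters "
            "(< 10x rule of thumb)",
            stacklevel=2,
        )
    design = enc[["lss"] + cov_cols].to_numpy()
    centered = design - design.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < design.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        kept: list[int] = []
        for j in range(design.shape[1]):
            if np.linalg.matrix_rank(centered[:, kept + [j]]) == len(kept):
                aliased.append((["lss"] + cov_cols)[j])
            else:
                kept.append(j)
        raise ValidationError(f"singular design matrix; aliased columns: {aliased}")
    cph = _fit_cox(enc, ["lss"] + cov_cols)
    s = cph.summary.loc["lss"]
    return AssocResult(
        cell_type=cell_type,
        coef=float(s["coef"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        wald_p=float(s["p"]),
        n=len(enc),
        n_events=int(enc["event"].sum()),
    )


def dichotomize_lss(
    scores, min_prominence: float = 0.10, grid_size: int = 512
) -> tuple[float, np.ndarray]:
    """Split scores into high/low groups from their kernel density estimate.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a grid; modes must
    exceed ``min_prominence`` x the peak density to count. With exactly two
    modes the threshold is the density minimum between them (a bimodal
    distribution is cut at the valley); otherwise the threshold is the
    density mode. Samples strictly above the threshold are labelled "high".
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 20:
        raise ValidationError(f"need >= 20 samples to dichotomize, got {x.size}")
    if np.std(x) == 0:
        raise ValidationError("constant scores cannot be dichotomized")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=min_prominence * dens.max())
    if len(peaks) == 2:
        lo, hi = peaks
        threshold = float(grid[lo + np.argmin(dens[lo : hi + 1])])
    else:
        threshold = float(grid[int(np.argmax(dens))])
    labels = np.where(x > threshold, "high", "low")
    if len(np.unique(labels)) < 2:
        raise ValidationError(
            f"dichotomization at {threshold:.4g} left one group empty"
        )
    return threshold, labels


def km_logrank(labels, clin: ClinicalTable) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan-Meier curves per label group and the log-rank p-value.

    ``labels`` maps clinical sample order (a sequence aligned to
    ``clin.sample_ids`` or a pandas Series indexed by sample id) to group
    names. Each group's curve is returned as a frame of event-time steps
    with censoring marks retained (``censored`` column).
    """
    if isinstance(labels, pd.Series):
        lab = labels.reindex(clin.sample_ids)
        if lab.isna().any():
            raise ValidationError("labels missing for some clinical samples")
        lab = lab.to_numpy()
    else:
        lab = np.asarray(labels)
        if lab.shape[0] != len(clin.sample_ids):
            raise ValidationError("labels length does not match clinical table")
    groups = pd.unique(lab)
    if len(groups) < 2:
        raise ValidationError("log-rank comparison needs >= 2 groups")
    df = clin.data
    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        sel = lab == g
        if df.loc[sel, "event"].sum() < 1:
            raise ValidationError(f"group {g!r} has no observed events")
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[sel, "time"], df.loc[sel, "event"], label=str(g))
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        cens_times = df.loc[sel & (df["event"] == 0), "time"]
        curve["censored"] = curve["time"].isin(set(cens_times)).astype(int)
        curves[str(g)] = curve
    res = multivariate_logrank_test(df["time"], lab, df["event"])
    p = float(res.p_value)
    if res.test_statistic < 1e-12:
        p = 1.0
    return curves, p


@dataclass
class GroupTestReport:
    """Nonparametric comparison of scores across categorical groups."""

    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    pairwise: pd.DataFrame | None = None


def group_tests(scores, groups, alternative: str = "two-sided") -> GroupTestReport:
    """Kruskal-Wallis across >2 groups, Wilcoxon rank-sum for 2.

    For more than two groups, all pairwise Wilcoxon rank-sum (Mann-Whitney)
    p-values are also reported.
    """
    x = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape:
        raise ValidationError("scores and groups must have equal length")
    levels = pd.unique(g)
    sizes = {str(lv): int((g == lv).sum()) for lv in levels}
    usable = [lv for lv in levels if sizes[str(lv)] >= 2]
    if len(usable) < 2:
        raise ValidationError("need >= 2 groups with >= 2 members each")
    samples = [x[g == lv] for lv in usable]
    if len(usable) == 2:
        stat, p = stats.mannwhitneyu(*samples, alternative=alternative)
        return GroupTestReport("wilcoxon-rank-sum", float(stat), float(p), sizes)
    stat, p = stats.kruskal(*samples)
    rows = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            s, pp = stats.mannwhitneyu(
                samples[i], samples[j], alternative=alternative
            )
            rows.append([str(usable[i]), str(usable[j]), float(s), float(pp)])
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])
    return GroupTestReport("kruskal-wallis", float(stat), float(p), sizes, pairwise)
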