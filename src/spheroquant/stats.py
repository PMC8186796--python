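"""Cohort statistics for spheroid biophysical measurements.

The pipeline mirrors common practice for device-derived cohorts of spheroid
mass density, weight and diameter: per-cell Shapiro-Wilk normality testing, a
single round of Tukey-fence outlier elimination (k = 1.5) when normality is
rejected, re-testing, two-tailed unpaired Student's t-tests of each treated
group against control, a Pearson dose-response correlation of per-dose means,
and a one-way ANOVA for the overall effect of fixation.  Quartiles use linear
interpolation throughout (the inclusive hinge convention is deliberately not
used; the convention is fixed here so fence positions are reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (CalibrationError, DegenerateVarianceError, PipelineError,
                     SchemaError, ValidationError)

CONDITIONS = ("CTRL", "CZB250", "CZB500")
STATES = ("live", "fixed")
PARAMETERS = ("density", "weight", "diameter")
#: Crizotinib dose (nM) associated with each condition label.
CONDITION_DOSE_NM = {"CTRL": 0.0, "CZB250": 250.0, "CZB500": 500.0}
#: Cohort-size convention: at least this many spheroids per condition.
MIN_SPHEROIDS_PER_CONDITION = 10

COHORT_COLUMNS = ["spheroid_id", "condition", "state", "parameter", "value"]


@dataclass
class CleaningReport:
    n_initial: int
    n_removed: int
    removed_values: list[float]
    sw_p_before: float
    sw_p_after: float
    converged: bool


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r2: float


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format cohort table; returns the table unchanged."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns {missing}")
    for row, cond in table["condition"].items():
        if cond not in CONDITIONS:
            raise SchemaError(f"row {row}: unknown condition {cond!r}")
    for row, state in table["state"].items():
        if state not in STATES:
            raise SchemaError(f"row {row}: unknown state {state!r}")
    for row, par in table["parameter"].items():
        if par not in PARAMETERS:
            raise SchemaError(f"row {row}: unknown parameter {par!r}")
    values = table["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise SchemaError("cohort values must be finite")
    return table


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test ``(W, p)`` for 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def tukey_outliers(values, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by Tukey fences ``Q1/Q3 -/+ k*IQR``.

    Quartiles use linear interpolation; points strictly outside the fences are
    removed, so an all-equal sample (IQR = 0) loses nothing and the operation
    is idempotent.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValidationError("Tukey fences require at least 4 values")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    outside = (values < lo) | (values > hi)
    return values[~outside], values[outside]


def normality_pipeline(values, alpha: float = 0.05, k: float = 1.5,
                       max_iter: int = 1) -> tuple[np.ndarray, CleaningReport]:
    """Normality-gated outlier elimination.

    Shapiro-Wilk first; only when normality is rejected (p < alpha) is one
    round (``max_iter`` rounds) of Tukey-fence removal applied, followed by a
    re-test.  Normal samples pass through untouched.  ``converged`` records
    whether the final sample looks normal.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValidationError("normality pipeline requires at least 4 values")
    _, p0 = shapiro_wilk(values)
    cleaned = values
    removed: list[float] = []
    p_final = p0
    if p0 < alpha:
        for _ in range(max_iter):
            kept, rem = tukey_outliers(cleaned, k=k)
            if len(kept) < 3:
                raise PipelineError("outlier removal would leave fewer than 3 values")
            removed.extend(rem.tolist())
            cleaned = kept
            _, p_final = shapiro_wilk(cleaned)
            if p_final >= alpha or len(rem) == 0:
                break
    return cleaned, CleaningReport(
        n_initial=len(values), n_removed=len(removed), removed_values=removed,
        sw_p_before=p0, sw_p_after=p_final, converged=bool(p_final >= alpha))


def compare_groups(a, b) -> dict:
    """Two-tailed unpaired Student's (equal-variance) t-test.

    Returns t, df, p and mean +/- SD per group.  With zero pooled variance the
    statistic is t = 0, p = 1 when the means agree and undefined otherwise
    (:class:`DegenerateVarianceError`).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 values")
    out = {"mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
           "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
           "df": len(a) + len(b) - 2}
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if pooled == 0:
        if out["mean_a"] == out["mean_b"]:
            out.update(t=0.0, p=1.0)
            return out
        raise DegenerateVarianceError("degenerate_variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    out.update(t=float(res.statistic), p=float(res.pvalue))
    return out


def pearson_dose_response(concentrations, group_means) -> float:
    """Sample Pearson correlation between dose and per-dose mean response."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(group_means, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need at least 3 paired (dose, mean) points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant_input")
    return float(sps.pearsonr(x, y).statistic)


def one_way_anova(*groups) -> dict:
    """Classical one-way ANOVA; returns F, df_between, df_within and p."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 values each")
    res = sps.f_oneway(*arrays)
    n_tot = sum(len(g) for g in arrays)
    return {"F": float(res.statistic), "df_between": len(arrays) - 1,
            "df_within": n_tot - len(arrays), "p": float(res.pvalue)}


def fixation_anova(table: pd.DataFrame) -> dict:
    """Overall effect of fixation on the measured parameters.

    Collapses the cohort to per-(condition x state x parameter) cell means,
    z-scores each parameter across its cells so density, weight and diameter
    are commensurable, and runs a one-way ANOVA with state (live vs fixed) as
    the single factor.  An F-ratio near zero means fixation leaves the
    standardized measurement profile unchanged.
    """
    validate_cohort(table)
    cells = (table.groupby(["parameter", "condition", "state"])["value"]
             .mean().reset_index())
    for par, grp in cells.groupby("parameter"):
        mu, sd = grp["value"].mean(), grp["value"].std(ddof=1)
        if sd == 0:
            sd = 1.0
        cells.loc[grp.index, "z"] = (grp["value"] - mu) / sd
    groups = []
    for state in STATES:
        vals = cells.loc[cells["state"] == state, "z"].to_numpy()
        if len(vals) < 2:
            raise ValidationError(f"state {state!r} has fewer than 2 cell means")
        groups.append(vals)
    return one_way_anova(*groups)


def calibrate_standard_curve(std_conc, std_fluorescence) -> StandardCurve:
    """OLS fit of fluorescence on concentration for a reference standard curve."""
    x = np.asarray(std_conc, dtype=float)
    y = np.asarray(std_fluorescence, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("need at least 3 paired standards")
    if len(np.unique(x)) < 2:
        raise CalibrationError("standards must span distinct concentrations")
    res = sps.linregress(x, y)
    if res.slope == 0:
        raise CalibrationError("zero-slope standard curve cannot be inverted")
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r2=min(max(r2, 0.0), 1.0))


def apply_curve(curve: StandardCurve, fluorescence) -> np.ndarray | float:
    """Invert the standard curve: concentration = (f - intercept) / slope."""
    if curve.slope == 0:
        raise CalibrationError("zero-slope standard curve cannot be inverted")
    f = np.asarray(fluorescence, dtype=float)
    out = (f - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


@dataclass
class CohortSummary:
    """Tidy per-cell report plus the cleaned long table."""

    cells: pd.DataFrame          # one row per (condition, state, parameter)
    cleaned: pd.DataFrame        # long table after outlier elimination
    warnings: list[str] = field(default_factory=list)


def cohort_summary(table: pd.DataFrame, alpha: float = 0.05,
                   k: float = 1.5) -> CohortSummary:
    """Full cohort report.

    Per (condition, state, parameter) cell: normality-gated cleaning, n, mean,
    SD; per (state, parameter): Student's t-tests of each treated condition
    against CTRL on cleaned values, and the Pearson correlation of cell means
    against dose.  Cells below the 10-spheroid convention are flagged with a
    warning, not rejected.
    """
    validate_cohort(table)
    warnings: list[str] = []
    cleaned_rows: list[pd.DataFrame] = []
    records: list[dict] = []
    cell_stats: dict[tuple[str, str, str], dict] = {}

    for (cond, state, par), grp in table.groupby(["condition", "state", "parameter"]):
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 3:
            raise ValidationError(
                f"cell ({cond}, {state}, {par}) has fewer than 3 values")
        if len(vals) < MIN_SPHEROIDS_PER_CONDITION:
            warnings.append(
                f"cell ({cond}, {state}, {par}) has n={len(vals)} < "
                f"{MIN_SPHEROIDS_PER_CONDITION}")
        if len(vals) >= 4:
            cleaned, rep = normality_pipeline(vals, alpha=alpha, k=k)
        else:
            cleaned, rep = vals, None
        keep = grp[grp["value"].isin(cleaned)] if rep and rep.n_removed else grp
        cleaned_rows.append(keep)
        cell_stats[(cond, state, par)] = {
            "values": cleaned,
            "report": rep,
        }
        records.append({
            "condition": cond, "state": state, "parameter": par,
            "n": len(cleaned), "mean": float(np.mean(cleaned)),
            "sd": float(np.std(cleaned, ddof=1)),
            "n_removed": rep.n_removed if rep else 0,
            "sw_p_before": rep.sw_p_before if rep else np.nan,
            "sw_p_after": rep.sw_p_after if rep else np.nan,
            "normality_converged": rep.converged if rep else True,
        })

    cells = pd.DataFrame.from_records(records)
    cells["t_vs_ctrl"] = np.nan
    cells["p_vs_ctrl"] = np.nan
    cells["dose_response_r"] = np.nan

    for state in sorted(table["state"].unique()):
        for par in sorted(table["parameter"].unique()):
            ctrl = cell_stats.get(("CTRL", state, par))
            if ctrl is None:
                continue
            means, doses = [], []
            for cond in CONDITIONS:
                cell = cell_stats.get((cond, state, par))
                if cell is None:
                    continue
                means.append(float(np.mean(cell["values"])))
                doses.append(CONDITION_DOSE_NM[cond])
                if cond == "CTRL":
                    continue
                cmp_ = compare_groups(cell["values"], ctrl["values"])
                sel = ((cells["condition"] == cond) & (cells["state"] == state)
                       & (cells["parameter"] == par))
                cells.loc[sel, "t_vs_ctrl"] = cmp_["t"]
                cells.loc[sel, "p_vs_ctrl"] = cmp_["p"]
            if len(means) >= 3 and np.ptp(means) > 0:
                r = pearson_dose_response(doses, means)
                sel = (cells["state"] == state) & (cells["parameter"] == par)
                cells.loc[sel, "dose_response_r"] = r

    cleaned_table = pd.concat(cleaned_rows, ignore_index=True)
    return CohortSummary(cells=cells, cleaned=cleaned_table, warnings=warnings)
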