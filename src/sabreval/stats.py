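"""Statistical analysis of case tables: stepwise multiple linear regression
of PTV D95% with collinearity diagnostics, one-way ANOVA by lung lobe, the
high-dHI subgroup refit, and residual-based outlier flagging.

Conventions follow the common clinical-statistics toolchain: classical
(non-robust) standard errors, classical one-way ANOVA without Welch
correction, and SPSS-style stepwise selection (entry p 0.05, removal p
0.10 by default).  The 288 fraction-level cases are treated as independent
observations; within-patient correlation is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import reference

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "ols_fit",
    "stepwise_mlr",
    "vif_tolerance",
    "oneway_anova",
    "filter_subgroup",
    "flag_outliers",
    "weighted_total_mean",
    "analyze_cases",
]


@dataclass
class RegressionResult:
    """Fitted linear model in the shape of a clinical regression table:
    per-term unstandardised B, SE, standardised beta, p, tolerance and VIF,
    plus intercept and adjusted R²."""

    terms: tuple[str, ...]
    coefficients: dict
    standard_errors: dict
    standardized_betas: dict
    p_values: dict
    tolerance: dict
    vif: dict
    intercept: float
    intercept_se: float
    intercept_p: float
    r2: float
    adjusted_r2: float
    nobs: int
    inclusion_order: tuple[str, ...] = ()
    _sm_result: object = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        rows = {
            t: {
                "B": self.coefficients[t],
                "SE": self.standard_errors[t],
                "beta": self.standardized_betas[t],
                "p": self.p_values[t],
                "tolerance": self.tolerance[t],
                "VIF": self.vif[t],
            }
            for t in self.terms
        }
        return {
            "constant": {"B": self.intercept, "SE": self.intercept_se, "p": self.intercept_p},
            "terms": rows,
            "adjusted_r2": self.adjusted_r2,
            "r2": self.r2,
            "n": self.nobs,
            "inclusion_order": list(self.inclusion_order),
        }


@dataclass
class AnovaResult:
    """One-way ANOVA: per-group n/mean/SD and the F test."""

    variable: str
    groups: dict            # group -> {"n", "mean", "sd"}
    f_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "groups": self.groups,
            "F": self.f_statistic,
            "p": self.p_value,
        }


def _design(records: pd.DataFrame, dependent: str, terms) -> tuple[np.ndarray, np.ndarray]:
    terms = list(terms)
    sub = records[[dependent, *terms]]
    if sub.isna().any().any():
        raise ValueError("missing values in fitted columns")
    y = sub[dependent].to_numpy(dtype=float)
    X = sub[terms].to_numpy(dtype=float)
    return y, X


def ols_fit(records: pd.DataFrame, dependent: str, terms) -> RegressionResult:
    """Ordinary least squares of ``dependent`` on ``terms`` plus intercept.

    Standardised beta_k = B_k * SD(x_k) / SD(y); adjusted R² uses the
    classical (n-1)/(n-k-1) correction.  Raises on rank deficiency, naming
    the collinear terms.
    """
    terms = list(terms)
    y, X = _design(records, dependent, terms)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need more observations than parameters")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < k + 1:
        if k >= 2:
            collinear = [t for t, v in vif_tolerance(records, terms).items()
                         if not np.isfinite(v[1]) or v[1] > 1e12]
        else:
            collinear = terms
        raise ValueError(f"design matrix is rank deficient; collinear terms: {collinear or terms}")
    res = sm.OLS(y, Xc).fit()
    sd_y = y.std(ddof=1)
    betas = {
        t: res.params[i + 1] * X[:, i].std(ddof=1) / sd_y for i, t in enumerate(terms)
    }
    tolvif = vif_tolerance(records, terms) if k >= 2 else {terms[0]: (1.0, 1.0)} if k == 1 else {}
    return RegressionResult(
        terms=tuple(terms),
        coefficients={t: float(res.params[i + 1]) for i, t in enumerate(terms)},
        standard_errors={t: float(res.bse[i + 1]) for i, t in enumerate(terms)},
        standardized_betas={t: float(b) for t, b in betas.items()},
        p_values={t: float(res.pvalues[i + 1]) for i, t in enumerate(terms)},
        tolerance={t: float(tolvif[t][0]) for t in terms},
        vif={t: float(tolvif[t][1]) for t in terms},
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        intercept_p=float(res.pvalues[0]),
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        nobs=n,
        inclusion_order=tuple(terms),
        _sm_result=res,
    )


def _tolerance_vif(X: np.ndarray) -> dict:
    out = {}
    n, k = X.shape
    for i in range(k):
        others = np.delete(X, i, axis=1)
        A = sm.add_constant(others, has_constant="add")
        beta, _, _, _ = np.linalg.lstsq(A, X[:, i], rcond=None)
        resid = X[:, i] - A @ beta
        sst = np.sum((X[:, i] - X[:, i].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
        tol = max(1.0 - r2, 0.0)
        out[i] = (tol, (1.0 / tol) if tol > 0 else np.inf)
    return out


def vif_tolerance(records: pd.DataFrame, terms) -> dict:
    """Per-term (tolerance, VIF): VIF_k = 1 / (1 - R²) of regressing term k
    on the remaining terms; tolerance = 1 / VIF.  Perfect collinearity is
    reported as infinite VIF."""
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("need at least two terms for collinearity diagnostics")
    X = records[terms].to_numpy(dtype=float)
    raw = _tolerance_vif(X)
    return {t: raw[i] for i, t in enumerate(terms)}


def stepwise_mlr(
    records: pd.DataFrame,
    dependent: str,
    candidates,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> RegressionResult:
    """SPSS-style stepwise selection.

    Repeatedly add the excluded candidate with the smallest entry p-value if
    it is <= p_enter, then remove any included term whose p-value has risen
    to >= p_remove; iterate to a fixed point.  Deterministic given the data.
    Returns an intercept-only result (no terms) if nothing enters.
    """
    candidates = list(candidates)
    included: list[str] = []
    order: list[str] = []
    for _ in range(max_steps):
        changed = False
        # entry
        excluded = [c for c in candidates if c not in included]
        best, best_p = None, np.inf
        for c in excluded:
            fit = ols_fit(records, dependent, included + [c])
            p = fit.p_values[c]
            if p < best_p:
                best, best_p = c, p
        if best is not None and best_p <= p_enter:
            included.append(best)
            order.append(best)
            changed = True
        # removal
        while included:
            fit = ols_fit(records, dependent, included)
            worst = max(included, key=lambda t: fit.p_values[t])
            if fit.p_values[worst] >= p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not included:
        import warnings

        warnings.warn("no candidate met the entry criterion; intercept-only model",
                      RuntimeWarning)
        y = records[dependent].to_numpy(dtype=float)
        n = y.size
        se = y.std(ddof=1) / np.sqrt(n)
        t = y.mean() / se
        p = 2 * sps.t.sf(abs(t), n - 1)
        return RegressionResult(
            terms=(), coefficients={}, standard_errors={}, standardized_betas={},
            p_values={}, tolerance={}, vif={},
            intercept=float(y.mean()), intercept_se=float(se), intercept_p=float(p),
            r2=0.0, adjusted_r2=0.0, nobs=n, inclusion_order=(),
        )
    result = ols_fit(records, dependent, included)
    result.inclusion_order = tuple(order[: len(included)]) if set(order) >= set(included) else tuple(included)
    return result


def oneway_anova(records: pd.DataFrame, variable: str, group: str = "lobe") -> AnovaResult:
    """Classical one-way ANOVA of ``variable`` across the levels of ``group``."""
    grouped = {g: sub[variable].to_numpy(dtype=float) for g, sub in records.groupby(group)}
    if len(grouped) < 2:
        raise ValueError("need at least two groups")
    for g, v in grouped.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    f, p = sps.f_oneway(*grouped.values())
    groups = {
        g: {"n": int(v.size), "mean": float(v.mean()), "sd": float(v.std(ddof=1))}
        for g, v in grouped.items()
    }
    return AnovaResult(variable=variable, groups=groups, f_statistic=float(f), p_value=float(p))


def filter_subgroup(
    records: pd.DataFrame,
    max_delta_hi: float = reference.SUBGROUP_DHI_MAX,
    on: str = "dhi",
) -> tuple[pd.DataFrame, int]:
    """Drop the high homogeneity-index cases: keeps records with
    ``records[on] <= max_delta_hi`` and reports how many were excluded.
    ``on`` may be "dhi" (the HI difference, default) or "hi_del" (absolute
    delivered HI)."""
    keep = records[records[on] <= max_delta_hi]
    return keep, int(len(records) - len(keep))


def flag_outliers(
    fit: RegressionResult, records: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag records with |internally studentized residual| > threshold.

    Returns (flagged records, residual table with predicted values and
    studentized residuals for every record).
    """
    if fit._sm_result is None:
        raise ValueError("fit does not carry a fitted model (intercept-only?)")
    res = fit._sm_result
    influence = res.get_influence()
    student = influence.resid_studentized_internal
    resid_table = records.copy()
    resid_table["predicted"] = res.fittedvalues
    resid_table["residual"] = res.resid
    resid_table["studentized"] = student
    flagged = resid_table[np.abs(student) > threshold]
    return flagged, resid_table


def weighted_total_mean(group_ns, group_means) -> float:
    """Cohort-weighted mean: sum(n_i * m_i) / sum(n_i)."""
    ns = np.asarray(group_ns, dtype=float)
    ms = np.asarray(group_means, dtype=float)
    if ns.shape != ms.shape:
        raise ValueError("group sizes and means must have the same length")
    if np.any(ns <= 0):
        raise ValueError("group sizes must be positive")
    return float(np.sum(ns * ms) / np.sum(ns))


def analyze_cases(
    cases: pd.DataFrame,
    dependent: str = "d95",
    candidates=("dhi", "dmean_pct", "dsc", "warp_mean"),
    subgroup_on: str = "dhi",
    subgroup_max: float = reference.SUBGROUP_DHI_MAX,
    outlier_threshold: float = 3.0,
) -> dict:
    """Full statistics block for a case table: stepwise regression, lobe
    ANOVAs, the high-dHI subgroup refit, and the flagged outliers."""
    df = cases
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    df = df.dropna(subset=[dependent, *candidates])
    full = stepwise_mlr(df, dependent, list(candidates))
    anovas = {
        v: oneway_anova(df, v).to_dict()
        for v in (dependent, "dsc", "warp_mean")
        if v in df.columns
    }
    kept, n_excluded = filter_subgroup(df, max_delta_hi=subgroup_max, on=subgroup_on)
    subgroup = stepwise_mlr(kept, dependent, list(candidates))
    out = {
        "regression": full.to_dict(),
        "anova": anovas,
        "subgroup": {"excluded": n_excluded, "regression": subgroup.to_dict()},
    }
    if full.terms:
        flagged, _ = flag_outliers(full, df, threshold=outlier_threshold)
        out["outliers"] = {
            "threshold_sd": outlier_threshold,
            "n": int(len(flagged)),
            "cases": flagged[["patient", "fraction"]].to_dict("records")
            if {"patient", "fraction"} <= set(flagged.columns)
            else flagged.index.tolist(),
        }
    return out
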