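"""Logistic model fitting and the comparison statistics reported alongside
reclassification measures: Wald tests and odds ratios, the likelihood-ratio
test, Nagelkerke pseudo-R2, AUC with a paired correlated-AUC (DeLong) test,
and a forward-stepwise helper for building a base model.

Fitting is maximum likelihood via statsmodels; everything here is a thin,
typed surface over the fit plus the statistics the fit does not expose
directly (DeLong covariance via placement values is computed in-house).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .core import SchemaError, DegenerateDataError

__all__ = [
    "FittedLogit",
    "AucComparison",
    "fit_logistic",
    "wald_or",
    "lr_test",
    "nagelkerke_r2",
    "auc",
    "auc_compare",
    "design_matrix",
    "forward_stepwise",
]


@dataclass(frozen=True)
class FittedLogit:
    """A converged (or flagged) maximum-likelihood logistic fit."""

    params: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    n: int
    fitted_risk: np.ndarray
    converged: bool
    covariate_names: tuple[str, ...]

    @property
    def k_params(self) -> int:
        return len(self.params)


def _with_const(X: pd.DataFrame) -> pd.DataFrame:
    return sm.add_constant(X.astype(float), has_constant="add")


def fit_logistic(X: pd.DataFrame, y) -> FittedLogit:
    """Fit outcome ~ intercept + X by maximum likelihood (Newton).

    ``X`` is a numeric design matrix without the intercept column (dummy
    coding for categorical covariates — see :func:`design_matrix`).  A fit
    that fails to converge (e.g. perfect separation) is returned with
    ``converged=False`` and a warning rather than raising.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise SchemaError("design and outcome lengths differ")
    if X.shape[0] <= X.shape[1] + 1:
        raise SchemaError("need more subjects than parameters")
    for col in X.columns:
        if np.ptp(X[col].to_numpy(dtype=float)) == 0:
            raise SchemaError(f"covariate {col!r} has zero variance")
    if X.shape[1] == 0:  # intercept-only null model
        Xc = pd.DataFrame({"const": np.ones(len(y))}, index=X.index)
    else:
        Xc = _with_const(X)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, Xc)
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = model.fit(disp=0, maxiter=500, method="bfgs")
            converged = bool(res.mle_retvals.get("converged", False))
    separated = any(
        issubclass(w.category, PerfectSeparationWarning) for w in caught
    )
    converged = converged and not separated
    if not converged:
        warnings.warn("logistic fit did not converge (possible separation)")
    return FittedLogit(
        params=res.params,
        cov=res.cov_params(),
        log_likelihood=float(res.llf),
        n=int(len(y)),
        fitted_risk=np.asarray(res.predict(Xc)),
        converged=converged,
        covariate_names=tuple(X.columns),
    )


def wald_or(fit: FittedLogit, include_intercept: bool = False) -> pd.DataFrame:
    """Per-coefficient odds ratios with Wald 95% CIs and two-sided p-values.

    Columns: or, ci_low, ci_high, p. Coefficients whose variance is not
    finite (singular information) are reported as NaN.
    """
    se = np.sqrt(np.diag(fit.cov.to_numpy()))
    beta = fit.params.to_numpy()
    z975 = stats.norm.ppf(0.975)
    with np.errstate(over="ignore", invalid="ignore"):
        out = pd.DataFrame(
            {
                "or": np.exp(beta),
                "ci_low": np.exp(beta - z975 * se),
                "ci_high": np.exp(beta + z975 * se),
                "p": 2 * stats.norm.sf(np.abs(np.divide(
                    beta, se, out=np.full_like(beta, np.nan), where=se > 0))),
            },
            index=fit.params.index,
        )
    if not include_intercept and "const" in out.index:
        out = out.drop(index="const")
    return out


def lr_test(base: FittedLogit, extended: FittedLogit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested logistic models: (stat, df, p)."""
    if base.n != extended.n:
        raise SchemaError("models fitted on different numbers of subjects")
    if not set(base.covariate_names) <= set(extended.covariate_names):
        raise SchemaError("models are not nested")
    df = extended.k_params - base.k_params
    if df < 0:
        raise SchemaError("extended model has fewer parameters than base")
    stat = max(0.0, 2 * (extended.log_likelihood - base.log_likelihood))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def nagelkerke_r2(fit: FittedLogit, null_fit: FittedLogit) -> float:
    """Nagelkerke pseudo-R2: Cox-Snell rescaled to a [0, 1] maximum."""
    if fit.n != null_fit.n:
        raise SchemaError("fits on different numbers of subjects")
    n = fit.n
    ll0, ll1 = null_fit.log_likelihood, fit.log_likelihood
    cox_snell = 1 - math.exp(2 * (ll0 - ll1) / n)
    max_cs = 1 - math.exp(2 * ll0 / n)
    if max_cs <= 0:
        return 0.0
    return cox_snell / max_cs


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Placement values: for each case, the fraction of controls it beats
    (ties counted 1/2), and symmetrically for controls."""
    ctrl_sorted = np.sort(controls)
    lo = np.searchsorted(ctrl_sorted, cases, side="left")
    hi = np.searchsorted(ctrl_sorted, cases, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / controls.size
    case_sorted = np.sort(cases)
    lo = np.searchsorted(case_sorted, controls, side="left")
    hi = np.searchsorted(case_sorted, controls, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / cases.size
    return v10, v01


def auc(risk, outcome) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, midrank ties)."""
    risk = np.asarray(risk, dtype=float)
    y = np.asarray(outcome)
    cases = risk[y == 1]
    controls = risk[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise DegenerateDataError("both outcome classes must be present")
    v10, _ = _placements(cases, controls)
    return float(np.mean(v10))


@dataclass(frozen=True)
class AucComparison:
    auc_base: float
    auc_new: float
    ci_base: tuple[float, float]
    ci_new: tuple[float, float]
    delta: float
    z: float
    p_value: float


def auc_compare(risk_base, risk_new, outcome, level: float = 0.95) -> AucComparison:
    """Paired comparison of two AUCs on the same subjects (DeLong style).

    Variances and the covariance of the two AUC estimates come from the
    empirical covariance of placement values over cases and controls; the
    change is tested with a two-sided z test. Identical risk vectors give
    delta 0 with p = 1.
    """
    r0 = np.asarray(risk_base, dtype=float)
    r1 = np.asarray(risk_new, dtype=float)
    y = np.asarray(outcome)
    if r0.shape != r1.shape or r0.shape != y.shape:
        raise SchemaError("risk vectors and outcome must have equal length")
    cases0, controls0 = r0[y == 1], r0[y == 0]
    cases1, controls1 = r1[y == 1], r1[y == 0]
    if cases0.size == 0 or controls0.size == 0:
        raise DegenerateDataError("both outcome classes must be present")
    m, n = cases0.size, controls0.size
    v10_0, v01_0 = _placements(cases0, controls0)
    v10_1, v01_1 = _placements(cases1, controls1)
    a0, a1 = float(np.mean(v10_0)), float(np.mean(v10_1))

    s10 = np.cov(np.vstack([v10_0, v10_1]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_0, v01_1]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = max(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1], 0.0)
    delta = a1 - a0
    if var_delta > 0:
        z = delta / math.sqrt(var_delta)
        p = 2 * stats.norm.sf(abs(z))
    else:
        z, p = 0.0, 1.0
    zq = stats.norm.ppf(0.5 + level / 2)

    def _ci(a: float, var: float) -> tuple[float, float]:
        se = math.sqrt(max(var, 0.0))
        return max(a - zq * se, 0.0), min(a + zq * se, 1.0)

    return AucComparison(
        auc_base=a0,
        auc_new=a1,
        ci_base=_ci(a0, cov[0, 0]),
        ci_new=_ci(a1, cov[1, 1]),
        delta=delta,
        z=z,
        p_value=p,
    )


def design_matrix(
    df: pd.DataFrame,
    covariates: list[str],
    reference: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Dummy-code the named covariates, dropping the reference category.

    Numeric columns pass through unchanged; categorical/object columns are
    expanded to ``name[category]`` indicator columns with the reference
    level (given in ``reference`` or the first category observed) dropped.
    """
    reference = reference or {}
    parts = []
    for name in covariates:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            parts.append(col.astype(float).rename(name))
        elif pd.api.types.is_numeric_dtype(col) and set(col.unique()) <= {0, 1}:
            parts.append(col.astype(float).rename(name))
        else:
            cats = list(pd.unique(col))
            ref = reference.get(name, cats[0])
            if ref not in cats:
                raise SchemaError(f"reference {ref!r} not a category of {name!r}")
            for cat in cats:
                if cat == ref:
                    continue
                parts.append((col == cat).astype(float).rename(f"{name}[{cat}]"))
    return pd.concat(parts, axis=1)


def forward_stepwise(
    df: pd.DataFrame,
    covariates: list[str],
    outcome: str,
    alpha: float = 0.05,
    reference: dict[str, str] | None = None,
    allow_removal: bool = False,
) -> list[str]:
    """Forward-entry covariate selection by the likelihood-ratio test.

    At each step the candidate whose addition gives the smallest LR p-value
    is entered if p < ``alpha``; with ``allow_removal`` a variable whose
    removal LR p exceeds ``alpha`` is dropped again after each entry.
    Returns the selected covariate names in entry order.
    """
    y = df[outcome].to_numpy()
    selected: list[str] = []

    def _fit(names: list[str]) -> FittedLogit:
        if not names:
            return fit_logistic(pd.DataFrame(index=df.index), y)
        return fit_logistic(design_matrix(df, names, reference), y)

    current = _fit(selected)
    remaining = list(covariates)
    while remaining:
        best = None
        for cand in remaining:
            trial = _fit(selected + [cand])
            _, _, p = lr_test(current, trial)
            if best is None or p < best[1]:
                best = (cand, p, trial)
        if best is None or best[1] >= alpha:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        current = best[2]
        if allow_removal and len(selected) > 1:
            for name in list(selected[:-1]):
                reduced = _fit([s for s in selected if s != name])
                _, _, p_rm = lr_test(reduced, current)
                if p_rm >= alpha:
                    selected.remove(name)
                    remaining.append(name)
                    current = _fit(selected)
    return selected
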