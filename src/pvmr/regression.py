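"""Logistic regression of a binary target-event indicator on report covariates.

Reproduces the usual pharmacoepidemiological presentation: univariable fits
per covariate, a P < alpha screen, then one multivariable model containing
the screen-passing covariates, everything reported as OR with Wald 95% CI
and Wald p per non-reference level.  Fitting is maximum likelihood via
iteratively reweighted least squares (binomial GLM); records with unknown
age or sex are removed listwise before fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .disproportionality import Z95
from .reports import ReportSet, assign_age_band

#: absolute log-OR beyond which a coefficient is treated as separated
SEPARATION_BOUND = 15.0
MAX_ITER = 50


@dataclass(frozen=True, slots=True)
class RegressionResult:
    """OR for one covariate level versus its reference."""

    term: str            # covariate name
    level: str           # non-reference level (or the reference itself)
    or_point: float
    ci_low: float
    ci_high: float
    p_wald: float
    model: str           # univariable | multivariable
    reference: bool = False
    separation: bool = False


def _design_matrix(
    design: pd.DataFrame,
    covariates: Sequence[str],
    references: Mapping[str, str],
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Dummy-code covariates with the declared reference level dropped."""
    cols: list[np.ndarray] = [np.ones(len(design))]
    names: list[tuple[str, str]] = [("const", "")]
    for cov in covariates:
        values = design[cov].astype(str)
        levels = sorted(values.unique())
        ref = references.get(cov)
        if ref is None:
            ref = levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from covariate {cov!r}")
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has no variation after filtering")
        for lev in levels:
            if lev == ref:
                continue
            cols.append((values == lev).to_numpy(float))
            names.append((cov, lev))
    return np.column_stack(cols), names


def fit_logistic(
    design: pd.DataFrame,
    y,
    references: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
    model_label: str = "multivariable",
) -> list[RegressionResult]:
    """Maximum-likelihood logistic fit; one result per covariate level.

    ``design`` holds categorical covariate columns; ``references`` names the
    reference level per covariate (default: first level in sort order).
    Reference levels are emitted with OR 1 by convention.  A coefficient
    diverging beyond +-15 on the log scale is flagged as (quasi-)separated
    and reported with an infinite-CI marker instead of crashing.
    """
    references = references or {}
    covariates = list(covariates) if covariates is not None else list(design.columns)
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has fewer than 2 distinct values")
    X, names = _design_matrix(design, covariates, references)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=MAX_ITER, tol=1e-10)
    if not res.converged and np.max(np.abs(res.params)) <= SEPARATION_BOUND:
        raise RuntimeError(f"IRLS did not converge within {MAX_ITER} iterations")

    results: list[RegressionResult] = []
    for cov in covariates:
        ref = references.get(cov, sorted(design[cov].astype(str).unique())[0])
        results.append(
            RegressionResult(cov, ref, 1.0, math.nan, math.nan, math.nan,
                             model_label, reference=True)
        )
        for i, (term, level) in enumerate(names):
            if term != cov:
                continue
            coef = res.params[i]
            se = res.bse[i]
            if abs(coef) > SEPARATION_BOUND or not math.isfinite(se):
                results.append(
                    RegressionResult(cov, level, math.exp(min(coef, SEPARATION_BOUND)),
                                     0.0, math.inf, math.nan, model_label,
                                     separation=True)
                )
                continue
            z = coef / se
            p = 2.0 * float(stats.norm.sf(abs(z)))
            results.append(
                RegressionResult(cov, level, math.exp(coef),
                                 math.exp(coef - Z95 * se), math.exp(coef + Z95 * se),
                                 p, model_label)
            )
    return results


def univariable_screen(
    design: pd.DataFrame,
    y,
    references: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> tuple[list[RegressionResult], list[str]]:
    """Fit each covariate alone; carry forward those with any level P < alpha."""
    results: list[RegressionResult] = []
    carried: list[str] = []
    for cov in design.columns:
        fit = fit_logistic(design, y, references, covariates=[cov],
                           model_label="univariable")
        results.extend(fit)
        if any((not r.reference) and (not r.separation) and r.p_wald < alpha for r in fit):
            carried.append(cov)
    return results, carried


def regression_report(
    design: pd.DataFrame,
    y,
    references: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariable screen plus one multivariable model of the carried covariates.

    Output mirrors the standard factor table: one row per covariate level with
    univariable OR/CI/P and, for carried covariates, multivariable OR/CI/P.
    """
    uni, carried = univariable_screen(design, y, references, alpha)
    multi: dict[tuple[str, str], RegressionResult] = {}
    if carried:
        for r in fit_logistic(design, y, references, covariates=carried,
                              model_label="multivariable"):
            multi[(r.term, r.level)] = r
    rows = []
    for r in uni:
        m = multi.get((r.term, r.level))
        rows.append(
            {
                "factor": r.term,
                "level": r.level,
                "reference": r.reference,
                "uni_or": r.or_point, "uni_ci_low": r.ci_low,
                "uni_ci_high": r.ci_high, "uni_p": r.p_wald,
                "multi_or": m.or_point if m and not m.reference else np.nan,
                "multi_ci_low": m.ci_low if m and not m.reference else np.nan,
                "multi_ci_high": m.ci_high if m and not m.reference else np.nan,
                "multi_p": m.p_wald if m and not m.reference else np.nan,
                "carried_forward": r.term in carried,
            }
        )
    return pd.DataFrame(rows)


def prepare_regression_frame(
    rs: ReportSet, drug: str, pt: int | str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariate frame (age band, sex) and target-event indicator for one drug.

    Restricts to reports listing the drug, codes age with the four
    regression bands, and drops records with unknown age or sex listwise.
    """
    rows = []
    for r in rs:
        if not r.has_drug(drug):
            continue
        band = assign_age_band(r.age_years, "regression")
        if band == "unknown" or r.sex == "unknown":
            continue
        rows.append({"age_band": band, "sex": r.sex, "y": float(r.has_pt(pt))})
    if not rows:
        raise ValueError("no usable records after listwise deletion")
    df = pd.DataFrame(rows)
    return df[["age_band", "sex"]], df["y"].to_numpy()
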