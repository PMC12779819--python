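"""Per-cell count regression: Poisson / quasi-Poisson GLMs with backward
selection.

The response is the number of deduplicated reports per occupied grid
cell; covariates are forest area, building count and binary event-type
indicators. Overdispersion is assessed with the Pearson dispersion
statistic; under the quasi-Poisson family standard errors are scaled by
its square root and inference uses t statistics on n - p degrees of
freedom. Model reduction follows backward selection: repeatedly drop the
least significant covariate with p above ``alpha`` and refit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

#: Pearson-dispersion cutoff above which the quasi-Poisson family is used
#: when the family is left unspecified.
DISPERSION_CUTOFF = 1.5


@dataclass
class GlmFit:
    terms: List[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    test_statistics: np.ndarray
    p_values: np.ndarray
    family: str                      # "poisson" | "quasipoisson"
    dispersion: float
    n: int
    log_likelihood: Optional[float]  # None for quasipoisson (quasi-deviance used)
    quasi_deviance: float
    statistic_label: str             # "z" | "t"
    eliminated: List[str] = field(default_factory=list)
    intercept_only_warning: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.estimates,
            "se": self.standard_errors,
            self.statistic_label: self.test_statistics,
            "p": self.p_values,
        })


def _design(rows: pd.DataFrame, covariates: Sequence[str]):
    X = sm.add_constant(rows[list(covariates)].astype(float), has_constant="add")
    y = rows["n_reports"].astype(float).to_numpy()
    return y, X


def fit_count_glm(rows: pd.DataFrame, covariates: Sequence[str],
                  family: Optional[str] = None) -> GlmFit:
    """Fit a log-link count GLM by IRLS.

    ``family`` is "poisson", "quasipoisson", or None to choose
    automatically: quasi-Poisson when the Pearson dispersion of the
    Poisson fit exceeds ``DISPERSION_CUTOFF``, Poisson otherwise.
    """
    covariates = list(covariates)
    if len(rows) <= len(covariates) + 1:
        raise ValueError("need more rows than covariates")
    for c in covariates:
        if rows[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    y, X = _design(rows, covariates)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular design: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in {res.fit_history['iteration']} iterations")
    df_resid = res.df_resid
    dispersion = float(res.pearson_chi2 / df_resid)
    if family is None:
        family = "quasipoisson" if dispersion > DISPERSION_CUTOFF else "poisson"

    est = np.asarray(res.params)
    if family == "quasipoisson":
        se = np.asarray(res.bse) * np.sqrt(dispersion)
        stat = est / se
        p = 2 * stats.t.sf(np.abs(stat), df_resid)
        disp_out, label, llf = dispersion, "t", None
    elif family == "poisson":
        se = np.asarray(res.bse)
        stat = est / se
        p = 2 * stats.norm.sf(np.abs(stat))
        disp_out, label, llf = 1.0, "z", float(res.llf)
    else:
        raise ValueError(f"unknown family {family!r}")
    return GlmFit(
        terms=["intercept", *covariates],
        estimates=est, standard_errors=se, test_statistics=stat, p_values=p,
        family=family, dispersion=disp_out, n=len(rows),
        log_likelihood=llf, quasi_deviance=float(res.deviance),
        statistic_label=label)


def dispersion_statistic(rows: pd.DataFrame, covariates: Sequence[str]) -> float:
    """Pearson chi-square of the Poisson fit divided by residual df."""
    y, X = _design(rows, list(covariates))
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-10)
    if res.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom; dispersion undefined")
    return float(res.pearson_chi2 / res.df_resid)


def covariate_correlations(rows: pd.DataFrame,
                           covariates: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations among covariates (collinearity check)."""
    return rows[list(covariates)].astype(float).corr(method="pearson")


def backward_select(rows: pd.DataFrame, covariates: Sequence[str],
                    family: Optional[str] = None, alpha: float = 0.05) -> GlmFit:
    """Backward selection: drop the highest-p covariate with p > alpha,
    refit, repeat until all remaining covariates are significant.

    The intercept is never dropped. If everything is eliminated the
    intercept-only fit is returned with ``intercept_only_warning`` set.
    Ties in the maximal p-value (within 1e-12) drop the later covariate
    in the declared order, for determinism.
    """
    remaining = list(covariates)
    eliminated: List[str] = []
    fit = fit_count_glm(rows, remaining, family=family)
    resolved_family = fit.family
    while remaining:
        pvals = fit.p_values[1:]  # skip intercept
        worst_p = float(np.max(pvals))
        if worst_p <= alpha:
            break
        ties = [i for i, p in enumerate(pvals) if worst_p - p <= 1e-12]
        drop_idx = max(ties)
        dropped = remaining.pop(drop_idx)
        eliminated.append(dropped)
        log.info("backward selection: dropping %s (p=%.4g)", dropped, worst_p)
        if not remaining:
            break
        fit = fit_count_glm(rows, remaining, family=resolved_family)
    if not remaining:
        fit = _intercept_only(rows, resolved_family)
        fit.intercept_only_warning = True
    fit.eliminated = eliminated
    return fit


def _intercept_only(rows: pd.DataFrame, family: str) -> GlmFit:
    y = rows["n_reports"].astype(float).to_numpy()
    X = np.ones((len(y), 1))
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-10)
    dispersion = float(res.pearson_chi2 / res.df_resid)
    if family == "quasipoisson":
        se = np.asarray(res.bse) * np.sqrt(dispersion)
        stat = np.asarray(res.params) / se
        p = 2 * stats.t.sf(np.abs(stat), res.df_resid)
        return GlmFit(terms=["intercept"], estimates=np.asarray(res.params),
                      standard_errors=se, test_statistics=stat, p_values=p,
                      family=family, dispersion=dispersion, n=len(y),
                      log_likelihood=None, quasi_deviance=float(res.deviance),
                      statistic_label="t")
    se = np.asarray(res.bse)
    stat = np.asarray(res.params) / se
    p = 2 * stats.norm.sf(np.abs(stat))
    return GlmFit(terms=["intercept"], estimates=np.asarray(res.params),
                  standard_errors=se, test_statistics=stat, p_values=p,
                  family="poisson", dispersion=1.0, n=len(y),
                  log_likelihood=float(res.llf),
                  quasi_deviance=float(res.deviance), statistic_label="z")
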