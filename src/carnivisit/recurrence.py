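"""Recurrence of carnivore reports: 30-day window tables and spatial
logistic mixed models.

The question: given the number of reports in a grid cell during one
30-day window, what is the probability of at least one report in the
*next* window? Three predictors are considered — all previous reports,
previous *feeding* events (successful food access), and previous
*damage* events — matching the three binomial models fitted per species.

The model is a logistic regression with a spatially correlated Gaussian
random intercept over cell centroids::

    logit P(y_ct = 1) = beta0 + beta1 * k_ct + b_c
    (b_1..b_q) ~ N(0, lambda * Matern_nu(rho * d))

with d the Euclidean distance between cell centroids in decimal degrees,
nu the Matérn smoothness (default 0.5, the exponential kernel), rho the
inverse spatial scale and lambda the variance of the spatial effect. The
marginal likelihood is maximised under the Laplace approximation: for
each candidate (beta, rho, lambda) the random-effect mode is found by
Newton iteration and the Gaussian curvature correction applied.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .landscape import GridCell
from .records import ReportRecord

log = logging.getLogger(__name__)

#: default classification of event types into the feeding / damage
#: predictor classes. Feeding requires successful food access; depredation
#: and beehive damage imply success by definition.
DEFAULT_EVENT_CLASS_MAP = {
    "feeding": {"depredation_domestic", "beehive_damage",
                "foraging_anthropogenic", "foraging_natural"},
    "damage": {"depredation_domestic", "beehive_damage", "property_damage"},
}

_ALWAYS_SUCCESS = {"depredation_domestic", "beehive_damage"}

PREDICTOR_COLUMNS = {"all": "n_all_prev", "feeding": "n_feeding_prev",
                     "damage": "n_damage_prev"}


def _is_feeding(r: ReportRecord, feeding_events: set) -> bool:
    if r.event_type not in feeding_events:
        return False
    return r.event_type in _ALWAYS_SUCCESS or r.foraging_success == "success"


def build_window_table(records: Sequence[ReportRecord],
                       occupied_cells: Sequence[GridCell],
                       window_days: int = 30,
                       event_class_map: Optional[dict] = None,
                       start: Optional[dt.datetime] = None,
                       end: Optional[dt.datetime] = None,
                       cell_size_deg: float = 0.01) -> pd.DataFrame:
    """Aggregate records into consecutive, non-overlapping windows.

    One row per (occupied cell, window t) for t = 1..T-1, where T is the
    number of *complete* windows between ``start`` and ``end`` (defaults:
    first/last record timestamps; the final partial window is dropped).
    Predictors are the counts in window t; ``outcome_next`` indicates at
    least one report in window t+1.
    """
    if event_class_map is None:
        event_class_map = DEFAULT_EVENT_CLASS_MAP
    feeding_events = set(event_class_map["feeding"])
    damage_events = set(event_class_map["damage"])
    records = sorted(records, key=lambda r: r.timestamp)
    if start is None:
        if not records:
            raise ValueError("no records and no explicit start date")
        start = records[0].timestamp
    if end is None:
        if not records:
            raise ValueError("no records and no explicit end date")
        end = records[-1].timestamp
    total_days = (end - start).total_seconds() / 86400.0
    n_windows = int(total_days // window_days)
    if (end - start) == dt.timedelta(days=n_windows * window_days) and n_windows > 0:
        pass  # exact multiple: final window is complete
    if n_windows < 2:
        raise ValueError(
            f"study period spans {total_days:.1f} days: fewer than two "
            f"{window_days}-day windows")

    from .landscape import cell_index, locate_cell
    index = cell_index(occupied_cells, cell_size_deg)
    counts: Dict[Tuple[str, int], Dict[str, int]] = {}
    for r in records:
        cell = locate_cell(r.lon, r.lat, index, cell_size_deg)
        if cell is None:
            continue
        w = int((r.timestamp - start).total_seconds() // (window_days * 86400))
        if w < 0 or w >= n_windows:
            continue
        c = counts.setdefault((cell.cell_id, w),
                              {"all": 0, "feeding": 0, "damage": 0})
        c["all"] += 1
        if _is_feeding(r, feeding_events):
            c["feeding"] += 1
        if r.event_type in damage_events:
            c["damage"] += 1

    rows = []
    for cell in sorted(occupied_cells, key=lambda c: c.cell_id):
        for t in range(n_windows - 1):
            cur = counts.get((cell.cell_id, t), {"all": 0, "feeding": 0,
                                                 "damage": 0})
            nxt = counts.get((cell.cell_id, t + 1))
            rows.append({
                "cell_id": cell.cell_id,
                "window_index": t + 1,
                "n_all_prev": cur["all"],
                "n_feeding_prev": cur["feeding"],
                "n_damage_prev": cur["damage"],
                "outcome_next": int(nxt is not None and nxt["all"] > 0),
                "centroid_lon": cell.centroid_lon,
                "centroid_lat": cell.centroid_lat,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Matérn kernel

def matern_correlation(d, rho: float, nu: float = 0.5):
    """Matérn correlation at distance ``d`` with inverse scale ``rho``.

    ``corr = 2^(1-nu)/Gamma(nu) * (rho d)^nu * K_nu(rho d)``, equal to 1 at
    d = 0. At nu = 0.5 this is exactly ``exp(-rho d)``.
    """
    d = np.asarray(d, dtype=float)
    if rho <= 0:
        raise ValueError("rho must be positive")
    if nu == 0.5:
        return np.exp(-rho * d)
    x = rho * d
    out = np.ones_like(x)
    pos = x > 0
    xp = x[pos]
    out[pos] = (2.0 ** (1.0 - nu) / special.gamma(nu)
                * xp ** nu * special.kv(nu, xp))
    return out


# ---------------------------------------------------------------------------
# spatial logistic GLMM

@dataclass
class SpatialGlmmFit:
    terms: List[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    rho: float
    lam: float                      # lambda: variance of the spatial effect
    nu: float
    aicc: float
    log_marginal: float
    n_obs: int
    n_cells: int
    converged: bool
    boundary_lambda: bool = False   # lambda collapsed to its lower bound
    boundary_rho: bool = False      # rho pinned at a box bound
    se_log_rho: float = float("nan")
    se_log_lambda: float = float("nan")
    predictor: str = "all"
    random_effect_modes: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "terms": self.terms,
            "estimates": self.estimates.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "z_values": self.z_values.tolist(),
            "p_values": self.p_values.tolist(),
            "rho": self.rho, "lambda": self.lam, "nu": self.nu,
            "aicc": self.aicc, "log_marginal": self.log_marginal,
            "n_obs": self.n_obs, "n_cells": self.n_cells,
            "converged": self.converged,
            "boundary_lambda": self.boundary_lambda,
            "boundary_rho": self.boundary_rho,
        }


_LOG_LAMBDA_MIN = math.log(1e-8)
_LOG_LAMBDA_MAX = math.log(1e3)
# rho below 0.5/degree (range > 2 degrees, far beyond a municipal study
# area) degenerates into a constant field confounded with the intercept
_LOG_RHO_MIN = math.log(0.5)
_LOG_RHO_MAX = math.log(1e4)


class _LaplaceProblem:
    """Laplace-approximated marginal log-likelihood for one window table."""

    def __init__(self, X: np.ndarray, y: np.ndarray, cell_idx: np.ndarray,
                 D: np.ndarray, nu: float):
        self.X, self.y, self.cell_idx, self.D, self.nu = X, y, cell_idx, D, nu
        self.n, self.p = X.shape
        self.q = D.shape[0]
        self._chol_cache: Dict[Tuple[float, float], Tuple[np.ndarray, np.ndarray, float]] = {}
        self._b_warm = np.zeros(self.q)

    def _sigma_factors(self, rho: float, lam: float):
        key = (rho, lam)
        hit = self._chol_cache.get(key)
        if hit is not None:
            return hit
        C = matern_correlation(self.D, rho, self.nu)
        sigma = lam * C + 1e-10 * np.eye(self.q)
        L = np.linalg.cholesky(sigma)
        sigma_inv = np.linalg.inv(sigma)
        logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(L))))
        if len(self._chol_cache) > 64:
            self._chol_cache.clear()
        self._chol_cache[key] = (sigma_inv, L, logdet_sigma)
        return sigma_inv, L, logdet_sigma

    def _mode(self, beta: np.ndarray, sigma_inv: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Newton iteration for the random-effect mode b-hat."""
        b = self._b_warm.copy()
        xb = self.X @ beta
        for _ in range(60):
            eta = xb + b[self.cell_idx]
            mu = special.expit(eta)
            w = mu * (1.0 - mu)
            grad = (np.bincount(self.cell_idx, weights=self.y - mu,
                                minlength=self.q) - sigma_inv @ b)
            wsum = np.bincount(self.cell_idx, weights=w, minlength=self.q)
            H = sigma_inv + np.diag(wsum)
            step = np.linalg.solve(H, grad)
            # dampen long steps for stability far from the mode
            norm = np.max(np.abs(step))
            if norm > 5.0:
                step *= 5.0 / norm
            b = b + step
            if np.max(np.abs(step)) < 1e-9:
                break
        self._b_warm = b.copy()
        eta = xb + b[self.cell_idx]
        mu = special.expit(eta)
        return b, mu, mu * (1.0 - mu)

    def log_marginal(self, beta: np.ndarray, rho: float, lam: float) -> float:
        sigma_inv, _, logdet_sigma = self._sigma_factors(rho, lam)
        b, mu, w = self._mode(beta, sigma_inv)
        eta = self.X @ beta + b[self.cell_idx]
        loglik = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        wsum = np.bincount(self.cell_idx, weights=w, minlength=self.q)
        H = sigma_inv + np.diag(wsum)
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
        return (loglik - 0.5 * float(b @ sigma_inv @ b)
                - 0.5 * logdet_sigma - 0.5 * logdet_h)

    def neg_obj(self, theta: np.ndarray) -> float:
        beta = theta[:self.p]
        rho = math.exp(theta[self.p])
        lam = math.exp(theta[self.p + 1])
        val = self.log_marginal(beta, rho, lam)
        return 1e10 if not np.isfinite(val) else -val

    def beta_covariance(self, beta: np.ndarray, rho: float, lam: float
                        ) -> np.ndarray:
        """Approximate fixed-effect covariance (Schur complement of the
        joint Hessian at the mode)."""
        sigma_inv, _, _ = self._sigma_factors(rho, lam)
        b, mu, w = self._mode(beta, sigma_inv)
        wsum = np.bincount(self.cell_idx, weights=w, minlength=self.q)
        H_bb = sigma_inv + np.diag(wsum)
        Xw = self.X * w[:, None]
        XWX = self.X.T @ Xw
        XWZ = np.zeros((self.p, self.q))
        for k in range(self.p):
            XWZ[k] = np.bincount(self.cell_idx, weights=Xw[:, k],
                                 minlength=self.q)
        schur = XWX - XWZ @ np.linalg.solve(H_bb, XWZ.T)
        return np.linalg.inv(schur)


def _plain_logistic(X: np.ndarray, y: np.ndarray):
    import statsmodels.api as sm
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    return np.asarray(res.params), np.asarray(res.bse), float(res.llf)


def laplace_marginal_loglik(rows: pd.DataFrame, beta, rho: float, lam: float,
                            predictor: str = "all", nu: float = 0.5) -> float:
    """Laplace-approximated marginal log-likelihood at given parameters.

    Exposed for diagnostics: as lambda -> 0 this converges to the plain
    logistic log-likelihood at ``beta``.
    """
    prob = _build_problem(rows, predictor, nu)
    return prob.log_marginal(np.asarray(beta, dtype=float), rho, lam)


def _build_problem(rows: pd.DataFrame, predictor: str, nu: float
                   ) -> "_LaplaceProblem":
    col = PREDICTOR_COLUMNS[predictor]
    cells = rows[["cell_id", "centroid_lon", "centroid_lat"]].drop_duplicates("cell_id")
    if len(cells) < 2:
        raise ValueError("need at least two distinct cells")
    cell_order = {cid: i for i, cid in enumerate(cells["cell_id"])}
    cell_idx = rows["cell_id"].map(cell_order).to_numpy()
    lonlat = cells[["centroid_lon", "centroid_lat"]].to_numpy()
    D = np.sqrt(((lonlat[:, None, :] - lonlat[None, :, :]) ** 2).sum(-1))
    y = rows["outcome_next"].to_numpy(dtype=float)
    k = rows[col].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(k), k])
    return _LaplaceProblem(X, y, cell_idx, D, nu)


def fit_spatial_logistic(rows: pd.DataFrame, predictor: str = "all",
                         nu: float = 0.5, n_starts: int = 3,
                         lambda_fixed: Optional[float] = None,
                         method: str = "REML",
                         compute_covariance_ses: bool = True
                         ) -> SpatialGlmmFit:
    """Fit the spatial logistic recurrence model by Laplace approximation.

    ``predictor`` selects the count column: "all", "feeding" or "damage".
    ``lambda_fixed=0`` degenerates to plain logistic regression (used as
    an internal consistency check). Multi-start bounded quasi-Newton over
    (beta, log rho, log lambda). ``method="REML"`` (default) estimates
    the covariance parameters from the restricted Laplace objective
    (marginal log-likelihood minus half the log-determinant of the
    fixed-effect information), which removes most of the small-sample
    downward bias of the maximum-likelihood variance estimate;
    ``method="ML"`` maximises the Laplace marginal likelihood directly.
    AICc is always computed from the unrestricted marginal likelihood at
    the fitted parameters, counting the two covariance parameters.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"unknown method {method!r}")
    prob = _build_problem(rows, predictor, nu)
    X, y = prob.X, prob.y
    n, p = X.shape
    n_cells_total = prob.q
    terms = ["intercept", f"n_{predictor}_prev"]

    beta0, bse0, llf0 = _plain_logistic(X, y)

    if lambda_fixed is not None and lambda_fixed == 0.0:
        zv = beta0 / bse0
        pv = 2 * stats.norm.sf(np.abs(zv))
        p_eff = p
        aicc = -2 * llf0 + 2 * p_eff + 2 * p_eff * (p_eff + 1) / (n - p_eff - 1)
        return SpatialGlmmFit(
            terms=terms, estimates=beta0, standard_errors=bse0, z_values=zv,
            p_values=pv, rho=float("nan"), lam=0.0, nu=nu, aicc=aicc,
            log_marginal=llf0, n_obs=n, n_cells=n_cells_total, converged=True,
            predictor=predictor)

    def objective(theta: np.ndarray) -> float:
        val = prob.neg_obj(theta)
        if val >= 1e9 or method == "ML":
            return val
        beta = theta[:p]
        rho = math.exp(theta[p])
        lam = math.exp(theta[p + 1])
        try:
            sign, ld = np.linalg.slogdet(prob.beta_covariance(beta, rho, lam))
        except np.linalg.LinAlgError:
            return 1e10
        if sign <= 0:
            return 1e10
        # restricted objective: + 0.5 logdet(info) = - 0.5 logdet(cov)
        return val - 0.5 * ld

    starts = [(math.log(25.0), math.log(0.3)),
              (math.log(5.0), math.log(0.1)),
              (math.log(125.0), math.log(1.0))][:max(1, n_starts)]
    bounds = ([(None, None)] * p
              + [(_LOG_RHO_MIN, _LOG_RHO_MAX), (_LOG_LAMBDA_MIN, _LOG_LAMBDA_MAX)])
    if lambda_fixed is not None:
        lf = math.log(lambda_fixed)
        bounds[p + 1] = (lf, lf)
        starts = [(s[0], lf) for s in starts]

    best = None
    for s_rho, s_lam in starts:
        theta0 = np.concatenate([beta0, [s_rho, s_lam]])
        prob._b_warm = np.zeros(prob.q)
        res = optimize.minimize(
            objective, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-7,
                     "eps": 1e-5})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    assert best is not None
    theta = best.x
    if method == "REML":
        # covariance parameters from the restricted objective; beta from
        # the unrestricted Laplace likelihood at those parameters
        fixed_tail = theta[p:]

        def neg_beta(beta_only: np.ndarray) -> float:
            return prob.neg_obj(np.concatenate([beta_only, fixed_tail]))

        res_b = optimize.minimize(neg_beta, theta[:p], method="L-BFGS-B",
                                  options={"maxiter": 200, "ftol": 1e-12,
                                           "eps": 1e-6})
        theta = np.concatenate([res_b.x, fixed_tail])
    beta = theta[:p]
    rho = math.exp(theta[p])
    lam = math.exp(theta[p + 1])
    boundary = theta[p + 1] <= _LOG_LAMBDA_MIN + 1e-6
    boundary_rho = (theta[p] <= _LOG_RHO_MIN + 1e-6
                    or theta[p] >= _LOG_RHO_MAX - 1e-6)
    if boundary:
        log.warning("lambda collapsed to its lower bound; spatial effect ~0")
    if boundary_rho and not boundary:
        log.warning("rho pinned at a bound; spatial scale not identified")

    cov_beta = prob.beta_covariance(beta, rho, lam)
    se = np.sqrt(np.diag(cov_beta))
    logml = -prob.neg_obj(theta)     # unrestricted, for AICc
    p_eff = p + 2
    aicc = -2 * logml + 2 * p_eff + 2 * p_eff * (p_eff + 1) / (n - p_eff - 1)

    se_lr = se_ll = float("nan")
    if compute_covariance_ses and not boundary and not boundary_rho:
        try:
            hess = _numeric_hessian(objective, theta, h=1e-3)
            cov_all = np.linalg.inv(hess)
            d = np.diag(cov_all)
            if np.all(d[p:] > 0):
                se_lr, se_ll = float(np.sqrt(d[p])), float(np.sqrt(d[p + 1]))
            # the full-Hessian beta SEs propagate covariance-parameter
            # uncertainty into the fixed effects; prefer them when defined
            if np.all(d[:p] > 0):
                se = np.sqrt(d[:p])
        except np.linalg.LinAlgError:
            pass
    zv = beta / se
    pv = 2 * stats.norm.sf(np.abs(zv))

    sigma_inv, _, _ = prob._sigma_factors(rho, lam)
    b_modes, _, _ = prob._mode(beta, sigma_inv)

    return SpatialGlmmFit(
        terms=terms, estimates=beta, standard_errors=np.asarray(se),
        z_values=np.asarray(zv), p_values=np.asarray(pv), rho=rho, lam=lam,
        nu=nu, aicc=aicc, log_marginal=logml, n_obs=n,
        n_cells=n_cells_total, converged=bool(best.success),
        boundary_lambda=bool(boundary), boundary_rho=bool(boundary_rho),
        se_log_rho=se_lr, se_log_lambda=se_ll, predictor=predictor,
        random_effect_modes=b_modes)


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    m = x.size
    H = np.zeros((m, m))
    f0 = f(x)
    for i in range(m):
        for j in range(i, m):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += h
                xmm[[i, j]] -= h
                xpm[i] += h
                xpm[j] -= h
                xmp[i] -= h
                xmp[j] += h
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h ** 2)
    return H


def predict_recurrence(fit: SpatialGlmmFit, k) -> np.ndarray:
    """Probability of a report in the next window given k previous reports.

    Fixed effects only: inverse-logit of beta0 + beta1 * k, the random
    effect at its zero mean.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    return special.expit(fit.estimates[0] + fit.estimates[1] * k)


# ---------------------------------------------------------------------------
# model-based simulation (for parameter-recovery checks)

def simulate_recurrence_data(n_cols: int = 20, n_rows: int = 10,
                             n_windows: int = 11, beta0: float = -1.4,
                             beta1: float = 0.3, lam: float = 0.3,
                             rho: float = 25.0, nu: float = 0.5,
                             mean_prev: float = 1.0,
                             cell_size_deg: float = 0.02,
                             seed: int = 0) -> pd.DataFrame:
    """Draw a window table directly from the spatial logistic model.

    Cells form an ``n_cols x n_rows`` lattice of centroids spaced
    ``cell_size_deg`` apart (default 0.02 degrees, so the default
    correlation range 1/rho = 0.04 degrees spans two lattice steps and
    the extent spans about ten ranges — a design in which rho and lambda
    are identifiable);
    previous-report counts are Poisson(``mean_prev``); outcomes are
    Bernoulli with logit beta0 + beta1*k + b_c, b ~ N(0, lambda *
    Matern_nu(rho * d)).
    """
    rng = np.random.default_rng(seed)
    q = n_cols * n_rows
    lon = (np.arange(n_cols) + 0.5) * cell_size_deg
    lat = (np.arange(n_rows) + 0.5) * cell_size_deg
    cl, ct = np.meshgrid(lon, lat)
    lonlat = np.column_stack([cl.ravel(), ct.ravel()])
    D = np.sqrt(((lonlat[:, None, :] - lonlat[None, :, :]) ** 2).sum(-1))
    cov = lam * matern_correlation(D, rho, nu) + 1e-10 * np.eye(q)
    b = np.linalg.cholesky(cov) @ rng.standard_normal(q)
    rows = []
    for c in range(q):
        k = rng.poisson(mean_prev, size=n_windows)
        pr = special.expit(beta0 + beta1 * k + b[c])
        y = rng.uniform(size=n_windows) < pr
        for t in range(n_windows):
            rows.append({"cell_id": f"s{c}", "window_index": t + 1,
                         "n_all_prev": int(k[t]),
                         "n_feeding_prev": int(k[t]),
                         "n_damage_prev": int(k[t]),
                         "outcome_next": int(y[t]),
                         "centroid_lon": lonlat[c, 0],
                         "centroid_lat": lonlat[c, 1]})
    return pd.DataFrame(rows)
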