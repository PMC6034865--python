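"""Random-intercept linear mixed models for plot-level diversity.

The model is y = X beta + a_region + b_island + e with independent Gaussian
random intercepts for region and for island nested in region, fitted by
restricted maximum likelihood (REML).  The covariance V = sigma2_e * W with
W = I + g_r Z_r Z_r' + g_i Z_i Z_i' is block-diagonal by region, so the
profiled (restricted) log-likelihood is evaluated block-wise and maximised
over the two variance ratios (g_r, g_i) on the log scale, with the three
boundary sub-models (either or both ratios zero) evaluated explicitly and
deterministic multi-starts for the interior optimum.  Likelihood-ratio tests
refit by maximum likelihood.

On top of the fitter: p-value-based backward selection to a minimal adequate
model, marginal/conditional pseudo-R2 (fixed-effects variance over total
variance, and fixed plus random over total), and the attribution of the
marginal R2 to variable-sets in proportion to the absolute fixed-effect
estimates on the common [0, 1] predictor scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .vegdata import VariableSetMap

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class LMMFit:
    """A fitted nested random-intercept model."""

    response: str
    fe_names: list[str]
    params: pd.Series
    sigma2_region: float
    sigma2_island: float
    sigma2_resid: float
    loglik: float
    reml: bool
    n: int
    converged: bool
    fitted_fixed: np.ndarray = field(repr=False, default=None)
    _data: tuple = field(repr=False, default=None)  # (y, X, region, island)

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "region": self.sigma2_region,
            "island": self.sigma2_island,
            "residual": self.sigma2_resid,
        }


class _Blocks:
    """Per-region blocks of the mixed-model design.

    The covariance W = I + g_r 1 1' + g_i Z Z' is low-rank within each
    region block, so W^{-1} and log|W| are evaluated with the Woodbury and
    matrix-determinant identities on (1 + n_islands)-dimensional cross
    products, precomputed once per fit.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, region, island):
        region = np.asarray(region)
        island = np.asarray(island)
        n, p = X.shape
        self.n, self.p = n, p
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        Ur = pd.get_dummies(pd.Series(region)).values.astype(float)
        Ui = pd.get_dummies(pd.Series(island)).values.astype(float)
        U = np.hstack([Ur, Ui])
        self.n_regions = Ur.shape[1]
        self.n_islands = Ui.shape[1]
        self.UtU = U.T @ U
        self.UtX = U.T @ X
        self.Uty = U.T @ y

    def profiled(self, g_r: float, g_i: float, reml: bool) -> tuple:
        """Profiled log-likelihood pieces for variance ratios (g_r, g_i)."""
        p = self.p
        XtWX = self.XtX.copy()
        XtWy = self.Xty.copy()
        ytWy = self.yty
        logdetW = 0.0
        d = np.concatenate(
            [np.full(self.n_regions, g_r), np.full(self.n_islands, g_i)]
        )
        idx = np.where(d > 0.0)[0]
        if idx.size:
            da = d[idx]
            # A = D^{-1} + U'U on the active random-effect columns
            A = self.UtU[np.ix_(idx, idx)] + np.diag(1.0 / da)
            cf = cho_factor(A, lower=True)
            logdetW = 2.0 * np.sum(np.log(np.diag(cf[0]))) + np.sum(np.log(da))
            UtX = self.UtX[idx]
            Uty = self.Uty[idx]
            Sx = cho_solve(cf, UtX)
            Sy = cho_solve(cf, Uty)
            XtWX = XtWX - UtX.T @ Sx
            XtWy = XtWy - UtX.T @ Sy
            ytWy = ytWy - float(Uty @ Sy)
        beta = np.linalg.solve(XtWX, XtWy)
        q_form = float(ytWy - beta @ XtWy)
        q_form = max(q_form, 1e-300)
        n = self.n
        if reml:
            dof = n - p
            _, logdet_xtwx = np.linalg.slogdet(XtWX)
            s2 = q_form / dof
            ll = -0.5 * (
                dof * (_LOG_2PI + math.log(s2))
                + logdetW
                + logdet_xtwx
                + dof
            )
        else:
            s2 = q_form / n
            ll = -0.5 * (n * (_LOG_2PI + math.log(s2)) + logdetW + n)
        return ll, beta, s2


def fit_lmm_reml(
    y,
    X: pd.DataFrame,
    region,
    island,
    reml: bool = True,
    response: str = "y",
) -> LMMFit:
    """Fit the nested random-intercept model by REML (or ML).

    ``X`` is the fixed-effect design; an intercept column is added when
    absent.  Requires at least two islands and a full-rank design.
    """
    y = np.asarray(y, dtype=float)
    Xd = X.copy()
    if not any(
        np.allclose(Xd[c].values, 1.0) for c in Xd.columns
    ):
        Xd.insert(0, "Intercept", 1.0)
    Xm = Xd.values.astype(float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("rank-deficient fixed-effect design")
    if len(pd.unique(np.asarray(island))) < 2:
        raise ValueError("need at least two islands to separate variance components")
    if len(y) != len(Xm):
        raise ValueError("response and design lengths differ")

    blocks = _Blocks(y, Xm, region, island)

    def neg(params_log: np.ndarray) -> float:
        g_r, g_i = np.exp(np.clip(params_log, -30.0, 30.0))
        return -blocks.profiled(g_r, g_i, reml)[0]

    candidates: list[tuple[float, float, float]] = []  # (ll, g_r, g_i)
    # boundary: both ratios zero (OLS limit)
    ll0 = blocks.profiled(0.0, 0.0, reml)[0]
    candidates.append((ll0, 0.0, 0.0))
    # boundary: one ratio zero, optimise the other on the log scale
    for which in ("region", "island"):
        def neg1(t: float) -> float:
            g = math.exp(t)
            gr, gi = (g, 0.0) if which == "region" else (0.0, g)
            return -blocks.profiled(gr, gi, reml)[0]

        res = minimize_scalar(neg1, bounds=(-25.0, 12.0), method="bounded",
                              options={"xatol": 1e-12})
        g = math.exp(res.x)
        gr, gi = (g, 0.0) if which == "region" else (0.0, g)
        candidates.append((-res.fun, gr, gi))
    # interior: deterministic multi-starts
    for start in ((0.0, 0.0), (math.log(0.1),) * 2, (math.log(3.0),) * 2):
        res = minimize(
            neg, np.array(start), method="Nelder-Mead",
            options={"xatol": 1e-11, "fatol": 1e-12, "maxiter": 800},
        )
        gr, gi = np.exp(np.clip(res.x, -30.0, 30.0))
        candidates.append((-res.fun, gr, gi))

    ll, g_r, g_i = max(candidates, key=lambda t: t[0])
    # ratios that collapsed to numerical zero are reported as exact boundary
    if g_r < 1e-9:
        g_r = 0.0
    if g_i < 1e-9:
        g_i = 0.0
    ll, beta, s2 = blocks.profiled(g_r, g_i, reml)
    if not np.isfinite(ll):
        raise RuntimeError("REML optimisation did not converge (non-finite likelihood)")
    params = pd.Series(beta, index=Xd.columns)
    return LMMFit(
        response=response,
        fe_names=list(Xd.columns),
        params=params,
        sigma2_region=g_r * s2,
        sigma2_island=g_i * s2,
        sigma2_resid=s2,
        loglik=float(ll),
        reml=reml,
        n=len(y),
        converged=True,
        fitted_fixed=Xm @ beta,
        _data=(y, Xd, np.asarray(region), np.asarray(island)),
    )


def lrt_compare(full: LMMFit, reduced: LMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed-effect structures.

    Both models are refit by maximum likelihood; the statistic is
    -2 (ll_reduced - ll_full) on a chi-square with df = difference in the
    number of fixed effects.  Returns (statistic, df, p).
    """
    if not set(reduced.fe_names) <= set(full.fe_names):
        raise ValueError("models are not nested (reduced terms not in full model)")
    df = len(full.fe_names) - len(reduced.fe_names)
    if df == 0:
        return 0.0, 0, 1.0
    refits = []
    for fit in (full, reduced):
        y, Xd, region, island = fit._data
        refits.append(
            fit
            if (not fit.reml)
            else fit_lmm_reml(y, Xd, region, island, reml=False, response=fit.response)
        )
    stat = max(0.0, 2.0 * (refits[0].loglik - refits[1].loglik))
    return stat, df, float(chi2.sf(stat, df)) if df > 0 else 1.0


def backward_select(
    y,
    X: pd.DataFrame,
    region,
    island,
    alpha: float = 0.05,
    response: str = "y",
) -> tuple[LMMFit, pd.DataFrame]:
    """Backward elimination of the least significant fixed effects.

    At each round every current term is tested by a single-term-deletion
    likelihood-ratio test (ML refits); the term with the largest p is dropped
    while that p exceeds alpha.  Returns the REML refit of the minimal
    adequate model and the elimination log (an intercept-only model is a
    legitimate outcome).
    """
    current = list(X.columns)
    log_rows = []
    while current:
        full_ml = fit_lmm_reml(y, X[current], region, island, reml=False,
                               response=response)
        worst, worst_p = None, -1.0
        for term in current:
            rest = [c for c in current if c != term]
            red_ml = fit_lmm_reml(y, X[rest] if rest else X[[]], region, island,
                                  reml=False, response=response)
            stat = max(0.0, 2.0 * (full_ml.loglik - red_ml.loglik))
            p = float(chi2.sf(stat, 1))
            if p > worst_p:
                worst, worst_p = term, p
        if worst_p > alpha:
            log_rows.append({"dropped": worst, "p": worst_p})
            current.remove(worst)
        else:
            break
    final = fit_lmm_reml(y, X[current] if current else X[[]], region, island,
                         reml=True, response=response)
    # keep per-term p-values of the retained terms for reporting
    term_p = {}
    if current:
        full_ml = fit_lmm_reml(y, X[current], region, island, reml=False,
                               response=response)
        for term in current:
            rest = [c for c in current if c != term]
            red_ml = fit_lmm_reml(y, X[rest] if rest else X[[]], region, island,
                                  reml=False, response=response)
            stat = max(0.0, 2.0 * (full_ml.loglik - red_ml.loglik))
            term_p[term] = float(chi2.sf(stat, 1))
    final.term_p = term_p  # type: ignore[attr-defined]
    return final, pd.DataFrame(log_rows, columns=["dropped", "p"])


def nakagawa_r2(fit: LMMFit) -> tuple[float, float]:
    """Marginal and conditional pseudo-R2 of a mixed model.

    mR2 = var(X beta) / (var(X beta) + s2_region + s2_island + s2_resid);
    cR2 adds the random-intercept variances to the numerator.  The variance
    of the fixed-effect predictor is the population variance across the
    observations.
    """
    sigma_f = float(np.var(fit.fitted_fixed))  # ddof=0: population variance
    total = sigma_f + fit.sigma2_region + fit.sigma2_island + fit.sigma2_resid
    if total <= 0:
        raise ValueError("zero total variance")
    mr2 = sigma_f / total
    cr2 = (sigma_f + fit.sigma2_region + fit.sigma2_island) / total
    return mr2, cr2


@dataclass
class DiversityPartition:
    """Variable-set attribution of a minimal adequate diversity model."""

    response: str
    mr2: float
    cr2: float
    table: pd.DataFrame  # per set: etv_pct, emv_pct

    @property
    def random_etv_pct(self) -> float:
        return 100.0 * (self.cr2 - self.mr2)

    @property
    def full_model_etv_pct(self) -> float:
        return 100.0 * self.cr2


def set_contributions(
    fit: LMMFit,
    setmap: VariableSetMap,
    use_squared: bool = False,
) -> DiversityPartition:
    """Attribute the marginal R2 to variable-sets via fixed-effect estimates.

    Each retained predictor contributes |beta| (or beta^2 with
    ``use_squared``) on the common [0, 1] predictor scale; set shares are the
    normalised sums of their members' contributions, scaled by mR2 to give
    ETV%.  The random term contributes cR2 - mR2.  EMV% rescales so that the
    set contributions plus the random contribution sum to 100.
    """
    mr2, cr2 = nakagawa_r2(fit)
    terms = [t for t in fit.fe_names if t != "Intercept"]
    weights = {}
    for t in terms:
        est = float(fit.params[t])
        weights[t] = est**2 if use_squared else abs(est)
        setmap.set_of(t)  # raises on unmapped variable
    total_w = sum(weights.values())
    rows = []
    for set_name in setmap.set_names:
        members = [t for t in terms if setmap.set_of(t) == set_name]
        if not members:
            continue
        share = sum(weights[t] for t in members) / total_w if total_w > 0 else 0.0
        etv = 100.0 * share * mr2
        rows.append(
            {
                "set": set_name,
                "variables": ", ".join(members),
                "share": share,
                "etv_pct": etv,
                "emv_pct": etv / cr2 if cr2 > 0 else np.nan,
            }
        )
    random_row = {
        "set": "random_effects",
        "variables": "REGION, ISLAND ID",
        "share": np.nan,
        "etv_pct": 100.0 * (cr2 - mr2),
        "emv_pct": 100.0 * (cr2 - mr2) / cr2 if cr2 > 0 else np.nan,
    }
    table = pd.DataFrame([random_row] + rows)
    return DiversityPartition(fit.response, mr2, cr2, table)


def exclude_outliers(data: pd.DataFrame, exclusion: list) -> pd.DataFrame:
    """Remove listed plots from a plot-indexed table."""
    if len(set(exclusion)) != len(exclusion):
        raise ValueError("duplicate plot ids in the exclusion list")
    unknown = [p for p in exclusion if p not in data.index]
    if unknown:
        raise ValueError(f"unknown plot ids: {unknown}")
    return data.drop(index=exclusion)
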