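"""Correspondence-analysis machinery for community data.

Implements (partial) canonical correspondence analysis from first principles:
the plot x species table is converted to chi-square-standardised residuals

    S_ij = (p_ij - r_i c_j) / sqrt(r_i c_j),

where ``p`` is the table scaled to unit grand total and ``r``/``c`` are its
row and column masses.  Total inertia is the squared Frobenius norm of S.
CA is the SVD of S; CCA projects the rows of S onto the span of the
(mass-weighted, centred) constraint columns before the SVD; pCCA first
removes the span of the covariable columns from both S and the constraints.
Optional species weights (rare-species down-weighting) multiply the
standardised residual columns by sqrt(weight).

Also provided: a pseudo-F statistic, unrestricted Monte-Carlo permutation
tests, Benjamini-Hochberg FDR adjustment, permutation-based forward selection
within variable-sets, gross/net variance partitioning (ETV/EMV), and the
gradient length of DCA axis 1 (detrending by segments with nonlinear
rescaling, reported in SD units of species turnover).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr, svd
from statsmodels.stats.multitest import multipletests

_EIG_TOL = 1e-12


@dataclass
class OrdinationResult:
    """Eigen-structure of a CA/CCA/pCCA fit."""

    total_inertia: float
    eigenvalues: np.ndarray  # unconstrained (residual) axes
    canonical_eigenvalues: np.ndarray
    site_scores: pd.DataFrame | None = None
    species_scores: pd.DataFrame | None = None
    constraint_names: list[str] = field(default_factory=list)
    covariable_names: list[str] = field(default_factory=list)
    covariable_inertia: float = 0.0
    n_plots: int = 0
    pseudo_f: float | None = None
    permutation_p: float | None = None

    @property
    def canonical_inertia(self) -> float:
        return float(np.sum(self.canonical_eigenvalues))


def _chi_square_residuals(
    m: pd.DataFrame, species_weights: pd.Series | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.Index, pd.Index]:
    """Standardised residual matrix S with row/column masses.

    Zero rows and columns are dropped with a warning (they carry no inertia
    and break the standardisation).
    """
    Y = m.values.astype(float)
    if (Y < 0).any():
        raise ValueError("community matrix must be non-negative")
    row_ok = Y.sum(axis=1) > 0
    col_ok = Y.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            f"dropping {int((~row_ok).sum())} empty plots and "
            f"{int((~col_ok).sum())} empty species before analysis",
            stacklevel=3,
        )
        Y = Y[np.ix_(row_ok, col_ok)]
    plots = m.index[row_ok]
    species = m.columns[col_ok]
    total = Y.sum()
    if total <= 0:
        raise ValueError("community matrix has zero grand total")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    if species_weights is not None:
        w = species_weights.reindex(species).fillna(1.0).values.astype(float)
        if (w < 0).any():
            raise ValueError("species weights must be non-negative")
        S = S * np.sqrt(w)
    return S, r, c, plots, species


def total_inertia(
    m: pd.DataFrame, species_weights: pd.Series | None = None
) -> float:
    """Total inertia: the chi-square statistic of the table over its total."""
    S, *_ = _chi_square_residuals(m, species_weights)
    return float(np.sum(S**2))


def _weighted_design(X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Mass-centre the columns of X and scale rows by sqrt(row mass)."""
    Xc = X - r @ X
    return np.sqrt(r)[:, None] * Xc


def _orth(A: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Orthonormal basis of the column space; errors on rank deficiency."""
    if A.size == 0 or A.shape[1] == 0:
        return np.empty((A.shape[0], 0))
    Q, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] < 1e-10:
        return np.empty((A.shape[0], 0))
    rank = int(np.sum(diag > 1e-10 * diag[0]))
    if names is not None and rank < A.shape[1]:
        dropped = [names[i] for i in piv[rank:]]
        raise ValueError(f"collinear constraints: {dropped} depend on the others")
    return Q[:, :rank]


def ca(m: pd.DataFrame, species_weights: pd.Series | None = None) -> OrdinationResult:
    """Correspondence analysis: eigen-decomposition of the standardised table."""
    S, r, c, plots, species = _chi_square_residuals(m, species_weights)
    if S.shape[0] < 2 or S.shape[1] < 2:
        raise ValueError("correspondence analysis needs >= 2 plots and species")
    U, sv, Vt = svd(S, full_matrices=False)
    lam = sv**2
    keep = lam > _EIG_TOL
    lam, U, Vt = lam[keep], U[:, keep], Vt[keep]
    site = pd.DataFrame(
        U / np.sqrt(r)[:, None],
        index=plots,
        columns=[f"CA{i+1}" for i in range(U.shape[1])],
    )
    spec = pd.DataFrame(
        Vt.T / np.sqrt(c)[:, None],
        index=species,
        columns=site.columns,
    )
    return OrdinationResult(
        total_inertia=float(np.sum(S**2)),
        eigenvalues=lam,
        canonical_eigenvalues=np.array([]),
        site_scores=site,
        species_scores=spec,
        n_plots=len(plots),
    )


def cca(
    m: pd.DataFrame,
    env: pd.DataFrame | None,
    covariables: pd.DataFrame | None = None,
    species_weights: pd.Series | None = None,
) -> OrdinationResult:
    """(Partial) canonical correspondence analysis.

    ``env`` holds the constraint columns, ``covariables`` the columns whose
    explained inertia is removed before constraining.  With ``env`` empty the
    canonical set is empty; with ``covariables`` empty this is plain CCA.
    """
    S, r, c, plots, species = _chi_square_residuals(m, species_weights)
    TI = float(np.sum(S**2))
    constraint_names = list(env.columns) if env is not None else []
    covariable_names = list(covariables.columns) if covariables is not None else []
    overlap = set(constraint_names) & set(covariable_names)
    if overlap:
        raise ValueError(f"constraints also listed as covariables: {sorted(overlap)}")

    cov_inertia = 0.0
    Qz = np.empty((len(plots), 0))
    if covariable_names:
        Z = covariables.loc[plots].values.astype(float)
        Qz = _orth(_weighted_design(Z, r))
        proj = Qz @ (Qz.T @ S)
        cov_inertia = float(np.sum(proj**2))
        S = S - proj

    if not constraint_names:
        lam = _residual_eigenvalues(S)
        return OrdinationResult(
            TI, lam, np.array([]), covariable_names=covariable_names,
            covariable_inertia=cov_inertia, n_plots=len(plots),
        )

    if len(plots) <= len(constraint_names):
        raise ValueError("need more plots than constraints")
    X = env.loc[plots].values.astype(float)
    Xs = _weighted_design(X, r)
    if Qz.shape[1]:
        Xs = Xs - Qz @ (Qz.T @ Xs)
        Qx = _orth(Xs)  # rank may legitimately drop after partialling
    else:
        Qx = _orth(Xs, names=constraint_names)

    F = Qx.T @ S
    if F.size:
        Uf, sv, Vtf = svd(F, full_matrices=False)
        lam_can = sv**2
        keep = lam_can > _EIG_TOL
        lam_can, Uf, Vtf = lam_can[keep], Uf[:, keep], Vtf[keep]
        fitted = Qx @ Uf
    else:
        lam_can = np.array([])
        fitted = np.empty((len(plots), 0))
        Vtf = np.empty((0, len(species)))
    S_res = S - Qx @ F
    lam_res = _residual_eigenvalues(S_res)

    axes = [f"CCA{i+1}" for i in range(lam_can.size)]
    site = pd.DataFrame(fitted / np.sqrt(r)[:, None], index=plots, columns=axes)
    spec = pd.DataFrame(Vtf.T / np.sqrt(c)[:, None], index=species, columns=axes)
    return OrdinationResult(
        total_inertia=TI,
        eigenvalues=lam_res,
        canonical_eigenvalues=lam_can,
        site_scores=site,
        species_scores=spec,
        constraint_names=constraint_names,
        covariable_names=covariable_names,
        covariable_inertia=cov_inertia,
        n_plots=len(plots),
    )


def pcca(
    m: pd.DataFrame,
    env: pd.DataFrame,
    covariables: pd.DataFrame | None,
    species_weights: pd.Series | None = None,
) -> OrdinationResult:
    """Partial CCA: alias of :func:`cca` with covariables made explicit."""
    return cca(m, env, covariables, species_weights)


def _residual_eigenvalues(S: np.ndarray) -> np.ndarray:
    sv = svd(S, compute_uv=False)
    lam = sv**2
    return lam[lam > _EIG_TOL]


def pseudo_f(result: OrdinationResult) -> float:
    """Pseudo-F of a constrained fit.

    F = (sum canonical / q) / (residual inertia / (n - q - q_cov - 1)) with
    residual inertia = TI - canonical - covariable-explained inertia.
    """
    q = len(result.constraint_names)
    q_cov = len(result.covariable_names)
    n = result.n_plots
    if q == 0:
        raise ValueError("pseudo-F needs at least one constraint")
    df_res = n - q - q_cov - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    resid = result.total_inertia - result.canonical_inertia - result.covariable_inertia
    if resid <= _EIG_TOL:
        raise ValueError("constraints explain (numerically) all inertia")
    return float((result.canonical_inertia / q) / (resid / df_res))


def permutation_test(
    m: pd.DataFrame,
    env: pd.DataFrame,
    covariables: pd.DataFrame | None = None,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    species_weights: pd.Series | None = None,
) -> tuple[float, float]:
    """Unrestricted Monte-Carlo permutation test of a (p)CCA.

    The constraint table is residualised on the covariables (under plot-mass
    weighting) and its plot rows are permuted; each permutation is refit and
    the p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm).  Returns
    (observed F, p).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    S, r, c, plots, _ = _chi_square_residuals(m, species_weights)
    TI = float(np.sum(S**2))
    n = len(plots)
    X = env.loc[plots].values.astype(float)
    q = X.shape[1]
    if covariables is not None and len(covariables.columns):
        Z = covariables.loc[plots].values.astype(float)
        Qz = _orth(_weighted_design(Z, r))
        q_cov = Z.shape[1]
    else:
        Qz = np.empty((n, 0))
        q_cov = 0
    cov_proj = Qz @ (Qz.T @ S) if Qz.shape[1] else 0.0
    cov_inertia = float(np.sum(cov_proj**2)) if Qz.shape[1] else 0.0
    S_res = S - cov_proj

    def fstat(Xmat: np.ndarray) -> float:
        Xs = _weighted_design(Xmat, r)
        if Qz.shape[1]:
            Xs = Xs - Qz @ (Qz.T @ Xs)
        Qx = _orth(Xs)
        can = float(np.sum((Qx.T @ S_res) ** 2))
        resid = TI - can - cov_inertia
        df_res = n - q - q_cov - 1
        if df_res <= 0 or resid <= _EIG_TOL:
            return np.inf
        return (can / q) / (resid / df_res)

    f_obs = fstat(X)
    # residualise the raw constraints on the covariables before permuting
    if Qz.shape[1]:
        Xs = _weighted_design(X, r)
        X_res = (Xs - Qz @ (Qz.T @ Xs)) / np.sqrt(r)[:, None]
    else:
        X_res = X
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if fstat(X_res[perm]) >= f_obs:
            hits += 1
    return f_obs, (1 + hits) / (1 + n_perm)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SelectionResult:
    """Forward-selection trace for one variable-set."""

    order: list[str]
    added_inertia: list[float]
    p_values: list[float]
    p_adjusted: list[float]
    selected: list[str]


def forward_select(
    m: pd.DataFrame,
    env: pd.DataFrame,
    candidates: list[str],
    covariables: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    species_weights: pd.Series | None = None,
) -> SelectionResult:
    """Greedy permutation forward selection within one variable-set.

    At each step the candidate adding the most canonical inertia (given the
    current selection and the covariables) enters, with a Monte-Carlo
    permutation p-value for the addition.  After the whole set is processed
    the step p-values are FDR-adjusted and members with adjusted p > alpha
    are dropped.  An empty selection is a legitimate outcome (the set is
    reported as non-significant).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    rng = np.random.default_rng(seed)
    remaining = list(candidates)
    order: list[str] = []
    added: list[float] = []
    pvals: list[float] = []
    while remaining:
        Z = _combine(covariables, env[order]) if order else covariables
        best, best_inertia = None, -np.inf
        for cand in remaining:
            fit = cca(m, env[[cand]], Z, species_weights)
            if fit.canonical_inertia > best_inertia:
                best, best_inertia = cand, fit.canonical_inertia
        _, p = permutation_test(
            m, env[[best]], Z, n_perm=n_perm, seed=rng, species_weights=species_weights
        )
        order.append(best)
        added.append(best_inertia)
        pvals.append(p)
        remaining.remove(best)
    adj = fdr_bh(pvals)
    selected = [v for v, pa in zip(order, adj) if pa <= alpha]
    return SelectionResult(order, added, pvals, list(adj), selected)


def _combine(a: pd.DataFrame | None, b: pd.DataFrame | None) -> pd.DataFrame | None:
    frames = [f for f in (a, b) if f is not None and len(f.columns)]
    if not frames:
        return None
    return pd.concat(frames, axis=1)


def variance_partition(
    m: pd.DataFrame,
    selections: dict[str, list[str]],
    env: pd.DataFrame,
    region_set: str = "region",
    species_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Gross and net explained variance per variable-set (ETV% and EMV%).

    The full model is a CCA on all selected variables of all sets.  For each
    set, the gross effect is the canonical inertia of a pCCA with region as
    the only covariable (region's own gross effect has no covariables); the
    net effect partials out all other selected variables including region.
    ETV% divides by total inertia, EMV% by the full-model canonical inertia.
    Sets with no selected variables are reported as not significant (NaN).
    """
    all_vars = [v for vs in selections.values() for v in vs]
    if not all_vars:
        raise ValueError("no selected variables in any set")
    full = cca(m, env[all_vars], None, species_weights)
    TI, full_can = full.total_inertia, full.canonical_inertia
    region_vars = selections.get(region_set, [])
    rows = []
    for set_name, vars_ in selections.items():
        if not vars_:
            rows.append(
                {"set": set_name, "variables": "n.s.", "gross_inertia": np.nan,
                 "gross_etv_pct": np.nan, "gross_emv_pct": np.nan,
                 "net_inertia": np.nan, "net_etv_pct": np.nan,
                 "net_emv_pct": np.nan}
            )
            continue
        if set_name == region_set:
            gross = cca(m, env[vars_], None, species_weights)
        else:
            Z = env[region_vars] if region_vars else None
            gross = cca(m, env[vars_], Z, species_weights)
        others = [v for s, vs in selections.items() if s != set_name for v in vs]
        net = cca(m, env[vars_], env[others] if others else None, species_weights)
        rows.append(
            {
                "set": set_name,
                "variables": ", ".join(vars_),
                "gross_inertia": gross.canonical_inertia,
                "gross_etv_pct": 100.0 * gross.canonical_inertia / TI,
                "gross_emv_pct": 100.0 * gross.canonical_inertia / full_can,
                "net_inertia": net.canonical_inertia,
                "net_etv_pct": 100.0 * net.canonical_inertia / TI,
                "net_emv_pct": 100.0 * net.canonical_inertia / full_can,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["total_inertia"] = TI
    out.attrs["full_model_inertia"] = full_can
    out.attrs["full_model_etv_pct"] = 100.0 * full_can / TI
    return out


# ---------------------------------------------------------------------------
# DCA gradient length


def dca_gradient_length(
    m: pd.DataFrame,
    segments: int = 26,
    rescale_iterations: int = 4,
) -> float:
    """Gradient length of DCA axis 1 in SD units of species turnover.

    Axis 1 of detrended correspondence analysis is the first CA axis
    rescaled nonlinearly (detrending by segments affects higher axes only).
    The axis is divided into segments; within each, the abundance-weighted
    within-plot dispersion of species scores is estimated, and the axis is
    stretched so that this dispersion is one everywhere.  The resulting range
    of plot scores is the gradient length: ~4 SD corresponds to a complete
    species turnover across the gradient.
    """
    Y = m.values.astype(float)
    row_ok = Y.sum(axis=1) > 0
    col_ok = Y.sum(axis=0) > 0
    Y = Y[np.ix_(row_ok, col_ok)]
    if Y.shape[0] < 3 or Y.shape[1] < 3:
        raise ValueError("DCA needs at least 3 plots and 3 species")
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = svd(S, full_matrices=False)
    if sv.size == 0 or sv[0] ** 2 < 1e-10:
        return 0.0  # no between-plot structure (e.g. duplicated plots)
    # species scores as weighted averages of standardised plot scores
    u = sv[0] * Vt[0] / np.sqrt(c)

    for _ in range(rescale_iterations):
        z = (P @ u) / r  # plot scores: weighted means of species scores
        disp = _within_plot_dispersion(Y, u, z)
        u = _piecewise_rescale(u, z, disp, r, segments)
    z = (P @ u) / r
    return float(z.max() - z.min())


def _within_plot_dispersion(Y: np.ndarray, u: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Abundance-weighted variance of species scores within each plot."""
    totals = Y.sum(axis=1)
    sq = Y @ (u**2)
    mean = (Y @ u) / totals
    return sq / totals - mean**2


def _piecewise_rescale(
    u: np.ndarray,
    z: np.ndarray,
    disp: np.ndarray,
    r: np.ndarray,
    segments: int,
) -> np.ndarray:
    """Stretch the axis so local within-plot SD of species scores is 1."""
    lo, hi = z.min(), z.max()
    if hi - lo < 1e-12:
        return u
    edges = np.linspace(lo, hi, segments + 1)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, segments - 1)
    seg_var = np.full(segments, np.nan)
    for k in range(segments):
        mask = idx == k
        if mask.any():
            seg_var[k] = np.average(disp[mask], weights=r[mask])
    # fill empty segments from neighbours, then lightly smooth
    filled = pd.Series(seg_var).interpolate(limit_direction="both").values
    smooth = np.convolve(
        np.pad(filled, 1, mode="edge"), [0.25, 0.5, 0.25], mode="valid"
    )
    sd = np.sqrt(np.maximum(smooth, 1e-12))
    widths = np.diff(edges) / sd
    new_edges = np.concatenate([[0.0], np.cumsum(widths)])
    # map any coordinate (species scores may overshoot plot range) linearly
    def remap(x: np.ndarray) -> np.ndarray:
        x_cl = np.clip(x, lo, hi)
        k = np.clip(np.searchsorted(edges, x_cl, side="right") - 1, 0, segments - 1)
        frac = (x_cl - edges[k]) / (edges[k + 1] - edges[k])
        out = new_edges[k] + frac * widths[k]
        below = x < lo
        above = x > hi
        out[below] = (x[below] - lo) / sd[0]
        out[above] = new_edges[-1] + (x[above] - hi) / sd[-1]
        return out

    return remap(u)
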