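"""Suitability-abundance link across transect units.

Nearest-16-cell suitability mapping, Moran's I with permutation or normal
inference, spatial-eigenvector filters from a connectivity matrix, forward
filter selection, OLS with the HC4m heteroscedasticity-robust covariance,
variance partitioning and bootstrap quantile regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .geodata import RasterGrid

__all__ = [
    "TransectUnits",
    "SEVMFilters",
    "LinkFit",
    "suitability_at_units",
    "morans_i",
    "build_sevm",
    "select_filters",
    "ols_hc4m",
    "variance_partition",
    "quantile_reg",
    "fit_link",
]


@dataclass
class TransectUnits:
    """Per-unit centroids, mean counts and mapped suitability."""

    table: pd.DataFrame  # unit_id, x, y, mean_count, suitability

    def __post_init__(self) -> None:
        req = {"unit_id", "x", "y", "mean_count"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.table["mean_count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.table["unit_id"].duplicated().any():
            raise ValueError("one row per unit required")


@dataclass
class SEVMFilters:
    """Candidate/selected spatial eigenvector filters."""

    weights: np.ndarray  # binary connectivity matrix used
    eigenvalues: np.ndarray  # of the double-centred matrix, descending, positive only
    vectors: np.ndarray  # n x k candidate eigenvectors (columns)
    selected: list[int] = field(default_factory=list)  # column indices into vectors
    residual_moran_i: float | None = None
    residual_moran_p: float | None = None

    @property
    def selected_vectors(self) -> np.ndarray:
        return self.vectors[:, self.selected]


@dataclass
class LinkFit:
    """OLS + HC4m + variance partition + quantile slopes for the link model."""

    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    names: list[str]
    partition: dict[str, float]
    quantiles: pd.DataFrame  # tau, slope, se, p
    filters: SEVMFilters


def suitability_at_units(
    suit: RasterGrid, centroids: pd.DataFrame, k: int = 16
) -> np.ndarray:
    """Mean suitability of the k nearest non-nodata cells to each centroid.

    Nearness is centre-to-centroid Euclidean distance; ties break
    deterministically by (distance, row, col) lexicographic order.
    """
    rows, cols = np.nonzero(~suit.nodata_mask)
    if rows.size < k:
        raise ValueError(f"map has only {rows.size} valid cells, need {k}")
    cx, cy = suit.cell_center(rows, cols)
    cells = np.column_stack([cx, cy])
    pts = centroids[["x", "y"]].to_numpy(dtype=float)
    out = np.empty(len(pts))
    for i, (px, py) in enumerate(pts):
        d = np.hypot(cells[:, 0] - px, cells[:, 1] - py)
        order = np.lexsort((cols, rows, d))[:k]
        out[i] = suit.values[rows[order], cols[order]].mean()
    return out


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "permutation",
) -> tuple[float, float]:
    """Moran's I with permutation (default) or normal-approximation p-value.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values.  The permutation p is two-sided.
    """
    z = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 units")
    if W.shape != (n, n) or (W < 0).any() or np.diag(W).any():
        raise ValueError("weights must be an n x n nonnegative matrix with zero diagonal")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for zero-variance values")
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("weights matrix has no links")

    def stat(zv: np.ndarray) -> float:
        return float((n / s0) * (zv @ W @ zv) / (zv @ zv))

    i_obs = stat(z)
    if method == "normal":
        e_i = -1.0 / (n - 1)
        s1 = 0.5 * ((W + W.T) ** 2).sum()
        s2 = ((W.sum(axis=0) + W.sum(axis=1)) ** 2).sum()
        b2 = n * (z**4).sum() / denom**2
        var = (
            n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
            - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
        zscore = (i_obs - e_i) / np.sqrt(var)
        return i_obs, float(2.0 * stats.norm.sf(abs(zscore)))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = stat(rng.permutation(z))
    ge = int((perm >= i_obs).sum())
    le = int((perm <= i_obs).sum())
    p = 2.0 * min((1 + ge) / (n_perm + 1), (1 + le) / (n_perm + 1))
    return i_obs, float(min(1.0, p))


def _mst_threshold(dists: np.ndarray) -> float:
    """Minimum distance threshold keeping the graph connected (max MST edge)."""
    mst = minimum_spanning_tree(sparse.csr_matrix(dists))
    return float(mst.data.max())


def _gabriel_weights(pts: np.ndarray, dists: np.ndarray) -> np.ndarray:
    n = len(pts)
    W = np.zeros((n, n))
    d2 = dists**2
    for i in range(n):
        for j in range(i + 1, n):
            # edge unless some k lies inside the circle with diameter (i, j)
            if not np.any(np.delete(d2[i] + d2[j], [i, j]) < d2[i, j]):
                W[i, j] = W[j, i] = 1.0
    return W


def build_sevm(
    centroids: pd.DataFrame,
    threshold: float | None = None,
    connectivity: str = "distance",
    eig_tol: float = 1e-10,
) -> SEVMFilters:
    """Candidate spatial eigenvector filters from a binary connectivity matrix.

    ``connectivity='distance'`` links units within a distance threshold
    (default: the smallest threshold keeping the graph connected, i.e. the
    longest minimum-spanning-tree edge); ``'gabriel'`` uses the Gabriel
    graph.  The symmetric binary matrix is double-centred and
    eigen-decomposed; candidates are the eigenvectors with positive
    eigenvalues, in decreasing eigenvalue order.
    """
    pts = centroids[["x", "y"]].to_numpy(dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 centroids")
    dists = cdist(pts, pts)
    if connectivity == "distance":
        if threshold is None:
            threshold = _mst_threshold(dists)
        W = ((dists <= threshold * (1 + 1e-12)) & (dists > 0)).astype(float)
    elif connectivity == "gabriel":
        W = _gabriel_weights(pts, dists)
    else:
        raise ValueError(f"unknown connectivity {connectivity!r}")
    C = np.eye(n) - np.ones((n, n)) / n
    M = C @ W @ C
    M = 0.5 * (M + M.T)
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_tol
    return SEVMFilters(W, evals[keep], evecs[:, keep])


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def select_filters(
    y: np.ndarray,
    X_base: np.ndarray,
    candidates: SEVMFilters,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    moran_method: str = "permutation",
    max_filters: int | None = None,
) -> SEVMFilters:
    """Forward selection of spatial filters on residual Moran's I.

    Repeatedly adds the candidate that most reduces |Moran's I| of the
    regression residuals; stops once the residual Moran's I p-value
    exceeds ``alpha`` (or candidates are exhausted).  At the ``alpha >= 1``
    boundary every I counts as nonsignificant and no filter is selected.
    """
    y = np.asarray(y, dtype=float)
    W = candidates.weights
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    remaining = list(range(candidates.vectors.shape[1]))
    if max_filters is None:
        max_filters = candidates.vectors.shape[1]

    def current_X() -> np.ndarray:
        return np.column_stack([X_base, candidates.vectors[:, selected]]) if selected else X_base

    i_res, p_res = morans_i(_ols_residuals(y, current_X()), W, n_perm=n_perm,
                            seed=rng.integers(2**31), method=moran_method)
    while alpha < 1.0 and p_res <= alpha and remaining and len(selected) < max_filters:
        best_j, best_abs = None, abs(i_res)
        for j in remaining:
            Xj = np.column_stack([current_X(), candidates.vectors[:, j]])
            ij = _moran_stat(_ols_residuals(y, Xj), W)
            if abs(ij) < best_abs - 1e-15:
                best_j, best_abs = j, abs(ij)
        if best_j is None:
            break  # no candidate reduces |I| further
        selected.append(best_j)
        remaining.remove(best_j)
        i_res, p_res = morans_i(_ols_residuals(y, current_X()), W, n_perm=n_perm,
                                seed=rng.integers(2**31), method=moran_method)
    return SEVMFilters(W, candidates.eigenvalues, candidates.vectors,
                       selected, i_res, p_res)


def _moran_stat(z: np.ndarray, W: np.ndarray) -> float:
    z = z - z.mean()
    return float((z.size / W.sum()) * (z @ W @ z) / (z @ z))


def ols_hc4m(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """OLS with the HC4m heteroscedasticity-consistent covariance.

    cov = (X'X)^-1 X' diag(e_i^2 / (1-h_i)^d_i) X (X'X)^-1 with
    d_i = min(1, n h_i / p) + min(1.5, n h_i / p).  Returns
    (coef, robust se, two-sided t p-values on n-p df, R^2).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (i, j) for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {p}); "
                         f"near-collinear column pairs: {pairs}")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    e = y - X @ beta
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    d = np.minimum(1.0, n * h / p) + np.minimum(1.5, n * h / p)
    omega = e**2 / (1.0 - h) ** d
    cov = XtX_inv @ (X.T * omega) @ X @ XtX_inv
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    ss_res = float(e @ e)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return beta, se, pvals, r2


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    e = _ols_residuals(y, X)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(e @ e) / ss_tot if ss_tot > 0 else 0.0


def variance_partition(
    y: np.ndarray, suitability: np.ndarray, filters: np.ndarray
) -> dict[str, float]:
    """Partition of R^2 between suitability and spatial filters.

    unique_suitability = R2_full - R2_filters; unique_spatial = R2_full -
    R2_suit; shared = R2_suit + R2_filters - R2_full.  Components sum to
    the full-model R^2.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(suitability, dtype=float).reshape(-1, 1)
    F = np.asarray(filters, dtype=float)
    if F.ndim == 1:
        F = F.reshape(-1, 1)
    ones = np.ones((y.size, 1))
    r2_full = _r_squared(y, np.hstack([ones, s, F])) if F.size else _r_squared(y, np.hstack([ones, s]))
    r2_suit = _r_squared(y, np.hstack([ones, s]))
    r2_filt = _r_squared(y, np.hstack([ones, F])) if F.size else 0.0
    return {
        "unique_suitability": r2_full - r2_filt,
        "unique_spatial": r2_full - r2_suit,
        "shared": r2_suit + r2_filt - r2_full,
        "total": r2_full,
    }


def _solve_quantile_lp(y: np.ndarray, X: np.ndarray, tau: float) -> np.ndarray:
    """Exact check-loss minimization as a linear program (HiGHS)."""
    n, p = X.shape
    # variables: [b+ (p), b- (p), u+ (n), u- (n)]
    c = np.concatenate([np.zeros(2 * p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = sparse.hstack([
        sparse.csr_matrix(X), -sparse.csr_matrix(X),
        sparse.eye(n), -sparse.eye(n),
    ], format="csr")
    bounds = [(0, None)] * (2 * p + 2 * n)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:p] - res.x[p:2 * p]


def check_loss(y: np.ndarray, X: np.ndarray, beta: np.ndarray, tau: float) -> float:
    u = np.asarray(y) - np.asarray(X) @ np.asarray(beta)
    return float(np.sum(u * (tau - (u < 0))))


def quantile_reg(
    y: np.ndarray,
    X: np.ndarray,
    tau: float,
    n_boot: int = 999,
    seed: int | None = None,
) -> dict[str, np.ndarray | float]:
    """Quantile regression with xy-pair bootstrap standard errors.

    The fit minimizes the check loss exactly by linear programming.  The
    bootstrap se is the sd of slopes over resampled (x, y) pairs; the
    two-sided p-value compares |b/se| with the studentized bootstrap
    distribution |b* - b| / se (a symmetric percentile-t with the pooled
    bootstrap sd as the denominator).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns")
    beta = _solve_quantile_lp(y, X, tau)
    se = np.full(p, np.nan)
    pvals = np.full(p, np.nan)
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, p))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                boots[b] = _solve_quantile_lp(y[idx], X[idx], tau)
            except RuntimeError:
                boots[b] = np.nan
        se = np.nanstd(boots, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_obs = np.abs(beta) / se
            t_boot = np.abs(boots - beta) / se
        pvals = (1.0 + np.nansum(t_boot >= t_obs, axis=0)) / (n_boot + 1.0)
    return {"coef": beta, "se": se, "p": pvals, "tau": tau}


def fit_link(
    units: TransectUnits,
    alpha: float = 0.05,
    taus: tuple[float, ...] = (0.1, 0.5, 0.9),
    n_boot: int = 999,
    n_perm: int = 999,
    seed: int | None = None,
    connectivity: str = "distance",
    moran_method: str = "permutation",
) -> LinkFit:
    """Full abundance-suitability link: filters, HC4m OLS, partition, quantiles."""
    t = units.table
    if "suitability" not in t.columns:
        raise ValueError("units table needs a 'suitability' column (see suitability_at_units)")
    y = t["mean_count"].to_numpy(dtype=float)
    s = t["suitability"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    cands = build_sevm(t, connectivity=connectivity)
    ones = np.ones((len(t), 1))
    X_base = np.hstack([ones, s.reshape(-1, 1)])
    filt = select_filters(y, X_base, cands, alpha=alpha, n_perm=n_perm,
                          seed=rng.integers(2**31), moran_method=moran_method)
    F = filt.selected_vectors
    X_full = np.hstack([X_base, F])
    names = ["intercept", "suitability"] + [f"filter_{j}" for j in filt.selected]

    coef, se, pvals, r2 = ols_hc4m(y, X_full)
    part = variance_partition(y, s, F) if F.size else {
        "unique_suitability": r2, "unique_spatial": 0.0, "shared": 0.0, "total": r2,
    }

    q_rows = []
    for tau in taus:
        q = quantile_reg(y, X_full, tau, n_boot=n_boot, seed=rng.integers(2**31))
        q_rows.append({"tau": tau, "slope": q["coef"][1], "se": q["se"][1], "p": q["p"][1]})
    quantiles = pd.DataFrame(q_rows)

    return LinkFit(coef, se, pvals, r2, names, part, quantiles, filt)
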