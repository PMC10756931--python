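"""Spatial statistics for county-level drinking-water exposure regression.

Implements the inferential chain used for environmental-justice analyses of
community-water-system (CWS) contaminant concentrations aggregated to
counties: queen-contiguity spatial weights, global Moran's I with permutation
inference, Lagrange-multiplier (LM) diagnostics discriminating spatial-lag
from spatial-error dependence, and maximum-likelihood estimation of the
spatial error model

    y = X beta + u,      u = lambda W u + eps,      eps ~ N(0, sigma2 I),

where ``y`` is log county fluoride concentration and ``W`` the
row-standardized contiguity matrix.  Associations are reported as geometric
mean ratios, GMR = exp(beta), per unit of the scaled covariate (racial/ethnic
composition entered as percent/10, so one unit = 10 percentage points).

The log-likelihood uses the eigenvalue decomposition of ``W`` for the
Jacobian term ln|I - lambda W| = sum_i ln(1 - lambda w_i); because ``W`` is
row-standardized from a symmetric binary adjacency, its spectrum is real and
is obtained from the similar symmetric matrix D^{-1/2} A D^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LMDiagnostics",
    "OLSFit",
    "SEMFit",
    "build_queen_weights",
    "morans_i",
    "ols_fit",
    "lm_diagnostics",
    "fit_spatial_error",
    "gmr_per_10pct",
    "percent_change",
    "run_models",
    "COMPOSITION_GROUPS",
]

# covariate column -> resident-count column, for the four groups modeled
COMPOSITION_GROUPS: dict[str, tuple[str, str]] = {
    "hispanic": ("pct_hispanic", "n_hispanic"),
    "nh_black": ("pct_nh_black", "n_nh_black"),
    "aian": ("pct_aian", "n_aian"),
    "nh_white": ("pct_nh_white", "n_nh_white"),
}


@dataclass
class SpatialWeights:
    """Queen-contiguity weights: binary adjacency plus row-standardized W."""

    ids: list
    adjacency: np.ndarray          # symmetric binary, zero diagonal
    w: np.ndarray                  # row-standardized (island rows all zero)
    islands: list = field(default_factory=list)
    _eigvals: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    def neighbor_lists(self) -> dict:
        idx = np.asarray(self.adjacency, dtype=bool)
        return {
            self.ids[i]: [self.ids[j] for j in np.flatnonzero(idx[i])]
            for i in range(self.n)
        }

    def eigenvalues(self) -> np.ndarray:
        """Real spectrum of W (islands excluded), cached after first use."""
        if self._eigvals is None:
            keep = [i for i in range(self.n) if self.ids[i] not in set(self.islands)]
            a = self.adjacency[np.ix_(keep, keep)]
            deg = a.sum(axis=1)
            d = 1.0 / np.sqrt(deg)
            sym = a * d[:, None] * d[None, :]
            self._eigvals = np.linalg.eigvalsh(sym)
        return self._eigvals

    def subset(self, ids: Sequence) -> "SpatialWeights":
        """Weights restricted to ``ids`` (order preserved), re-standardized."""
        pos = {cid: i for i, cid in enumerate(self.ids)}
        keep = [pos[c] for c in ids]
        a = self.adjacency[np.ix_(keep, keep)]
        return _standardize(list(ids), a)


def _standardize(ids: list, adjacency: np.ndarray) -> SpatialWeights:
    deg = adjacency.sum(axis=1)
    islands = [ids[i] for i in np.flatnonzero(deg == 0)]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(deg[:, None] > 0, adjacency / np.where(deg == 0, 1, deg)[:, None], 0.0)
    return SpatialWeights(ids=list(ids), adjacency=adjacency.astype(float), w=w, islands=islands)


def build_queen_weights(edges: Iterable[tuple], ids: Sequence) -> SpatialWeights:
    """Build symmetric binary adjacency and row-standardized weights.

    Parameters
    ----------
    edges : iterable of (id_a, id_b) pairs (undirected; one orientation per
        pair suffices, duplicates are idempotent).
    ids : full roster of county ids; counties with no edge become islands.
    """
    ids = list(ids)
    pos = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-edge on county {u!r} is not a valid contiguity")
        if u not in pos or v not in pos:
            raise ValueError(f"edge ({u!r}, {v!r}) references unknown county id")
        i, j = pos[u], pos[v]
        a[i, j] = a[j, i] = 1.0
    return _standardize(ids, a)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    i: float
    expected: float
    var_norm: float
    z_norm: float
    p_norm: float
    p_perm: float
    n_permutations: int


def morans_i(
    values: Sequence[float],
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MoranResult:
    """Global Moran's I with randomization-variance and permutation inference.

    I = (n / S0) * (z' A z) / (z' z) with z the demeaned values and A the
    (row-standardized) weight matrix; the null expectation is -1/(n-1).  The
    permutation p-value relabels values over counties; the default alternative
    is 'greater' (positive autocorrelation, the side relevant for clustering).
    """
    x = np.asarray(values, dtype=float)
    if weights.islands:
        raise ValueError(
            f"weights contain {len(weights.islands)} island(s); exclude them first"
        )
    n = weights.n
    if x.shape[0] != n:
        raise ValueError("length of values does not match weights")
    if n < 3:
        raise ValueError("Moran's I requires at least 3 observations")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("values are constant; Moran's I is undefined")
    w = weights.w
    s0 = float(w.sum())
    i_obs = (n / s0) * float(z @ w @ z) / denom
    expected = -1.0 / (n - 1)

    # randomization (non-normality-corrected) variance, standard closed form
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    rows = w.sum(axis=1)
    cols = w.sum(axis=0)
    s2 = float(((rows + cols) ** 2).sum())
    b2 = n * float((z ** 4).sum()) / denom ** 2
    num = n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2) - b2 * (
        (n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0 ** 2
    var_norm = num / den - expected ** 2
    if var_norm > 0:
        z_norm = (i_obs - expected) / np.sqrt(var_norm)
        p_norm = 2.0 * stats.norm.sf(abs(z_norm))
    else:  # degenerate topology (e.g. complete graph): I is constant
        var_norm, z_norm, p_norm = 0.0, np.nan, np.nan

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(z, (n_permutations, 1)), axis=1)
    i_perm = (n / s0) * np.einsum("ij,ij->i", perms @ w, perms) / denom
    if alternative == "greater":
        extreme = int((i_perm >= i_obs).sum())
    elif alternative == "less":
        extreme = int((i_perm <= i_obs).sum())
    elif alternative == "two-sided":
        extreme = int((np.abs(i_perm - expected) >= abs(i_obs - expected)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p_perm = (1 + extreme) / (n_permutations + 1)
    return MoranResult(i_obs, expected, var_norm, float(z_norm), float(p_norm),
                       float(p_perm), n_permutations)


# ---------------------------------------------------------------------------
# OLS baseline and LM diagnostics
# ---------------------------------------------------------------------------

@dataclass
class OLSFit:
    beta: np.ndarray
    resid: np.ndarray
    sigma2: float            # ML variant e'e/n, used by the LM statistics
    names: list


def ols_fit(y: Sequence[float], x: np.ndarray, names: Sequence[str] | None = None) -> OLSFit:
    """Ordinary least squares with an explicit rank check."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    names = list(names) if names is not None else [f"x{i}" for i in range(x.shape[1])]
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return OLSFit(beta=beta, resid=resid, sigma2=float(resid @ resid) / len(y), names=names)


@dataclass
class LMDiagnostics:
    lm_error: float
    p_error: float
    lm_lag: float
    p_lag: float


def lm_diagnostics(y: Sequence[float], x: np.ndarray, weights: SpatialWeights) -> LMDiagnostics:
    """Anselin's (non-robust) LM tests for spatial error and spatial lag.

    LM-error = [e'We / (e'e/n)]^2 / T with T = tr(W'W + WW); LM-lag uses the
    spatially lagged fitted values projected off the regressors.  Both refer
    to chi-square with 1 degree of freedom.
    """
    if weights.islands:
        raise ValueError("islands present; exclude them before LM diagnostics")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = weights.w
    n = len(y)
    fit = ols_fit(y, x)
    e = fit.resid
    s2 = fit.sigma2
    t = float(np.trace(w.T @ w + w @ w))
    lm_err = (float(e @ w @ e) / s2) ** 2 / t

    wy = w @ y
    num = (float(e @ wy) / s2) ** 2
    wxb = w @ (x @ fit.beta)
    xtx_inv = np.linalg.inv(x.T @ x)
    m_wxb = wxb - x @ (xtx_inv @ (x.T @ wxb))
    d = float(wxb @ m_wxb) / s2 + t
    lm_lag = num / d
    return LMDiagnostics(
        lm_error=lm_err,
        p_error=float(stats.chi2.sf(lm_err, 1)),
        lm_lag=lm_lag,
        p_lag=float(stats.chi2.sf(lm_lag, 1)),
    )


# ---------------------------------------------------------------------------
# Spatial error model (maximum likelihood)
# ---------------------------------------------------------------------------

@dataclass
class SEMFit:
    names: list
    beta: np.ndarray
    se_beta: np.ndarray
    lam: float
    se_lambda: float
    sigma2: float
    loglik: float
    loglik_lambda0: float
    n: int
    converged: bool
    warnings: list = field(default_factory=list)
    scaling: dict = field(default_factory=dict)

    def coef(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se_beta[i])


def _sem_loglik_full(beta, lam, sigma2, y, x, wy, wx, eigvals):
    n = len(y)
    e = (y - lam * wy) - (x - lam * wx) @ beta
    logdet = float(np.log(1.0 - lam * eigvals).sum())
    return (
        -0.5 * n * np.log(2 * np.pi * sigma2)
        + logdet
        - float(e @ e) / (2 * sigma2)
    )


def fit_spatial_error(
    y: Sequence[float],
    x: np.ndarray,
    weights: SpatialWeights,
    names: Sequence[str] | None = None,
    lambda_fixed: float | None = None,
) -> SEMFit:
    """Maximum-likelihood spatial error model on a row-standardized W.

    The spatial parameter is profiled out: for given lambda the filtered
    regression (I - lambda W)y on (I - lambda W)X is solved by least squares,
    and lambda is found by bounded scalar optimization of the concentrated
    log-likelihood over the eigenvalue-bounded interval (1/w_min, 1/w_max).
    Standard errors come from the observed information (central-difference
    Hessian of the full log-likelihood in (beta, lambda, sigma2)).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if weights.islands:
        raise ValueError("islands present; exclude them before fitting")
    if len(y) != weights.n:
        raise ValueError("length of y does not match weights")
    names = list(names) if names is not None else [f"x{i}" for i in range(x.shape[1])]
    ols_fit(y, x, names)  # rank check with named collinear columns
    n = len(y)
    w = weights.w
    wy = w @ y
    wx = w @ x
    eig = weights.eigenvalues()
    lo = 1.0 / eig.min() + 1e-8 if eig.min() < 0 else -0.999999
    hi = 1.0 / eig.max() - 1e-8 if eig.max() > 0 else 0.999999

    def concentrated(lam: float) -> tuple[float, np.ndarray, float]:
        ys = y - lam * wy
        xs = x - lam * wx
        beta, *_ = np.linalg.lstsq(xs, ys, rcond=None)
        e = ys - xs @ beta
        sigma2 = float(e @ e) / n
        logdet = float(np.log(1.0 - lam * eig).sum())
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
        return ll, beta, sigma2

    warnings_list: list[str] = []
    if lambda_fixed is not None:
        lam_hat = float(lambda_fixed)
        converged = True
    else:
        res = optimize.minimize_scalar(
            lambda lam: -concentrated(lam)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        converged = bool(res.success)
        if min(lam_hat - lo, hi - lam_hat) < 1e-5:
            warnings_list.append("lambda estimate at interval boundary")
            converged = False

    ll_hat, beta_hat, sigma2_hat = concentrated(lam_hat)
    ll_zero = concentrated(0.0)[0]

    # observed information via central differences on the full likelihood
    theta = np.concatenate([beta_hat, [lam_hat, sigma2_hat]])
    p = len(theta)

    def f(th):
        return _sem_loglik_full(th[:-2], th[-2], th[-1], y, x, wy, wx, eig)

    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            hess[i, j] = hess[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * h[i] * h[j])
    se_beta = np.full(len(beta_hat), np.nan)
    se_lambda = np.nan
    try:
        cov = np.linalg.inv(-hess)
        diag = np.diag(cov)
        if np.all(diag[: len(beta_hat)] > 0) and diag[len(beta_hat)] > 0:
            se_beta = np.sqrt(diag[: len(beta_hat)])
            se_lambda = float(np.sqrt(diag[len(beta_hat)]))
    except np.linalg.LinAlgError:
        pass
    if np.any(~np.isfinite(se_beta)) or not np.isfinite(se_lambda):
        # fall back to the filtered-GLS covariance for beta
        xs = x - lam_hat * wx
        cov_b = sigma2_hat * np.linalg.inv(xs.T @ xs)
        se_beta = np.sqrt(np.diag(cov_b))
        if not np.isfinite(se_lambda):
            se_lambda = np.nan
        warnings_list.append("Hessian not invertible; beta SEs from filtered GLS")

    return SEMFit(
        names=names,
        beta=beta_hat,
        se_beta=se_beta,
        lam=lam_hat,
        se_lambda=se_lambda,
        sigma2=sigma2_hat,
        loglik=ll_hat,
        loglik_lambda0=ll_zero,
        n=n,
        converged=converged,
        warnings=warnings_list,
    )


# ---------------------------------------------------------------------------
# Effect reporting
# ---------------------------------------------------------------------------

def gmr_per_10pct(fit: SEMFit, covariate: str, z: float = 1.959963984540054) -> dict:
    """Geometric mean ratio exp(beta) with a Wald 95% CI for one covariate."""
    if covariate not in fit.names:
        raise ValueError(f"covariate {covariate!r} not in fitted model {fit.names}")
    b, se = fit.coef(covariate)
    return {
        "beta": b,
        "se": se,
        "gmr": float(np.exp(b)),
        "ci_low": float(np.exp(b - z * se)),
        "ci_high": float(np.exp(b + z * se)),
    }


def percent_change(gmr: float, ci: tuple[float, float] | None = None):
    """Percent difference 100*(GMR - 1), rounded half-even to integer percent.

    Mirrors the reporting convention for log-outcome regressions: a GMR of
    1.25 is a +25% change in the geometric mean per unit of the covariate.
    """
    if gmr <= 0:
        raise ValueError("GMR must be positive")
    pct = int(round(100.0 * (gmr - 1.0)))
    if ci is None:
        return pct
    lo, hi = ci
    return pct, (int(round(100.0 * (lo - 1.0))), int(round(100.0 * (hi - 1.0))))


# ---------------------------------------------------------------------------
# Per-group model battery
# ---------------------------------------------------------------------------

def _model_design(df: pd.DataFrame, comp_col: str, scale: float, model: int):
    cols = {
        "intercept": np.ones(len(df)),
        "composition": df[comp_col].to_numpy() / scale,
        "density": df["density"].to_numpy() / 1000.0,
        "pct_groundwater": df["pct_groundwater"].to_numpy() / 100.0,
        "svi": df["svi"].to_numpy(),
    }
    if model == 2:
        cols["pct_fluoridated"] = df["pct_fluoridated"].to_numpy() / 100.0
    names = list(cols)
    return np.column_stack(list(cols.values())), names


def run_models(
    counties: pd.DataFrame,
    weights: SpatialWeights,
    outcome: str = "weighted_mean",
    scale: float = 10.0,
    models: Sequence[int] = (1, 2),
    min_count: int = 100,
    groups: Mapping[str, tuple[str, str]] | None = None,
    small_n: int = 30,
) -> tuple[pd.DataFrame, dict]:
    """Fit spatial error models per racial/ethnic group and model spec.

    ``counties`` must carry the outcome column, model covariates
    (density, pct_groundwater, svi, pct_fluoridated), composition percents
    and resident counts.  Each group's analysis set keeps counties with at
    least ``min_count`` residents of that group; islands created by the
    restriction are dropped (iteratively) with a warning recorded.
    """
    groups = dict(groups) if groups is not None else COMPOSITION_GROUPS
    rows = []
    fits: dict[tuple[str, int], SEMFit] = {}
    for gname, (comp_col, count_col) in groups.items():
        sub = counties[
            (counties[count_col] >= min_count)
            & np.isfinite(counties[outcome])
            & (counties[outcome] > 0)
        ].copy()
        # iteratively drop islands created by the restriction
        n_islands = 0
        sw = weights.subset(sub["county_id"].tolist())
        while sw.islands:
            n_islands += len(sw.islands)
            sub = sub[~sub["county_id"].isin(sw.islands)]
            sw = weights.subset(sub["county_id"].tolist())
        y = np.log(sub[outcome].to_numpy())
        for model in models:
            x, names = _model_design(sub, comp_col, scale, model)
            fit = fit_spatial_error(y, x, sw, names)
            if len(sub) < small_n:
                fit.warnings.append(
                    f"only {len(sub)} counties in stratum; estimates unstable"
                )
            fit.scaling = {"composition_scale": scale, "outcome": outcome}
            fits[(gname, model)] = fit
            g = gmr_per_10pct(fit, "composition")
            pct, (pct_lo, pct_hi) = percent_change(g["gmr"], (g["ci_low"], g["ci_high"]))
            rows.append(
                {
                    "group": gname,
                    "model": model,
                    "n": len(sub),
                    "n_islands_dropped": n_islands,
                    "gmr": g["gmr"],
                    "ci_low": g["ci_low"],
                    "ci_high": g["ci_high"],
                    "pct_change": pct,
                    "pct_change_low": pct_lo,
                    "pct_change_high": pct_hi,
                    "lambda": fit.lam,
                    "se_lambda": fit.se_lambda,
                    "loglik": fit.loglik,
                    "warnings": "; ".join(fit.warnings),
                }
            )
    return pd.DataFrame(rows), fits
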