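"""Spatial+ correction for spatial confounding in step-selection models.

Spatial confounding arises when the covariate of interest (here the
partner's occurrence distribution or the distance to it) is itself a smooth
function of space, so its effect cannot be separated from unmeasured
spatially structured drivers of movement.  Spatial+ (Dupont et al.)
de-biases the estimate in two stages: (1) regress the covariate on a
penalised thin-plate spline of the coordinates; (2) use the residuals of
that regression — plus the spline fit itself — as covariates in the
outcome model (the SSF).

The smoother is a low-rank thin-plate regression spline: radial basis
eta(r) = r^2 log r centred at knots plus unpenalised {1, x, y}, with the
bending-energy penalty on the radial part and the knot-polynomial
constraint absorbed by a null-space reparameterisation.  The smoothing
parameter is chosen by GCV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "SpatialPlusConfig",
    "SpatialFit",
    "tprs_basis",
    "fit_gam_spatial",
    "apply_spatial_plus",
    "fit_spatial_plus_ssf",
    "spatial_basis",
]


@dataclass(frozen=True)
class SpatialPlusConfig:
    n_knots: int = 100
    smoothing_selection: str = "gcv"
    fixed_lambda: float | None = None
    knot_placement: str = "kmeans"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_knots < 10:
            raise ValueError("n_knots must be >= 10")
        if self.smoothing_selection not in ("gcv", "fixed"):
            raise ValueError("smoothing_selection must be 'gcv' or 'fixed'")
        if self.smoothing_selection == "fixed" and self.fixed_lambda is None:
            raise ValueError("fixed smoothing requires fixed_lambda")
        if self.knot_placement not in ("kmeans", "random_subset"):
            raise ValueError("knot_placement must be 'kmeans' or 'random_subset'")


@dataclass(frozen=True)
class SpatialFit:
    fitted_values: np.ndarray
    residuals: np.ndarray
    effective_df: float
    lam: float
    knots: np.ndarray


def _eta(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis r^2 log r, with eta(0) = 0."""
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _place_knots(coords: np.ndarray, n_knots: int, method: str, rng) -> np.ndarray:
    uniq = np.unique(coords, axis=0)
    if len(uniq) < n_knots:
        warnings.warn(
            f"only {len(uniq)} unique coordinate points; reducing knots from {n_knots}",
            stacklevel=3,
        )
        n_knots = len(uniq)
    if method == "kmeans":
        km = KMeans(n_clusters=n_knots, n_init=1, max_iter=30, random_state=int(rng.integers(2**31)))
        km.fit(coords)
        knots = km.cluster_centers_
    else:
        idx = rng.choice(len(uniq), size=n_knots, replace=False)
        knots = uniq[idx]
    # collapse accidental duplicate knots
    knots = np.unique(np.round(knots, 10), axis=0)
    return knots


def tprs_basis(coords: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and penalty for a thin-plate regression spline.

    Returns ``(X, S)`` where ``X = [1, x, y, R @ Z]`` with ``R`` the radial
    basis at the knots and ``Z`` the null space of the knot-polynomial
    constraint, and ``S`` the (positive semi-definite) bending-energy
    penalty aligned with the columns of ``X`` (zero block on the
    unpenalised polynomial part).  A purely linear surface has zero
    penalty.
    """
    coords = np.asarray(coords, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    if K < 4:
        raise ValueError("need at least 4 knots")
    P = np.column_stack([np.ones(len(coords)), coords])
    R = _eta(np.hypot(coords[:, None, 0] - knots[None, :, 0], coords[:, None, 1] - knots[None, :, 1]))
    E = _eta(np.hypot(knots[:, None, 0] - knots[None, :, 0], knots[:, None, 1] - knots[None, :, 1]))
    T = np.column_stack([np.ones(K), knots])  # constraint T' c = 0
    # null-space basis of T'
    q, _ = np.linalg.qr(T, mode="complete")
    Z = q[:, 3:]
    Xr = R @ Z
    Sr = Z.T @ E @ Z
    Sr = (Sr + Sr.T) / 2.0
    # guard against roundoff: the bending energy is PSD on the constraint space
    w, V = np.linalg.eigh(Sr)
    Sr = (V * np.clip(w, 0.0, None)) @ V.T
    X = np.column_stack([P, Xr])
    S = np.zeros((X.shape[1], X.shape[1]))
    S[3:, 3:] = Sr
    return X, S


def _penalized_fit(X, S, y, lam):
    A = X.T @ X
    B = A + lam * S
    # tiny ridge on the radial block only (keeps exact polynomial surfaces exact)
    ridge = 1e-9 * max(1.0, np.trace(A) / len(A))
    B[np.diag_indices_from(B)[0][3:], np.diag_indices_from(B)[1][3:]] += ridge
    Xty = X.T @ y
    try:
        beta = np.linalg.solve(B, Xty)
        edf = float(np.trace(np.linalg.solve(B, A)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular normal equations in spatial smoother: {exc}") from exc
    return beta, edf


def fit_gam_spatial(
    covariate_values: np.ndarray,
    coords: np.ndarray,
    config: SpatialPlusConfig | None = None,
    rng=None,
) -> SpatialFit:
    """Penalised thin-plate regression of a covariate on coordinates.

    Coordinates are rescaled to the unit square for conditioning; the GCV
    criterion ``n * RSS / (n - edf)^2`` selects the smoothing parameter on
    a log grid unless a fixed lambda is configured.  ``fitted + residuals``
    reproduces the observed covariate exactly.
    """
    cfg = config or SpatialPlusConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    y = np.asarray(covariate_values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("covariate values must be finite")
    if len(y) != len(coords):
        raise ValueError("covariate values and coordinates must pair 1:1")

    lo = coords.min(axis=0)
    span = max(float(np.max(coords.max(axis=0) - lo)), 1e-12)
    scaled = (coords - lo) / span

    knots = _place_knots(scaled, cfg.n_knots, cfg.knot_placement, rng)
    X, S = tprs_basis(scaled, knots)

    if cfg.smoothing_selection == "fixed":
        lam = float(cfg.fixed_lambda)
        beta, edf = _penalized_fit(X, S, y, lam)
    else:
        n = len(y)
        best = None
        for lam in np.logspace(-8, 4, 13):
            beta, edf = _penalized_fit(X, S, y, lam)
            rss = float(np.sum((y - X @ beta) ** 2))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam, beta, edf)
        _, lam, beta, edf = best

    fitted = X @ beta
    return SpatialFit(
        fitted_values=fitted,
        residuals=y - fitted,
        effective_df=edf,
        lam=lam,
        knots=knots * span + lo,
    )


def spatial_basis(strata: pd.DataFrame, config: SpatialPlusConfig | None = None, rng=None):
    """Precompute the thin-plate design/penalty for a strata table.

    The basis depends only on the candidate coordinates, so it can be
    shared between Spatial+ fits of different covariates on the same
    strata.  Returns ``(X, S)`` as from :func:`tprs_basis`, on coordinates
    rescaled to the unit box.
    """
    cfg = config or SpatialPlusConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    coords = strata[["x", "y"]].to_numpy(dtype=float)
    lo = coords.min(axis=0)
    span = max(float(np.max(coords.max(axis=0) - lo)), 1e-12)
    scaled = (coords - lo) / span
    knots = _place_knots(scaled, cfg.n_knots, cfg.knot_placement, rng)
    return tprs_basis(scaled, knots)


def apply_spatial_plus(
    strata: pd.DataFrame,
    covariate_name: str,
    config: SpatialPlusConfig | None = None,
    rng=None,
    return_basis: bool = False,
    basis=None,
):
    """Residualise a covariate against space across all candidates.

    The spatial smoother is fitted over *all* candidate endpoints (used and
    available pooled) because the conditional-logit likelihood needs
    corrected covariates at every candidate.  Adds columns
    ``<covariate>_residual`` and ``spline_fit``; their sum reproduces the
    original covariate per candidate.

    With ``return_basis=True`` also returns the thin-plate design matrix
    evaluated at the candidate coordinates (without the intercept column),
    so the outcome model can carry its own free spatial smooth — the
    Spatial+ second stage pairs the residualised covariate with a spline of
    the coordinates re-estimated inside the SSF.
    """
    if covariate_name not in strata.columns:
        raise KeyError(f"covariate {covariate_name!r} not present on strata")
    cfg = config or SpatialPlusConfig()
    X, S = basis if basis is not None else spatial_basis(strata, cfg, rng)
    y = strata[covariate_name].to_numpy(dtype=float)
    if cfg.smoothing_selection == "fixed":
        lam = float(cfg.fixed_lambda)
        beta, _ = _penalized_fit(X, S, y, lam)
    else:
        n = len(y)
        best = None
        for lam in np.logspace(-8, 4, 13):
            beta, edf = _penalized_fit(X, S, y, lam)
            rss = float(np.sum((y - X @ beta) ** 2))
            gcv = n * rss / max(n - edf, 1e-8) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, beta)
        _, beta = best
    fitted = X @ beta
    out = strata.copy()
    out[f"{covariate_name}_residual"] = y - fitted
    out["spline_fit"] = fitted
    if return_basis:
        out.attrs["_spatial_penalty"] = S[1:, 1:]
        return out, X[:, 1:]  # drop intercept (cancels within strata)
    return out


def fit_spatial_plus_ssf(
    strata: pd.DataFrame,
    covariate_name: str,
    config: SpatialPlusConfig | None = None,
    rng=None,
    standardize: bool = True,
    lambda_grid=(1e-6, 1e-2, 1e2),
    robust_block_length: int | None = None,
    basis=None,
):
    """Spatial+ second stage: conditional logit of the residualised
    covariate alongside a penalised thin-plate smooth of the coordinates.

    The outcome model re-estimates its own spatial field, so any spatially
    structured selection is absorbed by the smooth and the residualised
    covariate only competes for non-spatial signal.  The smooth carries the
    bending-energy penalty; its weight is chosen by conditional AIC over
    ``lambda_grid``.  Returns the :class:`~dyadmove.ssf.SSFFit`; the
    interaction estimate is the ``<covariate>_residual`` coefficient.
    """
    from .ssf import fit_clogit

    corrected, names, S_big = _corrected_with_basis(strata, covariate_name, config, rng, basis)
    res_name = f"{covariate_name}_residual"
    if standardize:
        col = corrected[res_name].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            corrected[res_name] = (col - col.mean()) / sd
    covs = [res_name] + names

    best = None
    warm = None
    for lam in lambda_grid:
        fit = fit_clogit(
            corrected, covs, penalty=lam * S_big, robust_block_length=robust_block_length, beta0=warm
        )
        warm = np.array([fit.coefficients[c] for c in covs])
        if fit.model_covariance is None:
            continue
        # unpenalised log-likelihood at the penalised optimum
        beta = np.array([fit.coefficients[c] for c in covs])
        ll = fit.log_likelihood + 0.5 * lam * float(beta @ S_big @ beta)
        edf = len(covs) - lam * float(np.trace(fit.model_covariance @ S_big))
        caic = -2.0 * ll + 2.0 * edf
        if best is None or caic < best[0]:
            best = (caic, fit)
    if best is None:  # all penalised fits failed; fall back to unpenalised
        return fit_clogit(corrected, covs)
    return best[1]


def _corrected_with_basis(strata, covariate_name, config, rng, basis=None):
    """Shared stage-1 machinery: residualise and build the outcome smooth.

    Returns ``(corrected_frame, basis_column_names, penalty)`` where the
    penalty is aligned with ``[residual] + basis`` (zero on the residual and
    the linear terms, bending energy on the radial part, transformed for
    the standardised basis columns).
    """
    cfg = config or SpatialPlusConfig()
    corrected, basis = apply_spatial_plus(strata, covariate_name, cfg, rng, return_basis=True, basis=basis)
    S_basis = corrected.attrs.pop("_spatial_penalty")
    keep = basis.std(axis=0) > 0
    basis = basis[:, keep]
    S_basis = S_basis[np.ix_(keep, keep)]
    scales = basis.std(axis=0)
    basis = (basis - basis.mean(axis=0)) / scales
    # column scaled by s => coefficient scaled by 1/s => penalty by 1/s^2
    Dinv = np.diag(1.0 / scales)
    S_basis = Dinv @ S_basis @ Dinv
    names = [f"_sp{i}" for i in range(basis.shape[1])]
    corrected = pd.concat(
        [corrected, pd.DataFrame(basis, columns=names, index=corrected.index)], axis=1
    )
    k = 1 + basis.shape[1]
    S_big = np.zeros((k, k))
    S_big[1:, 1:] = (S_basis + S_basis.T) / 2.0
    return corrected, names, S_big
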