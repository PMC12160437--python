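"""Step-selection-function machinery.

An SSF compares each observed ("used") movement step of a focal individual
against a set of "available" steps drawn from its fitted movement kernel,
in terms of covariates evaluated at the step endpoints.  Selection
coefficients are estimated by conditional logistic regression: one stratum
per observed step, one used candidate among ``n_available + 1``.

Strata are held in a tidy :class:`pandas.DataFrame` with one row per
candidate and columns ``stratum_id, case, t_end, x, y, step_length,
turning_angle`` plus one column per covariate (``case`` is 1 for the used
step).  Interaction covariates:

* ``od`` — occurrence distribution of the partner (Gaussian KDE of its
  fixes rasterised on the landscape grid), evaluated at the endpoint;
* ``dist`` — distance from the endpoint to the partner's simultaneous fix
  (at the step's target time), negated by default so that a positive
  coefficient means attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .landscapes import LandscapeGrid
from .simulator import Trajectory, reflect, wrap_angle

__all__ = [
    "SSFConfig",
    "SSFFit",
    "OccurrenceDistribution",
    "DegenerateFitError",
    "InestimableCovariateError",
    "InsufficientDataError",
    "fit_step_distributions",
    "generate_available_steps",
    "occurrence_distribution",
    "attach_covariates",
    "fit_clogit",
    "fit_ssf",
    "kappa_from_resultant_length",
]


class DegenerateFitError(ValueError):
    """Observed steps carry no information about a distribution parameter."""


class InestimableCovariateError(ValueError):
    """A covariate is constant within every stratum."""


class InsufficientDataError(ValueError):
    """Too few observed steps."""


class SSFAlignmentError(ValueError):
    """Partner fix missing at a required time."""


@dataclass(frozen=True)
class SSFConfig:
    n_available: int = 20
    covariate_set: tuple[str, ...] = ("dist",)
    standardize: bool = True
    dist_sign: str = "negated"

    def __post_init__(self) -> None:
        if self.n_available < 1:
            raise ValueError("n_available must be >= 1")
        if not self.covariate_set:
            raise ValueError("covariate_set must be non-empty")
        if self.dist_sign not in ("negated", "raw"):
            raise ValueError("dist_sign must be 'negated' or 'raw'")


@dataclass(frozen=True)
class SSFFit:
    """Conditional-logit estimates with Wald inference."""

    coefficients: dict
    std_errors: dict
    z_values: dict
    p_values: dict
    log_likelihood: float
    converged: bool
    n_strata: int
    n_iterations: int = 0
    covariance: np.ndarray | None = None
    model_covariance: np.ndarray | None = None  # inverse information (pre-sandwich)


@dataclass(frozen=True)
class OccurrenceDistribution:
    """Kernel-density estimate of one individual's space use.

    ``density`` is the raster evaluated at grid cell centres (normalised so
    density x cell area sums to 1); ``evaluate`` gives the same normalised
    density as a smooth function of position, which is what covariates use
    (a raster staircase would leak cell-scale structure into the SSF).
    """

    density: np.ndarray  # (n_rows, n_cols), integrates to 1 over the grid
    cell_size: float
    origin: tuple[float, float]
    bandwidth: tuple[float, float]
    source_id: str
    fixes: np.ndarray | None = None  # (n, 2) KDE support points
    norm: float = 1.0  # raster renormalisation factor applied to the KDE

    def value_at(self, x, y):
        """Raster lookup (piecewise constant, clipped to the grid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.clip(np.floor((x - self.origin[0]) / self.cell_size).astype(int), 0, self.density.shape[1] - 1)
        row = np.clip(np.floor((y - self.origin[1]) / self.cell_size).astype(int), 0, self.density.shape[0] - 1)
        return self.density[row, col]

    def evaluate(self, x, y):
        """Smooth KDE density at arbitrary points (same normalisation)."""
        if self.fixes is None:
            return self.value_at(x, y)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        hx, hy = self.bandwidth
        zx = (x[:, None] - self.fixes[None, :, 0]) / hx
        zy = (y[:, None] - self.fixes[None, :, 1]) / hy
        dens = np.exp(-0.5 * (zx**2 + zy**2)).sum(axis=1) / (len(self.fixes) * 2 * np.pi * hx * hy)
        return dens * self.norm


def kappa_from_resultant_length(r: float) -> float:
    """Invert the von Mises Bessel ratio A(kappa) = I1(kappa)/I0(kappa) = r."""
    if r <= 0:
        return 0.0
    if r >= 1 - 1e-12:
        raise DegenerateFitError("mean resultant length at 1: turning angles are degenerate")
    f = lambda k: special.i1e(k) / special.i0e(k) - r
    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise DegenerateFitError("kappa inversion failed to bracket")
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-12))


def fit_step_distributions(traj: Trajectory) -> tuple[float, float, float]:
    """ML estimates (gamma_shape, gamma_scale, vm_kappa) from observed steps.

    Gamma parameters are fitted to positive step lengths (location fixed at
    0); the von Mises concentration is solved from the mean resultant
    length of the turning angles via the Bessel-ratio equation.
    """
    lengths = traj.step_lengths
    lengths = lengths[lengths > 0]
    if len(lengths) < 30:
        raise InsufficientDataError("need at least 30 positive-length steps")
    if np.ptp(lengths) == 0:
        raise DegenerateFitError("all step lengths identical")
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    angles = traj.turning_angles
    r = float(np.hypot(np.mean(np.cos(angles)), np.mean(np.sin(angles))))
    kappa = kappa_from_resultant_length(r)
    return float(shape), float(scale), kappa


def generate_available_steps(
    traj: Trajectory,
    fitted_distributions: tuple[float, float, float],
    n_available: int,
    rng,
    area_size: float | None = None,
) -> pd.DataFrame:
    """One stratum per usable observed step with ``n_available`` alternatives.

    The first observed step is dropped (its turning angle is undefined).
    Available turning angles are von Mises(0, kappa) around the previous
    observed heading; lengths are gamma(shape, scale).  If ``area_size`` is
    given, available endpoints are reflected into the arena so covariates
    are defined everywhere.
    """
    if traj.n_fixes < 3:
        raise InsufficientDataError("need at least 3 fixes (2 steps) to build strata")
    shape, scale, kappa = fitted_distributions
    heads = traj.headings
    n_strata = traj.n_fixes - 2  # steps 1 .. n_steps-1 (0-based)
    start_x = traj.x[1:-1]
    start_y = traj.y[1:-1]
    prev_head = heads[:-1]
    t_end = traj.t[2:]

    used = pd.DataFrame(
        {
            "stratum_id": np.arange(n_strata),
            "case": 1,
            "t_end": t_end,
            "x": traj.x[2:],
            "y": traj.y[2:],
            "step_length": traj.step_lengths[1:],
            "turning_angle": traj.turning_angles,
        }
    )

    turns = rng.vonmises(0.0, kappa, size=(n_strata, n_available))
    lengths = rng.gamma(shape, scale, size=(n_strata, n_available))
    headings = prev_head[:, None] + turns
    ax = start_x[:, None] + lengths * np.cos(headings)
    ay = start_y[:, None] + lengths * np.sin(headings)
    if area_size is not None:
        ax = reflect(ax, area_size)
        ay = reflect(ay, area_size)
    avail = pd.DataFrame(
        {
            "stratum_id": np.repeat(np.arange(n_strata), n_available),
            "case": 0,
            "t_end": np.repeat(t_end, n_available),
            "x": ax.ravel(),
            "y": ay.ravel(),
            "step_length": lengths.ravel(),
            "turning_angle": wrap_angle(turns.ravel()),
        }
    )
    strata = pd.concat([used, avail], ignore_index=True)
    return strata.sort_values(["stratum_id", "case"], ascending=[True, False], kind="stable").reset_index(
        drop=True
    )


def occurrence_distribution(
    other_traj: Trajectory,
    grid: LandscapeGrid,
    bandwidth: float | tuple[float, float] | str = "movement",
) -> OccurrenceDistribution:
    """Gaussian-KDE occurrence distribution of ``other_traj`` on the grid.

    The default ``"movement"`` bandwidth is the track's mean step length:
    an occurrence distribution estimated from a movement model (e.g. a
    Brownian bridge) is smoothed at the scale of the movement between
    fixes, not at the scale of the whole home range.  ``"silverman"``
    gives Silverman's rule per coordinate with the nominal n replaced by
    an autocorrelation-adjusted effective sample size (raw Silverman on
    autocorrelated fixes undersmooths badly).  A float or pair of floats
    fixes the bandwidth(s) in length units.  The density is evaluated at
    cell centres and renormalised so density x cell area sums to 1.
    """
    if other_traj.n_fixes < 2:
        raise InsufficientDataError("need at least 2 fixes for an occurrence distribution")
    fx, fy = other_traj.x, other_traj.y
    n = len(fx)
    if isinstance(bandwidth, str):
        if bandwidth == "movement":
            hx = hy = float(np.mean(other_traj.step_lengths))
        elif bandwidth == "silverman":
            def _lag1(v):
                v = v - v.mean()
                denom = float(v @ v)
                return float(v[:-1] @ v[1:]) / denom if denom > 0 else 0.0

            rho = np.clip(0.5 * (_lag1(fx) + _lag1(fy)), 0.0, 1.0 - 1e-6)
            n_eff = max(2.0, n * (1.0 - rho) / (1.0 + rho))
            hx = float(np.std(fx, ddof=1)) * n_eff ** (-1 / 6)
            hy = float(np.std(fy, ddof=1)) * n_eff ** (-1 / 6)
        else:
            raise ValueError("bandwidth must be 'movement', 'silverman' or numeric")
    elif np.isscalar(bandwidth):
        hx = hy = float(bandwidth)
    else:
        hx, hy = map(float, bandwidth)
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth must be positive (zero-variance fixes?)")

    X, Y = grid.cell_centres()
    zx = (X.ravel()[:, None] - fx[None, :]) / hx
    zy = (Y.ravel()[:, None] - fy[None, :]) / hy
    dens = np.exp(-0.5 * (zx**2 + zy**2)).sum(axis=1) / (n * 2 * np.pi * hx * hy)
    dens = dens.reshape(X.shape)
    cell_area = grid.cell_size**2
    total = dens.sum() * cell_area
    if total <= 0:
        raise ValueError("occurrence density vanished on the grid")
    return OccurrenceDistribution(
        density=dens / total,
        cell_size=grid.cell_size,
        origin=grid.origin,
        bandwidth=(hx, hy),
        source_id=other_traj.individual_id,
        fixes=np.column_stack((fx, fy)),
        norm=1.0 / total,
    )


def attach_covariates(
    strata: pd.DataFrame,
    grid: LandscapeGrid | None = None,
    other_traj: Trajectory | None = None,
    od: OccurrenceDistribution | None = None,
    config: SSFConfig | None = None,
) -> pd.DataFrame:
    """Add covariate columns (raw scale) to a strata table.

    ``landscape`` needs ``grid``; ``dist`` needs ``other_traj`` (the
    partner's fix at each candidate's target time); ``od`` needs an
    occurrence distribution.  Standardisation happens at fit time.
    """
    cfg = config or SSFConfig(covariate_set=("landscape", "dist", "od"))
    out = strata.copy()
    if "landscape" in cfg.covariate_set:
        if grid is None:
            raise ValueError("landscape covariate requires a grid")
        out["landscape"] = np.asarray(grid.value_at(out["x"].to_numpy(), out["y"].to_numpy()), dtype=float)
    if "dist" in cfg.covariate_set:
        if other_traj is None:
            raise ValueError("dist covariate requires the partner trajectory")
        t_to_idx = {int(t): i for i, t in enumerate(other_traj.t)}
        try:
            idx = np.array([t_to_idx[int(t)] for t in out["t_end"]])
        except KeyError as exc:
            raise SSFAlignmentError(f"partner fix missing at time {exc.args[0]}") from None
        d = np.hypot(out["x"].to_numpy() - other_traj.x[idx], out["y"].to_numpy() - other_traj.y[idx])
        out["dist"] = -d if cfg.dist_sign == "negated" else d
    if "od" in cfg.covariate_set:
        if od is None:
            raise ValueError("od covariate requires an occurrence distribution")
        out["od"] = np.asarray(od.evaluate(out["x"].to_numpy(), out["y"].to_numpy()), dtype=float)
    return out


# ---------------------------------------------------------------------------
# conditional logistic regression


def fit_clogit(
    strata: pd.DataFrame,
    covariate_set,
    tol: float = 1e-9,
    max_iter: int = 100,
    penalty: np.ndarray | None = None,
    robust_block_length: int | None = None,
    beta0: np.ndarray | None = None,
) -> SSFFit:
    """Maximise the conditional likelihood by Newton iteration with step-halving.

    The likelihood is prod over strata of exp(b'x_used) / sum_j exp(b'x_j).
    Wald standard errors come from the observed information; p-values are
    two-sided normal.  A covariate with no within-stratum variation raises
    :class:`InestimableCovariateError`.

    ``penalty`` (optional, k x k PSD) subtracts ``0.5 b' P b`` from the
    log-likelihood (a penalised smooth term inside the model); standard
    errors then come from the penalised information.

    ``robust_block_length`` switches to a cluster-robust (sandwich)
    covariance with per-stratum scores summed over temporal blocks of that
    many consecutive strata — within-stratum contrasts of spatially
    structured covariates are serially correlated along a track, which the
    model-based Wald variance ignores.
    """
    covs = list(covariate_set)
    df = strata.sort_values(["stratum_id", "case"], ascending=[True, False], kind="stable")
    sid = df["stratum_id"].to_numpy()
    case = df["case"].to_numpy().astype(bool)
    X = df[covs].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")

    uniq, starts, counts = np.unique(sid, return_index=True, return_counts=True)
    n_strata = len(uniq)
    if n_strata < 2:
        raise InsufficientDataError("need at least 2 strata")
    n_used = np.add.reduceat(case.astype(int), starts)
    if not np.all(n_used == 1):
        raise ValueError("each stratum must contain exactly one used candidate")

    for j, name in enumerate(covs):
        col = X[:, j]
        within_rng = np.maximum.reduceat(col, starts) - np.minimum.reduceat(col, starts)
        if np.all(within_rng == 0):
            raise InestimableCovariateError(name)

    k = X.shape[1]
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    rep = np.repeat(np.arange(n_strata), counts)

    def loglik_and_derivs(beta):
        eta = X @ beta
        emax = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - emax[rep])
        denom = np.add.reduceat(w, starts)
        p = w / denom[rep]
        ll = float(eta[case].sum() - (np.log(denom) + emax).sum())
        xbar = np.add.reduceat(p[:, None] * X, starts, axis=0)
        grad = X[case].sum(axis=0) - xbar.sum(axis=0)
        H = (X * p[:, None]).T @ X - xbar.T @ xbar
        if penalty is not None:
            ll -= 0.5 * float(beta @ penalty @ beta)
            grad = grad - penalty @ beta
            H = H + penalty
        return ll, grad, H

    ll, grad, H = loglik_and_derivs(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            ll_new, grad_new, H_new = loglik_and_derivs(beta + step * delta)
            if ll_new >= ll:
                break
            step *= 0.5
        else:
            break
        beta = beta + step * delta
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll, grad, H = ll_new, grad_new, H_new
            converged = True
            break
        ll, grad, H = ll_new, grad_new, H_new

    model_cov = None
    try:
        cov = np.linalg.inv(H)
        model_cov = cov
        if robust_block_length is not None:
            # per-stratum scores at the optimum, summed over temporal blocks
            eta = X @ beta
            emax = np.maximum.reduceat(eta, starts)
            w = np.exp(eta - emax[rep])
            denom = np.add.reduceat(w, starts)
            p = w / denom[rep]
            scores = X[case] - np.add.reduceat(p[:, None] * X, starts, axis=0)
            blocks = np.arange(n_strata) // max(1, robust_block_length)
            n_blocks = blocks.max() + 1
            meat = np.zeros((k, k))
            for g in range(n_blocks):
                sg = scores[blocks == g].sum(axis=0)
                meat += np.outer(sg, sg)
            if n_blocks > 1:
                meat *= n_blocks / (n_blocks - 1)
            cov = cov @ meat @ cov
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = None
        se = np.full(k, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return SSFFit(
        coefficients=dict(zip(covs, beta)),
        std_errors=dict(zip(covs, se)),
        z_values=dict(zip(covs, z)),
        p_values=dict(zip(covs, pvals)),
        log_likelihood=ll,
        converged=converged,
        n_strata=n_strata,
        n_iterations=it,
        covariance=cov,
        model_covariance=model_cov,
    )


def fit_ssf(strata: pd.DataFrame, covariate_set, config: SSFConfig | None = None) -> SSFFit:
    """Standardise covariates (optional) and fit the conditional logit."""
    cfg = config or SSFConfig(covariate_set=tuple(covariate_set))
    df = strata.copy()
    if cfg.standardize:
        for name in covariate_set:
            col = df[name].to_numpy(dtype=float)
            sd = col.std()
            if sd > 0:
                df[name] = (col - col.mean()) / sd
    return fit_clogit(df, covariate_set)
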