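"""Dynamic interaction index (DI) for two simultaneous trajectories.

DI measures the cohesiveness of simultaneous movement vectors with respect
to direction and displacement (Long et al. 2014).  Per simultaneous step t,

    g_t = cos(theta_1t - theta_2t)                     (direction)
    f_t = 1 - (|d_1t - d_2t| / (d_1t + d_2t)) ** delta  (displacement)

and DI is the mean over steps of g_t * f_t; the reported components di_theta
and di_d are the means of g_t and f_t.  DI lies in [-1, 1]: positive values
mean cohesive movement, negative values repulsive/opposing movement, values
near 0 independent movement.

Significance comes from a permutation test in the spirit of Benhamou's IAB:
the step series of the second trajectory is circularly time-shifted, which
preserves each track's autocorrelation while destroying cross-track
simultaneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import Trajectory

__all__ = ["DIConfig", "DIResult", "AlignmentError", "di_index", "permutation_pvalue"]


class AlignmentError(ValueError):
    """Trajectories do not share an identical time grid."""


class InsufficientDataError(ValueError):
    """Too few fixes to compute the statistic."""


@dataclass(frozen=True)
class DIConfig:
    delta: float = 1.0
    n_permutations: int = 999
    alternative: str = "greater"
    seed: int = 0
    min_shift: int | None = None  # default: n_steps // 20, at least 1

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.alternative not in ("two_sided", "greater"):
            raise ValueError("alternative must be 'two_sided' or 'greater'")


@dataclass(frozen=True)
class DIResult:
    di: float
    di_theta: float
    di_d: float
    p_value: float
    n_permutations: int


def _step_series(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    return traj.headings, traj.step_lengths


def _check_aligned(traj1: Trajectory, traj2: Trajectory) -> None:
    if traj1.n_fixes < 2 or traj2.n_fixes < 2:
        raise InsufficientDataError("DI needs at least 2 fixes per trajectory")
    if traj1.n_fixes != traj2.n_fixes or not np.array_equal(traj1.t, traj2.t):
        raise AlignmentError("trajectories must share an identical time grid")


def _di_from_steps(h1, d1, h2, d2, delta: float) -> tuple[float, float, float]:
    g = np.cos(h1 - h2)
    total = d1 + d2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, np.abs(d1 - d2) / np.where(total > 0, total, 1.0), 0.0)
    f = 1.0 - ratio**delta  # both steps zero => f = 1 (ratio 0)
    return float(np.mean(g * f)), float(np.mean(g)), float(np.mean(f))


def di_index(traj1: Trajectory, traj2: Trajectory, config: DIConfig | None = None, rng=None) -> DIResult:
    """DI, its direction/displacement components, and the permutation p-value."""
    cfg = config or DIConfig()
    _check_aligned(traj1, traj2)
    h1, d1 = _step_series(traj1)
    h2, d2 = _step_series(traj2)
    di, di_theta, di_d = _di_from_steps(h1, d1, h2, d2, cfg.delta)
    p = permutation_pvalue(traj1, traj2, cfg, rng)
    return DIResult(di=di, di_theta=di_theta, di_d=di_d, p_value=p, n_permutations=cfg.n_permutations)


def permutation_pvalue(traj1: Trajectory, traj2: Trajectory, config: DIConfig | None = None, rng=None) -> float:
    """Permutation p-value for DI via circular time-shifts of trajectory 2.

    The null distribution re-pairs trajectory 1's step series with circular
    shifts of trajectory 2's (heading, length) step series; the add-one
    formula p = (1 + exceedances) / (1 + n_permutations) is used.
    """
    cfg = config or DIConfig()
    _check_aligned(traj1, traj2)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h1, d1 = _step_series(traj1)
    h2, d2 = _step_series(traj2)
    obs, _, _ = _di_from_steps(h1, d1, h2, d2, cfg.delta)
    n_steps = len(h1)
    # short shifts barely decouple autocorrelated tracks; exclude them so the
    # null represents genuinely time-decoupled movement
    min_shift = cfg.min_shift if cfg.min_shift is not None else max(1, n_steps // 20)
    min_shift = min(min_shift, max(1, n_steps // 2 - 1))
    shifts = rng.integers(min_shift, n_steps - min_shift + 1, size=cfg.n_permutations)
    exceed = 0
    for k in shifts:
        perm, _, _ = _di_from_steps(h1, d1, np.roll(h2, k), np.roll(d2, k), cfg.delta)
        if cfg.alternative == "two_sided":
            exceed += abs(perm) >= abs(obs)
        else:
            exceed += perm >= obs
    return (1.0 + exceed) / (1.0 + cfg.n_permutations)
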