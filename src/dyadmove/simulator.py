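"""Agent-based simulation of two individuals moving by biased correlated random walk.

Two individuals move in discrete time inside a square arena with reflecting
borders.  At each time step every individual draws a set of candidate steps
(turning angle ~ von Mises around the current heading, step length ~ gamma)
and selects one according to the active scenario:

* ``A.a`` / ``A.b`` / ``B`` — habitat selection: the candidate in the cell
  with the highest habitat quality within the perceptual range is taken
  (softmax with strength ``beta_env``; the default ``beta_env = inf`` is the
  literal argmax with random tie-break).
* ``C`` — no habitat preference, but candidates landing in barrier cells
  are discarded; if every candidate is blocked the set is redrawn (bounded
  retries, then the individual stays put for that step).
* ``D`` — mutual attraction: candidates closer to the partner's current
  position are exponentially more likely (strength ``beta_soc`` per length
  unit); the landscape is ignored.

Scenarios A-C produce correlated trajectories without any direct
interaction; scenario D produces genuinely interacting individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .landscapes import (
    LandscapeGrid,
    NoiseConfig,
    make_barrier_landscape,
    make_gradient_landscape,
    make_perlin_landscape,
)

__all__ = [
    "MovementKernel",
    "ScenarioConfig",
    "Trajectory",
    "SimulationResult",
    "SCENARIOS",
    "draw_candidate_steps",
    "select_step_habitat",
    "select_step_social",
    "enforce_barriers",
    "reflect",
    "simulate_pair",
    "wrap_angle",
]

SCENARIOS = ("A.a", "A.b", "B", "C", "D")

#: retries of the full candidate set when all candidates are blocked (scenario C)
BARRIER_RETRY_BUDGET = 20


@dataclass(frozen=True)
class MovementKernel:
    """Step-length and turning-angle distributions of the random walk.

    Defaults: von Mises concentration 4 (strong directional persistence),
    gamma step lengths with shape 6 and scale 0.15 (mean step 0.9 length
    units).
    """

    kappa: float = 4.0
    gamma_shape: float = 6.0
    gamma_scale: float = 0.15

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("kernel parameters must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full configuration of one paired-movement simulation.

    ``beta_env = inf`` encodes deterministic argmax habitat choice;
    ``beta_soc`` is the social-attraction strength per length unit
    (scenario D).  ``initial_positions`` defaults to scenario-appropriate
    starts (see :func:`default_initial_positions`).
    """

    scenario: str
    n_steps: int = 1000
    area_size: float = 100.0
    n_grid_cells: int = 100
    kernel: MovementKernel = field(default_factory=MovementKernel)
    n_candidates: int = 10
    perceptual_range: float = 5.0
    beta_env: float = math.inf
    beta_soc: float = 10.0
    barrier_proportion: float = 0.0
    noise: NoiseConfig | None = None
    seed: int = 0
    initial_positions: tuple[tuple[float, float], tuple[float, float]] | None = None
    landscape: LandscapeGrid | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.area_size <= 0:
            raise ValueError("area_size must be > 0")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.beta_soc < 0:
            raise ValueError("beta_soc must be >= 0")
        if not 0.0 <= self.barrier_proportion <= 0.9:
            raise ValueError("barrier_proportion must be in [0, 0.9]")


@dataclass(frozen=True)
class Trajectory:
    """Ordered fixes of one individual at unit time steps."""

    individual_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=int)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) >= 2 and not np.all(np.diff(t) == 1):
            raise ValueError("t must increase strictly by 1")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_fixes(self) -> int:
        return len(self.t)

    @property
    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))

    @property
    def headings(self) -> np.ndarray:
        """Absolute heading per step (radians); zero-length steps carry the
        previous heading (first defaults to 0)."""
        dx, dy = np.diff(self.x), np.diff(self.y)
        head = np.arctan2(dy, dx)
        moved = (dx != 0) | (dy != 0)
        if not moved.all():
            head = head.copy()
            last = 0.0
            for i in range(len(head)):
                if moved[i]:
                    last = head[i]
                else:
                    head[i] = last
        return head

    @property
    def turning_angles(self) -> np.ndarray:
        """Turning angle per step after the first, wrapped to (-pi, pi]."""
        return wrap_angle(np.diff(self.headings))


@dataclass(frozen=True)
class SimulationResult:
    """Pair of simulated trajectories plus the landscape they moved in."""

    traj_a: Trajectory
    traj_b: Trajectory
    landscape: LandscapeGrid | None
    config: ScenarioConfig


def wrap_angle(angle):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.shape else float(wrapped)


def reflect(position, area_size: float):
    """Mirror coordinates at the arena borders until inside [0, area_size]."""
    p = np.asarray(position, dtype=float)
    period = 2.0 * area_size
    r = np.mod(p, period)
    out = area_size - np.abs(r - area_size)
    return out if out.shape else float(out)


def draw_candidate_steps(rng, kernel: MovementKernel, current_position, current_heading, n_candidates):
    """Draw candidate step endpoints from the movement kernel.

    Returns ``(endpoints (n, 2), step_lengths (n,), turning_angles (n,))``.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    turns = rng.vonmises(0.0, kernel.kappa, size=n_candidates)
    lengths = rng.gamma(kernel.gamma_shape, kernel.gamma_scale, size=n_candidates)
    headings = current_heading + turns
    pos = np.asarray(current_position, dtype=float)
    endpoints = pos + np.column_stack((lengths * np.cos(headings), lengths * np.sin(headings)))
    return endpoints, lengths, turns


def _softmax_choice(rng, log_weights: np.ndarray) -> int:
    w = np.exp(log_weights - log_weights.max())
    return int(rng.choice(len(w), p=w / w.sum()))


def select_step_habitat(candidates, grid: LandscapeGrid, perceptual_range, beta_env, rng, current_position=None):
    """Choose among candidate endpoints by habitat quality.

    Weight ~ exp(beta_env * habitat) over candidates within the perceptual
    range of the current position; candidates beyond it are weighted by the
    current cell's value.  ``beta_env = inf`` is argmax with a random
    tie-break.  Returns the chosen candidate index.
    """
    endpoints = np.asarray(candidates, dtype=float)
    habitat = grid.value_at(endpoints[:, 0], endpoints[:, 1])
    habitat = np.atleast_1d(np.asarray(habitat, dtype=float))
    if current_position is not None and np.isfinite(perceptual_range):
        d = np.hypot(endpoints[:, 0] - current_position[0], endpoints[:, 1] - current_position[1])
        beyond = d > perceptual_range
        if beyond.any():
            here = float(grid.value_at(current_position[0], current_position[1]))
            habitat = np.where(beyond, here, habitat)
    if math.isinf(beta_env):
        best = np.flatnonzero(habitat == habitat.max())
        return int(best[rng.integers(len(best))])
    return _softmax_choice(rng, beta_env * habitat)


def select_step_social(candidates, other_position, beta_soc, rng):
    """Choose among candidate endpoints by proximity to the partner.

    Weight ~ exp(-beta_soc * distance(endpoint, partner)).  Returns the
    chosen candidate index.
    """
    endpoints = np.asarray(candidates, dtype=float)
    d = np.hypot(endpoints[:, 0] - other_position[0], endpoints[:, 1] - other_position[1])
    return _softmax_choice(rng, -beta_soc * d)


def enforce_barriers(candidates, grid: LandscapeGrid):
    """Indices of candidates whose endpoints fall in non-barrier cells."""
    endpoints = np.asarray(candidates, dtype=float)
    blocked = grid.is_barrier_at(endpoints[:, 0], endpoints[:, 1])
    return np.flatnonzero(~np.atleast_1d(blocked))


def _build_landscape(config: ScenarioConfig, seed: int) -> LandscapeGrid | None:
    if config.landscape is not None:
        return config.landscape
    n = config.n_grid_cells
    cell = config.area_size / n
    if config.scenario == "A.a":
        return make_gradient_landscape(n, n, cell, mode="west_east")
    if config.scenario == "A.b":
        return make_gradient_landscape(n, n, cell, mode="radial")
    noise = config.noise or NoiseConfig(seed=seed)
    if config.scenario == "B":
        return make_perlin_landscape(n, n, cell, noise)
    if config.scenario == "C":
        base = make_perlin_landscape(n, n, cell, noise)
        return make_barrier_landscape(base, config.barrier_proportion)
    return None  # scenario D ignores the landscape


def _nearest_open_cell(grid: LandscapeGrid, point) -> tuple[float, float]:
    """Snap a point to the centre of the nearest non-barrier cell."""
    if grid.barrier_mask is None or not bool(grid.is_barrier_at(point[0], point[1])):
        return (float(point[0]), float(point[1]))
    X, Y = grid.cell_centres()
    open_x = X[~grid.barrier_mask]
    open_y = Y[~grid.barrier_mask]
    i = int(np.argmin(np.hypot(open_x - point[0], open_y - point[1])))
    return (float(open_x[i]), float(open_y[i]))


def default_initial_positions(config: ScenarioConfig, grid: LandscapeGrid | None, rng):
    """Scenario-appropriate starting positions for both individuals.

    A.a: side by side near the low (west) end of the gradient; A.b: opposite
    border midpoints; B: a shared random interior point, one cell apart;
    C: flanking the arena centre, snapped to open cells; D: at the centre,
    5 length units apart (within mutual attraction range).
    """
    L = config.area_size
    sep = L / config.n_grid_cells  # one cell
    if config.scenario == "A.a":
        return ((0.05 * L, 0.5 * L - sep / 2), (0.05 * L, 0.5 * L + sep / 2))
    if config.scenario == "A.b":
        return ((0.05 * L, 0.5 * L), (0.95 * L, 0.5 * L))
    if config.scenario == "B":
        cx, cy = rng.uniform(0.25 * L, 0.75 * L, size=2)
        return ((cx - sep / 2, cy), (cx + sep / 2, cy))
    if config.scenario == "C":
        p1 = (0.5 * L - sep, 0.5 * L)
        p2 = (0.5 * L + sep, 0.5 * L)
        if grid is not None:
            p1, p2 = _nearest_open_cell(grid, p1), _nearest_open_cell(grid, p2)
        return (p1, p2)
    # scenario D
    return ((0.5 * L - 2.5, 0.5 * L), (0.5 * L + 2.5, 0.5 * L))


def _step_individual(rng, config: ScenarioConfig, grid, pos, heading, other_pos):
    """One movement decision; returns (new_pos, new_heading)."""
    kernel = config.kernel
    scenario = config.scenario
    retries = BARRIER_RETRY_BUDGET if scenario == "C" else 1
    for _ in range(retries):
        endpoints, lengths, _ = draw_candidate_steps(rng, kernel, pos, heading, config.n_candidates)
        endpoints[:, 0] = reflect(endpoints[:, 0], config.area_size)
        endpoints[:, 1] = reflect(endpoints[:, 1], config.area_size)
        if scenario == "C":
            keep = enforce_barriers(endpoints, grid)
            if len(keep) == 0:
                continue
            idx = int(keep[rng.integers(len(keep))])
        elif scenario == "D":
            idx = select_step_social(endpoints, other_pos, config.beta_soc, rng)
        else:
            idx = select_step_habitat(
                endpoints, grid, config.perceptual_range, config.beta_env, rng, current_position=pos
            )
        new_pos = (float(endpoints[idx, 0]), float(endpoints[idx, 1]))
        dx, dy = new_pos[0] - pos[0], new_pos[1] - pos[1]
        new_heading = math.atan2(dy, dx) if (dx or dy) else heading
        return new_pos, new_heading
    return pos, heading  # all retries blocked: stay in place, keep heading


def simulate_pair(config: ScenarioConfig) -> SimulationResult:
    """Simulate both individuals for ``config.n_steps`` steps.

    Fully reproducible from ``config.seed``: the master seed is split into
    one stream per individual plus one for landscape generation and initial
    placement, so perturbing one individual's draws leaves the other's
    untouched.
    """
    ss = np.random.SeedSequence(config.seed)
    land_ss, ss_a, ss_b = ss.spawn(3)
    land_rng = np.random.default_rng(land_ss)
    rngs = (np.random.default_rng(ss_a), np.random.default_rng(ss_b))

    grid = _build_landscape(config, seed=int(land_rng.integers(2**31)))
    starts = config.initial_positions or default_initial_positions(config, grid, land_rng)
    for p in starts:
        if not (0 <= p[0] <= config.area_size and 0 <= p[1] <= config.area_size):
            raise ValueError("initial positions must lie inside the arena")
        if grid is not None and grid.barrier_mask is not None and bool(grid.is_barrier_at(p[0], p[1])):
            raise ValueError("initial positions must lie outside barriers")

    n = config.n_steps
    xs = np.empty((2, n + 1))
    ys = np.empty((2, n + 1))
    pos = [tuple(map(float, p)) for p in starts]
    headings = [float(land_rng.uniform(-np.pi, np.pi)) for _ in range(2)]
    for k in range(2):
        xs[k, 0], ys[k, 0] = pos[k]

    for t in range(1, n + 1):
        prev = list(pos)
        for k in range(2):
            pos[k], headings[k] = _step_individual(
                rngs[k], config, grid, prev[k], headings[k], prev[1 - k]
            )
            xs[k, t], ys[k, t] = pos[k]

    tgrid = np.arange(n + 1)
    return SimulationResult(
        traj_a=Trajectory("a", tgrid, xs[0], ys[0]),
        traj_b=Trajectory("b", tgrid, xs[1], ys[1]),
        landscape=grid,
        config=config,
    )


def simulate_crw_pair(
    n_steps: int = 1000,
    area_size: float = 100.0,
    kernel: MovementKernel | None = None,
    seed: int = 0,
    initial_positions=None,
) -> SimulationResult:
    """Two fully independent correlated random walks (the null of no
    interaction and no landscape effect): scenario C with zero barriers."""
    cfg = ScenarioConfig(
        scenario="C",
        n_steps=n_steps,
        area_size=area_size,
        kernel=kernel or MovementKernel(),
        barrier_proportion=0.0,
        seed=seed,
        initial_positions=initial_positions,
    )
    return simulate_pair(cfg)
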