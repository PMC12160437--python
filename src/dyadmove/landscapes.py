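"""Synthetic landscape rasters: habitat-quality gradients, Perlin patchworks, barriers.

A landscape is a regular grid of square cells holding habitat quality in
[0, 1]; barrier landscapes additionally carry a boolean mask of impassable
cells (which have quality 0).  The grid origin is the lower-left corner and
cells are half-open, so a point exactly on a cell's west/south edge belongs
to that cell.  Trajectories live in continuous space; rasters are piecewise
constant (nearest-cell lookup, no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandscapeGrid",
    "NoiseConfig",
    "ExtentError",
    "make_gradient_landscape",
    "make_perlin_landscape",
    "make_barrier_landscape",
    "value_at",
]


class ExtentError(ValueError):
    """A queried point lies outside the raster extent."""


@dataclass(frozen=True)
class NoiseConfig:
    """Parameters of the Perlin noise field.

    ``base_frequency`` is in cycles per grid width; ``persistence`` is the
    amplitude decay applied at each successive octave (each octave doubles
    the frequency).  Defaults give patches of roughly 1/8 grid width.
    """

    seed: int = 0
    octaves: int = 4
    base_frequency: float = 4.0
    persistence: float = 0.5

    def __post_init__(self) -> None:
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be > 0")
        if not 0 < self.persistence <= 1:
            raise ValueError("persistence must be in (0, 1]")


@dataclass(frozen=True)
class LandscapeGrid:
    """Raster of habitat quality with optional barrier mask.

    ``values`` has shape ``(n_rows, n_cols)`` with row 0 the southernmost
    row (lower-left origin).  Values are dimensionless habitat quality in
    [0, 1]; every barrier cell has value exactly 0.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    barrier_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError("landscape needs at least a 2x2 cell grid")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if not np.all(np.isfinite(values)):
            raise ValueError("habitat values must be finite")
        if values.min() < 0 or values.max() > 1:
            raise ValueError("habitat values must lie in [0, 1]")
        if self.barrier_mask is not None:
            mask = np.asarray(self.barrier_mask, dtype=bool)
            object.__setattr__(self, "barrier_mask", mask)
            if mask.shape != values.shape:
                raise ValueError("barrier_mask shape must match values")
            if np.any(values[mask] != 0):
                raise ValueError("barrier cells must have habitat value 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the raster."""
        x0, y0 = self.origin
        return (x0, x0 + self.width, y0, y0 + self.height)

    def cell_index(self, x, y):
        """Row/column of the half-open cell containing each point."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y - y0) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            raise ExtentError("point outside raster extent")
        return row, col

    def value_at(self, x, y):
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    def is_barrier_at(self, x, y):
        if self.barrier_mask is None:
            return np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape, dtype=bool)
        row, col = self.cell_index(x, y)
        return self.barrier_mask[row, col]

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of cell-centre coordinates, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def value_at(grid: LandscapeGrid, x, y):
    """Habitat value of the cell containing (x, y)."""
    return grid.value_at(x, y)


def make_gradient_landscape(
    n_rows: int,
    n_cols: int,
    cell_size: float = 1.0,
    mode: str = "west_east",
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandscapeGrid:
    """Linear habitat-quality gradient.

    ``west_east``: quality rises linearly with column index from 0 (west) to
    1 (east).  ``radial``: quality is ``1 - d/d_max`` where ``d`` is the
    cell's distance from the grid centre, so the centre cell has quality 1
    and quality falls off linearly toward the corners.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("gradient landscape needs n_rows, n_cols >= 2")
    if mode == "west_east":
        col = np.arange(n_cols, dtype=float)
        values = np.tile(col / (n_cols - 1), (n_rows, 1))
    elif mode == "radial":
        rows = np.arange(n_rows, dtype=float)[:, None]
        cols = np.arange(n_cols, dtype=float)[None, :]
        cr, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
        dist = np.hypot(rows - cr, cols - cc)
        values = np.clip(1.0 - dist / dist.max(), 0.0, 1.0)
    else:
        raise ValueError(f"unknown gradient mode {mode!r}")
    return LandscapeGrid(values=values, cell_size=cell_size, origin=origin)


def _perlin_octave(u: np.ndarray, v: np.ndarray, fx: int, fy: int, rng) -> np.ndarray:
    """One octave of 2-D gradient noise on the unit square.

    ``u, v`` are coordinates in [0, 1); ``fx, fy`` are lattice frequencies.
    """
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(fy + 1, fx + 1))
    gx, gy = np.cos(theta), np.sin(theta)

    x = u * fx
    y = v * fy
    i0 = np.floor(x).astype(int)
    j0 = np.floor(y).astype(int)
    dx = x - i0
    dy = y - j0

    def dot(di: int, dj: int) -> np.ndarray:
        return (dx - di) * gx[j0 + dj, i0 + di] + (dy - dj) * gy[j0 + dj, i0 + di]

    # quintic fade gives C2-continuous interpolation (classic improved Perlin)
    sx = dx**3 * (dx * (dx * 6 - 15) + 10)
    sy = dy**3 * (dy * (dy * 6 - 15) + 10)
    nx0 = dot(0, 0) * (1 - sx) + dot(1, 0) * sx
    nx1 = dot(0, 1) * (1 - sx) + dot(1, 1) * sx
    return nx0 * (1 - sy) + nx1 * sy


def make_perlin_landscape(
    n_rows: int,
    n_cols: int,
    cell_size: float = 1.0,
    noise_config: NoiseConfig | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LandscapeGrid:
    """Patchy habitat from octave-summed Perlin gradient noise.

    The field is sampled at cell centres and min-max normalised so the
    output exactly spans [0, 1].  Deterministic for a given seed.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("perlin landscape needs n_rows, n_cols >= 2")
    cfg = noise_config or NoiseConfig()
    rng = np.random.default_rng(cfg.seed)
    u, v = np.meshgrid(
        (np.arange(n_cols) + 0.5) / n_cols,
        (np.arange(n_rows) + 0.5) / n_rows,
    )
    total = np.zeros((n_rows, n_cols))
    amplitude = 1.0
    freq = cfg.base_frequency
    for _ in range(cfg.octaves):
        fx = max(1, int(round(freq)))
        fy = max(1, int(round(freq * n_rows / n_cols)))
        total += amplitude * _perlin_octave(u, v, fx, fy, rng)
        amplitude *= cfg.persistence
        freq *= 2.0
    lo, hi = total.min(), total.max()
    if hi == lo:  # pathological flat field; keep it valid
        values = np.zeros_like(total)
    else:
        values = (total - lo) / (hi - lo)
    return LandscapeGrid(values=values, cell_size=cell_size, origin=origin)


def make_barrier_landscape(noise_grid: LandscapeGrid, barrier_proportion: float) -> LandscapeGrid:
    """Threshold a noise landscape into barriers.

    The ``barrier_proportion`` highest-valued cells become impassable
    barriers (habitat value 0, mask true); the remaining matrix cells keep
    their values.  The threshold is the exact empirical quantile, so the
    realised barrier count is ``round(p * n_cells)``; ties are broken by
    cell index order.
    """
    if not 0.0 <= barrier_proportion <= 0.9:
        raise ValueError("barrier_proportion must be in [0, 0.9]")
    values = noise_grid.values.copy()
    n_cells = values.size
    k = int(round(barrier_proportion * n_cells))
    mask = np.zeros(n_cells, dtype=bool)
    if k > 0:
        # stable sort => ties resolved by cell index order
        order = np.argsort(values.ravel(), kind="stable")
        mask[order[n_cells - k:]] = True
    mask = mask.reshape(values.shape)
    values[mask] = 0.0
    return LandscapeGrid(
        values=values,
        cell_size=noise_grid.cell_size,
        origin=noise_grid.origin,
        barrier_mask=mask,
    )
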