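"""Deterministic toy and stochastic synthetic landscapes for desk-scale runs.

The generator emulates the structure of the real mountain-valley inputs
without any GIS download: a gentle slope field punctuated by ridge-like
steep patches (> 40 degrees, so escape terrain exists), spatially
clumped crown cover in [0, 100] (a Gaussian-smoothed noise field, giving
contiguous dense patches that block movement), one river and one road
rasterized as supercover polylines (no diagonal leaks), and occurrence
points jittered inside suitable cells.  Everything is a pure function of
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .landscape import (
    DEFAULT_RULES,
    GridLayer,
    MovementRules,
    RasterLandscape,
    assemble_landscape,
)
from .scenarios import OccurrenceSet, suitable_cells

__all__ = [
    "SynthParams",
    "make_toy_landscape",
    "make_synthetic_landscape",
    "make_synthetic_occurrences",
]


@dataclass
class SynthParams:
    """Knobs for the stochastic generator.

    ``ridge_slope_deg`` must exceed the 40-degree escape threshold so
    escape terrain exists; ``cover_clump_scale`` is the Gaussian
    smoothing radius in cells that sets the size of dense-canopy
    patches.  ``road_spec``/``river_spec`` are polylines as lists of
    (x, y) map coordinates, or None for an auto-generated wiggly line
    spanning the grid.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 75.0
    n_ridges: int = 6
    ridge_slope_deg: float = 50.0
    cover_mean: float = 30.0
    cover_clump_scale: float = 5.0
    road_spec: list[tuple[float, float]] | None = None
    river_spec: list[tuple[float, float]] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("stochastic landscapes must be at least 10x10")
        if self.n_ridges > 0 and self.ridge_slope_deg <= DEFAULT_RULES.slope_threshold_deg:
            raise ValueError(
                "ridge_slope_deg must exceed the escape-slope threshold "
                f"({DEFAULT_RULES.slope_threshold_deg} deg)"
            )


def make_toy_landscape(
    slope, cover, water, roads, cell_size: float = 75.0,
    rules: MovementRules = DEFAULT_RULES,
    origin_x: float = 0.0, origin_y: float | None = None,
) -> RasterLandscape:
    """Build a landscape from literal 2-D value lists; no randomness.

    Ragged rows are rejected.  The origin defaults so that cell (0, 0)
    has its top-left corner at map (0, n_rows * cell_size).
    """
    arrays = []
    for name, lit in (("slope", slope), ("cover", cover), ("water", water), ("roads", roads)):
        try:
            arr = np.array(lit)
        except ValueError as err:
            raise ValueError(f"{name}: ragged literal grid") from err
        if arr.dtype == object or arr.ndim != 2:
            raise ValueError(f"{name}: ragged or non-2-D literal grid")
        arrays.append(arr)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"layer shapes differ: {sorted(shapes)}")
    n_rows = arrays[0].shape[0]
    if origin_y is None:
        origin_y = n_rows * cell_size

    def layer(a: np.ndarray) -> GridLayer:
        return GridLayer(
            values=a, origin_x=origin_x, origin_y=origin_y, cell_size=cell_size
        )

    return assemble_landscape(*(layer(a) for a in arrays), rules=rules)


def _supercover_cells(
    polyline: list[tuple[float, float]],
    layer: GridLayer,
) -> np.ndarray:
    """Boolean grid of cells intersected by the polyline (no diagonal gaps)."""
    mask = np.zeros(layer.shape, dtype=bool)
    n_rows, n_cols = layer.shape

    def mark(r: int, c: int) -> None:
        if 0 <= r < n_rows and 0 <= c < n_cols:
            mask[r, c] = True

    for (x0, y0), (x1, y1) in zip(polyline[:-1], polyline[1:]):
        length = max(abs(x1 - x0), abs(y1 - y0))
        n = max(2, int(np.ceil(length / (layer.cell_size / 4))) + 1)
        ts = np.linspace(0.0, 1.0, n)
        prev = None
        for t in ts:
            cell = layer.cell_of(x0 + t * (x1 - x0), y0 + t * (y1 - y0))
            if prev is not None and cell != prev:
                dr, dc = cell.row - prev.row, cell.col - prev.col
                if dr != 0 and dc != 0:  # plug the diagonal leak
                    mark(prev.row, cell.col)
            mark(cell.row, cell.col)
            prev = cell
    return mask


def _wiggly_line(
    params: SynthParams, rng: np.random.Generator, vertical: bool
) -> list[tuple[float, float]]:
    """A polyline spanning the grid with mild random lateral wander."""
    w = params.n_cols * params.cell_size
    h = params.n_rows * params.cell_size
    n_knots = 8
    if vertical:
        ys = np.linspace(h, 0, n_knots)
        x0 = rng.uniform(0.3, 0.7) * w
        xs = x0 + np.cumsum(rng.normal(0, 0.04 * w, n_knots))
        xs = np.clip(xs, 0.05 * w, 0.95 * w)
    else:
        xs = np.linspace(0, w, n_knots)
        y0 = rng.uniform(0.3, 0.7) * h
        ys = y0 + np.cumsum(rng.normal(0, 0.04 * h, n_knots))
        ys = np.clip(ys, 0.05 * h, 0.95 * h)
    return list(zip(xs, ys))


def make_synthetic_landscape(
    params: SynthParams | None = None, rules: MovementRules = DEFAULT_RULES
) -> RasterLandscape:
    """Generate a stochastic landscape; deterministic given ``rng_seed``.

    Raises with a diagnostic if the parameters admit no suitable cell
    (e.g. ``n_ridges=0`` leaves no escape terrain).
    """
    params = params or SynthParams()
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed))
    n_rows, n_cols = params.n_rows, params.n_cols
    origin_y = n_rows * params.cell_size

    def layer(values: np.ndarray) -> GridLayer:
        return GridLayer(
            values=values, origin_x=0.0, origin_y=origin_y,
            cell_size=params.cell_size,
        )

    # Gentle base terrain: smoothed noise mapped to [0, 25] degrees.
    base = ndimage.gaussian_filter(rng.normal(size=(n_rows, n_cols)), 4.0)
    base = (base - base.min()) / (np.ptp(base) + 1e-12) * 25.0
    slope = base.copy()

    # Ridges: short thick line segments of steep terrain.
    for _ in range(params.n_ridges):
        r0 = rng.integers(0, n_rows)
        c0 = rng.integers(0, n_cols)
        angle = rng.uniform(0, np.pi)
        length = rng.integers(max(4, n_rows // 10), max(6, n_rows // 4))
        rr = r0 + np.cos(angle) * np.arange(length)
        cc = c0 + np.sin(angle) * np.arange(length)
        ridge = np.zeros((n_rows, n_cols), dtype=bool)
        for r, c in zip(rr, cc):
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < n_rows and 0 <= ci < n_cols:
                ridge[ri, ci] = True
        ridge = ndimage.binary_dilation(ridge, iterations=1)
        slope[ridge] = params.ridge_slope_deg + rng.uniform(0, 5)
    slope = np.clip(slope, 0.0, 90.0)

    # Clumped crown cover: smoothed noise rescaled around cover_mean.
    noise = ndimage.gaussian_filter(
        rng.normal(size=(n_rows, n_cols)), params.cover_clump_scale
    )
    noise = (noise - noise.mean()) / (noise.std() + 1e-12)
    cover = np.clip(params.cover_mean + 25.0 * noise, 0.0, 100.0)
    cover[slope > DEFAULT_RULES.slope_threshold_deg] = np.minimum(
        cover[slope > DEFAULT_RULES.slope_threshold_deg], 10.0
    )  # ridge tops are rocky, not forested

    slope_layer = layer(slope)
    river = params.river_spec or _wiggly_line(params, rng, vertical=True)
    road = params.road_spec or _wiggly_line(params, rng, vertical=False)
    water = _supercover_cells(river, slope_layer).astype(np.int64)
    roads = _supercover_cells(road, slope_layer).astype(np.int64)

    land = assemble_landscape(
        slope_layer, layer(cover), layer(water), layer(roads), rules=rules
    )
    if params.n_ridges > 0 and len(suitable_cells(land, rules)) == 0:
        raise ValueError(
            "synthetic landscape has no suitable cell: every passable cell is "
            "farther than the acceptance distance from escape terrain; "
            "increase n_ridges or lower cover_mean"
        )
    return land


def make_synthetic_occurrences(
    landscape: RasterLandscape,
    n: int,
    rules: MovementRules = DEFAULT_RULES,
    rng_seed: int = 0,
) -> OccurrenceSet:
    """Sample ``n`` occurrence points uniformly from suitable cells.

    Cells may repeat; each point is jittered uniformly within its cell,
    mimicking sightings concentrated in good habitat near escape
    terrain.  Deterministic given the seed.
    """
    if n <= 0:
        raise ValueError("no occurrences requested (n must be >= 1)")
    cells = suitable_cells(landscape, rules)
    if len(cells) == 0:
        raise ValueError("landscape has no suitable cells to place occurrences in")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    idx = rng.integers(len(cells), size=n)
    points = []
    cs = landscape.cell_size
    ref = landscape.slope
    for r, c in cells[idx]:
        x = ref.origin_x + (c + rng.uniform(0.05, 0.95)) * cs
        y = ref.origin_y - (r + rng.uniform(0.05, 0.95)) * cs
        points.append((float(x), float(y)))
    return OccurrenceSet(points=points)
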