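"""Usage-map accumulation, normalization, road-crossing extraction, validation.

Every cell an agent occupies — the seed cell and every revisit — adds one
to the per-pixel usage count.  The connectivity surface reported to end
users is the *relative frequency of use*: each count divided by the count
of the most-used pixel, with never-used pixels carried as nodata rather
than zero (they are "white" on the maps, not merely rare).

The road-permeability scenario is post-processed here too: among road
pixels that agents actually used, the top fraction (10% by default,
nearest-rank with ties at the cutoff included) are flagged as priority
crossing sites.  Model calibration is summarised by the occurrence
coverage: the fraction of known occurrence points whose pixel was used
at least once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .landscape import Cell, GridLayer, RasterLandscape, write_grid
from .movement import Trajectory

__all__ = [
    "UsageMap",
    "CrossingReport",
    "accumulate_trajectory",
    "relative_frequency",
    "road_crossing_sites",
    "occurrence_coverage",
    "write_usage_raster",
]

#: nodata value written for never-used pixels in relative-frequency rasters.
REL_FREQ_NODATA = -9999.0


@dataclass
class UsageMap:
    """Per-pixel visit-count accumulator aligned to a landscape."""

    counts: np.ndarray
    n_trajectories: int = 0
    metadata: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, landscape: RasterLandscape, **metadata) -> "UsageMap":
        return cls(
            counts=np.zeros(landscape.shape, dtype=np.int64),
            n_trajectories=0,
            metadata=dict(metadata),
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class CrossingReport:
    """Ranked road pixels by usage, with the top-fraction subset flagged.

    ``table`` columns: row, col, x, y, count, rank, highlighted —
    sorted by count descending (row/col break ties deterministically).
    """

    table: pd.DataFrame
    fraction: float

    @property
    def highlighted(self) -> pd.DataFrame:
        return self.table[self.table["highlighted"]]

    def __len__(self) -> int:
        return len(self.table)


def accumulate_trajectory(usage: UsageMap, traj: Trajectory) -> UsageMap:
    """Add one trajectory's occupancies to the usage map (in place).

    Each visited cell — the seed included — is incremented once per
    visit, so revisits count again.
    """
    n_rows, n_cols = usage.counts.shape
    rows = np.fromiter((c.row for c in traj.cells), dtype=np.intp, count=len(traj.cells))
    cols = np.fromiter((c.col for c in traj.cells), dtype=np.intp, count=len(traj.cells))
    if len(rows) and (
        rows.min() < 0 or rows.max() >= n_rows or cols.min() < 0 or cols.max() >= n_cols
    ):
        raise ValueError("trajectory visits cells outside the usage-map extent")
    np.add.at(usage.counts, (rows, cols), 1)
    usage.n_trajectories += 1
    return usage


def relative_frequency(usage: UsageMap) -> np.ndarray:
    """Counts divided by the most-used pixel's count; NaN where never used.

    The maximum over used cells is exactly 1; never-used cells are NaN so
    downstream rasters can carry them as nodata instead of zero.
    """
    max_count = usage.counts.max()
    if max_count <= 0:
        raise ValueError("usage map has no positive counts")
    rel = usage.counts / float(max_count)
    rel[usage.counts == 0] = np.nan
    return rel


def road_crossing_sites(
    usage: UsageMap,
    roads: GridLayer,
    landscape: RasterLandscape,
    fraction: float = 0.10,
) -> CrossingReport:
    """Rank used road pixels by count and flag the top fraction.

    Candidates are road pixels with count > 0 (a road pixel no agent
    crossed is not a crossing site).  The highlighted subset is the
    nearest-rank top ``ceil(fraction * N)`` by count; ties at the cutoff
    count are all included, so the subset may be larger.  An empty
    candidate set yields an empty (not erroneous) report.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    road = (np.asarray(roads.values) != 0) & ~roads.nodata_mask()
    used = road & (usage.counts > 0)
    rows, cols = np.nonzero(used)
    counts = usage.counts[rows, cols]
    order = np.lexsort((cols, rows, -counts))
    rows, cols, counts = rows[order], cols[order], counts[order]
    n = len(rows)
    highlighted = np.zeros(n, dtype=bool)
    if n:
        k = ceil(fraction * n)
        cutoff = counts[k - 1]
        highlighted = counts >= cutoff
    xy = [landscape.center_of(Cell(int(r), int(c))) for r, c in zip(rows, cols)]
    table = pd.DataFrame(
        {
            "row": rows.astype(int),
            "col": cols.astype(int),
            "x": [p[0] for p in xy],
            "y": [p[1] for p in xy],
            "count": counts.astype(int),
            "rank": np.arange(1, n + 1),
            "highlighted": highlighted,
        }
    )
    return CrossingReport(table=table, fraction=fraction)


def occurrence_coverage(
    usage: UsageMap, occurrences, landscape: RasterLandscape
) -> float:
    """Fraction of occurrence points whose pixel was used at least once."""
    points = getattr(occurrences, "points", occurrences)
    if len(points) == 0:
        raise ValueError("occurrence set is empty")
    hit = 0
    for x, y in points:
        cell = landscape.cell_of(x, y)
        if landscape.in_extent(cell) and usage.counts[cell.row, cell.col] > 0:
            hit += 1
    return hit / len(points)


def write_usage_raster(
    usage_or_grid,
    path: str,
    landscape: RasterLandscape,
    format: str | None = None,
) -> None:
    """Write counts (integer band) or relative frequency (float band).

    Relative-frequency grids carry never-used cells as the nodata value;
    count grids roundtrip bit-exact through :func:`hornwalk.read_grid`.
    """
    if isinstance(usage_or_grid, UsageMap):
        values = usage_or_grid.counts
        nodata = None
    else:
        values = np.asarray(usage_or_grid, dtype=np.float32)
        nodata = REL_FREQ_NODATA
        values = np.where(np.isnan(values), np.float32(nodata), values)
    if values.shape != landscape.shape:
        raise ValueError(
            f"grid shape {values.shape} does not match landscape {landscape.shape}"
        )
    ref = landscape.slope
    layer = GridLayer(
        values=values,
        origin_x=ref.origin_x,
        origin_y=ref.origin_y,
        cell_size=ref.cell_size,
        nodata=nodata,
    )
    write_grid(layer, path, format)
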