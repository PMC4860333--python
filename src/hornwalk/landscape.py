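"""Raster landscape assembly for the bighorn sheep movement model.

The simulation environment is a stack of aligned single-band rasters:
slope (degrees), percent crown cover, a water mask (lakes and rivers
merged) and a road mask.  From the slope layer two grids are derived at
assembly time and cached on the landscape:

* the *escape terrain* mask — cells whose slope strictly exceeds the
  escape-slope threshold (40 degrees by default); bighorn sheep use such
  steep, rocky ground to evade predators and stay close to it, and
* the *distance to escape terrain*, either an exact Euclidean distance
  transform (centre to centre, in metres) or a Chebyshev "grid ring"
  count multiplied by the cell size.

Movement behaviour itself lives in :mod:`hornwalk.movement`; this module
owns the spatial data model, the raster I/O (ESRI ASCII grids and
single-band GeoTIFF) and the per-cell habitat rules: passability and the
exponential distance-decay movement probability
``p(d) = a * exp(-b * d)`` with ``a = 188.21`` percent and
``b = 0.0016`` per metre.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Cell",
    "GridLayer",
    "MovementRules",
    "RasterLandscape",
    "DEFAULT_RULES",
    "NO_ESCAPE",
    "read_grid",
    "write_grid",
    "assemble_landscape",
    "escape_mask",
    "escape_distance",
    "is_passable",
    "movement_probability",
]

#: Sentinel distance used where the landscape contains no escape terrain.
NO_ESCAPE = math.inf

# GeoTIFF tag codes used for georeferencing single-band rasters.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class Cell(NamedTuple):
    """0-based (row, col) grid index; row 0 is the north edge.

    Instances are plain value tuples and may carry indices outside the
    raster extent — callers distinguish in-extent cells from exit
    markers with :meth:`RasterLandscape.in_extent`.
    """

    row: int
    col: int


@dataclass(frozen=True)
class MovementRules:
    """Behavioural thresholds and distance-decay constants.

    Defaults encode the field-calibrated bighorn rules: escape terrain
    is any slope strictly greater than 40 degrees; cells within 400 m of
    escape terrain are accepted outright; beyond that, acceptance is a
    chance draw against ``prob_coef_a * exp(-prob_rate_b * distance)``
    percent.  Cells with more than 40% crown cover, roads, or water are
    never occupied (each rule individually switchable for the
    management scenarios).
    """

    slope_threshold_deg: float = 40.0
    cover_threshold_pct: float = 40.0
    escape_accept_dist_m: float = 400.0
    prob_coef_a: float = 188.21
    prob_rate_b: float = 0.0016
    max_steps: int = 2000
    cover_rule_enabled: bool = True
    roads_block: bool = True
    water_blocks: bool = True
    distance_metric: str = "euclidean"

    def __post_init__(self) -> None:
        for name in (
            "slope_threshold_deg",
            "cover_threshold_pct",
            "escape_accept_dist_m",
            "prob_coef_a",
            "prob_rate_b",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.distance_metric not in ("euclidean", "grid_ring"):
            raise ValueError(
                f"distance_metric must be 'euclidean' or 'grid_ring', "
                f"got {self.distance_metric!r}"
            )

    def with_overrides(self, **kwargs) -> "MovementRules":
        return replace(self, **kwargs)


DEFAULT_RULES = MovementRules()


@dataclass
class GridLayer:
    """One raster band with a north-up, square-cell geotransform.

    ``origin_x``/``origin_y`` locate the *top-left corner* of cell
    (0, 0) in map units (metres); values are row-major with row 0 at the
    north edge.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask of nodata cells (NaN always counts as nodata)."""
        mask = np.zeros(self.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating):
            mask |= np.isnan(self.values)
        if self.nodata is not None and not (
            isinstance(self.nodata, float) and math.isnan(self.nodata)
        ):
            mask |= self.values == self.nodata
        return mask

    def aligned_with(self, other: "GridLayer") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
        )

    def cell_of(self, x: float, y: float) -> Cell:
        """Map coordinates -> cell by the floor convention.

        A point on a shared cell edge belongs to the cell with the
        larger index (floor of the offset in cell units).
        """
        col = math.floor((x - self.origin_x) / self.cell_size)
        row = math.floor((self.origin_y - y) / self.cell_size)
        return Cell(row, col)

    def center_of(self, cell: Cell) -> tuple[float, float]:
        x = self.origin_x + (cell.col + 0.5) * self.cell_size
        y = self.origin_y - (cell.row + 0.5) * self.cell_size
        return x, y


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid and single-band GeoTIFF
# ---------------------------------------------------------------------------

def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".asc", ".txt", ".grd"):
        return "esri_ascii"
    if ext in (".tif", ".tiff"):
        return "geotiff"
    raise ValueError(f"cannot infer raster format from extension of {path!r}")


def _read_esri_ascii(path: str) -> GridLayer:
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    else:
        raise ValueError(f"{path}: header-only ESRI ASCII grid, no data rows")
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field {key!r}")
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - header["cellsize"] / 2
        yll = header["yllcenter"] - header["cellsize"] / 2
    else:
        raise ValueError(f"{path}: missing georeferencing (xllcorner/xllcenter)")
    values = np.loadtxt(lines[data_start:], ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    if np.allclose(values, np.round(values)) and np.abs(values).max(initial=0) < 2**31:
        values = values.astype(np.int64)
    nodata = header.get("nodata_value")
    cell = header["cellsize"]
    return GridLayer(
        values=values,
        origin_x=xll,
        origin_y=yll + n_rows * cell,
        cell_size=cell,
        nodata=nodata,
    )


def _write_esri_ascii(layer: GridLayer, path: str) -> None:
    nodata = layer.nodata if layer.nodata is not None else -9999
    integer = np.issubdtype(layer.values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {layer.n_cols}\n")
        fh.write(f"nrows {layer.n_rows}\n")
        fh.write(f"xllcorner {layer.origin_x:.6f}\n")
        yll = layer.origin_y - layer.n_rows * layer.cell_size
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {layer.cell_size:.6f}\n")
        fh.write(f"NODATA_value {int(nodata) if integer else nodata}\n")
        vals = layer.values
        if np.issubdtype(vals.dtype, np.floating):
            vals = np.where(np.isnan(vals), nodata, vals)
        fmt = "%d" if integer else "%.8g"
        np.savetxt(fh, vals, fmt=fmt)


def _read_geotiff(path: str) -> GridLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = {tag.code: tag.value for tag in page.tags.values()}
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = float(tags[_TAG_MODEL_PIXEL_SCALE][0]), float(tags[_TAG_MODEL_PIXEL_SCALE][1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise ValueError(f"{path}: non-square cells ({sx} x {sy} m)")
    tie = tags[_TAG_MODEL_TIEPOINT]
    # tiepoint maps raster (i, j) -> map (x, y); anchor at the top-left corner
    origin_x = float(tie[3]) - float(tie[0]) * sx
    origin_y = float(tie[4]) + float(tie[1]) * sy
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
    return GridLayer(
        values=values, origin_x=origin_x, origin_y=origin_y,
        cell_size=sx, nodata=nodata,
    )


def _write_geotiff(layer: GridLayer, path: str) -> None:
    import tifffile

    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (layer.cell_size, layer.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, layer.origin_x, layer.origin_y, 0.0)),
    ]
    if layer.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(layer.nodata)))
    values = layer.values
    if values.dtype == np.int64:
        values = values.astype(np.int32)
    tifffile.imwrite(path, values, extratags=extratags)


def read_grid(path: str, format: str | None = None) -> GridLayer:
    """Read a single-band raster (ESRI ASCII grid or GeoTIFF).

    Rejects multi-band files and non-square pixels; the format is
    inferred from the file extension when not given.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "esri_ascii":
        return _read_esri_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_grid(layer: GridLayer, path: str, format: str | None = None) -> None:
    """Write a :class:`GridLayer`, bit-exact on roundtrip for integer grids."""
    fmt = format or _detect_format(path)
    if fmt == "esri_ascii":
        _write_esri_ascii(layer, path)
    elif fmt == "geotiff":
        _write_geotiff(layer, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


# ---------------------------------------------------------------------------
# Derived grids
# ---------------------------------------------------------------------------

def escape_mask(slope: GridLayer, threshold_deg: float) -> np.ndarray:
    """Escape-terrain mask: slope strictly greater than the threshold.

    The strict inequality matters at the boundary: a 40.0-degree cell is
    *not* escape terrain under the default 40-degree threshold.  Nodata
    slope cells are never escape terrain.
    """
    if threshold_deg < 0:
        raise ValueError("threshold_deg must be >= 0")
    mask = np.asarray(slope.values, dtype=float) > threshold_deg
    mask &= ~slope.nodata_mask()
    return mask


def escape_distance(
    mask: np.ndarray, cell_size: float, metric: str = "euclidean"
) -> np.ndarray:
    """Per-cell distance (m) to the nearest escape-terrain cell.

    ``euclidean`` is the exact centre-to-centre Euclidean distance
    transform; ``grid_ring`` counts Chebyshev (chessboard) rings and
    multiplies by the cell size, so a diagonal neighbour is one cell
    away.  If the mask is empty everywhere the sentinel ``NO_ESCAPE``
    (+inf) is returned for every cell.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, NO_ESCAPE)
    if metric == "euclidean":
        return ndimage.distance_transform_edt(~mask, sampling=cell_size)
    if metric == "grid_ring":
        rings = ndimage.distance_transform_cdt(~mask, metric="chessboard")
        return rings.astype(float) * cell_size
    raise ValueError(f"unknown distance metric {metric!r}")


@dataclass
class RasterLandscape:
    """Aligned layer stack plus cached escape mask and escape distance.

    Construct with :func:`assemble_landscape`; treat as immutable once
    built (the movement engine caches per-cell lookups derived from it).
    """

    slope: GridLayer
    cover: GridLayer
    water: GridLayer
    roads: GridLayer
    rules: MovementRules
    escape: np.ndarray = field(repr=False, default=None)
    escape_distance: np.ndarray = field(repr=False, default=None)

    @property
    def n_rows(self) -> int:
        return self.slope.n_rows

    @property
    def n_cols(self) -> int:
        return self.slope.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return self.slope.shape

    @property
    def cell_size(self) -> float:
        return self.slope.cell_size

    @property
    def has_escape(self) -> bool:
        return bool(self.escape.any())

    def in_extent(self, cell: Cell) -> bool:
        return 0 <= cell.row < self.n_rows and 0 <= cell.col < self.n_cols

    def cell_of(self, x: float, y: float) -> Cell:
        return self.slope.cell_of(x, y)

    def center_of(self, cell: Cell) -> tuple[float, float]:
        return self.slope.center_of(cell)

    def nodata_any(self) -> np.ndarray:
        """Cells where any input layer is nodata (impassable by policy)."""
        return (
            self.slope.nodata_mask()
            | self.cover.nodata_mask()
            | self.water.nodata_mask()
            | self.roads.nodata_mask()
        )

    def water_mask(self) -> np.ndarray:
        return (np.asarray(self.water.values) != 0) & ~self.water.nodata_mask()

    def road_mask(self) -> np.ndarray:
        return (np.asarray(self.roads.values) != 0) & ~self.roads.nodata_mask()

    def passable_grid(self, rules: MovementRules | None = None) -> np.ndarray:
        """Vectorised :func:`is_passable` over the whole raster."""
        rules = rules or self.rules
        ok = ~self.nodata_any()
        if rules.water_blocks:
            ok &= ~self.water_mask()
        if rules.roads_block:
            ok &= ~self.road_mask()
        if rules.cover_rule_enabled:
            cover = np.asarray(self.cover.values, dtype=float)
            ok &= ~(cover > rules.cover_threshold_pct)
        return ok


def assemble_landscape(
    slope: GridLayer,
    cover: GridLayer,
    water: GridLayer,
    roads: GridLayer,
    rules: MovementRules = DEFAULT_RULES,
) -> RasterLandscape:
    """Validate alignment and ranges, derive escape grids, build the landscape.

    Raises on misaligned layers, slope outside [0, 90] or cover outside
    [0, 100] (nodata cells exempt).
    """
    for name, layer in (("cover", cover), ("water", water), ("roads", roads)):
        if not slope.aligned_with(layer):
            raise ValueError(
                f"{name} layer is not aligned with the slope layer "
                f"(shape/origin/cell size must match)"
            )
    slope_vals = np.asarray(slope.values, dtype=float)
    valid = ~slope.nodata_mask()
    if valid.any() and (
        (slope_vals[valid] < 0).any() or (slope_vals[valid] > 90).any()
    ):
        raise ValueError("slope values outside [0, 90] degrees")
    cover_vals = np.asarray(cover.values, dtype=float)
    cvalid = ~cover.nodata_mask()
    if cvalid.any() and (
        (cover_vals[cvalid] < 0).any() or (cover_vals[cvalid] > 100).any()
    ):
        raise ValueError("crown cover values outside [0, 100] percent")

    esc = escape_mask(slope, rules.slope_threshold_deg)
    dist = escape_distance(esc, slope.cell_size, rules.distance_metric)
    return RasterLandscape(
        slope=slope, cover=cover, water=water, roads=roads,
        rules=rules, escape=esc, escape_distance=dist,
    )


def is_passable(
    landscape: RasterLandscape, cell: Cell, rules: MovementRules | None = None
) -> bool:
    """Whether a sheep may occupy ``cell`` under the habitat rules.

    False for roads (when roads block), water (when water blocks), crown
    cover strictly above the threshold (when the cover rule is on), and
    for nodata in any consulted layer.  Out-of-extent cells are a caller
    error — extent is handled before passability.
    """
    rules = rules or landscape.rules
    if not landscape.in_extent(cell):
        raise IndexError(f"cell {cell} is outside the raster extent")
    r, c = cell
    if landscape.nodata_any()[r, c]:
        return False
    if rules.water_blocks and landscape.water_mask()[r, c]:
        return False
    if rules.roads_block and landscape.road_mask()[r, c]:
        return False
    if rules.cover_rule_enabled:
        if float(landscape.cover.values[r, c]) > rules.cover_threshold_pct:
            return False
    return True


def movement_probability(distance: float, rules: MovementRules = DEFAULT_RULES) -> float:
    """Percent chance of moving to a cell ``distance`` metres from escape terrain.

    Evaluates ``a * exp(-b * distance)``; strictly decreasing, and may
    exceed 100 near escape terrain (acceptance logic caps the *effect*,
    not the value).
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return rules.prob_coef_a * math.exp(-rules.prob_rate_b * distance)
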