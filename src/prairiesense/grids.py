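"""Local metric raster grids and resampling between them.

All rasters in the package live on axis-aligned grids in a local metric
coordinate system: x increases eastward, y northward, the origin is the
lower-left corner of the scene, and pixel centers sit at half-integer
multiples of the ground sample distance (gsd).  Arrays are row-major with
row 0 at the *top* (northernmost) of the scene, matching image convention.

Two resampling schemes are provided:

* area-weighted box averaging (used to bring 1-m truth fields onto the
  coarser thermal grid — radiance-like fields mix linearly over area);
* nearest-center lookup (used to put the 1-m NDVI map onto the thermal
  grid, one source pixel per target pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, RangeError


@dataclass(frozen=True)
class Grid:
    """An axis-aligned raster grid in scene meters.

    Parameters
    ----------
    x0, y0:
        Lower-left corner of the gridded extent, meters.
    gsd:
        Ground sample distance (pixel edge length), meters.
    nrows, ncols:
        Raster shape; row 0 is the northernmost row.
    """

    x0: float
    y0: float
    gsd: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.gsd <= 0:
            raise GeometryError(f"gsd must be positive, got {self.gsd}")
        if self.nrows <= 0 or self.ncols <= 0:
            raise GeometryError("grid must have positive shape")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def x1(self) -> float:
        return self.x0 + self.ncols * self.gsd

    @property
    def y1(self) -> float:
        return self.y0 + self.nrows * self.gsd

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in scene meters."""
        return (self.x0, self.y0, self.x1, self.y1)

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.gsd

    def y_centers(self) -> np.ndarray:
        """Center y per row, row 0 first (north to south)."""
        return self.y1 - (np.arange(self.nrows) + 0.5) * self.gsd

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Pixel containing the point (x, y)."""
        if not (self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1):
            raise RangeError(
                f"point ({x}, {y}) outside grid extent {self.extent}"
            )
        col = min(int((x - self.x0) / self.gsd), self.ncols - 1)
        row = min(int((self.y1 - y) / self.gsd), self.nrows - 1)
        return row, col

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def to_meta(self) -> dict:
        return {
            "x0": self.x0,
            "y0": self.y0,
            "gsd": self.gsd,
            "nrows": self.nrows,
            "ncols": self.ncols,
        }

    @classmethod
    def from_meta(cls, meta: dict) -> "Grid":
        return cls(
            x0=float(meta["x0"]),
            y0=float(meta["y0"]),
            gsd=float(meta["gsd"]),
            nrows=int(meta["nrows"]),
            ncols=int(meta["ncols"]),
        )


def _overlap_weights(src_edges: np.ndarray, dst_edges: np.ndarray) -> np.ndarray:
    """Dense (n_dst, n_src) matrix of fractional interval overlaps.

    Row i holds, for destination interval i, the length of overlap with each
    source interval normalized by the total overlapping length, so rows sum
    to 1 wherever the destination interval intersects the source span.
    """
    n_dst = len(dst_edges) - 1
    n_src = len(src_edges) - 1
    w = np.zeros((n_dst, n_src))
    for i in range(n_dst):
        lo, hi = dst_edges[i], dst_edges[i + 1]
        left = np.maximum(src_edges[:-1], min(lo, hi))
        right = np.minimum(src_edges[1:], max(lo, hi))
        overlap = np.clip(right - left, 0.0, None)
        total = overlap.sum()
        if total > 0:
            w[i] = overlap / total
    return w


def box_average(field: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    """Area-weighted average of ``field`` (on ``src``) onto ``dst``.

    Destination pixels integrate the source field over their footprint with
    weights proportional to overlap area — the correct operation for
    quantities that mix linearly over area (radiance, cover fractions).
    """
    if field.shape != src.shape:
        raise GeometryError(
            f"field shape {field.shape} does not match grid {src.shape}"
        )
    if dst.x1 <= src.x0 or dst.x0 >= src.x1 or dst.y1 <= src.y0 or dst.y0 >= src.y1:
        raise GeometryError("grids have disjoint extents")
    src_x = src.x0 + np.arange(src.ncols + 1) * src.gsd
    dst_x = dst.x0 + np.arange(dst.ncols + 1) * dst.gsd
    # y edges north -> south to match row order
    src_y = src.y1 - np.arange(src.nrows + 1) * src.gsd
    dst_y = dst.y1 - np.arange(dst.nrows + 1) * dst.gsd
    wx = _overlap_weights(src_x, dst_x)                      # (dst_cols, src_cols)
    wy = _overlap_weights(-src_y, -dst_y)                    # monotone increasing trick
    return wy @ field @ wx.T


def nearest_index_map(src: Grid, dst: Grid) -> tuple[np.ndarray, np.ndarray]:
    """For each dst pixel center, the (row, col) of the nearest src center.

    Ties at exact midpoints resolve to the lower index (row-major order).
    """
    if dst.x1 <= src.x0 or dst.x0 >= src.x1 or dst.y1 <= src.y0 or dst.y0 >= src.y1:
        raise GeometryError("grids have disjoint extents")

    def nearest(
        src_centers: np.ndarray, dst_centers: np.ndarray, ties_left: bool
    ) -> np.ndarray:
        # src_centers must be sorted ascending
        idx = np.searchsorted(src_centers, dst_centers)
        idx = np.clip(idx, 1, len(src_centers) - 1)
        left = src_centers[idx - 1]
        right = src_centers[idx]
        d_left = dst_centers - left
        d_right = right - dst_centers
        choose_left = d_left <= d_right if ties_left else d_left < d_right
        return np.where(choose_left, idx - 1, idx)

    # columns: ascending centers; exact ties resolve to the lower column
    cols = nearest(src.x_centers(), dst.x_centers(), ties_left=True)
    # rows: work in ascending (south->north) order, where the lower original
    # row index is on the *right*; ties therefore resolve rightward
    asc = nearest(src.y_centers()[::-1], dst.y_centers(), ties_left=False)
    rows = src.nrows - 1 - asc
    return rows, cols


def resample_nearest(field: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    rows, cols = nearest_index_map(src, dst)
    return field[np.ix_(rows, cols)]


def sample_at(
    field: np.ndarray,
    grid: Grid,
    x: float,
    y: float,
    footprint: int = 1,
) -> float:
    """Value at a coordinate: nearest pixel, or mean of an n-by-n window.

    Missing pixels (NaN) propagate: the window mean is NaN if every pixel in
    it is missing, otherwise the mean of the finite pixels.
    """
    if footprint < 1 or footprint % 2 == 0:
        raise ValueError("footprint must be an odd positive integer")
    row, col = grid.rowcol(x, y)
    h = footprint // 2
    r0, r1 = max(row - h, 0), min(row + h + 1, grid.nrows)
    c0, c1 = max(col - h, 0), min(col + h + 1, grid.ncols)
    window = field[r0:r1, c0:c1]
    if np.all(np.isnan(window)):
        return float("nan")
    return float(np.nanmean(window))


def polygon_mean(
    field: np.ndarray,
    grid: Grid,
    polygon,
    edge_buffer_m: float = 0.0,
) -> float:
    """Mean of pixels whose centers fall inside ``polygon`` shrunk by a buffer."""
    from shapely.geometry import Point

    poly = polygon.buffer(-edge_buffer_m) if edge_buffer_m > 0 else polygon
    if poly.is_empty:
        raise GeometryError("edge buffer removed the whole polygon")
    xs = grid.x_centers()
    ys = grid.y_centers()
    minx, miny, maxx, maxy = poly.bounds
    cmask = (xs >= minx) & (xs <= maxx)
    rmask = (ys >= miny) & (ys <= maxy)
    vals = []
    for r in np.nonzero(rmask)[0]:
        for c in np.nonzero(cmask)[0]:
            if poly.contains(Point(xs[c], ys[r])):
                vals.append(field[r, c])
    if not vals:
        return float("nan")
    return float(np.nanmean(vals))
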