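"""Experimental layout and field sampling designs.

The simulated experiment mirrors a blocked prairie restoration trial:
eight blocks of three plots each (24 plots), every block holding one plot
per seeding level (control / mid / high diversity), with whole blocks
assigned to annual haying or spring burning.  Plots are 80 m x 50 m
(~0.40 ha) rectangles on a local metric grid.

Two sampling designs are generated per plot:

* the vegetation survey design — the plot center, meter-7 and meter-14
  points on four 15-m transects in the cardinal directions (9 points), plus
  six 2 x 3 subplots spaced 30 m apart along the east-west axis
  (15 locations in total);
* the ground-spectroscopy design — one position at every meter along the
  four 15-m transects (60 positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .errors import ConfigError, GeometryError

SEEDINGS = ("control", "mid", "high")
MANAGEMENTS = ("burn", "hay")

#: plot footprint, meters (east-west, north-south); ~0.40 ha
PLOT_W = 80.0
PLOT_H = 50.0


@dataclass(frozen=True)
class PlotRecord:
    plot_id: int
    block_id: int
    seeding: str
    management: str
    polygon: Polygon


@dataclass
class ExperimentLayout:
    """Blocks, plots and their treatment assignments in scene meters."""

    plots: list[PlotRecord]
    extent: tuple[float, float]   # scene (width, height), meters

    @property
    def n_blocks(self) -> int:
        return len({p.block_id for p in self.plots})

    def plot(self, plot_id: int) -> PlotRecord:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "block_id": [p.block_id for p in self.plots],
                "seeding": [p.seeding for p in self.plots],
                "management": [p.management for p in self.plots],
            }
        )


@dataclass(frozen=True)
class LayoutConfig:
    """Geometry of the simulated experiment."""

    extent: tuple[float, float] = (600.0, 400.0)
    n_blocks: int = 8
    plot_w: float = PLOT_W
    plot_h: float = PLOT_H
    plot_gap: float = 10.0       # between plots within a block
    margin: float = 20.0         # scene edge margin
    block_gap_y: float = 40.0    # vertical spacing between block rows


def make_layout(config: LayoutConfig = LayoutConfig(), seed: int = 0) -> ExperimentLayout:
    """Deterministically place blocks and assign treatments.

    Blocks are laid out in two columns; odd-numbered blocks burn, even ones
    hay (alternating, as in the field experiment).  Seeding levels are
    shuffled within each block from ``seed``.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    block_w = 3 * cfg.plot_w + 2 * cfg.plot_gap
    n_cols = 2 if cfg.n_blocks > 1 else 1
    n_rows = int(np.ceil(cfg.n_blocks / n_cols))
    need_w = cfg.margin * 2 + n_cols * block_w + (n_cols - 1) * cfg.plot_gap * 3
    need_h = cfg.margin * 2 + n_rows * cfg.plot_h + (n_rows - 1) * cfg.block_gap_y
    if need_w > cfg.extent[0] or need_h > cfg.extent[1]:
        raise ConfigError(
            f"scene extent {cfg.extent} too small: need at least "
            f"({need_w:.0f}, {need_h:.0f}) m for {cfg.n_blocks} blocks"
        )
    plots: list[PlotRecord] = []
    plot_id = 1
    for b in range(cfg.n_blocks):
        col, row = b % n_cols, b // n_cols
        bx = cfg.margin + col * (block_w + cfg.plot_gap * 3)
        by = cfg.margin + row * (cfg.plot_h + cfg.block_gap_y)
        management = MANAGEMENTS[b % 2]
        seedings = list(SEEDINGS)
        rng.shuffle(seedings)
        for i, seeding in enumerate(seedings):
            x0 = bx + i * (cfg.plot_w + cfg.plot_gap)
            poly = box(x0, by, x0 + cfg.plot_w, by + cfg.plot_h)
            plots.append(
                PlotRecord(
                    plot_id=plot_id,
                    block_id=b + 1,
                    seeding=seeding,
                    management=management,
                    polygon=poly,
                )
            )
            plot_id += 1
    return ExperimentLayout(plots=plots, extent=cfg.extent)


def _plot_center(polygon: Polygon) -> tuple[float, float]:
    c = polygon.centroid
    return float(c.x), float(c.y)


def _check_plot_size(polygon: Polygon) -> None:
    minx, miny, maxx, maxy = polygon.bounds
    if min(maxx - minx, maxy - miny) < 30.0:
        raise GeometryError(
            "plot must be at least 30 m across for 15-m transects "
            f"(bounds {polygon.bounds})"
        )


def make_survey_design(
    layout: ExperimentLayout,
    include_subplots: bool = True,
    subplot_spacing: float = 30.0,
) -> pd.DataFrame:
    """Vegetation sampling locations for every plot.

    Per plot: the center, meter-7 and meter-14 points on four 15-m
    transects (N, S, E, W), and (optionally) a 2 x 3 subplot array along
    the east-west axis — 15 locations when subplots are included.

    Returns a frame with plot_id, location_id, x, y, location_type.
    """
    rows = []
    for p in layout.plots:
        _check_plot_size(p.polygon)
        cx, cy = _plot_center(p.polygon)
        loc = 1
        rows.append((p.plot_id, loc, cx, cy, "center"))
        loc += 1
        for dx, dy, tag in ((0, 1, "N"), (0, -1, "S"), (1, 0, "E"), (-1, 0, "W")):
            for m in (7.0, 14.0):
                rows.append(
                    (p.plot_id, loc, cx + dx * m, cy + dy * m, f"transect_{tag}")
                )
                loc += 1
        if include_subplots:
            s = subplot_spacing
            for j, dy in enumerate((s / 2, -s / 2)):
                for i, dx in enumerate((-s, 0.0, s)):
                    x, y = cx + dx, cy + dy
                    if not p.polygon.buffer(1e-9).contains(Point(x, y)):
                        raise GeometryError(
                            f"subplot ({x:.1f}, {y:.1f}) falls outside plot "
                            f"{p.plot_id}; plot too small for {s} m spacing"
                        )
                    rows.append((p.plot_id, loc, x, y, "subplot"))
                    loc += 1
    return pd.DataFrame(
        rows, columns=["plot_id", "location_id", "x", "y", "location_type"]
    )


def make_spectral_design(polygon: Polygon) -> pd.DataFrame:
    """Ground-spectroscopy positions: every meter along four 15-m transects.

    Transects run north, south, east and west from the plot center; one
    position per meter (1..15 m), 60 positions in total.
    """
    _check_plot_size(polygon)
    cx, cy = _plot_center(polygon)
    rows = []
    pos = 1
    for dx, dy, tag in ((0, 1, "N"), (0, -1, "S"), (1, 0, "E"), (-1, 0, "W")):
        for m in range(1, 16):
            rows.append((pos, cx + dx * m, cy + dy * m, tag))
            pos += 1
    return pd.DataFrame(rows, columns=["position_id", "x", "y", "transect"])
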