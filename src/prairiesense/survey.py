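"""Quadrat percent-cover tables to diversity and composition variables.

Cover tables hold one row per (location, species-or-ground) with percent
cover in a 1-m2 quadrat; ``litter`` and ``bare_soil`` rows record ground
cover and are excluded from all diversity computations.  Shannon indices
use the natural log (the vegan convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Point

from .errors import DataError
from .layout import ExperimentLayout

logger = logging.getLogger(__name__)

GROUND_ROWS = ("litter", "bare_soil")


def edge_filter(
    table: pd.DataFrame, layout: ExperimentLayout, buffer_m: float = 5.0
) -> pd.DataFrame:
    """Drop rows sampled within ``buffer_m`` of their plot's boundary.

    Locations outside their plot entirely are a data error (listed in the
    message); a zero buffer returns the table unchanged.
    """
    if buffer_m < 0:
        raise ValueError("buffer must be non-negative")
    locs = table[["plot_id", "location_id", "x", "y"]].drop_duplicates()
    offenders = []
    keep: set[tuple[int, int]] = set()
    for rec in locs.itertuples(index=False):
        poly = layout.plot(rec.plot_id).polygon
        pt = Point(rec.x, rec.y)
        if not poly.buffer(1e-9).contains(pt):
            offenders.append((rec.plot_id, rec.location_id))
            continue
        if buffer_m == 0 or poly.exterior.distance(pt) >= buffer_m:
            keep.add((rec.plot_id, rec.location_id))
    if offenders:
        raise DataError(f"locations outside their plot: {offenders}")
    mask = [
        (pid, lid) in keep
        for pid, lid in zip(table["plot_id"], table["location_id"])
    ]
    out = table[mask].reset_index(drop=True)
    n_dropped = len(locs) - len(keep)
    if n_dropped:
        logger.info("edge filter dropped %d of %d locations", n_dropped, len(locs))
    return out


def _shannon(covers: np.ndarray) -> float:
    covers = covers[covers > 0]
    if covers.size == 0:
        return 0.0
    p = covers / covers.sum()
    return float(-(p * np.log(p)).sum())


def diversity_metrics(
    table: pd.DataFrame, functional_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-location richness, Shannon indices and cover fractions.

    Richness counts species with cover > 0; Shannon uses relative covers
    among vegetation rows (ground rows excluded), in nats.  Functional
    Shannon aggregates covers to {C3, C4, forb} and requires every species
    to be mapped.
    """
    records = []
    for (pid, lid), grp in table.groupby(["plot_id", "location_id"], sort=True):
        veg = grp[~grp["species"].isin(GROUND_ROWS)]
        veg = veg[veg["percent_cover"] > 0]
        covers = veg["percent_cover"].to_numpy(dtype=float)
        richness = len(veg)
        h_species = _shannon(covers)
        h_functional = np.nan
        if functional_map is not None:
            unmapped = set(veg["species"]) - set(functional_map)
            if unmapped:
                raise DataError(f"species without functional group: {sorted(unmapped)}")
            groups = veg["species"].map(functional_map)
            agg = veg.groupby(groups)["percent_cover"].sum().to_numpy(dtype=float)
            h_functional = _shannon(agg)
        ground = grp[grp["species"].isin(GROUND_ROWS)]
        litter = float(ground.loc[ground["species"] == "litter", "percent_cover"].sum())
        bare = float(ground.loc[ground["species"] == "bare_soil", "percent_cover"].sum())
        rec = {
            "plot_id": pid,
            "location_id": lid,
            "richness": richness,
            "shannon_species": h_species,
            "shannon_functional": h_functional,
            "veg_cover": float(covers.sum()),
            "litter_cover": litter,
            "bare_soil_cover": bare,
        }
        if functional_map is not None:
            fg_cover = veg.groupby(veg["species"].map(functional_map))[
                "percent_cover"
            ].sum()
            total = covers.sum()
            for fg in ("C3", "C4", "forb"):
                rec[f"{fg}_cover"] = float(fg_cover.get(fg, 0.0))
                rec[f"{fg}_share"] = (
                    float(fg_cover.get(fg, 0.0)) / total if total > 0 else np.nan
                )
        records.append(rec)
    return pd.DataFrame(records)


def relative_cover_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Plot x species relative-cover matrix.

    Species covers are first averaged over each plot's retained locations,
    then normalized by total vegetation cover (ground rows excluded) so
    rows sum to 1.  Plots with zero vegetation are excluded with a warning.
    """
    veg = table[~table["species"].isin(GROUND_ROWS)]
    n_locs = veg.groupby("plot_id")["location_id"].nunique()
    sums = veg.pivot_table(
        index="plot_id", columns="species", values="percent_cover",
        aggfunc="sum", fill_value=0.0,
    )
    mat = sums.div(n_locs, axis=0)           # mean cover across locations
    totals = mat.sum(axis=1)
    no_rows = sorted(set(table["plot_id"]) - set(mat.index))
    empty = totals[totals <= 0].index.tolist() + no_rows
    if empty:
        warnings.warn(
            f"plots with zero vegetation excluded: {sorted(empty)}", stacklevel=2
        )
        mat = mat.drop(index=[p for p in empty if p in mat.index])
        totals = totals.loc[mat.index]
    return mat.div(totals, axis=0)


def rare_species_filter(
    matrix: pd.DataFrame,
    threshold_percent: float = 5.0,
    rule: str = "max",
) -> pd.DataFrame:
    """Drop species whose relative cover never reaches the threshold.

    ``rule='max'`` (default) removes species whose maximum relative cover
    across plots is below ``threshold_percent`` (of total vegetation);
    ``rule='mean'`` uses the across-plot mean instead.  The operation is
    idempotent.  The matrix is taken to be in fractions (rows sum to 1).
    """
    if rule not in ("max", "mean"):
        raise ValueError(f"rule must be 'max' or 'mean', got {rule!r}")
    stat = matrix.max(axis=0) if rule == "max" else matrix.mean(axis=0)
    keep = stat >= threshold_percent / 100.0
    removed = int((~keep).sum())
    logger.info(
        "rare-species filter: retained %d, removed %d species (rule=%s, %.1f%%)",
        int(keep.sum()), removed, rule, threshold_percent,
    )
    return matrix.loc[:, keep]


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between rows.

    d(j, k) = sum|x_j - x_k| / sum(x_j + x_k), in [0, 1]; pairs of all-zero
    rows are undefined and flagged missing (NaN).
    """
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("Bray-Curtis requires a non-negative matrix")
    with np.errstate(invalid="ignore"):
        dm = squareform(pdist(values, metric="braycurtis"))
    zero = values.sum(axis=1) == 0
    dm[np.ix_(zero, zero)] = np.nan
    np.fill_diagonal(dm, np.where(zero, np.nan, 0.0))
    return pd.DataFrame(dm, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class BoxSummary:
    group: tuple
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


def box_summary(
    values: pd.Series | np.ndarray,
    groups: pd.DataFrame | pd.Series | None = None,
) -> list[BoxSummary]:
    """Tukey box-plot summaries per group.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    points within 1.5 IQR of the quartiles; points beyond are outliers.
    Empty groups are omitted with a warning.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    if groups is None:
        grouped = {(): values}
    else:
        gframe = pd.DataFrame(groups).reset_index(drop=True)
        grouped = {
            key if isinstance(key, tuple) else (key,): values[grp.index]
            for key, grp in gframe.groupby(list(gframe.columns), sort=True)
        }
    out = []
    for key, vals in grouped.items():
        vals = vals.dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"empty group {key} omitted from box summary", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
        out.append(
            BoxSummary(
                group=key,
                n=int(vals.size),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_lo=float(inside.min()),
                whisker_hi=float(inside.max()),
                outliers=tuple(sorted(float(v) for v in outliers)),
            )
        )
    return out
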