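"""Diversity-energy-balance linkage: grouped OLS regressions and ANCOVA.

For each remote-sensing response (NDVI, WBI, albedo, surface temperature)
against a field predictor (species Shannon index or C3 percent cover),
three sets of ordinary-least-squares lines are fitted: all data combined,
split by management (burn / hay), and split by seeding (control / mid /
high).  ANCOVA then tests, per grouping, whether the groups share a slope
(F-test of the interaction terms in response ~ predictor * group) and, in
the additive refit, whether intercepts differ (F-test of the group terms
in response ~ predictor + group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegeneracyError
from .vnir import extract_at

RESPONSES = ("NDVI", "WBI", "albedo", "temperature")
MIN_GROUP_N = 3


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def ols_fit(x: np.ndarray, y: np.ndarray) -> OLSFit:
    """Least-squares line with r2 and the slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < MIN_GROUP_N:
        raise DegeneracyError(f"need at least {MIN_GROUP_N} points, got {x.size}")
    if np.ptp(x) < 1e-12:
        raise DegeneracyError("constant predictor: degenerate fit")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return OLSFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p=float(res.pvalues[1]),
        n=int(x.size),
    )


def significance_code(p: float) -> str:
    """Map a p-value onto the conventional star code.

    ns for P >= 0.05, * for 0.01 <= P < 0.05, ** for 0.001 <= P < 0.01,
    *** for P < 0.001.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class AncovaResult:
    interaction_F: float
    interaction_p: float
    group_F: float
    group_p: float
    n: int


def ancova(
    data: pd.DataFrame, response: str, predictor: str, group: str
) -> AncovaResult:
    """Slope-heterogeneity and intercept tests across groups.

    The interaction test compares response ~ predictor * group against the
    additive model; the group (intercept) test compares the additive model
    against response ~ predictor.  Both p-values are reported regardless of
    the interaction outcome.
    """
    cols = [response, predictor, group]
    d = data[cols].dropna().rename(
        columns={response: "_y", predictor: "_x", group: "_g"}
    )
    counts = d.groupby("_g").size()
    if len(counts) < 2 or (counts < MIN_GROUP_N).any():
        raise DegeneracyError(
            f"ANCOVA needs >= 2 groups with >= {MIN_GROUP_N} points each; "
            f"got {counts.to_dict()}"
        )
    if np.ptp(d["_x"].to_numpy()) < 1e-12:
        raise DegeneracyError("constant predictor: rank-deficient ANCOVA")
    full = smf.ols("_y ~ _x * C(_g)", data=d).fit()
    additive = smf.ols("_y ~ _x + C(_g)", data=d).fit()
    slope_only = smf.ols("_y ~ _x", data=d).fit()
    f_int = full.compare_f_test(additive)
    f_grp = additive.compare_f_test(slope_only)
    return AncovaResult(
        interaction_F=float(f_int[0]),
        interaction_p=float(f_int[1]),
        group_F=float(f_grp[0]),
        group_p=float(f_grp[1]),
        n=int(len(d)),
    )


@dataclass
class LinkageResult:
    """Tables 3/4-style layout: overall + per-group fits + ANCOVA tests."""

    response: str
    predictor: str
    overall: OLSFit
    by_management: dict[str, OLSFit]
    by_seeding: dict[str, OLSFit]
    ancova_management: AncovaResult | None
    ancova_seeding: AncovaResult | None

    def table_row(self) -> dict:
        """One row of the r2 + significance-code summary table."""
        row = {"response": self.response, "predictor": self.predictor}
        cells = {"overall": self.overall}
        cells.update(self.by_management)
        cells.update(self.by_seeding)
        for name, fit in cells.items():
            row[name] = (
                f"{fit.r2:.3g}{significance_code(fit.p)}"
                if fit is not None else ""
            )
        return row

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for grouping, fits in (
            ("overall", {"all": self.overall}),
            ("management", self.by_management),
            ("seeding", self.by_seeding),
        ):
            for grp, fit in fits.items():
                if fit is None:
                    continue
                rows.append(
                    {
                        "response": self.response,
                        "predictor": self.predictor,
                        "grouping": grouping,
                        "group": grp,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "r2": fit.r2,
                        "p": fit.p,
                        "n": fit.n,
                        "code": significance_code(fit.p),
                    }
                )
        return pd.DataFrame(rows)


def grouped_regressions(
    data: pd.DataFrame, response: str, predictor: str
) -> LinkageResult:
    """Overall, by-management and by-seeding fits plus both ANCOVA tests.

    Groups with fewer than three points are skipped with a warning.
    """
    def fit_or_none(d: pd.DataFrame) -> OLSFit | None:
        try:
            return ols_fit(d[predictor].to_numpy(), d[response].to_numpy())
        except DegeneracyError as exc:
            warnings.warn(f"fit skipped: {exc}", stacklevel=2)
            return None

    overall = fit_or_none(data)
    by_mgmt = {
        m: fit_or_none(d) for m, d in data.groupby("management", sort=True)
    }
    by_seed = {
        s: fit_or_none(d) for s, d in data.groupby("seeding", sort=True)
    }

    def anc_or_none(group: str) -> AncovaResult | None:
        try:
            return ancova(data, response, predictor, group)
        except DegeneracyError as exc:
            warnings.warn(f"ANCOVA skipped: {exc}", stacklevel=2)
            return None

    return LinkageResult(
        response=response,
        predictor=predictor,
        overall=overall,
        by_management=by_mgmt,
        by_seeding=by_seed,
        ancova_management=anc_or_none("management"),
        ancova_seeding=anc_or_none("seeding"),
    )


def build_linkage_dataset(
    index_maps: dict,
    temperature_map,
    diversity: pd.DataFrame,
    survey: pd.DataFrame,
    layout_frame: pd.DataFrame,
    footprint: int = 1,
) -> pd.DataFrame:
    """Join per-location diversity metrics with extracted image values.

    ``index_maps`` holds the 1-m NDVI/WBI/albedo maps; the temperature map
    is sampled on its own (coarser) grid.  Locations whose extraction is
    entirely missing are listed and dropped with a warning.
    """
    locs = survey[["plot_id", "location_id", "x", "y"]].drop_duplicates()
    merged = diversity.merge(locs, on=["plot_id", "location_id"], how="inner")
    coords = list(zip(merged["x"], merged["y"]))
    for name, imap in index_maps.items():
        merged[name] = extract_at(imap, coords, footprint=footprint)
    merged["temperature"] = extract_at(temperature_map, coords, footprint=footprint)
    value_cols = list(index_maps) + ["temperature"]
    bad = merged[merged[value_cols].isna().all(axis=1)]
    if len(bad):
        warnings.warn(
            "locations with no usable image values dropped: "
            f"{list(zip(bad['plot_id'], bad['location_id']))}",
            stacklevel=2,
        )
        merged = merged.drop(bad.index)
    return merged.merge(
        layout_frame[["plot_id", "seeding", "management"]], on="plot_id", how="left"
    )


def linkage_tables(
    dataset: pd.DataFrame, predictors: tuple[str, ...] = ("shannon_species",)
) -> tuple[pd.DataFrame, pd.DataFrame, list[LinkageResult]]:
    """Fit every response against each predictor; return the compact r2
    table, the long-format coefficients, and the raw results."""
    results = []
    for pred in predictors:
        for resp in RESPONSES:
            if resp in dataset.columns:
                results.append(grouped_regressions(dataset, resp, pred))
    table = pd.DataFrame([r.table_row() for r in results])
    long = pd.concat([r.long_frame() for r in results], ignore_index=True)
    return table, long, results
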