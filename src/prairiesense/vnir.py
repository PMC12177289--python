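"""Empirical-line reflectance calibration and VNIR index rasters.

At-sensor VNIR radiance is mapped to surface reflectance with a per-band
linear (empirical-line) model anchored by three ground calibration tarps of
known reflectance, then reduced to the index rasters used downstream:

* NDVI  = (R800 - R680) / (R800 + R680) — green vegetation / productivity;
* WBI   = R900 / R970 — canopy water via the 970 nm liquid-water feature;
* albedo = unweighted mean reflectance over 450-900 nm.

Band selection is nearest-center (no interpolation; the ~2.3 nm sampling
makes the difference negligible).
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cube import (
    IndexMap,
    SpectralCube,
    UNITS_RADIANCE,
    UNITS_REFLECTANCE,
    nearest_band,
)
from .errors import DegeneracyError, GeometryError, RangeError
from .grids import Grid, polygon_mean, sample_at

logger = logging.getLogger(__name__)

#: reflectance clamping range applied after calibration; bright targets can
#: legitimately exceed 1 under noise, so the upper clamp is loose.
CLAMP_RANGE = (0.0, 1.5)


class EmpiricalLineCalibrator(BaseEstimator, TransformerMixin):
    """Per-band linear radiance-to-reflectance calibration from tarps.

    Fits, independently per band, the least-squares line

        radiance = gain * reflectance + offset

    through the (tarp reflectance, tarp at-sensor radiance) points, and
    inverts it to calibrate whole cubes.

    Parameters
    ----------
    clamp:
        (lo, hi) reflectance clamping range applied after inversion, or
        None to disable.

    Attributes
    ----------
    gain_, offset_ : ndarray, shape (n_bands,)
        Fitted line per band; gains are required to be positive.
    residual_ : ndarray, shape (n_bands,)
        Root-mean-square radiance residual of the fit per band.
    n_clamped_ : int
        Pixels clamped during the most recent :meth:`transform`.
    """

    def __init__(self, clamp: tuple[float, float] | None = CLAMP_RANGE):
        self.clamp = clamp

    def fit(self, tarp_reflectances: np.ndarray, tarp_radiances: np.ndarray):
        """Fit per-band lines.

        Parameters
        ----------
        tarp_reflectances, tarp_radiances : ndarray, shape (n_tarps, n_bands)
            Per-band ground reflectance and at-sensor radiance of each tarp.
        """
        R = np.atleast_2d(np.asarray(tarp_reflectances, dtype=float))
        L = np.atleast_2d(np.asarray(tarp_radiances, dtype=float))
        if R.shape != L.shape:
            raise GeometryError(
                f"reflectance {R.shape} and radiance {L.shape} shapes differ"
            )
        if R.shape[0] < 2:
            raise DegeneracyError("need at least 2 tarps to fit a line")
        n_bands = R.shape[1]
        gain = np.empty(n_bands)
        offset = np.empty(n_bands)
        resid = np.empty(n_bands)
        for b in range(n_bands):
            x, y = R[:, b], L[:, b]
            if np.ptp(x) < 1e-12:
                raise DegeneracyError(
                    f"tarp reflectances are collinear (constant) in band {b}"
                )
            coeffs, res, *_ = np.polyfit(x, y, 1, full=True)
            gain[b], offset[b] = coeffs
            resid[b] = np.sqrt(res[0] / len(x)) if res.size else 0.0
            if gain[b] <= 0:
                raise DegeneracyError(
                    f"non-positive empirical-line gain {gain[b]:.3g} in band {b}"
                )
        self.gain_ = gain
        self.offset_ = offset
        self.residual_ = resid
        return self

    def transform(self, cube: SpectralCube) -> SpectralCube:
        """Invert the lines: reflectance = (radiance - offset) / gain."""
        if not hasattr(self, "gain_"):
            raise RuntimeError("calibrator is not fitted")
        if cube.units != UNITS_RADIANCE:
            raise GeometryError(
                f"expected a radiance cube, got units={cube.units!r}"
            )
        if cube.n_bands != self.gain_.size:
            raise GeometryError(
                f"cube has {cube.n_bands} bands, model has {self.gain_.size}"
            )
        refl = (cube.values - self.offset_) / self.gain_
        self.n_clamped_ = 0
        if self.clamp is not None:
            lo, hi = self.clamp
            out = np.clip(refl, lo, hi)
            self.n_clamped_ = int(np.count_nonzero(out != refl))
            if self.n_clamped_:
                logger.info(
                    "clamped %d reflectance values to [%g, %g]",
                    self.n_clamped_, lo, hi,
                )
            refl = out
        return SpectralCube(
            values=refl,
            wavelengths=cube.wavelengths,
            grid=cube.grid,
            units=UNITS_REFLECTANCE,
        )


def empirical_line_fit(
    tarp_radiances: np.ndarray, tarp_reflectances: np.ndarray
) -> EmpiricalLineCalibrator:
    """Fit the per-band empirical line; returns the fitted calibrator."""
    return EmpiricalLineCalibrator().fit(tarp_reflectances, tarp_radiances)


def apply_empirical_line(
    cube: SpectralCube, model: EmpiricalLineCalibrator
) -> SpectralCube:
    return model.transform(cube)


def _require_reflectance(cube: SpectralCube) -> None:
    if cube.units != UNITS_REFLECTANCE:
        raise GeometryError(
            f"index computation needs a reflectance cube, got {cube.units!r}"
        )


def ndvi(cube: SpectralCube, red_nm: float = 680.0, nir_nm: float = 800.0) -> IndexMap:
    """(R_nir - R_red) / (R_nir + R_red); zero-sum pixels become missing."""
    _require_reflectance(cube)
    b_red = nearest_band(cube, red_nm)
    b_nir = nearest_band(cube, nir_nm)
    red = cube.band(b_red).astype(float)
    nir = cube.band(b_nir).astype(float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom != 0, (nir - red) / denom, np.nan)
    return IndexMap(
        name="NDVI",
        values=values,
        grid=cube.grid,
        wavelengths_used=(float(cube.wavelengths[b_red]),
                          float(cube.wavelengths[b_nir])),
    )


def wbi(cube: SpectralCube, num_nm: float = 900.0, den_nm: float = 970.0) -> IndexMap:
    """R900 / R970; pixels with zero denominator become missing."""
    _require_reflectance(cube)
    b_num = nearest_band(cube, num_nm)
    b_den = nearest_band(cube, den_nm)
    num = cube.band(b_num).astype(float)
    den = cube.band(b_den).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den != 0, num / den, np.nan)
    return IndexMap(
        name="WBI",
        values=values,
        grid=cube.grid,
        wavelengths_used=(float(cube.wavelengths[b_num]),
                          float(cube.wavelengths[b_den])),
    )


def albedo_vnir(
    cube: SpectralCube, lo_nm: float = 450.0, hi_nm: float = 900.0
) -> IndexMap:
    """Unweighted mean reflectance over bands with centers in [lo, hi] nm."""
    _require_reflectance(cube)
    mask = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not np.any(mask):
        raise RangeError(f"no bands with centers in [{lo_nm}, {hi_nm}] nm")
    values = cube.values[:, :, mask].mean(axis=2)
    return IndexMap(
        name="albedo",
        values=np.asarray(values, dtype=float),
        grid=cube.grid,
        wavelengths_used=tuple(float(w) for w in cube.wavelengths[mask][[0, -1]]),
    )


def extract_at(
    raster,
    coordinates,
    footprint: int = 1,
) -> np.ndarray:
    """Sample an IndexMap (or any (values, grid) raster) at coordinates.

    ``coordinates`` is an iterable of (x, y) scene-meter pairs.  With
    ``footprint`` 1 the nearest pixel value is returned; larger odd values
    average an n-by-n window.  Missing pixels propagate as NaN.
    """
    values, grid = raster.values, raster.grid
    out = np.empty(len(coordinates))
    for i, (x, y) in enumerate(coordinates):
        out[i] = sample_at(values, grid, x, y, footprint=footprint)
    return out


def extract_plot_mean(
    raster, polygon, edge_buffer_m: float = 0.0
) -> float:
    """Mean raster value over a plot polygon, optionally edge-buffered."""
    return polygon_mean(raster.values, raster.grid, polygon, edge_buffer_m)
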