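"""Single-channel broadband land-surface-temperature retrieval.

The airborne thermal camera has one broad 7.5-14 um channel, so all
radiative quantities here are band-effective: the at-sensor radiance of a
surface at temperature ``T_s`` with emissivity ``eps`` under an atmosphere
with transmittance ``tau``, downwelling radiance ``L_down`` and upwelling
path radiance ``L_up`` is

    L_sensor = tau * (eps * B(T_s) + (1 - eps) * L_down) + L_up

with ``B(T)`` the response-weighted band integral of the spectral Planck
function.  With a single channel, only band-effective (tau, L_down, L_up)
are identifiable; they are solved in closed form from three calibration
tarps of known emissivity and ground temperature.  Per-pixel emissivity is
then assigned from NDVI by linear interpolation between a bare-soil and a
dense-vegetation endpoint, and ``T_s`` recovered by inverting ``B``.

Radiance units are W m-2 sr-1 um-1 throughout (band-mean spectral
radiance); conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .cube import IndexMap, ThermalImage, UNITS_RADIANCE
from .errors import DegeneracyError, PhysicsError, RangeError
from .grids import Grid, resample_nearest

# Planck radiation constants for wavelengths in um and radiance in
# W m-2 sr-1 um-1 (CODATA):  c1 = 2 h c^2,  c2 = h c / k_B.
C1 = 1.191042972e8    # W um^4 m-2 sr-1
C2 = 1.438776877e4    # um K


def planck_spectral(wavelength_um: np.ndarray, T: float) -> np.ndarray:
    """Spectral Planck radiance B_lambda(T), W m-2 sr-1 um-1."""
    lam = np.asarray(wavelength_um, dtype=float)
    return C1 / (lam**5 * np.expm1(C2 / (lam * T)))


@dataclass
class BandResponse:
    """Spectral response of the broadband thermal channel.

    Defaults to a flat (boxcar) response over 7.5-14 um sampled at 0.01 um;
    arbitrary response shapes are accepted as per-wavelength weights.  The
    weights are normalized to integrate to one so band radiances are
    band-mean spectral radiances.
    """

    wavelength_um: np.ndarray = field(
        default_factory=lambda: np.arange(7.5, 14.0 + 1e-9, 0.01)
    )
    response: np.ndarray | None = None
    t_min: float = 250.0
    t_max: float = 370.0

    def __post_init__(self) -> None:
        self.wavelength_um = np.asarray(self.wavelength_um, dtype=float)
        if np.any(np.diff(self.wavelength_um) <= 0):
            raise PhysicsError("band wavelength grid must be increasing")
        if np.max(np.diff(self.wavelength_um)) > 0.05 + 1e-12:
            raise PhysicsError("band wavelength grid spacing must be <= 0.05 um")
        if self.response is None:
            self.response = np.ones_like(self.wavelength_um)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != self.wavelength_um.shape:
            raise PhysicsError("response shape must match wavelength grid")
        if np.any(self.response < 0):
            raise PhysicsError("response weights must be non-negative")
        # trapezoid quadrature weights folded into the response
        w = np.gradient(self.wavelength_um) * self.response
        norm = w.sum()
        if norm <= 0:
            raise PhysicsError("response integrates to zero")
        self._quad_weights = w / norm
        self._spline: CubicSpline | None = None
        self._dspline = None

    # -- exact quadrature -------------------------------------------------
    def radiance_exact(self, T: float) -> float:
        """Band-effective Planck radiance at scalar T by direct quadrature."""
        if T <= 0:
            raise PhysicsError(f"temperature must be positive, got {T}")
        return float(self._quad_weights @ planck_spectral(self.wavelength_um, T))

    def dradiance_dT_exact(self, T: float) -> float:
        lam = self.wavelength_um
        x = C2 / (lam * T)
        b = planck_spectral(lam, T)
        db = b * x / T * np.exp(x) / np.expm1(x)
        return float(self._quad_weights @ db)

    # -- cached spline for array work -------------------------------------
    def _build_spline(self) -> None:
        tgrid = np.arange(self.t_min, self.t_max + 1e-9, 0.02)
        vals = np.array(
            [self._quad_weights @ planck_spectral(self.wavelength_um, t) for t in tgrid]
        )
        self._spline = CubicSpline(tgrid, vals)
        self._dspline = self._spline.derivative()
        self._tgrid = tgrid
        self._vals = vals

    def radiance(self, T) -> np.ndarray | float:
        """Band-effective Planck radiance; vectorized over T."""
        if np.isscalar(T) or np.ndim(T) == 0:
            return self.radiance_exact(float(T))
        T = np.asarray(T, dtype=float)
        if np.any(T <= 0):
            raise PhysicsError("temperature must be positive")
        if self._spline is None:
            self._build_spline()
        return self._spline(T)

    def invert(self, L: float, xtol: float = 1e-4) -> float:
        """Scalar Planck inversion by bracketed root finding on [t_min, t_max]."""
        lo, hi = self.radiance_exact(self.t_min), self.radiance_exact(self.t_max)
        if not (lo <= L <= hi):
            raise RangeError(
                f"radiance {L} outside attainable band "
                f"[{lo:.6g}, {hi:.6g}] for T in [{self.t_min}, {self.t_max}] K"
            )
        return float(
            brentq(lambda t: self.radiance_exact(t) - L, self.t_min, self.t_max,
                   xtol=xtol)
        )

    def invert_array(self, L: np.ndarray) -> tuple[np.ndarray, int]:
        """Vectorized Planck inversion.

        Radiances outside the attainable range map to NaN; the count of such
        pixels is returned alongside.  Newton iterations from a table-lookup
        start converge to well below 1e-4 K.
        """
        if self._spline is None:
            self._build_spline()
        L = np.asarray(L, dtype=float)
        bad = ~((L >= self._vals[0]) & (L <= self._vals[-1]))
        n_missing = int(np.count_nonzero(bad))
        T = np.interp(L, self._vals, self._tgrid)
        for _ in range(4):
            T = T - (self._spline(T) - L) / self._dspline(T)
            T = np.clip(T, self.t_min, self.t_max)
        T = np.where(bad, np.nan, T)
        return T, n_missing


@dataclass(frozen=True)
class AtmosphericState:
    """Band-effective atmosphere for the thermal channel.

    tau is the transmittance, l_down / l_up the downwelling and upwelling
    path radiances (W m-2 sr-1 um-1).
    """

    tau: float
    l_down: float
    l_up: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 1.0):
            raise PhysicsError(f"tau must be in (0, 1], got {self.tau}")
        if self.l_down < 0 or self.l_up < 0:
            raise PhysicsError("atmospheric radiances must be non-negative")


@dataclass(frozen=True)
class EmissivityModel:
    """NDVI-threshold emissivity: soil below NDVI_s, vegetation above NDVI_v,
    linear in the vegetation fraction P_v in between."""

    eps_soil: float = 0.95
    eps_veg: float = 0.985
    ndvi_soil: float = 0.2
    ndvi_veg: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.eps_soil <= self.eps_veg <= 1.0):
            raise PhysicsError("require 0 < eps_soil <= eps_veg <= 1")
        if not self.ndvi_soil < self.ndvi_veg:
            raise PhysicsError("require NDVI_s < NDVI_v")


@dataclass
class TemperatureMap:
    """Retrieved surface temperature with its companion emissivity and
    vegetation-fraction maps on the thermal grid."""

    values: np.ndarray           # T_s, kelvin; NaN where not invertible
    emissivity: np.ndarray
    veg_fraction: np.ndarray | None
    grid: Grid
    n_missing: int = 0


def tarp_emissivity(t_irt: float, t_thermocouple: float) -> float:
    """Tarp broadband emissivity from paired radiometric/contact temperatures.

    By the Stefan-Boltzmann law the infrared-thermometer reading of a grey
    surface at true (thermocouple) temperature T satisfies
    eps = (T_IRT / T_thermocouple)^4.  Values above 1 (measurement noise)
    are clipped to 1 with a warning.
    """
    if t_irt <= 0 or t_thermocouple <= 0:
        raise PhysicsError("temperatures must be positive")
    eps = (t_irt / t_thermocouple) ** 4
    if eps > 1.0:
        warnings.warn(
            f"tarp emissivity {eps:.4f} > 1 clipped to 1 "
            "(T_IRT exceeds thermocouple temperature)",
            stacklevel=2,
        )
        eps = 1.0
    return eps


def solve_atmosphere(
    tarps: list[tuple[float, float, float]],
    band: BandResponse,
    cond_threshold: float = 1e10,
) -> AtmosphericState:
    """Solve (tau, L_down, L_up) from three tarps of known (eps, T_s, L_sensor).

    Substituting u = tau, v = tau * L_down, w = L_up makes the radiative
    transfer equation linear per tarp:

        L_i = eps_i * B(T_i) * u + (1 - eps_i) * v + w

    Three non-degenerate tarps give a unique closed-form solution.
    """
    if len(tarps) != 3:
        raise DegeneracyError(f"need exactly 3 tarps, got {len(tarps)}")
    eps = np.array([t[0] for t in tarps], dtype=float)
    ts = np.array([t[1] for t in tarps], dtype=float)
    rad = np.array([t[2] for t in tarps], dtype=float)
    planck = np.array([band.radiance_exact(t) for t in ts])
    A = np.column_stack([eps * planck, 1.0 - eps, np.ones(3)])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_threshold:
        # name the most similar pair of tarps
        diffs = {
            (i, j): np.linalg.norm(A[i] - A[j])
            for i in range(3) for j in range(i + 1, 3)
        }
        i, j = min(diffs, key=diffs.get)
        raise DegeneracyError(
            f"tarp system singular (condition number {cond:.3g}); "
            f"tarps {i} and {j} are nearly indistinguishable"
        )
    u, v, w = np.linalg.solve(A, rad)
    if not (0.0 < u <= 1.0 + 1e-12) or v < -1e-12 or w < -1e-12:
        raise PhysicsError(
            "tarp solve produced an inadmissible atmosphere "
            f"(tau={u:.6g}, tau*L_down={v:.6g}, L_up={w:.6g})"
        )
    return AtmosphericState(tau=min(u, 1.0), l_down=max(v, 0.0) / u,
                            l_up=max(w, 0.0))


def to_ground_brightness(image: ThermalImage, atm: AtmosphericState) -> ThermalImage:
    """Remove the atmosphere: ground-leaving radiance (L_sensor - L_up) / tau."""
    if atm.tau < 1e-3:
        raise PhysicsError(f"tau={atm.tau} below the 1e-3 floor")
    return ThermalImage(
        values=(image.values - atm.l_up) / atm.tau,
        grid=image.grid,
        units=UNITS_RADIANCE,
    )


def emissivity_from_ndvi(
    ndvi: np.ndarray, model: EmissivityModel = EmissivityModel()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (emissivity, vegetation fraction) from NDVI thresholds.

    P_v = (NDVI - NDVI_s) / (NDVI_v - NDVI_s) clipped to [0, 1];
    eps interpolates linearly between the soil and vegetation endpoints and
    is continuous at both thresholds.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    pv = np.clip(
        (ndvi - model.ndvi_soil) / (model.ndvi_veg - model.ndvi_soil), 0.0, 1.0
    )
    eps = model.eps_soil + (model.eps_veg - model.eps_soil) * pv
    return eps, pv


def resample_ndvi_to_thermal(ndvi: IndexMap, thermal_grid: Grid) -> IndexMap:
    """Nearest-center resampling of a fine NDVI map onto the thermal grid.

    Each thermal pixel takes the NDVI of the spatially closest fine pixel
    center (ties to the lower, row-major index).
    """
    values = resample_nearest(ndvi.values, ndvi.grid, thermal_grid)
    return IndexMap(
        name=ndvi.name,
        values=values,
        grid=thermal_grid,
        wavelengths_used=ndvi.wavelengths_used,
    )


def retrieve_lst(
    image: ThermalImage,
    atm: AtmosphericState,
    emissivity: np.ndarray,
    band: BandResponse,
    veg_fraction: np.ndarray | None = None,
) -> TemperatureMap:
    """Invert the single-channel equation for surface temperature.

    Per pixel:  B(T_s) = ((L_sensor - L_up)/tau - (1 - eps) * L_down) / eps,
    then T_s by Planck inversion.  Non-invertible radiances are flagged
    missing (NaN) with a count.
    """
    emissivity = np.asarray(emissivity, dtype=float)
    if np.any(emissivity <= 0):
        raise PhysicsError("emissivity must be positive everywhere")
    if emissivity.shape != image.values.shape:
        raise PhysicsError("emissivity map shape must match thermal image")
    ground = to_ground_brightness(image, atm).values
    b_surf = (ground - (1.0 - emissivity) * atm.l_down) / emissivity
    t_s, n_missing = band.invert_array(b_surf)
    return TemperatureMap(
        values=t_s,
        emissivity=emissivity,
        veg_fraction=veg_fraction,
        grid=image.grid,
        n_missing=n_missing,
    )


class SingleChannelLSTRetriever(BaseEstimator):
    """Estimator wrapping the full tarp-anchored LST retrieval.

    ``fit`` solves the band-effective atmosphere from three calibration
    tarps; ``predict`` maps an at-sensor thermal image (plus a fine NDVI
    map) to a :class:`TemperatureMap`.

    Parameters
    ----------
    eps_soil, eps_veg:
        Emissivity endpoints for bare soil and dense vegetation.
    ndvi_soil, ndvi_veg:
        NDVI thresholds bounding the mixed-pixel interpolation.
    band:
        Thermal channel response; a flat 7.5-14 um boxcar by default.

    Attributes
    ----------
    atmosphere_ : AtmosphericState
        Band-effective (tau, L_down, L_up) solved from the tarps.
    """

    def __init__(
        self,
        eps_soil: float = 0.95,
        eps_veg: float = 0.985,
        ndvi_soil: float = 0.2,
        ndvi_veg: float = 0.5,
        band: BandResponse | None = None,
    ):
        self.eps_soil = eps_soil
        self.eps_veg = eps_veg
        self.ndvi_soil = ndvi_soil
        self.ndvi_veg = ndvi_veg
        self.band = band

    def _band(self) -> BandResponse:
        return self.band if self.band is not None else BandResponse()

    def fit(self, tarps: list[tuple[float, float, float]], y=None):
        """Solve the atmosphere from tarps given as (eps, T_s, L_sensor)."""
        self.atmosphere_ = solve_atmosphere(tarps, self._band())
        return self

    def predict(self, image: ThermalImage, ndvi: IndexMap) -> TemperatureMap:
        """Retrieve LST for an at-sensor image using a fine-grid NDVI map."""
        if not hasattr(self, "atmosphere_"):
            raise RuntimeError("retriever is not fitted; call fit(tarps) first")
        model = EmissivityModel(
            eps_soil=self.eps_soil,
            eps_veg=self.eps_veg,
            ndvi_soil=self.ndvi_soil,
            ndvi_veg=self.ndvi_veg,
        )
        ndvi_thermal = (
            ndvi
            if ndvi.grid == image.grid
            else resample_ndvi_to_thermal(ndvi, image.grid)
        )
        eps, pv = emissivity_from_ndvi(ndvi_thermal.values, model)
        return retrieve_lst(
            image, self.atmosphere_, eps, self._band(), veg_fraction=pv
        )
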