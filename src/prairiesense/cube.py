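"""In-memory containers for imagery: spectral cubes, index maps, thermal rasters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, RangeError
from .grids import Grid

#: recognized units tags
UNITS_RADIANCE = "radiance"        # W m-2 sr-1 um-1 (VNIR: per-band at-sensor radiance)
UNITS_REFLECTANCE = "reflectance"  # unitless surface reflectance
UNITS_KELVIN = "kelvin"


@dataclass
class SpectralCube:
    """A georeferenced (row, col, band) VNIR array with a wavelength axis.

    ``values`` holds radiance or reflectance according to ``units``;
    ``wavelengths`` are band centers in nanometers, strictly increasing.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    grid: Grid
    units: str = UNITS_RADIANCE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("cube values must be (row, col, band)")
        if self.values.shape[2] != self.wavelengths.size:
            raise GeometryError(
                f"{self.values.shape[2]} bands but "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.values.shape[:2] != self.grid.shape:
            raise GeometryError("cube spatial shape does not match grid")
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise GeometryError("wavelengths must be strictly increasing")
        if self.units not in (UNITS_RADIANCE, UNITS_REFLECTANCE):
            raise ValueError(f"unknown units tag {self.units!r}")

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def band(self, index: int) -> np.ndarray:
        return self.values[:, :, index]


def nearest_band(cube: SpectralCube, target_nm: float, slack_nm: float = 5.0) -> int:
    """Index of the band center nearest ``target_nm``.

    Ties break toward the shorter wavelength.  Targets more than ``slack_nm``
    outside the covered range raise :class:`RangeError`.
    """
    wl = cube.wavelengths
    if wl.size == 0:
        raise RangeError("cube has no bands")
    if target_nm < wl[0] - slack_nm or target_nm > wl[-1] + slack_nm:
        raise RangeError(
            f"target {target_nm} nm outside covered range "
            f"[{wl[0]}, {wl[-1]}] nm (+/- {slack_nm} nm)"
        )
    dist = np.abs(wl - target_nm)
    return int(np.argmin(dist))  # argmin takes the first (shorter-wavelength) tie


@dataclass
class IndexMap:
    """A single-band index raster (NDVI, WBI, albedo, temperature...).

    ``wavelengths_used`` records the band centers that actually entered the
    computation, which may differ slightly from the nominal targets.
    """

    name: str
    values: np.ndarray
    grid: Grid
    wavelengths_used: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GeometryError("index map shape does not match grid")


@dataclass
class ThermalImage:
    """Broadband thermal raster: at-sensor or ground-leaving radiance.

    Values are band-effective radiances in W m-2 sr-1 um-1 over the
    7.5-14 um channel (units conversion happens at I/O boundaries only).
    """

    values: np.ndarray
    grid: Grid
    units: str = UNITS_RADIANCE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GeometryError("thermal image shape does not match grid")
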