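"""Synthetic prairie scene generator with forward-simulated imagery.

Every downstream stage of the pipeline is testable by parameter recovery
against this simulator.  The generative model is built around a single
latent "restoration success" field L(x, y) in [0, 1]:

* treatment means — seeding raises L (control < mid < high) and burning
  adds a bonus — plus block and plot random effects and spatially
  correlated noise;
* per-pixel fractional cover: green vegetation increases with L, litter
  decreases (much lower under burning), bare soil takes the remainder;
* canopy water content increases with L;
* surface temperature decreases with green cover and water content
  (evaporative cooling + thermal mass), with correlated noise;
* per-pixel reflectance is a cover-weighted mixture of smooth parametric
  endmember spectra (logistic red edge + Gaussian 970 nm water absorption
  for green vegetation; sloped featureless spectra for litter and soil);
* per-pixel broadband emissivity follows the same NDVI-threshold model
  used in retrieval, so truth and retrieval are commensurable.

Species percent-cover tables are drawn at the survey locations from the
same latent field, so field diversity and image indices genuinely covary:
a brome-like C3 grass dominates where L is low, while seeded C4 grasses
and forbs establish where L is high.

Forward models produce at-sensor imagery: a per-band linear gain/offset
(stand-in for atmospheric effects, exactly invertible by the empirical
line) for the VNIR cube, and the single-channel radiative transfer
equation (band-effective Planck emission, transmittance and path terms)
for the thermal image, with truth fields box-averaged from the 1-m VNIR
grid to the coarser thermal grid in radiance space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, box

from .cube import IndexMap, SpectralCube, ThermalImage, UNITS_RADIANCE, UNITS_REFLECTANCE
from .errors import ConfigError, PhysicsError
from .grids import Grid, box_average
from .layout import ExperimentLayout, LayoutConfig, make_layout, make_survey_design
from .thermal import AtmosphericState, BandResponse, EmissivityModel, emissivity_from_ndvi

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorModel:
    """Sensor geometry and noise for the two instruments."""

    vnir_band_start_nm: float = 400.0
    vnir_band_stop_nm: float = 1000.0
    vnir_band_spacing_nm: float = 2.3
    vnir_gsd: float = 1.0
    thermal_gsd: float = 1.4
    vnir_noise: float = 0.0015        # radiance units, per band
    thermal_noise_k: float = 1.5      # K-equivalent at-sensor noise

    def band_centers(self) -> np.ndarray:
        centers = np.arange(
            self.vnir_band_start_nm,
            self.vnir_band_stop_nm + 1e-9,
            self.vnir_band_spacing_nm,
        )
        if centers.size < 2:
            raise ConfigError("sensor must have at least 2 VNIR bands")
        return centers

    def vnir_grid(self, extent: tuple[float, float]) -> Grid:
        if self.vnir_gsd <= 0 or self.thermal_gsd <= 0:
            raise ConfigError("gsd must be positive")
        return Grid(
            0.0, 0.0, self.vnir_gsd,
            nrows=int(extent[1] / self.vnir_gsd),
            ncols=int(extent[0] / self.vnir_gsd),
        )

    def thermal_grid(self, extent: tuple[float, float]) -> Grid:
        return Grid(
            0.0, 0.0, self.thermal_gsd,
            nrows=int(extent[1] / self.thermal_gsd),
            ncols=int(extent[0] / self.thermal_gsd),
        )


@dataclass(frozen=True)
class LatentFieldConfig:
    """Treatment effects on the latent restoration-success field."""

    seeding_mean: tuple[float, float, float] = (0.25, 0.55, 0.65)  # control, mid, high
    burn_bonus: float = 0.12
    background: float = 0.20          # mowed alleys outside plots
    block_sd: float = 0.05
    plot_sd: float = 0.05
    spatial_sd: float = 0.12
    correlation_length_m: float = 8.0


@dataclass(frozen=True)
class SurfaceConfig:
    """Mapping from the latent field to surface state."""

    green_base: float = 0.15
    green_slope: float = 0.70
    litter_frac_hay: float = 0.55     # of the non-green remainder
    litter_frac_burn: float = 0.16
    water_base: float = 0.10
    water_slope: float = 0.80
    t_base_k: float = 318.0
    t_green_k: float = 12.0           # cooling per unit green cover
    t_water_k: float = 6.0            # cooling per unit water content
    t_noise_k: float = 0.4
    t_noise_corr_m: float = 5.0
    t_bounds: tuple[float, float] = (280.0, 330.0)


@dataclass(frozen=True)
class TarpConfig:
    """Three calibration tarps of contrasting brightness."""

    names: tuple[str, ...] = ("white", "silver", "black")
    vnir_reflectance: tuple[float, ...] = (0.80, 0.45, 0.05)
    thermal_emissivity: tuple[float, ...] = (0.88, 0.93, 0.97)
    temperature_k: tuple[float, ...] = (318.0, 322.0, 330.0)   # thermocouple
    size_m: float = 9.0
    origin: tuple[float, float] = (250.0, 5.0)   # scene margin, south edge
    spacing_m: float = 12.0


@dataclass(frozen=True)
class AtmosphereConfig:
    """Band-effective thermal atmosphere and the VNIR linear forward map."""

    tau: float = 0.92
    l_down: float = 5.0       # W m-2 sr-1 um-1
    l_up: float = 0.8
    vnir_gain_400: float = 1.6
    vnir_gain_1000: float = 1.0
    vnir_offset_400: float = 0.06
    vnir_offset_scale_nm: float = 300.0

    def state(self) -> AtmosphericState:
        return AtmosphericState(tau=self.tau, l_down=self.l_down, l_up=self.l_up)

    def vnir_gain(self, wavelengths: np.ndarray) -> np.ndarray:
        frac = (wavelengths - 400.0) / 600.0
        g = self.vnir_gain_400 + (self.vnir_gain_1000 - self.vnir_gain_400) * frac
        if np.any(g <= 0):
            raise ConfigError("VNIR gains must be positive")
        return g

    def vnir_offset(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.vnir_offset_400 * np.exp(
            -(wavelengths - 400.0) / self.vnir_offset_scale_nm
        )


@dataclass(frozen=True)
class SceneConfig:
    """Everything needed to simulate one scene."""

    layout: LayoutConfig = LayoutConfig()
    sensor: SensorModel = SensorModel()
    latent: LatentFieldConfig = LatentFieldConfig()
    surface: SurfaceConfig = SurfaceConfig()
    tarps: TarpConfig = TarpConfig()
    atmosphere: AtmosphereConfig = AtmosphereConfig()
    emissivity: EmissivityModel = EmissivityModel()

    @classmethod
    def compact(cls) -> "SceneConfig":
        """A down-scaled variant (2 m / 2.8 m pixels, 9.2 nm bands) for
        Monte-Carlo studies; same metric layout and effect sizes."""
        return cls(
            sensor=SensorModel(
                vnir_band_spacing_nm=9.2, vnir_gsd=2.0, thermal_gsd=2.8
            )
        )


# ---------------------------------------------------------------------------
# endmember spectra
# ---------------------------------------------------------------------------


def green_endmember(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Green vegetation without the water feature: logistic red edge plus a
    small green-peak Gaussian.  The 970 nm water absorption is applied
    separately, scaled by per-pixel water content."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    red_edge = 0.05 + 0.50 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    green_peak = 0.04 * np.exp(-((wl - 550.0) ** 2) / (2 * 25.0**2))
    return red_edge + green_peak


def water_absorption(wavelengths_nm: np.ndarray, depth: float = 0.15) -> np.ndarray:
    """Fractional Gaussian absorption centered at 970 nm (unit water content)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return depth * np.exp(-((wl - 970.0) ** 2) / (2 * 22.0**2))


def litter_endmember(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Standing dead material: featureless, gently sloped, no 970 nm dip."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 0.10 + 0.13 * (wl - 400.0) / 600.0


def soil_endmember(wavelengths_nm: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 0.12 + 0.10 * (wl - 400.0) / 600.0


def _check_endmembers(wl: np.ndarray) -> None:
    for name, em in (
        ("green", green_endmember(wl)),
        ("litter", litter_endmember(wl)),
        ("soil", soil_endmember(wl)),
    ):
        if np.any(em < 0) or np.any(em > 1):
            raise ConfigError(f"{name} endmember outside [0, 1]")


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesPool:
    """Species, functional groups, and treatment-dependent availability.

    ``availability`` maps seeding level -> per-species establishment factor
    (the mid-diversity mix excludes the tall competitive C4 grasses; the
    control holds only the extant species).  Mean cover scales with the
    latent field: the C3 dominant declines with L, seeded C4/forbs rise.
    """

    species: tuple[str, ...] = (
        "smooth_brome", "kentucky_bluegrass", "western_wheatgrass",
        "indiangrass", "big_bluestem", "switchgrass", "little_bluestem",
        "sideoats_grama",
        "black_eyed_susan", "purple_coneflower", "stiff_goldenrod",
        "heath_aster", "butterfly_milkweed", "wild_bergamot",
    )
    functional_group: tuple[str, ...] = (
        "C3", "C3", "C3",
        "C4", "C4", "C4", "C4", "C4",
        "forb", "forb", "forb", "forb", "forb", "forb",
    )
    c3_mean: tuple[float, ...] = (70.0, 9.0, 6.0)
    c4_weight: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.10)
    forb_weight: tuple[float, ...] = (0.24, 0.20, 0.17, 0.15, 0.13, 0.11)
    c4_total: float = 75.0
    forb_total: float = 35.0
    #: establishment by seeding, per species group pattern
    availability: dict = field(
        default_factory=lambda: {
            "control": {"C3": 1.0, "C4_tall": 0.35, "C4_short": 0.08, "forb": 0.12},
            "mid": {"C3": 0.9, "C4_tall": 0.30, "C4_short": 1.0, "forb": 1.0},
            "high": {"C3": 0.8, "C4_tall": 1.0, "C4_short": 1.0, "forb": 1.2},
        }
    )
    burn_forb_boost: float = 1.2
    burn_c3_suppress: float = 0.85
    gamma_shape: float = 3.0
    detection_floor: float = 0.5      # percent cover below which a draw is absent

    def functional_map(self) -> dict[str, str]:
        return dict(zip(self.species, self.functional_group))

    def mean_cover(self, latent: float, seeding: str, management: str) -> np.ndarray:
        """Expected percent cover per species before total-cover rescaling."""
        avail = self.availability[seeding]
        means = []
        c3 = iter(self.c3_mean)
        c4 = iter(self.c4_weight)
        forb = iter(self.forb_weight)
        tall_c4 = {"indiangrass", "big_bluestem", "switchgrass"}
        for sp, fg in zip(self.species, self.functional_group):
            if fg == "C3":
                m = next(c3) * (1.0 - latent) * avail["C3"]
                if management == "burn":
                    m *= self.burn_c3_suppress
            elif fg == "C4":
                a = avail["C4_tall"] if sp in tall_c4 else avail["C4_short"]
                m = self.c4_total * latent * next(c4) * a
            else:
                m = self.forb_total * latent * next(forb) * avail["forb"]
                if management == "burn":
                    m *= self.burn_forb_boost
            means.append(m)
        means = np.asarray(means)
        if np.any(means < 0):
            raise ConfigError("abundance parameters produced negative mean cover")
        return means


# ---------------------------------------------------------------------------
# scene truth
# ---------------------------------------------------------------------------


@dataclass
class SceneTruth:
    """Fully specified ground truth on the VNIR grid."""

    grid: Grid
    latent: np.ndarray
    cover_green: np.ndarray
    cover_litter: np.ndarray
    cover_soil: np.ndarray
    water_content: np.ndarray
    true_temperature: np.ndarray
    true_emissivity: np.ndarray
    reflectance: SpectralCube
    ndvi_true: IndexMap
    layout: ExperimentLayout
    tarp_mask: np.ndarray          # int: -1 outside tarps, else tarp index


@dataclass
class TarpRecord:
    """One calibration tarp: ground measurements plus at-sensor radiances."""

    name: str
    reflectance_spectrum: np.ndarray
    t_irt: float
    t_thermocouple: float
    polygon: Polygon
    at_sensor_radiance_thermal: float | None = None
    at_sensor_radiance_vnir: np.ndarray | None = None

    @property
    def emissivity(self) -> float:
        return (self.t_irt / self.t_thermocouple) ** 4


def _correlated_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, corr_px: float
) -> np.ndarray:
    """Gaussian smoothing of white noise, rescaled to the target pointwise sd."""
    white = rng.standard_normal(shape)
    if corr_px <= 0 or sd == 0:
        return sd * white
    smooth = gaussian_filter(white, sigma=corr_px, mode="reflect")
    s = smooth.std()
    return sd * smooth / s if s > 0 else np.zeros(shape)


def make_tarps(config: SceneConfig) -> list[TarpRecord]:
    cfg = config.tarps
    wl = config.sensor.band_centers()
    tarps = []
    x0, y0 = cfg.origin
    for i, name in enumerate(cfg.names):
        eps = cfg.thermal_emissivity[i]
        t_tc = cfg.temperature_k[i]
        poly = box(
            x0 + i * (cfg.size_m + cfg.spacing_m), y0,
            x0 + i * (cfg.size_m + cfg.spacing_m) + cfg.size_m, y0 + cfg.size_m,
        )
        tarps.append(
            TarpRecord(
                name=name,
                reflectance_spectrum=np.full(wl.size, cfg.vnir_reflectance[i]),
                t_irt=t_tc * eps**0.25,
                t_thermocouple=t_tc,
                polygon=poly,
            )
        )
    return tarps


def make_scene_truth(
    layout: ExperimentLayout,
    config: SceneConfig = SceneConfig(),
    seed: int = 0,
) -> SceneTruth:
    """Generate the latent field, cover fields, surface state and reflectance."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    grid = config.sensor.vnir_grid(layout.extent)
    wl = config.sensor.band_centers()
    _check_endmembers(wl)
    lat = config.latent
    surf = config.surface

    # latent field: treatment means per plot + block/plot effects + GP noise
    base = np.full(grid.shape, lat.background)
    block_eff = {
        b: rng.normal(0.0, lat.block_sd)
        for b in sorted({p.block_id for p in layout.plots})
    }
    xs = grid.x_centers()
    ys = grid.y_centers()
    seeding_mean = dict(zip(("control", "mid", "high"), lat.seeding_mean))
    for p in layout.plots:
        minx, miny, maxx, maxy = p.polygon.bounds
        cmask = (xs >= minx) & (xs <= maxx)
        rmask = (ys >= miny) & (ys <= maxy)
        mean = seeding_mean[p.seeding]
        if p.management == "burn":
            mean += lat.burn_bonus
        mean += block_eff[p.block_id] + rng.normal(0.0, lat.plot_sd)
        base[np.ix_(rmask, cmask)] = mean
    corr_px = lat.correlation_length_m / grid.gsd
    latent = base + _correlated_noise(rng, grid.shape, lat.spatial_sd, corr_px)
    latent = np.clip(latent, 0.0, 1.0)

    # cover fields (sum to 1 per pixel by construction)
    green = np.clip(surf.green_base + surf.green_slope * latent, 0.0, 1.0)
    litter_frac = np.full(grid.shape, surf.litter_frac_hay)
    for p in layout.plots:
        if p.management == "burn":
            minx, miny, maxx, maxy = p.polygon.bounds
            cmask = (xs >= minx) & (xs <= maxx)
            rmask = (ys >= miny) & (ys <= maxy)
            litter_frac[np.ix_(rmask, cmask)] = surf.litter_frac_burn
    litter = (1.0 - green) * litter_frac
    soil = 1.0 - green - litter

    water = surf.water_base + surf.water_slope * latent

    # reflectance: mixture linear in (green, green*water, litter, soil)
    em_green = green_endmember(wl)
    em_wat = em_green * water_absorption(wl)
    em_litter = litter_endmember(wl)
    em_soil = soil_endmember(wl)
    coeffs = np.stack([green, green * water, litter, soil], axis=-1)
    basis = np.stack([em_green, -em_wat, em_litter, em_soil], axis=0)
    refl = (coeffs.astype(np.float32) @ basis.astype(np.float32)).astype(np.float32)

    # temperature
    t_noise = _correlated_noise(
        rng, grid.shape, surf.t_noise_k, surf.t_noise_corr_m / grid.gsd
    )
    temp = surf.t_base_k - surf.t_green_k * green - surf.t_water_k * water + t_noise
    lo, hi = surf.t_bounds
    if temp.min() < lo or temp.max() > hi:
        raise PhysicsError(
            f"simulated temperatures [{temp.min():.1f}, {temp.max():.1f}] K "
            f"exceed configured bounds {surf.t_bounds}"
        )

    # paint tarps: reflectance, temperature, emissivity overrides
    tarps = make_tarps(config)
    tarp_mask = np.full(grid.shape, -1, dtype=int)
    eps_tarp = np.full(grid.shape, np.nan)
    for i, t in enumerate(tarps):
        minx, miny, maxx, maxy = t.polygon.bounds
        cmask = (xs >= minx) & (xs <= maxx)
        rmask = (ys >= miny) & (ys <= maxy)
        sel = np.ix_(rmask, cmask)
        tarp_mask[sel] = i
        refl[sel] = t.reflectance_spectrum.astype(np.float32)
        temp[sel] = t.t_thermocouple
        eps_tarp[sel] = t.emissivity

    cube = SpectralCube(
        values=refl, wavelengths=wl, grid=grid, units=UNITS_REFLECTANCE
    )

    # truth NDVI (noise-free) and emissivity via the retrieval's own model
    from .vnir import ndvi as ndvi_op

    ndvi_true = ndvi_op(cube)
    eps, _ = emissivity_from_ndvi(ndvi_true.values, config.emissivity)
    on_tarp = tarp_mask >= 0
    eps = np.where(on_tarp, eps_tarp, eps)

    return SceneTruth(
        grid=grid,
        latent=latent,
        cover_green=np.where(on_tarp, 0.0, green),
        cover_litter=np.where(on_tarp, 0.0, litter),
        cover_soil=np.where(on_tarp, 1.0, soil),
        water_content=np.where(on_tarp, 0.0, water),
        true_temperature=temp,
        true_emissivity=eps,
        reflectance=cube,
        ndvi_true=ndvi_true,
        layout=layout,
        tarp_mask=tarp_mask,
    )


# ---------------------------------------------------------------------------
# cover tables
# ---------------------------------------------------------------------------


def sample_cover_tables(
    layout: ExperimentLayout,
    truth: SceneTruth,
    pool: SpeciesPool = SpeciesPool(),
    seed: int = 0,
    survey: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw quadrat percent-cover tables at the survey locations.

    Species covers are gamma draws around latent-dependent means, rescaled
    so total vegetation cover matches the local green fraction; litter and
    bare-soil rows record the remaining ground cover.  Covers below the
    detection floor count as absent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    if survey is None:
        survey = make_survey_design(layout)
    meta = {p.plot_id: p for p in layout.plots}
    rows = []
    for rec in survey.itertuples(index=False):
        p = meta[rec.plot_id]
        r, c = truth.grid.rowcol(rec.x, rec.y)
        lat = float(truth.latent[r, c])
        veg_total = 100.0 * float(truth.cover_green[r, c])
        litter_total = 100.0 * float(truth.cover_litter[r, c])
        soil_total = 100.0 * float(truth.cover_soil[r, c])
        means = pool.mean_cover(lat, p.seeding, p.management)
        k = pool.gamma_shape
        draws = np.where(
            means > 0, rng.gamma(k, np.maximum(means, 1e-12) / k), 0.0
        )
        draws[draws < pool.detection_floor] = 0.0
        total = draws.sum()
        covers = draws * (veg_total / total) if total > 0 else draws
        for sp, cov in zip(pool.species, covers):
            if cov > 0:
                rows.append(
                    (rec.plot_id, rec.location_id, rec.x, rec.y, sp, cov)
                )
        rows.append((rec.plot_id, rec.location_id, rec.x, rec.y, "litter", litter_total))
        rows.append((rec.plot_id, rec.location_id, rec.x, rec.y, "bare_soil", soil_total))
    table = pd.DataFrame(
        rows, columns=["plot_id", "location_id", "x", "y", "species", "percent_cover"]
    )
    frame = layout.frame()
    return table.merge(frame[["plot_id", "seeding", "management"]], on="plot_id")


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------


@dataclass
class ThermalForwardResult:
    """At-sensor thermal image plus the commensurable truth on its grid.

    ``t_effective`` is the surface temperature implied by box-averaging the
    emitted radiance (average eps*B(T), then invert with the averaged
    emissivity) — the quantity a perfect retrieval recovers at the thermal
    scale.
    """

    image: ThermalImage
    tarp_radiances: np.ndarray
    t_effective: np.ndarray
    eps_effective: np.ndarray


def forward_vnir(
    truth: SceneTruth,
    config: SceneConfig = SceneConfig(),
    seed: int = 0,
    noise: float | None = None,
) -> tuple[SpectralCube, list[TarpRecord]]:
    """At-sensor VNIR radiance: gain * reflectance + offset (+ noise).

    Tarp records carry their analytic (noise-free) at-sensor radiances,
    standing in for the tarp-mean extraction a 9 m x 9 m target allows.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    wl = truth.reflectance.wavelengths
    gain = config.atmosphere.vnir_gain(wl).astype(np.float32)
    offset = config.atmosphere.vnir_offset(wl).astype(np.float32)
    sigma = config.sensor.vnir_noise if noise is None else noise
    rad = truth.reflectance.values * gain + offset
    if sigma > 0:
        rad = rad + rng.normal(0.0, sigma, rad.shape).astype(np.float32)
    cube = SpectralCube(
        values=rad, wavelengths=wl, grid=truth.grid, units=UNITS_RADIANCE
    )
    tarps = make_tarps(config)
    for t in tarps:
        t.at_sensor_radiance_vnir = (
            t.reflectance_spectrum * config.atmosphere.vnir_gain(wl)
            + config.atmosphere.vnir_offset(wl)
        )
    return cube, tarps


def forward_thermal(
    truth: SceneTruth,
    config: SceneConfig = SceneConfig(),
    seed: int = 0,
    band: BandResponse | None = None,
    noise_k: float | None = None,
    atm: AtmosphericState | None = None,
) -> ThermalForwardResult:
    """Single-channel at-sensor radiance on the thermal grid.

    Per VNIR pixel the ground-leaving radiance eps*B(T) + (1-eps)*L_down is
    computed, box-averaged onto the thermal grid (radiance mixes linearly
    over area), passed through the atmosphere, and optionally degraded with
    Gaussian noise expressed as a K-equivalent sigma at a 300 K reference.
    """
    band = band or BandResponse()
    atm = atm or config.atmosphere.state()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
    eps = truth.true_emissivity
    planck = np.asarray(band.radiance(truth.true_temperature))
    emitted = eps * planck                       # eps * B(T), VNIR grid
    ground = emitted + (1.0 - eps) * atm.l_down
    tgrid = config.sensor.thermal_grid(truth.layout.extent)
    ground_avg = box_average(ground, truth.grid, tgrid)
    emitted_avg = box_average(emitted, truth.grid, tgrid)
    eps_avg = box_average(eps, truth.grid, tgrid)
    at_sensor = atm.tau * ground_avg + atm.l_up
    sigma_k = config.sensor.thermal_noise_k if noise_k is None else noise_k
    if sigma_k > 0:
        sigma_l = sigma_k * band.dradiance_dT_exact(300.0)
        at_sensor = at_sensor + rng.normal(0.0, sigma_l, at_sensor.shape)
    # commensurable truth at the thermal scale
    t_eff, _ = band.invert_array(emitted_avg / eps_avg)
    tarps = make_tarps(config)
    tarp_rad = np.array(
        [
            atm.tau
            * (
                t.emissivity * band.radiance_exact(t.t_thermocouple)
                + (1.0 - t.emissivity) * atm.l_down
            )
            + atm.l_up
            for t in tarps
        ]
    )
    return ThermalForwardResult(
        image=ThermalImage(values=at_sensor, grid=tgrid, units=UNITS_RADIANCE),
        tarp_radiances=tarp_rad,
        t_effective=t_eff,
        eps_effective=eps_avg,
    )


# ---------------------------------------------------------------------------
# one-call scene simulation
# ---------------------------------------------------------------------------


@dataclass
class SceneBundle:
    """Everything one simulated overflight produces."""

    config: SceneConfig
    seed: int
    layout: ExperimentLayout
    truth: SceneTruth
    survey: pd.DataFrame
    cover_table: pd.DataFrame
    functional_map: dict[str, str]
    vnir_cube: SpectralCube           # at-sensor radiance
    tarps: list[TarpRecord]
    thermal: ThermalForwardResult
    atmosphere: AtmosphericState


def simulate_scene(
    config: SceneConfig = SceneConfig(),
    seed: int = 0,
    pool: SpeciesPool = SpeciesPool(),
    band: BandResponse | None = None,
    noise: bool = True,
) -> SceneBundle:
    """Generate layout, truth, field tables and at-sensor imagery in one call."""
    layout = make_layout(config.layout, seed=seed)
    truth = make_scene_truth(layout, config, seed=seed)
    survey = make_survey_design(layout)
    cover = sample_cover_tables(layout, truth, pool=pool, seed=seed, survey=survey)
    vnir_noise = None if noise else 0.0
    thermal_noise = None if noise else 0.0
    cube, tarps = forward_vnir(truth, config, seed=seed, noise=vnir_noise)
    thermal = forward_thermal(
        truth, config, seed=seed, band=band, noise_k=thermal_noise
    )
    for t, L in zip(tarps, thermal.tarp_radiances):
        t.at_sensor_radiance_thermal = float(L)
    return SceneBundle(
        config=config,
        seed=seed,
        layout=layout,
        truth=truth,
        survey=survey,
        cover_table=cover,
        functional_map=pool.functional_map(),
        vnir_cube=cube,
        tarps=tarps,
        thermal=thermal,
        atmosphere=config.atmosphere.state(),
    )
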