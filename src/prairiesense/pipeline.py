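"""End-to-end pipeline: simulate -> calibrate -> indices -> LST -> survey -> link.

A single structured configuration drives every stage; all randomness fans
out deterministically from one root seed, so identical configurations
reproduce byte-identical tabular outputs.  A run manifest (config
snapshot, seeds, per-stage counts, warnings) is written atomically at the
end of the run.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .cube import UNITS_KELVIN, UNITS_RADIANCE
from .errors import ConfigError
from .linkage import build_linkage_dataset, linkage_tables
from .survey import (
    bray_curtis,
    diversity_metrics,
    edge_filter,
    rare_species_filter,
    relative_cover_matrix,
)
from .synthetic import SceneConfig, SpeciesPool, simulate_scene
from .thermal import BandResponse, SingleChannelLSTRetriever
from .vnir import EmpiricalLineCalibrator, albedo_vnir, ndvi, wbi

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-scene run."""

    out_dir: str | Path = "prairiesense_run"
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    species: SpeciesPool = field(default_factory=SpeciesPool)
    edge_buffer_m: float = 5.0
    rare_threshold_percent: float = 5.0
    rare_rule: str = "max"
    footprint: int = 1
    noise: bool = True
    write_imagery: bool = False     # cubes are large; tables always written

    def validate(self) -> None:
        if self.edge_buffer_m < 0:
            raise ConfigError("edge buffer must be non-negative")
        if self.footprint < 1 or self.footprint % 2 == 0:
            raise ConfigError("footprint must be an odd positive integer")
        if self.rare_rule not in ("max", "mean"):
            raise ConfigError(f"unknown rare-species rule {self.rare_rule!r}")


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_counts: dict
    warnings: list


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and write outputs under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # ---- simulate -----------------------------------------------------
        band = BandResponse()
        bundle = simulate_scene(
            config.scene, seed=config.seed, pool=config.species,
            band=band, noise=config.noise,
        )
        counts["plots"] = len(bundle.layout.plots)
        counts["survey_locations"] = len(bundle.survey)
        psio.write_table(bundle.survey, out / "survey_design.csv")
        psio.write_table(bundle.cover_table, out / "cover_table.csv")
        psio.write_table(bundle.layout.frame(), out / "layout.csv")
        if config.write_imagery:
            psio.write_cube(bundle.vnir_cube, out / "vnir_at_sensor")
            psio.write_raster(
                bundle.thermal.image.values, bundle.thermal.image.grid,
                out / "thermal_at_sensor.tif", units=UNITS_RADIANCE,
            )

        # ---- calibrate VNIR ----------------------------------------------
        refl_tarps = np.stack([t.reflectance_spectrum for t in bundle.tarps])
        rad_tarps = np.stack([t.at_sensor_radiance_vnir for t in bundle.tarps])
        calibrator = EmpiricalLineCalibrator().fit(refl_tarps, rad_tarps)
        refl_cube = calibrator.transform(bundle.vnir_cube)
        counts["clamped_reflectance_px"] = calibrator.n_clamped_

        # ---- indices --------------------------------------------------
        maps = {
            "NDVI": ndvi(refl_cube),
            "WBI": wbi(refl_cube),
            "albedo": albedo_vnir(refl_cube),
        }
        if config.write_imagery:
            for name, m in maps.items():
                psio.write_raster(m.values, m.grid, out / f"{name}.tif", units=name)

        # ---- LST retrieval -------------------------------------------
        retriever = SingleChannelLSTRetriever(band=band)
        retriever.fit(
            [
                (t.emissivity, t.t_thermocouple, t.at_sensor_radiance_thermal)
                for t in bundle.tarps
            ]
        )
        tmap = retriever.predict(bundle.thermal.image, maps["NDVI"])
        counts["lst_missing_px"] = tmap.n_missing
        psio.write_atmosphere(
            retriever.atmosphere_, out / "atmosphere.json",
            provenance="three-tarp single-channel solve",
        )
        if config.write_imagery:
            psio.write_raster(
                tmap.values, tmap.grid, out / "temperature.tif", units=UNITS_KELVIN
            )

        # ---- survey ---------------------------------------------------
        retained = edge_filter(
            bundle.cover_table, bundle.layout, buffer_m=config.edge_buffer_m
        )
        counts["retained_locations"] = int(
            retained[["plot_id", "location_id"]].drop_duplicates().shape[0]
        )
        diversity = diversity_metrics(retained, bundle.functional_map)
        psio.write_table(diversity, out / "diversity.csv")
        community = relative_cover_matrix(retained)
        community = rare_species_filter(
            community, config.rare_threshold_percent, rule=config.rare_rule
        )
        counts["species_retained"] = community.shape[1]
        psio.write_table(community.reset_index(), out / "community_matrix.csv")
        distances = bray_curtis(community)
        psio.write_table(distances.reset_index(), out / "bray_curtis.csv")

        # ---- linkage --------------------------------------------------
        dataset = build_linkage_dataset(
            maps, tmap, diversity, bundle.survey, bundle.layout.frame(),
            footprint=config.footprint,
        )
        dataset["C3_percent_cover"] = dataset["C3_cover"]
        counts["linkage_rows"] = len(dataset)
        psio.write_table(dataset, out / "linkage_dataset.csv")
        table, long, _ = linkage_tables(
            dataset, predictors=("shannon_species", "C3_percent_cover")
        )
        psio.write_table(table, out / "linkage_r2_table.csv")
        psio.write_table(long, out / "linkage_long.csv")

        caught = [str(w.message) for w in wrec]

    manifest = RunManifest(
        config=_config_snapshot(config),
        version=__version__,
        seed=config.seed,
        stage_counts=counts,
        warnings=caught,
    )
    psio.write_json_atomic(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.ndarray, tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (Path, np.generic)):
            return str(obj)
        return obj

    return convert(config)
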