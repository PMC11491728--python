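"""End-to-end workflow: counts -> zones -> occurrence prep -> preference.

A single serializable :class:`PipelineConfig` drives the whole run; the
resolved configuration, a manifest of produced files and a log are
echoed into the output directory, and identical config + seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import climatology, occurrences, preference, synthetic, zonation
from .errors import ConfigurationError, StressZonesError
from .grids import write_ascii_grid

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "zones_from_counts", "write_zone_raster"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "stresszones_run"
    variables: list = field(default_factory=lambda: ["tmin", "tmax", "vpdmin", "vpdmax"])
    seed: int = 0
    # climate inputs: per-variable directory of daily grids, or None to simulate
    climate_dirs: dict = field(default_factory=dict)
    synthetic_climate: dict = field(default_factory=dict)  # overrides per variable
    sweeps: dict = field(default_factory=dict)  # variable -> [lo, hi, step]
    drop_leap_days: bool = True
    k_classes: int = 5
    # occurrences: CSV path, or None to simulate from the first variable's zones
    occurrences_csv: str | None = None
    simulate_occurrences: dict = field(default_factory=dict)
    thin_km: float = 20.0
    outlier_multiplier: float = 1.5
    drop_outliers: bool = True
    alpha: float = 0.05
    correction: str = "none"
    m_geojson: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def zones_from_counts(counts: climatology.CountStack, k: int = 5) -> tuple:
    """Counts -> oriented PC1 index -> equal-area zones."""
    index = zonation.pca_first_component(counts)
    index = zonation.orient_stress(index, counts)
    return index, zonation.classify_quantiles(index, k=k)


def write_zone_raster(zones: zonation.StressZoneRaster, path) -> None:
    """Zone raster as ASCII grid (nodata 0) plus a JSON breaks sidecar."""
    write_ascii_grid(path, zones.as_raster(), nodata=0, fmt="%d")
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "variable": zones.variable,
                "k": zones.k,
                "class_breaks": [float(b) for b in zones.class_breaks],
                "zone_counts": zones.zone_counts(),
            },
            indent=2,
        )
    )


def _climate_stack(cfg: PipelineConfig, var: str) -> climatology.ClimatologyStack:
    if var in cfg.climate_dirs:
        return climatology.read_daily_stack(
            cfg.climate_dirs[var], var, drop_leap_days=cfg.drop_leap_days
        )
    overrides = dict(cfg.synthetic_climate.get(var, {}))
    if "date_range" in overrides:
        overrides["date_range"] = tuple(
            dt.date.fromisoformat(d) if isinstance(d, str) else d
            for d in overrides["date_range"]
        )
    if "grid_shape" in overrides:
        overrides["grid_shape"] = tuple(overrides["grid_shape"])
    if "extent" in overrides:
        overrides["extent"] = tuple(overrides["extent"])
    overrides.setdefault("seed", cfg.seed + zlib.crc32(var.encode()) % 10000)
    overrides.setdefault("drop_leap_days", cfg.drop_leap_days)
    sim = synthetic.default_climate_config(var, **overrides)
    return synthetic.generate_daily_climate(sim)


def _load_domain(path):
    if path is None:
        return None
    import shapely
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return shapely.union_all([shape(f["geometry"]) for f in gj["features"]])
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run counts -> zones -> occurrence prep -> preference for every variable.

    Returns the manifest (also written to ``manifest.json`` in the output
    directory) listing every produced artifact.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("stresszones")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest = {"config": cfg.to_dict(), "artifacts": {}}
    try:
        (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
        manifest["artifacts"]["config"] = "config.yaml"

        zone_rasters = {}
        for var in cfg.variables:
            stage = f"zones[{var}]"
            try:
                stack = _climate_stack(cfg, var)
                sweep = tuple(cfg.sweeps[var]) if var in cfg.sweeps else None
                counts = climatology.sweep_thresholds(stack, sweep)
                index, zones = zones_from_counts(counts, k=cfg.k_classes)
                path = out / f"{var}_zones.asc"
                write_zone_raster(zones, path)
                zone_rasters[var] = zones
                manifest["artifacts"][f"zones_{var}"] = path.name
                log.info(
                    "%s: %d thresholds, PC1 EVF=%.3f, zone counts %s",
                    stage, len(counts.thresholds),
                    index.explained_variance_fraction, zones.zone_counts(),
                )
            except StressZonesError as exc:
                raise StressZonesError(f"stage {stage}: {exc}") from exc

        try:
            stage = "occurrences"
            if cfg.occurrences_csv is not None:
                raw = pd.read_csv(cfg.occurrences_csv)
            else:
                sim_kwargs = dict(cfg.simulate_occurrences)
                if "zone_weights" in sim_kwargs:
                    sim_kwargs["zone_weights"] = {
                        int(k): float(v) for k, v in sim_kwargs["zone_weights"].items()
                    }
                sim_kwargs.setdefault("seed", cfg.seed)
                occ_cfg = synthetic.OccurrenceSimConfig(**sim_kwargs)
                raw = synthetic.generate_occurrences(zone_rasters[cfg.variables[0]], occ_cfg)
            first = zone_rasters[cfg.variables[0]]
            extent = first.grid.extent
            table = occurrences.clean_occurrences(
                raw, extent=extent,
                outlier_multiplier=cfg.outlier_multiplier,
                drop_outliers=cfg.drop_outliers,
            )
            table = occurrences.thin_occurrences(table, cfg.thin_km, seed=cfg.seed)
            table = occurrences.annotate_zones(table, zone_rasters)
            occ_path = out / "occurrences_prepared.csv"
            table.to_csv(occ_path, index=False)
            manifest["artifacts"]["occurrences"] = occ_path.name
        except StressZonesError as exc:
            raise StressZonesError(f"stage {stage}: {exc}") from exc

        try:
            stage = "preference"
            domain = _load_domain(cfg.m_geojson)
            domain_name = "M" if domain is not None else "full_extent"
            results = []
            for var in cfg.variables:
                props = preference.zone_area_proportions(zone_rasters[var], domain)
                for species, sub in table.groupby("species"):
                    obs = preference.counts_by_zone(sub, var, k=cfg.k_classes)
                    if sum(obs.values()) == 0:
                        log.warning("%s/%s: no annotated records; skipping", species, var)
                        continue
                    results.append(
                        preference.chi_square_preference(
                            obs, props, species=species, variable=var,
                            alpha=cfg.alpha, correction=cfg.correction,
                            domain=domain_name,
                        )
                    )
            summary = preference.summarize_species(results)
            pref_path = out / "preference.csv"
            summary.to_csv(pref_path, index=False)
            manifest["artifacts"]["preference"] = pref_path.name
        except StressZonesError as exc:
            raise StressZonesError(f"stage {stage}: {exc}") from exc

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        manifest["artifacts"]["manifest"] = "manifest.json"
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
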