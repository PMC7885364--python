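"""End-to-end orchestration: buffers -> exposure -> harmonize -> fit.

The stages can be driven from an in-memory synthetic :class:`World` or
from files on disk (GeoJSON roads/land-use, CSV residences and panel); a
YAML config selects inputs and parameters, and every run writes a JSON
manifest with seeds, versions and exclusion counts at each filter so that
reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lumpanel import __version__
from lumpanel.errors import (
    ComputationError,
    UnlocatableResidenceError,
    ValidationError,
)
from lumpanel.exposure import (
    DEFAULT_CLASSES,
    clip_land_use,
    exposure_record,
    link_exposure,
    LandUseParcel,
)
from lumpanel.geo_network import (
    DEFAULT_BUFFER_SIZES_M,
    DEFAULT_HALFWIDTH_M,
    DEFAULT_MAX_SNAP_M,
    RoadNetwork,
    build_network,
    buffer_for_residence,
    segments_from_features,
)
from lumpanel.harmonize import (
    enforce_time_invariant,
    filter_nonmovers,
    impute_missing,
    missingness_report,
    pool_cohorts,
)
from lumpanel.rewb import DEFAULT_COVARIATES, run_all_models
from lumpanel.synthetic import World, WorldConfig, generate_panel, generate_world
from lumpanel import vector_io

logger = logging.getLogger(__name__)


class PipelineStageError(ComputationError):
    """A stage failure carrying the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[stage: {stage}] [{code}] {message}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    seed: int
    out_dir: str = "lumpanel_out"
    # inputs (None = generate a synthetic world with `seed`)
    roads_path: str | None = None
    land_use_paths: dict[int, str] = field(default_factory=dict)  # year -> path
    residences_path: str | None = None
    panel_path: str | None = None
    # parameters
    wave_to_year: dict[int, int] = field(default_factory=lambda: {1: 2003, 2: 2007, 3: 2011})
    buffer_sizes_m: tuple[float, ...] = DEFAULT_BUFFER_SIZES_M
    corridor_halfwidth_m: float = DEFAULT_HALFWIDTH_M
    snap_tolerance_m: float = DEFAULT_MAX_SNAP_M
    n_imputations: int = 5
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    reml: bool = True
    # attribute-name mapping for readers
    road_id_field: str = "segment_id"
    road_access_field: str = "accessible"
    parcel_class_field: str = "class_label"
    class_labels: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self):
        sizes = list(self.buffer_sizes_m)
        if len(set(sizes)) != len(sizes) or any(s <= 0 for s in sizes):
            raise ValidationError("buffer sizes must be positive and unique")
        for name in ("roads_path", "residences_path", "panel_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} does not exist: {p}")
        for year, p in self.land_use_paths.items():
            if not Path(p).exists():
                raise ValidationError(f"land-use file for {year} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key in ("wave_to_year", "land_use_paths"):
            if key in raw and raw[key]:
                raw[key] = {int(k): v for k, v in raw[key].items()}
        for key in ("buffer_sizes_m", "covariates", "class_labels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_network(cfg: RunConfig) -> RoadNetwork:
    geoms, props, _crs = vector_io.read_features(cfg.roads_path)
    segs = segments_from_features(
        geoms, props, id_field=cfg.road_id_field, access_field=cfg.road_access_field
    )
    return build_network(segs)


def load_parcels(cfg: RunConfig, year: int) -> list[LandUseParcel]:
    path = cfg.land_use_paths.get(year)
    if path is None:
        raise ValidationError(f"no land-use file configured for exposure year {year}")
    geoms, props, _crs = vector_io.read_features(path)
    return [
        LandUseParcel(
            parcel_id=str(p.get("parcel_id", i)),
            geometry=g,
            class_label=str(p[cfg.parcel_class_field]),
            valid_year=year,
        )
        for i, (g, p) in enumerate(zip(geoms, props))
    ]


def compute_exposures(
    net: RoadNetwork,
    residences: pd.DataFrame,
    parcels_by_year: dict[int, list[LandUseParcel]],
    wave_to_year: dict[int, int],
    buffer_sizes_m=DEFAULT_BUFFER_SIZES_M,
    corridor_halfwidth_m: float = DEFAULT_HALFWIDTH_M,
    snap_tolerance_m: float = DEFAULT_MAX_SNAP_M,
    n_classes: int = len(DEFAULT_CLASSES),
) -> tuple[pd.DataFrame, dict]:
    """Buffer + clip + entropy for every person-wave and buffer size.

    Buffers are cached per distinct residence location so non-movers cost
    one buffer per size; unlocatable residences and uncovered buffers are
    counted and skipped, degenerate (d=0/unreachable) buffers flagged.
    """
    from shapely.geometry import Point

    counts = {"unlocatable_residences": 0, "no_coverage": 0, "degenerate_buffers": 0}
    rows = []
    cache: dict[tuple, object] = {}
    for rec in residences.itertuples(index=False):
        wave = int(rec.wave_id)
        if wave not in wave_to_year:
            raise ValidationError(f"wave {wave} missing from wave_to_year map")
        year = wave_to_year[wave]
        if year not in parcels_by_year:
            raise ValidationError(f"no land-use snapshot for exposure year {year}")
        for size in buffer_sizes_m:
            key = (round(rec.res_x, 3), round(rec.res_y, 3), size)
            if key in cache:
                buf = cache[key]
            else:
                try:
                    buf = buffer_for_residence(
                        net,
                        Point(rec.res_x, rec.res_y),
                        person_id=str(rec.person_id),
                        wave_id=wave,
                        d=size,
                        w=corridor_halfwidth_m,
                        max_snap_m=snap_tolerance_m,
                    )
                except UnlocatableResidenceError:
                    buf = None
                cache[key] = buf
            if buf is None:
                counts["unlocatable_residences"] += 1
                continue
            if buf.degenerate:
                counts["degenerate_buffers"] += 1
            try:
                table = clip_land_use(buf, parcels_by_year[year], n_classes=n_classes)
            except ComputationError:
                counts["no_coverage"] += 1
                continue
            row = exposure_record(table, exposure_year=year)
            row.update(person_id=str(rec.person_id), wave_id=wave, buffer_size_m=float(size))
            rows.append(row)
    return pd.DataFrame(rows), counts


def harmonize_stage(
    panel: pd.DataFrame, cfg: RunConfig
) -> tuple[list[pd.DataFrame], dict]:
    """Non-mover restriction, time-invariance enforcement, imputation.

    Imputation runs within each cohort first; the k-th completed dataset
    of every cohort is then pooled, so cohort-specific covariate
    distributions inform their own imputations.
    """
    panel = enforce_time_invariant(panel)
    filtered, flow = filter_nonmovers(panel, required_waves=tuple(cfg.wave_to_year))
    miss = missingness_report(filtered)
    cohorts = (
        sorted(filtered["cohort_id"].unique())
        if "cohort_id" in filtered.columns
        else [None]
    )
    if len(cohorts) > 1:
        per_cohort = []
        for i, c in enumerate(cohorts):
            sub = filtered[filtered["cohort_id"] == c].reset_index(drop=True)
            per_cohort.append(
                impute_missing(
                    sub, m=cfg.n_imputations, seed=(cfg.seed + 9173 * i) % 2**31
                )
            )
        imputed = []
        for k in range(cfg.n_imputations):
            pooled = per_cohort[0][k]
            for rest in per_cohort[1:]:
                pooled = pool_cohorts(pooled, rest[k])
            imputed.append(pooled)
    else:
        imputed = impute_missing(filtered, m=cfg.n_imputations, seed=cfg.seed)
    flow["missingness"] = {k: float(v) for k, v in miss.items()}
    return imputed, flow


def run_pipeline(
    cfg: RunConfig,
    world: World | None = None,
) -> dict:
    """Execute the full chain and write the results bundle.

    With no input paths configured a synthetic world is generated from the
    run seed.  Returns a dict with the results table, exposure table,
    manifest and output paths.  Any stage failure raises with the stage
    name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "n_imputations": cfg.n_imputations,
        "buffer_sizes_m": list(cfg.buffer_sizes_m),
        "stages": {},
    }
    stage = "inputs"
    try:
        if cfg.roads_path is None and world is None:
            world = generate_world(WorldConfig(seed=cfg.seed))
        if world is not None:
            net = build_network([s for s in world.segments])
            residences = world.residences
            parcels_by_year = world.parcels_by_year
            wave_to_year = world.config.wave_to_year
        else:
            net = load_network(cfg)
            residences = pd.read_csv(cfg.residences_path)
            wave_to_year = dict(cfg.wave_to_year)
            parcels_by_year = {y: load_parcels(cfg, y) for y in set(wave_to_year.values())}

        stage = "buffers+exposure"
        exposures, expo_counts = compute_exposures(
            net,
            residences,
            parcels_by_year,
            wave_to_year,
            buffer_sizes_m=cfg.buffer_sizes_m,
            corridor_halfwidth_m=cfg.corridor_halfwidth_m,
            snap_tolerance_m=cfg.snap_tolerance_m,
            n_classes=len(cfg.class_labels),
        )
        manifest["stages"]["exposure"] = expo_counts
        exposures.to_csv(out / "exposures.csv", index=False)

        stage = "panel"
        if cfg.panel_path is not None:
            panel = pd.read_csv(cfg.panel_path)
            truth = None
        elif world is not None:
            # main exposure is the 1000-m buffer when configured, else the
            # first configured size
            main_size = (
                1000.0 if 1000.0 in cfg.buffer_sizes_m else cfg.buffer_sizes_m[0]
            )
            panel, truth = generate_panel(
                world.config, exposures, world.residences,
                main_buffer_size_m=main_size,
            )
        else:
            raise ValidationError("no panel input and no synthetic world")

        stage = "harmonize"
        imputed, flow = harmonize_stage(panel, cfg)
        manifest["stages"]["harmonize"] = flow

        stage = "link"
        linked = []
        link_counts = None
        for d in imputed:
            ld, link_counts = link_exposure(d, exposures, wave_to_year)
            linked.append(ld)
        manifest["stages"]["link"] = link_counts

        stage = "fit"
        results = run_all_models(
            linked[0],
            buffer_sizes=cfg.buffer_sizes_m,
            covariates=cfg.covariates,
            imputations=linked,
            reml=cfg.reml,
        )
        results.to_csv(out / "results.csv", index=False)
        if truth is not None:
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(truth, fh, indent=1, sort_keys=True, default=str)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        code = "validation" if isinstance(exc, ValidationError) else "computation"
        raise PipelineStageError(stage, code, str(exc)) from exc
    return {
        "results": results,
        "exposures": exposures,
        "manifest": manifest,
        "out_dir": str(out),
    }
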