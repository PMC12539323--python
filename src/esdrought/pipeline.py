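"""Staged analysis pipeline tying all modules together.

Stages (in dependency order): ``es`` → ``drought``, ``trends``,
``constraints`` → ``bundles`` → ``relationships``, ``attribution``.
Each stage writes its outputs under the run directory and registers them
in a run manifest (config hash, seeds, per-stage timing, warnings,
checksums), so a rerun with the same configuration reproduces every
output bit-identically.  Stages are re-entrant: a stage whose upstream
outputs already exist on disk can run alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .attribution import DRIVER_FEATURES, fit_surrogate, shap_summary
from .bundles import build_feature_matrix, som_cluster, summarize_bundles
from .constraints import DEFAULT_FAMILIES, constraint_analysis_by_landuse
from .drought import (
    DROUGHT_CLASSES,
    DroughtClassTable,
    binned_spei_surface,
    cell_drought_degree,
    classify_drought,
    stratify_es_by_drought,
    summarize_drought,
)
from .es_models import EsStack, compute_es_stack, zone_es_summary
from .exceptions import DependencyError
from .grid import ES_NAMES, GridField, LandscapeDataset
from .relationships import es_spei_regression, tradeoff_matrix
from .synthetic import SyntheticConfig, derive_wue, generate_landscape
from .trends import trend_raster, zone_mean_slopes

ALL_STAGES: tuple[str, ...] = (
    "es", "drought", "trends", "constraints", "bundles", "relationships", "attribution",
)
STAGE_DEPS: dict[str, tuple[str, ...]] = {
    "es": (),
    "drought": ("es",),
    "trends": ("es",),
    "constraints": ("es",),
    "bundles": ("es", "drought"),
    "relationships": ("es", "drought", "bundles"),
    "attribution": ("es", "drought", "bundles"),
}


@dataclass
class PipelineConfig:
    """Run configuration; all randomness flows from the seeds recorded here."""

    out_dir: str = "esdrought_run"
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    rusle_variant: str = "printed"
    drought_cutoffs: tuple[float, ...] = (-0.5, -1.0, -1.5, -2.0)
    tem_bin_width: float = 1.0
    pre_bin_width: float = 100.0
    constraint_n_bins: int = 100
    constraint_q: float = 99.9
    constraint_min_count: int = 10
    constraint_families: tuple[str, ...] = DEFAULT_FAMILIES
    som_k: int = 4
    som_grid_shape: tuple[int, int] | None = None
    som_epochs: int = 50
    som_seed: int = 0
    attribution_instances: int = 25
    attribution_background: int = 25
    attribution_trees: int = 60
    attribution_seed: int = 0
    attribution_targets: tuple[str, ...] = ES_NAMES
    alpha: float = 0.05

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o
        payload = enc(self)
        payload.pop("out_dir", None)  # run placement, not analysis configuration
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_field(path: Path, gf: GridField, name: str) -> None:
    fio.write_raster(path, np.asarray(gf.values, dtype=np.float32),
                     {"variable": name, "cell_km": gf.cell_km, "nodata": "nan"})


def _load_es(out: Path, dataset: LandscapeDataset) -> EsStack:
    stacks = {}
    for name in ES_NAMES:
        layers = []
        for year in dataset.years:
            p = out / f"{name}_{int(year)}.tif"
            if not p.exists():
                raise DependencyError(
                    f"stage requires 'es' outputs but {p.name} is missing; run --stages es first"
                )
            arr, _ = fio.read_raster(p)
            layers.append(arr)
        stacks[name] = np.stack(layers).astype(float)
    return EsStack(stacks["WR"], stacks["SC"], stacks["CS"], stacks["FS"],
                   dataset.mask, dataset.cell_km)


def _require(out: Path, filename: str, stage: str) -> Path:
    p = out / filename
    if not p.exists():
        raise DependencyError(
            f"stage requires '{stage}' outputs but {filename} is missing; "
            f"run --stages {stage} first"
        )
    return p


def run_pipeline(
    config: PipelineConfig,
    stages: tuple[str, ...] | str = "all",
    dataset: LandscapeDataset | None = None,
) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    if stages == "all" or stages == ("all",):
        requested = list(ALL_STAGES)
    else:
        requested = [s for s in ALL_STAGES if s in set(stages)]
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise DependencyError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        if config.synthetic is not None:
            dataset = generate_landscape(config.synthetic)
        elif config.input_dir is not None:
            dataset = fio.read_landscape(config.input_dir)
        else:
            raise DependencyError("config must provide synthetic config or input_dir")

    table = DroughtClassTable(cutoffs=config.drought_cutoffs)
    state: dict[str, object] = {}
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seeds": {
            "synthetic": config.synthetic.seed if config.synthetic else None,
            "som": config.som_seed,
            "attribution": config.attribution_seed,
        },
        "stages": {},
        "warnings": [],
        "files": {},
    }

    def record(path: Path) -> None:
        manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def get_es() -> EsStack:
        if "es" not in state:
            state["es"] = _load_es(out, dataset)
        return state["es"]  # type: ignore[return-value]

    def get_labels() -> np.ndarray:
        if "labels" not in state:
            state["labels"] = classify_drought(
                dataset.variables["SPEI"].astype(float), dataset.mask, table
            )
        return state["labels"]  # type: ignore[return-value]

    def get_spei_f() -> GridField:
        if "spei_f" not in state:
            p = _require(out, "spei_f.tif", "drought")
            arr, _ = fio.read_raster(p)
            state["spei_f"] = GridField(arr.astype(float), dataset.mask, dataset.cell_km)
        return state["spei_f"]  # type: ignore[return-value]

    def get_bundle_labels() -> np.ndarray:
        if "bundle_grid" not in state:
            p = _require(out, "bundles.tif", "bundles")
            arr, _ = fio.read_raster(p)
            state["bundle_grid"] = arr.astype(np.int32)
        return state["bundle_grid"]  # type: ignore[return-value]

    for stage in requested:
        t0 = time.perf_counter()
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            if stage == "es":
                es = compute_es_stack(dataset, rusle_variant=config.rusle_variant)
                state["es"] = es
                for name in ES_NAMES:
                    for t, year in enumerate(dataset.years):
                        p = out / f"{name}_{int(year)}.tif"
                        _write_field(p, GridField(es.get(name)[t], dataset.mask,
                                                  dataset.cell_km), name)
                        record(p)
                df = zone_es_summary(es, dataset.zones, dataset.years)
                df.to_csv(out / "zone_es_summary.csv", index=False)
                record(out / "zone_es_summary.csv")

            elif stage == "drought":
                es = get_es()
                summary = summarize_drought(
                    dataset.variables["SPEI"].astype(float), dataset.mask, table,
                    dataset.cell_km,
                )
                state["spei_f"] = summary.spei_f
                _write_field(out / "spei_f.tif", summary.spei_f, "SPEI_F")
                record(out / "spei_f.tif")
                for k, cls in enumerate(DROUGHT_CLASSES):
                    gf = GridField(
                        np.where(dataset.mask, summary.class_counts[k], np.nan),
                        dataset.mask, dataset.cell_km,
                    )
                    _write_field(out / f"class_freq_{cls}.tif", gf, f"freq_{cls}")
                    record(out / f"class_freq_{cls}.tif")
                strata = stratify_es_by_drought(es, get_labels(), dataset.land_use)
                strata.to_csv(out / "drought_strata.csv", index=False)
                record(out / "drought_strata.csv")
                tem = dataset.variables["TEM"].astype(float)
                pre = dataset.variables["PRE"].astype(float)
                t_lo = np.floor(np.nanmin(tem))
                t_hi = np.ceil(np.nanmax(tem)) + 1e-9
                p_lo = np.floor(np.nanmin(pre) / config.pre_bin_width) * config.pre_bin_width
                p_hi = np.ceil(np.nanmax(pre) / config.pre_bin_width) * config.pre_bin_width
                surface = binned_spei_surface(
                    tem, pre, dataset.variables["SPEI"].astype(float), dataset.mask,
                    np.arange(t_lo, t_hi + config.tem_bin_width, config.tem_bin_width),
                    np.arange(p_lo, p_hi + config.pre_bin_width, config.pre_bin_width),
                )
                surface.to_csv(out / "spei_surface.csv", index=False)
                record(out / "spei_surface.csv")

            elif stage == "trends":
                es = get_es()
                trend_fields = {}
                for name in ES_NAMES + ("SPEI",):
                    series = (
                        es.get(name) if name in ES_NAMES
                        else dataset.variables["SPEI"].astype(float)
                    )
                    fields = trend_raster(series, dataset.mask, alpha=config.alpha,
                                          cell_km=dataset.cell_km)
                    trend_fields[name] = fields
                    for key, suffix in (("slope", "sen"), ("p", "mk_p"), ("sig", "sig")):
                        p = out / f"{name}_{suffix}.tif"
                        _write_field(p, fields[key], f"{name}_{suffix}")
                        record(p)
                slopes = zone_mean_slopes(trend_fields, dataset.zones, dataset.mask)
                slopes.to_csv(out / "zone_mean_slopes.csv", index=False)
                record(out / "zone_mean_slopes.csv")

            elif stage == "constraints":
                es = get_es()
                fits = constraint_analysis_by_landuse(
                    dataset, es,
                    n_bins=config.constraint_n_bins, q=config.constraint_q,
                    min_count=config.constraint_min_count,
                    families=config.constraint_families,
                )
                fits["coefficients"] = fits["coefficients"].apply(json.dumps)
                fits.to_csv(out / "constraint_fits.csv", index=False)
                record(out / "constraint_fits.csv")

            elif stage == "bundles":
                es = get_es()
                features = build_feature_matrix(es, get_spei_f())
                assignment = som_cluster(
                    features, k=config.som_k, grid_shape=config.som_grid_shape,
                    epochs=config.som_epochs, seed=config.som_seed,
                )
                state["features"] = features
                state["assignment"] = assignment
                gf = assignment.label_grid(dataset.cell_km)
                fio.write_raster(
                    out / "bundles.tif", gf.values.astype(np.int32),
                    {"variable": "bundle", "cell_km": dataset.cell_km},
                )
                record(out / "bundles.tif")
                summarize_bundles(assignment, features).to_csv(
                    out / "bundle_summary.csv", index=False
                )
                record(out / "bundle_summary.csv")
                pd.DataFrame(assignment.codebook, columns=features.names).to_csv(
                    out / "codebook.csv", index=False
                )
                record(out / "codebook.csv")

            elif stage == "relationships":
                es = get_es()
                degree = cell_drought_degree(get_labels(), dataset.mask)
                by_degree = tradeoff_matrix(
                    es, degree,
                    stratum_names=dict(enumerate(DROUGHT_CLASSES)),
                )
                bundle_grid = get_bundle_labels()
                by_bundle = tradeoff_matrix(
                    es, bundle_grid,
                    stratum_names={b: f"B{b}" for b in range(1, config.som_k + 1)},
                    spei_f=get_spei_f(),
                )
                frames = [m.to_frame() for m in by_degree.values()]
                frames += [m.to_frame() for m in by_bundle.values()]
                pd.concat(frames, ignore_index=True).to_csv(
                    out / "tradeoffs.csv", index=False
                )
                record(out / "tradeoffs.csv")
                reg = es_spei_regression(
                    es, dataset.variables["SPEI"].astype(float), dataset.land_use
                )
                reg.to_csv(out / "es_spei_regression.csv", index=False)
                record(out / "es_spei_regression.csv")

            elif stage == "attribution":
                es = get_es()
                spei_f = get_spei_f()
                bundle_grid = get_bundle_labels()
                drivers = driver_feature_table(dataset, spei_f)
                rng = np.random.default_rng(config.attribution_seed)
                imp_frames = []
                for b in sorted(set(bundle_grid[dataset.mask]) - {0}):
                    sel = (bundle_grid == b) & dataset.mask
                    rows = drivers.loc[sel.ravel()[drivers.index]]
                    if len(rows) < 50:
                        manifest["warnings"].append(
                            f"attribution: bundle {b} has {len(rows)} cells (<50), skipped"
                        )
                        continue
                    for es_name in config.attribution_targets:
                        target = es.period_mean(es_name).ravel()[rows.index]
                        predictor = fit_surrogate(
                            rows, target, target_name=es_name,
                            seed=config.attribution_seed,
                            n_estimators=config.attribution_trees,
                        )
                        bg_idx = rng.choice(
                            len(rows),
                            size=min(config.attribution_background, len(rows)),
                            replace=False,
                        )
                        values, importance = shap_summary(
                            predictor, rows, rows.iloc[bg_idx],
                            max_instances=config.attribution_instances,
                            seed=config.attribution_seed,
                        )
                        values.to_csv(out / f"shap_values_B{b}_{es_name}.csv", index=False)
                        record(out / f"shap_values_B{b}_{es_name}.csv")
                        importance["bundle"] = b
                        importance["es"] = es_name
                        importance["holdout_r2"] = predictor.holdout_r2
                        imp_frames.append(importance)
                if imp_frames:
                    pd.concat(imp_frames, ignore_index=True).to_csv(
                        out / "importance.csv", index=False
                    )
                    record(out / "importance.csv")

        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
        }
        manifest["warnings"].extend(str(w.message) for w in caught)

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def driver_feature_table(dataset: LandscapeDataset, spei_f: GridField) -> pd.DataFrame:
    """Period-mean driver features per valid cell, indexed by flat cell index.

    Columns are the twelve standard drivers; WUE is derived as GPP/ET from
    the period-mean fields.
    """
    mask = dataset.mask
    idx = np.nonzero(mask.ravel())[0]
    cols: dict[str, np.ndarray] = {}
    for var in ("TEM", "PRE", "ET", "EL", "SL", "NDVI", "SOC", "RSMC", "GDP", "POP"):
        cols[var] = dataset.variables[var].astype(float)[:, mask].mean(axis=0)
    wue = derive_wue(dataset.static_field("GPP"), dataset.static_field("ET"))
    cols["WUE"] = np.nan_to_num(wue.values[mask], nan=0.0)
    cols["SPEI_F"] = spei_f.values[mask]
    df = pd.DataFrame({k: cols[k] for k in DRIVER_FEATURES})
    df.index = idx
    return df
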