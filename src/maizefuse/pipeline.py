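"""Configuration-driven orchestration of the full analysis pipeline.

Stages run in dependency order: simulate → rasterize (point cloud →
surfaces) → prep (chips, segmentation, band means) → ndsi + features →
train-ml → train-dl → evaluate.  Every stage's outputs land under the run
directory; a manifest records the configuration, seeds and a content hash of
every artifact so a rerun with the same config and seed is verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import synthetic_field as sf
from .evaluation import describe_traits, morans_i, prediction_map, regression_metrics
from .features import feature_registry_json, feature_table
from .lidar_surface import canopy_height, rasterize_dsm, rasterize_dtm, rasterize_intensity
from .ndsi import best_pair_table, screen_all_traits
from .nn import FusionNetRegressor, FusionNetSpec, TrainConfig
from .plot_prep import band_mean_table, prepare_plots
from .shallow import SearchSpace, bootstrap_evaluate, stratified_splits

log = logging.getLogger("maizefuse")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "maizefuse_run",
    "stages": {
        "simulate": True,
        "rasterize": True,
        "prep": True,
        "ndsi": True,
        "features": True,
        "train_ml": True,
        "train_dl": True,
        "evaluate": True,
    },
    "simulate": {
        "n_blocks": 6,
        "plots_per_block": 10,
        "n_bands": 12,
        "plot_length": 0.96,
        "plot_width": 0.30,
        "noise_sd": 0.01,
        "lidar_density": 1600.0,
    },
    "prep": {"margin": 2},
    "train_ml": {
        "feature_sets": ["hyper", "hyper+dsm"],
        "regressors": ["rfr"],
        "n_shuffles": 2,
        "traits": ["dry_grain_yield", "total_plant_n"],
    },
    "train_dl": {
        "modalities": ["hyperspectral", "lidar_height"],
        "n_layers": 2,
        "filters": [8, 16],
        "n_crops": 5,
        "crop_window": [24, 8],
        "max_epochs": 15,
        "patience": 5,
        "batch_size": 64,
    },
    "evaluate": {"moran_k": 8, "n_permutations": 999},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    user = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULT_CONFIG, user)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; returns the run manifest."""
    seed = int(config["seed"])
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    manifest: dict = {"seed": seed, "config": config, "stages": {}, "artifacts": {}}

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        for f in files:
            manifest["artifacts"][str(f.relative_to(out))] = _hash_file(f)
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    scene = prep = feats = traits = None
    try:
        if stages.get("simulate"):
            t0 = time.time()
            sim = config["simulate"]
            design = sf.generate_design(
                sim["n_blocks"], sim["plots_per_block"], seed,
                plot_length=sim["plot_length"], plot_width=sim["plot_width"],
            )
            phenotypes = sf.sample_trait_population(design, seed=seed)
            scene = sf.render_scene(
                design, phenotypes,
                sf.RenderSpec(n_bands=sim["n_bands"], noise_sd=sim["noise_sd"]),
                seed=seed,
            )
            scene_dir = mio.save_scene(scene, out / "scene")
            points = sf.generate_pointcloud(scene, density=sim["lidar_density"], seed=seed)
            pc_path = mio.save_pointcloud(points, out / "scene" / "pointcloud.tsv")
            record("simulate", t0, sorted(scene_dir.glob("*")) + [pc_path])

        if stages.get("rasterize"):
            t0 = time.time()
            points = mio.load_pointcloud(out / "scene" / "pointcloud.tsv")
            origin = tuple(scene.origin)
            shape = scene.height.shape
            dsm = rasterize_dsm(points, scene.gsd, origin, shape)
            dtm = rasterize_dtm(points, scene.gsd, origin, shape)
            chm = canopy_height(dsm, dtm)
            inten = rasterize_intensity(points, scene.gsd, origin, shape)
            import tifffile

            files = []
            for name, ras in (("dsm", dsm), ("dtm", dtm), ("chm", chm),
                              ("lidar_intensity", inten)):
                p = out / "surfaces" / f"{name}.tif"
                p.parent.mkdir(exist_ok=True)
                tifffile.imwrite(p, ras.values.astype(np.float32))
                files.append(p)
            record("rasterize", t0, files)

        if stages.get("prep"):
            t0 = time.time()
            prep = prepare_plots(scene, margin=config["prep"]["margin"], seed=seed)
            bands = band_mean_table(scene, prep)
            p = out / "band_means.csv"
            bands.to_csv(p)
            record("prep", t0, [p])

        traits = scene.phenotypes[list(sf.reference.TRAIT_NAMES)]
        strata = scene.phenotypes["treatment"]

        if stages.get("ndsi"):
            t0 = time.time()
            bands = pd.read_csv(out / "band_means.csv", index_col="plot_id")
            heatmaps = screen_all_traits(bands, traits)
            files = []
            hm_dir = out / "ndsi"
            hm_dir.mkdir(exist_ok=True)
            for name, hm in heatmaps.items():
                p = hm_dir / f"heatmap_{name}.csv"
                hm.r2.to_csv(p)
                files.append(p)
            p = hm_dir / "best_pairs.csv"
            best_pair_table(heatmaps).to_csv(p)
            files.append(p)
            record("ndsi", t0, files)

        if stages.get("features"):
            t0 = time.time()
            feats = feature_table(scene, prep)
            p = out / "features.csv"
            feats.to_csv(p)
            reg = out / "feature_registry.json"
            reg.write_text(feature_registry_json())
            record("features", t0, [p, reg])

        if stages.get("train_ml"):
            t0 = time.time()
            ml = config["train_ml"]
            space = SearchSpace(rfr_trees=(100,), rfr_depth=(None,), rfr_min_leaf=(1,),
                                svr_c=(1.0, 10.0), svr_gamma_mult=(1.0,), inner_folds=3)
            report = bootstrap_evaluate(
                feats, traits[ml["traits"]], strata,
                feature_sets=tuple(ml["feature_sets"]),
                regressors=tuple(ml["regressors"]),
                n_shuffles=ml["n_shuffles"], space=space, seed=seed,
            )
            p = out / "ml_report.csv"
            report.table.to_csv(p, index=False)
            record("train_ml", t0, [p])

        predictions = None
        if stages.get("train_dl"):
            t0 = time.time()
            dl = config["train_dl"]
            cfg = TrainConfig(
                n_crops=dl["n_crops"], crop_window=tuple(dl["crop_window"]),
                max_epochs=dl["max_epochs"], patience=dl["patience"],
                batch_size=dl["batch_size"], seed=seed,
            )
            train, val, test = stratified_splits(traits.index, strata, seed)
            net = FusionNetRegressor(
                modalities=tuple(dl["modalities"]),
                spec=FusionNetSpec(n_layers=dl["n_layers"], filters=tuple(dl["filters"])),
                config=cfg, seed=seed,
            )
            net.fit(prep, traits, train_plots=list(train), val_plots=list(val))
            predictions = net.predict(prep, plot_ids=list(traits.index))
            p = out / "dl_predictions.csv"
            predictions.to_csv(p)
            h = out / "dl_history.csv"
            net.history_.to_csv(h, index=False)
            manifest["dl_test_plots"] = list(map(str, test))
            record("train_dl", t0, [p, h])

        if stages.get("evaluate"):
            t0 = time.time()
            files = []
            p = out / "trait_summary.csv"
            describe_traits(traits).to_csv(p)
            files.append(p)
            if predictions is None and (out / "dl_predictions.csv").exists():
                predictions = pd.read_csv(out / "dl_predictions.csv", index_col="plot_id")
            if predictions is not None:
                ev = config["evaluate"]
                metrics = {
                    trait: regression_metrics(
                        traits[trait].to_numpy(), predictions[trait].to_numpy()
                    )
                    for trait in traits.columns
                }
                p = out / "metrics.json"
                p.write_text(json.dumps(metrics, indent=2))
                files.append(p)
                cent = np.array([[pl.polygon.centroid.x, pl.polygon.centroid.y]
                                 for pl in scene.plots])
                resid = (traits["dry_grain_yield"]
                         - predictions["dry_grain_yield"]).to_numpy()
                mr = morans_i(resid, cent, k=ev["moran_k"],
                              n_permutations=ev["n_permutations"], seed=seed)
                p = out / "moran.json"
                p.write_text(json.dumps({
                    "i": mr.i, "expected": mr.expected, "p_value": mr.p_value,
                    "significant": mr.significant, "weights": mr.weights,
                }, indent=2))
                files.append(p)
                gj = prediction_map(predictions["dry_grain_yield"],
                                    traits["dry_grain_yield"], scene.plots,
                                    path=str(out / "prediction_map.png"))
                p = out / "prediction_map.geojson"
                p.write_text(json.dumps(gj))
                files.extend([p, out / "prediction_map.png"])
            record("evaluate", t0, files)
    except Exception as exc:
        manifest["failed_stage"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
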