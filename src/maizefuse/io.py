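"""Scene and artifact serialization.

Rasters are written as plain multi-band TIFF (band-interleaved, float32)
with a JSON sidecar carrying georeferencing (origin, ground sampling
distance) and the wavelength list; plot boundaries as GeoJSON polygons with
treatment properties; phenotypes and tables as CSV; point clouds as
tab-separated tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import shape as shapely_shape

from .synthetic_field import FieldScene, PlotDesign


def save_scene(scene: FieldScene, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "hyperspectral.tif",
                     np.moveaxis(scene.hyperspectral, -1, 0).astype(np.float32))
    for name in ("height", "intensity", "thermal", "terrain"):
        tifffile.imwrite(out / f"{name}.tif", getattr(scene, name).astype(np.float32))
    tifffile.imwrite(out / "truth_mask.tif", scene.truth_mask.astype(np.uint8))
    meta = {
        "gsd": scene.gsd,
        "origin": list(scene.origin),
        "wavelengths_nm": [float(w) for w in scene.wavelengths],
    }
    (out / "scene.json").write_text(json.dumps(meta, indent=2))
    (out / "plots.geojson").write_text(json.dumps(plots_to_geojson(scene.plots), indent=2))
    scene.phenotypes.to_csv(out / "phenotypes.csv")
    return out


def load_scene(in_dir: str | Path) -> FieldScene:
    src = Path(in_dir)
    meta = json.loads((src / "scene.json").read_text())
    hyper = np.moveaxis(tifffile.imread(src / "hyperspectral.tif"), 0, -1)
    plots = plots_from_geojson(json.loads((src / "plots.geojson").read_text()))
    phenotypes = pd.read_csv(src / "phenotypes.csv", index_col="plot_id")
    return FieldScene(
        hyperspectral=hyper.astype(np.float32),
        wavelengths=np.asarray(meta["wavelengths_nm"], dtype=float),
        height=tifffile.imread(src / "height.tif"),
        intensity=tifffile.imread(src / "intensity.tif"),
        thermal=tifffile.imread(src / "thermal.tif"),
        terrain=tifffile.imread(src / "terrain.tif"),
        gsd=float(meta["gsd"]),
        origin=tuple(meta["origin"]),
        plots=plots,
        truth_mask=tifffile.imread(src / "truth_mask.tif").astype(bool),
        phenotypes=phenotypes,
    )


def plots_to_geojson(plots: list[PlotDesign]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": p.polygon.__geo_interface__,
                "properties": {
                    "plot_id": p.plot_id,
                    "block_id": p.block_id,
                    "grid_row": p.grid_row,
                    "grid_col": p.grid_col,
                    "treatment": p.treatment,
                    "genotype_id": p.genotype_id,
                },
            }
            for p in plots
        ],
    }


def plots_from_geojson(collection: dict) -> list[PlotDesign]:
    plots = []
    for feat in collection["features"]:
        props = feat["properties"]
        plots.append(
            PlotDesign(
                plot_id=props["plot_id"],
                block_id=props["block_id"],
                grid_row=int(props["grid_row"]),
                grid_col=int(props["grid_col"]),
                polygon=shapely_shape(feat["geometry"]),
                treatment=props["treatment"],
                genotype_id=int(props["genotype_id"]),
            )
        )
    return plots


def save_pointcloud(points: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    points.to_csv(path, sep="\t", index=False)
    return path


def load_pointcloud(path: str | Path) -> pd.DataFrame:
    pts = pd.read_csv(path, sep="\t")
    if "ground" in pts.columns:
        pts["ground"] = pts["ground"].astype(bool)
    return pts
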