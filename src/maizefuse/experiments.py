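"""Reproducible study drivers: scaled-down parameter-recovery experiments.

These functions wire the full pipeline together at a desk-scale problem
size — 300 plots, a dozen binned spectral bands, 24 x 8 crop windows on
32 x 12-pixel plot chips and a two-layer filter ladder — chosen so a
complete recovery experiment (segmentation, features, shallow baselines,
the fusion network with and without augmentation) runs on one CPU in
minutes.  The statistical structure of the trial (alternating nitrogen
blocks, bimodal yield/nitrogen traits, linear trait-to-signal links) is the
same as the full-scale defaults; only sizes shrink.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic_field as sf
from .evaluation import morans_i, regression_metrics
from .features import feature_table
from .nn import FusionNetRegressor, FusionNetSpec, TrainConfig
from .plot_prep import prepare_plots
from .shallow import SearchSpace, ShallowRegressorCV, stratified_splits

SIGNAL_TRAITS = ("dry_grain_yield", "grain_n", "total_plant_n")
NOISE_TRAIT = "grain_density"  # independent of the rendered scene by construction


def small_scene(
    seed: int,
    n_blocks: int = 20,
    plots_per_block: int = 15,
    n_bands: int = 12,
    plot_length: float = 0.96,
    plot_width: float = 0.30,
    noise_sd: float = 0.01,
):
    """A scaled-down synthetic trial: (design, phenotypes, scene)."""
    design = sf.generate_design(
        n_blocks, plots_per_block, seed, plot_length=plot_length,
        plot_width=plot_width, alley=0.24, plot_gap=0.06,
    )
    phenotypes = sf.sample_trait_population(design, seed=seed)
    spec = sf.RenderSpec(n_bands=n_bands, noise_sd=noise_sd)
    scene = sf.render_scene(design, phenotypes, spec, seed=seed)
    return design, phenotypes, scene


def small_experiment_config(seed: int) -> TrainConfig:
    return TrainConfig(
        n_crops=20,
        crop_window=(24, 8),
        batch_size=64,
        max_epochs=40,
        patience=10,
        seed=seed,
    )


def small_search_space() -> SearchSpace:
    """A reduced grid keeping the recovery experiment inside minutes."""
    return SearchSpace(
        svr_c=(1.0, 10.0),
        svr_kernels=("rbf", "linear"),
        svr_gamma_mult=(1.0,),
        rfr_trees=(100, 300),
        rfr_depth=(None, 10),
        rfr_min_leaf=(1, 3),
    )


def recovery_experiment(
    seed: int,
    n_crops_levels: tuple[int, ...] = (0, 20),
    margin: int = 2,
) -> dict:
    """Parameter recovery on the default scaled synthetic field (n = 300).

    Runs segmentation, the 95-feature table, a grid-searched RFR baseline on
    a signal trait and on the pure-noise trait, and the multi-task fusion
    network (hyperspectral + LiDAR canopy height) at each augmentation level.
    Reports test-split R² values on a stratified 60/20/20 split.
    """
    design, phenotypes, scene = small_scene(seed)
    prep = prepare_plots(scene, margin=margin, seed=seed)

    # segmentation accuracy against the rendered truth
    correct = total = 0
    for plot in scene.plots:
        rs, cs = scene.plot_pixel_window(plot, margin)
        truth = scene.truth_mask[rs, cs]
        mask = prep[plot.plot_id]["mask"]
        correct += int((mask == truth).sum())
        total += truth.size
    seg_accuracy = correct / total

    traits = phenotypes[list(sf.reference.TRAIT_NAMES)]
    strata = phenotypes["treatment"]
    train, val, test = stratified_splits(traits.index, strata, seed)

    # shallow baseline (RFR) on the handcrafted features
    feats = feature_table(scene, prep)
    space = small_search_space()
    rfr_r2 = {}
    for trait in (SIGNAL_TRAITS[0], NOISE_TRAIT):
        est = ShallowRegressorCV("rfr", space, random_state=seed)
        est.fit(feats.loc[train].to_numpy(), traits.loc[train, trait].to_numpy())
        pred = est.predict(feats.loc[test].to_numpy())
        rfr_r2[trait] = regression_metrics(traits.loc[test, trait].to_numpy(), pred)["r2"]

    # multi-task fusion network at each augmentation level
    fusion: dict[int, dict[str, float]] = {}
    for n_crops in n_crops_levels:
        cfg = small_experiment_config(seed)
        cfg.n_crops = n_crops
        net = FusionNetRegressor(
            modalities=("hyperspectral", "lidar_height"),
            spec=FusionNetSpec(n_layers=2, filters=(8, 16)),
            config=cfg,
            seed=seed,
        )
        net.fit(prep, traits, train_plots=list(train), val_plots=list(val))
        pred = net.predict(prep, plot_ids=list(test))
        fusion[n_crops] = {
            trait: regression_metrics(
                traits.loc[test, trait].to_numpy(), pred[trait].to_numpy()
            )["r2"]
            for trait in traits.columns
        }

    return {
        "design": design,
        "phenotypes": phenotypes,
        "scene": scene,
        "prep": prep,
        "splits": (train, val, test),
        "segmentation_accuracy": seg_accuracy,
        "rfr_test_r2": rfr_r2,
        "fusion_test_r2": fusion,
    }


def fusion_signal_r2(fusion_r2: dict[str, float]) -> float:
    """Mean test R² over the signal-bearing traits."""
    return float(np.mean([fusion_r2[t] for t in SIGNAL_TRAITS]))


# --------------------------------------------------------------------------
# Moran's I calibration
# --------------------------------------------------------------------------

def _grid_centroids(n_plots: int) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_plots)))
    xy = np.array([(i % side, i // side) for i in range(n_plots)], dtype=float)
    return xy


def moran_null_calibration(
    seed: int, n_plots: int = 100, n_reps: int = 200, n_permutations: int = 1999,
    alpha: float = 0.001,
) -> dict:
    """Null behavior of the Moran's I test on spatially random residuals.

    Returns the mean observed I over independent Gaussian residual fields
    (should approach −1/(n−1)) and the rejection rate at ``alpha`` (should
    stay at or below the nominal level).
    """
    coords = _grid_centroids(n_plots)
    rng = np.random.default_rng(seed)
    i_values = np.empty(n_reps)
    rejections = 0
    for rep in range(n_reps):
        resid = rng.standard_normal(n_plots)
        res = morans_i(resid, coords, n_permutations=n_permutations,
                       alpha=alpha, seed=seed + rep + 1)
        i_values[rep] = res.i
        rejections += int(res.significant)
    return {
        "mean_i": float(i_values.mean()),
        "expected_i": -1.0 / (n_plots - 1),
        "rejection_rate": rejections / n_reps,
        "alpha": alpha,
        "n_plots": n_plots,
        "n_reps": n_reps,
    }


def moran_clustered_detection(seed: int, n_plots: int = 100) -> dict:
    """Detection power on a maximally clustered residual field.

    Residuals are +1 on one spatial half of the grid and −1 on the other
    (plus a whisper of noise to break exact ties), the strongest possible
    clustering; the permutation test should reject decisively.
    """
    coords = _grid_centroids(n_plots)
    rng = np.random.default_rng(seed)
    half = np.median(coords[:, 1])
    resid = np.where(coords[:, 1] > half, 1.0, -1.0) + rng.normal(0, 1e-6, n_plots)
    res = morans_i(resid, coords, n_permutations=1999, alpha=0.001, seed=seed)
    return {"i": res.i, "p_value": res.p_value, "significant": res.significant}
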