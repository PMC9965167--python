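"""Fusion network: Huber loss, augmentation alignment, architecture, training."""

import numpy as np
import pandas as pd
import pytest

import maizefuse as mf
from maizefuse.nn import (
    AugmentationSpec,
    FusionNet,
    FusionNetRegressor,
    FusionNetSpec,
    TrainConfig,
    augment_crops,
    build_network,
    huber_loss,
    multitask_huber,
)


class TestHuberLoss:
    def test_branch_values(self):
        assert huber_loss(0.5, 0.0, delta=1.0) == pytest.approx(0.125)
        assert huber_loss(2.0, 0.0, delta=1.0) == pytest.approx(1.5)

    def test_continuity_at_delta(self):
        for delta in (0.5, 1.0, 2.3):
            quad = 0.5 * delta**2
            lin = delta * delta - 0.5 * delta**2
            assert quad == pytest.approx(lin)
            assert huber_loss(delta, 0.0, delta) == pytest.approx(quad)

    def test_equals_half_mse_below_delta_and_less_beyond(self, rng):
        r = rng.uniform(-0.99, 0.99, 100)
        np.testing.assert_allclose(huber_loss(r, 0.0, 1.0), 0.5 * r**2)
        big = rng.uniform(1.01, 10, 100)
        assert (huber_loss(big, 0.0, 1.0) < 0.5 * big**2).all()

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            huber_loss(1.0, 0.0, delta=0.0)

    def test_gradient_is_clipped_residual(self, rng):
        y = rng.normal(0, 2, (8, 3))
        f = rng.normal(0, 2, (8, 3))
        _, g = multitask_huber(y, f, delta=1.0)
        expect = -np.clip(y - f, -1, 1) / y.size
        np.testing.assert_allclose(g, expect)


class TestAugmentation:
    def _chipset(self, rng, shape=(30, 12)):
        return {
            "hyperspectral": rng.random((*shape, 6)),
            "height": rng.random(shape),
            "thermal": rng.random(shape),
        }

    def test_window_sized_chip_forces_zero_offsets(self, rng):
        chips = self._chipset(rng, shape=(24, 8))
        spec = AugmentationSpec(window=(24, 8), n_crops=20)
        crops, offsets = augment_crops(chips, spec, seed=0)
        assert len(crops) == 20
        assert (offsets == 0).all()

    def test_crop_count_multiplies_plots(self, rng):
        spec = AugmentationSpec(window=(20, 8), n_crops=20)
        total = 0
        for plot in range(10):
            crops, _ = augment_crops(self._chipset(rng), spec, seed=plot)
            total += len(crops)
        assert total == 200

    def test_offsets_identical_across_modalities(self, rng):
        chips = self._chipset(rng)
        spec = AugmentationSpec(window=(20, 8), n_crops=15)
        crops, offsets = augment_crops(chips, spec, seed=3)
        for (r, c), crop in zip(offsets, crops):
            for name, arr in chips.items():
                np.testing.assert_array_equal(
                    crop[name], arr[r : r + 20, c : c + 8]
                )

    def test_chip_smaller_than_window_raises(self, rng):
        chips = self._chipset(rng, shape=(10, 6))
        with pytest.raises(ValueError):
            augment_crops(chips, AugmentationSpec(window=(24, 8), n_crops=5), seed=0)


class TestArchitecture:
    def test_three_streams_fuse_to_192(self):
        spec = build_network(
            ("hyperspectral", "lidar_height", "lidar_intensity", "thermal"), n_tasks=8
        )
        assert len(spec.streams()) == 3  # LiDAR height+intensity share a stream
        assert spec.fusion_length == 192
        assert spec.filters == (8, 16, 32, 64)

    def test_single_stream_fusion_is_64(self):
        spec = build_network(("hyperspectral",), n_tasks=1)
        assert spec.fusion_length == 64

    def test_multitask_head_width(self):
        spec = build_network(("thermal",), n_tasks=8)
        net = FusionNet(spec, seed=0)
        assert net.head[-1].W.shape == (32, 8)

    def test_empty_modalities_rejected(self):
        with pytest.raises(ValueError):
            build_network((), n_tasks=1)

    def test_mono_and_multi_task_share_stream_init(self):
        small = dict(n_layers=2, filters=(4, 8))
        mono = FusionNet(build_network(("hyperspectral", "thermal"), 1, **small), seed=7)
        multi = FusionNet(build_network(("hyperspectral", "thermal"), 8, **small), seed=7)
        for name in mono.streams:
            for lm, lmu in zip(mono.streams[name], multi.streams[name]):
                for pm, pmu in zip(lm.params, lmu.params):
                    np.testing.assert_array_equal(pm, pmu)
        assert mono.head[-1].W.shape[1] == 1
        assert multi.head[-1].W.shape[1] == 8

    def test_full_scale_geometry_forward_pass(self):
        # the published geometry: 176 x 25 window, 270 bands, 4 conv layers
        spec = build_network(
            ("hyperspectral", "lidar_height", "lidar_intensity", "thermal"), n_tasks=8
        )
        net = FusionNet(spec, seed=0)
        rng = np.random.default_rng(0)
        X = {
            "hyperspectral": rng.random((1, 270, 176, 25, 1)),
            "lidar": rng.random((1, 176, 25, 2)),
            "thermal": rng.random((1, 176, 25, 1)),
        }
        out = net.forward(X, train=False)
        assert out.shape == (1, 8)
        assert np.isfinite(out).all()

    def test_zeroing_a_modality_only_changes_its_stream(self, rng):
        spec = build_network(("hyperspectral", "thermal"), 2, n_layers=2,
                             filters=(4, 8), dropout=0.0)
        net = FusionNet(spec, seed=1)
        X = {
            "hyperspectral": rng.random((2, 8, 12, 6, 1)),
            "thermal": rng.random((2, 12, 6, 1)),
        }
        pooled = {}
        for name, layers in net.streams.items():
            h = X[name]
            for layer in layers:
                h = layer.forward(h, train=False)
            pooled[name] = h
        X2 = dict(X)
        X2["thermal"] = np.zeros_like(X["thermal"])
        h = X2["hyperspectral"]
        for layer in net.streams["hyperspectral"]:
            h = layer.forward(h, train=False)
        np.testing.assert_array_equal(h, pooled["hyperspectral"])


@pytest.fixture(scope="module")
def tiny_trial():
    design, phenotypes, scene = mf.experiments.small_scene(
        seed=31, n_blocks=2, plots_per_block=4
    )
    prep = mf.plot_prep.prepare_plots(scene, margin=2, seed=0)
    traits = phenotypes[["dry_grain_yield", "total_plant_n"]]
    return prep, traits


class TestTraining:
    def test_memorizes_small_sample(self, tiny_trial):
        prep, traits = tiny_trial
        ids = list(traits.index)
        cfg = TrainConfig(n_crops=3, crop_window=(24, 8), batch_size=8,
                          max_epochs=50, patience=50, seed=0)
        net = FusionNetRegressor(
            modalities=("hyperspectral", "lidar_height"),
            spec=FusionNetSpec(n_layers=2, filters=(8, 16), dropout=0.1),
            config=cfg, seed=0,
        )
        net.fit(prep, traits, train_plots=ids[:6], val_plots=ids[6:])
        assert net.history_["train_loss"].iloc[-1] < 0.5 * net.history_["train_loss"].iloc[0]
        pred = net.predict(prep, plot_ids=ids[:6])
        assert np.isfinite(pred.to_numpy()).all()

    def test_no_plot_straddles_split(self, tiny_trial):
        prep, traits = tiny_trial
        cfg = TrainConfig(n_crops=1, crop_window=(24, 8), max_epochs=1, seed=0)
        net = FusionNetRegressor(
            modalities=("lidar_height",),
            spec=FusionNetSpec(n_layers=1, filters=(4,)),
            config=cfg, seed=0,
        )
        net.fit(prep, traits)
        assert not set(net.train_plots_) & set(net.val_plots_)
        assert set(net.train_plots_) | set(net.val_plots_) == set(traits.index)
        with pytest.raises(ValueError, match="straddle"):
            ids = list(traits.index)
            net.fit(prep, traits, train_plots=ids, val_plots=ids[:1])

    def test_inverse_standardization_roundtrip(self, tiny_trial):
        prep, traits = tiny_trial
        cfg = TrainConfig(n_crops=1, crop_window=(24, 8), max_epochs=1, seed=0)
        net = FusionNetRegressor(
            modalities=("lidar_height",),
            spec=FusionNetSpec(n_layers=1, filters=(4,)),
            config=cfg, seed=0,
        )
        net.fit(prep, traits)
        std = net.y_scaler_.transform(traits)
        back = net.y_scaler_.inverse_transform(std)
        pd.testing.assert_frame_equal(back, traits)

    def test_five_crop_aggregation(self, tiny_trial):
        prep, traits = tiny_trial
        ids = list(traits.index)
        cfg = TrainConfig(n_crops=1, crop_window=(24, 8), max_epochs=2, seed=0)
        net = FusionNetRegressor(
            modalities=("lidar_height",),
            spec=FusionNetSpec(n_layers=1, filters=(4,)),
            config=cfg, seed=0,
        )
        net.fit(prep, traits, train_plots=ids[:6], val_plots=ids[6:])
        center = net.predict(prep, plot_ids=ids[:3], aggregate="center")
        five = net.predict(prep, plot_ids=ids[:3], aggregate="five_crop")
        assert np.isfinite(five.to_numpy()).all()
        # corner views overlap the center view heavily; aggregates stay close
        assert np.abs(center.to_numpy() - five.to_numpy()).max() < 10 * np.abs(
            center.to_numpy()
        ).max()
        with pytest.raises(ValueError):
            net.predict(prep, plot_ids=ids[:1], aggregate="bogus")

    def test_same_seed_same_history(self, tiny_trial):
        prep, traits = tiny_trial
        ids = list(traits.index)

        def run():
            cfg = TrainConfig(n_crops=2, crop_window=(24, 8), batch_size=8,
                              max_epochs=3, seed=4)
            net = FusionNetRegressor(
                modalities=("lidar_height",),
                spec=FusionNetSpec(n_layers=1, filters=(4,)),
                config=cfg, seed=4,
            )
            net.fit(prep, traits, train_plots=ids[:6], val_plots=ids[6:])
            return net.history_

        pd.testing.assert_frame_equal(run(), run())
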