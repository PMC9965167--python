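"""Feature library: band lookup, index formulas, distribution-metric oracles."""

import numpy as np
import pytest

from maizefuse import features as ft


@pytest.fixture()
def flat_spectrum():
    wl = np.linspace(400, 1000, 121)  # 5 nm sampling
    return np.full_like(wl, 0.3), wl


class TestReflectanceAt:
    def test_nearest_band_with_lower_tie(self):
        wl = np.array([669.9, 672.1])
        spec = np.array([1.0, 2.0])
        # 670 is nearer 669.9; a perfect tie also resolves to the lower band
        assert ft.reflectance_at(spec, wl, 670.0) == 1.0
        assert ft.reflectance_at(spec, wl, 671.0) == 1.0

    def test_exact_center_returns_that_band(self, flat_spectrum):
        spec, wl = flat_spectrum
        spec = spec.copy()
        spec[40] = 0.77
        assert ft.reflectance_at(spec, wl, wl[40]) == 0.77

    def test_out_of_range_names_the_requester(self, flat_spectrum):
        spec, wl = flat_spectrum
        with pytest.raises(ValueError, match="NDVI"):
            ft.reflectance_at(spec, wl, 1100.0, requested_by="NDVI")


class TestHyperspectralIndices:
    def test_count_is_34_with_unique_names(self, flat_spectrum):
        out = ft.hyperspectral_indices(*flat_spectrum)
        assert len(out) == 34
        assert len(set(out)) == 34

    def test_ndvi_hand_value(self, flat_spectrum):
        spec, wl = flat_spectrum
        spec = spec.copy()
        spec[wl == 670.0] = 0.1
        spec[wl == 860.0] = 0.5
        out = ft.hyperspectral_indices(spec, wl)
        assert out["NDVI"] == pytest.approx((0.5 - 0.1) / (0.5 + 0.1))

    def test_flat_spectrum_identities(self, flat_spectrum):
        out = ft.hyperspectral_indices(*flat_spectrum)
        assert out["NDVI"] == pytest.approx(0.0)
        assert out["SR"] == pytest.approx(1.0)
        assert out["FRI2"] == pytest.approx(1.0)
        assert out["RGI"] == pytest.approx(1.0)
        assert out["FCI"] == pytest.approx(1.0)   # R²683/(R675*R691) with R ≡ c
        assert out["PRI"] == pytest.approx(0.0)
        # printed GNDVI is not a plain normalized difference: with R ≡ c it is
        # (c - c + c)/(c + c - c) = 1
        assert out["GNDVI"] == pytest.approx(1.0)
        # printed SIPI asymmetry (R800-R450)/(R800+R650) -> 0 for flat spectra
        assert out["SIPI"] == pytest.approx(0.0)

    def test_normalized_differences_bounded(self, rng):
        wl = np.linspace(400, 1000, 270)
        for _ in range(20):
            spec = rng.uniform(0.01, 1.0, size=270)
            out = ft.hyperspectral_indices(spec, wl)
            for name in ("NDVI", "NRI", "PRI", "NCPI", "PPR", "RNDVI", "WSCT", "CI", "NPQI"):
                assert -1.0 <= out[name] <= 1.0, name


class TestDistributionMetrics:
    def test_hand_values_on_small_sample(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        out = ft.distribution_metrics(vals, "H", canopy_ground_counts=(5, 0))
        assert out["Hmad"] == pytest.approx(1.4826)      # median 3, |dev| median 1
        assert out["Hcrr"] == pytest.approx(21 / 99)     # (22-1)/(100-1)
        assert out["Haad"] == pytest.approx(31.2)        # mean |dev| from mean 22
        assert out["Hiqr"] == pytest.approx(np.percentile(vals, 75) - np.percentile(vals, 25))
        assert out["Hmax"] == 100.0 and out["Hmin"] == 1.0

    def test_count_is_30_per_modality(self, rng):
        vals = rng.random(50)
        h = ft.distribution_metrics(vals, "H", canopy_ground_counts=(40, 10))
        i = ft.distribution_metrics(vals * 50, "I", canopy_ground_counts=(40, 10))
        assert len(h) == 30 and len(i) == 30
        assert all(k.startswith("H") for k in h)
        assert all(k.startswith("I") for k in i)

    def test_median_density_near_half_on_large_uniform(self, rng):
        vals = rng.random(100_000)
        out = ft.distribution_metrics(vals, "H", canopy_ground_counts=(1, 1))
        assert out["Hd50"] == pytest.approx(0.5, abs=0.01)

    def test_matches_bruteforce_oracle(self, rng):
        # sort/loop oracle for every percentile-type metric on random samples
        for _ in range(100):
            n = int(rng.integers(5, 1000))
            vals = rng.normal(2.0, 1.5, n)
            out = ft.distribution_metrics(vals, "H", canopy_ground_counts=(n, 0))
            s = np.sort(vals)
            for p in (10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 98, 99):
                # linear-interpolation percentile, computed by hand
                pos = (p / 100) * (n - 1)
                lo, hi = int(np.floor(pos)), int(np.ceil(pos))
                expect = s[lo] + (pos - lo) * (s[hi] - s[lo])
                assert out[f"H{p}"] == pytest.approx(expect, abs=1e-10)
            assert out["Hmean"] == pytest.approx(sum(vals) / n)
            assert out["Hsd"] == pytest.approx(np.sqrt(((vals - vals.mean()) ** 2).mean()))
            for p in (10, 30, 50, 70, 90):
                q = out[f"H{p}"]
                assert out[f"Hd{p}"] == pytest.approx(sum(v > q for v in vals) / n)

    def test_constant_input_warns_and_zeroes_cv_crr(self):
        with pytest.warns(UserWarning):
            out = ft.distribution_metrics(np.full(10, 3.0), "I",
                                          canopy_ground_counts=(10, 0))
        assert out["Icv"] == 0.0 and out["Icrr"] == 0.0

    def test_constant_shift_moves_location_not_spread(self, rng):
        vals = rng.normal(0, 1, 500)
        a = ft.distribution_metrics(vals, "H", canopy_ground_counts=(1, 1))
        b = ft.distribution_metrics(vals + 5.0, "H", canopy_ground_counts=(1, 1))
        for key in ("Hmean", "Hmin", "Hmax", "H50"):
            assert b[key] == pytest.approx(a[key] + 5.0, abs=1e-9)
        for key in ("Hsd", "Hmad", "Haad", "Hiqr"):
            assert b[key] == pytest.approx(a[key], abs=1e-9)


class TestThermalIndex:
    def test_printed_form_hand_value(self):
        # (30-20)/(30-40) = -1 exactly as the formula prints
        assert ft.thermal_index(30, 20, 40, form="printed") == pytest.approx(-1.0)

    def test_conventional_form_hand_value(self):
        assert ft.thermal_index(30, 20, 40, form="conventional") == pytest.approx(0.5)
        assert ft.thermal_index(20, 20, 40, form="conventional") == 0.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            ft.thermal_index(30, 40, 40)


class TestFeatureTable:
    def test_95_features_with_modality_split(self, prepped):
        scene, prep = prepped
        table = ft.feature_table(scene, prep)
        assert table.shape[1] == 95
        hyper = [c for c in table.columns if c in ft.SPECTRAL_INDEX_REGISTRY]
        height = [c for c in table.columns if c.startswith("H") and c not in hyper]
        inten = [c for c in table.columns if c.startswith("I") and c not in hyper]
        assert (len(hyper), len(height), len(inten)) == (34, 30, 30)
        assert "Tir" in table.columns
        assert not table.isna().any().any()
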