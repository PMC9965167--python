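"""Plot chip extraction, vegetation segmentation and feature scaling.

Each plot's multimodal chip (all spectral bands plus height, intensity and
thermal) is clustered into two classes with k-means++ on per-pixel z-scored
features; the cluster with the higher mean NIR reflectance (750-1000 nm) is
labeled vegetation — the NIR plateau of green canopy dominates soil and
shadow regardless of cluster index order.  Standardization is fit on
training rows only and is invertible, so deep-learning targets can be
rescaled back to physical units.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .synthetic_field import FieldScene


def polygon_window(
    polygon: Polygon,
    raster_shape: tuple[int, int],
    gsd: float,
    origin: tuple[float, float],
    margin: int = 0,
) -> tuple[slice, slice]:
    """Axis-aligned half-open pixel window covering ``polygon`` plus margin.

    Pixel (0, 0) covers field coords ``origin .. origin + gsd``; rows advance
    along +y, columns along +x.  The window is clipped at the raster edge.
    """
    minx, miny, maxx, maxy = polygon.bounds
    n_rows, n_cols = raster_shape
    c0 = int(np.floor((minx - origin[0]) / gsd + 1e-9)) - margin
    c1 = int(np.ceil((maxx - origin[0]) / gsd - 1e-9)) + margin
    r0 = int(np.floor((miny - origin[1]) / gsd + 1e-9)) - margin
    r1 = int(np.ceil((maxy - origin[1]) / gsd - 1e-9)) + margin
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, n_rows), min(c1, n_cols)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("polygon does not overlap the raster extent")
    return slice(r0, r1), slice(c0, c1)


def extract_chip(
    raster: np.ndarray,
    polygon: Polygon,
    gsd: float,
    origin: tuple[float, float],
    margin: int = 0,
) -> np.ndarray:
    """Cut the axis-aligned pixel window covering ``polygon`` (+margin)."""
    rs, cs = polygon_window(polygon, raster.shape[:2], gsd, origin, margin)
    return raster[rs, cs]


class VegetationSegmenter(BaseEstimator, ClusterMixin):
    """Two-class k-means++ vegetation/non-vegetation pixel segmentation.

    Parameters
    ----------
    n_clusters : int
        Number of pixel classes; a plot essentially has two (vegetation and
        everything else), so the default is 2.
    nir_range : tuple of float
        Wavelength window (nm) whose mean reflectance identifies the
        vegetation cluster.
    random_state : int
        Seed for the k-means++ initialization; segmentation is deterministic
        per seed.

    Attributes
    ----------
    kmeans_ : fitted :class:`sklearn.cluster.KMeans`
    vegetation_label_ : int
        Cluster index assigned to vegetation.
    degenerate_ : bool
        True when the chip had (near-)zero contrast and the whole chip was
        labeled vegetation by the fallback rule.
    """

    def __init__(self, n_clusters: int = 2, nir_range=(750.0, 1000.0), random_state: int = 0):
        self.n_clusters = n_clusters
        self.nir_range = nir_range
        self.random_state = random_state

    def _pixel_matrix(self, chip_stack: np.ndarray) -> np.ndarray:
        if chip_stack.ndim != 3:
            raise ValueError("chip_stack must be (rows, cols, n_features)")
        X = chip_stack.reshape(-1, chip_stack.shape[-1]).astype(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    def fit_predict_mask(self, chip_stack: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        """Segment one multimodal chip; returns a boolean vegetation mask.

        ``chip_stack`` is (rows, cols, n_spectral + n_aux); the first
        ``len(wavelengths)`` features are the reflectance bands used for the
        NIR labeling rule.
        """
        h, w, _ = chip_stack.shape
        if h * w < self.n_clusters:
            raise ValueError("chip has fewer pixels than clusters")
        X = self._pixel_matrix(chip_stack)
        if np.allclose(X.std(axis=0), 0.0):
            warnings.warn("degenerate chip (no pixel contrast): labeling all vegetation",
                          stacklevel=2)
            self.degenerate_ = True
            self.vegetation_label_ = 0
            return np.ones((h, w), dtype=bool)
        self.degenerate_ = False
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=10,
            random_state=self.random_state,
        )
        labels = km.fit_predict(X)
        self.kmeans_ = km

        wl = np.asarray(wavelengths, dtype=float)
        nir = (wl >= self.nir_range[0]) & (wl <= self.nir_range[1])
        if not nir.any():
            raise ValueError("no spectral bands inside the NIR labeling window")
        spectra = chip_stack.reshape(-1, chip_stack.shape[-1])[:, : len(wl)]
        nir_means = [
            spectra[labels == k][:, nir].mean() if (labels == k).any() else -np.inf
            for k in range(self.n_clusters)
        ]
        self.vegetation_label_ = int(np.argmax(nir_means))
        return (labels == self.vegetation_label_).reshape(h, w)


def segment_vegetation(
    chip_stack: np.ndarray, wavelengths: np.ndarray, k: int = 2, seed: int = 0
) -> np.ndarray:
    """Functional wrapper over :class:`VegetationSegmenter`."""
    return VegetationSegmenter(n_clusters=k, random_state=seed).fit_predict_mask(
        chip_stack, wavelengths
    )


def masked_mean(chip_band: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of masked pixels; NaN (nodata) pixels are excluded."""
    band = np.asarray(chip_band, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if band.shape != m.shape:
        raise ValueError("band and mask shapes differ")
    vals = band[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("mask selects no valid pixels")
    return float(vals.mean())


class TraitScaler(BaseEstimator):
    """Column z-scoring fit on training rows only, with exact inversion.

    Unlike a plain standard scaler this refuses zero-variance columns by
    name, because silently passing them through would poison downstream
    normalized indices.
    """

    def fit(self, table: pd.DataFrame, fit_rows=None) -> "TraitScaler":
        X = table.loc[fit_rows] if fit_rows is not None else table
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        dead = sd[sd == 0].index.tolist()
        if dead:
            raise ValueError(f"zero-variance columns: {dead}")
        self.columns_ = list(table.columns)
        self.mean_ = mu
        self.scale_ = sd
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted(table)
        return (table - self.mean_) / self.scale_

    def fit_transform(self, table: pd.DataFrame, fit_rows=None) -> pd.DataFrame:
        return self.fit(table, fit_rows).transform(table)

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted(table)
        return table * self.scale_ + self.mean_

    def inverse_transform_array(self, arr: np.ndarray) -> np.ndarray:
        return np.asarray(arr) * self.scale_.to_numpy() + self.mean_.to_numpy()

    def _check_fitted(self, table: pd.DataFrame) -> None:
        if not hasattr(self, "mean_"):
            raise ValueError("TraitScaler is not fitted")
        if list(table.columns) != self.columns_:
            raise ValueError("column mismatch with the fitted table")


def standardize(table: pd.DataFrame, fit_rows=None) -> tuple[pd.DataFrame, TraitScaler]:
    """Z-score ``table`` using statistics from ``fit_rows`` only."""
    scaler = TraitScaler()
    return scaler.fit_transform(table, fit_rows), scaler


# --------------------------------------------------------------------------
# scene-level preparation
# --------------------------------------------------------------------------

def prepare_plots(
    scene: FieldScene,
    margin: int = 0,
    seed: int = 0,
    use_truth_masks: bool = False,
) -> dict[str, dict]:
    """Extract and segment every plot of a scene.

    Returns ``{plot_id: {"window", "hyperspectral", "height", "intensity",
    "thermal", "mask"}}`` where the mask is the k-means vegetation mask
    (or the rendered truth mask when ``use_truth_masks``).
    """
    out: dict[str, dict] = {}
    for plot in scene.plots:
        rs, cs = scene.plot_pixel_window(plot, margin)
        hyper = scene.hyperspectral[rs, cs]
        aux = np.stack(
            [scene.height[rs, cs], scene.intensity[rs, cs], scene.thermal[rs, cs]], axis=-1
        )
        if use_truth_masks:
            mask = scene.truth_mask[rs, cs]
        else:
            stack = np.concatenate([hyper, aux], axis=-1)
            mask = segment_vegetation(stack, scene.wavelengths, seed=seed)
        out[plot.plot_id] = {
            "window": (rs, cs),
            "hyperspectral": hyper,
            "height": scene.height[rs, cs],
            "intensity": scene.intensity[rs, cs],
            "thermal": scene.thermal[rs, cs],
            "mask": mask,
        }
    return out


def band_mean_table(scene: FieldScene, prep: dict[str, dict]) -> pd.DataFrame:
    """Plot-wise masked mean of every band: n_plots x (n_spectral + 3).

    Columns are wavelengths (as strings, nm) followed by ``height``,
    ``intensity`` and ``thermal`` — the band stack consumed by the extended
    NDSI screen.
    """
    rows = {}
    wl = scene.wavelengths
    for plot_id, chips in prep.items():
        mask = chips["mask"]
        spectral = chips["hyperspectral"][mask].mean(axis=0)
        rows[plot_id] = np.r_[
            spectral,
            masked_mean(chips["height"], mask),
            masked_mean(chips["intensity"], mask),
            masked_mean(chips["thermal"], mask),
        ]
    cols = [f"{w:.1f}" for w in wl] + ["height", "intensity", "thermal"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).rename_axis("plot_id")
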