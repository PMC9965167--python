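"""Classified point clouds to canopy surface rasters.

The canopy height model (CHM) is the difference between the digital surface
model (DSM, highest non-ground return per grid cell) and the digital terrain
model (DTM, lowest ground return per cell, with voids filled by linear
interpolation over a triangulation of the ground points — the TIN method —
and cells outside the ground convex hull taking the nearest ground value).
Gridding is 2-D at the hyperspectral pixel size (3 cm) so the modalities
align without resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree

NODATA = np.nan


@dataclass
class SurfaceRaster:
    """A single-band surface grid in field coordinates.

    ``values[0, 0]`` is the cell whose lower-left corner sits at ``origin``;
    rows advance along +y, columns along +x.  Void cells hold NaN.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def aligned_with(self, other: "SurfaceRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


def _as_points(points: pd.DataFrame | np.ndarray, columns=("x", "y", "z")) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        return points
    arr = np.asarray(points, dtype=float)
    return pd.DataFrame(arr, columns=list(columns)[: arr.shape[1]])


def remove_outliers(
    points: pd.DataFrame,
    k_neighbors: int = 8,
    sigma_mult: float = 3.0,
    max_removed_fraction: float = 0.1,
) -> pd.DataFrame:
    """Statistical outlier removal on 3-D point positions.

    Drops points whose mean distance to their ``k_neighbors`` nearest
    neighbors exceeds the global mean by more than ``sigma_mult`` global
    standard deviations (isolated points in low-density regions).  At most
    ``max_removed_fraction`` of the cloud is ever removed; if the threshold
    flags more, only the worst offenders go.
    """
    pts = _as_points(points)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    n = len(pts)
    if n <= k_neighbors:
        raise ValueError(f"need more than {k_neighbors} points, got {n}")
    xyz = pts[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(xyz)
    dist, _ = tree.query(xyz, k=k_neighbors + 1)  # first neighbor is the point itself
    mean_d = dist[:, 1:].mean(axis=1)
    mu, sd = mean_d.mean(), mean_d.std()
    threshold = mu + sigma_mult * sd
    keep = mean_d <= threshold
    n_flagged = int((~keep).sum())
    cap = int(np.floor(max_removed_fraction * n))
    if n_flagged > cap:
        order = np.argsort(mean_d)[::-1]
        keep = np.ones(n, dtype=bool)
        keep[order[:cap]] = False
    return pts.loc[keep].reset_index(drop=True)


def _grid_shape(
    pts: pd.DataFrame, cell_size: float, origin: tuple[float, float] | None
) -> tuple[tuple[float, float], int, int]:
    if origin is None:
        origin = (float(pts["x"].min()), float(pts["y"].min()))
    n_cols = max(int(np.ceil((pts["x"].max() - origin[0]) / cell_size)), 1)
    n_rows = max(int(np.ceil((pts["y"].max() - origin[1]) / cell_size)), 1)
    # points exactly on the upper edge fall into the last cell
    if pts["x"].max() >= origin[0] + n_cols * cell_size:
        n_cols += 1
    if pts["y"].max() >= origin[1] + n_rows * cell_size:
        n_rows += 1
    return origin, n_rows, n_cols


def _cell_indices(
    pts: pd.DataFrame, cell_size: float, origin: tuple[float, float], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    col = np.clip(((pts["x"] - origin[0]) / cell_size).astype(int), 0, shape[1] - 1)
    row = np.clip(((pts["y"] - origin[1]) / cell_size).astype(int), 0, shape[0] - 1)
    return row.to_numpy(), col.to_numpy()


def rasterize_dsm(
    points: pd.DataFrame,
    cell_size: float = 0.03,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> SurfaceRaster:
    """Digital surface model: maximum non-ground z per cell, NaN where empty."""
    pts = _as_points(points)
    if "ground" in pts.columns:
        pts = pts.loc[~pts["ground"].astype(bool)]
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if len(pts) == 0:
        warnings.warn("no non-ground points; DSM is all nodata", stacklevel=2)
        out_shape = shape or (1, 1)
        return SurfaceRaster(np.full(out_shape, NODATA), cell_size, origin or (0.0, 0.0))
    if shape is None or origin is None:
        origin, n_rows, n_cols = _grid_shape(pts, cell_size, origin)
        shape = (n_rows, n_cols)
    row, col = _cell_indices(pts, cell_size, origin, shape)
    values = np.full(shape, -np.inf)
    np.maximum.at(values, (row, col), pts["z"].to_numpy(dtype=float))
    values[~np.isfinite(values)] = NODATA
    return SurfaceRaster(values, cell_size, origin)


def rasterize_intensity(
    points: pd.DataFrame,
    cell_size: float = 0.03,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
    rule: str = "max_height",
) -> SurfaceRaster:
    """Intensity surface from non-ground points.

    ``rule='max_height'`` (default) records the intensity carried by the
    highest point in each cell, mirroring DSM construction; ``rule='max'``
    records the per-cell maximum intensity instead.
    """
    pts = _as_points(points, columns=("x", "y", "z", "intensity"))
    if "ground" in pts.columns:
        pts = pts.loc[~pts["ground"].astype(bool)]
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if rule not in ("max_height", "max"):
        raise ValueError("rule must be 'max_height' or 'max'")
    if len(pts) == 0:
        warnings.warn("no non-ground points; intensity raster is all nodata", stacklevel=2)
        out_shape = shape or (1, 1)
        return SurfaceRaster(np.full(out_shape, NODATA), cell_size, origin or (0.0, 0.0))
    if shape is None or origin is None:
        origin, n_rows, n_cols = _grid_shape(pts, cell_size, origin)
        shape = (n_rows, n_cols)
    row, col = _cell_indices(pts, cell_size, origin, shape)
    values = np.full(shape, NODATA)
    if rule == "max":
        tmp = np.full(shape, -np.inf)
        np.maximum.at(tmp, (row, col), pts["intensity"].to_numpy(dtype=float))
        values = np.where(np.isfinite(tmp), tmp, NODATA)
    else:
        flat = row * shape[1] + col
        order = np.lexsort((pts["z"].to_numpy(dtype=float), flat))
        flat_sorted = flat[order]
        # last occurrence per cell after sorting by (cell, z) = highest point
        last = np.r_[flat_sorted[1:] != flat_sorted[:-1], True]
        idx = order[last]
        values.ravel()[flat[idx]] = pts["intensity"].to_numpy(dtype=float)[idx]
    return SurfaceRaster(values, cell_size, origin)


def rasterize_dtm(
    points: pd.DataFrame,
    cell_size: float = 0.03,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> SurfaceRaster:
    """Digital terrain model from ground points.

    Cells containing ground points take the minimum z (the lowest return best
    approximates bare earth); void cells are filled by linear interpolation
    over the Delaunay triangulation of the ground points (TIN); cells outside
    the convex hull take the nearest ground value.
    """
    pts = _as_points(points)
    if "ground" in pts.columns:
        pts = pts.loc[pts["ground"].astype(bool)]
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if len(pts) < 3:
        raise ValueError("need at least 3 ground points for a DTM")
    xy = pts[["x", "y"]].to_numpy(dtype=float)
    if np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        raise ValueError("ground points are collinear; TIN undefined")
    if shape is None or origin is None:
        origin, n_rows, n_cols = _grid_shape(pts, cell_size, origin)
        shape = (n_rows, n_cols)
    row, col = _cell_indices(pts, cell_size, origin, shape)
    values = np.full(shape, np.inf)
    np.minimum.at(values, (row, col), pts["z"].to_numpy(dtype=float))
    filled = np.isfinite(values)

    void_r, void_c = np.where(~filled)
    if void_r.size:
        cx = origin[0] + (void_c + 0.5) * cell_size
        cy = origin[1] + (void_r + 0.5) * cell_size
        centers = np.column_stack([cx, cy])
        lin = LinearNDInterpolator(xy, pts["z"].to_numpy(dtype=float))
        z_fill = lin(centers)
        outside = ~np.isfinite(z_fill)
        if outside.any():
            nn = NearestNDInterpolator(xy, pts["z"].to_numpy(dtype=float))
            z_fill[outside] = nn(centers[outside])
        values[void_r, void_c] = z_fill
    return SurfaceRaster(values, cell_size, origin)


def canopy_height(dsm: SurfaceRaster, dtm: SurfaceRaster) -> SurfaceRaster:
    """CHM = DSM − DTM, clipped at zero; nodata propagates."""
    if not dsm.aligned_with(dtm):
        raise ValueError("DSM and DTM grids are not aligned")
    chm = dsm.values - dtm.values
    chm = np.where(np.isnan(dsm.values) | np.isnan(dtm.values), NODATA, np.maximum(chm, 0.0))
    return SurfaceRaster(chm, dsm.cell_size, dsm.origin)
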