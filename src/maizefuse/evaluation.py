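"""Model evaluation: regression metrics, trait summaries, spatial residual
analysis and prediction maps.

Metric conventions follow the emulated study's printed formulas: R² is
1 − SS_res/SS_tot, MAE is the mean absolute residual, and RMSE divides the
squared-residual sum by n − 1 (the published form) by default; the
conventional n-denominator RMSE is one flag away.

Global Moran's I with row-standardized k-nearest-neighbor weights tests
whether plot-level prediction residuals are spatially random (expected value
−1/(n−1) under the null) using a two-sided permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


def regression_metrics(y: np.ndarray, yhat: np.ndarray, rmse_denominator: str = "n-1") -> dict:
    """R², RMSE and MAE of measured vs. predicted values.

    ``rmse_denominator`` selects the published ``'n-1'`` form (default) or
    the conventional ``'n'`` form.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D and aligned")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.std(y) == 0:
        raise ValueError("constant measured values: R² undefined")
    resid = yhat - y
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    r2 = 1.0 - ss_res / float(yc @ yc)
    if rmse_denominator == "n-1":
        rmse = float(np.sqrt(ss_res / (n - 1)))
    elif rmse_denominator == "n":
        rmse = float(np.sqrt(ss_res / n))
    else:
        raise ValueError("rmse_denominator must be 'n-1' or 'n'")
    return {"r2": r2, "rmse": rmse, "mae": float(np.mean(np.abs(resid))), "n": n}


def describe_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary per trait: count, mean, sd, cv%, min, quartiles, max.

    cv% = 100·sd/mean (NaN where the mean is zero); quartiles use linear
    interpolation.  Matches the layout of the emulated trial's published
    ground-truth summary.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 rows")
    num = traits.select_dtypes("number")
    rows = {}
    for col in num.columns:
        v = num[col].to_numpy(dtype=float)
        mean = v.mean()
        sd = v.std(ddof=1)
        rows[col] = {
            "count": len(v),
            "mean": mean,
            "sd": sd,
            "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
            "min": v.min(),
            "q25": np.percentile(v, 25),
            "q50": np.percentile(v, 50),
            "q75": np.percentile(v, 75),
            "max": v.max(),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("trait")


def cv_percent(mean: float, sd: float, decimals: int | None = None) -> float:
    """Coefficient of variation in percent, optionally rounded."""
    if mean == 0:
        raise ValueError("cv undefined for zero mean")
    cv = 100.0 * sd / mean
    return round(cv, decimals) if decimals is not None else cv


# --------------------------------------------------------------------------
# Global Moran's I
# --------------------------------------------------------------------------

@dataclass
class MoranResult:
    i: float                # observed Moran's I
    expected: float         # −1/(n−1)
    p_value: float          # two-sided permutation p
    significant: bool       # p < alpha
    alpha: float
    weights: str
    n_permutations: int


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardized k-nearest-neighbor spatial weights (dense)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError("k must be smaller than the number of locations")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    W[rows, idx[:, 1:].ravel()] = 1.0 / k
    return W


def inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """Row-standardized inverse-distance weights (dense, zero diagonal)."""
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    W /= W.sum(axis=1, keepdims=True)
    return W


def _moran_stat(z: np.ndarray, W: np.ndarray) -> float:
    # row-standardized: S0 = n, so I = z'Wz / z'z
    return float(z @ (W @ z) / (z @ z))


def morans_i(
    residuals: np.ndarray,
    coords: np.ndarray,
    weights: str = "knn",
    k: int = 8,
    n_permutations: int = 999,
    alpha: float = 0.001,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I of plot residuals with a permutation significance test.

    The null hypothesis is complete spatial randomness of the residuals; its
    analytic expectation is −1/(n−1).  The p-value is two-sided: the share of
    label permutations whose |I − E[I]| reaches the observed one.
    """
    resid = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(resid)
    if n < 4:
        raise ValueError("need at least 4 plots")
    if np.std(resid) == 0:
        raise ValueError("all residuals equal: Moran's I undefined")
    if weights == "knn":
        W = knn_weights(coords, k=k)
        scheme = f"knn(k={k}, row-standardized)"
    elif weights == "idw":
        W = inverse_distance_weights(coords)
        scheme = "inverse-distance (row-standardized)"
    else:
        raise ValueError("weights must be 'knn' or 'idw'")

    z = resid - resid.mean()
    i_obs = _moran_stat(z, W)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for b in range(n_permutations):
        perm[b] = _moran_stat(rng.permutation(z), W)
    extreme = np.abs(perm - expected) >= abs(i_obs - expected) - 1e-15
    p = (1.0 + extreme.sum()) / (n_permutations + 1.0)
    return MoranResult(
        i=i_obs,
        expected=expected,
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
        weights=scheme,
        n_permutations=n_permutations,
    )


# --------------------------------------------------------------------------
# prediction maps
# --------------------------------------------------------------------------

def prediction_map(
    predictions: pd.Series,
    measured: pd.Series,
    plots,
    path: str | None = None,
) -> dict:
    """GeoJSON FeatureCollection of plot polygons with prediction attributes.

    Each feature carries predicted, measured and residual (= measured −
    predicted) values plus the treatment label.  Optionally renders a
    choropleth PNG of the predictions when ``path`` is given.
    """
    missing = [p.plot_id for p in plots if p.plot_id not in predictions.index]
    if missing:
        raise ValueError(f"plots without predictions: {missing}")
    features = []
    for plot in plots:
        pred = float(predictions.loc[plot.plot_id])
        meas = float(measured.loc[plot.plot_id])
        features.append(
            {
                "type": "Feature",
                "geometry": plot.polygon.__geo_interface__,
                "properties": {
                    "plot_id": plot.plot_id,
                    "treatment": plot.treatment,
                    "predicted": pred,
                    "measured": meas,
                    "residual": meas - pred,
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        _render_choropleth(collection, path)
    return collection


def plot_moran_bars(results: dict[str, MoranResult], path: str) -> None:
    """Bar chart of Moran's I per label, asterisked where significant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(results)), 4))
    labels = list(results)
    values = [results[k].i for k in labels]
    ax.bar(labels, values)
    for x, k in enumerate(labels):
        if results[k].significant:
            ax.annotate("*", (x, results[k].i), ha="center", fontsize=14)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("Moran's I")
    ax.tick_params(axis="x", rotation=45, labelsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _render_choropleth(collection: dict, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    fig, ax = plt.subplots(figsize=(6, 8))
    patches, values = [], []
    for feat in collection["features"]:
        ring = feat["geometry"]["coordinates"][0]
        patches.append(MplPolygon(np.asarray(ring)[:, :2], closed=True))
        values.append(feat["properties"]["predicted"])
    pc = PatchCollection(patches, cmap="viridis")
    pc.set_array(np.asarray(values))
    ax.add_collection(pc)
    ax.autoscale()
    ax.set_aspect("equal")
    fig.colorbar(pc, ax=ax, label="predicted")
    fig.savefig(path, dpi=120)
    plt.close(fig)
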