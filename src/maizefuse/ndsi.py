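"""Extended normalized difference spectral index (NDSI) screening.

NDSI(i, j) = (M_i − M_j) / (M_i + M_j) over plot-wise band means M, extended
beyond spectral pairs to LiDAR canopy height, LiDAR intensity and thermal
"bands".  The screen evaluates every unordered band pair against every trait
via the squared Pearson correlation (equivalently, simple-regression R²) and
reports a heatmap plus the best pair per trait.

Auxiliary bands are z-scored across plots before entering the index by
default: raw heights in meters or temperatures in °C would make M_i + M_j
scale-dependent and can push the index far outside [−1, 1].  Raw-scale mode
is available via ``standardize_aux=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AUX_BANDS = ("height", "intensity", "thermal")


def ndsi(m_i, m_j):
    """Normalized difference of two band means; NaN where the sum is ~0.

    Antisymmetric under index swap, and within [−1, 1] whenever both means
    are nonnegative.
    """
    m_i = np.asarray(m_i, dtype=float)
    m_j = np.asarray(m_j, dtype=float)
    denom = m_i + m_j
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(denom) < 1e-300, np.nan, (m_i - m_j) / denom)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class NdsiHeatmap:
    """R² over all unordered band pairs for one trait."""

    r2: pd.DataFrame          # symmetric matrix, NaN on the diagonal/invalid pairs
    trait: str
    best: tuple[str, str, float]  # (band_i, band_j, R²)


def _prepare_stack(stack: pd.DataFrame, standardize_aux: bool) -> pd.DataFrame:
    if stack.isna().any().any():
        raise ValueError("band stack contains missing values")
    out = stack.astype(float).copy()
    if standardize_aux:
        for aux in AUX_BANDS:
            if aux in out.columns:
                col = out[aux]
                sd = col.std(ddof=0)
                out[aux] = (col - col.mean()) / sd if sd > 0 else 0.0
    return out


def heatmap(
    stack: pd.DataFrame,
    trait: pd.Series,
    trait_name: str = "trait",
    standardize_aux: bool = True,
) -> NdsiHeatmap:
    """Exhaustive NDSI-vs-trait R² screen over all band pairs.

    ``stack`` is the plot x band matrix of masked means (spectral columns
    first, optionally followed by height/intensity/thermal).  R² is the
    squared Pearson correlation between per-plot NDSI values and the trait.
    Pairs with an undefined NDSI on any plot are flagged NaN.
    """
    if len(stack) < 3:
        raise ValueError("need at least 3 plots")
    y = np.asarray(trait, dtype=float)
    if len(y) != len(stack):
        raise ValueError("trait length does not match the stack")
    if np.std(y) == 0:
        raise ValueError("trait is constant; R² undefined")

    M = _prepare_stack(stack, standardize_aux).to_numpy()
    bands = list(stack.columns)
    n_bands = M.shape[1]
    yc = y - y.mean()
    ss_y = float(yc @ yc)

    r2 = np.full((n_bands, n_bands), np.nan)
    for i in range(n_bands):
        denom = M[:, [i]] + M[:, i + 1 :]
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = (M[:, [i]] - M[:, i + 1 :]) / denom
        vals[np.abs(denom) < 1e-300] = np.nan
        valid = ~np.isnan(vals).any(axis=0)
        vc = vals - vals.mean(axis=0)
        ss_v = np.einsum("ij,ij->j", vc, vc)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (yc @ np.nan_to_num(vc)) / np.sqrt(ss_v * ss_y)
        row = np.where(valid & (ss_v > 0), corr**2, np.nan)
        r2[i, i + 1 :] = row
        r2[i + 1 :, i] = row
    frame = pd.DataFrame(r2, index=bands, columns=bands)
    return NdsiHeatmap(r2=frame, trait=trait_name, best=best_pair(frame))


def best_pair(r2: pd.DataFrame | NdsiHeatmap) -> tuple[str, str, float]:
    """Argmax pair of a heatmap; ties break toward smaller band labels.

    Band labels sort numerically where possible (wavelengths), with the
    named auxiliary bands after all spectral bands.
    """
    frame = r2.r2 if isinstance(r2, NdsiHeatmap) else r2
    vals = frame.to_numpy()
    mask = np.triu(np.ones_like(vals, dtype=bool), k=1) & np.isfinite(vals)
    if not mask.any():
        raise ValueError("no valid band pairs in the heatmap")
    best_val = vals[mask].max()
    ii, jj = np.where(mask & np.isclose(vals, best_val, rtol=0, atol=0))

    def sort_key(idx: int):
        label = frame.index[idx]
        try:
            return (0, float(label))
        except (TypeError, ValueError):
            return (1, AUX_BANDS.index(label) if label in AUX_BANDS else 99)

    order = sorted(zip(ii, jj), key=lambda p: (sort_key(p[0]), sort_key(p[1])))
    i, j = order[0]
    return (str(frame.index[i]), str(frame.columns[j]), float(vals[i, j]))


def screen_all_traits(
    stack: pd.DataFrame,
    traits: pd.DataFrame,
    standardize_aux: bool = True,
) -> dict[str, NdsiHeatmap]:
    """One heatmap per trait column; returns ``{trait: NdsiHeatmap}``."""
    return {
        name: heatmap(stack, traits[name], name, standardize_aux) for name in traits.columns
    }


def save_heatmap_png(hm: NdsiHeatmap, path: str) -> None:
    """Render one R² heatmap with the best pair marked by a cross."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(hm.r2.to_numpy(), cmap="jet", vmin=0, vmax=1, origin="lower")
    labels = list(hm.r2.index)
    i, j = labels.index(hm.best[0]), labels.index(hm.best[1])
    ax.plot([j], [i], marker="x", color="lime", markersize=10, mew=3)
    ax.set_title(f"{hm.trait}: best R² = {hm.best[2]:.3f} at ({hm.best[0]}, {hm.best[1]})")
    ax.set_xlabel("band j")
    ax.set_ylabel("band i")
    fig.colorbar(im, ax=ax, label="R²")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def best_pair_table(heatmaps: dict[str, NdsiHeatmap]) -> pd.DataFrame:
    rows = {
        name: {"band_i": hm.best[0], "band_j": hm.best[1], "r2": hm.best[2]}
        for name, hm in heatmaps.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("trait")
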