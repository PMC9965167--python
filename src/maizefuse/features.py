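"""Handcrafted feature library across data modalities.

95 named features per plot: 34 hyperspectral vegetation indices evaluated on
the masked plot-mean spectrum, 30 distribution metrics of canopy height, the
same 30 metrics of LiDAR intensity, and one normalized relative canopy
temperature index.  Formulas follow the published index definitions; where a
published cell is blank (e.g. the mode of a continuous sample, or the
canopy/ground ratio in raster space) the convention used here is declared in
the docstring of the relevant function.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats

UNDEFINED = float("nan")

# acronym -> (formula description, wavelengths used)
SPECTRAL_INDEX_REGISTRY: dict[str, tuple[str, tuple[float, ...]]] = {
    "Ant_Gitelson": ("(1/R550 - 1/R700) * R780", (550, 700, 780)),
    "CI": ("(R750 - R705)/(R750 + R705)", (750, 705)),
    "OSAVI": ("(1 + 0.16)*(R800 - R670)/(R800 + R670 + 0.16)", (800, 670)),
    "RGI": ("R690/R550", (690, 550)),
    "SIPI": ("(R800 - R450)/(R800 + R650)", (800, 450, 650)),
    "TCARI": ("3*((R700 - R670) - 0.2*(R700 - R550)*(R700/R670))", (700, 670, 550)),
    "NRI": ("(R570 - R670)/(R570 + R670)", (570, 670)),
    "mCARI": ("1.2*(2.5*(R761 - R651) - 1.3*(R761 - R581))", (761, 651, 581)),
    "PRI": ("(R531 - R570)/(R531 + R570)", (531, 570)),
    "RARSa": ("R675/R700", (675, 700)),
    "RARSb": ("R675/(R700 * R650)", (675, 700, 650)),
    "RARSc": ("R760/R500", (760, 500)),
    "PSSR": ("R800/R680", (800, 680)),
    "PSRI": ("(R660 - R510)/R760", (660, 510, 760)),
    "NCPI": ("(R670 - R450)/(R670 + R450)", (670, 450)),
    "PPR": ("(R550 - R450)/(R550 + R450)", (550, 450)),
    "NDVI": ("(R860 - R670)/(R860 + R670)", (860, 670)),
    "GI": ("R554/R677", (554, 677)),
    "GNDVI": ("(R750 - R540 + R570)/(R750 + R540 - R570)", (750, 540, 570)),
    "SR": ("R900/R680", (900, 680)),
    "RNDVI": ("(R750 - R705)/(R750 + R705)", (750, 705)),
    "MTVI": ("1.2*(1.2*(R800 - R550) - 2.5*(R670 - R550))", (800, 550, 670)),
    "TVI": ("0.5*(120*(R761 - R581) - 200*(R651 - R581))", (761, 581, 651)),
    "FRI1": ("R690/R630", (690, 630)),
    "FRI2": ("R750/R800", (750, 800)),
    "FRI3": ("R690/R600", (690, 600)),
    "FRI4": ("R740/R800", (740, 800)),
    "FCI": ("R683^2/(R675 * R691)", (683, 675, 691)),
    "mRESR": ("(R750 - R445)/(R705 + R445)", (750, 445, 705)),
    "NPQI": ("(R415 - R435)/(R415 + R435)", (415, 435)),
    "RVS1": ("((R651 + R750)/2) - R733", (651, 750, 733)),
    "RVS2": ("((R651 + R750)/2) - R751", (651, 750, 751)),
    "WI": ("R900/R970", (900, 970)),
    "WSCT": ("(R970 - R850)/(R970 + R850)", (970, 850)),
}

DISTRIBUTION_METRIC_SUFFIXES = (
    ["max", "min", "mean", "mode", "sd", "cv", "mad", "aad"]
    + [f"{p}" for p in (10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 98, 99)]
    + ["iqr", "skn", "kurt", "d10", "d30", "d50", "d70", "d90", "crr", "cg"]
)

N_SPECTRAL_FEATURES = len(SPECTRAL_INDEX_REGISTRY)       # 34
N_DISTRIBUTION_FEATURES = len(DISTRIBUTION_METRIC_SUFFIXES)  # 30
N_THERMAL_FEATURES = 1


def reflectance_at(
    mean_spectrum: np.ndarray,
    wavelengths: np.ndarray,
    wavelength_nm: float,
    requested_by: str = "?",
) -> float:
    """Reflectance of the band nearest the requested wavelength.

    Ties between two equally near band centers resolve to the lower
    wavelength.  Requests outside the sensed range (± half a sampling
    interval) raise, naming the index that asked.
    """
    wl = np.asarray(wavelengths, dtype=float)
    spectrum = np.asarray(mean_spectrum, dtype=float)
    half_step = np.median(np.diff(wl)) / 2.0 if len(wl) > 1 else 0.0
    if wavelength_nm < wl[0] - half_step or wavelength_nm > wl[-1] + half_step:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside sensed range "
            f"[{wl[0]}, {wl[-1]}] (requested by {requested_by})"
        )
    dist = np.abs(wl - wavelength_nm)
    # argmin returns the first (= lower-wavelength) index on exact ties
    return float(spectrum[int(np.argmin(dist))])


def hyperspectral_indices(
    mean_spectrum: np.ndarray, wavelengths: np.ndarray
) -> dict[str, float]:
    """All 34 vegetation indices of the library, from one mean spectrum."""

    def R(nm: float, who: str) -> float:
        return reflectance_at(mean_spectrum, wavelengths, nm, who)

    def safe_div(num: float, den: float) -> float:
        return num / den if abs(den) > 1e-12 else UNDEFINED

    out: dict[str, float] = {}
    out["Ant_Gitelson"] = (
        (safe_div(1.0, R(550, "Ant_Gitelson")) - safe_div(1.0, R(700, "Ant_Gitelson")))
        * R(780, "Ant_Gitelson")
    )
    out["CI"] = safe_div(R(750, "CI") - R(705, "CI"), R(750, "CI") + R(705, "CI"))
    out["OSAVI"] = 1.16 * safe_div(
        R(800, "OSAVI") - R(670, "OSAVI"), R(800, "OSAVI") + R(670, "OSAVI") + 0.16
    )
    out["RGI"] = safe_div(R(690, "RGI"), R(550, "RGI"))
    out["SIPI"] = safe_div(R(800, "SIPI") - R(450, "SIPI"), R(800, "SIPI") + R(650, "SIPI"))
    out["TCARI"] = 3.0 * (
        (R(700, "TCARI") - R(670, "TCARI"))
        - 0.2 * (R(700, "TCARI") - R(550, "TCARI")) * safe_div(R(700, "TCARI"), R(670, "TCARI"))
    )
    out["NRI"] = safe_div(R(570, "NRI") - R(670, "NRI"), R(570, "NRI") + R(670, "NRI"))
    out["mCARI"] = 1.2 * (
        2.5 * (R(761, "mCARI") - R(651, "mCARI")) - 1.3 * (R(761, "mCARI") - R(581, "mCARI"))
    )
    out["PRI"] = safe_div(R(531, "PRI") - R(570, "PRI"), R(531, "PRI") + R(570, "PRI"))
    out["RARSa"] = safe_div(R(675, "RARSa"), R(700, "RARSa"))
    out["RARSb"] = safe_div(R(675, "RARSb"), R(700, "RARSb") * R(650, "RARSb"))
    out["RARSc"] = safe_div(R(760, "RARSc"), R(500, "RARSc"))
    out["PSSR"] = safe_div(R(800, "PSSR"), R(680, "PSSR"))
    out["PSRI"] = safe_div(R(660, "PSRI") - R(510, "PSRI"), R(760, "PSRI"))
    out["NCPI"] = safe_div(R(670, "NCPI") - R(450, "NCPI"), R(670, "NCPI") + R(450, "NCPI"))
    out["PPR"] = safe_div(R(550, "PPR") - R(450, "PPR"), R(550, "PPR") + R(450, "PPR"))
    out["NDVI"] = safe_div(R(860, "NDVI") - R(670, "NDVI"), R(860, "NDVI") + R(670, "NDVI"))
    out["GI"] = safe_div(R(554, "GI"), R(677, "GI"))
    out["GNDVI"] = safe_div(
        R(750, "GNDVI") - R(540, "GNDVI") + R(570, "GNDVI"),
        R(750, "GNDVI") + R(540, "GNDVI") - R(570, "GNDVI"),
    )
    out["SR"] = safe_div(R(900, "SR"), R(680, "SR"))
    out["RNDVI"] = safe_div(
        R(750, "RNDVI") - R(705, "RNDVI"), R(750, "RNDVI") + R(705, "RNDVI")
    )
    out["MTVI"] = 1.2 * (
        1.2 * (R(800, "MTVI") - R(550, "MTVI")) - 2.5 * (R(670, "MTVI") - R(550, "MTVI"))
    )
    out["TVI"] = 0.5 * (
        120.0 * (R(761, "TVI") - R(581, "TVI")) - 200.0 * (R(651, "TVI") - R(581, "TVI"))
    )
    out["FRI1"] = safe_div(R(690, "FRI1"), R(630, "FRI1"))
    out["FRI2"] = safe_div(R(750, "FRI2"), R(800, "FRI2"))
    out["FRI3"] = safe_div(R(690, "FRI3"), R(600, "FRI3"))
    out["FRI4"] = safe_div(R(740, "FRI4"), R(800, "FRI4"))
    out["FCI"] = safe_div(R(683, "FCI") ** 2, R(675, "FCI") * R(691, "FCI"))
    out["mRESR"] = safe_div(
        R(750, "mRESR") - R(445, "mRESR"), R(705, "mRESR") + R(445, "mRESR")
    )
    out["NPQI"] = safe_div(R(415, "NPQI") - R(435, "NPQI"), R(415, "NPQI") + R(435, "NPQI"))
    out["RVS1"] = (R(651, "RVS1") + R(750, "RVS1")) / 2.0 - R(733, "RVS1")
    out["RVS2"] = (R(651, "RVS2") + R(750, "RVS2")) / 2.0 - R(751, "RVS2")
    out["WI"] = safe_div(R(900, "WI"), R(970, "WI"))
    out["WSCT"] = safe_div(R(970, "WSCT") - R(850, "WSCT"), R(970, "WSCT") + R(850, "WSCT"))
    assert list(out) == list(SPECTRAL_INDEX_REGISTRY)
    return out


def distribution_metrics(
    values: np.ndarray,
    prefix: str,
    mode_bin_width: float | None = None,
    canopy_ground_counts: tuple[int, int] | None = None,
) -> dict[str, float]:
    """30 distribution metrics of masked plot pixel values.

    Conventions for quantities the source table leaves blank:

    * percentiles use linear interpolation between order statistics;
    * ``mode`` is the midpoint of the argmax bin of a histogram with
      ``mode_bin_width`` (default 0.05 for height ('H'), 5.0 for
      intensity ('I'));
    * ``d10..d90`` (canopy return densities) are the proportion of values
      strictly above the sample's own 10th..90th quantiles;
    * ``crr`` (canopy relief ratio) is (mean − min)/(max − min);
    * ``cg`` is the canopy-to-ground return ratio from
      ``canopy_ground_counts`` (vegetation vs. non-vegetation pixel counts
      within the plot); with zero ground returns it falls back to the canopy
      count, and when counts are not supplied it is NaN;
    * skewness is moment-based; kurtosis is excess kurtosis.

    Constant input makes cv and crr undefined: both become 0 with a warning.
    """
    if prefix not in ("H", "I"):
        raise ValueError("prefix must be 'H' (height) or 'I' (intensity)")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if mode_bin_width is None:
        mode_bin_width = 0.05 if prefix == "H" else 5.0

    vmax, vmin, vmean = float(v.max()), float(v.min()), float(v.mean())
    sd = float(v.std(ddof=0))
    constant = vmax == vmin
    if constant:
        warnings.warn("constant input: cv and relief ratio set to 0", stacklevel=2)
        cv = 0.0
        crr = 0.0
        mode_val = vmean
    else:
        cv = sd / vmean if vmean != 0 else UNDEFINED
        crr = (vmean - vmin) / (vmax - vmin)
        n_bins = max(int(np.ceil((vmax - vmin) / mode_bin_width)), 1)
        counts, edges = np.histogram(v, bins=n_bins, range=(vmin, vmin + n_bins * mode_bin_width))
        k = int(np.argmax(counts))
        mode_val = float((edges[k] + edges[k + 1]) / 2.0)

    med = float(np.median(v))
    mad = 1.4826 * float(np.median(np.abs(v - med)))
    aad = float(np.mean(np.abs(v - vmean)))
    pcts = {p: float(np.percentile(v, p)) for p in (10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 98, 99)}
    iqr = pcts[75] - pcts[25]
    skn = float(stats.skew(v, bias=True)) if not constant else 0.0
    kurt = float(stats.kurtosis(v, fisher=True, bias=True)) if not constant else 0.0
    densities = {f"d{p}": float(np.mean(v > pcts[p])) for p in (10, 30, 50, 70, 90)}

    if canopy_ground_counts is None:
        cg = UNDEFINED
    else:
        n_canopy, n_ground = canopy_ground_counts
        cg = n_canopy / n_ground if n_ground > 0 else float(n_canopy)

    out = {
        f"{prefix}max": vmax,
        f"{prefix}min": vmin,
        f"{prefix}mean": vmean,
        f"{prefix}mode": mode_val,
        f"{prefix}sd": sd,
        f"{prefix}cv": cv,
        f"{prefix}mad": mad,
        f"{prefix}aad": aad,
    }
    for p in (10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 98, 99):
        out[f"{prefix}{p}"] = pcts[p]
    out[f"{prefix}iqr"] = iqr
    out[f"{prefix}skn"] = skn
    out[f"{prefix}kurt"] = kurt
    for name, val in densities.items():
        out[f"{prefix}{name}"] = val
    out[f"{prefix}crr"] = crr
    out[f"{prefix}cg"] = cg
    assert len(out) == N_DISTRIBUTION_FEATURES
    return out


def thermal_index(
    t_plot: float, t_min: float, t_max: float, form: str = "printed"
) -> float:
    """Normalized relative canopy temperature index Tir.

    ``form='printed'`` evaluates (Ti − Tmin)/(Ti − Tmax) — the formula as
    published, whose denominator is negative for canopy cooler than the field
    maximum.  ``form='conventional'`` selects the usual normalization
    (Ti − Tmin)/(Tmax − Tmin).
    """
    if t_max <= t_min:
        raise ValueError("t_max must exceed t_min")
    if form == "printed":
        denom = t_plot - t_max
        return (t_plot - t_min) / denom if abs(denom) > 1e-12 else UNDEFINED
    if form == "conventional":
        return (t_plot - t_min) / (t_max - t_min)
    raise ValueError("form must be 'printed' or 'conventional'")


def feature_vector(
    mean_spectrum: np.ndarray,
    wavelengths: np.ndarray,
    height_values: np.ndarray,
    intensity_values: np.ndarray,
    t_plot: float,
    t_min: float,
    t_max: float,
    canopy_ground_counts: tuple[int, int] | None = None,
    thermal_form: str = "printed",
) -> dict[str, float]:
    """The full 95-feature vector (34 spectral + 30 H + 30 I + 1 thermal)."""
    out = hyperspectral_indices(mean_spectrum, wavelengths)
    out.update(distribution_metrics(height_values, "H",
                                    canopy_ground_counts=canopy_ground_counts))
    out.update(distribution_metrics(intensity_values, "I",
                                    canopy_ground_counts=canopy_ground_counts))
    out["Tir"] = thermal_index(t_plot, t_min, t_max, form=thermal_form)
    assert len(out) == N_SPECTRAL_FEATURES + 2 * N_DISTRIBUTION_FEATURES + N_THERMAL_FEATURES
    return out


def feature_table(
    scene, prep: dict[str, dict], thermal_form: str = "printed"
) -> pd.DataFrame:
    """Per-plot 95-feature table for a prepared scene.

    Tir normalizes each plot-mean canopy temperature against the field's
    pixel-level thermal range, so the printed form stays defined for every
    plot (canopy means sit strictly below the field's hottest pixel).
    """
    from .plot_prep import masked_mean

    t_means = {
        pid: masked_mean(chips["thermal"], chips["mask"]) for pid, chips in prep.items()
    }
    t_min = float(np.nanmin(scene.thermal))
    t_max = float(np.nanmax(scene.thermal))
    if t_max <= t_min:
        t_max = t_min + 1e-6
    rows = {}
    for pid, chips in prep.items():
        mask = chips["mask"]
        counts = (int(mask.sum()), int((~mask).sum()))
        rows[pid] = feature_vector(
            mean_spectrum=chips["hyperspectral"][mask].mean(axis=0),
            wavelengths=scene.wavelengths,
            height_values=chips["height"][mask],
            intensity_values=chips["intensity"][mask],
            t_plot=t_means[pid],
            t_min=t_min,
            t_max=t_max,
            canopy_ground_counts=counts,
            thermal_form=thermal_form,
        )
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("plot_id")


def feature_registry_json() -> str:
    """Machine-readable registry mapping feature names to their formulas."""
    registry: dict[str, str] = {
        name: formula for name, (formula, _) in SPECTRAL_INDEX_REGISTRY.items()
    }
    for prefix, modality in (("H", "canopy height"), ("I", "canopy intensity")):
        for suffix in DISTRIBUTION_METRIC_SUFFIXES:
            registry[f"{prefix}{suffix}"] = f"{modality}: distribution metric '{suffix}'"
    registry["Tir"] = "(Ti - Tmin)/(Ti - Tmax) [printed form; conventional form available]"
    return json.dumps(registry, indent=2)
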