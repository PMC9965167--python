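"""Reference constants for the maize nitrogen field trial the package emulates.

The simulated study mirrors a 2020 Urbana (IL) corn experiment: 369 single-row
plots of roughly 5.33 m x 0.76 m, randomized along adjacent north-south blocks
that received either no supplemental nitrogen (low N) or 225 kg/ha of granular
ammonium sulfate (high N).  Aerial data were collected at 3 cm ground sampling
distance with a 270-band VNIR imager (400-1000 nm), a 905 nm LiDAR and a
thermal camera.

``FIELD_TRIAL_SUMMARY`` holds the published end-of-season descriptive
statistics of the eight ground-truth phenotypes (plot count, mean, standard
deviation, coefficient of variation in percent, minimum, quartiles, maximum).
The synthetic-field generator targets these scales and shapes; the acceptance
script recomputes the cv column from the mean/sd columns as a worked example.
"""

from __future__ import annotations

import pandas as pd

TRAIT_NAMES = (
    "dry_stalk_biomass",
    "cob_biomass",
    "dry_grain_yield",
    "harvest_index",
    "grain_nute",
    "grain_n",
    "total_plant_n",
    "grain_density",
)

TRAIT_UNITS = {
    "dry_stalk_biomass": "kg/ha",
    "cob_biomass": "kg/ha",
    "dry_grain_yield": "kg/ha",
    "harvest_index": "-",
    "grain_nute": "-",
    "grain_n": "kg/ha",
    "total_plant_n": "kg/ha",
    "grain_density": "-",
}

# columns: count, mean, sd, cv_pct, min, q25, q50, q75, max
_SUMMARY_ROWS = {
    "dry_stalk_biomass": (369, 6510.82, 2153.74, 33.1, 1477, 5033, 6315, 7756, 22035),
    "cob_biomass": (369, 1470.71, 498.90, 33.9, 415, 1091, 1432, 1822, 3853),
    "dry_grain_yield": (369, 7176.92, 3300.98, 46.0, 425, 4282, 7038, 9848, 17450),
    "harvest_index": (369, 0.45, 0.09, 19.4, 0.03, 0.40, 0.46, 0.52, 0.75),
    "grain_nute": (369, 55.92, 11.10, 19.9, 5, 50, 57, 63, 77),
    "grain_n": (369, 91.70, 49.48, 53.9, 9, 44, 90, 136, 218),
    "total_plant_n": (369, 135.88, 70.18, 51.7, 26, 68, 141, 198, 314),
    "grain_density": (369, 1.27, 0.038, 3.0, 1.02, 1.25, 1.27, 1.3, 1.35),
}


def field_trial_summary() -> pd.DataFrame:
    """Published descriptive statistics of the eight phenotypes, as a frame."""
    return pd.DataFrame.from_dict(
        _SUMMARY_ROWS,
        orient="index",
        columns=["count", "mean", "sd", "cv_pct", "min", "q25", "q50", "q75", "max"],
    ).rename_axis("trait")


FIELD_TRIAL_SUMMARY = field_trial_summary()

# Rows whose printed mean/sd reproduce the printed cv at the printed precision.
# (harvest_index prints cv 19.4 but 100*0.09/0.45 = 20.0: the mean/sd rounding
# is too coarse for the check, so the row is not usable as a worked example.)
CV_CONSISTENT_ROWS = (
    "dry_stalk_biomass",
    "cob_biomass",
    "dry_grain_yield",
    "grain_density",
)

#: Jones factor: grams of grain protein per gram of nitrogen in maize grain.
JONES_FACTOR = 6.25

#: Field geometry of the emulated trial.
PLOT_LENGTH_M = 5.33
PLOT_WIDTH_M = 0.76
N_FIELD_PLOTS = 369
GSD_M = 0.03
N_VNIR_BANDS = 270
WAVELENGTH_MIN_NM = 400.0
WAVELENGTH_MAX_NM = 1000.0
LIDAR_DENSITY_PTS_M2 = 1600.0

#: Spatial augmentation window of the plot interior at 3 cm GSD.
CROP_WINDOW = (176, 25)
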