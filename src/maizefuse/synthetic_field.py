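"""Synthetic maize nitrogen-trial generator.

Emulates the field experiment described in :mod:`maizefuse.reference`:
single-row plots arranged in adjacent north-south blocks under alternating
low/high nitrogen treatment, with eight end-of-season phenotypes whose
population statistics mirror the published trial summary (bimodal yield and
nitrogen traits driven by the treatment, positively correlated biomass traits,
and a narrow, left-skewed grain density).

The renderer produces co-registered plot rasters for four modalities
(hyperspectral reflectance cube, LiDAR canopy height, LiDAR intensity,
thermal) in which the trait-to-signal links are *linear by construction*:
the canopy NIR plateau scales linearly with a configurable signal trait and
canopy height scales linearly with stalk biomass.  This makes parameter
recovery by the downstream models analyzable, which is the whole point of the
synthetic stage.  All random draws flow from a single seed through named
substreams so regeneration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from . import reference

LOW_N = "low_N"
HIGH_N = "high_N"

_LATENTS = ("stalk_g", "cob_g", "grain_g", "protein_pct", "stalk_n_pct")


def _substream(seed: int, name: str) -> np.random.Generator:
    """A named child stream of one master seed (reproducible across stages)."""
    key = zlib.crc32(name.encode("utf-8")) % 2**31
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotDesign:
    """One single-row plot: position in the trial grid plus field geometry."""

    plot_id: str
    block_id: str
    grid_row: int          # block index (north-south)
    grid_col: int          # plot index within the block (east-west)
    polygon: Polygon       # footprint in field meters
    treatment: str         # LOW_N or HIGH_N, alternating by block
    genotype_id: int


def generate_design(
    n_blocks: int,
    plots_per_block: int,
    seed: int,
    *,
    plot_length: float = reference.PLOT_LENGTH_M,
    plot_width: float = reference.PLOT_WIDTH_M,
    alley: float = 0.76,
    plot_gap: float = 0.04,
    n_genotypes: int = 66,
) -> list[PlotDesign]:
    """Lay out ``n_blocks`` adjacent north-south blocks of single-row plots.

    Treatment alternates block by block (even blocks low N, odd blocks high N),
    mirroring a split-plot nitrogen trial randomized along adjacent blocks.
    Plot polygons are pairwise disjoint rectangles of ``plot_length`` x
    ``plot_width`` meters.  Deterministic for a fixed seed (the seed only
    shuffles genotype assignment).
    """
    if n_blocks < 1 or plots_per_block < 1:
        raise ValueError("n_blocks and plots_per_block must be >= 1")
    if plot_length <= 0 or plot_width <= 0:
        raise ValueError("plot dimensions must be positive")
    rng = _substream(seed, "design")
    genotypes = rng.integers(0, n_genotypes, size=n_blocks * plots_per_block)
    plots: list[PlotDesign] = []
    for b in range(n_blocks):
        y0 = b * (plot_length + alley)
        treatment = LOW_N if b % 2 == 0 else HIGH_N
        for p in range(plots_per_block):
            x0 = p * (plot_width + plot_gap)
            poly = box(x0, y0, x0 + plot_width, y0 + plot_length)
            plots.append(
                PlotDesign(
                    plot_id=f"B{b:02d}P{p:03d}",
                    block_id=f"B{b:02d}",
                    grid_row=b,
                    grid_col=p,
                    polygon=poly,
                    treatment=treatment,
                    genotype_id=int(genotypes[b * plots_per_block + p]),
                )
            )
    return plots


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeRecord:
    """The eight plot-level maize traits with their standard units."""

    dry_stalk_biomass: float  # kg/ha
    cob_biomass: float        # kg/ha
    dry_grain_yield: float    # kg/ha
    harvest_index: float      # unitless, in (0, 1)
    grain_nute: float         # g grain per g plant N
    grain_n: float            # kg/ha
    total_plant_n: float      # kg/ha
    grain_density: float      # unitless

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def derive_phenotypes(
    stalk_g_per_plant: float,
    cob_g_per_plant: float,
    grain_g_per_plant: float,
    stalk_n_pct: float,
    grain_protein_pct: float,
    standing_plants: int,
    plot_area_ha: float,
    grain_density: float = float("nan"),
) -> PhenotypeRecord:
    """Derive the plot-level trait record from per-plant field measurements.

    Implements the trial's trait formulas: area-scaled biomasses
    (``g/plant * plants / plot area``), harvest index as the grain share of
    total aboveground biomass, grain nitrogen via the Jones factor
    (protein % / 6.25), plant nitrogen as stalk N plus grain N, and grain
    nitrogen utilization efficiency as grain biomass per unit plant N.
    Grain density is a direct analyzer measurement, so it is passed through.
    """
    if plot_area_ha <= 0:
        raise ValueError("plot_area_ha must be positive")
    for name, v in (
        ("stalk_g_per_plant", stalk_g_per_plant),
        ("cob_g_per_plant", cob_g_per_plant),
        ("grain_g_per_plant", grain_g_per_plant),
        ("stalk_n_pct", stalk_n_pct),
        ("grain_protein_pct", grain_protein_pct),
        ("standing_plants", standing_plants),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    total_biomass = stalk_g_per_plant + cob_g_per_plant + grain_g_per_plant
    if total_biomass <= 0:
        raise ValueError("total biomass is zero; harvest index undefined")

    per_ha = standing_plants / plot_area_ha / 1000.0  # g/plant -> kg/ha
    grain_n_g = (grain_protein_pct / 100.0 / reference.JONES_FACTOR) * grain_g_per_plant
    stalk_n_g = (stalk_n_pct / 100.0) * stalk_g_per_plant
    plant_n_g = stalk_n_g + grain_n_g
    return PhenotypeRecord(
        dry_stalk_biomass=stalk_g_per_plant * per_ha,
        cob_biomass=cob_g_per_plant * per_ha,
        dry_grain_yield=grain_g_per_plant * per_ha,
        harvest_index=grain_g_per_plant / total_biomass,
        grain_nute=grain_g_per_plant / plant_n_g if plant_n_g > 0 else float("inf"),
        grain_n=grain_n_g * per_ha,
        total_plant_n=plant_n_g * per_ha,
        grain_density=grain_density,
    )


@dataclass
class EffectSpec:
    """Treatment effect sizes, latent-trait correlations and noise scales.

    Latent per-plant variables are (stalk g, cob g, grain g, grain protein %,
    stalk N %).  Treatment means interpolate between the low-N means and the
    high-N means by ``effect_scale`` (0 = no nitrogen response, 1 = the
    response calibrated to the emulated trial).  ``corr`` couples the latent
    draws; standing-plant counts are Poisson and multiply every mass trait,
    which adds shared (positively correlating) variation.
    """

    means_low: dict[str, float] = field(
        default_factory=lambda: {
            "stalk_g": 105.0, "cob_g": 25.0, "grain_g": 85.0,
            "protein_pct": 7.0, "stalk_n_pct": 0.55,
        }
    )
    means_high: dict[str, float] = field(
        default_factory=lambda: {
            "stalk_g": 160.0, "cob_g": 34.5, "grain_g": 205.0,
            "protein_pct": 10.5, "stalk_n_pct": 0.95,
        }
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {
            "stalk_g": 30.0, "cob_g": 8.0, "grain_g": 25.0,
            "protein_pct": 0.8, "stalk_n_pct": 0.12,
        }
    )
    corr: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                # stalk  cob   grain prot  stalkN
                [1.00, 0.60, 0.50, 0.10, 0.20],
                [0.60, 1.00, 0.55, 0.10, 0.10],
                [0.50, 0.55, 1.00, 0.20, 0.10],
                [0.10, 0.10, 0.20, 1.00, 0.40],
                [0.20, 0.10, 0.10, 0.40, 1.00],
            ]
        )
    )
    effect_scale: float = 1.0
    plants_mean: float = 20.0
    # grain density = gd_offset - gd_scale * Gamma(gd_shape): narrow, left-skewed
    gd_offset: float = 1.324
    gd_scale: float = 0.027
    gd_shape: float = 2.0

    def validate(self) -> None:
        c = np.asarray(self.corr, dtype=float)
        if c.shape != (len(_LATENTS), len(_LATENTS)):
            raise ValueError(f"corr must be {len(_LATENTS)}x{len(_LATENTS)}")
        if not np.allclose(c, c.T):
            raise ValueError("corr must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("corr must be positive semi-definite")


def sample_trait_population(
    design: Sequence[PlotDesign],
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
    plot_area_ha: float | None = None,
) -> pd.DataFrame:
    """Draw the eight phenotypes for every plot in ``design``.

    Returns a frame indexed by plot_id with the eight trait columns plus
    ``treatment``.  Deterministic per seed.  ``plot_area_ha`` defaults to the
    reference single-row plot area (5.33 m x 0.76 m) rather than the polygon
    area, so geometrically scaled-down scenes keep agronomically realistic
    kg/ha trait scales.
    """
    if plot_area_ha is None:
        plot_area_ha = reference.PLOT_LENGTH_M * reference.PLOT_WIDTH_M / 10_000.0
    if plot_area_ha <= 0:
        raise ValueError("plot_area_ha must be positive")
    spec = effect_spec or EffectSpec()
    spec.validate()
    rng = _substream(seed, "traits")
    n = len(design)
    chol = np.linalg.cholesky(
        np.asarray(spec.corr, float) + 1e-12 * np.eye(len(_LATENTS))
    )
    z = rng.standard_normal((n, len(_LATENTS))) @ chol.T
    plants = np.maximum(rng.poisson(spec.plants_mean, size=n), 4)
    gd = spec.gd_offset - spec.gd_scale * rng.gamma(spec.gd_shape, 1.0, size=n)

    rows = {}
    for i, plot in enumerate(design):
        high = plot.treatment == HIGH_N
        latents = {}
        for j, name in enumerate(_LATENTS):
            lo, hi = spec.means_low[name], spec.means_high[name]
            mean = lo + spec.effect_scale * (hi - lo) * (1.0 if high else 0.0)
            latents[name] = max(mean + spec.sds[name] * z[i, j], 1e-3)
        rec = derive_phenotypes(
            stalk_g_per_plant=latents["stalk_g"],
            cob_g_per_plant=latents["cob_g"],
            grain_g_per_plant=latents["grain_g"],
            stalk_n_pct=latents["stalk_n_pct"],
            grain_protein_pct=latents["protein_pct"],
            standing_plants=int(plants[i]),
            plot_area_ha=plot_area_ha,
            grain_density=float(gd[i]),
        )
        row = rec.as_dict()
        row["treatment"] = plot.treatment
        rows[plot.plot_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("plot_id")
    return out[list(reference.TRAIT_NAMES) + ["treatment"]]


# --------------------------------------------------------------------------
# scene rendering
# --------------------------------------------------------------------------

@dataclass
class RenderSpec:
    """Controls for rasterizing a synthetic field scene.

    The canopy reflectance template has a green bump, a chlorophyll red
    absorption dip, a logistic red edge and a flat NIR plateau whose amplitude
    is ``nir_base + nir_gain * signal_trait`` per plot — a linear, recoverable
    trait-to-signal link.  Canopy height is ``height_base + height_gain *
    dry_stalk_biomass``.  Thermal is roughly uniform (water was not limiting
    in the emulated trial).  Soil/shadow pixels appear as a plot border plus
    random speckle; fractions are of the plot interior.
    """

    n_bands: int = reference.N_VNIR_BANDS
    gsd: float = reference.GSD_M
    soil_fraction: float = 0.15
    shadow_fraction: float = 0.10
    border_px: int = 1
    noise_sd: float = 0.01

    signal_trait: str = "total_plant_n"
    nir_base: float = 0.25
    nir_gain: float = 1.0e-3        # per unit of the signal trait
    height_base: float = 0.8        # m
    height_gain: float = 1.2e-4     # m per kg/ha stalk biomass
    height_noise_sd: float = 0.03   # m, scaled by noise_sd>0
    canopy_intensity: float = 45.0
    soil_intensity: float = 18.0
    intensity_noise_sd: float = 3.0
    air_temp_c: float = 30.0
    canopy_temp_offset: float = -1.5
    thermal_noise_sd: float = 0.3
    terrain_ramp: tuple[float, float] = (0.0, 0.0)  # dz/dx, dz/dy (m/m)

    def validate(self) -> None:
        for name in ("soil_fraction", "shadow_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.soil_fraction + self.shadow_fraction > 1.0:
            raise ValueError("soil + shadow fractions must not exceed 1")
        if self.n_bands < 2:
            raise ValueError("need at least 2 spectral bands")

    def wavelengths(self) -> np.ndarray:
        return np.linspace(
            reference.WAVELENGTH_MIN_NM, reference.WAVELENGTH_MAX_NM, self.n_bands
        )


def vegetation_template(wavelengths: np.ndarray, nir_amplitude: float) -> np.ndarray:
    """Canopy reflectance spectrum with a flat NIR plateau at ``nir_amplitude``."""
    wl = np.asarray(wavelengths, dtype=float)
    base = 0.04 + 0.06 * np.exp(-(((wl - 550.0) / 30.0) ** 2))
    base -= 0.02 * np.exp(-(((wl - 670.0) / 25.0) ** 2))
    edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    spectrum = base * (1.0 - edge) + nir_amplitude * edge
    return np.clip(spectrum, 0.0, 1.0)


def soil_template(wavelengths: np.ndarray) -> np.ndarray:
    """Bright, gently sloping bare-soil spectrum."""
    wl = np.asarray(wavelengths, dtype=float)
    return np.clip(0.12 + 1.5e-4 * (wl - 400.0), 0.0, 1.0)


def shadow_template(wavelengths: np.ndarray) -> np.ndarray:
    return np.full_like(np.asarray(wavelengths, dtype=float), 0.02)


@dataclass
class FieldScene:
    """Co-registered multimodal rasters plus design and truth for one field."""

    hyperspectral: np.ndarray       # (rows, cols, n_bands) reflectance in [0,1]
    wavelengths: np.ndarray         # nm, ascending
    height: np.ndarray              # (rows, cols) canopy height above terrain, m
    intensity: np.ndarray           # (rows, cols), unitless >= 0
    thermal: np.ndarray             # (rows, cols), deg C
    terrain: np.ndarray             # (rows, cols) ground elevation, m
    gsd: float
    origin: tuple[float, float]     # field coords (x, y) of the [0, 0] pixel corner
    plots: list[PlotDesign]
    truth_mask: np.ndarray          # (rows, cols) bool, vegetation truth
    phenotypes: pd.DataFrame

    def validate(self) -> None:
        wl = self.wavelengths
        if not (np.all(np.diff(wl) > 0) and wl[0] >= 400.0 and wl[-1] <= 1000.0):
            raise ValueError("wavelengths must ascend within [400, 1000] nm")
        if self.hyperspectral.min() < 0 or self.hyperspectral.max() > 1:
            raise ValueError("reflectance must lie in [0, 1]")
        shape = self.hyperspectral.shape[:2]
        for name in ("height", "intensity", "thermal", "terrain", "truth_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} raster does not share the grid shape")
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")

    def plot_pixel_window(self, plot: PlotDesign, margin: int = 0) -> tuple[slice, slice]:
        """Axis-aligned half-open pixel window covering a plot polygon."""
        from .plot_prep import polygon_window

        return polygon_window(
            plot.polygon, self.hyperspectral.shape[:2], self.gsd, self.origin, margin
        )


def render_scene(
    design: Sequence[PlotDesign],
    phenotypes: pd.DataFrame,
    render_spec: RenderSpec | None = None,
    seed: int = 0,
) -> FieldScene:
    """Rasterize a synthetic multimodal scene for a designed, phenotyped field."""
    spec = render_spec or RenderSpec()
    spec.validate()
    rng = _substream(seed, "render")

    xs = [p.polygon.bounds for p in design]
    minx = min(b[0] for b in xs)
    miny = min(b[1] for b in xs)
    maxx = max(b[2] for b in xs)
    maxy = max(b[3] for b in xs)
    pad = 2  # soil margin pixels around the trial
    origin = (minx - pad * spec.gsd, miny - pad * spec.gsd)
    n_rows = int(np.ceil((maxy - miny) / spec.gsd)) + 2 * pad
    n_cols = int(np.ceil((maxx - minx) / spec.gsd)) + 2 * pad

    wl = spec.wavelengths()
    veg_edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 12.0))  # for noise clipping only
    del veg_edge

    soil_spec = soil_template(wl).astype(np.float32)
    shadow_spec = shadow_template(wl).astype(np.float32)

    hyper = np.broadcast_to(soil_spec, (n_rows, n_cols, spec.n_bands)).copy()
    height = np.zeros((n_rows, n_cols), dtype=np.float32)
    intensity = np.full((n_rows, n_cols), spec.soil_intensity, dtype=np.float32)
    thermal = np.full((n_rows, n_cols), spec.air_temp_c, dtype=np.float32)
    truth = np.zeros((n_rows, n_cols), dtype=bool)

    yy, xx = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    terrain = (
        spec.terrain_ramp[0] * (origin[0] + (xx + 0.5) * spec.gsd)
        + spec.terrain_ramp[1] * (origin[1] + (yy + 0.5) * spec.gsd)
    ).astype(np.float32)

    from .plot_prep import polygon_window  # local import avoids a cycle

    for plot in design:
        rs, cs = polygon_window(plot.polygon, (n_rows, n_cols), spec.gsd, origin, 0)
        h = rs.stop - rs.start
        w = cs.stop - cs.start
        traits = phenotypes.loc[plot.plot_id]

        # vegetation layout: border soil + interior speckle
        veg = np.ones((h, w), dtype=bool)
        b = min(spec.border_px, (min(h, w) - 1) // 2)
        if b > 0:
            veg[:b, :] = veg[-b:, :] = False
            veg[:, :b] = veg[:, -b:] = False
        interior = veg.copy()
        n_int = int(interior.sum())
        if n_int > 0:
            u = rng.random((h, w))
            frac = spec.soil_fraction + spec.shadow_fraction
            speckle = interior & (u < frac)
            shadow = interior & (u < spec.shadow_fraction)
            veg &= ~speckle
        else:
            speckle = np.zeros((h, w), dtype=bool)
            shadow = speckle

        nir_amp = float(
            np.clip(spec.nir_base + spec.nir_gain * traits[spec.signal_trait], 0.05, 0.95)
        )
        veg_spec = vegetation_template(wl, nir_amp).astype(np.float32)
        chip = np.broadcast_to(soil_spec, (h, w, spec.n_bands)).copy()
        chip[veg] = veg_spec
        chip[shadow] = shadow_spec

        canopy_h = spec.height_base + spec.height_gain * float(traits["dry_stalk_biomass"])
        h_chip = np.zeros((h, w), dtype=np.float32)
        h_chip[veg | shadow] = canopy_h
        i_chip = np.full((h, w), spec.soil_intensity, dtype=np.float32)
        i_chip[veg | shadow] = spec.canopy_intensity
        t_chip = np.full((h, w), spec.air_temp_c, dtype=np.float32)
        t_chip[veg | shadow] += spec.canopy_temp_offset

        if spec.noise_sd > 0:
            chip += rng.normal(0.0, spec.noise_sd, size=chip.shape).astype(np.float32)
            h_chip[veg | shadow] += rng.normal(
                0.0, spec.height_noise_sd, size=int((veg | shadow).sum())
            ).astype(np.float32)
            i_chip += rng.normal(0.0, spec.intensity_noise_sd, size=i_chip.shape).astype(
                np.float32
            )
            t_chip += rng.normal(0.0, spec.thermal_noise_sd, size=t_chip.shape).astype(
                np.float32
            )

        hyper[rs, cs] = np.clip(chip, 0.0, 1.0)
        height[rs, cs] = np.maximum(h_chip, 0.0)
        intensity[rs, cs] = np.maximum(i_chip, 0.0)
        thermal[rs, cs] = t_chip
        truth[rs, cs] = veg

    scene = FieldScene(
        hyperspectral=hyper,
        wavelengths=wl,
        height=height,
        intensity=intensity,
        thermal=thermal,
        terrain=terrain,
        gsd=spec.gsd,
        origin=origin,
        plots=list(design),
        truth_mask=truth,
        phenotypes=phenotypes,
    )
    scene.validate()
    return scene


# --------------------------------------------------------------------------
# point cloud
# --------------------------------------------------------------------------

def generate_pointcloud(
    scene: FieldScene,
    density: float = reference.LIDAR_DENSITY_PTS_M2,
    seed: int = 0,
    *,
    canopy_penetration: float = 0.2,
    z_noise_sd: float = 0.02,
    canopy_intensity: float = 45.0,
    ground_intensity: float = 18.0,
    intensity_sd: float = 3.0,
) -> pd.DataFrame:
    """Sample a classified LiDAR point table (x, y, z, intensity, ground flag).

    Points fall uniformly over the scene footprint at ``density`` points/m².
    Over canopy, a ``canopy_penetration`` fraction of pulses reaches the
    ground (z = terrain); the rest return from the canopy surface.  Canopy
    returns carry higher intensity than ground returns.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = _substream(seed, "pointcloud")
    n_rows, n_cols = scene.height.shape
    width = n_cols * scene.gsd
    length = n_rows * scene.gsd
    n_pts = rng.poisson(density * width * length)

    x = scene.origin[0] + rng.random(n_pts) * width
    y = scene.origin[1] + rng.random(n_pts) * length
    col = np.clip(((x - scene.origin[0]) / scene.gsd).astype(int), 0, n_cols - 1)
    row = np.clip(((y - scene.origin[1]) / scene.gsd).astype(int), 0, n_rows - 1)

    canopy_h = scene.height[row, col]
    terrain_z = scene.terrain[row, col]
    over_canopy = canopy_h > 0
    hits_ground = ~over_canopy | (rng.random(n_pts) < canopy_penetration)

    z = np.where(hits_ground, terrain_z, terrain_z + canopy_h)
    if z_noise_sd > 0:
        z = z + rng.normal(0.0, z_noise_sd, size=n_pts)
    inten = np.where(
        hits_ground,
        rng.normal(ground_intensity, intensity_sd, size=n_pts),
        rng.normal(canopy_intensity, intensity_sd, size=n_pts),
    )
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "z": z,
            "intensity": np.maximum(inten, 0.0),
            "ground": hits_ground,
        }
    )
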