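"""Shared fixtures: small synthetic scenes generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import maizefuse as mf
from maizefuse import reference


@pytest.fixture(scope="session")
def small_scene():
    """A 20-plot scaled-down trial with rendered rasters (seed 11)."""
    design, phenotypes, scene = mf.experiments.small_scene(
        seed=11, n_blocks=4, plots_per_block=5
    )
    return design, phenotypes, scene


@pytest.fixture(scope="session")
def prepped(small_scene):
    design, phenotypes, scene = small_scene
    prep = mf.plot_prep.prepare_plots(scene, margin=2, seed=0)
    return scene, prep


@pytest.fixture(scope="session")
def trait_frame(small_scene):
    _, phenotypes, _ = small_scene
    return phenotypes[list(reference.TRAIT_NAMES)]


@pytest.fixture(scope="session")
def noiseless_scene():
    """Noise-free render: plot means equal the planted linear mapping exactly."""
    design = mf.synthetic_field.generate_design(
        2, 4, 21, plot_length=0.96, plot_width=0.30, alley=0.24, plot_gap=0.06
    )
    phenotypes = mf.synthetic_field.sample_trait_population(design, seed=21)
    spec = mf.synthetic_field.RenderSpec(n_bands=12, noise_sd=0.0)
    scene = mf.synthetic_field.render_scene(design, phenotypes, spec, seed=21)
    return design, phenotypes, scene, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
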