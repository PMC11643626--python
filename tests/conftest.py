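"""Shared fixtures: synthetic movies and their pipeline results.

The two full-size movies (centripetal and stalled) and their pipeline runs
are expensive (~20 s each), so they are session-scoped and shared between
the unit tests and the acceptance suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import ccsflow as cf

SEED = 42

# imaging conditions emulated throughout: 512x512 field, 60 frames at 5 s,
# ~100 mobile puncta (30% of particles static), Poisson shot noise
CELL_CENTER = (256.0, 256.0)
CELL_RADIUS = 230.0
MEMBRANE_SPEED = 0.5  # px/frame at the cell edge
JITTER_SD = 0.2  # px/frame positional jitter of stalled structures


@pytest.fixture(scope="session")
def centripetal_data():
    model = cf.FlowModel(
        "centripetal", CELL_CENTER,
        speed=cf.linear_ramp(MEMBRANE_SPEED, CELL_RADIUS),
    )
    movie, truth = cf.generate_ccs_movie(
        model, n_particles=140, static_fraction=0.3, n_frames=60,
        shape=(512, 512), seed=SEED, cell_radius=CELL_RADIUS,
    )
    return movie, truth


@pytest.fixture(scope="session")
def centripetal_result(centripetal_data):
    movie, _ = centripetal_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cf.run_flow_pipeline(cf.PipelineConfig(seed=SEED), movie=movie)


@pytest.fixture(scope="session")
def stalled_data():
    model = cf.FlowModel("stalled", CELL_CENTER, jitter_sd=JITTER_SD)
    movie, truth = cf.generate_ccs_movie(
        model, n_particles=140, static_fraction=0.3, n_frames=60,
        shape=(512, 512), seed=SEED, cell_radius=CELL_RADIUS,
    )
    return movie, truth


@pytest.fixture(scope="session")
def stalled_result(stalled_data):
    movie, _ = stalled_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cf.run_flow_pipeline(cf.PipelineConfig(seed=SEED), movie=movie)


@pytest.fixture(scope="session")
def smooth_texture():
    """A smooth random texture pair with a known integer (8, 0) px shift:
    two crops of one larger texture, so edges hold true scene content."""
    rng = np.random.default_rng(SEED)
    big = gaussian_filter(rng.uniform(size=(256, 264)), 2.0)
    frame_a = big[:, 8:264].copy()
    frame_b = big[:, 0:256].copy()  # scene translated by +8 px in x
    return frame_a, frame_b
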