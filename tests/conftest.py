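"""Shared synthetic-scene fixtures.

Scenes are rendered once per session: the clean benchmark (three
well-separated, slow swimmers, no clutter) and a cluttered variant of the
same field with cell clusters, head-like debris and forced tail occlusion.
"""

import numpy as np
import pytest

from spermtrack.core import CalibrationProfile
from spermtrack.simulate import (
    SceneConfig,
    Sinusoidal,
    SpermPhantom,
    Stationary,
    Straight,
    simulate_scene,
)

CAL = CalibrationProfile(microns_per_pixel=0.28, frames_per_second=10.0)

BENCH_SPERM = (
    SpermPhantom(position_um=(40, 30), motion=Straight(speed=4, heading_deg=15)),
    SpermPhantom(
        position_um=(25, 75),
        motion=Sinusoidal(speed=3, amplitude=3, frequency=1.5, heading_deg=80),
    ),
    SpermPhantom(position_um=(95, 95), motion=Stationary(heading_deg=230)),
)


def make_clean_config(duration_s: float = 2.0, seed: int = 11) -> SceneConfig:
    return SceneConfig(
        width_px=448,
        height_px=448,
        duration_s=duration_s,
        calibration=CAL,
        sperm=BENCH_SPERM,
        seed=seed,
    )


@pytest.fixture(scope="session")
def calibration() -> CalibrationProfile:
    return CAL


@pytest.fixture(scope="session")
def clean_scene():
    """Clean benchmark: 3 sperm x 20 frames = 60 instances, no clutter."""
    return simulate_scene(make_clean_config())


@pytest.fixture(scope="session")
def long_clean_scene():
    """Same field over 100 frames, for identity-preservation checks."""
    return simulate_scene(make_clean_config(duration_s=10.0))


@pytest.fixture(scope="session")
def cluttered_scene():
    """Benchmark field plus clusters, head-like debris, and forced occlusion."""
    config = SceneConfig(
        width_px=448,
        height_px=448,
        duration_s=2.0,
        calibration=CAL,
        sperm=BENCH_SPERM,
        n_cell_clusters=3,
        n_debris=6,
        occlusion_probability=1.0,
        seed=12,
    )
    return simulate_scene(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
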