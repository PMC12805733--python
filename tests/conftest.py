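import warnings

import numpy as np
import pytest

import mosaicmove as mm
from mosaicmove.synthetic import DEFAULT_LANDSCAPE_PROPORTIONS

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def mosaic_landscape() -> mm.LandscapeRaster:
    """Patchy six-class landscape at the default (pasture-dominated) mix."""
    return mm.generate_landscape(
        300, 300, DEFAULT_LANDSCAPE_PROPORTIONS, patch_scale=8, rng_seed=1
    )


@pytest.fixture(scope="session")
def uniform_landscape() -> mm.LandscapeRaster:
    return mm.generate_landscape(80, 80, {"pasture": 1.0}, rng_seed=0)


@pytest.fixture(scope="session")
def clean_trajectory(mosaic_landscape) -> mm.Trajectory:
    """One artifact-free simulated individual (2000 steps)."""
    cfg = mm.SimConfig(
        n_individuals=1,
        n_fixes=2001,
        missing_fix_rate=0.0,
        outlier_rate=0.0,
        zero_step_rate=0.0,
        rng_seed=11,
    )
    return mm.simulate_trajectory(mosaic_landscape, cfg, 0)


@pytest.fixture(scope="session")
def clean_steps(clean_trajectory):
    """Preprocessed step table of the artifact-free individual."""
    return mm.preprocess_steps(mm.build_step_table([clean_trajectory]))
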