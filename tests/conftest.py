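import numpy as np
import pytest

import habsel as hs
from habsel.landscape import LandscapeConfig
from habsel.pipeline import DEFAULT_TRUTH


@pytest.fixture(scope="session")
def stack():
    """Mid-sized synthetic landscape shared across tests."""
    return hs.generate_landscape(LandscapeConfig(shape=(96, 96)), seed=11)


@pytest.fixture(scope="session")
def zstack(stack):
    return hs.standardize_stack(stack)


@pytest.fixture(scope="session")
def truth():
    return DEFAULT_TRUTH


@pytest.fixture(scope="session")
def small_cohort(zstack, truth):
    """Eight animals, two per age-sex class, with kills."""
    tracks, kills = hs.simulate_cohort(
        zstack, {c: truth for c in hs.AGE_SEX_CLASSES},
        {"AF": 2, "AM": 2, "DF": 2, "DM": 2},
        n_steps=200, n_kills=25, seed=21)
    return tracks, kills


@pytest.fixture(scope="session")
def movement_design(small_cohort, zstack):
    tracks, _ = small_cohort
    return hs.pipeline.build_movement_design(
        tracks, zstack, J=10, seed=31,
        covariate_spec=[("forest_edge_density", None),
                        ("development_cover", 150)])


@pytest.fixture(scope="session")
def rsf_design(small_cohort, zstack):
    tracks, kills = small_cohort
    return hs.build_rsf_design(
        kills, tracks, zstack,
        [("forest_cover", 500), ("development_cover", 500)],
        per_kill=10, seed=41)


def uniform_grid(values, name="layer", res=30.0):
    return hs.RasterGrid(np.asarray(values, dtype=float), resolution=res,
                         name=name)
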