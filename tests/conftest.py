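import numpy as np
import pytest

from deformsense import (ClipGeometry, DeformingBarSpec, NormalizationConstants,
                         PipelineConfig, render_deforming_bar,
                         compute_direction_map, generate_fixtures)


@pytest.fixture(scope="session")
def fixtures():
    """Miniature seeded clips and maps shared across the suite."""
    return generate_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_geom():
    """A coarse, short geometry for fast rendering tests."""
    return ClipGeometry(pixels_per_degree=50.0, width_deg=1.2,
                        height_deg=5.5, n_frames=12)


@pytest.fixture(scope="session")
def exp1_direction_maps():
    """Direction maps for three deformation frequencies at full resolution.

    Rendered once per session: the 200 px/deg pipeline is the costly part
    of the suite.
    """
    geom = ClipGeometry(n_frames=12)
    maps = {}
    for sf in (0.4, 0.8, 3.2):
        clip = render_deforming_bar(
            DeformingBarSpec(deform_sf=sf, drift_sign=-1), geom)
        maps[sf] = compute_direction_map(clip, PipelineConfig())
    return maps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
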