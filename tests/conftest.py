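import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from flowseg import PipelineConfig, generate_movie, presets


@pytest.fixture(scope="session")
def smooth_texture():
    """A smooth random texture (Gaussian-blurred noise, sigma 3) in [0,1]."""
    rng = np.random.default_rng(42)
    tex = ndi.gaussian_filter(rng.standard_normal((128, 128)), 3.0)
    return (tex - tex.min()) / np.ptp(tex)


@pytest.fixture(scope="session")
def default_movie():
    return generate_movie(dataclasses.replace(presets()["default"], seed=1))


@pytest.fixture(scope="session")
def lowcontrast_movie():
    return generate_movie(dataclasses.replace(presets()["lowcontrast"], seed=1))


@pytest.fixture(scope="session")
def debris_movie():
    return generate_movie(dataclasses.replace(presets()["debris"], seed=1))


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_segmentation(default_movie, pipeline_config):
    """Segmentation of the default movie, shared across tests for speed."""
    from flowseg import segment_stack

    return segment_stack(default_movie.stack, pipeline_config)
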