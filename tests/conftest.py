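import numpy as np
import pytest

from cpcquant import (
    detect_signals,
    exclude_edge,
    load_cohort_fixture,
    segment_tissue,
    separate_stains,
    split_single_concatenated,
)
from cpcquant.synthetic_slide import PhantomSpec, generate_slide


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def phantom(default_spec):
    """One default 1024x1024 phantom: (slide, truth)."""
    return generate_slide(default_spec)


@pytest.fixture(scope="session")
def phantom_maps(phantom):
    slide, _ = phantom
    return separate_stains(slide)


@pytest.fixture(scope="session")
def phantom_tissue(phantom, phantom_maps):
    slide, _ = phantom
    return segment_tissue(slide, phantom_maps)


@pytest.fixture(scope="session")
def phantom_components(phantom, phantom_maps, phantom_tissue, default_spec):
    comps = detect_signals(phantom_maps, exclude_edge(phantom_tissue, 0.0))
    return split_single_concatenated(comps, phantom_maps, default_spec.mpp)


@pytest.fixture(scope="session")
def cohort():
    return load_cohort_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
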