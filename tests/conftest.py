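import numpy as np
import pytest

from aptasl import GroupFeatureParams, PhantomSpec, generate_phantom_subject


@pytest.fixture
def noiseless_spec():
    return PhantomSpec(noise_sd=0.0, seed=7)


@pytest.fixture
def noiseless_subject(noiseless_spec):
    return generate_phantom_subject(noiseless_spec)


@pytest.fixture
def null_group_params():
    """Both outcome groups drawn from the same standard normal."""
    names = GroupFeatureParams().feature_names
    return GroupFeatureParams(stats={f: (0.0, 1.0, 0.0, 1.0) for f in names})


@pytest.fixture
def rng():
    return np.random.default_rng(20230129)
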