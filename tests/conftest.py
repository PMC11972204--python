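import numpy as np
import pytest

from lamiquartet.synth import AcquisitionParams, make_patch


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_acq():
    return AcquisitionParams(noise_sd=0.0, ar1=0.0)


@pytest.fixture
def flat_patch():
    """Small zero-curvature patch: equivolume depth equals equidistant depth."""
    return make_patch(n_columns=4, voxels_per_column=6, curvature_range=(0.0, 0.0), seed=7)


@pytest.fixture
def curved_patch():
    return make_patch(n_columns=6, voxels_per_column=6, curvature_range=(-0.5, 0.5), seed=11)
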