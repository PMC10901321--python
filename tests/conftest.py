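import numpy as np
import pytest

from mcmrs.core import AcquisitionSet
from mcmrs.quantify import LorentzianComponent, LorentzianModel
from mcmrs.simulate import (
    ArraySpec,
    default_two_peak_model,
    generate_model_fid,
    make_channels,
)

FS = 2000.0
N_POINTS = 2048


@pytest.fixture(scope="session")
def two_peak_model() -> LorentzianModel:
    """Creatine CH3/CH2 two-peak phantom: a=15, d=10 s^-1, f=132/56 Hz."""
    return default_two_peak_model(FS, N_POINTS)


@pytest.fixture(scope="session")
def clean_fid(two_peak_model) -> np.ndarray:
    return generate_model_fid(two_peak_model)


@pytest.fixture(scope="session")
def eight_channel_clean(clean_fid) -> AcquisitionSet:
    """Noise-free eight-channel acquisition with the reference scale factors."""
    return make_channels(clean_fid, ArraySpec(), FS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240228)


def single_lorentzian(
    a=1.0, theta=0.0, d=10.0, f=132.0, fs=FS, n_points=N_POINTS
) -> LorentzianModel:
    return LorentzianModel([LorentzianComponent(a, theta, d, f)], fs, n_points)
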