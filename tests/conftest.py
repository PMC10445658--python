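import dataclasses

import numpy as np
import pytest

from trfdr.core import default_time_axis
from trfdr.dr import default_lut
from trfdr.pipeline import extract_features
from trfdr.simulate import (IRFSpec, default_class_models, simulate_cohort)


@pytest.fixture(scope="session")
def irf() -> IRFSpec:
    return IRFSpec(fwhm=0.5, t0=1.0)


@pytest.fixture(scope="session")
def time_axis() -> np.ndarray:
    return default_time_axis()


@pytest.fixture(scope="session")
def lut():
    return default_lut()


@pytest.fixture(scope="session")
def noiseless_models():
    """Class models with every noise and within-patient spread zeroed."""
    return {name: dataclasses.replace(
        m, trace_snr=0.0, reflectance_snr=0.0, spot_amplitude_sigma=0.0,
        spot_lifetime_rel_sd=0.0, spot_weight_sigma=0.0)
        for name, m in default_class_models().items()}


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient cohort at the default noise levels (64 spectra)."""
    return simulate_cohort(6, (36, 8, 20), seed=11)


@pytest.fixture(scope="session")
def small_features(small_cohort, lut):
    """Features extracted from the small cohort via the full raw pipeline."""
    features, tally = extract_features(small_cohort, lut)
    assert tally["invalid_trf"] == 0 and tally["invalid_dr"] == 0
    return features
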