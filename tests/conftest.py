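import dataclasses

import numpy as np
import pytest

from fnirs_fc.montage import build_default_montage, build_default_schedule
from fnirs_fc.pipeline import PipelineConfig
from fnirs_fc.simulate import PhysioModel, SimulationSpec


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def schedule():
    return build_default_schedule()


@pytest.fixture(scope="session")
def small_spec():
    """Three-subject cohort under the default study conditions."""
    return SimulationSpec(n_subjects=3, seed=7)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free spec: planted task responses only, no latent/physio/noise."""
    return SimulationSpec(
        n_subjects=1, seed=11,
        physio=PhysioModel(cardiac_amp=0.0, respiratory_amp=0.0, mayer_amp=0.0),
        noise_sd_um=0.0, hbr_noise_sd_um=0.0, artifact_rate_per_min=0.0,
        latent_sd_um=0.0,
    )


@pytest.fixture(scope="session")
def light_config():
    """Pipeline config without the (slow) wavelet stage, for simulations."""
    return PipelineConfig(wavelet_enabled=False)


def clean_variant(spec: SimulationSpec, **overrides) -> SimulationSpec:
    return dataclasses.replace(spec, **overrides)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
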