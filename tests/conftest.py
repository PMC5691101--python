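import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from epr_oximetry import AcquisitionSettings, PipelineConfig, ProbeModel

hyp_settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
hyp_settings.load_profile("suite")


@pytest.fixture
def paper_settings() -> AcquisitionSettings:
    """The emulated L-band acquisition (all defaults)."""
    return AcquisitionSettings()


@pytest.fixture
def clean_settings() -> AcquisitionSettings:
    """Acquisition with modulation and RC distortion switched off."""
    return AcquisitionSettings(time_constant=0.0, modulation_amplitude=0.0)


@pytest.fixture
def single_probe_config() -> PipelineConfig:
    return PipelineConfig(n_probes=1)


def probe_with_width(delta_bpp: float, **kwargs) -> ProbeModel:
    """A probe whose true peak-to-peak width is exactly ``delta_bpp``."""
    p = ProbeModel(pO2_true=0.0, footprint_length=kwargs.pop("footprint_length", 0.0),
                   **kwargs)
    po2 = (delta_bpp - p.anoxic_linewidth) / p.oxygen_sensitivity
    assert po2 >= 0, "width below the anoxic intercept"
    return ProbeModel(
        position=p.position,
        pO2_true=po2,
        anoxic_linewidth=p.anoxic_linewidth,
        oxygen_sensitivity=p.oxygen_sensitivity,
        amplitude=p.amplitude,
        footprint_length=p.footprint_length,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
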