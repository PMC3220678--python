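import numpy as np
import pytest

from retrotrack import PipelineConfig
from retrotrack.simgen import KineticsConfig, SimConfig, simulate_control, simulate_field


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A small stationary field: 12 cells, 13 frames, default noise."""
    cfg = SimConfig(n_cells=12, image_shape=(220, 300), seed=5, mover_fraction=0.0)
    return cfg, *simulate_field(cfg)


@pytest.fixture(scope="session")
def control_sim():
    """A cell-movement control field (single live frame, no movers)."""
    cfg = SimConfig(n_cells=30, image_shape=(360, 460), seed=11, mover_fraction=0.0)
    return cfg, *simulate_control(cfg)


@pytest.fixture(scope="session")
def noisefree_responder_sim():
    """Noise-free responders with fixed kinetics (fold 3, inflection 60 min)."""
    cfg = SimConfig(
        n_cells=25,
        image_shape=(400, 520),
        seed=7,
        mover_fraction=0.0,
        noise_gaussian_sd=0.0,
        noise_cv=0.0,
        fixation_unevenness=0.0,
        responder_fraction=1.0,
        kinetics=KineticsConfig(
            lag_min=(20.0, 0.0), t_half_min=(40.0, 0.0), plateau_fold=(3.0, 0.0)
        ),
    )
    return cfg, *simulate_field(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
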