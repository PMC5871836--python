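import numpy as np
import pytest

from larvataxis.segmentation import SegmentationParams
from larvataxis.simulator import AgentParams, SimConfig, simulate_experiment
from larvataxis.stimulus import DirectionalField, TemporalRamp


@pytest.fixture
def field():
    return DirectionalField()


@pytest.fixture
def ramp():
    return TemporalRamp()


@pytest.fixture
def seg_params():
    """Segmentation params that keep the whole recording (no initial discard)."""
    return SegmentationParams(discard_initial_s=0.0)


@pytest.fixture
def clean_agent_params():
    """High-contrast parameters for oracle-grade segmentation recovery."""
    return AgentParams(p_accept_dec=0.65, p_accept_inc=0.45,
                       sweep_amp_mean_deg=45.0, sweep_amp_sd_deg=4.0,
                       sweep_amp_min_deg=35.0, turn_speed_fraction=0.1)


@pytest.fixture(scope="session")
def small_temporal_sim():
    """One small shared simulated experiment under the temporal ramp."""
    ramp = TemporalRamp()
    cfg = SimConfig(n_agents=6, duration_s=660.0, stimulus=ramp, seed=42)
    params = AgentParams(p_accept_dec=0.65, p_accept_inc=0.45,
                         sweep_amp_mean_deg=45.0, sweep_amp_sd_deg=4.0,
                         sweep_amp_min_deg=35.0)
    tracks, truth = simulate_experiment(cfg, params, experiment_id="exp0")
    return cfg, params, tracks, truth
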