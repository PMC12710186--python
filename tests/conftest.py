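import pytest

import betaburst as bb


@pytest.fixture(scope="session")
def default_config() -> bb.RunConfig:
    """The reference study conditions: 600 s at 600 Hz, 18 Hz beta,
    30 bursts/min, dip depth 0.6 at 90 ms pre-onset, SNR 15 dB."""
    return bb.RunConfig()


@pytest.fixture(scope="session")
def main_result(default_config) -> bb.PipelineResult:
    """Full sliding-scheme pipeline on the reference simulation
    (shared by the end-to-end checks; training takes a few minutes)."""
    return bb.run_synthetic_pipeline(default_config)


@pytest.fixture(scope="session")
def surrogate_result(default_config) -> bb.PipelineResult:
    """Negative control: trained and tested on the phase-randomized
    surrogate with the original burst annotation carried over."""
    return bb.run_surrogate_control(default_config, surrogate_seed=12345)


@pytest.fixture(scope="session")
def small_sim():
    """120 s reference simulation for preprocessing-level tests."""
    params = bb.SimulationParams(duration=120.0, seed=7)
    rec, truth = bb.simulate_recording(params)
    return params, rec, truth


@pytest.fixture(scope="session")
def small_pre(small_sim):
    _, rec, _ = small_sim
    return bb.preprocess_recording(rec)
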