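import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from corneagaze import cli_io, synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rig():
    return synthetic.make_rig(0)


@pytest.fixture(scope="session")
def small_session():
    """A reduced noisy session shared by pipeline-level tests."""
    sc = synthetic.make_scenario(7, n_model_frames=60, n_match_pairs=80,
                                 n_eval_events=40)
    obs, truth = synthetic.simulate_session(sc)
    return obs, truth


@pytest.fixture(scope="session")
def small_tables(small_session):
    obs, truth = small_session
    return cli_io.observations_to_tables(obs, truth)


@pytest.fixture(scope="session")
def noiseless_session():
    sc = synthetic.make_scenario(
        11, pixel_noise=0.0, feature_noise=0.0, outlier_frac=0.0,
        n_model_frames=30, n_match_pairs=40, n_eval_events=25)
    obs, truth = synthetic.simulate_session(sc)
    return obs, truth


@pytest.fixture(scope="session")
def calibrated(small_tables):
    eye, hom = cli_io.run_autocalibrate(small_tables)
    return eye, hom
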