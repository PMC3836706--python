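import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dreadchoice as dc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1_design():
    """A default 95-pair counterbalanced shock-task choice set."""
    return dc.generate_exp1_choice_set(dc.DesignConfig(), seed=11)


@pytest.fixture(scope="session")
def exp1_design_190():
    """A 190-pair choice set (two runs' worth, as fitted per subject)."""
    return dc.generate_exp1_choice_set(
        dc.DesignConfig(n_choice_trials=190), seed=12)


@pytest.fixture(scope="session")
def undiscounted_agent():
    return dc.AgentSpec(
        spec=dc.ModelSpec("undiscounted_dread"),
        params=dc.ModelParams(beta=0.25, gamma_p=0.9, alpha=0.5))


@pytest.fixture(scope="session")
def undiscounted_data(exp1_design_190, undiscounted_agent):
    """190 choices simulated from the undiscounted dread model."""
    return dc.simulate_agent(exp1_design_190, undiscounted_agent, seed=21)


@pytest.fixture(scope="session")
def fast_fit_config():
    return dc.FitConfig(n_starts=6, check_curvature=False)


def simulate_cohort_frames(n_subjects, base_params, relief_overrides, seed,
                           n_choices=95):
    """Two-frame cohort simulated from the general dread model."""
    cfg = dc.DesignConfig(n_choice_trials=n_choices)
    rng = np.random.default_rng(seed)
    pain, relief = {}, {}
    for i in range(n_subjects):
        agent = dc.AgentSpec(
            spec=dc.ModelSpec("general_dread"), params=base_params,
            frame_overrides={"relief": relief_overrides} if relief_overrides else {})
        sid = f"s{i:02d}"
        d_p = dc.generate_exp1_choice_set(cfg, seed=int(rng.integers(2**31)))
        d_r = dc.generate_exp1_choice_set(cfg, seed=int(rng.integers(2**31)))
        pain[sid] = dc.simulate_agent(d_p, agent, seed=int(rng.integers(2**31)),
                                      frame="pain", subject_id=sid)
        relief[sid] = dc.simulate_agent(d_r, agent, seed=int(rng.integers(2**31)),
                                        frame="relief", subject_id=sid)
    return pain, relief
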