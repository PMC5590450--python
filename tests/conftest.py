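"""Shared fixtures: small parameter sets, feed profiles, and the
reference synthetic study (simulated once per session)."""

import numpy as np
import pytest

from fedbatch_ukf import (Belief, FeedProfile, ProcessParameters,
                          UKFConfig, build_training_set,
                          generate_training_runs, reference_scenario,
                          train_observation_model)


@pytest.fixture(scope="session")
def params():
    return ProcessParameters(Yxs=0.5, Yps=1.0, Ypx=0.05, ms=0.02, cF_S=600.0)


@pytest.fixture(scope="session")
def zero_feed():
    return FeedProfile([0.0], [0.0], t_start=0.0, t_end=100.0)


@pytest.fixture(scope="session")
def reference_study():
    """Three replicate training cultivations of the default scenario plus
    the observation model trained on their pooled offline pairing.

    The first run doubles as the evaluation run (the observation model is
    trained on the same cultivations it is later applied to, as is common
    practice when sister runs of one process are available).
    """
    scenario = reference_scenario()
    runs = generate_training_runs(seed=1, n_runs=3)
    ts = build_training_set(
        [(r.offline, r.measurements, r.scenario.name) for r in runs])
    model, report = train_observation_model(ts, seed=1)
    return {"scenario": scenario, "runs": runs, "training_set": ts,
            "model": model, "report": report}


@pytest.fixture(scope="session")
def default_init_belief():
    cfg = UKFConfig()
    return Belief(mean=np.array([0.5, 2.0, 0.0, 0.45]),
                  cov=np.diag(cfg.V_state0), t=0.0, W=5.0)


def trajectory_rmse(estimate, truth):
    return float(np.sqrt(np.mean((np.asarray(estimate)
                                  - np.asarray(truth)) ** 2)))
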