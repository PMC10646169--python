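import dataclasses

import numpy as np
import pytest

from avitrend import model, simulate as sim


@pytest.fixture(scope="session")
def tiny_study():
    rng = np.random.default_rng(3)
    cfg = sim.default_sim_config("tiny", rng)
    return sim.simulate_study(cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_model(tiny_study):
    cfg = tiny_study.config
    spec = model.ModelSpec(
        fixed=list(cfg.beta),
        scaled=list(cfg.gamma),
        k_spline=6,
        include_survey_effect=True,
    )
    data, basis = model.build_model_data(
        tiny_study.surveys, tiny_study.detections, tiny_study.stack, spec
    )
    return spec, data, basis


@pytest.fixture(scope="session")
def recovery_study():
    """Mid-sized study with signal, used by sampler-facing tests."""
    rng = np.random.default_rng(3)
    cfg = sim.default_sim_config("tiny", rng)
    cfg = dataclasses.replace(
        cfg, n_grids=60, n_years=3, beta0=(0.6,), mu=(0.05,),
        psi_logit_mean=1.2, psi_logit_amplitude=1.0,
    )
    return sim.simulate_study(cfg, seed=11)
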