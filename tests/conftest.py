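import numpy as np
import pytest

from valenceddm import ddm, task
from valenceddm import validation as val


@pytest.fixture(scope="session")
def biased_task_cohort():
    """Task-emulator cohort of agents biased toward desirable conclusions.

    20 participants x 80 trials with a starting point shifted toward the
    desirable bound (z = 0.55) and a positive valence drift term
    (beta2 = 0.2) on top of the calibrated task agent.
    """
    rng = np.random.default_rng(2024)
    truth = ddm.DDMParams(z=0.55, beta2=0.2)
    params = task.draw_cohort_params(20, rng, mean=truth)
    cfg = task.TaskConfig(rng_seed=2024)
    return task.simulate_cohort(cfg, params, ddm.MODEL_SPECS[4], 20, seed=2024)


@pytest.fixture(scope="session")
def unbiased_task_cohort():
    """Task-emulator cohort with all bias parameters neutral."""
    rng = np.random.default_rng(77)
    params = task.draw_cohort_params(16, rng, mean=ddm.DDMParams())
    cfg = task.TaskConfig(rng_seed=77)
    return task.simulate_cohort(cfg, params, ddm.MODEL_SPECS[1], 16, seed=77)


@pytest.fixture(scope="session")
def spec4_direct_cohort():
    """Model-generated cohort (spec 4 truth) for fitting tests."""
    rng = np.random.default_rng(11)
    truth = ddm.DDMParams(a=1.5, z=0.55, t0=0.3, sz=0.1, beta0=0.0, beta1=3.0, beta2=0.2)
    subj = task.draw_cohort_params(10, rng, mean=truth)
    data = val.simulate_ddm_cohort(subj, 4, n_trials=80, seed=11)
    return data, subj
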