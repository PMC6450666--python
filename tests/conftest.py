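import numpy as np
import pytest

import transrev as tr


@pytest.fixture(scope="session")
def odors() -> tr.OdorSet:
    return tr.OdorSet()


@pytest.fixture(scope="session")
def design() -> tr.TaskDesign:
    return tr.TaskDesign()


@pytest.fixture(scope="session")
def schedule(design, odors) -> tr.TrialSchedule:
    return tr.generate_schedule(design, odors, seed=7)


@pytest.fixture(scope="session")
def agent(schedule) -> tr.AgentData:
    # pleasantness matched up to the small residual differences the
    # screening procedure tolerates (within two rating units)
    params = tr.SubjectParams(alpha=0.9, c=0.8)
    pleasantness = np.array([6.2, 5.8, 6.1, 5.9])
    return tr.simulate_agent(schedule, params, pleasantness, seed=11)


def naive_nll(alpha, c, schedule, choices, n_odors=4):
    """Per-trial pure-Python likelihood oracle, independent of the
    vectorized/jitted implementation."""
    theta = 3.0**c - 1.0
    E = {0: [1.0 / n_odors] * n_odors, 1: [1.0 / n_odors] * n_odors}
    nll = 0.0
    for t in range(schedule.n_trials):
        cs, us, ch = int(schedule.cs[t]), int(schedule.us[t]), int(choices[t])
        if ch >= 0:
            exps = [np.exp(theta * e) for e in E[cs]]
            p = exps[ch] / sum(exps)
            nll -= np.log(p)
        a = alpha[t] if np.ndim(alpha) else alpha
        for k in range(n_odors):
            target = 1.0 if k == us else 0.0
            E[cs][k] += a * (target - E[cs][k])
    return nll
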