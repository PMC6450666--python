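"""Identity-expectation associative learning model.

For each CS the agent maintains a vector of identity expectations
``E_k`` over the four odors, initialized at 1/4 and updated by a delta rule
driven by the identity prediction error

    PE_k,t = I_k,t - E_k,t        (I one-hot in the delivered odor)
    E_k,t+1 = E_k,t + alpha * PE_k,t

while the non-presented CS carries its expectations forward unchanged.
Because the update is applied to every element simultaneously, the
expectation vector keeps summing to 1 and the PE vector sums to 0.

Predictions are drawn from a softmax over E with slope theta = 3**c - 1
(c in (0,1), so theta in (0,2)); this compressive parameterization keeps
near-deterministic choice strategies inside the searchable range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .task_design import TrialSchedule


def theta_from_c(c: float | np.ndarray) -> float | np.ndarray:
    """Softmax slope ("temperature") theta = 3**c - 1."""
    return np.power(3.0, c) - 1.0


@dataclass(frozen=True)
class SubjectParams:
    """Learning rate and softmax slope for one subject (single-rate model)."""

    alpha: float
    c: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")

    @property
    def theta(self) -> float:
        return float(theta_from_c(self.c))


@dataclass
class AgentData:
    """Trial-level traces of one simulated (or fitted) agent."""

    schedule: TrialSchedule
    choices: np.ndarray  # (T,) predicted odor id, -1 = missing
    E_trace: np.ndarray  # (T, 4) pre-update expectations of the presented CS
    pe_vector_trace: np.ndarray  # (T, 4)
    identity_pe: np.ndarray  # (T,)
    value_pe: np.ndarray  # (T,)
    probs: np.ndarray  # (T, 4) softmax prediction probabilities

    def to_frame(self) -> pd.DataFrame:
        T = self.schedule.n_trials
        df = pd.DataFrame({"trial": np.arange(1, T + 1)})
        df["identity_pe"] = self.identity_pe
        df["value_pe"] = self.value_pe
        for k in range(self.E_trace.shape[1]):
            df[f"E_{k + 1}"] = self.E_trace[:, k]
        for k in range(self.probs.shape[1]):
            df[f"p_{k + 1}"] = self.probs[:, k]
        return df


def init_expectations(n_odors: int = 4, n_cs: int = 2) -> np.ndarray:
    """Uniform initial expectations, one row per CS (each entry 1/n_odors)."""
    if n_odors < 2:
        raise ValueError("need at least 2 odors")
    return np.full((n_cs, n_odors), 1.0 / n_odors)


def update_expectations(
    E: np.ndarray, delivered: int, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """One delta-rule step: returns (E_new, pe) with pe = one_hot - E."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    E = np.asarray(E, float)
    one_hot = np.zeros_like(E)
    one_hot[delivered] = 1.0
    pe = one_hot - E
    return E + alpha * pe, pe


def predict_probs(E: np.ndarray, c: float) -> np.ndarray:
    """Softmax prediction probabilities with slope theta = 3**c - 1."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must lie in [0, 1]")
    z = theta_from_c(c) * np.asarray(E, float)
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def identity_pe_scalar(pe: np.ndarray, delivered: int) -> float:
    """Scalar identity PE: the delivered-odor element of the PE vector.

    Equals 1 - E[delivered]; maximal (0.75 after initialization) when the
    outcome was unexpected, 0 once the association is fully learned.
    """
    return float(pe[delivered])


def value_pe_scalar(
    E: np.ndarray, delivered: int, pleasantness: np.ndarray
) -> float:
    """Value PE: pleasantness of the received minus the expected odor.

    The expected-odor pleasantness is the expectation-weighted mean
    ``sum_k E_k * v_k``, so the trace stays model-derived and is defined
    even on trials without a prediction response.
    """
    v = np.asarray(pleasantness, float)
    E = np.asarray(E, float)
    if len(v) != len(E):
        raise ValueError("pleasantness must cover every odor")
    return float(v[delivered] - E @ v)


@njit(cache=True)
def _forward_pass(us, cs, alpha_t, n_odors):  # pragma: no cover - jitted
    """Sequential expectation recursion; returns (T, n_odors) pre-update E
    of the presented CS on each trial."""
    T = us.shape[0]
    E = np.full((2, n_odors), 1.0 / n_odors)
    out = np.empty((T, n_odors))
    for t in range(T):
        c = cs[t]
        for k in range(n_odors):
            out[t, k] = E[c, k]
        a = alpha_t[t]
        for k in range(n_odors):
            target = 1.0 if k == us[t] else 0.0
            E[c, k] += a * (target - E[c, k])
    return out


@njit(cache=True)
def _nll_kernel(us, cs, choices, alpha_t, theta, n_odors):  # pragma: no cover
    """Negative log likelihood of observed choices under the softmax rule."""
    T = us.shape[0]
    E = np.full((2, n_odors), 1.0 / n_odors)
    nll = 0.0
    for t in range(T):
        c = cs[t]
        ch = choices[t]
        if ch >= 0:
            m = E[c, 0]
            for k in range(1, n_odors):
                if E[c, k] > m:
                    m = E[c, k]
            denom = 0.0
            for k in range(n_odors):
                denom += np.exp(theta * (E[c, k] - m))
            nll -= theta * (E[c, ch] - m) - np.log(denom)
        a = alpha_t[t]
        for k in range(n_odors):
            target = 1.0 if k == us[t] else 0.0
            E[c, k] += a * (target - E[c, k])
    return nll


def expectation_trace(
    schedule: TrialSchedule, alpha: float | np.ndarray, n_odors: int = 4
) -> np.ndarray:
    """Pre-update expectation vectors of the presented CS, trial by trial.

    ``alpha`` may be a scalar (single learning rate) or a per-trial vector
    (dual-rate model, the rate gated by reversal type).
    """
    T = schedule.n_trials
    alpha_t = np.broadcast_to(np.asarray(alpha, float), (T,)).copy()
    return _forward_pass(
        schedule.us.astype(np.int64), schedule.cs.astype(np.int64), alpha_t, n_odors
    )


def simulate_agent(
    schedule: TrialSchedule,
    params: SubjectParams,
    pleasantness: np.ndarray,
    seed: int | None = None,
) -> AgentData:
    """Run the model through a schedule, sampling a prediction each trial.

    Expectations are updated by the delivered odors only; sampled choices
    never feed back into the learning state.
    """
    rng = np.random.default_rng(seed)
    T = schedule.n_trials
    n_odors = len(np.asarray(pleasantness))
    E_trace = expectation_trace(schedule, params.alpha, n_odors)
    theta = params.theta
    z = theta * E_trace
    z -= z.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)

    choices = np.array(
        [rng.choice(n_odors, p=probs[t]) for t in range(T)], dtype=int
    )
    one_hot = np.zeros((T, n_odors))
    one_hot[np.arange(T), schedule.us] = 1.0
    pe_vec = one_hot - E_trace
    identity_pe = pe_vec[np.arange(T), schedule.us]
    v = np.asarray(pleasantness, float)
    value_pe = v[schedule.us] - E_trace @ v
    return AgentData(
        schedule=schedule,
        choices=choices,
        E_trace=E_trace,
        pe_vector_trace=pe_vec,
        identity_pe=identity_pe,
        value_pe=value_pe,
        probs=probs,
    )


def negative_log_likelihood(
    params: SubjectParams | tuple[float, float],
    schedule: TrialSchedule,
    choices: np.ndarray,
    alpha_t: np.ndarray | None = None,
    n_odors: int = 4,
) -> float:
    """NLL of the observed predictions; missing choices (coded -1) are dropped.

    The expectation state evolves from the delivered US sequence alone.
    ``alpha_t`` overrides the per-trial learning rate (dual-rate model).
    """
    if isinstance(params, SubjectParams):
        alpha, c = params.alpha, params.c
    else:
        alpha, c = params
    choices = np.asarray(choices)
    T = schedule.n_trials
    if len(choices) != T:
        raise ValueError("choices must align with the schedule")
    valid = choices[choices >= 0]
    if valid.size and (valid.max() >= n_odors):
        raise ValueError("choice id outside the odor set")
    if alpha_t is None:
        alpha_t = np.full(T, float(alpha))
    else:
        alpha_t = np.asarray(alpha_t, float)
    return float(
        _nll_kernel(
            schedule.us.astype(np.int64),
            schedule.cs.astype(np.int64),
            choices.astype(np.int64),
            alpha_t,
            float(theta_from_c(c)),
            n_odors,
        )
    )


def dual_rate_alpha_trace(
    schedule: TrialSchedule,
    alpha_within: float,
    alpha_between: float,
    pre_first_reversal: str = "between",
) -> np.ndarray:
    """Per-trial learning rate for the dual-rate model.

    The rate applied on a trial is set by the type of the most recent
    reversal of the presented CS; trials before a CS's first reversal use
    ``pre_first_reversal`` ("between" by default).
    """
    rates = {"within": alpha_within, "between": alpha_between}
    current = [rates[pre_first_reversal], rates[pre_first_reversal]]
    out = np.empty(schedule.n_trials)
    for t in range(schedule.n_trials):
        c = int(schedule.cs[t])
        rt = schedule.reversal_type[t]
        if rt in rates:
            current[c] = rates[rt]
        out[t] = current[c]
    return out
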