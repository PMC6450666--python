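"""Parametric prediction-error regressors for the fMRI design matrices.

Four z-scored trial-length traces per subject:

* ``identity_pe_z`` — model-derived identity PE (delivered-odor element of
  I - E), the parametric modulator of the main GLM;
* ``value_pe_z``    — pleasantness difference between received and expected
  odor, included to soak up residual value PEs;
* ``unmodulated_pe_z`` — reversal indicator (1 on reversal trials, else 0),
  the perceptual-distance-free identity PE regressor;
* ``modulated_pe_z``   — MDS-derived expected-vs-received odor distances,
  the perceptual-distance-weighted identity PE regressor.

Convolution with a hemodynamic response and design-matrix assembly are the
job of neuroimaging software; this module only builds and diagnoses the
modulator traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .learning_model import AgentData


class DegenerateRegressorError(ValueError):
    """A would-be regressor is constant (zero variance)."""


@dataclass
class RegressorSet:
    identity_pe_z: np.ndarray
    value_pe_z: np.ndarray
    unmodulated_pe_z: np.ndarray
    modulated_pe_z: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.identity_pe_z)

    def to_frame(self, subject_id: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "identity_pe_z": self.identity_pe_z,
                "value_pe_z": self.value_pe_z,
                "unmodulated_pe_z": self.unmodulated_pe_z,
                "modulated_pe_z": self.modulated_pe_z,
            }
        )
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


def zscore(trace: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with sample sd (ddof=1).

    A constant trace raises :class:`DegenerateRegressorError`: silently
    emitting zeros would corrupt a downstream design matrix.
    """
    x = np.asarray(trace, float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("trace must be 1-D with length >= 2")
    sd = x.std(ddof=1)
    # constant up to float dust counts as constant (e.g. a value-PE trace
    # under exactly matched pleasantness is zero plus rounding error)
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise DegenerateRegressorError("constant trace cannot be z-scored")
    return (x - x.mean()) / sd


def build_regressors(
    agent: AgentData,
    distances: np.ndarray,
) -> RegressorSet:
    """Assemble the four z-scored traces for one subject.

    ``distances`` is the per-trial expected-vs-received odor distance from
    :func:`transrev.perceptual_space.reversal_distances` (zero off
    reversals). All traces must align with the agent's schedule.
    """
    T = agent.schedule.n_trials
    distances = np.asarray(distances, float)
    if len(distances) != T:
        raise ValueError("distance trace does not align with the schedule")
    indicator = agent.schedule.is_reversal.astype(float)
    return RegressorSet(
        identity_pe_z=zscore(agent.identity_pe),
        value_pe_z=zscore(agent.value_pe),
        unmodulated_pe_z=zscore(indicator),
        modulated_pe_z=zscore(distances),
    )


def regressor_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two non-constant traces."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("traces must share length")
    if a.std(ddof=1) == 0.0 or b.std(ddof=1) == 0.0:
        raise DegenerateRegressorError("correlation undefined for constant trace")
    return float(stats.pearsonr(a, b).statistic)


def regressor_diagnostics(sets: list[RegressorSet]) -> pd.DataFrame:
    """Per-subject r(modulated, unmodulated) and r(identity PE, value PE)."""
    rows = []
    for s, rs in enumerate(sets):
        rows.append(
            {
                "subject_id": s,
                "r_mod_unmod": regressor_correlation(
                    rs.modulated_pe_z, rs.unmodulated_pe_z
                ),
                "r_identity_value": regressor_correlation(
                    rs.identity_pe_z, rs.value_pe_z
                ),
            }
        )
    return pd.DataFrame(rows)
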