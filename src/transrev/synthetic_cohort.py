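"""Synthetic study generator and recovery experiments.

The trial-level behavioral and rating data behind the published cohort are
not deposited, so validation runs on synthetic studies that mirror the
design: 19 subjects x 128 trials, two CS over four odors in a 2x2
sweet/savory structure, reversals after 4-6 presentations, choices sampled
from the identity-expectation model with subject parameters drawn from
beta parent distributions, similarity ratings derived from an explicit
planar odor geometry plus noise, and pleasantness matched across odors up
to small noise (screening keeps only odors rated > 5 and within two units
of each other).

The latent geometry is a within x between rectangle (default 1 x 2): the
four corner coordinates are an exact oracle for MDS round-trip tests.
Per-subject RNG streams are spawned from the master seed by subject index,
so adding a subject never perturbs earlier subjects' data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchical_fit import (
    DUAL_RATE,
    SINGLE_RATE,
    beta_shapes,
    compare_models,
    fit_hierarchical,
    fit_subject_mle,
)
from .learning_model import (
    AgentData,
    SubjectParams,
    dual_rate_alpha_trace,
    expectation_trace,
    theta_from_c,
)
from .task_design import OdorSet, TaskDesign, TrialSchedule, generate_schedule


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for one synthetic study."""

    n_subjects: int = 19
    n_trials: int = 128
    alpha_mean: float = 0.87
    alpha_sd: float = 0.1
    # c chosen so the implied softmax slope matches the cohort-average
    # temperature theta = 1.11: c = log3(1 + 1.11) ~= 0.68
    c_mean: float = 0.68
    c_sd: float = 0.1
    # dual-rate generator (used when variant="dual_rate")
    alpha_within: float = 0.5
    alpha_between: float = 0.95
    variant: str = SINGLE_RATE
    within_distance: float = 1.0
    between_distance: float = 2.0
    rating_noise_sd: float = 0.1
    pleasantness_base: float = 6.0
    pleasantness_noise_sd: float = 0.25
    run_length_range: tuple[int, int] = (4, 6)
    reversal_type_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_distance > self.between_distance:
            raise ValueError("within_distance must not exceed between_distance")
        if self.within_distance <= 0:
            raise ValueError("geometry distances must be positive")
        beta_shapes(self.alpha_mean, self.alpha_sd)  # validates feasibility
        beta_shapes(self.c_mean, self.c_sd)


def latent_geometry(spec: CohortSpec) -> np.ndarray:
    """Planar 2x2-category odor configuration (rectangle corners).

    Odors 0,1 (sweet) sit on one short side, odors 2,3 (savory) on the
    other; the short side is the within-category distance, the long side
    the between-category separation.
    """
    w, b = spec.within_distance, spec.between_distance
    return np.array([[0.0, 0.0], [0.0, w], [b, 0.0], [b, w]])


@dataclass
class SyntheticSubject:
    subject_id: int
    params: dict
    schedule: TrialSchedule
    agent: AgentData
    dissimilarity: np.ndarray  # 4x4 rating-derived matrix


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    odors: OdorSet
    subjects: list[SyntheticSubject]
    group_dissimilarity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.group_dissimilarity = np.mean(
            [s.dissimilarity for s in self.subjects], axis=0
        )

    def fitting_data(self) -> list[tuple[TrialSchedule, np.ndarray]]:
        return [(s.schedule, s.agent.choices) for s in self.subjects]

    def true_params_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({"subject_id": s.subject_id, **s.params})
        return pd.DataFrame(rows)


def _draw_subject_params(spec: CohortSpec, rng: np.random.Generator) -> dict:
    a_a, b_a = beta_shapes(spec.alpha_mean, spec.alpha_sd)
    a_c, b_c = beta_shapes(spec.c_mean, spec.c_sd)
    c = float(rng.beta(a_c, b_c))
    if spec.variant == SINGLE_RATE:
        alpha = float(rng.beta(a_a, b_a))
        return {"alpha": alpha, "c": c, "theta": float(theta_from_c(c))}
    return {
        "alpha_within": spec.alpha_within,
        "alpha_between": spec.alpha_between,
        "c": c,
        "theta": float(theta_from_c(c)),
    }


def _simulate_choices(
    schedule: TrialSchedule,
    params: dict,
    spec: CohortSpec,
    pleasantness: np.ndarray,
    rng: np.random.Generator,
) -> AgentData:
    if spec.variant == SINGLE_RATE:
        alpha_t = np.full(schedule.n_trials, params["alpha"])
    else:
        alpha_t = dual_rate_alpha_trace(
            schedule, params["alpha_within"], params["alpha_between"]
        )
    E_trace = expectation_trace(schedule, alpha_t)
    theta = theta_from_c(params["c"])
    z = theta * E_trace
    z -= z.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    T = schedule.n_trials
    choices = np.array([rng.choice(4, p=probs[t]) for t in range(T)], dtype=int)
    one_hot = np.zeros((T, 4))
    one_hot[np.arange(T), schedule.us] = 1.0
    pe_vec = one_hot - E_trace
    v = np.asarray(pleasantness, float)
    return AgentData(
        schedule=schedule,
        choices=choices,
        E_trace=E_trace,
        pe_vector_trace=pe_vec,
        identity_pe=pe_vec[np.arange(T), schedule.us],
        value_pe=v[schedule.us] - E_trace @ v,
        probs=probs,
    )


def _subject_ratings(
    spec: CohortSpec, geometry: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Noisy rating-scale dissimilarity matrix from the latent geometry."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(geometry))
    d_max = d.max()
    D = d / d_max
    noise = rng.normal(0.0, spec.rating_noise_sd, size=6)
    iu = np.triu_indices(4, k=1)
    vals = np.clip(D[iu] + noise, 0.0, 1.0)
    out = np.zeros((4, 4))
    out[iu] = vals
    return out + out.T


def simulate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete synthetic study from one master seed."""
    spec = spec or CohortSpec()
    master = spec.seed if seed is None else seed
    geometry = latent_geometry(spec)
    odor_rng = np.random.default_rng([int(master), 10_000])
    pleasantness = spec.pleasantness_base + odor_rng.normal(
        0.0, spec.pleasantness_noise_sd, size=4
    )
    pleasantness = np.clip(pleasantness, -10.0, 10.0)
    odors = OdorSet(
        pleasantness={k: float(pleasantness[k]) for k in range(4)}
    )
    design = TaskDesign(
        n_trials=spec.n_trials,
        run_length_range=spec.run_length_range,
        reversal_type_prob=spec.reversal_type_prob,
    )
    subjects = []
    for i in range(spec.n_subjects):
        # fixed per-subject stream: independent of n_subjects
        rng = np.random.default_rng([int(master), i])
        params = _draw_subject_params(spec, rng)
        schedule = generate_schedule(design, odors, seed=int(rng.integers(2**31)))
        agent = _simulate_choices(schedule, params, spec, pleasantness, rng)
        dissim = _subject_ratings(spec, geometry, rng)
        subjects.append(
            SyntheticSubject(
                subject_id=i,
                params=params,
                schedule=schedule,
                agent=agent,
                dissimilarity=dissim,
            )
        )
    return SyntheticCohort(spec=spec, odors=odors, subjects=subjects)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort directory: odors, trials/choices per subject, ratings,
    true parameters, and a JSON manifest of spec + seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.odors.to_frame().to_csv(outdir / "odors.csv", index=False)
    ratings_rows = []
    iu = np.triu_indices(4, k=1)
    for s in cohort.subjects:
        sid = f"s{s.subject_id:02d}"
        s.schedule.to_frame().to_csv(outdir / f"trials_{sid}.csv", index=False)
        pd.DataFrame(
            {
                "trial": np.arange(1, s.schedule.n_trials + 1),
                "predicted_odor": s.agent.choices,
            }
        ).to_csv(outdir / f"choices_{sid}.csv", index=False)
        for i, j in zip(*iu):
            ratings_rows.append(
                {
                    "subject_id": s.subject_id,
                    "odor_i": int(i),
                    "odor_j": int(j),
                    "rating": float(s.dissimilarity[i, j]),
                }
            )
    pd.DataFrame(ratings_rows).to_csv(outdir / "ratings.csv", index=False)
    cohort.true_params_frame().to_csv(outdir / "true_params.csv", index=False)
    spec_dict = asdict(cohort.spec)
    spec_dict["run_length_range"] = list(spec_dict["run_length_range"])
    (outdir / "manifest.json").write_text(
        json.dumps({"spec": spec_dict, "format": "transrev-cohort-v1"}, indent=2)
    )


def read_cohort_dir(indir: str | Path) -> list[tuple[TrialSchedule, np.ndarray]]:
    """Load (schedule, choices) pairs from a cohort directory."""
    indir = Path(indir)
    out = []
    for trials_path in sorted(indir.glob("trials_*.csv")):
        sid = trials_path.stem.split("_", 1)[1]
        schedule = TrialSchedule.from_frame(pd.read_csv(trials_path))
        choices_path = indir / f"choices_{sid}.csv"
        choices = pd.read_csv(choices_path)["predicted_odor"].to_numpy(int)
        out.append((schedule, choices))
    return out


@dataclass
class RecoveryReport:
    """True-vs-estimated parameter table plus model-selection frequencies."""

    params: pd.DataFrame  # replicate, subject_id, parameter, true, estimated
    selection: pd.DataFrame | None = None  # generator, n, chosen_single, ...

    def summary(self) -> pd.DataFrame:
        g = self.params.groupby("parameter")
        out = g.apply(
            lambda d: pd.Series(
                {
                    "bias": float((d["estimated"] - d["true"]).mean()),
                    "rmse": float(
                        np.sqrt(((d["estimated"] - d["true"]) ** 2).mean())
                    ),
                    "n": len(d),
                }
            ),
            include_groups=False,
        )
        return out.reset_index()


def recovery_experiment(
    spec: CohortSpec | None = None,
    n_replicates: int = 10,
    method: str = "mle",
    n_starts: int = 10,
    mcmc_samples: int = 2000,
    mcmc_burnin: int = 500,
    seed: int = 0,
) -> RecoveryReport:
    """Simulate -> fit -> compare true vs estimated parameters.

    ``method`` is "mle" or "hierarchical" (the latter reports subject-level
    posterior means and parent means at reduced sample counts).
    """
    spec = spec or CohortSpec()
    rows = []
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        cohort = simulate_cohort(spec, seed=int(rng.integers(2**31)))
        data = cohort.fitting_data()
        if method == "mle":
            for s, (schedule, choices) in zip(cohort.subjects, data):
                est, _ = fit_subject_mle(
                    schedule,
                    choices,
                    variant=spec.variant,
                    n_starts=n_starts,
                    seed=int(rng.integers(2**31)),
                )
                for name, true_val in s.params.items():
                    if name in est and name != "theta":
                        rows.append(
                            {
                                "replicate": rep,
                                "subject_id": s.subject_id,
                                "parameter": name,
                                "true": true_val,
                                "estimated": est[name],
                            }
                        )
        elif method == "hierarchical":
            post = fit_hierarchical(
                data,
                n_samples=mcmc_samples,
                n_burnin=mcmc_burnin,
                seed=int(rng.integers(2**31)),
            )
            for s, (_, arow) in zip(cohort.subjects, post.subject.iterrows()):
                rows.append(
                    {
                        "replicate": rep,
                        "subject_id": s.subject_id,
                        "parameter": "alpha",
                        "true": s.params["alpha"],
                        "estimated": float(arow["alpha_mean"]),
                    }
                )
            mu_alpha = float(
                post.group.loc[post.group["parameter"] == "alpha", "mu_mean"]
            )
            rows.append(
                {
                    "replicate": rep,
                    "subject_id": -1,
                    "parameter": "parent_alpha_mean",
                    "true": spec.alpha_mean,
                    "estimated": mu_alpha,
                }
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return RecoveryReport(params=pd.DataFrame(rows))


def model_recovery(
    n_replicates: int = 20,
    n_subjects: int = 19,
    n_trials: int = 128,
    n_starts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Crossed model-recovery: generate under each variant, select by AIC.

    Returns one row per generator with the fraction of replicates in which
    each variant won AIC.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gen in (SINGLE_RATE, DUAL_RATE):
        wins = {SINGLE_RATE: 0, DUAL_RATE: 0}
        for _ in range(n_replicates):
            spec = CohortSpec(
                n_subjects=n_subjects, n_trials=n_trials, variant=gen
            )
            cohort = simulate_cohort(spec, seed=int(rng.integers(2**31)))
            cmp_ = compare_models(
                cohort.fitting_data(),
                n_starts=n_starts,
                seed=int(rng.integers(2**31)),
            )
            wins[cmp_.preferred_aic] += 1
        rows.append(
            {
                "generator": gen,
                "n_replicates": n_replicates,
                "frac_single": wins[SINGLE_RATE] / n_replicates,
                "frac_dual": wins[DUAL_RATE] / n_replicates,
            }
        )
    return pd.DataFrame(rows)
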