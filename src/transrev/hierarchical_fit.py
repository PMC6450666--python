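"""Parameter estimation and model comparison.

Subject-level point estimates come from multi-start bounded maximum
likelihood. Group-level estimation follows the hierarchical scheme in
which each subject's learning rate alpha_i and slope c_i are draws from
independent beta parent distributions parameterized by mean and SD; the
parent mean has a truncated-normal hyperprior on (0,1) and the parent SD a
uniform hyperprior on its feasible range (0, sqrt(mu(1-mu))). The joint
posterior is sampled with an adaptive Metropolis-within-Gibbs scheme on
the natural constrained scale (one chain of 10,000 draws after 1,000
burn-in by default; more chains enable split-R-hat checks via arviz).

Model variants: ``single_rate`` (one alpha) vs ``dual_rate`` (independent
alpha for within- and between-category reversals, gated per trial by the
most recent reversal type of the presented CS). Variants are compared by
AIC/BIC computed from summed per-subject MLE likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .learning_model import (
    SubjectParams,
    dual_rate_alpha_trace,
    negative_log_likelihood,
    theta_from_c,
)
from .task_design import TrialSchedule

SINGLE_RATE = "single_rate"
DUAL_RATE = "dual_rate"

_EPS = 1e-4  # parameter box [eps, 1-eps]


def beta_shapes(mean: float, sd: float) -> tuple[float, float]:
    """Convert a (mean, sd) pair to beta shape parameters (a, b).

    Requires sd**2 < mean*(1-mean); the implied concentration
    nu = mean*(1-mean)/sd**2 - 1 must be positive.
    """
    var = sd * sd
    lim = mean * (1.0 - mean)
    if not 0.0 < mean < 1.0 or not 0.0 < var < lim:
        raise ValueError("need 0<mean<1 and 0<sd^2<mean(1-mean)")
    nu = lim / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class ParentSpec:
    """Hyperprior specification for the beta parents of alpha and c."""

    mu_loc: float = 0.5  # truncated-normal location of the parent mean
    mu_scale: float = 1.0
    sd_frac_max: float = 0.99  # parent sd ~ U(0, sd_frac_max*sqrt(mu(1-mu)))


@dataclass
class PosteriorSummary:
    """Posterior summaries of a hierarchical fit."""

    subject: pd.DataFrame  # subject_id, alpha_mean, alpha_sd, c_mean, c_sd, theta_mean
    group: pd.DataFrame  # parameter, mu_mean, mu_sd, sigma_mean, sigma_sd
    diagnostics: pd.DataFrame  # parameter, ess, rhat
    draws: dict[str, np.ndarray]  # raw post-burn-in draws, per chain stacked
    settings: dict


@dataclass
class ModelComparison:
    """AIC/BIC comparison of the single- vs dual-learning-rate variants."""

    table: pd.DataFrame  # model, nll, k, n_obs, aic, bic

    @property
    def preferred_aic(self) -> str:
        return str(self.table.loc[self.table["aic"].idxmin(), "model"])

    @property
    def preferred_bic(self) -> str:
        return str(self.table.loc[self.table["bic"].idxmin(), "model"])


def information_criteria(nll: float, k: int, n_obs: int) -> tuple[float, float]:
    """AIC = 2k + 2 NLL; BIC = k ln(n_obs) + 2 NLL."""
    return 2.0 * k + 2.0 * nll, k * float(np.log(n_obs)) + 2.0 * nll


def _variant_nll(x: np.ndarray, schedule: TrialSchedule, choices, variant: str) -> float:
    if variant == SINGLE_RATE:
        return negative_log_likelihood((x[0], x[1]), schedule, choices)
    alpha_t = dual_rate_alpha_trace(schedule, x[0], x[1])
    return negative_log_likelihood((np.nan, x[2]), schedule, choices, alpha_t=alpha_t)


def fit_subject_mle(
    schedule: TrialSchedule,
    choices: np.ndarray,
    variant: str = SINGLE_RATE,
    n_starts: int = 10,
    seed: int | None = None,
) -> tuple[dict, float]:
    """Multi-start bounded MLE for one subject.

    Returns (params, nll). ``params`` carries ``alpha`` and ``c`` for the
    single-rate variant, ``alpha_within``/``alpha_between``/``c`` for the
    dual-rate variant, plus the derived ``theta``.
    """
    choices = np.asarray(choices)
    if not np.any(choices >= 0):
        raise ValueError("no observed choices to fit")
    ndim = 2 if variant == SINGLE_RATE else 3
    rng = np.random.default_rng(seed)
    bounds = [(_EPS, 1.0 - _EPS)] * ndim
    starts = rng.uniform(0.1, 0.9, size=(n_starts, ndim))
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            _variant_nll,
            x0,
            args=(schedule, choices, variant),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
    if variant == SINGLE_RATE:
        params = {
            "alpha": float(best_x[0]),
            "c": float(best_x[1]),
            "theta": float(theta_from_c(best_x[1])),
        }
    else:
        params = {
            "alpha_within": float(best_x[0]),
            "alpha_between": float(best_x[1]),
            "c": float(best_x[2]),
            "theta": float(theta_from_c(best_x[2])),
        }
    return params, best_f


def compare_models(
    cohort: list[tuple[TrialSchedule, np.ndarray]],
    n_starts: int = 10,
    seed: int | None = None,
) -> ModelComparison:
    """Fit both variants by MLE and tabulate AIC/BIC.

    k counts free parameters per subject times subjects (2 vs 3);
    N_obs is the total number of observed choices in the cohort.
    """
    rng = np.random.default_rng(seed)
    n_obs = int(sum(np.sum(np.asarray(ch) >= 0) for _, ch in cohort))
    rows = []
    for variant, per_subj in ((SINGLE_RATE, 2), (DUAL_RATE, 3)):
        total_nll = 0.0
        for schedule, choices in cohort:
            _, nll = fit_subject_mle(
                schedule,
                choices,
                variant,
                n_starts=n_starts,
                seed=int(rng.integers(2**31)),
            )
            total_nll += nll
        k = per_subj * len(cohort)
        aic, bic = information_criteria(total_nll, k, n_obs)
        rows.append(
            {"model": variant, "nll": total_nll, "k": k, "n_obs": n_obs,
             "aic": aic, "bic": bic}
        )
    return ModelComparison(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# hierarchical MCMC
# ---------------------------------------------------------------------------


def _log_beta_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    # closed form instead of stats.beta.logpdf: this sits in the MCMC inner
    # loop and the frozen-distribution machinery is ~50x slower
    a, b = beta_shapes(mu, sd)
    x = np.asarray(x, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - special.betaln(a, b)


class _HierModel:
    """Log-density pieces of the hierarchical single-rate model."""

    def __init__(self, cohort, spec: ParentSpec):
        self.cohort = cohort
        self.spec = spec
        self.n = len(cohort)

    def loglik_subject(self, i: int, alpha: float, c: float) -> float:
        schedule, choices = self.cohort[i]
        return -negative_log_likelihood((alpha, c), schedule, choices)

    def log_parent(self, values: np.ndarray, mu: float, frac: float) -> float:
        """Log density of (mu, frac) given the subject values.

        The parent SD is parameterized as the fraction ``frac`` of its
        feasible maximum sqrt(mu(1-mu)): sd = frac * sqrt(mu(1-mu)). Under
        sd | mu ~ U(0, f_max*sqrt(mu(1-mu))) this makes frac ~ U(0, f_max)
        independent of mu (the Jacobian is the mu-dependent range, which
        cancels), so mu and the SD can random-walk independently.
        """
        if not (0.0 < mu < 1.0 and 0.0 < frac < self.spec.sd_frac_max):
            return -np.inf
        sd = frac * np.sqrt(mu * (1.0 - mu))
        z = (mu - self.spec.mu_loc) / self.spec.mu_scale
        lp = -0.5 * z * z - np.log(self.spec.mu_scale)  # Gaussian kernel; norm const cancels
        with np.errstate(divide="ignore"):
            ll = _log_beta_pdf(values, mu, sd)
        if not np.all(np.isfinite(ll)):
            return -np.inf
        return float(lp + ll.sum())


def fit_hierarchical(
    cohort: list[tuple[TrialSchedule, np.ndarray]],
    spec: ParentSpec | None = None,
    n_samples: int = 10_000,
    n_burnin: int = 1_000,
    n_chains: int = 1,
    thin: int = 1,
    subject_sweeps: int = 3,
    parent_sweeps: int = 5,
    seed: int | None = None,
) -> PosteriorSummary:
    """Sample the joint posterior over subject and parent parameters.

    Adaptive random-walk Metropolis-within-Gibbs: per sweep, each subject's
    alpha_i and c_i and the four parent parameters get one proposal each;
    step sizes adapt toward ~44% acceptance during burn-in and are frozen
    afterwards. Deterministic given (seed, settings).
    """
    if len(cohort) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    spec = spec or ParentSpec()
    model = _HierModel(cohort, spec)
    n = model.n
    rng_master = np.random.default_rng(seed)
    chain_seeds = rng_master.integers(2**31, size=n_chains)

    names = ["mu_alpha", "frac_alpha", "mu_c", "frac_c"]
    all_draws: dict[str, list[np.ndarray]] = {
        **{k: [] for k in names},
        "alpha": [],
        "c": [],
    }

    for chain in range(n_chains):
        rng = np.random.default_rng(int(chain_seeds[chain]))
        alpha = rng.uniform(0.3, 0.9, n)
        c = rng.uniform(0.3, 0.9, n)
        parents = {"mu_alpha": 0.6, "frac_alpha": 0.3, "mu_c": 0.6, "frac_c": 0.3}
        loglik = np.array([model.loglik_subject(i, alpha[i], c[i]) for i in range(n)])

        step_subj = np.full((n, 2), 0.1)  # per-subject (alpha, c) steps
        step_par = dict.fromkeys(names, 0.05)

        def parent_sd(par: dict, which: str) -> float:
            mu = par[f"mu_{which}"]
            return par[f"frac_{which}"] * np.sqrt(mu * (1.0 - mu))

        def parent_logp(par: dict) -> float:
            return model.log_parent(
                alpha, par["mu_alpha"], par["frac_alpha"]
            ) + model.log_parent(c, par["mu_c"], par["frac_c"])

        lp_parent = parent_logp(parents)
        keep_a = np.empty((n_samples // thin, n))
        keep_c = np.empty((n_samples // thin, n))
        keep_par = {k: np.empty(n_samples // thin) for k in names}
        kept = 0

        for it in range(n_burnin + n_samples):
            adapting = it < n_burnin
            # subject-level updates (several proposal rounds per recorded
            # sweep shorten the autocorrelation of the parent means, which
            # track the subject-value averages)
            for _ in range(subject_sweeps):
                for i in range(n):
                    for j, (vec, which) in enumerate(((alpha, "alpha"), (c, "c"))):
                        mu_k = parents[f"mu_{which}"]
                        sd_k = parent_sd(parents, which)
                        cur = vec[i]
                        prop = cur + step_subj[i, j] * rng.standard_normal()
                        accept = False
                        if 0.0 < prop < 1.0:
                            with np.errstate(divide="ignore"):
                                lp_cur = _log_beta_pdf(cur, mu_k, sd_k)
                                lp_prop = _log_beta_pdf(prop, mu_k, sd_k)
                            if np.isfinite(lp_prop):
                                a_new = prop if j == 0 else alpha[i]
                                c_new = prop if j == 1 else c[i]
                                ll_prop = model.loglik_subject(i, a_new, c_new)
                                log_r = (ll_prop + lp_prop) - (loglik[i] + lp_cur)
                                if np.log(rng.random()) < log_r:
                                    vec[i] = prop
                                    loglik[i] = ll_prop
                                    accept = True
                        if adapting:
                            step_subj[i, j] *= np.exp(
                                ((1.0 if accept else 0.0) - 0.44)
                                / np.sqrt(it + 1.0)
                            )
            # parent-level updates (refresh: subject moves changed the
            # parent density's data term). These need no choice-likelihood
            # evaluations, so several cheap sweeps per iteration improve
            # parent mixing at negligible cost.
            lp_parent = parent_logp(parents)
            for _ in range(parent_sweeps):
                for k in names:
                    prop = dict(parents)
                    prop[k] = parents[k] + step_par[k] * rng.standard_normal()
                    lp_prop = parent_logp(prop)
                    accept = np.isfinite(lp_prop) and np.log(rng.random()) < (
                        lp_prop - lp_parent
                    )
                    if accept:
                        parents, lp_parent = prop, lp_prop
                    if adapting:
                        step_par[k] *= np.exp(
                            ((1.0 if accept else 0.0) - 0.44) / np.sqrt(it + 1.0)
                        )
            if not adapting and (it - n_burnin) % thin == 0 and kept < keep_a.shape[0]:
                keep_a[kept] = alpha
                keep_c[kept] = c
                for k in names:
                    keep_par[k][kept] = parents[k]
                kept += 1

        all_draws["alpha"].append(keep_a[:kept])
        all_draws["c"].append(keep_c[:kept])
        for k in names:
            all_draws[k].append(keep_par[k][:kept])

    draws = {k: np.stack(v) for k, v in all_draws.items()}  # (chains, draws, ...)
    for which in ("alpha", "c"):
        mu = draws[f"mu_{which}"]
        draws[f"sd_{which}"] = draws[f"frac_{which}"] * np.sqrt(mu * (1.0 - mu))
    theta_draws = theta_from_c(draws["c"])

    subj = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "alpha_mean": draws["alpha"].mean(axis=(0, 1)),
            "alpha_sd": draws["alpha"].std(axis=(0, 1), ddof=1),
            "c_mean": draws["c"].mean(axis=(0, 1)),
            "c_sd": draws["c"].std(axis=(0, 1), ddof=1),
            "theta_mean": theta_draws.mean(axis=(0, 1)),
        }
    )
    group = pd.DataFrame(
        {
            "parameter": ["alpha", "c"],
            "mu_mean": [draws["mu_alpha"].mean(), draws["mu_c"].mean()],
            "mu_sd": [draws["mu_alpha"].std(ddof=1), draws["mu_c"].std(ddof=1)],
            "sigma_mean": [draws["sd_alpha"].mean(), draws["sd_c"].mean()],
            "sigma_sd": [draws["sd_alpha"].std(ddof=1), draws["sd_c"].std(ddof=1)],
        }
    )
    diagnostics = _mcmc_diagnostics(draws)
    return PosteriorSummary(
        subject=subj,
        group=group,
        diagnostics=diagnostics,
        draws=draws,
        settings={
            "n_samples": n_samples,
            "n_burnin": n_burnin,
            "n_chains": n_chains,
            "thin": thin,
            "seed": seed,
        },
    )


def _mcmc_diagnostics(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    import logging

    import arviz as az

    rows = []
    logging.getLogger("arviz").setLevel(logging.ERROR)  # 1-chain ESS is intended
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in ("mu_alpha", "sd_alpha", "mu_c", "sd_c"):
            arr = draws[k]  # (chains, draws)
            rows.append(
                {
                    "parameter": k,
                    "ess": float(az.ess(az.convert_to_dataset(arr))["x"]),
                    "rhat": float(az.rhat(az.convert_to_dataset(arr))["x"]),
                }
            )
    return pd.DataFrame(rows)
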