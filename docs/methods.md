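# Methods

## The learning model

Each of the two conditioned stimuli (CS) carries a vector of identity
expectations `E = (E_1..E_4)` over the four odor outcomes, initialized
uniformly at 0.25. When a CS is presented and odor `u` delivered, the full
vector updates by a delta rule driven by the identity prediction-error
vector:

    PE_k = I_k − E_k,   E_k ← E_k + α·PE_k        (I = one-hot at u)

The non-presented CS is untouched. Because the update is applied to every
element simultaneously, `Σ_k E_k = 1` is conserved to machine precision and
`Σ_k PE_k = 0`; both are enforced as test invariants. Expectations evolve
from the *delivered* odor sequence only — the subject's predictions enter
the likelihood but never the learning state.

Predictions follow a softmax over E with slope

    θ = 3^c − 1,  c ∈ (0, 1)  ⇒  θ ∈ (0, 2).

The compressive `3^c − 1` parameterization keeps near-deterministic choice
regimes inside a bounded, well-conditioned search box; the package reports
both `c` and the derived `θ` ("temperature").

Two scalar PE traces are derived per trial:

* **identity PE** — the delivered-odor element of the PE vector,
  `1 − E_delivered ∈ [0, 1]`. It is the one element tied to the experienced
  outcome, and it reduces exactly to the reversal indicator once learning
  has saturated (`E_delivered ∈ {0, 1}`).
* **value PE** — `v_delivered − Σ_k E_k·v_k`, the pleasantness of the
  received odor minus the expectation-weighted pleasantness of the expected
  outcome. Using the expectation-weighted convention (rather than the
  pleasantness of the button-press prediction) keeps the trace
  model-derived and defined on trials without a response; the
  prediction-based convention can be obtained by passing a one-hot E.

Trained associations produce growing surprise at reversal: after `k`
consecutive presentations of the old US, `E[new US] = 0.25(1−α)^k`, so the
identity PE on the reversal trial increases monotonically in run length
toward its ceiling of 1.

## Task schedules

Each CS runs an independent US sequence: run lengths are drawn uniformly
from {4, 5, 6} presentations (the final run may be truncated by the
64-presentation budget), and at each run boundary the US changes — to the
single same-category alternative (within-category reversal) or to one of
the two other-category odors (between-category reversal). The two per-CS
sequences are interleaved by a balanced random order with at most 3
consecutive same-CS trials (sequential sampling proportional to remaining
counts; dead ends restart the draw).

By default the two CS never predict the same odor simultaneously. That
constraint interacts with the reversal-type draw: whenever the other CS
holds this CS's category alternative — which is the forced landing spot of
every between-category reversal — a within move is infeasible. A naive
"draw within with probability p, fall back to between when blocked" scheme
therefore produces exactly 1/3 within reversals instead of p = 1/2 (the
two-state Markov chain over same-/cross-category CS configurations has
stationary mass 2/3 on the cross state, and within moves only happen
there). The generator instead draws a within reversal with probability

    q = 2p / (1 + p)

whenever it is feasible (q = 2/3 for p = 1/2), which makes the stationary
marginal within fraction equal the configured p; the empirical fraction
over 10,000 runs is 0.497. With sharing allowed, the plain probability p is
used. Completed-run lengths are uniform on {4, 5, 6} up to a small
(~0.7 percentage point) deficit of long runs caused by truncation
censoring at the end of the session; the schedule tests allow a
1-percentage-point deviation for this reason.

Exact reversal-count bounds per CS follow from the run-length composition:
with 64 presentations and runs in [4, 6], between 10 and 15 reversals per
CS, hence 20–30 per session.

## Fitting

**Maximum likelihood.** The categorical NLL of the observed predictions
(missing responses dropped) is minimized over `(α, c) ∈ [1e-4, 1−1e-4]²`
(three parameters for the dual-rate variant) by L-BFGS-B from 10 seeded
uniform starts. The sequential expectation recursion is compiled with
numba; a pure-Python per-trial oracle in the test suite checks the kernel
to 1e-10, and a 201×201 grid search was used during development to confirm
the multi-start optimum is global. The likelihood is flat when choices are
uninformative (α → 0 and θ → 0 both yield uniform predictions), so
individual point estimates in that regime are arbitrary along the ridge —
a property, not a failure, of the MLE.

**Hierarchical Bayes.** Subject parameters are modeled as draws from beta
parent distributions parameterized by mean μ and SD σ, with hyperpriors
μ ~ Normal(0.5, 1) truncated to (0,1) and σ | μ ~ Uniform(0,
0.99·√(μ(1−μ))). Internally σ is parameterized as the fraction
f = σ/√(μ(1−μ)) ∈ (0, 0.99), which makes f uniform independent of μ (the
Jacobian is the μ-dependent range itself) and decouples the two
random-walk directions. Sampling is adaptive Metropolis-within-Gibbs on
the natural constrained scale: per recorded sweep, 3 proposal rounds over
every subject's α and c (each requiring one likelihood evaluation) and 5
rounds over the four parent parameters (likelihood-free, essentially
free); step sizes adapt toward 44% acceptance during burn-in and are
frozen afterwards. Defaults are one chain of 10,000 draws after 1,000
burn-in; multiple chains are supported and feed split-R̂/ESS diagnostics
via arviz. Runs are bit-reproducible given (seed, settings).

**Model comparison.** Single-rate (α, c) and dual-rate (α_within,
α_between, c) variants are compared by AIC = 2k + 2·NLL and
BIC = k·ln(N_obs) + 2·NLL, with per-subject MLE NLLs summed, k counted per
subject times subjects (2n vs 3n) and N_obs the total observed choices.
The dual-rate model applies, on every trial, the rate selected by the type
of the presented CS's most recent reversal; trials before a CS's first
reversal use α_between (configurable). Since BIC's per-parameter penalty
ln(N_obs) exceeds AIC's 2 whenever N_obs > e², BIC punishes the dual model
harder on any realistic cohort.

## Perceptual spaces

Pairwise similarity ratings (0 = identical, 1 = completely different,
repeats averaged) map linearly to a 4×4 dissimilarity matrix. Each matrix
is embedded in 2-D by stress-minimizing metric MDS initialized from
classical (Torgerson) scaling — a deterministic initialization, so the
pipeline needs no seed and identical ratings give identical spaces. The
group space embeds the element-wise mean dissimilarity matrix. Individual
spaces are aligned to it by full Procrustes superimposition (translation,
isotropic scaling, rotation/reflection); the reported disparity follows
the scipy convention (sum of squared residuals after unit-norm scaling of
both configurations), and the applied scale factor is exposed. Noiseless
planar configurations survive the distances → MDS → alignment round trip
with disparity < 1e-6.

On a reversal trial the expected odor is defined model-free as the
pre-reversal US of the presented CS, and the trial's perceptual distance is
the Euclidean distance between expected and received odors in the aligned
space; non-reversal trials get 0.

## Regressors

Four trial-length modulator traces per subject, each z-scored with sample
SD (ddof 1): the model-derived identity PE, the value PE, the reversal
indicator (the "unmodulated" identity PE), and the MDS-distance-modulated
PE. A constant trace — no reversals, or value PEs under exactly matched
pleasantness — raises an explicit degenerate-regressor error rather than
silently emitting zeros, since a zero column would corrupt a downstream
design matrix; "constant" includes traces that are zero up to float dust.
When all reversal distances are equal the modulated and unmodulated
regressors coincide exactly after z-scoring, and r(modulated, unmodulated)
decreases monotonically as distance dispersion grows — the quantitative
reason distance-modulated and unmodulated GLMs are hard to distinguish.
Convolution with a hemodynamic response and design-matrix assembly are out
of scope.

## Synthetic cohorts

The generator emulates the study design: 19 subjects × 128 trials, subject
(α, c) drawn from beta parents, choices sampled from the model, similarity
ratings derived from an explicit planar odor geometry, pleasantness
matched across odors with small noise. Defaults:

| parameter | default | rationale |
|---|---|---|
| n_subjects / n_trials | 19 / 128 | cohort and session size of the design |
| α parent mean / sd | 0.87 / 0.1 | published cohort mean learning rate; dispersion from the reported ±0.026 read as an SEM at n=19 |
| c parent mean / sd | 0.68 / 0.1 | c = log₃(1 + 1.11), matching the published mean temperature θ = 1.11 |
| dual-rate generator | α_within 0.5, α_between 0.95 | well-separated rates for model-recovery experiments |
| odor geometry | 1 × 2 rectangle | within-category distance 1, between-category separation 2; the explicit corners are an exact oracle for MDS round-trip tests (equal between-pair distances of 2 with within = 1 are not realizable by 4 planar points) |
| rating noise sd | 0.1 | keeps the category ordering intact (gap on the unit rating scale ≈ 0.45) while leaving visible subject variation |
| pleasantness base / noise sd | 6.0 / 0.25 | screening admits odors rated > 5 within two units of each other |

Per-subject RNG streams are spawned as `(master_seed, subject_index)`, so
adding subjects never perturbs earlier subjects' data, and a cohort
directory written twice from the same seed is byte-identical.

What the generator does **not** emulate: identification responses,
response times, sniff behavior, missing responses, session fatigue or
drift, fMRI noise of any kind, and subject-specific odor geometries
(all subjects share one latent geometry plus rating noise). Passing tests
therefore certify the computational pipeline — not that real cohorts meet
the generator's assumptions.

## Validation results and problem sizes

The test suite and `scripts/acceptance.py` compute, at the sizes noted:

* Equation fidelity to hand-computed values at 1e-10; vectorized NLL vs a
  per-trial loop oracle on 100 random instances (1e-10).
* Conservation and boundedness over 10,000 random update trajectories.
* 10,000 seeded schedules pass all validator rules; reversal totals within
  the derived [20, 30] (spec-level bound [20, 32]); run-length frequencies
  within 1 percentage point of uniform.
* MLE recovery at 19 × 128: |bias(α)| ≈ 0.044 over 150 replicate cohorts
  (the negative sign comes from boundary truncation near α ≈ 1 plus
  wrong-basin estimates for low-slope subjects whose choices are nearly
  uninformative). Hierarchical parent means recovered within ±0.05 of the
  generating (0.87, 0.68), averaged over 3 cohorts at 2,000 post-burn-in
  draws.
* Crossed model recovery at 100 replicates: single-rate-generated cohorts
  are selected as single-rate by AIC essentially always; dual-rate-generated
  cohorts are selected as dual-rate in ~42% of replicates. At these study
  conditions the expected total log-likelihood gain of the true dual model
  (~18 nats per 19-subject cohort) sits almost exactly at the AIC penalty
  for its 19 extra parameters, so detection is a coin flip — a genuine
  sensitivity limit of AIC at this sample size, documented rather than
  tuned away.
* Perceptual round trip below 1e-6 disparity; within/between distance
  ordering holds for every category-structured space.
* Regressor diagnostics on a default cohort: mean r(modulated,
  unmodulated) ≈ 0.92, mean r(identity PE, value PE) ≈ 0.006 under
  matched-with-noise pleasantness.
* Behavioral signature: prediction accuracy ≈ 0.57 pre-reversal, ≈ 0.17 at
  reversal, ≈ 0.49 on the first post-reversal trial (chance 0.25).

## Known limitations

* Subject-level MLEs of α are weakly identified when the subject's slope is
  low; cohort-level bias of about −0.04 at n = 19 × 128 is inherent to the
  bounded MLE, not an optimizer artifact (verified against grid search).
* The single-chain MCMC default mirrors common practice but cannot compute
  split-chain R̂ meaningfully; use `n_chains ≥ 2` for convergence checks.
  Parent-mean mixing is slow relative to subject-level mixing (the parent
  tracks the subject average); the ESS estimates reported by the
  diagnostics table are the honest currency for Monte-Carlo error.
* AIC-based detection of dual learning rates at this design size is at the
  edge of its sensitivity (see above); larger trial counts or more
  reversals per type would be needed for reliable detection.
* Metric MDS with a classical-scaling start is deterministic but can in
  principle settle in a local stress minimum for pathological inputs;
  for 4-point category-structured matrices no such case has been observed.
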