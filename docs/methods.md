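# Methods

`durnet` re-creates, on fully synthetic data, an analysis chain for
duration-selective brain networks: simulate a duration-discrimination fMRI
experiment from a known bilinear effective-connectivity model, select
duration-selective voxel clusters with a mass-univariate GLM, extract
cross-validated tuning curves, invert hemodynamic network models by
variational Laplace, compare duration-specificity hypotheses by Bayesian
model reduction and random-effects model selection, discover the group-level
architecture with parametric empirical Bayes, and characterize the resulting
directed graph. This note documents the models, the numerical choices, and
what the synthetic studies do and do not establish.

## Generative model

**Neural dynamics.** Each node (a brain region, or a duration-selective
cluster within a region) carries one hidden state. The state vector obeys
the deterministic bilinear equation

    dx/dt = (A + Σ_j u_j B(j)) x + C u

with latent coupling `A` (Hz), input-dependent coupling modulation `B(j)` and
driving inputs `C`. Inputs are stick functions: a zero-duration event becomes
a unit-area impulse (height 1/dt over one microtime bin). Self-connections
are parameterized as `A_ii = −0.5·exp(a_ii)` so estimation can never
destabilize the intrinsic decay; the prior mean `a_ii = 0` corresponds to the
conventional −0.5 Hz.

Input mean-centering (so that `A` describes coupling at average input) is
available but off by default: with impulse-train inputs, centering injects a
tonic negative drive, and during stimulus-free stretches a strongly coupled
node can settle below `x = −γ`, where the balloon model's flow equilibrium
`f = 1 + x/γ` turns negative and the log-flow state diverges. Because
centering only reparameterizes `A ← A + ū·B` (about 0.01 Hz at these event
rates), nothing of substance is lost by leaving inputs raw.

**Hemodynamics.** Each node's activity drives the standard balloon model
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q; f, v, q
integrated in log space so they stay positive) and the static BOLD equation

    y = V0·[k1(1−q) + k2(1−q/v) + k3(1−v)]

with 7-Tesla constants: echo time 0.026 s, intra/extravascular ratio 0.026,
intravascular relaxation 340 s⁻¹, frequency offset 197.9 Hz, resting oxygen
extraction 0.34 (k1 = 4.3·ν₀·E₀·TE, k2 = ε·r₀·E₀·TE, k3 = 1−ε). Balloon
constants (signal decay 0.64 s⁻¹, autoregulation 0.32 s⁻¹, transit time
2.0 s, stiffness 0.32, V0 = 4%) take conventional values and are
configurable; the hemodynamic constants are *fixed*, not estimated, during
inversion — a deliberate scope choice that keeps the recovery studies at
desk scale and is harmless when (as here) the generator and estimator share
the constants.

**Integration.** Classical RK4 on a microtime grid of 16 steps per volume
(t_volume = 1.368 s), with inputs held constant within a step. The same
kernel at 10× finer steps serves as the accuracy reference; agreement is
~4·10⁻⁶ percent signal, far below the 10⁻⁴ target. Estimation uses 8 steps
per volume (identical trajectories to within ~10⁻⁵), which halves inversion
cost. Trial parameter values that diverge (spectral abscissa > 0 explored by
the optimizer) are caught by a state-magnitude guard and rejected via
non-finite predictions.

**Experiment design.** A run presents each S1 duration × orientation
combination exactly once (4×4 = 16 trial types by default), with S2 shorter
or longer by a Weber fraction of 0.5, inter-stimulus and inter-trial
intervals drawn uniformly from the 4–5.2 s grid in 0.08 s steps, a 2 s
response period, 169 volumes per run, 18 runs, 11 subjects. Events are
logged at S1 offset (duration 0), S2 onset, and response onset. Orientation
is generated but carries no signal. Between-subject variability multiplies
each nonzero coupling entry by `1 + 0.1·ε` (self-connections jittered on
their log scale) and redraws if the spectral abscissa rises above −0.08:
a near-unstable subject would hold activity for minutes, which cortex does
not. Observation noise is white Gaussian per node with sd = (temporal sd of
the clean signal)/SNR, plus slow cosine drift; a voxel stage expands each
node into noisy gain-scaled copies on a baseline of 100 units.

## Voxel selection and tuning

The GLM uses six HRF-convolved condition regressors per run (four S1-offset
duration regressors, S2 onset, response onset; all events zero-duration),
per-run discrete-cosine high-pass confounds (cutoff 0.0083 Hz) and per-run
mean columns, with runs concatenated. The canonical HRF is the usual
double-gamma (peak ≈ 5 s, 1:6 undershoot). Winner-take-all labels each voxel
with its argmax duration contrast where t ≥ 3.13 (ties toward the lower
duration; a region qualifies only if every duration label reaches 20
voxels). "Cluster size" is a voxel count — synthetic voxels have no
geometry. Cluster summaries use the first principal component, sign-aligned
to the mean signal.

The tuning normalization follows the two-stage recipe: per voxel, percent
signal change about the voxel's mean over runs; voxel-averaged; run-averaged;
divided by the mean across runs of the *temporal* standard deviation of the
run-wise voxel-averaged series (the axis of "std" is a documented reading,
isolated in one function); responses read at the 2nd volume after S1 offset
(offset volume found by flooring offset/TR); finally each cluster's curve is
divided by its preferred-duration response, which is therefore exactly 1.
Cross-validation defines clusters on one half of the runs and measures
curves on the other half, over seeded random 9/9 splits.

The tuning demonstrations use a fast hemodynamic variant (transit 1.2 s,
decay 1.0 s⁻¹, autoregulation 0.5 s⁻¹) and runs with a quiet tail: with the
conventional transit time the 2nd-volume probe precedes the response rise,
and with densely packed large-amplitude synthetic responses the session mean
(the normalization baseline) sits well above the inter-trial baseline, which
can push probe values negative — real data, with weak responses against
large noise, do not have this problem at the same severity.

## Inversion

`variational_laplace` fits y = h(θ) + Xβ + ε with white per-node noise and
one log-precision hyperparameter per node. Gauss–Newton with
Levenberg–Marquardt damping ascends the variational free energy F; a step is
accepted only if F increases, so the accepted-step F sequence is monotone.
Convergence: |ΔF| < 0.05 nats on 4 consecutive accepted steps, max 128
iterations (non-convergence flags the result). Jacobians come from batched
forward finite differences (step 10⁻³) through the compiled integrator —
one batched integration per iteration; analytic forward sensitivity
equations would cost the same and were not needed. Confounds are either estimated as
explicit coefficients with broad priors or, faster and default in the
studies, projected out of both data and predictions (exact profiling; the
noise degrees of freedom are reduced accordingly). Multi-run (subject-level)
joint inversion stacks runs with shared coupling parameters, each run
simulated from rest. Noise log-precisions update by fixed-point steps
clipped to ±2 per iteration with a broad Gaussian hyperprior.

Priors: zero-mean shrinkage on coupling entries (variance 0.25 for A
off-diagonal, B and C; 1/16 for self log-scales). Masked-out entries have
zero prior variance, implemented as exclusion from the free vector; reduced
priors in model reduction pin entries with variance 10⁻⁸.

## Model comparison and group inference

**Bayesian model reduction** evaluates a reduced (nested-prior) model's free
energy and posterior analytically from the full model's Gaussian prior and
posterior; it agrees with explicit re-inversion to ~0.01 nats on 3-node
tests (both with fixed noise precision, isolating the Gaussian algebra from
hyperparameter re-estimation) and composes across chains of reductions.

**Random-effects model selection** uses the variational Dirichlet scheme
(prior α₀ = 1 per model), Monte-Carlo exceedance probabilities (10⁵ seeded
draws), and the Bayesian omnibus risk from the free-energy comparison
against the equal-frequency null; protected exceedance probabilities follow
PEP = (1−BOR)·EP + BOR/K. Family inference marginalizes member models per
subject under a uniform within-family prior (log-mean-exp) and runs the same
scheme over families — this corrects unequal family sizes exactly and avoids
the rich-get-richer pathology that fractional Dirichlet priors (α₀ < 1)
exhibit under flat evidence.

**Parametric empirical Bayes.** Each first-level posterior is reduced to its
prior-free data message N(m_i, D_i⁻¹), D_i = P_i − P₀, handled in the
eigenbasis of D_i (uninformed directions get essentially flat messages —
never inverted). The second level is θ_i = β + ε_i. Two estimators of the
between-unit covariance are provided: the default matches it per parameter
to the excess dispersion of the unit estimates over their claimed variances
(a DerSimonian–Laird moment estimator, restricted to units whose data
actually constrain the parameter) — robust when individual Laplace
curvatures are imperfect, which they demonstrably are at unit SNR; the
alternative maximizes group free energy over a single precision scaling of
the first-level prior (the textbook scheme). Greedy pruning switches off the
parameter whose removal most increases the group evidence until no removal
helps; each parameter's posterior probability of being nonzero is the
sigmoid of the evidence difference between keeping and pinning it, and the
surviving architecture is {Pp > 0.99}.

## Synthetic validation studies

* **Parameter recovery** (3 nodes, 200 volumes, SNR 1, 10 seeds): mean
  correlation between true and posterior-mean A off-diagonals ≈ 0.85.
* **Family recovery** (3 regions × 3 duration clusters, 4 subjects, 64
  volumes, SNR 1): cohorts generated with duration-dependent input
  specificity; the union model is inverted per subject, all 108 hypothesis
  models scored by reduction, and family inference run. The
  duration-dependent family wins in ≥ 8/10 seeds.
* **Architecture recovery** (5 regions, 9 edges; 6 subjects × 5 runs,
  SNR 1): per-run units pooled by PEB and pruned at Pp > 0.99.
  Identifiability at unit SNR requires heterogeneous exogenous input. The
  event streams are allocated so that at *every target node* the streams of
  its sources and of its own drive are pairwise disjoint event sets:
  duration-1/2 S1 offsets → cerebellum, S2 onsets → V1, duration-3 S1
  offsets → IPS, duration-4 S1 offsets → IFG, and SMA — the network's pure
  sink — receives no direct drive (any stream it could receive would collide
  with one of its sources'). Input entry points are taken as known from the
  earlier selection stages (their gains stay free), and the fast hemodynamic
  variant preserves lag information. Under these conditions the full 9-edge
  set is recovered exactly in 10/10 seeds. With a single shared stimulus
  stream, by contrast, the node trajectories are nearly collinear and the
  edge set is *not* identifiable at any desk-scale data volume — verified by
  initializing the optimizer at the truth, which converges to the same
  displaced solution.
* **Tuning recovery**: cross-validated winner-take-all plus curve
  extraction recovers peak-at-preferred with the preferred response exactly 1.

What these studies show: the estimator chain is internally consistent — data
generated by the package's own forward model, at the stated noise levels and
with the stated identifiability structure, are correctly analyzed end to
end. What they do not show: performance on real BOLD data, whose noise is
colored and non-Gaussian, whose hemodynamics vary regionally and are not
known to the estimator, and whose true coupling need not be bilinear.

## Known limitations

* One-state neural model only; no stochastic, two-state or nonlinear
  (D-matrix) variants.
* Hemodynamic parameters are fixed during inversion.
* The second-level design is a group mean only (no covariates).
* Winner-take-all clusters are voxel-count sets, not spatial components.
* The moment-based between-unit variance is diagonal (per parameter);
  cross-parameter correlations of the random effects are ignored at the
  second level.
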