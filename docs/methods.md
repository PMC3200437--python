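# Methods

## Problem and scope

`evidence-bench` is a simulation benchmark for three approximations to the
log model evidence used to compare brain-connectivity models: the Laplace
free energy `F_L`, Akaike's information criterion (AIC, with its
small-sample correction AICc) and the Bayesian information criterion
(BIC).  Two model classes are covered: conjugate Bayesian general linear
models (GLMs), where everything is analytic, and bilinear dynamic causal
models (DCMs) for fMRI, where a variational Laplace optimiser fits a
nonlinear forward model.  In both classes a *full* and a *nested* model
are defined (the nested model fixes a parameter subset at zero), data are
simulated from one of them with known parameters, both are fitted and
scored, and oriented log Bayes factors are aggregated over replications
across signal-to-noise (SNR) and sample-size grids.

## The criteria

For a model with posterior parameter belief N(m_θ, S_θ) under prior
N(μ_θ, C_θ), residuals e_y = y − g(m_θ) and noise covariance C_y over n
data points:

    Accuracy   = −½ e_yᵀ C_y⁻¹ e_y − ½ log|C_y| − (n/2) log 2π
    Complexity = ½ e_θᵀ C_θ⁻¹ e_θ + ½ log(|C_θ|/|S_θ|)   (+ the analogous
                 hyperparameter row when noise precisions are estimated)
    F_L  = Accuracy − Complexity
    AIC  = Accuracy − p
    BIC  = Accuracy − (p/2) log n
    AICc = AIC − p(p+1)/(n−p−1),  valid only for n > p + 1

All logarithms are natural; the conventional "log Bayes factor 3"
decision threshold corresponds to a Bayes factor exp(3) ≈ 20 and a
posterior model probability above 0.95 under equal model priors.  `p`
counts *free* parameters — those with nonzero prior variance — because
parameters fixed at zero are not estimated (GLMs: 12 vs 9 regressors;
DCMs: 21 vs 20, see below).  Hyperparameters are not included in `p`.
Log-determinants are always computed from a Cholesky factor, never as
`log(det(C))`.

The per-region accuracy decomposition is exact because noise is
independent across regions (block-diagonal C_y); the per-parameter-set
complexity decomposition ignores cross-set posterior correlation, is
flagged `approximate` in serialised records, and is always reported
alongside the exact totals.

## GLM arm

The GLM uses an isotropic Gaussian prior N(0, σ_p² I) with σ_p = 6.05
(the deviation of empirically fitted coefficients about zero in the
face-repetition data set the benchmark emulates) and known isotropic
noise.  The posterior is conjugate (precision = data precision + prior
precision) and the marginal likelihood is the Gaussian density
N(y; Xμ_θ, X C_θ Xᵀ + C_y), evaluated with the matrix-determinant lemma
and Woodbury identity so cost scales with the number of regressors.
Because the model is linear and the noise known, `F_L` computed from the
analytic posterior *equals* this log evidence, which is the package's
primary internal oracle (tested to 1e−6 over random instances, with
`scipy.stats.multivariate_normal` as the independent reference).

The emulated design has 351 scans (TR 2 s) and four event-related
conditions, each modelled by three basis functions: a double-gamma
canonical hemodynamic response (peak 6 s, undershoot 16 s, ratio 6) with
its temporal and dispersion derivatives.  Event schedules are
pseudo-random with mean inter-trial interval 8 s, seeded.  The nested
design removes the first condition's three columns.  The real paradigm's
timing is not public, so the schedule is a synthetic stand-in; this
affects regressor correlations but none of the analytic identities.

## DCM arm

Neurodynamics follow the bilinear system dz/dt = (A + Σ_j u_j B^j) z + C u
over three regions labelled (P, F, A).  Auditory input u_aud (1-s events,
mean inter-stimulus interval 8 s, seeded) drives P; an intelligibility
indicator u_int (alternate events) modulates P→F in both models and
additionally P→A in the full model, so the pair differ by exactly one
free parameter, b_AP.  Priors: self-connections N(−1, 0.177²) — implying
decay half-lives with mean ≈ 720 ms and ≈ 94% of mass in [500, 1000] ms —
cross connections N(1/64, 0.5²), modulatory and input strengths N(0, 2²).
Under these priors about 97% of drawn A matrices are Hurwitz-stable;
occasional large cross-connections dominate the −1 diagonal, so stability
is encouraged rather than guaranteed.

Each region's activity passes through an extended Balloon model
(vasodilatory signal, flow, venous volume with Grubb exponent α = 0.32,
deoxyhemoglobin with resting extraction E₀ = 0.4) and the revised
nonlinear BOLD equation (k₁ = 4.3·θ₀·E₀·TE, k₂ = ε·r₀·E₀·TE, k₃ = 1 − ε;
θ₀ = 40.3 s⁻¹, r₀ = 25 s⁻¹, TE = 40 ms, V₀ = 4%).  Signal decay κ
(0.64 s⁻¹), transit time τ (2 s) and the intra/extravascular ratio ε (1)
are scaled exponentials of per-region Gaussian latents with variance
1/64; autoregulation γ = 0.32 s⁻¹, α and E₀ are fixed.  These are the
standard defaults of the DCM-for-fMRI lineage this benchmark models; the
hemodynamic stage is isolated behind `balloon_bold` so an alternative
parameterisation can be swapped in.  Free parameters per model: 9
intrinsic + 2 (full) or 1 (nested) modulatory + 1 input + 9 hemodynamic
latents.

Integration is a fixed-step classical Runge–Kutta scheme at dt = TR/16,
with flow/volume/deoxyhemoglobin evolved in log space so positivity is
structural.  `predict` integrates the joint neuronal-plus-hemodynamic
state in a single pass; against a high-accuracy adaptive reference
(`scipy.integrate.solve_ivp`, rtol 1e−9) the relative error is below
1e−3 on random prior draws.  Pure neuronal decay matches exp(−t) to
better than 1e−4 over a 5-s transient; being a fixed-step scheme, the
*relative* error against a decaying closed form grows linearly with the
number of steps and reaches ~3e−4 after ~1000 steps, which is
inconsequential at fMRI noise levels.  Trajectories whose neuronal norm
exceeds 1e6 (or whose hemodynamic log-states leave [−49, 49]) raise an
instability error naming the offending draw.

### Data generation

Simulated DCM data hold everything except the modulatory parameters at
fixed values (self-connections −1, cross connections 0.3, c_P = 0.3,
hemodynamics at prior means — synthetic stand-ins for the study's
unpublished empirical estimates, override-able per run) and draw the
modulatory strengths from N(0, 2²), taking absolute values so modulation
is facilitating.  Draws whose dynamics diverge during integration are
resampled with a logged count; an eigenvalue pre-screen is deliberately
*not* used because transient modulation tolerates connection strengths a
sustained-stability test would reject, and screening was found to
truncate the modulatory prior severely.  Noise is white Gaussian with
σ_e = ⟨σ_y⟩ / SNR, where ⟨σ_y⟩ averages the temporal SDs of the three
noiseless region series (GLM arm: of X·θ over 1000 prior draws of θ).

### Variational Laplace

The optimiser maximises the accuracy-minus-complexity free energy under
the factorised Gaussian posterior q(θ)q(λ): a Gauss–Newton update of m_θ
from the central-difference Jacobian of g (relative step
max(|θ_i|, 1)·1e−4), Levenberg–Marquardt damping with step rejection
whenever F_L would decrease, and a damped Newton update of the
log-precision hyperparameters λ from residual sufficient statistics
(precision bases are diagonal; in the fMRI case one identity block per
region, hyperprior λ ~ N(0, 1), mean prior precision e^0.5 ≈ 1.65).
Initialisation is at the prior means; convergence is declared when the
free-energy gain stays below 1e−2 for two consecutive accepted steps
(max 128 iterations, all config-exposed through `VLOptions`).
Non-convergence is reported via a flag, not an exception.  A non-finite
prediction at the prior mean or during Jacobian evaluation is an error; a
non-finite prediction at a *trial* step is treated as a rejected step so
transiently unstable trial parameters do not abort the fit.  Fixed
parameters (zero prior variance) are excluded from the update and keep
their prior belief.  On linear models the first undamped step lands on
the conjugate posterior exactly (tested to 1e−5).

## Sweeps and aggregation

GLM sweeps are fully vectorised over replications (the posterior
covariance depends only on the design and noise level) and aggregate the
oriented log Bayes factor with the mean over 1000 replications per grid
point; DCM sweeps fit both models per replication and aggregate with the
median over 50 replications (the study scale), with non-converged
replications excluded and counted.  Dispersion is reported as the SD and
central 90% interval; replication seeds derive from the master seed
through `numpy.random.SeedSequence` counters so every grid point is
independently reproducible.  Shipped desk-scale defaults (50 GLM / 10 DCM
replications, 128 DCM scans; `--paper-scale` restores 1000/50/488) keep a
full run on one CPU in minutes; the acceptance checks use 10 DCM
replications at 128 scans.

## What the synthetic conditions do and do not show

The GLM arm reproduces the benchmark's analytic results exactly: at very
low SNR the free energy's mean log Bayes factor is unbiased (|mean| <
0.05 at SNR 0.0025) while BIC favours the nested model by ≈ −8.8 nats and
AIC by ≈ −3 (the penalty differences, since the posterior collapses to
the prior), and all criteria's Bayes factors grow with sample size when
the full model is true.

The DCM arm reproduces the mechanism of the free energy's advantage: when
the full model generates the data, the nested fit compensates by
inflating the intrinsic F→A connection (≈ 2× the full-model estimate with
the default stand-in parameters), paying a complexity penalty that only
F_L registers — the free-energy difference is complexity-driven, with the
accuracy difference realised in region A, and median BIC stays ≤ 0 while
median F_L is positive.  One quantitative aspect does not carry over from
the original study conditions: with the synthetic stand-in network
(uniform 0.3 cross-connections, 1-s alternating-intelligibility events)
the full model's median accuracy advantage is ≈ 2 nats rather than < 1,
so AIC — whose full-vs-nested penalty difference is exactly 1 — correctly
identifies the full model here, whereas the original study's empirically
parameterised network hid the modulation from AIC.  How far the nested
model can mimic the full one depends on the (unpublished) fixed
parameters and paradigm timing; the corresponding acceptance check
therefore fails on its AIC clause and is left failing by design.
Parameter recovery is well calibrated at the tested conditions: 95%
credible intervals cover the true modulatory strengths in 100% of 20
fits at SNR 2, and per-region noise precisions are recovered within 10%
at 488 scans.

## Known limitations

- Noise is white within regions (pre-whitened-data assumption); no
  drift, autocorrelation or scanner artefacts are emulated.
- The hemodynamic stage uses standard constants, not the original
  study's appendix values; it is swappable but untested against other
  parameterisations.
- Precision bases are diagonal; fully general PSD bases would need a
  dense-matrix hyperparameter update.
- Prior means and variances are taken as known (no empirical-Bayes
  estimation of prior variances), matching the framework under test.
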