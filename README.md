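# evidence-bench

A simulation benchmark of model-evidence approximations for brain
connectivity modelling.  It compares the **Laplace free energy** against
**AIC**, **BIC** and **AICc** as criteria for choosing between competing
models — analytic Bayesian general linear models (GLMs) and bilinear
dynamic causal models (DCMs) for fMRI — by generating data from models
with known parameters, fitting *full* and *nested* candidates, and
tracking oriented log Bayes factors across signal-to-noise and
sample-size sweeps.

For a fitted model `m` with posterior N(m_θ, S_θ), prior N(μ_θ, C_θ),
residuals e_y and noise covariance C_y over n data points,

```
F_L(m)  = Accuracy(m) − Complexity(m)
Accuracy(m)   = −½ e_yᵀC_y⁻¹e_y − ½ log|C_y| − (n/2) log 2π
Complexity(m) = ½ e_θᵀC_θ⁻¹e_θ + ½ log(|C_θ|/|S_θ|)  [+ hyperparameter row]
AIC  = Accuracy − p          BIC = Accuracy − (p/2) log n
AICc = AIC − p(p+1)/(n−p−1)
```

where p is the number of free parameters.  The log-determinant ratio is
an Occam factor: the free energy penalises a parameter by how far and how
confidently its posterior departs from its prior, while AIC/BIC charge
the same flat price for every parameter.  That difference is the entire
point of the benchmark: whether prior-aware complexity makes a practical
difference when selecting between closely related network models.

The package is pure simulation — no imaging data are required.  It
emulates the study conditions it models: a 351-scan, 12-regressor
event-related GLM design (prior SD σ_p = 6.05), and a three-region
speech network in which auditory input drives region P and an
intelligibility input modulates P→F (both models) and P→A (full model
only), observed through an extended Balloon/BOLD forward model at 488
scans per region.

## Worked example

Score a full and a nested GLM on data simulated from the full model at
very low SNR:

```python
import numpy as np
from evidence_bench import (GLMSpec, bayes_factor, generate_glm_dataset,
                            glm_criteria, glm_signal_sd, make_glm_design)
from evidence_bench.synthetic_data import SNRSpec

X_full = make_glm_design(seed=0)            # 351 x 12, four conditions
X_nested = X_full[:, 3:]                    # first condition removed
sig = glm_signal_sd(X_full, sigma_p=6.05, seed=1)
snr = SNRSpec(target_snr=0.0025, signal_sd=sig, noise_sd=sig / 0.0025)
y, theta = generate_glm_dataset(X_full, 6.05, snr, seed=2)

full = glm_criteria(GLMSpec(X_full, prior_sd=6.05, noise_sd=snr.noise_sd), y)
nested = glm_criteria(GLMSpec(X_nested, prior_sd=6.05, noise_sd=snr.noise_sd), y)
for name in ("f_l", "aic", "bic"):
    print(name, round(getattr(full, name) - getattr(nested, name), 3))
```

prints

```
f_l -0.0
aic -3.0
bic -8.791
```

At this SNR the experimental effects are undetectable, so neither model
should be preferred: the free-energy log Bayes factor is (correctly)
zero, while AIC and BIC report a spurious preference for the nested
model of exactly their penalty differences (3 parameters × 1, and
3/2 · log 351).  Averaged over 1000 replications the same pattern holds
(mean F_L log BF −1.3e−5, BIC −8.79).

The DCM arm runs the same comparison through the nonlinear pipeline:

```
evidence-bench dcm-sweep --seed 0 --out out/        # desk scale: 10 reps
evidence-bench decompose --snr 2 --seed 0 --out out/
```

`decompose` reports which regions' accuracy and which parameter sets'
complexity drive the free-energy difference between the full and nested
fits — with full-model data the nested fit inflates the intrinsic F→A
connection to mimic the missing modulation and is punished through the
complexity term, which only the free energy registers.

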