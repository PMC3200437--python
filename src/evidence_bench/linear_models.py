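"""Analytic Bayesian inference for general linear models.

With a Gaussian prior ``theta ~ N(mu, sigma_p^2 I)`` and isotropic known
noise ``y = X theta + e``, ``e ~ N(0, sigma_e^2 I)``, the posterior is
conjugate and the marginal likelihood is available in closed form:

    y | m  ~  N(X mu, X C X' + sigma_e^2 I).

Because the model is linear and the noise variance known, the Laplace free
energy computed from the analytic posterior equals this log marginal
likelihood exactly, which makes the GLM arm the oracle for the free-energy
code path.  Evidence computations use the matrix-determinant lemma and
Woodbury identity so cost scales with the number of regressors, not scans.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .criteria import (
    CriterionSet,
    EvidenceBreakdown,
    GaussianBelief,
    aic,
    aicc,
    bic,
    laplace_free_energy,
)

__all__ = ["GLMSpec", "GLMFit", "glm_posterior", "glm_log_evidence",
           "glm_criteria", "glm_fit", "glm_criteria_batch"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GLMSpec:
    """Design matrix plus isotropic Gaussian prior and known noise level."""

    design: np.ndarray
    prior_sd: float
    noise_sd: float
    prior_mean: np.ndarray | None = None

    def __post_init__(self):
        X = np.asarray(self.design, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("design must be a 2-D matrix with n >= 1, p >= 1")
        if self.prior_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("prior_sd and noise_sd must be positive")
        mu = self.prior_mean
        mu = np.zeros(X.shape[1]) if mu is None else np.asarray(mu, dtype=float)
        if mu.shape != (X.shape[1],):
            raise ValueError("prior_mean length must match the number of regressors")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("design matrix is column-rank deficient", stacklevel=2)
        object.__setattr__(self, "design", X)
        object.__setattr__(self, "prior_mean", mu)

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def p(self) -> int:
        return self.design.shape[1]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"prior_sd": self.prior_sd, "noise_sd": self.noise_sd,
                       "prior_mean": self.prior_mean.tolist(),
                       "n": self.n, "p": self.p}, fh, indent=1)

    def design_to_csv(self, path) -> None:
        pd.DataFrame(self.design,
                     columns=[f"x{j}" for j in range(self.p)]).to_csv(path, index=False)


@dataclass
class GLMFit:
    posterior: GaussianBelief
    breakdown: EvidenceBreakdown
    criteria: CriterionSet


def _validate_y(spec: GLMSpec, y) -> np.ndarray:
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.shape != (spec.n,):
        raise ValueError(f"data vector has shape {y.shape}, expected ({spec.n},)")
    if not np.all(np.isfinite(y)):
        raise ValueError("data vector contains non-finite values")
    return y


def glm_posterior(spec: GLMSpec, y) -> GaussianBelief:
    """Conjugate posterior: precision = data precision + prior precision."""
    y = _validate_y(spec, y)
    X = spec.design
    prec = X.T @ X / spec.noise_sd**2 + np.eye(spec.p) / spec.prior_sd**2
    cf = linalg.cho_factor(prec, lower=True)
    rhs = X.T @ y / spec.noise_sd**2 + spec.prior_mean / spec.prior_sd**2
    mean = linalg.cho_solve(cf, rhs)
    cov = linalg.cho_solve(cf, np.eye(spec.p))
    return GaussianBelief(mean=mean, cov=0.5 * (cov + cov.T))


def glm_log_evidence(spec: GLMSpec, y) -> float:
    """Closed-form log marginal likelihood log N(y; X mu, X C X' + Cy)."""
    y = _validate_y(spec, y)
    X, n, p = spec.design, spec.n, spec.p
    s2e, s2p = spec.noise_sd**2, spec.prior_sd**2
    r = y - X @ spec.prior_mean
    M = X.T @ X + (s2e / s2p) * np.eye(p)
    cf = linalg.cho_factor(M, lower=True)
    a = linalg.cho_solve(cf, X.T @ r)
    quad = float(r @ (r - X @ a)) / s2e
    # |s2e I + s2p X X'| = s2e^n (s2p/s2e)^p |X'X + (s2e/s2p) I|
    logdet = (n * math.log(s2e) + p * (math.log(s2p) - math.log(s2e))
              + 2.0 * float(np.sum(np.log(np.diag(cf[0])))))
    return -0.5 * quad - 0.5 * logdet - 0.5 * n * _LOG2PI


def glm_fit(spec: GLMSpec, y,
            region_index: dict | None = None,
            param_sets: dict | None = None) -> GLMFit:
    """Posterior, free-energy breakdown and all criteria for one data set.

    The noise variance is known, so hyperparameter complexity is zero and
    the free energy equals the closed-form log evidence.  AIC/BIC/AICc use
    the same accuracy term (residuals at the posterior mean) with p = the
    number of regressors.
    """
    y = _validate_y(spec, y)
    post = glm_posterior(spec, y)
    e_y = y - spec.design @ post.mean
    e_theta = post.mean - spec.prior_mean
    bd = laplace_free_energy(
        e_y, np.full(spec.n, spec.noise_sd**2), spec.n,
        e_theta, np.full(spec.p, spec.prior_sd**2), post.cov,
        region_index=region_index, param_sets=param_sets)
    cs = CriterionSet(
        f_l=bd.f_l,
        aic=aic(bd.accuracy, spec.p),
        bic=bic(bd.accuracy, spec.p, spec.n),
        aicc=(aicc(bd.accuracy, spec.p, spec.n)
              if spec.n > spec.p + 1 else float("nan")),
        p=spec.p, n=spec.n)
    return GLMFit(posterior=post, breakdown=bd, criteria=cs)


def glm_criteria(spec: GLMSpec, y) -> CriterionSet:
    return glm_fit(spec, y).criteria


def glm_criteria_batch(spec: GLMSpec, Y: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised criteria over many data sets sharing one design.

    ``Y`` has one column per replication.  The posterior covariance (and
    therefore the Occam factor) depends only on the design and noise level,
    so it is computed once; means and residuals vectorise across columns.
    Requires the default zero prior mean.  Returns arrays keyed by
    criterion name, matching :func:`glm_criteria` per column.
    """
    if np.any(spec.prior_mean != 0.0):
        raise ValueError("batch path assumes zero prior mean")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != spec.n:
        raise ValueError(f"Y must have shape ({spec.n}, reps)")
    X, n, p = spec.design, spec.n, spec.p
    s2e, s2p = spec.noise_sd**2, spec.prior_sd**2
    prec = X.T @ X / s2e + np.eye(p) / s2p
    cf = linalg.cho_factor(prec, lower=True)
    M = linalg.cho_solve(cf, X.T @ Y / s2e)           # posterior means, (p, reps)
    logdet_S = -2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    E = Y - X @ M                                      # residuals
    acc = (-0.5 * np.sum(E * E, axis=0) / s2e
           - 0.5 * n * math.log(s2e) - 0.5 * n * _LOG2PI)
    comp = 0.5 * np.sum(M * M, axis=0) / s2p + 0.5 * (p * math.log(s2p) - logdet_S)
    out = {
        "f_l": acc - comp,
        "aic": acc - p,
        "bic": acc - 0.5 * p * math.log(n),
    }
    if n > p + 1:
        out["aicc"] = out["aic"] - p * (p + 1) / (n - p - 1)
    return out
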