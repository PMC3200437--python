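"""Model-evidence approximations: Laplace free energy, AIC, BIC, AICc.

The Laplace free energy scores a fitted model as

    F_L = Accuracy - Complexity,

where the accuracy term is the log-likelihood of the data evaluated at the
posterior means, and the complexity term measures how far, and how
confidently, the posterior has moved away from the prior.  The
log-determinant ratio ``0.5 * log(|C| / |S|)`` of prior to posterior
covariance is an Occam factor: the more the data compress the posterior
volume relative to the prior, the larger the penalty.  AIC and BIC instead
charge a fixed penalty per parameter, blind to prior expectations.

All quantities use natural logarithms and log-density units throughout.
Covariances may be passed as a scalar (isotropic), a 1-D array (diagonal)
or a full 2-D matrix; log-determinants of full matrices go through a
Cholesky factorisation, never through ``log(det(C))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import expit

__all__ = [
    "GaussianBelief",
    "EvidenceBreakdown",
    "CriterionSet",
    "BayesFactor",
    "NotPositiveDefiniteError",
    "accuracy",
    "complexity",
    "laplace_free_energy",
    "aic",
    "bic",
    "aicc",
    "bayes_factor",
]

_LOG2PI = math.log(2.0 * math.pi)


class NotPositiveDefiniteError(ValueError):
    """A covariance that must be positive definite is not."""


# ---------------------------------------------------------------------------
# covariance helpers: scalar = isotropic, 1-D = diagonal, 2-D = full
# ---------------------------------------------------------------------------

def _cov_logdet(C, dim: int) -> float:
    C = np.asarray(C, dtype=float)
    if C.ndim == 0:
        if C <= 0:
            raise NotPositiveDefiniteError("isotropic variance must be > 0")
        return dim * math.log(float(C))
    if C.ndim == 1:
        if C.shape[0] != dim:
            raise ValueError(f"diagonal covariance has length {C.shape[0]}, expected {dim}")
        if np.any(C <= 0):
            raise NotPositiveDefiniteError("diagonal covariance has non-positive entries")
        return float(np.sum(np.log(C)))
    _check_square(C, dim)
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as err:
        raise NotPositiveDefiniteError("covariance is not positive definite") from err
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def _cov_quad(C, e: np.ndarray) -> float:
    """Quadratic form e' C^{-1} e."""
    C = np.asarray(C, dtype=float)
    e = np.asarray(e, dtype=float)
    if C.ndim == 0:
        if C <= 0:
            raise NotPositiveDefiniteError("isotropic variance must be > 0")
        return float(e @ e) / float(C)
    if C.ndim == 1:
        if np.any(C <= 0):
            raise NotPositiveDefiniteError("diagonal covariance has non-positive entries")
        return float(np.sum(e * e / C))
    _check_square(C, e.shape[0])
    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as err:
        raise NotPositiveDefiniteError("covariance is not positive definite") from err
    return float(e @ linalg.cho_solve(cf, e))


def _cov_sub(C, idx: np.ndarray):
    """Marginal covariance block for the given indices."""
    C = np.asarray(C, dtype=float)
    if C.ndim == 0:
        return C
    if C.ndim == 1:
        return C[idx]
    return C[np.ix_(idx, idx)]


def _check_square(C: np.ndarray, dim: int) -> None:
    if C.shape != (dim, dim):
        raise ValueError(f"covariance has shape {C.shape}, expected ({dim}, {dim})")


def _check_partition(index_map: dict, total: int, what: str) -> dict:
    """Validate that index arrays form a partition of range(total)."""
    out = {}
    seen = np.zeros(total, dtype=bool)
    for label, idx in index_map.items():
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= total):
            raise ValueError(f"{what} map for {label!r} has out-of-range indices")
        if np.any(seen[idx]):
            raise ValueError(f"{what} map is not a partition: {label!r} overlaps")
        seen[idx] = True
        out[label] = idx
    if not np.all(seen):
        raise ValueError(f"{what} map is not a partition: indices missing")
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianBelief:
    """A multivariate Gaussian over parameters or hyperparameters.

    Represents priors, posteriors and hyper-beliefs alike.  The covariance
    must be symmetric positive semi-definite; a zero diagonal entry encodes
    a parameter fixed at its mean (infinitely confident belief), which is
    how reduced/nested models pin parameters at zero.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 0:
            cov = cov.reshape(1, 1)
        if cov.ndim == 1:
            cov = np.diag(cov)
        d = mean.shape[0]
        if d < 1:
            raise ValueError("belief must have dimension >= 1")
        _check_square(cov, d)
        scale = max(1.0, float(np.max(np.abs(cov))))
        if np.max(np.abs(cov - cov.T)) > 1e-8 * scale:
            raise ValueError("covariance is not symmetric")
        cov = 0.5 * (cov + cov.T)
        if np.min(linalg.eigvalsh(cov)) < -1e-10 * scale:
            raise NotPositiveDefiniteError("covariance has negative eigenvalues")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def credible_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Marginal central credible interval per coordinate."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return self.mean - z * self.sd, self.mean + z * self.sd


@dataclass
class EvidenceBreakdown:
    """Laplace free energy split into accuracy and complexity terms.

    ``f_l = accuracy - complexity_params - complexity_hypers`` holds exactly.
    The per-region and per-parameter-set maps are an approximate
    decomposition (correlations between sets are ignored, flagged in
    ``decomposition``); the exact totals are always the scalar fields.
    """

    accuracy: float
    complexity_params: float
    complexity_hypers: float
    accuracy_by_region: dict = field(default_factory=dict)
    complexity_by_set: dict = field(default_factory=dict)
    decomposition: str = "approximate"

    @property
    def f_l(self) -> float:
        return self.accuracy - self.complexity_params - self.complexity_hypers

    def to_record(self) -> dict:
        rec = {
            "f_l": self.f_l,
            "accuracy": self.accuracy,
            "complexity_params": self.complexity_params,
            "complexity_hypers": self.complexity_hypers,
            "decomposition": self.decomposition,
        }
        for k, v in self.accuracy_by_region.items():
            rec[f"accuracy_region_{k}"] = v
        for k, v in self.complexity_by_set.items():
            rec[f"complexity_set_{k}"] = v
        return rec


@dataclass
class CriterionSet:
    """All four log-evidence approximations for one fitted model."""

    f_l: float
    aic: float
    bic: float
    aicc: float
    p: int
    n: int

    def __post_init__(self):
        if self.p < 0:
            raise ValueError("parameter count p must be >= 0")
        if self.n < 1:
            raise ValueError("data-point count n must be >= 1")

    def to_record(self) -> dict:
        return {
            "f_l": self.f_l,
            "aic": self.aic,
            "bic": self.bic,
            "aicc": self.aicc,
            "p": self.p,
            "n": self.n,
        }


@dataclass(frozen=True)
class BayesFactor:
    log_bf: float
    bf: float
    posterior_prob_1: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def accuracy(e_y, C_y, n: int | None = None) -> float:
    """Log-likelihood of the data at the posterior means.

    ``-0.5 e' C_y^{-1} e - 0.5 log|C_y| - (n/2) log 2*pi`` for residual
    vector ``e_y`` and noise covariance ``C_y``.
    """
    e_y = np.atleast_1d(np.asarray(e_y, dtype=float))
    if n is None:
        n = e_y.shape[0]
    if e_y.shape[0] != n:
        raise ValueError(f"residual has length {e_y.shape[0]}, expected n={n}")
    return -0.5 * _cov_quad(C_y, e_y) - 0.5 * _cov_logdet(C_y, n) - 0.5 * n * _LOG2PI


def complexity(e_theta, C_theta, S_theta,
               e_lambda=None, C_lambda=None, S_lambda=None) -> tuple[float, float]:
    """Complexity penalty of the free energy.

    Parameter part: ``0.5 e' C^{-1} e + 0.5 log|C| - 0.5 log|S|`` for
    prior-mean deviation ``e_theta``, prior covariance ``C_theta`` and
    posterior covariance ``S_theta``.  The hyperparameter part has the same
    form and is zero when the hyper arguments are omitted (noise known).
    Returns ``(complexity_params, complexity_hypers)``.
    """
    e_theta = np.atleast_1d(np.asarray(e_theta, dtype=float))
    d = e_theta.shape[0]
    cp = (0.5 * _cov_quad(C_theta, e_theta)
          + 0.5 * _cov_logdet(C_theta, d)
          - 0.5 * _cov_logdet(S_theta, d))
    if e_lambda is None:
        if C_lambda is not None or S_lambda is not None:
            raise ValueError("hyper covariances given without hyper deviation")
        return cp, 0.0
    e_lambda = np.atleast_1d(np.asarray(e_lambda, dtype=float))
    h = e_lambda.shape[0]
    ch = (0.5 * _cov_quad(C_lambda, e_lambda)
          + 0.5 * _cov_logdet(C_lambda, h)
          - 0.5 * _cov_logdet(S_lambda, h))
    return cp, ch


def laplace_free_energy(e_y, C_y, n, e_theta, C_theta, S_theta,
                        e_lambda=None, C_lambda=None, S_lambda=None,
                        region_index: dict | None = None,
                        param_sets: dict | None = None) -> EvidenceBreakdown:
    """Laplace free energy with its accuracy/complexity decomposition.

    ``region_index`` maps region labels to index arrays partitioning the
    data vector; per-region accuracy terms are exact (and sum to the total)
    when the noise covariance has no cross-region terms, as here.
    ``param_sets`` maps parameter-set labels to index arrays partitioning
    the parameter vector; per-set complexities ignore cross-set posterior
    correlation and only approximate the exact total.
    """
    e_y = np.atleast_1d(np.asarray(e_y, dtype=float))
    e_theta = np.atleast_1d(np.asarray(e_theta, dtype=float))
    acc = accuracy(e_y, C_y, n)
    cp, ch = complexity(e_theta, C_theta, S_theta, e_lambda, C_lambda, S_lambda)

    acc_by_region: dict = {}
    if region_index is not None:
        parts = _check_partition(region_index, n, "region")
        for label, idx in parts.items():
            acc_by_region[label] = accuracy(e_y[idx], _cov_sub(C_y, idx), idx.size)

    comp_by_set: dict = {}
    if param_sets is not None:
        parts = _check_partition(param_sets, e_theta.shape[0], "parameter-set")
        for label, idx in parts.items():
            comp_by_set[label], _ = complexity(
                e_theta[idx], _cov_sub(C_theta, idx), _cov_sub(S_theta, idx))

    return EvidenceBreakdown(
        accuracy=acc,
        complexity_params=cp,
        complexity_hypers=ch,
        accuracy_by_region=acc_by_region,
        complexity_by_set=comp_by_set,
    )


def aic(accuracy: float, p: int) -> float:
    """Akaike's criterion: accuracy minus one unit per free parameter."""
    if p < 0:
        raise ValueError("parameter count p must be >= 0")
    return accuracy - p


def bic(accuracy: float, p: int, n: int) -> float:
    """Bayesian information criterion: accuracy minus (p/2) log n."""
    if p < 0:
        raise ValueError("parameter count p must be >= 0")
    if n < 1:
        raise ValueError("data-point count n must be >= 1")
    return accuracy - 0.5 * p * math.log(n)


def aicc(accuracy: float, p: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > p + 1.

    Below that the correction denominator flips sign and the criterion
    penalises parameters less than AIC, so that regime is rejected.
    """
    if p < 0:
        raise ValueError("parameter count p must be >= 0")
    if n <= p + 1:
        raise ValueError(f"AICc requires n > p + 1 (got n={n}, p={p})")
    return aic(accuracy, p) - p * (p + 1) / (n - p - 1)


def bayes_factor(log_ev_1: float, log_ev_2: float) -> BayesFactor:
    """Bayes factor of model 1 over model 2 from their log evidences.

    The posterior probability of model 1 assumes equal model priors and is
    computed in log space, so extreme evidence differences do not overflow.
    A Bayes factor of 20 (log BF = 3) gives posterior probability > 0.95,
    the conventional decision threshold.
    """
    log_bf = float(log_ev_1) - float(log_ev_2)
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_bf))
    return BayesFactor(log_bf=log_bf, bf=bf, posterior_prob_1=float(expit(log_bf)))
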