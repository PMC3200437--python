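"""Variational Laplace fitting of nonlinear observation models.

Fits y = g(theta) + e with Gaussian parameter priors and a noise precision
composed from known bases, C_y^{-1} = sum_i exp(lambda_i) Q_i, under the
factorised Gaussian posterior q(theta) q(lambda).  The scheme is the
standard fixed-form one: a Gauss-Newton update of the parameter posterior
mean using the local Jacobian of g, Levenberg-Marquardt damping with step
rejection whenever the Laplace free energy would decrease, and a Newton
update of the log-precision hyperparameters from residual sufficient
statistics.  Fixed parameters are encoded by zero prior variance and the
optimiser works in the reduced free subspace.

The objective maximised — and reported — is the accuracy-minus-complexity
free energy of :mod:`evidence_bench.criteria`; for a linear g with known
noise a single undamped Gauss-Newton step lands exactly on the analytic
conjugate posterior.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
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

__all__ = ["NoiseModel", "VLOptions", "FitResult", "ModelEvaluationError",
           "numerical_jacobian", "vl_fit"]


class ModelEvaluationError(RuntimeError):
    """The prediction function returned non-finite output where required."""


@dataclass(frozen=True)
class NoiseModel:
    """Noise precision as a positive combination of diagonal bases.

    ``bases`` has one row per hyperparameter, each a non-negative diagonal
    of a precision basis Q_i; their exp(lambda)-weighted sum is the noise
    precision.  In the fMRI DCM case each basis is the indicator of one
    region's scans (independent, identically distributed noise per
    region).  ``estimate=False`` pins lambda at its prior mean, the
    known-noise case, in which the hyperparameter complexity is zero.
    """

    bases: np.ndarray
    mu_lambda: np.ndarray
    cov_lambda: np.ndarray
    estimate: bool = True

    def __post_init__(self):
        q = np.atleast_2d(np.asarray(self.bases, dtype=float))
        mu = np.atleast_1d(np.asarray(self.mu_lambda, dtype=float))
        cl = np.asarray(self.cov_lambda, dtype=float)
        if cl.ndim == 0:
            cl = cl.reshape(1, 1)
        if cl.ndim == 1:
            cl = np.diag(cl)
        if np.any(q < 0):
            raise ValueError("precision bases must be non-negative")
        if q.shape[0] != mu.shape[0] or cl.shape != (mu.shape[0],) * 2:
            raise ValueError("hyperprior dimensions do not match the bases")
        prec_at_prior = (np.exp(mu)[:, None] * q).sum(axis=0)
        if np.any(prec_at_prior <= 0):
            raise ValueError("precision not positive definite at the prior mean")
        object.__setattr__(self, "bases", q)
        object.__setattr__(self, "mu_lambda", mu)
        object.__setattr__(self, "cov_lambda", cl)

    @property
    def n_hypers(self) -> int:
        return self.mu_lambda.shape[0]

    @property
    def n_data(self) -> int:
        return self.bases.shape[1]

    def precision(self, lam: np.ndarray) -> np.ndarray:
        return (np.exp(lam)[:, None] * self.bases).sum(axis=0)

    @classmethod
    def iid_regions(cls, n_scans: int, n_regions: int,
                    mu_lambda: float = 0.0, var_lambda: float = 1.0,
                    estimate: bool = True) -> "NoiseModel":
        """One identity precision basis per region over region-major data."""
        n = n_scans * n_regions
        q = np.zeros((n_regions, n))
        for i in range(n_regions):
            q[i, i * n_scans:(i + 1) * n_scans] = 1.0
        return cls(bases=q, mu_lambda=np.full(n_regions, mu_lambda),
                   cov_lambda=np.eye(n_regions) * var_lambda, estimate=estimate)

    @classmethod
    def known(cls, noise_var, n: int) -> "NoiseModel":
        """Fixed, known noise with variance scalar or diagonal vector."""
        v = np.broadcast_to(np.asarray(noise_var, dtype=float), (n,))
        return cls(bases=(1.0 / v)[None, :], mu_lambda=np.zeros(1),
                   cov_lambda=np.eye(1), estimate=False)


@dataclass
class VLOptions:
    """Engineering knobs of the optimiser (all config-exposed).

    Convergence is declared after the free-energy increase stays below
    ``tol`` for ``tol_hits`` consecutive accepted steps.
    """

    max_iter: int = 128
    tol: float = 1e-2
    tol_hits: int = 2
    jacobian_rel_step: float = 1e-4
    init_damping: float = 0.0
    damping_grow: float = 8.0
    damping_shrink: float = 0.25
    max_rejects: int = 10
    lambda_newton_steps: int = 4


@dataclass
class FitResult:
    """Posterior beliefs, evidence breakdown and criteria for one fit."""

    theta: GaussianBelief
    lam: GaussianBelief
    breakdown: EvidenceBreakdown
    criteria: CriterionSet
    iterations: int
    converged: bool
    f_trajectory: np.ndarray
    data_hash: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "theta_mean": self.theta.mean.tolist(),
                "theta_cov": self.theta.cov.tolist(),
                "lambda_mean": self.lam.mean.tolist(),
                "lambda_cov": self.lam.cov.tolist(),
                "breakdown": self.breakdown.to_record(),
                "criteria": self.criteria.to_record(),
                "iterations": self.iterations,
                "converged": self.converged,
                "f_trajectory": np.asarray(self.f_trajectory).tolist(),
                "data_hash": self.data_hash,
            }, fh, indent=1)


def numerical_jacobian(g, theta0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Jacobian of g at theta0.

    Per-coordinate step ``max(|theta0_i|, 1) * rel_step``.  Every column is
    computed, including columns for parameters a caller may later hold
    fixed; masking is the optimiser's business, not the differentiator's.
    """
    theta0 = np.asarray(theta0, dtype=float)
    f0 = np.asarray(g(theta0), dtype=float)
    if not np.all(np.isfinite(f0)):
        raise ModelEvaluationError("g is non-finite at the expansion point")
    J = np.empty((f0.shape[0], theta0.shape[0]))
    for i in range(theta0.shape[0]):
        h = max(abs(theta0[i]), 1.0) * rel_step
        tp = theta0.copy()
        tp[i] += h
        tm = theta0.copy()
        tm[i] -= h
        fp = np.asarray(g(tp), dtype=float)
        fm = np.asarray(g(tm), dtype=float)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            raise ModelEvaluationError(f"g non-finite when perturbing coordinate {i}")
        J[:, i] = (fp - fm) / (2.0 * h)
    return J


def _try_predict(g, theta: np.ndarray):
    """Evaluate g, mapping divergence/instability to None (step rejection)."""
    try:
        out = np.asarray(g(theta), dtype=float)
    except (FloatingPointError, OverflowError, RuntimeError):
        return None
    if not np.all(np.isfinite(out)):
        return None
    return out


def _lambda_objective_terms(noise: NoiseModel, lam, e_y, jsj_diag):
    """Per-hyperparameter residual statistics G_i = sum_k q_ik (e_k^2 + V_k)."""
    stats = e_y * e_y + jsj_diag
    return noise.bases @ stats


def _update_lambda(noise: NoiseModel, lam, e_y, jsj_diag, n_steps):
    """Damped Newton ascent on the free energy as a function of lambda."""
    cl_inv = linalg.inv(noise.cov_lambda)
    G = _lambda_objective_terms(noise, lam, e_y, jsj_diag)
    for _ in range(n_steps):
        gam = np.exp(lam)
        # d/d lambda_i of [0.5 sum log D - 0.5 sum (e^2 + V) D] with
        # D = sum_i gamma_i q_i; first term via q_ik / D_k
        D = noise.precision(lam)
        grad = 0.5 * gam * (noise.bases @ (1.0 / D)) - 0.5 * gam * G \
            - cl_inv @ (lam - noise.mu_lambda)
        curv = 0.5 * gam * G + np.diag(cl_inv)
        step = grad / curv
        lam = lam + np.clip(step, -2.0, 2.0)
    gam = np.exp(lam)
    s_lam = linalg.inv(np.diag(0.5 * gam * G) + cl_inv)
    return lam, 0.5 * (s_lam + s_lam.T)


def vl_fit(g, prior: GaussianBelief, noise: NoiseModel, y,
           options: VLOptions | None = None,
           region_index: dict | None = None,
           param_sets: dict | None = None) -> FitResult:
    """Maximise the Laplace free energy of y = g(theta) + e.

    ``g`` maps the full parameter vector to a prediction vector the length
    of ``y``.  Parameters with zero prior variance are held at their prior
    mean and excluded from the update (their posterior equals their
    prior).  Non-convergence within ``max_iter`` is reported through the
    ``converged`` flag, not an exception; a non-finite prediction at the
    prior mean is a :class:`ModelEvaluationError`.
    """
    opts = options or VLOptions()
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = y.shape[0]
    if noise.n_data != n:
        raise ValueError("noise model and data length disagree")
    if not np.all(np.isfinite(y)):
        raise ValueError("data vector contains non-finite values")

    prior_var = np.diag(prior.cov)
    free = prior_var > 0.0
    n_free = int(np.count_nonzero(free))
    if n_free == 0:
        raise ValueError("no free parameters (all prior variances are zero)")
    mu_free = prior.mean[free]
    c_free = prior.cov[np.ix_(free, free)]
    c_free_inv = linalg.inv(c_free)

    def g_free(x):
        full = prior.mean.copy()
        full[free] = x
        return g(full)

    # parameter-set maps are given over the full vector; complexity is
    # evaluated in the free subspace, so re-index (fixed parameters
    # contribute exactly zero complexity and drop out)
    if param_sets is not None:
        pos = np.cumsum(free) - 1
        param_sets = {
            label: pos[np.asarray(idx, dtype=int)[free[np.asarray(idx, dtype=int)]]]
            for label, idx in param_sets.items()}
        param_sets = {k: v for k, v in param_sets.items() if v.size}

    m = mu_free.copy()
    lam = noise.mu_lambda.copy()
    pred = _try_predict(g_free, m)
    if pred is None:
        raise ModelEvaluationError("g is non-finite at the prior mean")
    if pred.shape[0] != n:
        raise ValueError("g output length does not match the data")

    def free_energy(e_y, lam, s_theta, m_free, s_lam):
        d = noise.precision(lam)
        if noise.estimate:
            bd = laplace_free_energy(
                e_y, 1.0 / d, n, m_free - mu_free, c_free, s_theta,
                e_lambda=lam - noise.mu_lambda, C_lambda=noise.cov_lambda,
                S_lambda=s_lam,
                region_index=region_index, param_sets=param_sets)
        else:
            bd = laplace_free_energy(
                e_y, 1.0 / d, n, m_free - mu_free, c_free, s_theta,
                region_index=region_index, param_sets=param_sets)
        return bd

    nu = opts.init_damping
    traj: list[float] = []
    s_theta = c_free
    s_lam = noise.cov_lambda
    bd = None
    hits = 0
    converged = False
    iterations = 0

    for it in range(opts.max_iter):
        iterations = it + 1
        J = numerical_jacobian(g_free, m, rel_step=opts.jacobian_rel_step)
        D = noise.precision(lam)
        e_y = y - pred
        H = (J.T * D) @ J + c_free_inv
        grad = J.T @ (D * e_y) - c_free_inv @ (m - mu_free)

        if bd is None:
            s_theta = _spd_inv(H)
            if noise.estimate:
                jsj = np.einsum("ij,jk,ik->i", J, s_theta, J)
                lam, s_lam = _update_lambda(noise, lam, e_y, jsj,
                                            opts.lambda_newton_steps)
                D = noise.precision(lam)
                H = (J.T * D) @ J + c_free_inv
                grad = J.T @ (D * e_y) - c_free_inv @ (m - mu_free)
                s_theta = _spd_inv(H)
            bd = free_energy(e_y, lam, s_theta, m, s_lam)
            traj.append(bd.f_l)

        accepted = False
        scale = np.diag(H).copy()
        for _ in range(opts.max_rejects):
            step = linalg.solve(H + nu * np.diag(scale), grad, assume_a="pos")
            m_new = m + step
            pred_new = _try_predict(g_free, m_new)
            if pred_new is not None:
                e_new = y - pred_new
                s_new = _spd_inv(H)
                lam_new, s_lam_new = lam, s_lam
                if noise.estimate:
                    jsj = np.einsum("ij,jk,ik->i", J, s_new, J)
                    lam_new, s_lam_new = _update_lambda(
                        noise, lam, e_new, jsj, opts.lambda_newton_steps)
                bd_new = free_energy(e_new, lam_new, s_new, m_new, s_lam_new)
                if bd_new.f_l >= bd.f_l - 1e-12:
                    gain = bd_new.f_l - bd.f_l
                    m, pred, lam, s_lam = m_new, pred_new, lam_new, s_lam_new
                    s_theta, bd = s_new, bd_new
                    traj.append(bd.f_l)
                    nu = max(nu * opts.damping_shrink, 0.0) if nu > 1e-8 else 0.0
                    accepted = True
                    hits = hits + 1 if gain < opts.tol else 0
                    break
            nu = opts.damping_grow * nu if nu > 0 else 0.25
        if not accepted:
            # no improving step found at any damping: treat as converged
            # at a local maximum of the free energy
            converged = True
            break
        if hits >= opts.tol_hits:
            converged = True
            break

    # assemble full-space posterior: fixed parameters keep their prior
    full_mean = prior.mean.copy()
    full_mean[free] = m
    full_cov = np.zeros_like(prior.cov)
    full_cov[np.ix_(free, free)] = s_theta
    theta_belief = GaussianBelief(mean=full_mean, cov=full_cov)
    lam_belief = GaussianBelief(mean=lam, cov=s_lam if noise.estimate
                                else noise.cov_lambda)

    cs = CriterionSet(
        f_l=bd.f_l,
        aic=aic(bd.accuracy, n_free),
        bic=bic(bd.accuracy, n_free, n),
        aicc=aicc(bd.accuracy, n_free, n) if n > n_free + 1 else float("nan"),
        p=n_free, n=n)
    return FitResult(
        theta=theta_belief, lam=lam_belief, breakdown=bd, criteria=cs,
        iterations=iterations, converged=converged,
        f_trajectory=np.asarray(traj),
        data_hash=hashlib.sha1(y.tobytes()).hexdigest())


def _spd_inv(H: np.ndarray) -> np.ndarray:
    cf = linalg.cho_factor(H, lower=True)
    S = linalg.cho_solve(cf, np.eye(H.shape[0]))
    return 0.5 * (S + S.T)
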