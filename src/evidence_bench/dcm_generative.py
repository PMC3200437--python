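"""Bilinear dynamic causal model for fMRI: priors, dynamics, BOLD forward model.

Neuronal activity z in each region obeys the bilinear system

    dz/dt = (A + sum_j u_j B^j) z + C u,

where A holds intrinsic (baseline) coupling, B^j the input-dependent
modulation of coupling, and C the direct driving inputs.  Each region's
activity passes through an extended Balloon model — vasodilatory signal s,
normalised blood flow f, venous volume v and deoxyhemoglobin content q —
and a nonlinear BOLD observation equation, then is sampled at the scan
repetition time.

Priors follow the standard fMRI DCM convention: self-connections
N(-1, 0.177^2) (implying decay half-lives centred near 720 ms), cross
connections N(1/64, 0.5^2) chosen to favour stable dynamics, and shrinkage
priors N(0, 2^2) on modulatory and input strengths.  Hemodynamic
parameters are scaled exponentials of Gaussian latents: decay and transit
time per region, plus the intra/extravascular signal ratio epsilon, each
with latent prior N(0, 1/64); the remaining Balloon constants are fixed.

Both ODE stages integrate with a fixed-step classical Runge-Kutta scheme
on a fine grid (default TR/16), with flow/volume/deoxyhemoglobin evolved
in log space so positivity is structural.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .criteria import GaussianBelief

__all__ = [
    "DCMSpec", "DCMParams", "RegionTimeseries", "InputSet", "ParameterMap",
    "InstabilityError", "sample_prior", "halflife_prior_stats",
    "integrate_neurodynamics", "balloon_bold", "predict", "build_speech_models",
    "HEMO_CONSTANTS",
]

# prior standard deviations (three-region model)
SIGMA_SELF = 0.177
SIGMA_CROSS = 0.5
SIGMA_S = 2.0
CROSS_PRIOR_MEAN = 1.0 / 64.0
HEMO_LATENT_SD = 0.125          # sqrt(1/64) on log-scaling latents

# Balloon / BOLD constants (3T-style observation model)
HEMO_CONSTANTS = {
    "kappa": 0.64,     # signal decay rate, 1/s (scaled by exp latent)
    "gamma": 0.32,     # flow autoregulation, 1/s
    "tau": 2.0,        # venous transit time, s (scaled by exp latent)
    "alpha": 0.32,     # Grubb vessel stiffness exponent
    "e0": 0.4,         # resting oxygen extraction fraction
    "epsilon": 1.0,    # intra/extravascular ratio (scaled by exp latent)
    "v0": 4.0,         # resting venous volume fraction, percent signal units
    "te": 0.04,        # echo time, s
    "theta0": 40.3,    # frequency offset of fully deoxygenated blood, 1/s
    "r0": 25.0,        # intravascular relaxation slope, 1/s
}

_STATE_BOUND = 1e6


class InstabilityError(RuntimeError):
    """Neuronal or hemodynamic integration diverged for this parameter draw."""


# ---------------------------------------------------------------------------
# specification and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DCMSpec:
    """Structure (masks) and prior hyperparameters of a multi-region DCM."""

    n_regions: int
    a_mask: np.ndarray
    b_masks: np.ndarray          # (n_inputs, r, r)
    c_mask: np.ndarray           # (r, n_inputs)
    tr: float = 2.0
    n_scans: int = 488
    region_labels: tuple = ()
    sigma_self: float = SIGMA_SELF
    sigma_cross: float = SIGMA_CROSS
    sigma_s: float = SIGMA_S
    mu_lambda: float = 0.0       # hyperprior on log noise precision, per region
    var_lambda: float = 1.0
    hemo_latent_sd: float = HEMO_LATENT_SD

    def __post_init__(self):
        r = self.n_regions
        a = np.asarray(self.a_mask, dtype=float)
        b = np.asarray(self.b_masks, dtype=float)
        c = np.asarray(self.c_mask, dtype=float)
        if a.shape != (r, r):
            raise ValueError("a_mask must be (r, r)")
        if not np.all(np.diag(a) == 1):
            raise ValueError("self-connections must always be present (diag of a_mask == 1)")
        if b.ndim != 3 or b.shape[1:] != (r, r):
            raise ValueError("b_masks must be (n_inputs, r, r)")
        if c.shape != (r, b.shape[0]):
            raise ValueError("c_mask must be (r, n_inputs)")
        labels = self.region_labels or tuple(f"R{i}" for i in range(r))
        if len(labels) != r:
            raise ValueError("region_labels length must equal n_regions")
        if self.tr <= 0 or self.n_scans < 1:
            raise ValueError("tr must be positive and n_scans >= 1")
        object.__setattr__(self, "a_mask", a)
        object.__setattr__(self, "b_masks", b)
        object.__setattr__(self, "c_mask", c)
        object.__setattr__(self, "region_labels", tuple(labels))

    @property
    def n_inputs(self) -> int:
        return self.b_masks.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "n_regions": self.n_regions,
                "a_mask": self.a_mask.tolist(),
                "b_masks": self.b_masks.tolist(),
                "c_mask": self.c_mask.tolist(),
                "tr": self.tr, "n_scans": self.n_scans,
                "region_labels": list(self.region_labels),
            }, fh, indent=1)


@dataclass
class DCMParams:
    """One realisation of the DCM parameter vector theta = {A, B, C, h}.

    ``h_latent`` has one row per region with columns (decay, transit,
    epsilon) log-scaling latents; zeros give the standard constants.
    Entries are exactly zero wherever the owning spec's mask is zero.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    h_latent: np.ndarray

    def hemo(self) -> dict:
        """Per-region hemodynamic parameter values after exp scaling."""
        hc = HEMO_CONSTANTS
        return {
            "kappa": hc["kappa"] * np.exp(self.h_latent[:, 0]),
            "tau": hc["tau"] * np.exp(self.h_latent[:, 1]),
            "epsilon": hc["epsilon"] * np.exp(self.h_latent[:, 2]),
            "gamma": np.full(self.A.shape[0], hc["gamma"]),
            "alpha": np.full(self.A.shape[0], hc["alpha"]),
            "e0": np.full(self.A.shape[0], hc["e0"]),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"A": self.A.tolist(), "B": self.B.tolist(),
                       "C": self.C.tolist(), "h_latent": self.h_latent.tolist()},
                      fh, indent=1)


@dataclass
class RegionTimeseries:
    """BOLD time series, one column per region, sampled at the TR."""

    values: np.ndarray
    tr: float
    region_labels: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be (n_scans, n_regions)")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        self.values = v
        self.region_labels = tuple(self.region_labels)

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def as_vector(self) -> np.ndarray:
        """Concatenate region series in fixed region order: the model
        prediction vector g(theta)."""
        return self.values.T.reshape(-1)

    def to_csv(self, path, sidecar: dict | None = None) -> None:
        pd.DataFrame(self.values, columns=list(self.region_labels)).to_csv(path, index=False)
        if sidecar is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump({"tr": self.tr, **sidecar}, fh, indent=1)


@dataclass
class InputSet:
    """Experimental inputs on the fine integration grid (t = k * dt)."""

    u: np.ndarray                # (n_fine + 1, n_inputs)
    dt: float
    labels: tuple

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 2 or not np.all(np.isfinite(u)):
            raise ValueError("u must be a finite 2-D array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.u = u
        self.labels = tuple(self.labels)

    def steps_per_scan(self, tr: float) -> int:
        spt = tr / self.dt
        if abs(spt - round(spt)) > 1e-9:
            raise ValueError("dt must divide the TR")
        return int(round(spt))


# ---------------------------------------------------------------------------
# parameter packing: DCMParams <-> flat vector with prior beliefs
# ---------------------------------------------------------------------------

class ParameterMap:
    """Flat ordering of the free parameters of a DCM specification.

    Only mask-present entries appear in the vector; parameters a model
    fixes at zero are simply absent, so the vector length is the model's
    free-parameter count.  Order: intrinsic A (row-major over mask), then
    modulatory B per input, then input C, then hemodynamic latents per
    region (decay, transit, epsilon).
    """

    def __init__(self, spec: DCMSpec):
        self.spec = spec
        r = spec.n_regions
        entries: list[tuple] = []
        for i in range(r):
            for k in range(r):
                if spec.a_mask[i, k]:
                    entries.append(("A", i, k))
        for j in range(spec.n_inputs):
            for i in range(r):
                for k in range(r):
                    if spec.b_masks[j, i, k]:
                        entries.append(("B", j, i, k))
        for i in range(r):
            for j in range(spec.n_inputs):
                if spec.c_mask[i, j]:
                    entries.append(("C", i, j))
        for i in range(r):
            for l in range(3):
                entries.append(("h", i, l))
        self.entries = entries

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        out = []
        lab = self.spec.region_labels
        for e in self.entries:
            if e[0] == "A":
                out.append(f"a_{lab[e[1]]}{lab[e[2]]}")
            elif e[0] == "B":
                out.append(f"b{e[1]}_{lab[e[2]]}{lab[e[3]]}")
            elif e[0] == "C":
                out.append(f"c_{lab[e[1]]}u{e[2]}")
            else:
                out.append(f"h_{lab[e[1]]}_{('decay', 'transit', 'epsilon')[e[2]]}")
        return out

    def sets(self) -> dict[str, np.ndarray]:
        """Index partition by parameter set (for complexity decomposition)."""
        groups = {"intrinsic": [], "modulatory": [], "input": [], "hemodynamic": []}
        names = {"A": "intrinsic", "B": "modulatory", "C": "input", "h": "hemodynamic"}
        for idx, e in enumerate(self.entries):
            groups[names[e[0]]].append(idx)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items() if v}

    def set_of(self, prefix: str) -> np.ndarray:
        return self.sets()[prefix]

    def pack(self, params: DCMParams) -> np.ndarray:
        theta = np.empty(self.size)
        for idx, e in enumerate(self.entries):
            if e[0] == "A":
                theta[idx] = params.A[e[1], e[2]]
            elif e[0] == "B":
                theta[idx] = params.B[e[1], e[2], e[3]]
            elif e[0] == "C":
                theta[idx] = params.C[e[1], e[2]]
            else:
                theta[idx] = params.h_latent[e[1], e[2]]
        return theta

    def unpack(self, theta: np.ndarray) -> DCMParams:
        s = self.spec
        r = s.n_regions
        A = np.zeros((r, r))
        B = np.zeros((s.n_inputs, r, r))
        C = np.zeros((r, s.n_inputs))
        h = np.zeros((r, 3))
        for idx, e in enumerate(self.entries):
            if e[0] == "A":
                A[e[1], e[2]] = theta[idx]
            elif e[0] == "B":
                B[e[1], e[2], e[3]] = theta[idx]
            elif e[0] == "C":
                C[e[1], e[2]] = theta[idx]
            else:
                h[e[1], e[2]] = theta[idx]
        return DCMParams(A=A, B=B, C=C, h_latent=h)

    def prior(self) -> GaussianBelief:
        s = self.spec
        mean = np.zeros(self.size)
        var = np.zeros(self.size)
        for idx, e in enumerate(self.entries):
            if e[0] == "A":
                if e[1] == e[2]:
                    mean[idx], var[idx] = -1.0, s.sigma_self**2
                else:
                    mean[idx], var[idx] = CROSS_PRIOR_MEAN, s.sigma_cross**2
            elif e[0] in ("B", "C"):
                mean[idx], var[idx] = 0.0, s.sigma_s**2
            else:
                mean[idx], var[idx] = 0.0, s.hemo_latent_sd**2
        return GaussianBelief(mean=mean, cov=np.diag(var))


# ---------------------------------------------------------------------------
# prior sampling and its half-life implication
# ---------------------------------------------------------------------------

def sample_prior(spec: DCMSpec, seed=None) -> DCMParams:
    """Draw a full parameter set from the prior; masked entries stay zero."""
    rng = np.random.default_rng(seed)
    pm = ParameterMap(spec)
    prior = pm.prior()
    theta = prior.mean + prior.sd * rng.standard_normal(pm.size)
    return pm.unpack(theta)


def halflife_prior_stats(n_samples: int = 10**6, seed=None) -> tuple[float, float]:
    """Monte-Carlo summary of the half-life prior implied by A_ii ~ N(-1, 0.177^2).

    Activity decays as exp(A_ii t), reaching half its value after
    (1/A_ii) log 0.5.  Non-negative draws (probability ~ 1e-8) are
    rejected so the transform stays defined.  Returns the mean half-life
    in milliseconds and the fraction within [500, 1000] ms.
    """
    if n_samples < 10**4:
        raise ValueError("n_samples must be >= 1e4")
    rng = np.random.default_rng(seed)
    a = rng.normal(-1.0, SIGMA_SELF, size=n_samples)
    a = a[a < 0.0]
    halflife_ms = (math.log(0.5) / a) * 1000.0
    frac = float(np.mean((halflife_ms >= 500.0) & (halflife_ms <= 1000.0)))
    return float(np.mean(halflife_ms)), frac


# ---------------------------------------------------------------------------
# numerical integration (fixed-step classical Runge-Kutta)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _neuro_deriv(A, B, C, z, u):
    M = A.copy()
    for j in range(u.shape[0]):
        if u[j] != 0.0:
            M = M + u[j] * B[j]
    return M @ z + C @ u


@njit(cache=True)
def _rk4_neuro(A, B, C, u, dt, z0):
    T = u.shape[0] - 1
    r = A.shape[0]
    z = np.empty((T + 1, r))
    z[0] = z0
    for k in range(T):
        u0 = u[k]
        u1 = u[k + 1]
        um = 0.5 * (u0 + u1)
        k1 = _neuro_deriv(A, B, C, z[k], u0)
        k2 = _neuro_deriv(A, B, C, z[k] + 0.5 * dt * k1, um)
        k3 = _neuro_deriv(A, B, C, z[k] + 0.5 * dt * k2, um)
        k4 = _neuro_deriv(A, B, C, z[k] + dt * k3, u1)
        z[k + 1] = z[k] + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if np.any(np.abs(z[k + 1]) > _STATE_BOUND):
            z[k + 1:] = np.inf
            break
    return z


@njit(cache=True)
def _clamp(x):
    # keep exp() away from 0/inf so diverging trajectories surface as the
    # state-bound check, not as a zero division mid-step
    if x > 50.0:
        return 50.0
    if x < -50.0:
        return -50.0
    return x


@njit(cache=True)
def _hemo_deriv(zt, s, lf, lv, lq, kappa, gamma, tau, alpha, e0):
    f = math.exp(_clamp(lf))
    v = math.exp(_clamp(lv))
    q = math.exp(_clamp(lq))
    fv = v ** (1.0 / alpha)
    ds = zt - kappa * s - gamma * (f - 1.0)
    dlf = s / f
    dlv = (f - fv) / (tau * v)
    ee = 1.0 - (1.0 - e0) ** (1.0 / f)
    dlq = (f * ee / e0 - fv * q / v) / (tau * q)
    return ds, dlf, dlv, dlq


@njit(cache=True)
def _rk4_hemo(z, kappa, gamma, tau, alpha, e0, dt):
    """Integrate the Balloon states per region driven by neuronal z.

    Returns volume v and deoxyhemoglobin q on the fine grid; flow, volume
    and q evolve in log space.
    """
    T = z.shape[0] - 1
    r = z.shape[1]
    v_out = np.ones((T + 1, r))
    q_out = np.ones((T + 1, r))
    for i in range(r):
        s = 0.0
        lf = 0.0
        lv = 0.0
        lq = 0.0
        for k in range(T):
            z0 = z[k, i]
            z1 = z[k + 1, i]
            zm = 0.5 * (z0 + z1)
            a1, b1, c1, d1 = _hemo_deriv(z0, s, lf, lv, lq,
                                         kappa[i], gamma[i], tau[i], alpha[i], e0[i])
            a2, b2, c2, d2 = _hemo_deriv(zm, s + 0.5 * dt * a1, lf + 0.5 * dt * b1,
                                         lv + 0.5 * dt * c1, lq + 0.5 * dt * d1,
                                         kappa[i], gamma[i], tau[i], alpha[i], e0[i])
            a3, b3, c3, d3 = _hemo_deriv(zm, s + 0.5 * dt * a2, lf + 0.5 * dt * b2,
                                         lv + 0.5 * dt * c2, lq + 0.5 * dt * d2,
                                         kappa[i], gamma[i], tau[i], alpha[i], e0[i])
            a4, b4, c4, d4 = _hemo_deriv(z1, s + dt * a3, lf + dt * b3,
                                         lv + dt * c3, lq + dt * d3,
                                         kappa[i], gamma[i], tau[i], alpha[i], e0[i])
            s += (dt / 6.0) * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            lf += (dt / 6.0) * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            lv += (dt / 6.0) * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
            lq += (dt / 6.0) * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
            v_out[k + 1, i] = math.exp(lv)
            q_out[k + 1, i] = math.exp(lq)
            if not (np.isfinite(s) and np.isfinite(lf) and np.isfinite(lv)
                    and np.isfinite(lq)) or abs(lv) > 49.0 or abs(lq) > 49.0:
                v_out[k + 1:, i] = np.inf
                q_out[k + 1:, i] = np.inf
                break
    return v_out, q_out


@njit(cache=True)
def _joint_deriv(A, B, C, u, x, kappa, gamma, tau, alpha, e0):
    r = A.shape[0]
    dx = np.empty(5 * r)
    z = x[0:r]
    M = A.copy()
    for j in range(u.shape[0]):
        if u[j] != 0.0:
            M = M + u[j] * B[j]
    dx[0:r] = M @ z + C @ u
    for i in range(r):
        s = x[r + i]
        f = math.exp(_clamp(x[2 * r + i]))
        v = math.exp(_clamp(x[3 * r + i]))
        q = math.exp(_clamp(x[4 * r + i]))
        fv = v ** (1.0 / alpha[i])
        dx[r + i] = z[i] - kappa[i] * s - gamma[i] * (f - 1.0)
        dx[2 * r + i] = s / f
        dx[3 * r + i] = (f - fv) / (tau[i] * v)
        ee = 1.0 - (1.0 - e0[i]) ** (1.0 / f)
        dx[4 * r + i] = (f * ee / e0[i] - fv * q / v) / (tau[i] * q)
    return dx


@njit(cache=True)
def _rk4_joint(A, B, C, u, dt, kappa, gamma, tau, alpha, e0):
    """One-pass integration of neuronal and hemodynamic states together,
    avoiding the interpolation error of the staged path.  Returns volume
    and deoxyhemoglobin on the fine grid."""
    T = u.shape[0] - 1
    r = A.shape[0]
    x = np.zeros(5 * r)
    v_out = np.ones((T + 1, r))
    q_out = np.ones((T + 1, r))
    for k in range(T):
        u0 = u[k]
        u1 = u[k + 1]
        um = 0.5 * (u0 + u1)
        k1 = _joint_deriv(A, B, C, u0, x, kappa, gamma, tau, alpha, e0)
        k2 = _joint_deriv(A, B, C, um, x + 0.5 * dt * k1, kappa, gamma, tau, alpha, e0)
        k3 = _joint_deriv(A, B, C, um, x + 0.5 * dt * k2, kappa, gamma, tau, alpha, e0)
        k4 = _joint_deriv(A, B, C, u1, x + dt * k3, kappa, gamma, tau, alpha, e0)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        bad = False
        for i in range(r):
            if not np.isfinite(x[i]) or abs(x[i]) > _STATE_BOUND \
                    or abs(x[3 * r + i]) > 49.0 or abs(x[4 * r + i]) > 49.0:
                bad = True
        if bad:
            v_out[k + 1:] = np.inf
            q_out[k + 1:] = np.inf
            break
        for i in range(r):
            v_out[k + 1, i] = math.exp(x[3 * r + i])
            q_out[k + 1, i] = math.exp(x[4 * r + i])
    return v_out, q_out


def _bold_equation(v: np.ndarray, q: np.ndarray, h: dict) -> np.ndarray:
    """Nonlinear BOLD observation from volume and deoxyhemoglobin."""
    hc = HEMO_CONSTANTS
    k1 = 4.3 * hc["theta0"] * h["e0"] * hc["te"]
    k2 = h["epsilon"] * hc["r0"] * h["e0"] * hc["te"]
    k3 = 1.0 - h["epsilon"]
    return hc["v0"] * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def integrate_neurodynamics(params: DCMParams, inputs: InputSet,
                            z0: np.ndarray | None = None) -> np.ndarray:
    """Fine-grid neuronal states for one parameter draw.

    Raises :class:`InstabilityError` if the trajectory diverges (norm
    exceeding 1e6), which flags an unstable parameter draw.
    """
    r = params.A.shape[0]
    z0 = np.zeros(r) if z0 is None else np.asarray(z0, dtype=float)
    if z0.shape != (r,) or not np.all(np.isfinite(z0)):
        raise ValueError("z0 must be a finite vector of length n_regions")
    z = _rk4_neuro(np.ascontiguousarray(params.A), np.ascontiguousarray(params.B),
                   np.ascontiguousarray(params.C), np.ascontiguousarray(inputs.u),
                   inputs.dt, z0)
    if not np.all(np.isfinite(z)):
        raise InstabilityError(
            f"neuronal integration diverged (A diag={np.diag(params.A)}, "
            f"max|B|={np.max(np.abs(params.B)):.3g})")
    return z


def balloon_bold(z_fine: np.ndarray, params_or_h, tr: float, dt: float,
                 region_labels: tuple | None = None) -> RegionTimeseries:
    """Map fine-grid neuronal states through the Balloon/BOLD model.

    Output is sampled at the end of each repetition time (scan i at time
    (i + 1) * TR).  ``params_or_h`` is a :class:`DCMParams` or the dict its
    ``hemo()`` method returns.
    """
    h = params_or_h.hemo() if isinstance(params_or_h, DCMParams) else params_or_h
    z_fine = np.asarray(z_fine, dtype=float)
    r = z_fine.shape[1]
    spt = tr / dt
    if abs(spt - round(spt)) > 1e-9:
        raise ValueError("dt must divide the TR")
    spt = int(round(spt))
    v, q = _rk4_hemo(np.ascontiguousarray(z_fine),
                     np.ascontiguousarray(h["kappa"], dtype=float),
                     np.ascontiguousarray(h["gamma"], dtype=float),
                     np.ascontiguousarray(h["tau"], dtype=float),
                     np.ascontiguousarray(h["alpha"], dtype=float),
                     np.ascontiguousarray(h["e0"], dtype=float), dt)
    if not (np.all(np.isfinite(v)) and np.all(v > 0)):
        raise InstabilityError("hemodynamic integration produced non-physical volume")
    bold = _bold_equation(v, q, h)
    n_scans = (z_fine.shape[0] - 1) // spt
    sample_idx = (np.arange(1, n_scans + 1) * spt)
    labels = region_labels or tuple(f"R{i}" for i in range(r))
    return RegionTimeseries(values=bold[sample_idx], tr=tr, region_labels=labels)


def predict(params: DCMParams, spec: DCMSpec, inputs: InputSet) -> RegionTimeseries:
    """Full forward model: neurodynamics through hemodynamics, sampled at TR.

    The joint state is integrated in a single pass (rather than staging
    neuronal then hemodynamic integration) so no interpolation error of
    the neuronal drive enters the Balloon states.
    """
    spt = inputs.steps_per_scan(spec.tr)
    needed = spec.n_scans * spt
    if inputs.u.shape[0] - 1 < needed:
        raise ValueError("input grid shorter than n_scans * TR")
    h = params.hemo()
    v, q = _rk4_joint(np.ascontiguousarray(params.A),
                      np.ascontiguousarray(params.B),
                      np.ascontiguousarray(params.C),
                      np.ascontiguousarray(inputs.u[:needed + 1]), inputs.dt,
                      np.ascontiguousarray(h["kappa"], dtype=float),
                      np.ascontiguousarray(h["gamma"], dtype=float),
                      np.ascontiguousarray(h["tau"], dtype=float),
                      np.ascontiguousarray(h["alpha"], dtype=float),
                      np.ascontiguousarray(h["e0"], dtype=float))
    if not np.all(np.isfinite(v)):
        raise InstabilityError(
            f"integration diverged (A diag={np.diag(params.A)}, "
            f"max|B|={np.max(np.abs(params.B)):.3g})")
    bold = _bold_equation(v, q, h)
    sample_idx = np.arange(1, spec.n_scans + 1) * spt
    return RegionTimeseries(values=bold[sample_idx], tr=spec.tr,
                            region_labels=spec.region_labels)


# ---------------------------------------------------------------------------
# the intelligible-speech network pair
# ---------------------------------------------------------------------------

def build_speech_models(tr: float = 2.0, n_scans: int = 488) -> tuple[DCMSpec, DCMSpec]:
    """Full and nested three-region speech networks.

    Regions are ordered (P, F, A): posterior temporal, frontal, anterior
    temporal.  Auditory input drives P only.  Intelligibility modulates
    the P->F connection in both models and additionally P->A in the full
    model; the nested model fixes that modulatory connection at zero, so
    the pair differ by exactly one free parameter.  Row i, column k of A
    (or B) is the connection from region k to region i.
    """
    r = 3
    a_mask = np.ones((r, r))
    c_mask = np.zeros((r, 2))
    c_mask[0, 0] = 1.0                      # u_aud -> P
    b_aud = np.zeros((r, r))
    b_full = np.zeros((r, r))
    b_full[1, 0] = 1.0                      # u_int modulates P -> F
    b_full[2, 0] = 1.0                      # u_int modulates P -> A (full only)
    b_nested = np.zeros((r, r))
    b_nested[1, 0] = 1.0
    common = dict(n_regions=r, a_mask=a_mask, c_mask=c_mask, tr=tr,
                  n_scans=n_scans, region_labels=("P", "F", "A"))
    full = DCMSpec(b_masks=np.stack([b_aud, b_full]), **common)
    nested = DCMSpec(b_masks=np.stack([b_aud, b_nested]), **common)
    return full, nested
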