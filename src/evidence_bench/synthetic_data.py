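"""Generators for every input the benchmark needs.

The study's empirical inputs — a four-condition event-related fMRI design
(351 scans, 12 regressors built from three hemodynamic basis functions per
condition) and a three-region speech-paradigm DCM (488 scans per region) —
are emulated here: seeded event schedules, a double-gamma canonical
hemodynamic response with temporal and dispersion derivatives, prior-drawn
parameters, and additive white Gaussian noise calibrated so that

    SNR = <sigma_y> / sigma_e,

the ratio of the average temporal standard deviation of the noiseless
signal to the noise standard deviation.  For the GLM arm <sigma_y> is
averaged over prior draws of the regression coefficients; for the DCM arm
it is averaged over the three predicted region time series.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .dcm_generative import (
    DCMParams,
    DCMSpec,
    InputSet,
    RegionTimeseries,
    predict,
)

__all__ = ["SNRSpec", "DCMDataset", "hrf_basis", "make_glm_design",
           "make_speech_inputs", "calibrate_snr", "glm_signal_sd",
           "generate_glm_dataset", "generate_dcm_dataset",
           "default_speech_params"]


@dataclass(frozen=True)
class SNRSpec:
    """Signal-to-noise calibration: target_snr = signal_sd / noise_sd."""

    target_snr: float
    signal_sd: float
    noise_sd: float

    def __post_init__(self):
        if min(self.target_snr, self.signal_sd, self.noise_sd) <= 0:
            raise ValueError("SNR quantities must be positive")
        if abs(self.target_snr - self.signal_sd / self.noise_sd) > 1e-9 * self.target_snr:
            raise ValueError("target_snr must equal signal_sd / noise_sd")


@dataclass
class DCMDataset:
    """One simulated DCM data set with its generating truth."""

    timeseries: RegionTimeseries
    params: DCMParams
    snr: SNRSpec
    inputs: InputSet
    resample_count: int
    seed: int | None


# ---------------------------------------------------------------------------
# hemodynamic basis set and GLM design
# ---------------------------------------------------------------------------

def hrf_basis(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF with temporal and dispersion derivatives.

    Peak at 6 s, undershoot at 16 s, peak/undershoot ratio 6.  The
    temporal derivative is the (negative) derivative with respect to onset
    delay and the dispersion derivative the sensitivity to the peak
    dispersion; columns are scaled so the canonical response peaks at 1.
    Returns an array of shape (duration/dt, 3).
    """
    t = np.arange(0.0, duration, dt)

    def canon(disp: float, shift: float = 0.0) -> np.ndarray:
        ts = t - shift
        h = (gamma_dist.pdf(ts, 6.0, scale=disp)
             - gamma_dist.pdf(ts, 16.0, scale=1.0) / 6.0)
        h[ts < 0] = 0.0
        return h

    h0 = canon(1.0)
    dtemp = (canon(1.0) - canon(1.0, shift=1.0)) / 1.0
    ddisp = (canon(1.0) - canon(1.01)) / 0.01
    basis = np.column_stack([h0, dtemp, ddisp])
    return basis / np.max(h0)


def _event_schedule(duration: float, conditions: int, mean_iti: float,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Pseudo-random interleaved event onsets, one array per condition.

    Inter-trial intervals are uniform on mean_iti +/- 50%; conditions are
    assigned in shuffled blocks so each occurs equally often.
    """
    onsets: list[float] = []
    t = float(rng.uniform(0.0, mean_iti))
    while t < duration - 1.0:
        onsets.append(t)
        t += float(rng.uniform(0.5 * mean_iti, 1.5 * mean_iti))
    labels = np.empty(len(onsets), dtype=int)
    for start in range(0, len(onsets), conditions):
        block = rng.permutation(conditions)
        take = min(conditions, len(onsets) - start)
        labels[start:start + take] = block[:take]
    return [np.asarray([o for o, c in zip(onsets, labels) if c == j])
            for j in range(conditions)]


def make_glm_design(n_scans: int = 351, conditions: int = 4,
                    basis_per_condition: int = 3, tr: float = 2.0,
                    events: list[np.ndarray] | None = None,
                    seed=None, mean_iti: float = 8.0) -> np.ndarray:
    """Event-related design matrix, columns ordered condition-major.

    Each condition's event train is convolved with the canonical HRF and
    its derivatives sampled at the TR, giving ``conditions *
    basis_per_condition`` regressors.  The nested design used throughout
    the benchmark is this matrix with the first condition's columns
    removed.  Supplying ``events`` (onset arrays in seconds, one per
    condition) overrides the seeded pseudo-random schedule.
    """
    if conditions * basis_per_condition < 1:
        raise ValueError("need at least one regressor")
    if basis_per_condition > 3:
        raise ValueError("at most 3 basis functions are available")
    duration = n_scans * tr
    if events is None:
        rng = np.random.default_rng(seed)
        events = _event_schedule(duration, conditions, mean_iti, rng)
    if len(events) != conditions:
        raise ValueError("one onset array per condition required")
    dt = tr / 8.0
    n_fine = int(round(duration / dt))
    basis = hrf_basis(dt)[:, :basis_per_condition]
    X = np.zeros((n_scans, conditions * basis_per_condition))
    scan_idx = (np.arange(n_scans) * 8).astype(int)
    for j, ons in enumerate(events):
        ons = np.asarray(ons, dtype=float)
        if ons.size and ons.max() >= duration:
            raise ValueError("event schedule exceeds the scan duration")
        stick = np.zeros(n_fine)
        stick[np.floor(ons / dt).astype(int)] = 1.0
        for b in range(basis_per_condition):
            reg = np.convolve(stick, basis[:, b])[:n_fine]
            X[:, j * basis_per_condition + b] = reg[scan_idx]
    return X


# ---------------------------------------------------------------------------
# SNR calibration
# ---------------------------------------------------------------------------

def calibrate_snr(predictions: np.ndarray, target_snr: float) -> SNRSpec:
    """Noise level achieving a target SNR for the given signals.

    ``predictions`` is (k, n): one row per signal (prior draw or region);
    <sigma_y> is the mean of their temporal standard deviations and
    sigma_e = <sigma_y> / target_snr.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    P = np.atleast_2d(np.asarray(predictions, dtype=float))
    sds = P.std(axis=1)
    if np.all(sds == 0):
        raise ValueError("all signals are constant; SNR undefined")
    sig = float(sds.mean())
    return SNRSpec(target_snr=target_snr, signal_sd=sig, noise_sd=sig / target_snr)


def glm_signal_sd(design: np.ndarray, sigma_p: float,
                  n_draws: int = 1000, seed=None) -> float:
    """<sigma_y> for a GLM: average temporal SD of X theta over prior draws."""
    rng = np.random.default_rng(seed)
    X = np.asarray(design, dtype=float)
    theta = rng.normal(0.0, sigma_p, size=(X.shape[1], n_draws))
    return float((X @ theta).std(axis=0).mean())


def generate_glm_dataset(design: np.ndarray, sigma_p: float, snr_spec: SNRSpec,
                         seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw theta ~ N(0, sigma_p^2 I), return (y = X theta + e, theta)."""
    rng = np.random.default_rng(seed)
    X = np.asarray(design, dtype=float)
    theta = rng.normal(0.0, sigma_p, size=X.shape[1])
    y = X @ theta + rng.normal(0.0, snr_spec.noise_sd, size=X.shape[0])
    return y, theta


# ---------------------------------------------------------------------------
# DCM inputs and data sets
# ---------------------------------------------------------------------------

def make_speech_inputs(n_scans: int = 488, tr: float = 2.0, dt: float | None = None,
                       event_duration: float = 1.0, mean_isi: float = 8.0,
                       seed=None) -> InputSet:
    """Auditory spike train u_aud plus intelligibility indicator u_int.

    One-second auditory events with pseudo-random inter-stimulus intervals
    (mean 8 s); alternate events are intelligible, so u_int equals u_aud on
    half the trials and is zero on the rest.
    """
    dt = tr / 16.0 if dt is None else dt
    rng = np.random.default_rng(seed)
    duration = n_scans * tr
    n_fine = int(round(duration / dt))
    u = np.zeros((n_fine + 1, 2))
    t = float(rng.uniform(0.0, mean_isi))
    intelligible = bool(rng.integers(0, 2))
    while t + event_duration < duration:
        a = int(round(t / dt))
        b = int(round((t + event_duration) / dt))
        u[a:b + 1, 0] = 1.0
        if intelligible:
            u[a:b + 1, 1] = 1.0
        intelligible = not intelligible
        t += float(rng.uniform(0.5 * mean_isi, 1.5 * mean_isi))
    return InputSet(u=u, dt=dt, labels=("u_aud", "u_int"))


def default_speech_params(spec: DCMSpec) -> DCMParams:
    """Held-constant parameter values for the speech simulations.

    Self-connections -1, intrinsic cross connections 0.3, auditory input
    strength c_P = 0.3, hemodynamics at their prior means.  Modulatory
    entries are zero here; :func:`generate_dcm_dataset` draws them.
    """
    r = spec.n_regions
    A = np.full((r, r), 0.3) * spec.a_mask
    np.fill_diagonal(A, -1.0)
    B = np.zeros_like(spec.b_masks)
    C = 0.3 * spec.c_mask
    return DCMParams(A=A, B=B, C=C, h_latent=np.zeros((r, 3)))


def generate_dcm_dataset(spec: DCMSpec, snr: float,
                         fixed_params: DCMParams | None = None,
                         seed=None, inputs: InputSet | None = None,
                         max_resample: int = 100) -> DCMDataset:
    """Simulate one noisy data set from a speech-model specification.

    Modulatory connections present in the spec's masks are drawn from
    their shrinkage prior and made positive (facilitation only, by taking
    the absolute value); every other parameter is held at ``fixed_params``
    (defaults from :func:`default_speech_params`).  Draws whose dynamics
    diverge during integration are resampled, with the count recorded
    (transient modulation tolerates connection strengths a sustained
    eigenvalue test would reject, so divergence is the operative test).
    White Gaussian noise is added at the target SNR, with <sigma_y>
    averaged over the regions of this draw's noiseless prediction.
    """
    from .dcm_generative import InstabilityError

    rng = np.random.default_rng(seed)
    base = fixed_params or default_speech_params(spec)
    if inputs is None:
        inputs = make_speech_inputs(spec.n_scans, spec.tr,
                                    seed=rng.integers(0, 2**31 - 1))
    resamples = 0
    while True:
        B = np.abs(rng.normal(0.0, spec.sigma_s, size=spec.b_masks.shape)) \
            * spec.b_masks
        params = DCMParams(A=base.A.copy(), B=B, C=base.C.copy(),
                           h_latent=base.h_latent.copy())
        try:
            clean = predict(params, spec, inputs)
            break
        except InstabilityError:
            resamples += 1
            if resamples > max_resample:
                raise RuntimeError("could not draw stable modulatory parameters")
    snr_spec = calibrate_snr(clean.values.T, snr)
    noisy = clean.values + rng.normal(0.0, snr_spec.noise_sd, size=clean.values.shape)
    ts = RegionTimeseries(values=noisy, tr=spec.tr, region_labels=spec.region_labels)
    return DCMDataset(timeseries=ts, params=params, snr=snr_spec,
                      inputs=inputs, resample_count=resamples,
                      seed=seed if isinstance(seed, (int, type(None))) else None)
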