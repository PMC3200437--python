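"""Study orchestration: SNR and sample-size sweeps, full vs nested models.

Each sweep simulates data from a known ("true") model — either the full
model or the nested one with a parameter subset fixed at zero — fits both
candidates, scores them with every criterion, and aggregates the oriented
log Bayes factor (true model versus the other) over replications.  GLM
sweeps aggregate with the mean over 1000 replications per grid point; DCM
sweeps with the median, which is robust to the heavier variability of the
nonlinear fits.  Replication seeds derive from the master seed through a
counter-based spawn so every grid point is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dcm_generative import DCMSpec, ParameterMap, build_speech_models, predict
from .linear_models import GLMSpec, glm_criteria_batch
from .synthetic_data import generate_dcm_dataset, glm_signal_sd, make_glm_design
from .variational_laplace import FitResult, NoiseModel, VLOptions, vl_fit

__all__ = ["SweepResult", "ComparisonReport", "glm_snr_sweep", "glm_n_sweep",
           "dcm_snr_sweep", "fit_dcm", "decompose_comparison",
           "PAPER_SCALE", "DESK_SCALE"]

# replication counts and sizes matching the original study conditions,
# and reduced desk-scale settings for smoke runs
PAPER_SCALE = {"glm_reps": 1000, "dcm_reps": 50, "dcm_n_scans": 488}
DESK_SCALE = {"glm_reps": 50, "dcm_reps": 10, "dcm_n_scans": 128}

SIGMA_P_DEFAULT = 6.05   # prior SD of regression coefficients (empirical calibration)


@dataclass
class SweepResult:
    """Aggregated log Bayes factors over an SNR or N grid.

    ``table`` holds one row per (grid point, criterion) with the
    aggregated oriented log Bayes factor of the true model versus the
    alternative, its SD and central 90% interval over replications, and
    the number of replications excluded (non-converged fits).
    """

    axis: str
    grid: np.ndarray
    table: pd.DataFrame
    aggregator: str
    reps: int
    true_model: str
    seed: int
    config: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def manifest(self) -> dict:
        return {"axis": self.axis, "grid": np.asarray(self.grid).tolist(),
                "aggregator": self.aggregator, "reps": self.reps,
                "true_model": self.true_model, "seed": self.seed,
                "config": self.config}

    def criterion_curve(self, criterion: str) -> np.ndarray:
        sub = self.table[self.table.criterion == criterion]
        return sub.sort_values(self.axis).log_bf.to_numpy()


def _rep_seed(master: int, *counters: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master)] + [int(c) for c in counters])


def _aggregate(rows: list[dict], axis: str, values: dict[str, np.ndarray],
               point, aggregator: str, n_excluded: int = 0) -> None:
    agg = np.mean if aggregator == "mean" else np.median
    for crit, v in values.items():
        v = np.asarray(v, dtype=float)
        rows.append({
            axis: point, "criterion": crit, "log_bf": float(agg(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "q05": float(np.quantile(v, 0.05)),
            "q95": float(np.quantile(v, 0.95)),
            "reps": int(v.size), "n_excluded": int(n_excluded),
        })


# ---------------------------------------------------------------------------
# GLM sweeps (analytic fits, fully vectorised over replications)
# ---------------------------------------------------------------------------

def _glm_designs(n_scans: int, seed, sigma_p: float,
                 conditions: int = 4, basis: int = 3):
    X_full = make_glm_design(n_scans=n_scans, conditions=conditions,
                             basis_per_condition=basis, seed=seed)
    X_nested = X_full[:, basis:]          # first condition's columns removed
    return X_full, X_nested


def _glm_point(X_true, X_full, X_nested, sigma_p, sigma_e, reps, seed,
               true_model):
    """Oriented per-replication log Bayes factors for one grid point."""
    rng = np.random.default_rng(_rep_seed(seed, 0))
    theta = rng.normal(0.0, sigma_p, size=(X_true.shape[1], reps))
    Y = X_true @ theta + rng.normal(0.0, sigma_e, size=(X_true.shape[0], reps))
    spec_f = GLMSpec(design=X_full, prior_sd=sigma_p, noise_sd=sigma_e)
    spec_n = GLMSpec(design=X_nested, prior_sd=sigma_p, noise_sd=sigma_e)
    cf = glm_criteria_batch(spec_f, Y)
    cn = glm_criteria_batch(spec_n, Y)
    sign = 1.0 if true_model == "full" else -1.0
    return {crit: sign * (cf[crit] - cn[crit])
            for crit in cf.keys() & cn.keys()}


def glm_snr_sweep(snr_grid, reps: int = 1000, true_model: str = "full",
                  seed: int = 0, n_scans: int = 351,
                  sigma_p: float = SIGMA_P_DEFAULT,
                  calib_draws: int = 1000) -> SweepResult:
    """Mean log Bayes factor of the true GLM versus the other, per SNR.

    One design matrix (seeded) is shared by the whole sweep; the noise SD
    realising each target SNR comes from the prior-predictive signal SD of
    the generating design.
    """
    snr_grid = np.asarray(snr_grid, dtype=float)
    if np.any(snr_grid <= 0):
        raise ValueError("all SNRs must be positive")
    if true_model not in ("full", "nested"):
        raise ValueError("true_model must be 'full' or 'nested'")
    X_full, X_nested = _glm_designs(n_scans, _rep_seed(seed, 10_000), sigma_p)
    X_true = X_full if true_model == "full" else X_nested
    sig = glm_signal_sd(X_true, sigma_p, n_draws=calib_draws,
                        seed=_rep_seed(seed, 10_001))
    rows: list[dict] = []
    for gi, snr in enumerate(snr_grid):
        vals = _glm_point(X_true, X_full, X_nested, sigma_p, sig / snr,
                          reps, _rep_seed(seed, 1, gi).generate_state(1)[0] % 2**31,
                          true_model)
        _aggregate(rows, "snr", vals, snr, "mean")
    return SweepResult(axis="snr", grid=snr_grid, table=pd.DataFrame(rows),
                       aggregator="mean", reps=reps, true_model=true_model,
                       seed=seed, config={"n_scans": n_scans, "sigma_p": sigma_p,
                                          "signal_sd": sig})


def glm_n_sweep(n_grid=None, snr: float = 0.5, reps: int = 1000,
                true_model: str = "full", seed: int = 0,
                sigma_p: float = SIGMA_P_DEFAULT,
                calib_draws: int = 1000) -> SweepResult:
    """Mean log Bayes factor versus the number of scans at fixed SNR.

    Default grid: 20 sizes evenly spaced in [32, 512].  The event
    schedule (hence design) is regenerated at each size and the noise SD
    recalibrated, so every point satisfies n > p + 1 (AICc validity).
    """
    if n_grid is None:
        n_grid = np.unique(np.round(np.linspace(32, 512, 20)).astype(int))
    n_grid = np.asarray(n_grid, dtype=int)
    if true_model not in ("full", "nested"):
        raise ValueError("true_model must be 'full' or 'nested'")
    p_max = 12
    if np.any(n_grid <= p_max + 1):
        raise ValueError("every n must exceed p + 1 for AICc")
    rows: list[dict] = []
    for gi, n in enumerate(n_grid):
        X_full, X_nested = _glm_designs(int(n), _rep_seed(seed, 2, gi), sigma_p)
        X_true = X_full if true_model == "full" else X_nested
        sig = glm_signal_sd(X_true, sigma_p, n_draws=calib_draws,
                            seed=_rep_seed(seed, 3, gi))
        vals = _glm_point(X_true, X_full, X_nested, sigma_p, sig / snr,
                          reps, _rep_seed(seed, 4, gi).generate_state(1)[0] % 2**31,
                          true_model)
        _aggregate(rows, "n", vals, int(n), "mean")
    return SweepResult(axis="n", grid=n_grid, table=pd.DataFrame(rows),
                       aggregator="mean", reps=reps, true_model=true_model,
                       seed=seed, config={"snr": snr, "sigma_p": sigma_p})


# ---------------------------------------------------------------------------
# DCM sweep (variational Laplace fits)
# ---------------------------------------------------------------------------

def fit_dcm(spec: DCMSpec, inputs, y_vector, options: VLOptions | None = None) -> FitResult:
    """Variational Laplace fit of one DCM spec to a concatenated data vector."""
    pm = ParameterMap(spec)
    prior = pm.prior()
    noise = NoiseModel.iid_regions(spec.n_scans, spec.n_regions,
                                   mu_lambda=spec.mu_lambda,
                                   var_lambda=spec.var_lambda)
    region_index = {lab: np.arange(i * spec.n_scans, (i + 1) * spec.n_scans)
                    for i, lab in enumerate(spec.region_labels)}

    def g(theta):
        return predict(pm.unpack(theta), spec, inputs).as_vector()

    return vl_fit(g, prior, noise, y_vector, options=options,
                  region_index=region_index, param_sets=pm.sets())


def dcm_snr_sweep(snr_grid, reps: int = 50, true_model: str = "full",
                  seed: int = 0, n_scans: int = 488, tr: float = 2.0,
                  options: VLOptions | None = None) -> SweepResult:
    """Median log Bayes factor of the true DCM versus the other, per SNR.

    Per replication: draw positive modulatory parameters, simulate noisy
    BOLD from the true model, fit full and nested specs by variational
    Laplace, score.  Replications whose fits did not converge are excluded
    from the median, with the exclusion count reported.
    """
    snr_grid = np.asarray(snr_grid, dtype=float)
    if np.any(snr_grid <= 0):
        raise ValueError("all SNRs must be positive")
    if true_model not in ("full", "nested"):
        raise ValueError("true_model must be 'full' or 'nested'")
    full, nested = build_speech_models(tr=tr, n_scans=n_scans)
    gen_spec = full if true_model == "full" else nested
    sign = 1.0 if true_model == "full" else -1.0
    rows: list[dict] = []
    for gi, snr in enumerate(snr_grid):
        vals: dict[str, list] = {"f_l": [], "aic": [], "bic": []}
        excluded = 0
        for rep in range(reps):
            ss = _rep_seed(seed, 5, gi, rep)
            child = ss.spawn(2)
            ds = generate_dcm_dataset(gen_spec, snr,
                                      seed=int(child[0].generate_state(1)[0] % 2**31))
            y = ds.timeseries.as_vector()
            rf = fit_dcm(full, ds.inputs, y, options)
            rn = fit_dcm(nested, ds.inputs, y, options)
            if not (rf.converged and rn.converged):
                excluded += 1
                continue
            vals["f_l"].append(sign * (rf.criteria.f_l - rn.criteria.f_l))
            vals["aic"].append(sign * (rf.criteria.aic - rn.criteria.aic))
            vals["bic"].append(sign * (rf.criteria.bic - rn.criteria.bic))
        _aggregate(rows, "snr", {k: np.asarray(v) for k, v in vals.items()},
                   snr, "median", n_excluded=excluded)
    return SweepResult(axis="snr", grid=snr_grid, table=pd.DataFrame(rows),
                       aggregator="median", reps=reps, true_model=true_model,
                       seed=seed, config={"n_scans": n_scans, "tr": tr})


# ---------------------------------------------------------------------------
# free-energy difference diagnosis
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Where a free-energy difference between two fits comes from.

    Differences are full minus nested.  The per-region accuracy and
    per-set complexity maps identify which data regions and parameter
    sets drive the total; ``dominant_term`` names whichever of accuracy
    or complexity contributes more to |delta F|.
    """

    delta_f: float
    delta_accuracy: float
    delta_complexity: float
    accuracy_by_region: dict
    complexity_by_set: dict
    dominant_term: str

    def to_record(self) -> dict:
        return {
            "delta_f": self.delta_f,
            "delta_accuracy": self.delta_accuracy,
            "delta_complexity": self.delta_complexity,
            "dominant_term": self.dominant_term,
            **{f"delta_accuracy_region_{k}": v
               for k, v in self.accuracy_by_region.items()},
            **{f"delta_complexity_set_{k}": v
               for k, v in self.complexity_by_set.items()},
        }


def decompose_comparison(fit_full: FitResult, fit_nested: FitResult) -> ComparisonReport:
    """Diagnose a full-vs-nested comparison fitted to the same data."""
    if fit_full.data_hash and fit_full.data_hash != fit_nested.data_hash:
        raise ValueError("fits were made on different data vectors")
    bf, bn = fit_full.breakdown, fit_nested.breakdown
    d_acc = bf.accuracy - bn.accuracy
    d_comp = ((bf.complexity_params + bf.complexity_hypers)
              - (bn.complexity_params + bn.complexity_hypers))
    regions = {k: bf.accuracy_by_region[k] - bn.accuracy_by_region[k]
               for k in bf.accuracy_by_region.keys() & bn.accuracy_by_region.keys()}
    sets = {k: bf.complexity_by_set[k] - bn.complexity_by_set[k]
            for k in bf.complexity_by_set.keys() & bn.complexity_by_set.keys()}
    dominant = "accuracy" if abs(d_acc) >= abs(d_comp) else "complexity"
    return ComparisonReport(
        delta_f=bf.f_l - bn.f_l, delta_accuracy=d_acc, delta_complexity=d_comp,
        accuracy_by_region=regions, complexity_by_set=sets,
        dominant_term=dominant)
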