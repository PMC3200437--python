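"""Tests of the bilinear DCM forward model against closed forms and an
adaptive-step reference integrator."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from evidence_bench.dcm_generative import (
    DCMParams,
    DCMSpec,
    HEMO_CONSTANTS,
    InputSet,
    InstabilityError,
    ParameterMap,
    balloon_bold,
    build_speech_models,
    halflife_prior_stats,
    integrate_neurodynamics,
    predict,
    sample_prior,
)
from evidence_bench.synthetic_data import make_speech_inputs


def _zero_inputs(n_fine, n_inputs=2, dt=0.125):
    return InputSet(u=np.zeros((n_fine + 1, n_inputs)), dt=dt, labels=("a", "b")[:n_inputs])


def _plain_params(A, B=None, C=None, r=None):
    A = np.atleast_2d(np.asarray(A, dtype=float))
    r = A.shape[0]
    B = np.zeros((2, r, r)) if B is None else B
    C = np.zeros((r, 2)) if C is None else C
    return DCMParams(A=A, B=B, C=C, h_latent=np.zeros((r, 3)))


class TestPriors:
    def test_sampled_moments_match_prior(self, speech_models_small):
        full, _ = speech_models_small
        rng = np.random.default_rng(0)
        selfs, crosses, mods = [], [], []
        for _ in range(2000):
            p = sample_prior(full, seed=int(rng.integers(2**31)))
            selfs.extend(np.diag(p.A))
            crosses.extend(p.A[~np.eye(3, dtype=bool)])
            mods.extend(p.B[1][full.b_masks[1] > 0])
        assert np.mean(selfs) == pytest.approx(-1.0, abs=0.01)
        assert np.std(selfs) == pytest.approx(0.177, abs=0.01)
        assert np.mean(crosses) == pytest.approx(1 / 64, abs=0.03)
        assert np.std(mods) == pytest.approx(2.0, abs=0.05)

    def test_masked_entries_always_zero(self, speech_models_small):
        full, nested = speech_models_small
        for seed in range(20):
            p = sample_prior(nested, seed=seed)
            assert p.B[1][2, 0] == 0.0          # b_AP absent in nested
            assert np.all(p.B[0] == 0.0)        # u_aud modulates nothing
            assert np.all(p.C[1:, :] == 0.0)    # input drives P only

    def test_halflife_point_mass(self):
        # a self-connection of exactly -1 decays with half-life log(2) s
        assert (math.log(0.5) / -1.0) * 1000 == pytest.approx(693.1, abs=0.1)

    def test_halflife_prior_summary(self):
        mean_ms, frac = halflife_prior_stats(10**5, seed=4)
        assert mean_ms == pytest.approx(717.0, abs=10.0)
        assert frac > 0.9

    def test_prior_encourages_stable_intrinsic_dynamics(self, speech_models_small):
        """Without modulation, the large majority of prior draws of A are
        Hurwitz-stable (the stated purpose of the intrinsic priors)."""
        full, _ = speech_models_small
        rng = np.random.default_rng(99)
        stable = 0
        n = 2000
        for _ in range(n):
            p = sample_prior(full, seed=int(rng.integers(2**31)))
            stable += np.max(np.linalg.eigvals(p.A).real) < 0
        assert stable / n >= 0.96


class TestNeurodynamics:
    def test_pure_decay_matches_closed_form(self):
        inp = _zero_inputs(40)      # 5 s at dt = 0.125
        z = integrate_neurodynamics(_plain_params(-np.eye(3)), inp,
                                    z0=np.ones(3))
        t = np.arange(41) * 0.125
        rel = np.abs(z[:, 0] - np.exp(-t)) / np.exp(-t)
        assert np.max(rel) < 1e-4

    def test_modulation_shifts_effective_rate(self):
        """With u = 1, B = 0.5 and A = -1 the decay rate is A + uB = -0.5."""
        u = np.ones((41, 1))
        inp = InputSet(u=u, dt=0.125, labels=("m",))
        params = DCMParams(A=np.array([[-1.0]]), B=np.array([[[0.5]]]),
                           C=np.array([[0.0]]), h_latent=np.zeros((1, 3)))
        z = integrate_neurodynamics(params, inp, z0=np.ones(1))
        t = np.arange(41) * 0.125
        assert z[:, 0] == pytest.approx(np.exp(-0.5 * t), rel=1e-4)

    def test_rest_is_a_fixed_point(self):
        z = integrate_neurodynamics(_plain_params(-np.eye(2) + 0.3), _zero_inputs(32))
        assert np.all(z == 0.0)

    def test_divergence_raises_naming_draw(self):
        with pytest.raises(InstabilityError, match="diverged"):
            integrate_neurodynamics(_plain_params([[1.0]]),
                                    _zero_inputs(500, n_inputs=2),
                                    z0=np.ones(1))


class TestBalloonBold:
    def test_rest_gives_zero_bold(self):
        ts = balloon_bold(np.zeros((65, 2)), _plain_params(-np.eye(2)), tr=2.0,
                          dt=0.125)
        assert np.all(ts.values == 0.0)

    def test_impulse_response_shape(self):
        """A brief neuronal impulse produces a single-peaked BOLD response
        that returns near baseline within 30 s."""
        dt = 0.125
        n_fine = int(40 / dt)
        z = np.zeros((n_fine + 1, 1))
        z[8:16, 0] = 1.0            # 1 s of activity
        ts = balloon_bold(z, _plain_params([[-1.0]]), tr=1.0, dt=dt)
        y = ts.values[:, 0]
        peak = np.argmax(y)
        assert y[peak] > 0.1
        assert 2 <= peak <= 10       # peaks a few seconds after the impulse
        assert abs(y[32]) < 0.05 * y[peak]   # back near baseline by 32 s
        # single-peaked up to the undershoot: strictly rising then falling
        assert np.all(np.diff(y[:peak + 1]) > 0)

    def test_response_is_nonlinear_in_input_amplitude(self):
        dt = 0.125
        n_fine = int(30 / dt)
        z = np.zeros((n_fine + 1, 1))
        z[8:16, 0] = 1.0
        y1 = balloon_bold(z, _plain_params([[-1.0]]), tr=1.0, dt=dt).values
        y2 = balloon_bold(2 * z, _plain_params([[-1.0]]), tr=1.0, dt=dt).values
        ratio = np.max(y2) / np.max(y1)
        assert ratio != pytest.approx(2.0, abs=0.05)

    def test_agrees_with_adaptive_reference(self, speech_models_small):
        """Joint neuronal + hemodynamic integration matches a high-accuracy
        adaptive solver on random prior draws."""
        full, _ = speech_models_small
        spec = DCMSpec(n_regions=3, a_mask=full.a_mask, b_masks=full.b_masks,
                       c_mask=full.c_mask, tr=2.0, n_scans=16,
                       region_labels=full.region_labels)
        inputs = make_speech_inputs(n_scans=16, tr=2.0, seed=5)
        hc = HEMO_CONSTANTS
        checked = 0
        for seed in range(40):
            params = sample_prior(spec, seed=seed)
            if np.max(np.linalg.eigvals(params.A).real) >= 0:
                continue
            params.B[:] = np.abs(params.B) * spec.b_masks

            t_grid = np.arange(inputs.u.shape[0]) * inputs.dt

            def rhs(t, x):
                # same piecewise-linear input rendering the fixed-step
                # scheme assumes, so the comparison isolates solver error
                u = np.array([np.interp(t, t_grid, inputs.u[:, j])
                              for j in range(inputs.u.shape[1])])
                z = x[:3]
                s, lf, lv, lq = x[3:6], x[6:9], x[9:12], x[12:15]
                h = params.hemo()
                f, v, q = np.exp(lf), np.exp(lv), np.exp(lq)
                dz = (params.A + np.tensordot(u, params.B, axes=1)) @ z \
                    + params.C @ u
                ds = z - h["kappa"] * s - h["gamma"] * (f - 1)
                dlf = s / f
                fv = v ** (1 / h["alpha"])
                dlv = (f - fv) / (h["tau"] * v)
                ee = 1 - (1 - h["e0"]) ** (1 / f)
                dlq = (f * ee / h["e0"] - fv * q / v) / (h["tau"] * q)
                return np.concatenate([dz, ds, dlf, dlv, dlq])

            try:
                ours = predict(params, spec, inputs).values
            except InstabilityError:
                continue           # genuinely divergent draw; not comparable
            t_out = (np.arange(1, 17)) * 2.0
            sol = solve_ivp(rhs, (0, 32.0), np.zeros(15), t_eval=t_out,
                            rtol=1e-9, atol=1e-11, max_step=inputs.dt)
            if not sol.success or sol.y.shape[1] != t_out.size:
                continue           # reference solver also failed: near-divergent
            v = np.exp(sol.y[9:12].T)
            q = np.exp(sol.y[12:15].T)
            h = params.hemo()
            k1 = 4.3 * hc["theta0"] * h["e0"] * hc["te"]
            k2 = h["epsilon"] * hc["r0"] * h["e0"] * hc["te"]
            k3 = 1 - h["epsilon"]
            ref = hc["v0"] * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))
            scale = max(np.max(np.abs(ref)), 1e-3)
            assert np.max(np.abs(ours - ref)) / scale < 1e-3
            checked += 1
            if checked == 20:
                break
        assert checked == 20


class TestPredict:
    def test_prediction_vector_length(self):
        full, _ = build_speech_models(n_scans=488)
        params = _plain_params(-np.eye(3) + 0.1 * (1 - np.eye(3)),
                               B=np.zeros((2, 3, 3)), C=np.zeros((3, 2)))
        params.C[0, 0] = 0.3
        inputs = make_speech_inputs(n_scans=488, tr=2.0, seed=1)
        g = predict(params, full, inputs).as_vector()
        assert g.shape == (488 * 3,)

    def test_region_order_fixes_block_order(self, speech_models_small):
        full, _ = speech_models_small
        inputs = make_speech_inputs(n_scans=64, tr=2.0, seed=2)
        params = _plain_params(-np.eye(3), C=np.zeros((3, 2)))
        params.C[0, 0] = 0.5
        ts = predict(params, full, inputs)
        g = ts.as_vector()
        assert np.array_equal(g[:64], ts.values[:, 0])
        assert np.array_equal(g[64:128], ts.values[:, 1])

    def test_no_input_no_signal(self, speech_models_small):
        full, _ = speech_models_small
        inputs = make_speech_inputs(n_scans=64, tr=2.0, seed=3)
        params = _plain_params(-np.eye(3) + 0.2 * (1 - np.eye(3)))
        assert np.all(predict(params, full, inputs).values == 0.0)


class TestSpeechModels:
    def test_structure(self):
        full, nested = build_speech_models()
        assert full.n_scans == 488 and full.region_labels == ("P", "F", "A")
        # input mask: a single nonzero entry (u_aud -> P)
        assert np.sum(full.c_mask) == 1 and full.c_mask[0, 0] == 1
        # nested fixes b_AP at zero; full has exactly one more free parameter
        assert nested.b_masks[1][2, 0] == 0 and full.b_masks[1][2, 0] == 1
        assert (ParameterMap(full).size - ParameterMap(nested).size) == 1

    def test_free_parameter_counts(self):
        full, nested = build_speech_models()
        assert ParameterMap(full).size == 21
        assert ParameterMap(nested).size == 20

    def test_parameter_roundtrip_and_sets(self):
        full, _ = build_speech_models()
        pm = ParameterMap(full)
        params = sample_prior(full, seed=0)
        theta = pm.pack(params)
        back = pm.unpack(theta)
        assert np.array_equal(back.A, params.A)
        assert np.array_equal(back.B, params.B)
        sets = pm.sets()
        assert sorted(sets) == ["hemodynamic", "input", "intrinsic", "modulatory"]
        assert sum(len(v) for v in sets.values()) == pm.size

    def test_spec_requires_self_connections(self):
        with pytest.raises(ValueError):
            DCMSpec(n_regions=2, a_mask=np.zeros((2, 2)),
                    b_masks=np.zeros((1, 2, 2)), c_mask=np.zeros((2, 1)))
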