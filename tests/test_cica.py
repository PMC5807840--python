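"""Contrast function, negentropy, constraints, and the constrained solver."""

import numpy as np
import pytest

from cica_rppg.cica import (
    ConstraintSpec,
    ObjectiveSpec,
    SolverConfig,
    adaptive_zeta1,
    constraint_g1,
    constraint_g2,
    constraint_h,
    g_function,
    negentropy,
    solve_cica,
)
from cica_rppg.chrominance import chrom_model, map_weights_to_whitened
from cica_rppg.ingest import TraceMatrix
from cica_rppg.periodicity import LagQuadratics
from cica_rppg.preprocess import bandpass, center, detrend_smoothness_priors, whiten
from cica_rppg.synthdata import mix_to_rgb, scenario_preset


class TestContrastFunction:
    def test_value_at_zero(self):
        g, g1, g2 = g_function(0.0, a=1.5)
        assert g == pytest.approx(0.0, abs=1e-15)
        assert g1 == pytest.approx(0.0, abs=1e-15)
        assert g2 == pytest.approx(1.5)

    def test_even_odd_symmetry(self, rng):
        u = rng.standard_normal(100)
        gp, g1p, _ = g_function(u, 1.5)
        gm, g1m, _ = g_function(-u, 1.5)
        np.testing.assert_allclose(gp, gm, rtol=1e-12)
        np.testing.assert_allclose(g1p, -g1m, rtol=1e-12)

    def test_derivative_matches_finite_difference(self):
        u = np.linspace(-5, 5, 101)
        eps = 1e-6
        _, g1, g2 = g_function(u, 1.5)
        fd1 = (g_function(u + eps, 1.5)[0] - g_function(u - eps, 1.5)[0]) / (2 * eps)
        fd2 = (g_function(u + eps, 1.5)[1] - g_function(u - eps, 1.5)[1]) / (2 * eps)
        np.testing.assert_allclose(g1, fd1, atol=1e-8)
        np.testing.assert_allclose(g2, fd2, atol=1e-8)

    def test_overflow_free_at_large_arguments(self):
        g, g1, g2 = g_function(np.array([-50.0, 50.0]), 1.5)
        assert np.all(np.isfinite(g))
        np.testing.assert_allclose(g1, [-1.0, 1.0], rtol=1e-12)

    def test_parameter_range_enforced(self):
        with pytest.raises(ValueError):
            g_function(1.0, a=2.5)


class TestObjectiveSpec:
    def test_gaussian_reference_reproducible_by_quadrature(self):
        """Gauss-Hermite value agrees with adaptive quadrature to 1e-10."""
        import math

        from scipy.integrate import quad

        from cica_rppg.cica import _expected_g_gauss, g_function

        ref = quad(
            lambda u: g_function(u, 1.5)[0] * math.exp(-u * u / 2)
            / math.sqrt(2 * math.pi),
            -30, 30, limit=200, epsabs=1e-14,
        )[0]
        assert _expected_g_gauss(1.5) == pytest.approx(ref, abs=1e-10)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(rho=-1.0)
        with pytest.raises(ValueError):
            ObjectiveSpec(a=3.0)


class TestNegentropy:
    def test_gaussian_signal_has_near_zero_negentropy(self, rng):
        z = rng.standard_normal((3, 50000))
        w = np.array([1.0, 0.0, 0.0])
        spec = ObjectiveSpec(rho=1.0)
        j, _, _ = negentropy(w, z, spec)
        assert j <= 0.01 * spec.rho

    def test_even_in_w(self, rng):
        z = rng.standard_normal((3, 300))
        w = rng.standard_normal(3)
        spec = ObjectiveSpec()
        assert negentropy(w, z, spec)[0] == pytest.approx(
            negentropy(-w, z, spec)[0], rel=1e-12
        )

    def test_gradient_matches_finite_differences(self, rng):
        spec = ObjectiveSpec()
        for _ in range(20):
            z = rng.standard_normal((3, 200))
            w = rng.standard_normal(3)
            _, grad, _ = negentropy(w, z, spec)
            eps = 1e-6 * (1 + np.linalg.norm(w))
            fd = np.zeros(3)
            for i in range(3):
                wp, wm = w.copy(), w.copy()
                wp[i] += eps
                wm[i] -= eps
                fd[i] = (negentropy(wp, z, spec)[0] - negentropy(wm, z, spec)[0]) / (2 * eps)
            np.testing.assert_allclose(grad, fd, rtol=1e-5,
                                       atol=1e-9 * (1 + np.abs(fd).max()))

    def test_hessian_matches_finite_differences(self, rng):
        spec = ObjectiveSpec()
        z = rng.standard_normal((3, 300))
        w = rng.standard_normal(3)
        _, _, hess = negentropy(w, z, spec)
        eps = 1e-6
        fd = np.zeros((3, 3))
        for i in range(3):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            fd[:, i] = (negentropy(wp, z, spec)[1] - negentropy(wm, z, spec)[1]) / (2 * eps)
        np.testing.assert_allclose(hess, fd, rtol=1e-4,
                                   atol=1e-8 * (1 + np.abs(fd).max()))


class TestConstraints:
    def test_g1_boundary_and_violation(self, rng):
        from cica_rppg.periodicity import periodicity_score

        lq = LagQuadratics.from_traces(rng.standard_normal((3, 50)))
        w = rng.standard_normal(3)
        zeta1 = periodicity_score(w, lq)
        assert constraint_g1(w, lq, zeta1)[0] == pytest.approx(0.0, abs=1e-12)
        assert constraint_g1(np.zeros(3), lq, 5.0)[0] == 5.0

    def test_g1_gradient_finite_difference(self, rng):
        lq = LagQuadratics.from_traces(rng.standard_normal((3, 50)))
        for _ in range(20):
            w = rng.standard_normal(3)
            _, grad = constraint_g1(w, lq, 1.0)
            eps = 1e-6 * (1 + np.linalg.norm(w))
            fd = np.zeros(3)
            for i in range(3):
                wp, wm = w.copy(), w.copy()
                wp[i] += eps
                wm[i] -= eps
                fd[i] = (constraint_g1(wp, lq, 1.0)[0] - constraint_g1(wm, lq, 1.0)[0]) / (2 * eps)
            np.testing.assert_allclose(grad, fd, rtol=1e-5,
                                       atol=1e-8 * (1 + np.abs(fd).max()))

    def test_g2_at_anchor_and_sign_alignment(self, rng):
        wc = rng.standard_normal(3)
        spec = ConstraintSpec(zeta1=1.0, zeta2=0.8, w_chrom_white=wc)
        assert constraint_g2(spec.w_chrom_white, spec)[0] == pytest.approx(-0.8)
        assert constraint_g2(-spec.w_chrom_white, spec)[0] == pytest.approx(-0.8)

    def test_g2_gradient_finite_difference(self, rng):
        spec = ConstraintSpec(zeta1=1.0, zeta2=0.8,
                              w_chrom_white=rng.standard_normal(3))
        checked = 0
        while checked < 20:
            w = rng.standard_normal(3)
            what = w / np.linalg.norm(w)
            d = min(np.linalg.norm(what - spec.w_chrom_white),
                    np.linalg.norm(what + spec.w_chrom_white))
            if d <= 1e-3:
                continue
            _, grad = constraint_g2(w, spec)
            eps = 1e-7 * (1 + np.linalg.norm(w))
            fd = np.zeros(3)
            for i in range(3):
                wp, wm = w.copy(), w.copy()
                wp[i] += eps
                wm[i] -= eps
                fd[i] = (constraint_g2(wp, spec)[0] - constraint_g2(wm, spec)[0]) / (2 * eps)
            np.testing.assert_allclose(grad, fd, rtol=1e-5,
                                       atol=1e-7 * (1 + np.abs(fd).max()))
            checked += 1

    def test_h_unit_norm_and_direct_expectation(self, rng):
        w = rng.standard_normal(3)
        w /= np.linalg.norm(w)
        assert constraint_h(w)[0] == pytest.approx(0.0, abs=1e-12)
        assert constraint_h(np.zeros(3))[0] == -1.0
        # h equals E{y^2}-1 on whitened data
        x = rng.standard_normal((3, 5000))
        x -= x.mean(axis=1, keepdims=True)
        z, _ = whiten(TraceMatrix(values=x, fs=30.0))
        w = rng.standard_normal(3)
        y = w @ z.values
        assert constraint_h(w)[0] == pytest.approx(np.mean(y**2) - 1.0, abs=1e-8)


def _whitened_sinusoid_problem(seed=0, n=900, fs=30.0, freq=1.1):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    s = np.sin(2 * np.pi * freq * t)
    s = (s - s.mean()) / s.std()
    z = np.vstack([s, rng.standard_normal(n), rng.standard_normal(n)])
    lq = LagQuadratics.from_traces(z)
    anchor = np.ones(3) / np.sqrt(3.0)
    cons = ConstraintSpec(
        zeta1=adaptive_zeta1(lq, anchor), zeta2=float("inf"), w_chrom_white=anchor
    )
    return z, lq, cons, s


class TestSolver:
    def test_recovers_pure_sinusoid_direction(self):
        z, lq, cons, s = _whitened_sinusoid_problem()
        res = solve_cica(z, lq, ObjectiveSpec(), cons, SolverConfig())
        assert res.converged
        assert abs(np.corrcoef(res.pulse, s)[0, 1]) >= 0.99

    def test_warm_start_is_fixed_point(self):
        z, lq, cons, _ = _whitened_sinusoid_problem()
        cfg = SolverConfig()
        res1 = solve_cica(z, lq, ObjectiveSpec(), cons, cfg)
        res2 = solve_cica(z, lq, ObjectiveSpec(), cons, cfg, w_init=res1.w_star)
        assert np.linalg.norm(res2.w_star - res1.w_star) <= 1e-6
        assert res2.n_iter <= 3

    def test_backends_agree(self):
        z, lq, cons, s = _whitened_sinusoid_problem(seed=4)
        r_nlp = solve_cica(z, lq, ObjectiveSpec(), cons, SolverConfig(backend="nlp"))
        r_al = solve_cica(z, lq, ObjectiveSpec(), cons,
                          SolverConfig(backend="augmented-lagrangian"))
        assert abs(np.corrcoef(r_nlp.pulse, r_al.pulse)[0, 1]) >= 0.99

    def test_converged_solution_satisfies_constraints(self):
        z, lq, cons, _ = _whitened_sinusoid_problem(seed=8)
        res = solve_cica(z, lq, ObjectiveSpec(), cons, SolverConfig())
        assert res.converged
        tol = 1e-4
        assert res.g1 <= tol
        assert abs(res.h) <= tol

    def test_infeasible_threshold_flags_not_converged(self):
        z, lq, cons, _ = _whitened_sinusoid_problem(seed=2)
        bad = ConstraintSpec(zeta1=1e12, zeta2=cons.zeta2,
                             w_chrom_white=cons.w_chrom_white)
        res = solve_cica(z, lq, ObjectiveSpec(), bad, SolverConfig())
        assert not res.converged  # flagged, no exception

    def test_channel_scaling_invariance_with_consistent_anchor(self):
        """Whitening absorbs per-channel scaling when the raw-space anchor
        is transformed along with the data."""
        scen = scenario_preset("clean", duration_s=40.0, hr_bpm=72.0, seed=9,
                               pulse_snr_db=12.0)
        traces, _ = mix_to_rgb(scen)
        d = np.diag([2.0, 0.5, 1.5])
        xd0 = detrend_smoothness_priors(traces)
        w_raw = chrom_model(bandpass(xd0, (0.7, 3.0), 4)).w_chrom

        def solve(tm, w_raw_anchor):
            xd = detrend_smoothness_priors(tm)
            xc, _ = center(xd)
            z, wh = whiten(xc)
            wcw = map_weights_to_whitened(w_raw_anchor, wh)
            lq = LagQuadratics.from_traces(z)
            cons = ConstraintSpec(zeta1=adaptive_zeta1(lq, wcw), zeta2=0.8,
                                  w_chrom_white=wcw)
            return solve_cica(z, lq, ObjectiveSpec(), cons, SolverConfig()).pulse

        p1 = solve(traces, w_raw)
        scaled = TraceMatrix(values=d @ traces.values, fs=traces.fs)
        p2 = solve(scaled, np.linalg.inv(d) @ w_raw)
        assert abs(np.corrcoef(p1, p2)[0, 1]) >= 1.0 - 1e-6

    def test_objective_not_worse_than_feasible_start(self):
        z, lq, cons, _ = _whitened_sinusoid_problem(seed=6)
        spec = ObjectiveSpec()
        w0 = cons.w_chrom_white
        res = solve_cica(z, lq, spec, cons, SolverConfig(), w_init=w0)
        j0, _, _ = negentropy(w0, z, spec)
        assert res.objective >= j0 - 1e-12
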