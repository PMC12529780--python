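import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdcsampler.core_rdc import BOND_CLASSES, CONSTANTS, RDCTarget, legendre_p2
from rdcsampler.hrs_engine import (RestraintParams, SimParams, init_state,
                                   langevin_step, mfv_force, p2_gradient,
                                   restraint_energy, restraint_force_dD,
                                   run_hrs, update_exp_average)
from rdcsampler.structure_io import RDCVector

P = RestraintParams(K=100.0, dD_fb=2.0, dD_h=1.0, tau_theta=10000.0)


class TestRestraintPotential:
    def test_flat_bottom_is_zero(self):
        assert restraint_energy(10.0 + 1.0, 10.0, P) == 0.0
        assert restraint_energy(10.0 - 2.0, 10.0, P) == 0.0
        assert restraint_force_dD(10.0 + 1.9, 10.0, P) == 0.0

    def test_value_at_harmonic_linear_junction(self):
        # half-harmonic reaches K dDh^2 / 2 where the linear branch starts
        e = restraint_energy(0.0 + P.dD_fb + P.dD_h, 0.0, P)
        assert e == pytest.approx(0.5 * P.K * P.dD_h ** 2)
        assert e == pytest.approx(50.0)

    def test_linear_branch_slope(self):
        e1 = restraint_energy(10.0, 0.0, P)
        e2 = restraint_energy(11.0, 0.0, P)
        assert e2 - e1 == pytest.approx(P.K * P.dD_h)

    def test_force_saturates_beyond_harmonic_band(self):
        assert restraint_force_dD(100.0, 0.0, P) == pytest.approx(-P.K * P.dD_h)
        assert restraint_force_dD(-100.0, 0.0, P) == pytest.approx(P.K * P.dD_h)

    @given(st.floats(-50.0, 50.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_even_about_target(self, x):
        d0 = 3.7
        assert restraint_energy(d0 + x, d0, P) == \
            pytest.approx(restraint_energy(d0 - x, d0, P), rel=1e-12)

    def test_continuity_at_both_junctions(self):
        d0 = 0.0
        for junction in (P.dD_fb, P.dD_fb + P.dD_h, -P.dD_fb,
                         -P.dD_fb - P.dD_h):
            e_lo = restraint_energy(d0 + junction - 1e-9, d0, P)
            e_hi = restraint_energy(d0 + junction + 1e-9, d0, P)
            f_lo = restraint_force_dD(d0 + junction - 1e-9, d0, P)
            f_hi = restraint_force_dD(d0 + junction + 1e-9, d0, P)
            assert e_hi == pytest.approx(e_lo, abs=1e-6)
            assert f_hi == pytest.approx(f_lo, abs=1e-6)

    def test_force_is_negative_energy_gradient(self, rng):
        """Central finite differences across all three regimes."""
        d0 = 1.5
        h = 1e-5
        points = rng.uniform(-12.0, 12.0, 100)
        for x in points:
            if min(abs(abs(x - d0) - P.dD_fb),
                   abs(abs(x - d0) - P.dD_fb - P.dD_h)) < 2 * h:
                continue  # the force is only piecewise-smooth at the kinks
            fd = -(restraint_energy(x + h, d0, P)
                   - restraint_energy(x - h, d0, P)) / (2 * h)
            f = restraint_force_dD(x, d0, P)
            assert f == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            RestraintParams(K=-1.0)
        with pytest.raises(ValueError):
            RestraintParams(tau_theta=0.0)


class TestExpAverage:
    def test_constant_signal_fixed_point(self):
        p = 0.37
        pbar = p
        for _ in range(100):
            pbar = update_exp_average(pbar, p, 0.002, 10.0)
        assert pbar == pytest.approx(p, rel=1e-12)

    def test_infinite_memory_keeps_initial_value(self):
        pbar = update_exp_average(0.9, -0.4, 0.002, 1e15)
        assert pbar == pytest.approx(0.9, abs=1e-12)

    def test_step_response_matches_continuous_integral(self):
        # signal jumps 0 -> 1; discrete recursion vs (1 - exp(-t/tau))
        dt, tau = 0.002, 1.0
        pbar = 1.0 * (1 - math.exp(-dt / tau))  # after first update from 0
        for n in range(2, 2001):
            pbar = update_exp_average(pbar, 1.0, dt, tau)
            exact = 1.0 - math.exp(-n * dt / tau)
            assert pbar == pytest.approx(exact, abs=2 * dt / tau)

    def test_convex_combination_bounds(self, rng):
        pbar = 0.0
        lo, hi = -0.5, 1.0
        for p in rng.uniform(lo, hi, 1000):
            pbar = update_exp_average(pbar, p, 0.002, 0.05)
            assert lo - 1e-12 <= pbar <= hi + 1e-12


class TestNormalizedExpAverage:
    def test_early_time_is_plain_running_mean(self, rng):
        from rdcsampler.hrs_engine import NormalizedExpAverage
        # t << tau: the normalized memory average is the plain mean so far
        samples = rng.uniform(-0.5, 1.0, 50)
        avg = NormalizedExpAverage(samples[0], dt=0.002, tau=1e4)
        for i, p in enumerate(samples[1:], start=2):
            avg.update(p)
            assert float(avg.value) == pytest.approx(samples[:i].mean(),
                                                     abs=1e-5)

    def test_late_time_matches_bare_recursion(self, rng):
        from rdcsampler.hrs_engine import NormalizedExpAverage
        dt, tau = 0.002, 0.01  # t >> tau after a few hundred steps
        samples = rng.uniform(-0.5, 1.0, 3000)
        avg = NormalizedExpAverage(samples[0], dt=dt, tau=tau)
        bare = samples[0]
        for p in samples[1:]:
            avg.update(p)
            bare = update_exp_average(bare, p, dt, tau)
        assert float(avg.value) == pytest.approx(float(bare), abs=1e-9)

    def test_constant_signal_fixed_point(self):
        from rdcsampler.hrs_engine import NormalizedExpAverage
        avg = NormalizedExpAverage(0.42, dt=0.002, tau=5.0)
        for _ in range(500):
            avg.update(0.42)
        assert float(avg.value) == pytest.approx(0.42, rel=1e-12)


class TestP2Gradient:
    def test_zero_when_perpendicular(self):
        g = p2_gradient(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]),
                        0.153)
        np.testing.assert_allclose(g, 0.0, atol=1e-15)

    def test_parallel_gives_tangent_zero(self):
        u = np.array([0.0, 0.0, 1.0])
        g = p2_gradient(u, u, 0.153)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)
        assert abs(float(g @ u)) < 1e-15

    def test_tangency(self, rng):
        u_mfv = rng.normal(size=3)
        u_mfv /= np.linalg.norm(u_mfv)
        u_rdc = rng.normal(size=3)
        u_rdc /= np.linalg.norm(u_rdc)
        g = p2_gradient(u_mfv, u_rdc, 0.153)
        assert abs(float(g @ u_mfv)) < 1e-12

    def test_finite_difference(self, rng):
        bond = 0.153
        u_rdc = rng.normal(size=3)
        u_rdc /= np.linalg.norm(u_rdc)
        for _ in range(20):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r1, r2 = 0.5 * bond * u, -0.5 * bond * u
            g = p2_gradient(u, u_rdc, bond)

            def p2_of_r1(r):
                d = r - r2
                return legendre_p2(float(d @ u_rdc) / np.linalg.norm(d))

            h = 1e-7
            fd = np.empty(3)
            for i in range(3):
                e = np.zeros(3)
                e[i] = h
                fd[i] = (p2_of_r1(r1 + e) - p2_of_r1(r1 - e)) / (2 * h)
            np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-8)


def _single_restraint_setup(d0_hz, restrained=True):
    u = np.array([1.0, 0.0, 0.0])
    vec = RDCVector(1, "N-HN", u, 0.1)
    tgt = RDCTarget(1, "N-HN", d0_hz, restrained=restrained)
    return [vec], [tgt]


class TestMfvForce:
    def test_zero_inside_flat_bottom(self):
        vecs, tgts = _single_restraint_setup(0.0)
        sim = SimParams(n_steps=1, n_runs=1)
        state = init_state(vecs, tgts, sim, np.random.default_rng(0))
        # mfv along z, restraint vector along x: P = -0.5, D_bar huge, so
        # move the target onto the current average instead
        dcr = BOND_CLASSES["N-HN"].dc_r_hz
        tgts[0].d0 = dcr * float(state.p_bar[0])
        f1, f2 = mfv_force(state, vecs, tgts, P, sim.dt)
        np.testing.assert_allclose(f1, 0.0, atol=1e-15)

    def test_newton_third_law(self):
        vecs, tgts = _single_restraint_setup(5.0)
        sim = SimParams(n_steps=1, n_runs=1)
        state = init_state(vecs, tgts, sim, np.random.default_rng(0))
        # tilt the mfv off the restraint vector so cos(theta) != 0
        c, s = math.cos(0.4), math.sin(0.4)
        state.r1 = 0.5 * sim.bond * np.array([s, 0.0, c])
        state.r2 = -state.r1
        state.p_bar[:] = 0.3
        f1, f2 = mfv_force(state, vecs, tgts, P, sim.dt)
        np.testing.assert_allclose(f1, -f2, atol=1e-18)
        assert np.linalg.norm(f1) > 0

    def test_force_in_span_of_the_two_vectors(self):
        u_rdc = np.array([1.0, 0.0, 0.0])
        vecs = [RDCVector(1, "N-HN", u_rdc, 0.1)]
        tgts = [RDCTarget(1, "N-HN", 8.0, restrained=True)]
        sim = SimParams(n_steps=1, n_runs=1)
        rng = np.random.default_rng(1)
        state = init_state(vecs, tgts, sim, rng)
        # tilt the mfv off both axes
        c, s = math.cos(0.7), math.sin(0.7)
        state.r1 = 0.5 * 0.153 * np.array([s, 0.0, c])
        state.r2 = -state.r1
        state.p_bar[:] = 0.2
        f1, _ = mfv_force(state, vecs, tgts, P, sim.dt)
        normal = np.array([0.0, 1.0, 0.0])  # orthogonal to span{x, z}
        assert abs(float(f1 @ normal)) < 1e-15


class TestLangevinStep:
    def test_bond_precision_maintained(self):
        vecs, tgts = _single_restraint_setup(0.0, restrained=False)
        sim = SimParams(n_steps=1, n_runs=1)
        rng = np.random.default_rng(4)
        state = init_state(vecs, tgts, sim, rng)
        zero = (np.zeros(3), np.zeros(3))
        worst = 0.0
        for _ in range(20000):
            langevin_step(state, zero, sim, rng)
            worst = max(worst, abs(state.bond_length - sim.bond) / sim.bond)
        assert worst <= 1e-4

    def test_same_seed_reproduces_trajectory(self):
        vecs, tgts = _single_restraint_setup(0.0, restrained=False)
        sim = SimParams(n_steps=1, n_runs=1)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            state = init_state(vecs, tgts, sim, rng)
            for _ in range(200):
                langevin_step(state, (np.zeros(3), np.zeros(3)), sim, rng)
            out.append(state.r1.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_force_free_equipartition(self):
        """Mean kinetic energy of the constrained dimer: (5/2) kT."""
        vecs, tgts = _single_restraint_setup(0.0, restrained=False)
        sim = SimParams(n_steps=1, n_runs=1)
        rng = np.random.default_rng(21)
        state = init_state(vecs, tgts, sim, rng)
        zero = (np.zeros(3), np.zeros(3))
        n, burn = 30000, 2000
        ke = np.empty(n)
        for i in range(n + burn):
            langevin_step(state, zero, sim, rng)
            if i >= burn:
                ke[i - burn] = 0.5 * sim.mass * (
                    float(state.v1 @ state.v1) + float(state.v2 @ state.v2))
        target = 2.5 * CONSTANTS.kB * sim.T
        blocks = ke.reshape(100, -1).mean(axis=1)
        sem = blocks.std(ddof=1) / math.sqrt(blocks.size)
        assert abs(ke.mean() - target) < 3 * sem + 1e-12

    def test_shake_failure_raises(self):
        from rdcsampler.hrs_engine import _shake
        r1 = np.array([0.0, 0.0, 0.0])
        r2 = np.array([0.0, 0.0, 0.0])  # zero separation cannot converge
        with pytest.raises((RuntimeError, ZeroDivisionError)):
            _shake(r1, r2, 0.153)


class TestRunHrs:
    def test_identical_seed_identical_output(self, clean_vectors,
                                             restrained_targets):
        sim = SimParams(n_steps=2000, n_runs=2, seed=5)
        a = run_hrs(clean_vectors, restrained_targets, P, sim)
        b = run_hrs(clean_vectors, restrained_targets, P, sim)
        np.testing.assert_array_equal(a.reported_d, b.reported_d)
        np.testing.assert_array_equal(a.traj, b.traj)

    def test_reported_magnitude_bounded_by_prefactor(self, clean_vectors,
                                                     restrained_targets):
        sim = SimParams(n_steps=5000, n_runs=1, seed=2)
        res = run_hrs(clean_vectors, restrained_targets, P, sim)
        scales = np.array([BOND_CLASSES[v.bond_class].dc_r_hz
                           for v in clean_vectors])
        assert np.all(np.abs(res.reported_d) <= np.abs(scales) * (1 + 1e-9))

    def test_exponential_average_stays_in_p2_range(self, clean_vectors,
                                                   restrained_targets):
        from rdcsampler.hrs_engine import NormalizedExpAverage
        sim = SimParams(n_steps=200, n_runs=1, seed=3)
        rng = np.random.default_rng(sim.seed)
        state = init_state(clean_vectors, restrained_targets, sim, rng)
        avg = NormalizedExpAverage(state.p_bar, sim.dt, P.tau_theta)
        u_r = np.array([v.u for v in clean_vectors])[
            [t.restrained for t in restrained_targets]]
        for _ in range(sim.n_steps):
            f = mfv_force(state, clean_vectors, restrained_targets, P, sim.dt)
            langevin_step(state, f, sim, rng)
            state.p_bar = avg.update(legendre_p2(u_r @ state.unit_vector))
            assert np.all(state.p_bar >= -0.5 - 1e-12)
            assert np.all(state.p_bar <= 1.0 + 1e-12)

    def test_step_api_agrees_with_fast_loop(self, clean_vectors,
                                            restrained_targets):
        """The public single-step path and the optimized internal loop
        integrate the same dynamics from the same seed."""
        n = 100
        sim = SimParams(n_steps=n, n_runs=1, seed=11)
        res = run_hrs(clean_vectors, restrained_targets, P, sim,
                      traj_stride=1)
        from rdcsampler.hrs_engine import NormalizedExpAverage
        rng = np.random.default_rng(11)
        state = init_state(clean_vectors, restrained_targets, sim, rng)
        avg = NormalizedExpAverage(state.p_bar, sim.dt, P.tau_theta)
        u_r = np.array([v.u for v in clean_vectors])[
            [t.restrained for t in restrained_targets]]
        us = []
        for i in range(n):
            if i > 0:
                state.p_bar = avg.update(
                    legendre_p2(u_r @ state.unit_vector))
            f = mfv_force(state, clean_vectors, restrained_targets, P, sim.dt)
            langevin_step(state, f, sim, rng)
            us.append(state.unit_vector)
        np.testing.assert_allclose(np.array(us), res.traj, atol=1e-6)

    def test_convergence_trace_ends_at_reported_value(self, clean_vectors,
                                                      restrained_targets):
        sim = SimParams(n_steps=3000, n_runs=1, seed=8)
        res = run_hrs(clean_vectors, restrained_targets, P, sim,
                      trace_stride=1000)
        np.testing.assert_allclose(res.trace_d[-1], res.per_run_d[0],
                                   atol=1e-9)
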