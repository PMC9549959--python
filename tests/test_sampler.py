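"""Minimization, Langevin dynamics, barostat, and replica exchange."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from fepkit.alchemy import AlchemicalSystem, LambdaState
from fepkit.constants import BAR_NM3_TO_KJ, KB_KJ
from fepkit.fixtures import HarmonicState, make_ideal_gas, make_lj_dimer
from fepkit.sampler import (
    SimulationConfig,
    ThermodynamicState,
    langevin_step,
    mc_barostat_move,
    minimize_energy,
    run_replica_exchange,
)

LAM = LambdaState(0, 0.0, 1.0, 0.0, 1.0)


class QuadraticBowl:
    """U = k |x - x0|^2 with analytic gradient; convex minimization case."""

    def __init__(self, k=5.0, x0=(1.0, -2.0, 0.5)):
        self.k = k
        self.x0 = np.array(x0)

    def energy(self, x):
        return float(self.k * np.sum((x - self.x0) ** 2))

    def forces(self, x):
        return -2.0 * self.k * (x - self.x0)


class TestMinimize:
    def test_quadratic_bowl_converges_to_center(self):
        bowl = QuadraticBowl()
        res = minimize_energy(bowl, np.array([[10.0, 10.0, -3.0]]), tolerance=1e-8)
        assert res.converged
        assert np.allclose(res.positions, bowl.x0, atol=1e-6)

    def test_already_at_minimum_is_noop(self):
        bowl = QuadraticBowl()
        res = minimize_energy(bowl, bowl.x0.reshape(1, 3), tolerance=1e-8)
        assert res.converged
        assert np.allclose(res.positions, bowl.x0, atol=1e-12)

    def test_lj_dimer_finds_analytic_minimum(self):
        sigma = 0.34
        dim = make_lj_dimer(sigma=sigma, epsilon=1.0, separation=0.9 * sigma)
        system = AlchemicalSystem.from_molecule(dim)
        st = ThermodynamicState(system, LAM, 300.0)
        res = minimize_energy(st, system.initial_positions, tolerance=1e-8)
        r = np.linalg.norm(res.positions[1] - res.positions[0])
        assert r == pytest.approx(2 ** (1 / 6) * sigma, rel=1e-7)


class TestLangevin:
    def test_free_particle_zero_friction_is_uniform_motion(self):
        x = np.zeros((1, 3))
        v = np.array([[1.0, -0.5, 0.25]])
        f = np.zeros((1, 3))
        force_fn = lambda xx: np.zeros_like(xx)
        rng = np.random.default_rng(0)
        for _ in range(100):
            x, v, f = langevin_step(x, v, f, force_fn, np.ones(1),
                                    0.01, 0.0, 0.0, rng)
        assert np.allclose(x, v * 1.0, atol=1e-12)  # x = v * t, t = 100*0.01
        assert np.allclose(v, [[1.0, -0.5, 0.25]], atol=1e-15)

    def test_harmonic_equipartition(self):
        """Long BAOAB run at kT=1: position variance = kT/k within 3 SE."""
        k = 2.0
        hs = HarmonicState(k)
        rng = np.random.default_rng(7)
        x, v = np.zeros((1, 1)), np.zeros((1, 1))
        f = hs.forces(x)
        dt, gamma = 0.02, 2.0
        xs = []
        for i in range(60000):
            x, v, f = langevin_step(x, v, f, hs.forces, np.ones(1),
                                    dt, gamma, 1.0, rng)
            if i % 20 == 0:
                xs.append(x[0, 0])
        xs = np.array(xs[100:])
        var = xs.var()
        # effective sample size from the autocorrelation of the series
        from fepkit.estimators import statistical_inefficiency

        n_eff = len(xs) / statistical_inefficiency(xs)
        se = var * math.sqrt(2.0 / n_eff)
        assert abs(var - 1.0 / k) < 3 * se + 0.01 / k

    def test_same_seed_gives_bitwise_identical_trajectories(self):
        def run(seed):
            hs = HarmonicState(1.5)
            rng = np.random.default_rng(seed)
            x, v = np.ones((1, 1)), np.zeros((1, 1))
            f = hs.forces(x)
            traj = []
            for _ in range(500):
                x, v, f = langevin_step(x, v, f, hs.forces, np.ones(1),
                                        0.05, 1.0, 1.0, rng)
                traj.append(x.copy())
            return np.array(traj)

        assert np.array_equal(run(42), run(42))
        assert not np.array_equal(run(42), run(43))

    def test_nonfinite_force_halts(self):
        x, v = np.zeros((1, 3)), np.zeros((1, 3))
        bad = np.full((1, 3), np.nan)
        with pytest.raises(FloatingPointError):
            langevin_step(x, v, bad, lambda xx: bad, np.ones(1), 0.01, 1.0,
                          1.0, np.random.default_rng(0))


class TestBarostat:
    def test_ideal_gas_law(self):
        """NPT ideal gas: <V> = (N+1) kT / p within 3 SE."""
        N, T, p = 20, 300.0, 200.0
        rng = np.random.default_rng(5)
        x = make_ideal_gas(N, 3.0, seed=4).positions()
        box = 3.0
        vols = []
        for _ in range(15000):
            x, box, _ = mc_barostat_move(x, box, lambda xx, bb: 0.0, N, p, T,
                                         2.0, rng)
            vols.append(box ** 3)
        vols = np.array(vols[2000:])
        from fepkit.estimators import statistical_inefficiency

        n_eff = len(vols) / statistical_inefficiency(vols)
        se = vols.std() / math.sqrt(n_eff)
        expected = (N + 1) * KB_KJ * T / (p * BAR_NM3_TO_KJ)
        assert abs(vols.mean() - expected) < 3 * se

    def test_rejected_move_leaves_state_exactly(self):
        rng = np.random.default_rng(1)
        x = np.random.default_rng(0).uniform(0, 2, (5, 3))
        # energy spikes on any volume change -> certain rejection
        energy = lambda xx, bb: 0.0 if bb == 2.0 else 1e9
        x2, box2, acc = mc_barostat_move(x, 2.0, energy, 5, 1.0, 300.0, 0.5, rng)
        assert not acc
        assert box2 == 2.0
        assert np.array_equal(x2, x)

    def test_zero_max_dv_never_changes_volume(self):
        rng = np.random.default_rng(2)
        x = np.zeros((3, 3))
        for _ in range(50):
            x, box, acc = mc_barostat_move(x, 2.5, lambda xx, bb: 0.0, 3,
                                           1.0, 300.0, 0.0, rng)
            assert box == 2.5 and not acc


class FrozenState(HarmonicState):
    """Harmonic state whose dynamics are frozen (propagate = identity) or
    replaced by exact Gaussian redraws; isolates the swap move."""

    def __init__(self, spring_k, redraw=False):
        super().__init__(spring_k)
        self.redraw = redraw

    def propagate(self, x, v, rng, n_steps, config, box=None):
        if self.redraw:
            x = rng.normal(0.0, 1.0 / math.sqrt(self.spring_k), size=x.shape)
        return x, v, box


class TestReplicaExchange:
    CFG = SimulationConfig(timestep_fs=50.0, swap_interval_ps=0.05,
                           friction_per_ps=2.0, pressure=None)

    def test_identical_hamiltonians_accept_every_swap(self):
        states = [FrozenState(1.0, redraw=True) for _ in range(4)]
        rep = run_replica_exchange(states, [np.zeros((1, 1))] * 4, 200,
                                   self.CFG, rng_seed=9)
        assert np.all(rep.swap_accepts == rep.swap_attempts)
        assert np.all(rep.acceptance_matrix() == 1.0)

    def test_sample_bookkeeping(self):
        states = [FrozenState(1.0, redraw=True) for _ in range(3)]
        rep = run_replica_exchange(states, [np.zeros((1, 1))] * 3, 57,
                                   self.CFG, rng_seed=3)
        assert all(len(rep.samples[k]) == 57 for k in range(3))
        with pytest.raises(ValueError):
            run_replica_exchange(states, [np.zeros((1, 1))] * 2, 5, self.CFG, 3)

    def test_two_state_acceptance_matches_quadrature(self):
        """Empirical swap acceptance between two harmonic states equals the
        analytically averaged Metropolis acceptance (double Gaussian
        integral), within 3 binomial SE."""
        k1, k2 = 1.0, 4.0
        states = [FrozenState(k1, redraw=True), FrozenState(k2, redraw=True)]
        n_iter = 4000
        rep = run_replica_exchange(states, [np.zeros((1, 1))] * 2, n_iter,
                                   self.CFG, rng_seed=17)
        emp = rep.swap_accepts[0] / rep.swap_attempts[0]

        def integrand(x2, x1):
            delta = 0.5 * (k1 - k2) * (x2 ** 2 - x1 ** 2)
            acc = min(1.0, math.exp(-delta))
            p1 = math.sqrt(k1 / (2 * math.pi)) * math.exp(-0.5 * k1 * x1 ** 2)
            p2 = math.sqrt(k2 / (2 * math.pi)) * math.exp(-0.5 * k2 * x2 ** 2)
            return acc * p1 * p2

        expected, _ = integrate.dblquad(integrand, -6, 6, -3, 3)
        se = math.sqrt(expected * (1 - expected) / rep.swap_attempts[0])
        assert abs(emp - expected) < 3 * se

    def test_swap_move_detailed_balance(self):
        """Frozen 2-replica toy: occupancy of the two arrangements matches
        the Boltzmann ratio implied by the swap acceptance (detailed
        balance), within Monte Carlo error."""
        k1, k2 = 1.0, 3.0
        x_a, x_b = np.array([[0.9]]), np.array([[0.2]])
        states = [FrozenState(k1), FrozenState(k2)]
        rep_positions = [x_a.copy(), x_b.copy()]
        # manual swap chain using the same acceptance rule
        rng = np.random.default_rng(123)
        counts = {0: 0, 1: 0}  # arrangement 0: (a,b); 1: (b,a)
        arrangement = 0
        u = lambda k, x: 0.5 * k * float(x[0, 0]) ** 2
        for _ in range(200000):
            xa, xb = (x_a, x_b) if arrangement == 0 else (x_b, x_a)
            delta = u(k1, xb) + u(k2, xa) - u(k1, xa) - u(k2, xb)
            if delta <= 0 or rng.random() < math.exp(-delta):
                arrangement = 1 - arrangement
            counts[arrangement] += 1
        ratio_emp = counts[0] / counts[1]
        ratio_exact = math.exp(-(u(k1, x_a) + u(k2, x_b))) \
            / math.exp(-(u(k1, x_b) + u(k2, x_a)))
        assert ratio_emp == pytest.approx(ratio_exact, rel=0.05)

    def test_hrex_preserves_harmonic_marginals(self):
        """Per-state sampled distributions on a 4-state ladder with real
        BAOAB dynamics match the analytic Gaussians (KS below the 1%
        critical value)."""
        ks = [1.0, 2.0, 3.0, 4.0]
        states = [HarmonicState(k) for k in ks]
        cfg = SimulationConfig(timestep_fs=50.0, swap_interval_ps=2.0,
                               friction_per_ps=2.0, pressure=None)
        rep = run_replica_exchange(states, [np.zeros((1, 1))] * 4, 1200,
                                   cfg, rng_seed=21)
        for k, spring in enumerate(ks):
            xs = np.array([s[0][0, 0] for s in rep.samples[k]])
            d, _ = stats.kstest(xs, "norm", args=(0.0, 1.0 / math.sqrt(spring)))
            crit = 1.628 / math.sqrt(len(xs))
            assert d < crit

    def test_seeded_determinism(self):
        states = [HarmonicState(k) for k in (1.0, 2.0)]
        cfg = SimulationConfig(timestep_fs=50.0, swap_interval_ps=1.0,
                               friction_per_ps=2.0, pressure=None)
        r1 = run_replica_exchange(states, [np.zeros((1, 1))] * 2, 50, cfg, 5)
        r2 = run_replica_exchange(states, [np.zeros((1, 1))] * 2, 50, cfg, 5)
        for k in range(2):
            a = np.array([s[0] for s in r1.samples[k]])
            b = np.array([s[0] for s in r2.samples[k]])
            assert np.array_equal(a, b)


class TestSimulationConfig:
    def test_swap_interval_must_divide_timestep(self):
        with pytest.raises(ValueError, match="multiple"):
            SimulationConfig(timestep_fs=3.0, swap_interval_ps=0.01)

    def test_defaults_match_production_protocol(self):
        cfg = SimulationConfig()
        assert cfg.temperature == 300.0
        assert cfg.pressure == pytest.approx(1.01325)
        assert cfg.timestep_fs == 4.0
        assert cfg.equilibration_ps == 500.0
        assert cfg.production_ns == 5.0
        assert cfg.swap_interval_ps == 4.0
        assert cfg.cutoff_nm == 1.0
        assert cfg.n_lambda_windows == 12
        assert cfg.hydrogen_mass_amu == 4.0
        assert cfg.steps_per_swap == 1000
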