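"""Desk-scale sampling: minimization, Langevin dynamics, a Monte Carlo
barostat, and Hamiltonian replica exchange (HREX) across λ-states.

Units follow the GROMACS convention (nm, ps, amu, kJ/mol), under which
kinetic energy is ``0.5 * m * v**2`` with no conversion factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .alchemy import AlchemicalSystem, LambdaState, reduced_potential
from .constants import ATM_IN_BAR, KB_KJ
from .estimators import ReducedPotentialMatrix

__all__ = [
    "SimulationConfig",
    "ThermodynamicState",
    "MinimizationResult",
    "minimize_energy",
    "langevin_step",
    "run_langevin",
    "mc_barostat_move",
    "ReplicaSet",
    "run_replica_exchange",
]


@dataclass
class SimulationConfig:
    """Sampling parameters; defaults mirror the production protocol
    (300 K, 1 atm NPT, 4 fs timestep with repartitioned hydrogens, 500 ps
    equilibration, replica swaps every 4 ps, 1.0 nm cutoff) — test runs
    scale the lengths down."""

    temperature: float = 300.0          # K
    pressure: float | None = ATM_IN_BAR  # bar; None = NVT
    timestep_fs: float = 4.0
    friction_per_ps: float = 1.0
    equilibration_ps: float = 500.0
    production_ns: float = 5.0
    swap_interval_ps: float = 4.0
    sample_interval_ps: float = 4.0
    cutoff_nm: float = 1.0
    buffer_nm: float = 0.9
    ionic_strength_mM: float = 150.0
    n_lambda_windows: int = 12
    hydrogen_mass_amu: float = 4.0
    barostat_interval_steps: int = 25
    barostat_max_dV_nm3: float = 0.05
    seed: int = 2026

    def __post_init__(self):
        for name in ("timestep_fs", "equilibration_ps", "swap_interval_ps",
                     "sample_interval_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        ratio = self.swap_interval_ps * 1000.0 / self.timestep_fs
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("swap_interval must be a multiple of the timestep")

    @property
    def timestep_ps(self) -> float:
        return self.timestep_fs / 1000.0

    @property
    def steps_per_swap(self) -> int:
        return int(round(self.swap_interval_ps / self.timestep_ps))

    @property
    def kT(self) -> float:
        return KB_KJ * self.temperature


class ThermodynamicState:
    """An alchemical system bound to one λ-state, a temperature and an
    optional pressure; the unit of HREX and of the reduced potential."""

    def __init__(
        self,
        system: AlchemicalSystem,
        lambda_state: LambdaState,
        temperature: float,
        pressure: float | None = None,
    ):
        self.system = system
        self.lambda_state = lambda_state
        self.temperature = temperature
        self.pressure = pressure

    @property
    def kT(self) -> float:
        return KB_KJ * self.temperature

    def energy(self, positions: np.ndarray, box: float | None = None) -> float:
        if box is not None and box != self.system.box:
            prev, self.system.box = self.system.box, box
            try:
                return self.system.energy(positions, self.lambda_state)
            finally:
                self.system.box = prev
        return self.system.energy(positions, self.lambda_state)

    def forces(self, positions: np.ndarray) -> np.ndarray:
        return self.system.forces(positions, self.lambda_state)

    def reduced_potential(self, positions: np.ndarray, box: float | None = None) -> float:
        b = box if box is not None else self.system.box
        vol = b ** 3 if b is not None else None
        return reduced_potential(self.energy(positions, b), vol,
                                 self.temperature, self.pressure)

    def initial_velocities(self, rng: np.random.Generator) -> np.ndarray:
        scale = np.sqrt(self.kT / self.system.masses)[:, None]
        return scale * rng.standard_normal((self.system.n_atoms, 3))

    def propagate(
        self,
        positions: np.ndarray,
        velocities: np.ndarray,
        rng: np.random.Generator,
        n_steps: int,
        config: "SimulationConfig",
        box: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray, float | None]:
        """BAOAB dynamics (with optional barostat moves) under this state."""
        box = box if box is not None else self.system.box
        prev_box = self.system.box
        self.system.box = box
        try:
            x, v = positions, velocities
            f = self.forces(x)
            for step in range(n_steps):
                x, v, f = langevin_step(
                    x, v, f, self.forces, self.system.masses,
                    config.timestep_ps, config.friction_per_ps, self.kT, rng,
                )
                if (
                    self.pressure is not None
                    and box is not None
                    and (step + 1) % config.barostat_interval_steps == 0
                ):
                    x, new_box, accepted = mc_barostat_move(
                        x, self.system.box,
                        lambda xx, bb: self.energy(xx, bb),
                        self.system.n_atoms, self.pressure, self.temperature,
                        config.barostat_max_dV_nm3, rng,
                    )
                    if accepted:
                        self.system.box = new_box
                        f = self.forces(x)
            return x, v, self.system.box
        finally:
            # restore the shared system's box; the evolved box is returned
            self.system.box = prev_box


@dataclass
class MinimizationResult:
    positions: np.ndarray
    energy: float
    gradient_norm: float
    converged: bool
    n_iterations: int


def minimize_energy(
    state, positions: np.ndarray, tolerance: float = 10.0, max_iter: int = 1000
) -> MinimizationResult:
    """Local energy minimization (L-BFGS) to a gradient-norm tolerance
    (kJ/mol/nm).  ``state`` needs ``energy(x)`` and ``forces(x)``."""
    x0 = np.asarray(positions, float)
    shape = x0.shape
    e0 = state.energy(x0)
    if not np.isfinite(e0):
        # crude steepest-descent rescue from overlapping starting points
        x = x0.copy()
        for _ in range(200):
            f = np.nan_to_num(state.forces(x), nan=0.0, posinf=1e6, neginf=-1e6)
            nrm = np.max(np.abs(f))
            x = x + f / max(nrm, 1.0) * 0.01
            if np.isfinite(state.energy(x)):
                break
        else:
            raise ValueError("non-finite starting energy could not be reduced")
        x0 = x

    def fun(flat):
        x = flat.reshape(shape)
        e = state.energy(x)
        g = -state.forces(x).ravel()
        if not np.isfinite(e):
            return 1e30, np.nan_to_num(g, nan=0.0, posinf=1e8, neginf=-1e8)
        return e, g

    res = _scipy_minimize(
        fun, x0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 1e-12, "ftol": 1e-14},
    )
    x = res.x.reshape(shape)
    gnorm = float(np.max(np.abs(state.forces(x))))
    return MinimizationResult(x, float(state.energy(x)), gnorm,
                              gnorm <= tolerance, int(res.nit))


def langevin_step(
    x: np.ndarray,
    v: np.ndarray,
    f: np.ndarray,
    force_fn,
    masses: np.ndarray,
    dt: float,
    friction: float,
    kT: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One BAOAB step.  Reduces to velocity Verlet at zero friction and
    temperature.  Returns (x, v, forces-at-new-x); forces at the current x
    are passed in so each step costs one force evaluation."""
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force encountered")
    m = masses[:, None]
    v = v + 0.5 * dt * f / m
    x = x + 0.5 * dt * v
    if friction > 0.0:
        c1 = math.exp(-friction * dt)
        c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
        v = c1 * v + c2 * np.sqrt(kT / m) * rng.standard_normal(v.shape)
    elif kT > 0.0:
        pass  # zero friction: no thermostat coupling
    x = x + 0.5 * dt * v
    f_new = force_fn(x)
    v = v + 0.5 * dt * f_new / m
    return x, v, f_new


def run_langevin(
    state, positions, velocities, n_steps, config: SimulationConfig,
    rng: np.random.Generator, sample_every: int | None = None,
):
    """Convenience loop around ``langevin_step``; returns final (x, v) and
    the sampled positions."""
    x = np.asarray(positions, float)
    v = np.asarray(velocities, float)
    f = state.forces(x)
    samples = []
    for step in range(n_steps):
        x, v, f = langevin_step(x, v, f, state.forces, state.system.masses,
                                config.timestep_ps, config.friction_per_ps,
                                state.kT, rng)
        if sample_every and (step + 1) % sample_every == 0:
            samples.append(x.copy())
    return x, v, samples


def mc_barostat_move(
    positions: np.ndarray,
    box: float,
    energy_fn,
    n_particles: int,
    pressure: float,
    temperature: float,
    max_dV: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, bool]:
    """One isotropic Monte Carlo volume move (per-particle scaling).

    Accepts with min(1, exp(-beta [dU + p dV - N kT ln(V'/V)])); pressure in
    bar, volumes in nm^3.  Returns (positions, box, accepted).
    """
    if max_dV <= 0.0:
        return positions, box, False
    kT = KB_KJ * temperature
    from .constants import BAR_NM3_TO_KJ

    V = box ** 3
    dV = rng.uniform(-max_dV, max_dV)
    V_new = V + dV
    if V_new <= 0:
        return positions, box, False
    scale = (V_new / V) ** (1.0 / 3.0)
    new_box = box * scale
    u_old = energy_fn(positions, box)
    x_new = positions * scale
    u_new = energy_fn(x_new, new_box)
    arg = -(u_new - u_old + pressure * dV * BAR_NM3_TO_KJ
            - n_particles * kT * math.log(V_new / V)) / kT
    if math.log(max(rng.random(), 1e-300)) < arg:
        return x_new, new_box, True
    return positions, box, False


@dataclass
class ReplicaSet:
    """State of an HREX run: one replica (configuration) per λ-state, the
    per-state sample stores, and neighbour-swap statistics."""

    positions: list[np.ndarray]
    velocities: list[np.ndarray]
    boxes: list[float | None]
    samples: list[list[tuple[np.ndarray, float | None]]] = field(default_factory=list)
    swap_attempts: np.ndarray | None = None
    swap_accepts: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.positions)

    def acceptance_matrix(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.swap_attempts > 0,
                            self.swap_accepts / np.maximum(self.swap_attempts, 1), np.nan)

    def sample_positions(self, k: int) -> list[np.ndarray]:
        return [s[0] for s in self.samples[k]]

    def build_u_kn(self, states) -> ReducedPotentialMatrix:
        """Evaluate every stored sample under every state (the MBAR input).

        Samples are ordered state-major: all samples drawn in state 0, then
        state 1, and so on."""
        flat = [s for store in self.samples for s in store]
        N_k = np.array([len(store) for store in self.samples], int)
        K, N = len(states), len(flat)
        u_kn = np.empty((K, N))
        for k, st in enumerate(states):
            u_kn[k] = [st.reduced_potential(x, box) for x, box in flat]
        return ReducedPotentialMatrix(u_kn=u_kn, N_k=N_k)


def run_replica_exchange(
    states,
    initial_positions,
    n_iterations: int,
    config: SimulationConfig,
    rng_seed: int,
    initial_boxes=None,
    steps_per_segment: int | None = None,
    samples_per_segment: int = 1,
) -> ReplicaSet:
    """Hamiltonian replica exchange over a ladder of thermodynamic states.

    Each iteration propagates every replica for one swap interval under its
    current state, stores a sample, then performs a deterministic
    even/odd alternating sweep of neighbour swap attempts, accepting a swap
    of the configurations in states i and i+1 with probability
    min(1, exp(-[u_i(x_j) + u_j(x_i) - u_i(x_i) - u_j(x_j)])).

    ``states`` need ``reduced_potential(x, box)``, ``propagate(x, v, rng,
    n_steps, config, box)`` and ``initial_velocities(rng)``.  Per-replica RNG
    streams are derived deterministically from ``rng_seed``.
    """
    K = len(states)
    if len(initial_positions) != K:
        raise ValueError(f"{len(initial_positions)} replicas for {K} states")
    steps = steps_per_segment if steps_per_segment is not None else config.steps_per_swap
    rngs = [np.random.default_rng([rng_seed, k]) for k in range(K)]
    swap_rng = np.random.default_rng([rng_seed, 10_000])

    boxes = list(initial_boxes) if initial_boxes is not None else [
        getattr(st.system, "box", None) if hasattr(st, "system") else None for st in states
    ]
    xs = [np.array(p, float) for p in initial_positions]
    vs = [states[k].initial_velocities(rngs[k]) for k in range(K)]
    rep = ReplicaSet(xs, vs, boxes, [[] for _ in range(K)],
                     np.zeros(K - 1, int), np.zeros(K - 1, int))

    seg = max(steps // samples_per_segment, 1)
    for it in range(n_iterations):
        for k in range(K):
            done = 0
            while done < steps:
                chunk = min(seg, steps - done)
                out = states[k].propagate(rep.positions[k], rep.velocities[k],
                                          rngs[k], chunk, config, rep.boxes[k])
                rep.positions[k], rep.velocities[k], rep.boxes[k] = out
                done += chunk
                rep.samples[k].append((rep.positions[k].copy(), rep.boxes[k]))
        start = it % 2
        for i in range(start, K - 1, 2):
            j = i + 1
            uii = states[i].reduced_potential(rep.positions[i], rep.boxes[i])
            ujj = states[j].reduced_potential(rep.positions[j], rep.boxes[j])
            uij = states[i].reduced_potential(rep.positions[j], rep.boxes[j])
            uji = states[j].reduced_potential(rep.positions[i], rep.boxes[i])
            rep.swap_attempts[i] += 1
            delta = uij + uji - uii - ujj
            if delta <= 0 or swap_rng.random() < math.exp(-delta):
                rep.swap_accepts[i] += 1
                for attr in ("positions", "velocities", "boxes"):
                    seq = getattr(rep, attr)
                    seq[i], seq[j] = seq[j], seq[i]
    return rep
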