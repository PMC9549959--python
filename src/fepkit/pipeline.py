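"""End-to-end alchemical legs at desk scale.

``run_alchemical_leg`` takes a hybrid molecule (plus an optional inert
environment), builds one thermodynamic state per λ-window, minimizes,
equilibrates, runs Hamiltonian replica exchange, and estimates the leg Δf
with MBAR.  ``run_rbfe_edge`` combines a "complex" leg and a "solvent" leg
into an edge ΔΔG, mirroring the two-leg thermodynamic cycle used for
relative binding free energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alchemy import AlchemicalSchedule, AlchemicalSystem, SoftcoreParameters, build_lambda_schedule
from .estimators import FreeEnergyResult, ReducedPotentialMatrix, mbar_solve, subsample_matrix
from .molecules import HybridTopology, Molecule
from .sampler import (
    ReplicaSet,
    SimulationConfig,
    ThermodynamicState,
    minimize_energy,
    run_replica_exchange,
)

__all__ = ["LegResult", "run_alchemical_leg", "run_rbfe_edge"]


@dataclass
class LegResult:
    free_energy: FreeEnergyResult
    matrix: ReducedPotentialMatrix
    replicas: ReplicaSet
    schedule: AlchemicalSchedule


def _center_in_box(positions: np.ndarray, box: float | None) -> np.ndarray:
    if box is None:
        return positions
    return positions - positions.mean(axis=0) + 0.5 * box


def run_alchemical_leg(
    hybrid: HybridTopology,
    environment: Molecule | None,
    config: SimulationConfig,
    box: float | None,
    n_iterations: int,
    schedule: AlchemicalSchedule | None = None,
    softcore: SoftcoreParameters = SoftcoreParameters(),
    equilibration_steps: int | None = None,
    decorrelate: bool = False,
    reverse: bool = False,
) -> LegResult:
    """Minimize → equilibrate → HREX → MBAR for one transformation leg.

    ``n_iterations`` HREX iterations of one swap interval each;
    ``reverse=True`` runs the schedule B→A (states reversed), which the
    antisymmetry checks use.  NVT production (the barostat, when a pressure
    is configured, acts during equilibration only, keeping every sample's
    box recorded alongside it).
    """
    schedule = schedule or build_lambda_schedule(config.n_lambda_windows)
    lam_states = list(reversed(schedule.states)) if reverse else list(schedule.states)
    system = AlchemicalSystem.from_hybrid(
        hybrid, environment, box=box, cutoff=config.cutoff_nm if box else None,
        softcore=softcore,
    )
    states = [
        ThermodynamicState(system, ls, config.temperature, pressure=None)
        for ls in lam_states
    ]

    x0 = _center_in_box(system.initial_positions.copy(), box)
    mini = minimize_energy(states[0], x0, tolerance=100.0, max_iter=500)
    x_min = mini.positions

    eq_steps = (equilibration_steps if equilibration_steps is not None
                else int(round(config.equilibration_ps / config.timestep_ps)))
    positions = []
    for k, st in enumerate(states):
        rng = np.random.default_rng([config.seed, 777, k])
        x, v, _ = st.propagate(x_min.copy(), st.initial_velocities(rng), rng,
                               eq_steps, config, box)
        positions.append(x)

    replicas = run_replica_exchange(
        states, positions, n_iterations, config, rng_seed=config.seed,
        initial_boxes=[box] * len(states),
    )
    matrix = replicas.build_u_kn(states)
    matrix.temperature = config.temperature
    if decorrelate:
        matrix = subsample_matrix(matrix)
    fe = mbar_solve(matrix)
    fe.temperature = config.temperature
    return LegResult(fe, matrix, replicas, schedule)


def run_rbfe_edge(
    hybrid: HybridTopology,
    complex_environment: Molecule,
    solvent_environment: Molecule,
    config: SimulationConfig,
    box: float,
    n_iterations: int,
    **kwargs,
):
    """Run both legs of the thermodynamic cycle and assemble the edge ΔΔG."""
    from .estimators import assemble_edge

    leg_c = run_alchemical_leg(hybrid, complex_environment, config, box,
                               n_iterations, **kwargs)
    leg_s = run_alchemical_leg(hybrid, solvent_environment, config, box,
                               n_iterations, **kwargs)
    edge = assemble_edge(leg_c.free_energy, leg_s.free_energy, config.temperature)
    return edge, leg_c, leg_s
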