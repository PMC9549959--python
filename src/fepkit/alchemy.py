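"""Alchemical energy model: softcore nonbonded potentials and λ-schedules.

To transform ligand A into ligand B without endpoint singularities, the
Lennard-Jones interaction of appearing/disappearing atoms is evaluated at a
softened effective distance

    r_eff = sigma * (alpha * (1-lambda)^b + (r/sigma)^c)^(1/c)
    U     = lambda^a * 4 eps * [(sigma/r_eff)^12 - (sigma/r_eff)^6]

and the Coulomb interaction at

    r_eff = (beta * (1-lambda)^e + r^f)^(1/f)
    U     = lambda^d * k_e q1 q2 / r_eff.

Defaults are alpha=0.5, a=1, b=1, c=6, beta=0.0, d=1, e=1, f=2, under which
the electrostatic form reduces to linear scaling of the plain Coulomb
energy.  At lambda=1 both forms are exactly the standard potentials; at
lambda=0 both vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BAR_NM3_TO_KJ, COULOMB_KJ, KB_KJ
from .molecules import HybridTopology, Molecule

__all__ = [
    "SoftcoreParameters",
    "LambdaState",
    "AlchemicalSchedule",
    "softcore_sterics",
    "softcore_electrostatics",
    "build_lambda_schedule",
    "AlchemicalSystem",
    "potential_energy",
    "reduced_potential",
]

DEFAULT_BOND_K = 25000.0  # kJ/mol/nm^2, generic stiff harmonic bond


@dataclass(frozen=True)
class SoftcoreParameters:
    """The eight softcore constants (dimensionless except beta, nm^2)."""

    alpha: float = 0.5
    a: float = 1.0
    b: float = 1.0
    c: float = 6.0
    beta: float = 0.0
    d: float = 1.0
    e: float = 1.0
    f: float = 2.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("softcore alpha and beta must be >= 0")
        if self.c <= 0 or self.f <= 0:
            raise ValueError("softcore exponents c and f must be > 0")


@dataclass(frozen=True)
class LambdaState:
    """One alchemical window: the four coupling components, each in [0, 1].

    Insert channels (0 -> 1 along the transformation) couple atoms unique to
    the new molecule; delete channels (1 -> 0) decouple atoms unique to the
    old one.
    """

    index: int
    lambda_sterics_insert: float
    lambda_sterics_delete: float
    lambda_elec_insert: float
    lambda_elec_delete: float

    def __post_init__(self):
        for name in ("lambda_sterics_insert", "lambda_sterics_delete",
                     "lambda_elec_insert", "lambda_elec_delete"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class AlchemicalSchedule:
    states: list[LambdaState]
    master_lambdas: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)


def softcore_sterics(r, sigma, epsilon, lam, sc: SoftcoreParameters = SoftcoreParameters()):
    """Softcore Lennard-Jones energy (kJ/mol) at separation r (nm).

    Vectorized over r.  Finite at r=0 whenever lam < 1 and alpha > 0;
    exactly 4*eps*[(s/r)^12-(s/r)^6] at lam=1 and exactly 0 at lam=0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be >= 0")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")
    if lam == 0.0 and sc.a >= 1:
        return np.zeros_like(r) if r.ndim else 0.0
    with np.errstate(divide="ignore", over="ignore"):
        s = sc.alpha * (1.0 - lam) ** sc.b + (r / sigma) ** sc.c
        inv6 = 1.0 / s ** (6.0 / sc.c)  # (sigma/r_eff)^6
        u = lam ** sc.a * 4.0 * epsilon * (inv6 * inv6 - inv6)
    return u if r.ndim else float(u)


def softcore_sterics_force(r, sigma, epsilon, lam, sc: SoftcoreParameters = SoftcoreParameters()):
    """-dU/dr of the softcore LJ (kJ/mol/nm), vectorized over r."""
    r = np.asarray(r, dtype=float)
    if lam == 0.0 and sc.a >= 1:
        return np.zeros_like(r)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        x = (r / sigma) ** sc.c
        s = sc.alpha * (1.0 - lam) ** sc.b + x
        inv6 = s ** (-6.0 / sc.c)
        # dU/ds = 4 eps lam^a * (-12/c s^{-12/c-1} + 6/c s^{-6/c-1})
        du_ds = lam ** sc.a * 4.0 * epsilon * (6.0 / sc.c) * (inv6 / s) * (1.0 - 2.0 * inv6)
        ds_dr = sc.c * x / np.where(r > 0, r, np.inf)
        f = -du_ds * ds_dr
    return np.where(r > 0, f, 0.0)


def softcore_electrostatics(r, q1, q2, lam, sc: SoftcoreParameters = SoftcoreParameters()):
    """Softcore Coulomb energy (kJ/mol); with beta=0 this is lam^d times the
    plain Coulomb energy at the same separation."""
    r = np.asarray(r, dtype=float)
    if sc.beta == 0.0 and np.any(r <= 0):
        raise ValueError("r must be > 0 when softcore beta is 0 (singular)")
    if lam == 0.0 and sc.d >= 1:
        return np.zeros_like(r) if r.ndim else 0.0
    r_eff = (sc.beta * (1.0 - lam) ** sc.e + r ** sc.f) ** (1.0 / sc.f)
    u = lam ** sc.d * COULOMB_KJ * q1 * q2 / r_eff
    return u if r.ndim else float(u)


def build_lambda_schedule(
    n_windows: int = 12,
    sc_protocol: str = "two_phase",
    switch: float = 0.5,
) -> AlchemicalSchedule:
    """Equally-spaced master-λ schedule with a component protocol.

    ``two_phase`` (default): for master λ in [0, switch] the old
    electrostatics are turned off while the sterics of both endpoints are
    switched (insert 0→1, delete 1→0); for λ in [switch, 1] the new
    electrostatics are turned on.  Sterics are thus entirely settled before
    the new charges appear.  ``linear``: all four components move linearly
    together.  The first state is pure A, the last pure B, and every
    component trajectory is monotone.
    """
    if n_windows < 2:
        raise ValueError(f"need at least 2 lambda windows, got {n_windows}")
    if not 0.0 < switch < 1.0:
        raise ValueError("switch point must lie strictly inside (0, 1)")
    if sc_protocol not in ("two_phase", "linear"):
        raise ValueError(f"unknown protocol {sc_protocol!r}")
    masters = [m / (n_windows - 1) for m in range(n_windows)]
    states = []
    for i, lam in enumerate(masters):
        if sc_protocol == "linear":
            si, sd, ei, ed = lam, 1.0 - lam, lam, 1.0 - lam
        else:
            if lam <= switch:
                x = lam / switch
                si, sd, ei, ed = x, 1.0 - x, 0.0, 1.0 - x
            else:
                y = (lam - switch) / (1.0 - switch)
                si, sd, ei, ed = 1.0, 0.0, y, 0.0
        states.append(LambdaState(i, si, sd, ei, ed))
    return AlchemicalSchedule(states, masters)


def reduced_potential(
    energy: float, volume: float | None, temperature: float, pressure: float | None = None
) -> float:
    """Dimensionless reduced potential u = (U + p V) / k_B T.

    ``pressure`` in bar, ``volume`` in nm^3; the pV term is included only
    when a pressure is given (NPT ensemble).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    kt = KB_KJ * temperature
    u = energy / kt
    if pressure is not None:
        if volume is None:
            raise ValueError("volume required when pressure is given")
        u += pressure * volume * BAR_NM3_TO_KJ / kt
    return u


class AlchemicalSystem:
    """Vectorized energy/force model for a hybrid (plus optional inert
    environment atoms) in a cubic periodic box.

    Pair rules (minimum image, spherical cutoff, 1-2 bonded exclusions):

    * pairs within {core, environment}: plain LJ with state-interpolated
      sigma/epsilon;
    * pairs touching a unique_old atom: softcore LJ at the sterics-delete λ;
    * pairs touching a unique_new atom: softcore LJ at the sterics-insert λ;
    * unique_old–unique_new pairs never interact (dual topology);
    * electrostatics: plain Coulomb between per-atom effective charges
      q_core = q_A·λ_elec_delete + q_B·λ_elec_insert, q_old = q_A·λ_ed,
      q_new = q_B·λ_ei (equivalent to the softcore form at beta = 0).

    Bonded terms are harmonic in bond length and independent of λ.
    """

    def __init__(
        self,
        charges_a: np.ndarray,
        sigmas_a: np.ndarray,
        epsilons_a: np.ndarray,
        charges_b: np.ndarray,
        sigmas_b: np.ndarray,
        epsilons_b: np.ndarray,
        masses: np.ndarray,
        classes: list[str],
        bonds: list[tuple[int, int]],
        bond_params: dict[tuple[int, int], tuple[float, float]],
        initial_positions: np.ndarray,
        box: float | None,
        cutoff: float | None,
        softcore: SoftcoreParameters = SoftcoreParameters(),
    ):
        n = len(masses)
        self.n_atoms = n
        self.qa, self.qb = np.asarray(charges_a, float), np.asarray(charges_b, float)
        self.sa, self.sb = np.asarray(sigmas_a, float), np.asarray(sigmas_b, float)
        self.ea, self.eb = np.asarray(epsilons_a, float), np.asarray(epsilons_b, float)
        self.masses = np.asarray(masses, float)
        self.classes = list(classes)
        self.softcore = softcore
        self.box = box
        self.cutoff = cutoff
        if box is not None and cutoff is not None and box <= 2.0 * cutoff:
            raise ValueError(f"box edge {box} must exceed twice the cutoff {cutoff}")
        self.initial_positions = np.array(initial_positions, float)

        self.bond_i = np.array([b[0] for b in sorted(bonds)], int)
        self.bond_j = np.array([b[1] for b in sorted(bonds)], int)
        k0, r0 = [], []
        p0 = self.initial_positions
        for bi, bj in zip(self.bond_i, self.bond_j):
            k, r = bond_params.get(
                (int(bi), int(bj)),
                (DEFAULT_BOND_K, float(np.linalg.norm(p0[bj] - p0[bi]))),
            )
            k0.append(k)
            r0.append(r)
        self.bond_k = np.array(k0, float)
        self.bond_r0 = np.array(r0, float)

        cls = np.array([{"core": 0, "env": 0, "unique_old": 1, "unique_new": 2}[c]
                        for c in classes])
        excluded = {(min(i, j), max(i, j)) for i, j in bonds}
        plain, ins, dele = [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excluded:
                    continue
                ci, cj = cls[i], cls[j]
                if {ci, cj} >= {1, 2}:
                    continue  # old and new endpoints never see each other
                if 1 in (ci, cj):
                    dele.append((i, j))
                elif 2 in (ci, cj):
                    ins.append((i, j))
                else:
                    plain.append((i, j))
        self.pairs_plain = np.array(plain, int).reshape(-1, 2)
        self.pairs_insert = np.array(ins, int).reshape(-1, 2)
        self.pairs_delete = np.array(dele, int).reshape(-1, 2)
        self._is_core = cls == 0
        self._is_old = cls == 1
        self._is_new = cls == 2

    # ---- constructors -------------------------------------------------

    @classmethod
    def from_hybrid(
        cls,
        hybrid: HybridTopology,
        environment: Molecule | None = None,
        box: float | None = None,
        cutoff: float | None = None,
        softcore: SoftcoreParameters = SoftcoreParameters(),
    ) -> "AlchemicalSystem":
        atoms = hybrid.atoms
        qa = [a.charge_a for a in atoms]
        qb = [a.charge_b for a in atoms]
        sa = [a.sigma_a for a in atoms]
        sb = [a.sigma_b for a in atoms]
        ea = [a.epsilon_a for a in atoms]
        eb = [a.epsilon_b for a in atoms]
        masses = [a.mass for a in atoms]
        classes = [a.atom_class for a in atoms]
        pos = [a.position for a in atoms]
        bonds = sorted(hybrid.bonds)
        bond_params = dict(hybrid.bond_params)
        if environment is not None:
            off = len(atoms)
            for a in environment.atoms:
                qa.append(a.charge); qb.append(a.charge)
                sa.append(a.lj_sigma); sb.append(a.lj_sigma)
                ea.append(a.lj_epsilon); eb.append(a.lj_epsilon)
                masses.append(a.mass)
                classes.append("env")
                pos.append(a.position)
            for (i, j) in sorted(environment.bonds):
                bonds.append((i + off, j + off))
                if (i, j) in environment.bond_params:
                    bond_params[(i + off, j + off)] = environment.bond_params[(i, j)]
        return cls(qa, sa, ea, qb, sb, eb, masses, classes, bonds, bond_params,
                   np.array(pos, float), box, cutoff, softcore)

    @classmethod
    def from_molecule(
        cls,
        mol: Molecule,
        box: float | None = None,
        cutoff: float | None = None,
        softcore: SoftcoreParameters = SoftcoreParameters(),
    ) -> "AlchemicalSystem":
        """A non-alchemical system: every atom has one parameter set."""
        q = [a.charge for a in mol.atoms]
        s = [a.lj_sigma for a in mol.atoms]
        e = [a.lj_epsilon for a in mol.atoms]
        m = [a.mass for a in mol.atoms]
        return cls(q, s, e, q, s, e, m, ["env"] * mol.n_atoms,
                   sorted(mol.bonds), dict(mol.bond_params),
                   mol.positions(), box, cutoff, softcore)

    # ---- state-dependent parameters ------------------------------------

    def _interp(self, state: LambdaState):
        si, sd = state.lambda_sterics_insert, state.lambda_sterics_delete
        w = 0.5 * (1.0 - sd + si)  # 0 at pure A, 1 at pure B
        sig = np.where(self._is_old, self.sa,
                       np.where(self._is_new, self.sb,
                                (1 - w) * self.sa + w * self.sb))
        eps = np.where(self._is_old, self.ea,
                       np.where(self._is_new, self.eb,
                                (1 - w) * self.ea + w * self.eb))
        q = np.where(self._is_old, self.qa * state.lambda_elec_delete,
                     np.where(self._is_new, self.qb * state.lambda_elec_insert,
                              self.qa * state.lambda_elec_delete
                              + self.qb * state.lambda_elec_insert))
        return sig, eps, q

    def _minimum_image(self, dx: np.ndarray) -> np.ndarray:
        if self.box is not None:
            dx = dx - self.box * np.round(dx / self.box)
        return dx

    def _pair_geometry(self, positions, pairs):
        dx = self._minimum_image(positions[pairs[:, 1]] - positions[pairs[:, 0]])
        r = np.sqrt(np.sum(dx * dx, axis=1))
        return dx, r

    # ---- energy and forces ---------------------------------------------

    def energy(self, positions: np.ndarray, state: LambdaState) -> float:
        positions = np.asarray(positions, float)
        u = 0.0
        if len(self.bond_i):
            _, rb = self._pair_geometry(positions, np.column_stack([self.bond_i, self.bond_j]))
            u += float(np.sum(0.5 * self.bond_k * (rb - self.bond_r0) ** 2))
        sig, eps, q = self._interp(state)
        sc = self.softcore
        for pairs, lam in (
            (self.pairs_plain, 1.0),
            (self.pairs_insert, state.lambda_sterics_insert),
            (self.pairs_delete, state.lambda_sterics_delete),
        ):
            if not len(pairs):
                continue
            _, r = self._pair_geometry(positions, pairs)
            mask = np.ones(len(r), bool) if self.cutoff is None else (r < self.cutoff)
            i, j = pairs[mask, 0], pairs[mask, 1]
            rr = r[mask]
            s_ij = 0.5 * (sig[i] + sig[j])
            e_ij = np.sqrt(eps[i] * eps[j])
            if lam == 1.0:
                with np.errstate(divide="ignore", over="ignore"):
                    x6 = (s_ij / rr) ** 6
                    # x6*(x6-1) stays +inf (not nan) for overlapping particles
                    u += float(np.sum(4.0 * e_ij * (x6 * (x6 - 1.0))))
            elif lam > 0.0:
                u += float(np.sum(softcore_sterics(rr, s_ij, e_ij, lam, sc)))
            qq = q[i] * q[j]
            live = qq != 0.0
            if np.any(live):
                u += float(np.sum(COULOMB_KJ * qq[live] / rr[live]))
        return u

    def forces(self, positions: np.ndarray, state: LambdaState) -> np.ndarray:
        positions = np.asarray(positions, float)
        f = np.zeros_like(positions)
        if len(self.bond_i):
            bp = np.column_stack([self.bond_i, self.bond_j])
            dx, rb = self._pair_geometry(positions, bp)
            mag = -self.bond_k * (rb - self.bond_r0)  # along +dx acts on j
            fv = (mag / rb)[:, None] * dx
            np.add.at(f, self.bond_j, fv)
            np.add.at(f, self.bond_i, -fv)
        sig, eps, q = self._interp(state)
        sc = self.softcore
        for pairs, lam in (
            (self.pairs_plain, 1.0),
            (self.pairs_insert, state.lambda_sterics_insert),
            (self.pairs_delete, state.lambda_sterics_delete),
        ):
            if not len(pairs):
                continue
            dx, r = self._pair_geometry(positions, pairs)
            mask = np.ones(len(r), bool) if self.cutoff is None else (r < self.cutoff)
            i, j = pairs[mask, 0], pairs[mask, 1]
            rr, dd = r[mask], dx[mask]
            s_ij = 0.5 * (sig[i] + sig[j])
            e_ij = np.sqrt(eps[i] * eps[j])
            if lam == 1.0:
                with np.errstate(divide="ignore", over="ignore"):
                    x6 = (s_ij / rr) ** 6
                    fmag = 24.0 * e_ij * (2.0 * x6 * x6 - x6) / rr  # -dU/dr
            elif lam > 0.0:
                fmag = softcore_sterics_force(rr, s_ij, e_ij, lam, sc)
            else:
                fmag = np.zeros_like(rr)
            qq = q[i] * q[j]
            with np.errstate(divide="ignore"):
                fmag = fmag + COULOMB_KJ * qq / rr ** 2
            fv = (fmag / rr)[:, None] * dd  # on atom j along +dx
            np.add.at(f, j, fv)
            np.add.at(f, i, -fv)
        return f


def potential_energy(
    hybrid: HybridTopology,
    positions: np.ndarray,
    state: LambdaState,
    box: float | None = None,
    cutoff: float | None = None,
    sc: SoftcoreParameters = SoftcoreParameters(),
    environment: Molecule | None = None,
) -> float:
    """Total potential energy (kJ/mol) of a hybrid system at one λ-state."""
    positions = np.asarray(positions, float)
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    system = AlchemicalSystem.from_hybrid(hybrid, environment, box, cutoff, sc)
    return system.energy(positions, state)
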