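"""Deterministic toy-system generators with known ground truth.

These are the desk-scale stand-ins for protein–ligand systems: harmonic
oscillator ladders (exact Gaussian sampling, analytic free energies),
Lennard-Jones dimers and lattice fluids, ideal gases, solvated-box
construction with ion counts, synthetic perturbation networks, and a small
catalogue of toy mutation pairs with hand-verified atom mappings.  Every
generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, STANDARD_MASSES
from .estimators import EdgeEstimate, ReducedPotentialMatrix
from .molecules import Atom, AtomMapping, Molecule
from .network import PerturbationNetwork

__all__ = [
    "HarmonicLadder",
    "make_harmonic_ladder",
    "HarmonicState",
    "make_lj_dimer",
    "make_lj_fluid",
    "make_ideal_gas",
    "SolvatedBox",
    "build_solvated_box",
    "SyntheticNetworkSpec",
    "make_synthetic_network",
    "make_toy_mutation_pair",
    "make_water",
    "make_methane",
    "TOY_MUTATION_KINDS",
]


# ---------------------------------------------------------------------------
# harmonic ladder: the analytic workhorse for estimator tests
# ---------------------------------------------------------------------------

@dataclass
class HarmonicLadder:
    """Exact samples from K 1-D harmonic states u_k(x) = k_k x^2 / 2
    (reduced units), with the analytic reduced free energies attached:
    f_k = -ln sqrt(2 pi / k_k), so Δf_ij = ½ ln(k_j / k_i)."""

    k_values: np.ndarray
    samples: list[np.ndarray]
    matrix: ReducedPotentialMatrix
    analytic_f: np.ndarray = field(init=False)

    def __post_init__(self):
        f = -0.5 * np.log(2.0 * np.pi / self.k_values)
        self.analytic_f = f - f[0]

    @property
    def analytic_delta_f(self) -> float:
        return float(self.analytic_f[-1])


def make_harmonic_ladder(k_values, n_samples: int, seed: int) -> HarmonicLadder:
    """Draw exact Gaussian samples per state and fill u_kn directly."""
    k = np.asarray(k_values, float)
    if np.any(k <= 0):
        raise ValueError("all spring constants must be > 0")
    rng = np.random.default_rng(seed)
    samples = [rng.normal(0.0, 1.0 / math.sqrt(kk), size=n_samples) for kk in k]
    x = np.concatenate(samples)
    u_kn = 0.5 * k[:, None] * x[None, :] ** 2
    matrix = ReducedPotentialMatrix(u_kn=u_kn, N_k=np.full(len(k), n_samples, int))
    return HarmonicLadder(k, samples, matrix)


class HarmonicState:
    """A 1-particle harmonic thermodynamic state in reduced units (kT = 1,
    m = 1), exposing the interface the replica-exchange driver needs."""

    def __init__(self, spring_k: float):
        self.spring_k = float(spring_k)
        self.kT = 1.0
        self.system = _HarmonicSystemShim()

    def energy(self, x, box=None) -> float:
        return float(0.5 * self.spring_k * np.sum(np.asarray(x) ** 2))

    def forces(self, x) -> np.ndarray:
        return -self.spring_k * np.asarray(x, float)

    def reduced_potential(self, x, box=None) -> float:
        return self.energy(x)

    def initial_velocities(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((1, 1))

    def propagate(self, x, v, rng, n_steps, config, box=None):
        from .sampler import langevin_step

        x = np.asarray(x, float)
        v = np.asarray(v, float)
        f = self.forces(x)
        dt = getattr(config, "timestep_ps", 0.05)
        friction = getattr(config, "friction_per_ps", 1.0)
        for _ in range(n_steps):
            x, v, f = langevin_step(x, v, f, self.forces, np.ones(len(x)),
                                    dt, friction, self.kT, rng)
        return x, v, box


class _HarmonicSystemShim:
    box = None
    masses = np.ones(1)
    n_atoms = 1


# ---------------------------------------------------------------------------
# Lennard-Jones / ideal-gas toys
# ---------------------------------------------------------------------------

def make_lj_dimer(sigma: float = 0.34, epsilon: float = 1.0,
                  separation: float | None = None, bonded: bool = False) -> Molecule:
    """Two LJ beads on the x axis; analytic minimum at r = 2^(1/6) sigma."""
    r = separation if separation is not None else sigma
    atoms = [
        Atom(0, "Ar", 39.948, 0.0, sigma, epsilon, (0.0, 0.0, 0.0)),
        Atom(1, "Ar", 39.948, 0.0, sigma, epsilon, (r, 0.0, 0.0)),
    ]
    bonds = {(0, 1)} if bonded else set()
    return Molecule("lj_dimer", atoms, bonds)


def make_lj_fluid(n_particles: int, box: float, sigma: float = 0.34,
                  epsilon: float = 0.5, jitter: float = 0.0,
                  seed: int = 0) -> Molecule:
    """n inert LJ beads on a cubic lattice inside a periodic box (edge nm);
    optional uniform jitter breaks lattice symmetry deterministically."""
    per_side = math.ceil(n_particles ** (1.0 / 3.0))
    spacing = box / per_side
    rng = np.random.default_rng(seed)
    atoms = []
    i = 0
    for a in range(per_side):
        for b in range(per_side):
            for c in range(per_side):
                if i >= n_particles:
                    break
                pos = (np.array([a, b, c]) + 0.5) * spacing
                if jitter > 0:
                    pos = pos + rng.uniform(-jitter, jitter, 3)
                atoms.append(Atom(i, "Ar", 39.948, 0.0, sigma, epsilon, tuple(pos)))
                i += 1
    return Molecule("lj_fluid", atoms)


def make_ideal_gas(n_particles: int, box: float, seed: int = 0) -> Molecule:
    """Non-interacting point particles (epsilon = 0, q = 0) in a box."""
    rng = np.random.default_rng(seed)
    atoms = [
        Atom(i, "Ar", 39.948, 0.0, 0.3, 0.0, tuple(rng.uniform(0, box, 3)))
        for i in range(n_particles)
    ]
    return Molecule("ideal_gas", atoms)


# ---------------------------------------------------------------------------
# solvated-box construction
# ---------------------------------------------------------------------------

@dataclass
class SolvatedBox:
    """Cubic box metadata: edge length, ion counts, and total charge."""

    box_edge_nm: float
    n_ion_pairs: int
    n_sodium: int
    n_chloride: int
    solute_charge: float

    @property
    def total_charge(self) -> float:
        return self.solute_charge + self.n_sodium - self.n_chloride

    @property
    def volume_nm3(self) -> float:
        return self.box_edge_nm ** 3


def build_solvated_box(
    solute_extent_nm: float,
    buffer_nm: float = 0.9,
    ionic_strength_mM: float = 150.0,
    neutralizing_charge: float = 0.0,
    cutoff_nm: float | None = None,
) -> SolvatedBox:
    """Box edge = solute extent + 2 * buffer; NaCl pairs from the molar
    concentration (round-half-up), then extra counterions cancel the solute
    charge exactly so the total system charge is zero."""
    if buffer_nm <= 0:
        raise ValueError("buffer must be > 0")
    edge = solute_extent_nm + 2.0 * buffer_nm
    volume_litres = edge ** 3 * 1e-24
    pairs_exact = ionic_strength_mM / 1000.0 * AVOGADRO * volume_litres
    n_pairs = int(math.floor(pairs_exact + 0.5))
    n_na = n_pairs + max(0, int(round(-neutralizing_charge)))
    n_cl = n_pairs + max(0, int(round(neutralizing_charge)))
    if cutoff_nm is not None and edge <= 2.0 * cutoff_nm:
        import warnings

        warnings.warn(
            f"box edge {edge:.3f} nm will violate the minimum-image condition "
            f"for cutoff {cutoff_nm} nm", RuntimeWarning,
        )
    return SolvatedBox(edge, n_pairs, n_na, n_cl, neutralizing_charge)


# ---------------------------------------------------------------------------
# synthetic perturbation networks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNetworkSpec:
    """Ground-truth network recipe.  Defaults mimic a lead-optimization
    series: true ΔGs uniform on [-12, -6] kcal/mol; ``exp_noise_sigma``
    optionally perturbs the reported experimental values (0.64 kcal/mol is a
    typical experimental reproducibility)."""

    n_nodes: int = 10
    topology: str = "dense"  # star | chain | dense | random
    dg_range: tuple[float, float] = (-12.0, -6.0)
    edge_noise_sigma: float = 0.0
    exp_noise_sigma: float = 0.0
    random_p: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("need at least 2 ligands")
        if self.edge_noise_sigma < 0 or self.exp_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.topology not in ("star", "chain", "dense", "random"):
            raise ValueError(f"unknown topology {self.topology!r}")


def make_synthetic_network(
    spec: SyntheticNetworkSpec,
) -> tuple[PerturbationNetwork, dict[str, float]]:
    """Generate a connected ligand network with known node ΔGs.

    Edge ΔΔG = true difference + N(0, edge_noise_sigma); experimental ΔGs
    are the true values, optionally perturbed by N(0, exp_noise_sigma).
    Random topologies are drawn until connected (spanning chain guaranteed).
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"lig{i:02d}" for i in range(spec.n_nodes)]
    lo, hi = spec.dg_range
    true_dg = {x: float(rng.uniform(lo, hi)) for x in names}

    pairs: list[tuple[int, int]] = []
    n = spec.n_nodes
    if spec.topology == "star":
        pairs = [(0, i) for i in range(1, n)]
    elif spec.topology == "chain":
        pairs = [(i, i + 1) for i in range(n - 1)]
    elif spec.topology == "dense":
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:  # random: spanning chain plus Bernoulli extras keeps it connected
        pairs = [(i, i + 1) for i in range(n - 1)]
        for i in range(n):
            for j in range(i + 2, n):
                if rng.random() < spec.random_p:
                    pairs.append((i, j))

    edges = []
    for i, j in pairs:
        a, b = names[i], names[j]
        noise = rng.normal(0.0, spec.edge_noise_sigma) if spec.edge_noise_sigma else 0.0
        edges.append(EdgeEstimate(
            a, b, true_dg[b] - true_dg[a] + noise,
            uncertainty=spec.edge_noise_sigma,
        ))
    experimental = {
        x: true_dg[x] + (rng.normal(0.0, spec.exp_noise_sigma)
                         if spec.exp_noise_sigma else 0.0)
        for x in names
    }
    net = PerturbationNetwork(edges, experimental, name=f"synthetic-{spec.topology}")
    return net, true_dg


# ---------------------------------------------------------------------------
# small molecules and toy mutation pairs
# ---------------------------------------------------------------------------

def make_water() -> Molecule:
    """A TIP3P-like water (O 15.999 amu, H 1.008 amu); used by the
    hydrogen-mass-repartitioning checks."""
    atoms = [
        Atom(0, "O", STANDARD_MASSES["O"], -0.834, 0.31507, 0.6364, (0.0, 0.0, 0.0)),
        Atom(1, "H", STANDARD_MASSES["H"], 0.417, 0.1, 0.0, (0.09572, 0.0, 0.0)),
        Atom(2, "H", STANDARD_MASSES["H"], 0.417, 0.1, 0.0, (-0.024, 0.0927, 0.0)),
    ]
    bp = {(0, 1): (40000.0, 0.09572), (0, 2): (40000.0, 0.09572)}
    return Molecule("water", atoms, {(0, 1), (0, 2)}, bp)


def make_methane() -> Molecule:
    """CH4 with tetrahedral geometry; four hydrogens at 4 amu would drain
    12.011 - 4*(4 - 1.008) < 0 amu, triggering the repartitioning refusal."""
    d = 0.1087 / math.sqrt(3.0)
    verts = [(d, d, d), (d, -d, -d), (-d, d, -d), (-d, -d, d)]
    atoms = [Atom(0, "C", STANDARD_MASSES["C"], -0.4, 0.34, 0.45, (0.0, 0.0, 0.0))]
    atoms += [
        Atom(i + 1, "H", STANDARD_MASSES["H"], 0.1, 0.25, 0.065, v)
        for i, v in enumerate(verts)
    ]
    bonds = {(0, i) for i in range(1, 5)}
    return Molecule("methane", atoms, bonds,
                    {b: (30000.0, 0.1087) for b in bonds})


def _ethane() -> Molecule:
    atoms = [
        Atom(0, "C", 12.011, -0.09, 0.34, 0.45, (0.0, 0.0, 0.0)),
        Atom(1, "C", 12.011, -0.09, 0.34, 0.45, (0.154, 0.0, 0.0)),
    ]
    h_offsets = [
        (-0.051, 0.099, 0.0), (-0.051, -0.050, 0.086), (-0.051, -0.050, -0.086),
    ]
    idx = 2
    for parent, sign in ((0, -1.0), (1, 1.0)):
        base = np.array(atoms[parent].position)
        for off in h_offsets:
            pos = base + sign * np.array(off)
            atoms.append(Atom(idx, "H", 1.008, 0.03, 0.26, 0.066, tuple(pos)))
            idx += 1
    bonds = {(0, 1), (0, 2), (0, 3), (0, 4), (1, 5), (1, 6), (1, 7)}
    bp = {b: ((25000.0, 0.154) if b == (0, 1) else (30000.0, 0.109)) for b in bonds}
    return Molecule("ethane", atoms, bonds, bp)


def _ethanol() -> Molecule:
    atoms = [
        Atom(0, "C", 12.011, -0.10, 0.34, 0.45, (0.0, 0.0, 0.0)),
        Atom(1, "C", 12.011, 0.15, 0.34, 0.45, (0.154, 0.0, 0.0)),
        Atom(2, "O", 15.999, -0.60, 0.30, 0.71, (0.205, 0.132, 0.0)),
    ]
    idx = 3
    for parent, sign, n_h, q in ((0, -1.0, 3, 0.03), (1, 1.0, 2, 0.05)):
        base = np.array(atoms[parent].position)
        offs = [(-0.051, 0.099, 0.0), (-0.051, -0.050, 0.086),
                (-0.051, -0.050, -0.086)][:n_h]
        for off in offs:
            pos = base + sign * np.array(off)
            atoms.append(Atom(idx, "H", 1.008, q, 0.26, 0.066, tuple(pos)))
            idx += 1
    atoms.append(Atom(idx, "H", 1.008, 0.40, 0.05, 0.0, (0.275, 0.115, 0.06)))
    bonds = {(0, 1), (1, 2), (0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (2, 8)}
    bp = {}
    for b in bonds:
        if b == (0, 1):
            bp[b] = (25000.0, 0.154)
        elif b == (1, 2):
            bp[b] = (28000.0, 0.141)
        elif b == (2, 8):
            bp[b] = (45000.0, 0.096)
        else:
            bp[b] = (30000.0, 0.109)
    return Molecule("ethanol", atoms, bonds, bp)


def _bead(name: str, sigma: float, epsilon: float, charge: float,
          element: str = "Ar") -> Molecule:
    return Molecule(name, [Atom(0, element, 39.948, charge, sigma, epsilon,
                                (0.0, 0.0, 0.0))])


def _two_beads(name: str, sigma: float, epsilon: float, charge2: float = 0.0) -> Molecule:
    atoms = [
        Atom(0, "Ar", 39.948, 0.0, sigma, epsilon, (0.0, 0.0, 0.0)),
        Atom(1, "Ar", 39.948, charge2, sigma, epsilon, (0.38, 0.0, 0.0)),
    ]
    return Molecule(name, atoms, {(0, 1)}, {(0, 1): (20000.0, 0.38)})


TOY_MUTATION_KINDS = (
    "identical",
    "ethane_ethanol",
    "bead_swap",
    "bead_growth",
    "neutral_charged",
)


def make_toy_mutation_pair(kind: str) -> tuple[Molecule, Molecule, AtomMapping]:
    """Catalogue of parameterized molecule pairs with hand-verified expected
    MCS mappings, the oracle data for mapping and hybrid tests."""
    if kind == "identical":
        a, b = _ethane(), _ethane()
        mapping = AtomMapping([(i, i) for i in range(a.n_atoms)], set(), set())
    elif kind == "ethane_ethanol":
        a, b = _ethane(), _ethanol()
        # heavy core: the C-C unit (ethanol's O is unique); hydrogens paired
        # in index order on each mapped carbon -> ethane H7 and ethanol's
        # hydroxyl branch stay unique
        mapping = AtomMapping(
            [(0, 0), (1, 1), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7)],
            unique_a={7}, unique_b={2, 8},
        )
    elif kind == "bead_swap":
        a = _bead("beadA", 0.34, 0.50, 0.0)
        b = _bead("beadB", 0.30, 0.80, 0.0)
        mapping = AtomMapping([(0, 0)], set(), set())
    elif kind == "bead_growth":
        a = _bead("bead1", 0.34, 0.50, 0.0)
        b = _two_beads("bead2", 0.34, 0.50)
        mapping = AtomMapping([(0, 0)], set(), {1})
    elif kind == "neutral_charged":
        a = _bead("neutral", 0.32, 0.60, 0.0, element="Na")
        b = _bead("charged", 0.32, 0.60, 1.0, element="Na")
        mapping = AtomMapping([(0, 0)], set(), set())
    else:
        raise ValueError(
            f"unknown toy mutation kind {kind!r}; available: {TOY_MUTATION_KINDS}"
        )
    return a, b, mapping
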