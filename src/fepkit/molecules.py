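"""Molecule representation, atom mapping, and dual-topology hybrids.

A relative free-energy transformation between two congeneric ligands A and B
is set up by (i) finding the maximum common substructure (MCS) — the largest
shared connected fragment — which defines the *core*, (ii) building a hybrid
molecule that contains the union of both ligands' atoms, where core atoms
carry two parameter sets (state A and state B) and atoms unique to one
endpoint appear or disappear along the coupling parameter, and (iii)
repartitioning hydrogen masses so a 4 fs timestep is stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import STANDARD_MASSES

__all__ = [
    "Atom",
    "Molecule",
    "AtomMapping",
    "HybridAtom",
    "HybridTopology",
    "find_maximum_common_substructure",
    "enumerate_common_cores",
    "build_hybrid_topology",
    "repartition_hydrogen_mass",
    "kabsch_superpose",
]


@dataclass(frozen=True)
class Atom:
    """One atom with the nonbonded parameters the alchemical model consumes.

    Units: mass amu, charge e, lj_sigma nm, lj_epsilon kJ/mol, position nm.
    """

    index: int
    element: str
    mass: float
    charge: float = 0.0
    lj_sigma: float = 0.3
    lj_epsilon: float = 0.0
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.index < 0:
            raise ValueError(f"atom index must be >= 0, got {self.index}")
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be > 0, got {self.mass}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.index}: LJ parameters must be >= 0")
        if not self.element or not self.element[0].isalpha():
            raise ValueError(f"atom {self.index}: invalid element {self.element!r}")


@dataclass
class Molecule:
    """An ordered list of atoms plus an undirected bond graph.

    ``bond_params`` optionally maps a bond (i, j), i < j, to a harmonic
    (force constant kJ/mol/nm^2, equilibrium length nm) pair used by the
    bonded part of the potential; bonds without parameters default to the
    input geometry at a stiff generic force constant.
    """

    name: str
    atoms: list[Atom]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    bond_params: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        norm = set()
        for b in self.bonds:
            i, j = b
            if i == j:
                raise ValueError(f"{self.name}: self-bond on atom {i}")
            if not (0 <= i < len(self.atoms) and 0 <= j < len(self.atoms)):
                raise ValueError(f"{self.name}: bond {b} references missing atom")
            norm.add((min(i, j), max(i, j)))
        self.bonds = norm
        self.bond_params = {(min(i, j), max(i, j)): v for (i, j), v in self.bond_params.items()}

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def total_mass(self) -> float:
        return sum(a.mass for a in self.atoms)

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]

    def hydrogens_on(self, heavy: int) -> list[int]:
        adj = self.adjacency()
        return sorted(h for h in adj[heavy] if self.atoms[h].element == "H")


@dataclass
class AtomMapping:
    """Core atom pairing between two molecules plus the unique-atom sets."""

    core_pairs: list[tuple[int, int]]
    unique_a: set[int]
    unique_b: set[int]

    def validate(self, mol_a: Molecule, mol_b: Molecule) -> None:
        a_side = [p[0] for p in self.core_pairs]
        b_side = [p[1] for p in self.core_pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("core_pairs is not one-to-one")
        for i, j in self.core_pairs:
            if not (0 <= i < mol_a.n_atoms) or not (0 <= j < mol_b.n_atoms):
                raise ValueError(f"core pair ({i}, {j}) out of range")
        if set(a_side) | self.unique_a != set(range(mol_a.n_atoms)) or set(a_side) & self.unique_a:
            raise ValueError("core + unique_a does not partition molecule A")
        if set(b_side) | self.unique_b != set(range(mol_b.n_atoms)) or set(b_side) & self.unique_b:
            raise ValueError("core + unique_b does not partition molecule B")


@dataclass(frozen=True)
class HybridAtom:
    """A hybrid atom carrying both endpoint nonbonded parameter sets."""

    index: int
    element: str
    mass: float
    position: tuple[float, float, float]
    charge_a: float
    sigma_a: float
    epsilon_a: float
    charge_b: float
    sigma_b: float
    epsilon_b: float
    atom_class: str  # core | unique_old | unique_new


@dataclass
class HybridTopology:
    """Dual-topology hybrid: union of A and B atoms with per-state parameters."""

    name: str
    atoms: list[HybridAtom]
    bonds: set[tuple[int, int]]
    bond_params: dict[tuple[int, int], tuple[float, float]]
    index_in_a: dict[int, int]  # hybrid index -> original A index (core + unique_old)
    index_in_b: dict[int, int]  # hybrid index -> original B index (core + unique_new)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom_classes(self) -> list[str]:
        return [a.atom_class for a in self.atoms]

    def endpoint_molecule(self, state: str) -> Molecule:
        """Project the hybrid onto one physical endpoint ('A' or 'B')."""
        keep = self.index_in_a if state == "A" else self.index_in_b
        order = sorted(keep, key=lambda h: keep[h])
        remap = {h: n for n, h in enumerate(order)}
        atoms = []
        for h in order:
            ha = self.atoms[h]
            q, s, e = (
                (ha.charge_a, ha.sigma_a, ha.epsilon_a)
                if state == "A"
                else (ha.charge_b, ha.sigma_b, ha.epsilon_b)
            )
            atoms.append(
                Atom(remap[h], ha.element, ha.mass, q, s, e, ha.position)
            )
        bonds = set()
        bond_params = {}
        for (i, j) in self.bonds:
            if i in remap and j in remap:
                b = (min(remap[i], remap[j]), max(remap[i], remap[j]))
                bonds.add(b)
                if (i, j) in self.bond_params:
                    bond_params[b] = self.bond_params[(i, j)]
        return Molecule(f"{self.name}:{state}", atoms, bonds, bond_params)


def kabsch_superpose(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of `moving` onto `target`.

    Returns (rotation matrix, translation, ssd) such that
    ``moving @ R.T + t`` best fits target; ssd is the summed squared
    residual distance after the fit.
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape or moving.ndim != 2:
        raise ValueError("point sets must have identical (n, 3) shapes")
    cm, ct = moving.mean(axis=0), target.mean(axis=0)
    if len(moving) == 1:
        return np.eye(3), ct - cm, 0.0
    import warnings

    with warnings.catch_warnings():
        # collinear point sets leave a rotation axis free; any optimal fit is fine
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(target - ct, moving - cm)
    R = rot.as_matrix()
    fitted = (moving - cm) @ R.T + ct
    ssd = float(np.sum((fitted - target) ** 2))
    return R, ct - cm @ R.T, ssd


def _heavy_graph(mol: Molecule) -> tuple[list[int], dict[int, set[int]]]:
    heavy = mol.heavy_indices()
    hset = set(heavy)
    adj = {i: {j for j in nbrs if j in hset} for i, nbrs in mol.adjacency().items() if i in hset}
    return heavy, adj


def enumerate_common_cores(mol_a: Molecule, mol_b: Molecule) -> list[list[tuple[int, int]]]:
    """Enumerate every maximal-size common connected induced heavy-atom
    subgraph mapping between two molecules.

    Matching rule: elements equal; a bond exists between two mapped atoms in
    A iff it exists between their images in B (bond order ignored).  Exact
    branch-and-bound search; intended for small-molecule graphs.
    """
    heavy_a, adj_a = _heavy_graph(mol_a)
    heavy_b, adj_b = _heavy_graph(mol_b)
    if not heavy_a or not heavy_b:
        return [[]]

    best: list[list[tuple[int, int]]] = [[]]

    def record(mapping: dict[int, int]) -> None:
        if not mapping:
            return
        pairs = sorted(mapping.items())
        if len(pairs) > len(best[0]):
            best.clear()
            best.append(pairs)
        elif len(pairs) == len(best[0]) and pairs not in best:
            best.append(pairs)

    elem_a = {i: mol_a.atoms[i].element for i in heavy_a}
    elem_b = {j: mol_b.atoms[j].element for j in heavy_b}

    def extend(mapping: dict[int, int], used_b: set[int], excluded: set[int]) -> None:
        if mapping:
            frontier = sorted(
                a
                for a in set().union(*(adj_a[m] for m in mapping))
                if a not in mapping and a not in excluded
            )
        else:
            frontier = [a for a in heavy_a if a not in excluded]
        # bound: even mapping every remaining candidate cannot beat the best
        remaining = min(
            len([a for a in heavy_a if a not in mapping and a not in excluded]),
            len(heavy_b) - len(used_b),
        )
        if len(mapping) + remaining < len(best[0]):
            return
        if not frontier:
            record(mapping)
            return
        a = frontier[0]
        mapped_a = list(mapping)
        for b in sorted(j for j in heavy_b if j not in used_b and elem_b[j] == elem_a[a]):
            # induced consistency; B-side connectivity follows because a
            # frontier atom always touches the mapped set
            if all((m in adj_a[a]) == (mapping[m] in adj_b[b]) for m in mapped_a):
                mapping[a] = b
                extend(mapping, used_b | {b}, excluded)
                del mapping[a]
        extend(mapping, used_b, excluded | {a})

    extend({}, set(), set())
    return best


def _attach_hydrogens(
    mol_a: Molecule, mol_b: Molecule, heavy_pairs: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Pair hydrogens on mapped heavy atoms, in index order; excess stays unique."""
    pairs = list(heavy_pairs)
    for a, b in heavy_pairs:
        ha = mol_a.hydrogens_on(a)
        hb = mol_b.hydrogens_on(b)
        pairs.extend(zip(ha, hb))
    return pairs


def _core_ssd(mol_a: Molecule, mol_b: Molecule, pairs: list[tuple[int, int]]) -> float:
    pa = np.array([mol_a.atoms[i].position for i, _ in pairs])
    pb = np.array([mol_b.atoms[j].position for _, j in pairs])
    _, _, ssd = kabsch_superpose(pb, pa)
    return ssd


def find_maximum_common_substructure(mol_a: Molecule, mol_b: Molecule) -> AtomMapping:
    """Maximum common substructure mapping between two molecules.

    Heavy atoms are matched by exact search for the largest common connected
    induced subgraph (elements must match, bond order is ignored); hydrogens
    on mapped heavy atoms are then paired in index order.  Ties between
    equal-size cores are broken by the smallest summed squared inter-atom
    distance after rigid superposition on the candidate core, then by
    lexicographic order, so the result is deterministic.  An empty core is a
    valid result.
    """
    if mol_a.n_atoms == 0 or mol_b.n_atoms == 0:
        raise ValueError("both molecules must be non-empty")
    candidates = enumerate_common_cores(mol_a, mol_b)
    if candidates == [[]]:
        chosen: list[tuple[int, int]] = []
    elif len(candidates) == 1:
        chosen = candidates[0]
    else:
        keyed = sorted(
            candidates, key=lambda c: (round(_core_ssd(mol_a, mol_b, c), 12), c)
        )
        chosen = keyed[0]
    pairs = _attach_hydrogens(mol_a, mol_b, chosen)
    mapped_a = {p[0] for p in pairs}
    mapped_b = {p[1] for p in pairs}
    return AtomMapping(
        core_pairs=sorted(pairs),
        unique_a=set(range(mol_a.n_atoms)) - mapped_a,
        unique_b=set(range(mol_b.n_atoms)) - mapped_b,
    )


def build_hybrid_topology(
    mol_a: Molecule, mol_b: Molecule, mapping: AtomMapping
) -> HybridTopology:
    """Construct the dual-topology hybrid of A and B under a core mapping.

    Core atoms carry both endpoint parameter sets; atoms unique to A keep
    their A parameters and are decoupled in state B (charge 0, epsilon 0,
    sigma retained so softcore distances stay defined); symmetrically for
    atoms unique to B.  Initial coordinates of unique-B atoms come from
    molecule B after rigid superposition of B's core onto A's core.
    """
    mapping.validate(mol_a, mol_b)
    core_a = [p[0] for p in mapping.core_pairs]
    b_for_a = dict(mapping.core_pairs)

    # rigid placement of the B endpoint onto A's frame
    if len(mapping.core_pairs) >= 1:
        pa = np.array([mol_a.atoms[i].position for i in core_a])
        pb = np.array([mol_b.atoms[b_for_a[i]].position for i in core_a])
        R, t, _ = kabsch_superpose(pb, pa)
        b_pos = mol_b.positions() @ R.T + t
    else:
        b_pos = mol_b.positions()

    atoms: list[HybridAtom] = []
    a_to_h: dict[int, int] = {}
    b_to_h: dict[int, int] = {}

    for i in sorted(core_a):
        j = b_for_a[i]
        aa, ab = mol_a.atoms[i], mol_b.atoms[j]
        h = len(atoms)
        a_to_h[i], b_to_h[j] = h, h
        atoms.append(
            HybridAtom(h, aa.element, aa.mass, aa.position,
                       aa.charge, aa.lj_sigma, aa.lj_epsilon,
                       ab.charge, ab.lj_sigma, ab.lj_epsilon, "core")
        )
    for i in sorted(mapping.unique_a):
        aa = mol_a.atoms[i]
        h = len(atoms)
        a_to_h[i] = h
        atoms.append(
            HybridAtom(h, aa.element, aa.mass, aa.position,
                       aa.charge, aa.lj_sigma, aa.lj_epsilon,
                       0.0, aa.lj_sigma, 0.0, "unique_old")
        )
    for j in sorted(mapping.unique_b):
        ab = mol_b.atoms[j]
        h = len(atoms)
        b_to_h[j] = h
        atoms.append(
            HybridAtom(h, ab.element, ab.mass, tuple(b_pos[j]),
                       0.0, ab.lj_sigma, 0.0,
                       ab.charge, ab.lj_sigma, ab.lj_epsilon, "unique_new")
        )

    bonds: set[tuple[int, int]] = set()
    bond_params: dict[tuple[int, int], tuple[float, float]] = {}
    for (i, j) in sorted(mol_a.bonds):
        b = (min(a_to_h[i], a_to_h[j]), max(a_to_h[i], a_to_h[j]))
        bonds.add(b)
        if (i, j) in mol_a.bond_params:
            bond_params[b] = mol_a.bond_params[(i, j)]
    for (i, j) in sorted(mol_b.bonds):
        b = (min(b_to_h[i], b_to_h[j]), max(b_to_h[i], b_to_h[j]))
        if b not in bonds:
            bonds.add(b)
            if (i, j) in mol_b.bond_params:
                bond_params[b] = mol_b.bond_params[(i, j)]

    return HybridTopology(
        name=f"{mol_a.name}~{mol_b.name}",
        atoms=atoms,
        bonds=bonds,
        bond_params=bond_params,
        index_in_a={h: i for i, h in a_to_h.items()},
        index_in_b={h: j for j, h in b_to_h.items()},
    )


def repartition_hydrogen_mass(
    mol: Molecule, hydrogen_mass: float = 4.0, min_heavy_mass: float = 1.008
) -> Molecule:
    """Shift mass from heavy atoms to their bonded hydrogens (HMR).

    Every hydrogen is set to ``hydrogen_mass`` (default 4 amu) and the bonded
    heavy atom loses the transferred amount, conserving total mass exactly.
    Refuses if any heavy atom would end up with non-positive mass, or below
    ``min_heavy_mass`` (default one proton): a methane carbon at hydrogen
    mass 4 would keep only 0.043 amu, which defeats the purpose of the
    repartitioning (the heavy-atom modes would become the stiffest ones).
    """
    adj = mol.adjacency()
    transfer: dict[int, float] = {}
    new_h_mass: dict[int, float] = {}
    for a in mol.atoms:
        if a.element != "H":
            continue
        heavies = [n for n in adj[a.index] if mol.atoms[n].element != "H"]
        if len(heavies) != 1:
            raise ValueError(
                f"hydrogen {a.index} bonded to {len(heavies)} heavy atoms; "
                "repartitioning requires exactly one"
            )
        delta = hydrogen_mass - a.mass
        transfer[heavies[0]] = transfer.get(heavies[0], 0.0) + delta
        new_h_mass[a.index] = hydrogen_mass

    new_atoms = []
    for a in mol.atoms:
        if a.index in new_h_mass:
            new_atoms.append(replace(a, mass=new_h_mass[a.index]))
        elif a.index in transfer:
            m = a.mass - transfer[a.index]
            if m < min_heavy_mass:
                raise ValueError(
                    f"repartitioning would give atom {a.index} ({a.element}) "
                    f"mass {m:.4f} amu < {min_heavy_mass} amu; lower hydrogen_mass"
                )
            new_atoms.append(replace(a, mass=m))
        else:
            new_atoms.append(a)
    return Molecule(mol.name, new_atoms, set(mol.bonds), dict(mol.bond_params))
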