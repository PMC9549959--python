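"""File interfaces: SDF V2000 molecules with a parameter sidecar, edge and
experimental CSV tables, hybrid-topology text dumps, YAML configs, and run
manifests.

The sidecar is a CSV with columns ``atom_index, mass_amu, charge_e,
sigma_nm, epsilon_kj_mol`` joined to the SDF by 0-based atom index; charge
and parameter *derivation* is out of scope, they are inputs here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import EdgeEstimate, ReducedPotentialMatrix
from .molecules import Atom, HybridTopology, Molecule
from .network import PerturbationNetwork

__all__ = [
    "read_sdf_v2000",
    "read_molecule",
    "write_sdf_v2000",
    "write_parameter_sidecar",
    "write_hybrid",
    "read_edges_csv",
    "write_edges_csv",
    "read_experimental_csv",
    "load_config",
    "RunManifest",
    "write_u_kn",
    "read_u_kn",
]

EDGE_COLUMNS = ["ligand_a", "ligand_b", "ddG_kcal", "uncertainty_kcal"]


class ParseError(ValueError):
    pass


def read_sdf_v2000(path) -> tuple[str, list[tuple[str, tuple[float, float, float]]], set[tuple[int, int]]]:
    """Parse a minimal SDF/MOL V2000 block: name, atoms (element, position
    in nm — SDF coordinates are Å and are converted), bonds (0-based)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4:
        raise ParseError(f"{path}: truncated SDF (needs 4 header lines)")
    name = lines[0].strip() or Path(path).stem
    counts = lines[3]
    try:
        n_atoms, n_bonds = int(counts[0:3]), int(counts[3:6])
    except ValueError as err:
        raise ParseError(f"{path}: malformed counts line 4: {counts!r}") from err
    atoms = []
    for i in range(n_atoms):
        ln = lines[4 + i]
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            element = ln[31:34].strip()
        except (ValueError, IndexError) as err:
            raise ParseError(f"{path}: bad atom line {5 + i}: {ln!r}") from err
        atoms.append((element, (x * 0.1, y * 0.1, z * 0.1)))
    bonds = set()
    for i in range(n_bonds):
        ln = lines[4 + n_atoms + i]
        try:
            a, b = int(ln[0:3]) - 1, int(ln[3:6]) - 1
        except (ValueError, IndexError) as err:
            raise ParseError(f"{path}: bad bond line {5 + n_atoms + i}: {ln!r}") from err
        bonds.add((min(a, b), max(a, b)))
    return name, atoms, bonds


def read_molecule(path, parameter_sidecar) -> Molecule:
    """SDF V2000 structure + per-atom parameter table -> Molecule."""
    name, raw_atoms, bonds = read_sdf_v2000(path)
    params = pd.read_csv(parameter_sidecar)
    required = {"atom_index", "mass_amu", "charge_e", "sigma_nm", "epsilon_kj_mol"}
    missing = required - set(params.columns)
    if missing:
        raise ParseError(f"{parameter_sidecar}: missing columns {sorted(missing)}")
    params = params.set_index("atom_index")
    atoms = []
    for i, (element, pos) in enumerate(raw_atoms):
        if i not in params.index:
            raise ParseError(f"{parameter_sidecar}: no parameter row for atom index {i}")
        row = params.loc[i]
        atoms.append(Atom(i, element, float(row.mass_amu), float(row.charge_e),
                          float(row.sigma_nm), float(row.epsilon_kj_mol), pos))
    return Molecule(name, atoms, bonds)


def write_sdf_v2000(mol: Molecule, path) -> None:
    lines = [mol.name, "  fepkit", "", f"{mol.n_atoms:>3d}{len(mol.bonds):>3d}"
             "  0  0  0  0  0  0  0  0999 V2000"]
    for a in mol.atoms:
        x, y, z = (c * 10.0 for c in a.position)  # nm -> Å
        lines.append(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {a.element:<3s}"
                     " 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j in sorted(mol.bonds):
        lines.append(f"{i + 1:>3d}{j + 1:>3d}  1  0  0  0  0")
    lines += ["M  END", "$$$$"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_parameter_sidecar(mol: Molecule, path) -> None:
    pd.DataFrame({
        "atom_index": [a.index for a in mol.atoms],
        "mass_amu": [a.mass for a in mol.atoms],
        "charge_e": [a.charge for a in mol.atoms],
        "sigma_nm": [a.lj_sigma for a in mol.atoms],
        "epsilon_kj_mol": [a.lj_epsilon for a in mol.atoms],
    }).to_csv(path, index=False)


def write_hybrid(hybrid: HybridTopology, path) -> None:
    """Columnar text dump of the hybrid: both endpoint parameter sets per
    atom, the atom class, and the union bond list."""
    out = ["# fepkit hybrid topology",
           f"# name {hybrid.name}",
           "index element class mass_amu x_nm y_nm z_nm "
           "chargeA_e sigmaA_nm epsilonA_kj chargeB_e sigmaB_nm epsilonB_kj"]
    for a in hybrid.atoms:
        x, y, z = a.position
        out.append(
            f"{a.index} {a.element} {a.atom_class} {a.mass:.6f} "
            f"{x:.6f} {y:.6f} {z:.6f} "
            f"{a.charge_a:.6f} {a.sigma_a:.6f} {a.epsilon_a:.6f} "
            f"{a.charge_b:.6f} {a.sigma_b:.6f} {a.epsilon_b:.6f}"
        )
    out.append("# bonds i j")
    for i, j in sorted(hybrid.bonds):
        out.append(f"bond {i} {j}")
    Path(path).write_text("\n".join(out) + "\n")


def read_edges_csv(path, log=None) -> PerturbationNetwork:
    """Edge table -> network skeleton.  Columns: ligand_a, ligand_b,
    ddG_kcal, optional uncertainty_kcal and target.  Duplicate edges (same
    pair, either direction) are kept and flagged."""
    df = pd.read_csv(path)
    missing = {"ligand_a", "ligand_b", "ddG_kcal"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    edges = []
    seen = set()
    for r, row in df.iterrows():
        try:
            ddg = float(row["ddG_kcal"])
        except (TypeError, ValueError) as err:
            raise ParseError(f"{path}: row {r + 2}: non-numeric ddG "
                             f"{row['ddG_kcal']!r}") from err
        unc = float(row["uncertainty_kcal"]) if "uncertainty_kcal" in df.columns \
            and pd.notna(row.get("uncertainty_kcal")) else 0.0
        target = str(row["target"]) if "target" in df.columns \
            and pd.notna(row.get("target")) else None
        a, b = str(row["ligand_a"]), str(row["ligand_b"])
        key = frozenset((a, b))
        if key in seen and log is not None:
            log(f"duplicate edge {a}~{b} at row {r + 2} (kept)")
        seen.add(key)
        edges.append(EdgeEstimate(a, b, ddg, unc, target=target))
    return PerturbationNetwork(edges)


def write_edges_csv(network: PerturbationNetwork, path) -> None:
    pd.DataFrame({
        "ligand_a": [e.ligand_a for e in network.edges],
        "ligand_b": [e.ligand_b for e in network.edges],
        "ddG_kcal": [e.ddg for e in network.edges],
        "uncertainty_kcal": [e.uncertainty for e in network.edges],
        "target": [e.target for e in network.edges],
    }).to_csv(path, index=False)


def read_experimental_csv(path) -> dict[str, float]:
    """Columns: ligand, dG_kcal."""
    df = pd.read_csv(path)
    missing = {"ligand", "dG_kcal"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return {str(r.ligand): float(r.dG_kcal) for r in df.itertuples()}


def write_u_kn(matrix: ReducedPotentialMatrix, path) -> None:
    """Columnar text serialization: a JSON header line (N_k, temperature)
    then one `state sample u` row per entry."""
    header = {"N_k": [int(n) for n in matrix.N_k],
              "temperature_K": matrix.temperature}
    lines = ["# fepkit reduced potentials (dimensionless, kT)",
             "#HEADER " + json.dumps(header), "state sample u"]
    K, N = matrix.u_kn.shape
    for k in range(K):
        for n in range(N):
            lines.append(f"{k} {n} {float(matrix.u_kn[k, n])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_u_kn(path) -> ReducedPotentialMatrix:
    lines = Path(path).read_text().splitlines()
    header = None
    rows = []
    for ln in lines:
        if ln.startswith("#HEADER "):
            header = json.loads(ln[len("#HEADER "):])
        elif ln and not ln.startswith("#") and not ln.startswith("state"):
            k, n, u = ln.split()
            rows.append((int(k), int(n), float(u)))
    if header is None:
        raise ParseError(f"{path}: missing #HEADER line")
    N_k = np.array(header["N_k"], int)
    K, N = len(N_k), int(N_k.sum())
    u_kn = np.empty((K, N))
    for k, n, u in rows:
        u_kn[k, n] = u
    return ReducedPotentialMatrix(u_kn, N_k, header.get("temperature_K"))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


@dataclass
class RunManifest:
    """Everything needed to re-run a CLI invocation bit-identically."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    stages: list = field(default_factory=list)  # (name, status, seconds)
    version: str = "0.1.0"

    def add_input(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.inputs[str(path)] = digest

    def add_stage(self, name: str, status: str, seconds: float) -> None:
        self.stages.append({"name": name, "status": status,
                            "seconds": round(seconds, 3)})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
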