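"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive physics by brute force (direct
pairwise sums, exhaustive subgraph enumeration, definitional statistics) so
the package's vectorized implementations are checked against something that
shares no code with them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fepkit.alchemy import DEFAULT_BOND_K
from fepkit.constants import COULOMB_KJ
from fepkit.molecules import Molecule


def direct_sum_energy(mol: Molecule, box: float | None, cutoff: float | None) -> float:
    """Plain LJ + Coulomb + harmonic-bond energy by explicit double loop
    (minimum image, 1-2 exclusions, Lorentz-Berthelot combining)."""
    pos = mol.positions()
    n = mol.n_atoms
    excl = {(min(i, j), max(i, j)) for i, j in mol.bonds}
    U = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            d = pos[j] - pos[i]
            if box is not None:
                d = d - box * np.round(d / box)
            r = float(np.sqrt((d ** 2).sum()))
            if cutoff is not None and r >= cutoff:
                continue
            ai, aj = mol.atoms[i], mol.atoms[j]
            s = 0.5 * (ai.lj_sigma + aj.lj_sigma)
            e = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            if e > 0:
                U += 4.0 * e * ((s / r) ** 12 - (s / r) ** 6)
            if ai.charge * aj.charge != 0.0:
                U += COULOMB_KJ * ai.charge * aj.charge / r
    for (i, j) in sorted(mol.bonds):
        k, r0 = mol.bond_params.get(
            (i, j), (DEFAULT_BOND_K, float(np.linalg.norm(pos[j] - pos[i])))
        )
        d = pos[j] - pos[i]
        if box is not None:
            d = d - box * np.round(d / box)
        U += 0.5 * k * (float(np.sqrt((d ** 2).sum())) - r0) ** 2
    return U


def hybrid_endpoint_energy_oracle(hybrid, x, box, cutoff, which: str) -> float:
    """Endpoint energy of a hybrid by brute force: nonbonded terms over the
    atoms alive at that endpoint with that endpoint's parameters, plus ALL
    harmonic bond terms (dummy-atom bonds are λ-independent spectators)."""
    keep = hybrid.index_in_a if which == "A" else hybrid.index_in_b
    live = sorted(keep)
    excl = {(min(i, j), max(i, j)) for i, j in hybrid.bonds}
    U = 0.0
    for ii in range(len(live)):
        for jj in range(ii + 1, len(live)):
            i, j = live[ii], live[jj]
            if (i, j) in excl:
                continue
            d = x[j] - x[i]
            if box is not None:
                d = d - box * np.round(d / box)
            r = float(np.sqrt((d ** 2).sum()))
            if cutoff is not None and r >= cutoff:
                continue
            ai, aj = hybrid.atoms[i], hybrid.atoms[j]
            if which == "A":
                qi, si, ei = ai.charge_a, ai.sigma_a, ai.epsilon_a
                qj, sj, ej = aj.charge_a, aj.sigma_a, aj.epsilon_a
            else:
                qi, si, ei = ai.charge_b, ai.sigma_b, ai.epsilon_b
                qj, sj, ej = aj.charge_b, aj.sigma_b, aj.epsilon_b
            s = 0.5 * (si + sj)
            e = np.sqrt(ei * ej)
            if e > 0:
                U += 4.0 * e * ((s / r) ** 12 - (s / r) ** 6)
            if qi * qj != 0.0:
                U += COULOMB_KJ * qi * qj / r
    for (i, j) in sorted(hybrid.bonds):
        k, r0 = hybrid.bond_params[(i, j)]
        d = x[j] - x[i]
        if box is not None:
            d = d - box * np.round(d / box)
        U += 0.5 * k * (float(np.sqrt((d ** 2).sum())) - r0) ** 2
    return U


def brute_force_mcs_size(mol_a: Molecule, mol_b: Molecule) -> int:
    """Exhaustive maximum common connected induced heavy-subgraph size by
    enumerating all subsets of A's heavy atoms and all injections into B."""
    heavy_a = mol_a.heavy_indices()
    heavy_b = mol_b.heavy_indices()
    adj_a = mol_a.adjacency()
    adj_b = mol_b.adjacency()

    def connected(sub, adj):
        if not sub:
            return True
        seen = {sub[0]}
        stack = [sub[0]]
        ss = set(sub)
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w in ss and w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == len(sub)

    best = 0
    for size in range(len(heavy_a), 0, -1):
        if size <= best:
            break
        for sub in itertools.combinations(heavy_a, size):
            if not connected(list(sub), adj_a):
                continue
            for perm in itertools.permutations(heavy_b, size):
                if any(mol_a.atoms[a].element != mol_b.atoms[b].element
                       for a, b in zip(sub, perm)):
                    continue
                ok = True
                for (a1, b1), (a2, b2) in itertools.combinations(zip(sub, perm), 2):
                    if (a2 in adj_a[a1]) != (b2 in adj_b[b1]):
                        ok = False
                        break
                if ok:
                    best = max(best, size)
                    break
            if best == size:
                break
    return best


def kendall_tau_bruteforce(x, y) -> float:
    """Tau-b by O(n^2) pair counting with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (conc - disc) / denom if denom > 0 else np.nan


def spearman_bruteforce(x, y) -> float:
    """Spearman via explicit mid-ranks and the Pearson formula."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
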