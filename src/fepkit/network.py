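"""Perturbation-network analysis.

A relative free-energy campaign yields edge ΔΔG values on a graph of
ligands.  Per-ligand absolute ΔG predictions are recovered by weighted
least squares over the edges (weights 1/σ²), with the overall additive
constant fixed by shifting the predictions so their mean matches the mean
experimental ΔG of the same ligands.  Thermodynamic consistency is
diagnosed by cycle-closure errors — the signed sum of edge ΔΔGs around each
cycle of a fundamental cycle basis, which is zero for perfectly consistent
estimates.  Accuracy against experiment is summarized by MUE, RMSE, R²
(squared Pearson), Spearman ρ and Kendall τ-b per compound (not per edge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats as _stats

from .estimators import EdgeEstimate

__all__ = [
    "PerturbationNetwork",
    "AccuracyStats",
    "estimate_node_dGs",
    "cycle_closure_errors",
    "compute_accuracy_stats",
    "summarize_by_target",
]


@dataclass
class PerturbationNetwork:
    """Ligand graph: nodes with optional experimental ΔG (kcal/mol) and
    directed ΔΔG edges (kcal/mol)."""

    edges: list[EdgeEstimate]
    experimental: dict[str, float] = field(default_factory=dict)
    name: str = "network"

    def __post_init__(self):
        for lig in self.experimental:
            if lig not in self.nodes():
                raise ValueError(f"experimental value for unknown ligand {lig!r}")

    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.ligand_a)
            seen.setdefault(e.ligand_b)
        return list(seen)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes())
        for e in self.edges:
            if not g.has_edge(e.ligand_a, e.ligand_b):
                g.add_edge(e.ligand_a, e.ligand_b)
        return g


@dataclass
class AccuracyStats:
    """Per-compound accuracy summary (kcal/mol for mue/rmse)."""

    mue: float
    rmse: float
    r_squared: float
    spearman_rho: float
    kendall_tau: float
    n: int

    def __post_init__(self):
        if self.mue > self.rmse + 1e-12:
            raise ValueError("MUE cannot exceed RMSE")
        for name in ("spearman_rho", "kendall_tau"):
            v = getattr(self, name)
            if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared={self.r_squared} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "MUE_kcal_mol": self.mue,
            "RMSE_kcal_mol": self.rmse,
            "R2": self.r_squared,
            "spearman_rho": self.spearman_rho,
            "kendall_tau": self.kendall_tau,
            "n": self.n,
        }


def estimate_node_dGs(network: PerturbationNetwork) -> dict[str, float]:
    """Per-ligand predicted ΔG (kcal/mol) by weighted least squares.

    Minimizes sum_edges w_ij (g_j - g_i - ddG_ij)^2 with w = 1/σ² (unit
    weights where uncertainties are missing or zero).  The gauge is fixed by
    shifting predictions so their mean over ligands with experimental data
    equals the mean experimental ΔG; without any experimental data the first
    ligand is pinned at 0 and a warning is issued.
    """
    if not network.edges:
        raise ValueError("network has no edges")
    g = network.graph()
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"perturbation graph is disconnected: components {comps}")
    nodes = network.nodes()
    idx = {n: i for i, n in enumerate(nodes)}
    m, n = len(network.edges), len(nodes)
    A = np.zeros((m, n))
    b = np.zeros(m)
    for r, e in enumerate(network.edges):
        # rows scaled by sqrt(w), w = 1/sigma^2, so the normal equations
        # carry weight w
        s = 1.0 / e.uncertainty if e.uncertainty and e.uncertainty > 0 else 1.0
        A[r, idx[e.ligand_b]] = s
        A[r, idx[e.ligand_a]] = -s
        b[r] = s * e.ddg
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)

    with_exp = [x for x in nodes if x in network.experimental]
    if with_exp:
        shift = float(np.mean([network.experimental[x] for x in with_exp])
                      - np.mean([sol[idx[x]] for x in with_exp]))
    else:
        warnings.warn("no experimental values; predictions reported relative "
                      "to the first ligand at 0", RuntimeWarning)
        shift = -sol[idx[nodes[0]]]
    return {x: float(sol[idx[x]] + shift) for x in nodes}


def cycle_closure_errors(
    network: PerturbationNetwork,
) -> tuple[list[tuple[list[str], float]], dict[str, float]]:
    """Cycle-closure errors over a fundamental cycle basis.

    Returns (cycles, per_node): each basis cycle as (node list, signed sum
    of edge ΔΔGs traversed head-to-tail, kcal/mol), and a per-ligand error
    aggregated as the root-sum-square of the closures of basis cycles
    through that ligand (0 for ligands on no cycle).
    """
    ddg: dict[tuple[str, str], float] = {}
    for e in network.edges:
        key = (e.ligand_a, e.ligand_b)
        if key in ddg or (key[1], key[0]) in ddg:
            continue  # duplicate edge: the first occurrence defines the cycle sum
        ddg[key] = e.ddg
    g = network.graph()
    cycles = []
    per_node = {x: 0.0 for x in network.nodes()}
    for cyc in nx.cycle_basis(g):
        total = 0.0
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            if (a, b) in ddg:
                total += ddg[(a, b)]
            else:
                total -= ddg[(b, a)]
        cycles.append((list(cyc), float(total)))
        for x in cyc:
            per_node[x] += total * total
    per_node = {x: float(np.sqrt(v)) for x, v in per_node.items()}
    return cycles, per_node


def compute_accuracy_stats(predicted, experimental) -> AccuracyStats:
    """MUE, RMSE, R² (squared Pearson), Spearman ρ and Kendall τ-b between
    per-compound predicted and experimental ΔG vectors."""
    pred = np.asarray(predicted, float)
    expv = np.asarray(experimental, float)
    if pred.shape != expv.shape or pred.ndim != 1:
        raise ValueError("predicted and experimental must be equal-length vectors")
    if pred.size < 2:
        raise ValueError("need at least two compounds")
    diff = pred - expv
    mue = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    if np.std(pred) == 0 or np.std(expv) == 0:
        r2, rho, tau = 1.0 if np.allclose(diff, diff[0]) else 0.0, 1.0, 1.0
    else:
        r2 = float(_stats.pearsonr(pred, expv).statistic ** 2)
        rho = float(_stats.spearmanr(pred, expv).statistic)
        tau = float(_stats.kendalltau(pred, expv, variant="b").statistic)
    return AccuracyStats(mue, rmse, r2, rho, tau, int(pred.size))


def summarize_by_target(
    networks: dict[str, PerturbationNetwork],
) -> tuple[dict[str, AccuracyStats], AccuracyStats, dict[str, dict[str, float]]]:
    """Analyze several per-target networks and pool the results.

    Runs node-ΔG estimation and accuracy statistics per target, then
    computes pooled statistics over the concatenated per-ligand values
    (pooling compounds, not averaging per-target numbers).  Returns
    (per_target_stats, pooled_stats, per_target_predictions).  Targets that
    fail are reported with a warning and omitted from the pool.
    """
    if not networks:
        raise ValueError("no targets given")
    per_target: dict[str, AccuracyStats] = {}
    predictions: dict[str, dict[str, float]] = {}
    pooled_pred: list[float] = []
    pooled_exp: list[float] = []
    for name, net in networks.items():
        try:
            pred = estimate_node_dGs(net)
            ligs = [x for x in net.nodes() if x in net.experimental]
            if len(ligs) < 2:
                raise ValueError(f"target {name!r}: fewer than 2 experimental values")
            p = [pred[x] for x in ligs]
            e = [net.experimental[x] for x in ligs]
            per_target[name] = compute_accuracy_stats(p, e)
            predictions[name] = pred
            pooled_pred.extend(p)
            pooled_exp.extend(e)
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"target {name!r} failed: {err}", RuntimeWarning)
    if not pooled_pred:
        raise ValueError("every target failed")
    pooled = compute_accuracy_stats(pooled_pred, pooled_exp)
    return per_target, pooled, predictions
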