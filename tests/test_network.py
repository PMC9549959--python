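"""Perturbation-network least squares, cycle closure, and accuracy stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fepkit.estimators import EdgeEstimate
from fepkit.fixtures import SyntheticNetworkSpec, make_synthetic_network
from fepkit.network import (
    PerturbationNetwork,
    compute_accuracy_stats,
    cycle_closure_errors,
    estimate_node_dGs,
    summarize_by_target,
)

from conftest import kendall_tau_bruteforce, spearman_bruteforce


def triangle(ab=1.0, bc=1.0, ca=-1.5):
    return PerturbationNetwork([
        EdgeEstimate("A", "B", ab),
        EdgeEstimate("B", "C", bc),
        EdgeEstimate("C", "A", ca),
    ])


class TestNodeEstimation:
    def test_single_edge_by_hand(self):
        """ddG=1.0 between experimental (-10.0, -9.2): relative solution
        (0, 1) shifted so the mean matches the experimental mean -9.6."""
        net = PerturbationNetwork(
            [EdgeEstimate("A", "B", 1.0)],
            {"A": -10.0, "B": -9.2},
        )
        pred = estimate_node_dGs(net)
        assert pred["A"] == pytest.approx(-10.1, abs=1e-10)
        assert pred["B"] == pytest.approx(-9.1, abs=1e-10)

    @pytest.mark.parametrize("topology", ["star", "chain", "dense"])
    @pytest.mark.parametrize("n", [5, 20, 50])
    def test_zero_noise_exact_recovery(self, topology, n):
        spec = SyntheticNetworkSpec(n_nodes=n, topology=topology,
                                    edge_noise_sigma=0.0, seed=n)
        net, truth = make_synthetic_network(spec)
        pred = estimate_node_dGs(net)
        for lig in truth:
            assert pred[lig] == pytest.approx(truth[lig], abs=1e-10)

    def test_noisy_triangle_matches_normal_equations(self):
        """Weighted least squares equals the explicit pseudo-inverse
        solution built from the normal equations."""
        edges = [
            EdgeEstimate("A", "B", 1.1, 0.2),
            EdgeEstimate("B", "C", 0.8, 0.1),
            EdgeEstimate("A", "C", 2.2, 0.4),
        ]
        exp = {"A": -10.0, "B": -9.0, "C": -8.0}
        net = PerturbationNetwork(edges, exp)
        pred = estimate_node_dGs(net)

        nodes = ["A", "B", "C"]
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for r, e in enumerate(edges):
            w = 1.0 / e.uncertainty
            A[r, nodes.index(e.ligand_b)] = w
            A[r, nodes.index(e.ligand_a)] = -w
            b[r] = w * e.ddg
        sol = np.linalg.pinv(A.T @ A) @ A.T @ b
        sol += np.mean(list(exp.values())) - sol.mean()
        for i, lig in enumerate(nodes):
            assert pred[lig] == pytest.approx(sol[i], abs=1e-9)

    def test_disconnected_graph_lists_components(self):
        net = PerturbationNetwork([
            EdgeEstimate("A", "B", 1.0),
            EdgeEstimate("C", "D", 0.5),
        ])
        with pytest.raises(ValueError, match="disconnected"):
            estimate_node_dGs(net)

    def test_no_experimental_values_pins_first_ligand(self):
        net = PerturbationNetwork([EdgeEstimate("A", "B", 1.0)])
        with pytest.warns(RuntimeWarning, match="experimental"):
            pred = estimate_node_dGs(net)
        assert pred["A"] == pytest.approx(0.0, abs=1e-12)
        assert pred["B"] == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-50.0, 50.0))
    def test_gauge_invariance(self, shift):
        spec = SyntheticNetworkSpec(n_nodes=8, topology="dense",
                                    edge_noise_sigma=0.4, seed=5)
        net, _ = make_synthetic_network(spec)
        pred0 = estimate_node_dGs(net)
        shifted = PerturbationNetwork(
            net.edges, {k: v + shift for k, v in net.experimental.items()})
        pred1 = estimate_node_dGs(shifted)
        for lig in pred0:
            assert pred1[lig] - pred0[lig] == pytest.approx(shift, abs=1e-8)
        ligs = sorted(pred0)
        s0 = compute_accuracy_stats([pred0[x] for x in ligs],
                                    [net.experimental[x] for x in ligs])
        s1 = compute_accuracy_stats([pred1[x] for x in ligs],
                                    [shifted.experimental[x] for x in ligs])
        assert s0.mue == pytest.approx(s1.mue, abs=1e-8)
        assert s0.rmse == pytest.approx(s1.rmse, abs=1e-8)
        assert s0.kendall_tau == pytest.approx(s1.kendall_tau, abs=1e-12)

    def test_rmse_grows_with_edge_noise(self):
        """Monotone noise response: mean recovery RMSE over 50 seeds per σ
        is strictly rank-correlated with σ."""
        sigmas = [0.0, 0.2, 0.4, 0.8, 1.6]
        mean_rmse = []
        for s in sigmas:
            vals = []
            for seed in range(50):
                spec = SyntheticNetworkSpec(n_nodes=8, topology="dense",
                                            edge_noise_sigma=s, seed=seed)
                net, truth = make_synthetic_network(spec)
                pred = estimate_node_dGs(net)
                err = [pred[x] - truth[x] for x in truth]
                vals.append(float(np.sqrt(np.mean(np.square(err)))))
            mean_rmse.append(np.mean(vals))
        rho = sps.spearmanr(sigmas, mean_rmse).statistic
        assert rho > 0.95


class TestCycleClosure:
    def test_consistent_triangle_closes_exactly(self):
        cycles, per_node = cycle_closure_errors(triangle(1.0, 1.0, -2.0))
        assert len(cycles) == 1
        assert cycles[0][1] == pytest.approx(0.0, abs=1e-15)
        assert all(v == pytest.approx(0.0, abs=1e-15) for v in per_node.values())

    def test_inconsistent_triangle_closure_half(self):
        cycles, per_node = cycle_closure_errors(triangle(1.0, 1.0, -1.5))
        assert abs(cycles[0][1]) == pytest.approx(0.5, abs=1e-12)
        for v in per_node.values():
            assert v == pytest.approx(0.5, abs=1e-12)

    def test_tree_has_no_cycles(self):
        net = PerturbationNetwork([
            EdgeEstimate("A", "B", 1.0),
            EdgeEstimate("B", "C", 2.0),
            EdgeEstimate("B", "D", -1.0),
        ])
        cycles, per_node = cycle_closure_errors(net)
        assert cycles == []
        assert all(v == 0.0 for v in per_node.values())

    def test_zero_noise_network_closes_everywhere(self):
        spec = SyntheticNetworkSpec(n_nodes=12, topology="dense",
                                    edge_noise_sigma=0.0, seed=77)
        net, _ = make_synthetic_network(spec)
        cycles, _ = cycle_closure_errors(net)
        assert len(cycles) > 0
        for _, closure in cycles:
            assert closure == pytest.approx(0.0, abs=1e-10)

    def test_closure_magnitude_scales_with_noise(self):
        """|closure| of a noisy triangle averages σ·sqrt(3)·sqrt(2/π)."""
        sigma = 0.3
        vals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            net = triangle(*(rng.normal(0, sigma, 3)))
            cycles, _ = cycle_closure_errors(net)
            vals.append(abs(cycles[0][1]))
        expected = sigma * np.sqrt(3.0) * np.sqrt(2.0 / np.pi)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se


class TestAccuracyStats:
    def test_perfect_prediction(self):
        s = compute_accuracy_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.mue == 0.0 and s.rmse == 0.0
        assert s.r_squared == pytest.approx(1.0, abs=1e-12)
        assert s.spearman_rho == 1.0 and s.kendall_tau == 1.0

    def test_reversed_ranking(self):
        s = compute_accuracy_stats([3.0, 2.0, 1.0], [1.0, 2.0, 3.0])
        assert s.spearman_rho == -1.0 and s.kendall_tau == -1.0

    def test_worked_example(self):
        s = compute_accuracy_stats([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert s.mue == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert s.rmse == pytest.approx(1.0 / np.sqrt(3.0), abs=1e-12)
        assert s.kendall_tau == pytest.approx(1.0, abs=1e-12)
        assert s.spearman_rho == pytest.approx(1.0, abs=1e-12)
        assert s.r_squared == pytest.approx(0.9643, abs=5e-5)

    def test_matches_bruteforce_definitions_on_random_vectors(self, rng):
        """Library statistics agree with O(n²) pair counting (τ-b) and
        explicit mid-ranks (ρ) on random vectors, including ties."""
        for trial in range(100):
            n = int(rng.integers(4, 20))
            pred = np.round(rng.normal(size=n), 1)  # rounding induces ties
            exp = np.round(rng.normal(size=n), 1)
            if np.std(pred) == 0 or np.std(exp) == 0:
                continue
            s = compute_accuracy_stats(pred, exp)
            assert s.kendall_tau == pytest.approx(
                kendall_tau_bruteforce(pred, exp), abs=1e-12)
            assert s.spearman_rho == pytest.approx(
                spearman_bruteforce(pred, exp), abs=1e-12)
            assert s.mue == pytest.approx(np.mean(np.abs(pred - exp)), abs=1e-12)
            assert s.rmse == pytest.approx(
                np.sqrt(np.mean((pred - exp) ** 2)), abs=1e-12)
            assert s.mue <= s.rmse + 1e-12

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            compute_accuracy_stats([1.0], [1.0])
        with pytest.raises(ValueError):
            compute_accuracy_stats([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSummarizeByTarget:
    def _net(self, seed, sigma=0.2):
        spec = SyntheticNetworkSpec(n_nodes=6, topology="dense",
                                    edge_noise_sigma=sigma, seed=seed)
        return make_synthetic_network(spec)[0]

    def test_single_group_equals_direct_analysis(self):
        net = self._net(1)
        per, pooled, _ = summarize_by_target({"t1": net})
        pred = estimate_node_dGs(net)
        ligs = sorted(net.experimental)
        direct = compute_accuracy_stats([pred[x] for x in ligs],
                                        [net.experimental[x] for x in ligs])
        assert per["t1"].mue == pytest.approx(direct.mue, abs=1e-12)
        assert pooled.mue == pytest.approx(direct.mue, abs=1e-12)

    def test_duplicated_group_pooled_mue_unchanged(self):
        net = self._net(2)
        _, pooled_one, _ = summarize_by_target({"t1": net})
        _, pooled_two, _ = summarize_by_target({"t1": net, "t2": net})
        assert pooled_two.mue == pytest.approx(pooled_one.mue, abs=1e-12)
        assert pooled_two.n == 2 * pooled_one.n

    def test_per_group_error_tracks_injected_noise(self):
        """Eight targets with increasing edge noise: per-target MUE ordering
        follows the injected noise ordering (Spearman over the group set)."""
        noises = [0.05 * (i + 1) ** 2 for i in range(8)]
        nets = {}
        for i, s in enumerate(noises):
            # average several seeds into one group via a denser network to
            # stabilize the ordering
            spec = SyntheticNetworkSpec(n_nodes=12, topology="dense",
                                        edge_noise_sigma=s, seed=100 + i)
            nets[f"t{i}"] = make_synthetic_network(spec)[0]
        per, _, _ = summarize_by_target(nets)
        mues = [per[f"t{i}"].mue for i in range(8)]
        rho = sps.spearmanr(noises, mues).statistic
        assert rho > 0.7

    def test_failing_group_reported_not_fatal(self):
        good = self._net(3)
        bad = PerturbationNetwork([
            EdgeEstimate("A", "B", 1.0), EdgeEstimate("C", "D", 1.0)])
        with pytest.warns(RuntimeWarning, match="failed"):
            per, pooled, _ = summarize_by_target({"g": good, "b": bad})
        assert "g" in per and "b" not in per
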