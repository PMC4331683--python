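"""MI network construction, permutation threshold, filtering, penalties."""

import numpy as np
import pandas as pd
import pytest

from micox.information import binarize_outcome
from micox.network import (
    MINetwork,
    build_penalty,
    coexpression_network,
    complete_mi_network,
    filter_network,
    network_stats,
    pairwise_pair_outcome_mi,
    permutation_threshold,
    OutcomeGuidedMINetwork,
)
from micox.information import pair_outcome_mi
from micox.synthetic import SimulationSpec, simulate


def frame(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=genes)


@pytest.fixture
def labels6():
    return np.array([0, 1, 0, 1, 0, 1])


class TestCompleteNetwork:
    def test_three_genes_three_edges(self, rng, labels6):
        net = complete_mi_network(frame(rng.normal(size=(6, 3))), labels6)
        assert net.n_edges == 3
        assert net.complete

    def test_planted_xor_pair_has_largest_weight(self):
        spec = SimulationSpec(
            n_samples=200, n_genes=12, n_modules=0, module_size=0,
            n_interaction_pairs=1, seed=7,
        )
        ds = simulate(spec)
        net = complete_mi_network(ds.expression, binarize_outcome(ds.survival))
        best = max(net.edges, key=net.edges.get)
        assert set(best) == set(ds.interaction_pairs[0])

    def test_duplicated_gene_symmetry(self, rng, labels6):
        x = rng.normal(size=6)
        z = rng.normal(size=6)
        expr = frame(np.column_stack([x, x, z]), genes=["g", "g_dup", "h"])
        net = complete_mi_network(expr, labels6)
        assert net.edges[("g", "h")] == pytest.approx(net.edges[("g_dup", "h")], abs=1e-14)

    def test_constant_labels_error(self, rng):
        with pytest.raises(ValueError, match="identical"):
            complete_mi_network(frame(rng.normal(size=(6, 3))), np.zeros(6, dtype=int))

    def test_matches_scalar_pair_statistic(self, rng, labels6):
        expr = frame(rng.normal(size=(6, 4)))
        net = complete_mi_network(expr, labels6, n_bins=2)
        from micox.information import discretize

        codes = {g: discretize(expr[g].to_numpy(), 2).codes for g in expr.columns}
        for (a, b), w in net.edges.items():
            assert w == pytest.approx(pair_outcome_mi(codes[a], codes[b], labels6), abs=1e-12)


class TestPermutationThreshold:
    def test_single_pair_single_perm(self, rng, labels6):
        expr = frame(rng.normal(size=(6, 2)))
        theta = permutation_threshold(expr, labels6, n_bins=2, n_perm=1, seed=7)
        y_perm = np.random.default_rng(7).permutation(labels6)
        from micox.information import discretize

        c0 = discretize(expr.iloc[:, 0].to_numpy(), 2).codes
        c1 = discretize(expr.iloc[:, 1].to_numpy(), 2).codes
        assert theta == pytest.approx(pair_outcome_mi(c0, c1, y_perm), abs=1e-14)

    def test_deterministic_given_seed(self, rng, labels6):
        expr = frame(rng.normal(size=(6, 3)))
        a = permutation_threshold(expr, labels6, n_perm=10, seed=3)
        b = permutation_threshold(expr, labels6, n_perm=10, seed=3)
        assert a == b

    def test_decreases_with_sample_size(self):
        r = np.random.default_rng(11)
        thetas = []
        for n in (50, 500, 5000):
            expr = frame(r.normal(size=(n, 5)))
            y = r.integers(0, 2, size=n)
            thetas.append(permutation_threshold(expr, y, n_perm=10, seed=0))
        assert thetas[0] > thetas[1] > thetas[2]

    def test_invalid_n_perm(self, rng, labels6):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_threshold(frame(rng.normal(size=(6, 2))), labels6, n_perm=0)

    def test_weak_null_calibration(self):
        """theta is a weak base cutoff by construction: averaging over
        permutations pulls it toward the null mean of MI, so a sizeable
        minority of null pairs still exceeds it (this is exactly why the
        sigma amplification exists). The provable bound is strict
        sub-half exceedance for the right-skewed MI null."""
        r = np.random.default_rng(21)
        fracs = []
        for i in range(15):
            expr = frame(r.normal(size=(80, 10)))
            y = r.integers(0, 2, size=80)
            net = complete_mi_network(expr, y)
            theta = permutation_threshold(expr, y, n_perm=20, seed=i)
            fracs.append((net.weights() >= theta).mean())
        assert np.mean(fracs) <= 0.45


class TestFilterNetwork:
    def make_net(self, weights):
        genes = tuple(f"g{j}" for j in range(len(weights) + 1))
        edges = {(genes[0], genes[j + 1]): w for j, w in enumerate(weights)}
        return MINetwork(genes=genes, edges=edges, complete=True)

    def test_cutoff_arithmetic(self):
        net = self.make_net([0.5, 0.3, 0.1])
        out = filter_network(net, theta=0.2, sigma=0.3)
        assert out.n_edges == 2 and out.theta == 0.2 and out.sigma == 0.3

    def test_sigma_zero_keeps_everything_at_theta(self):
        net = self.make_net([0.5, 0.3, 0.2])
        assert filter_network(net, theta=0.2, sigma=0.0).n_edges == 3

    def test_tie_at_cutoff_kept(self):
        net = self.make_net([0.26])
        assert filter_network(net, theta=0.2, sigma=0.3).n_edges == 1

    def test_monotone_over_sigma_grid(self, rng):
        weights = rng.uniform(0, 1, size=45)
        net = self.make_net(list(weights))
        counts = [
            filter_network(net, theta=0.3, sigma=s).n_edges
            for s in (0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_negative_sigma_error(self):
        with pytest.raises(ValueError, match="sigma"):
            filter_network(self.make_net([0.5]), theta=0.1, sigma=-0.1)


class TestCoexpressionNetwork:
    def test_perfect_linear_dependence(self, rng):
        g1 = rng.normal(size=10)
        expr = frame(np.column_stack([g1, 2 * g1 + 1]), genes=["a", "b"])
        net = coexpression_network(expr, cutoff=0.0)
        assert net.edges[("a", "b")] == pytest.approx(1.0)

    def test_anticorrelation_absolute_value(self, rng):
        g1 = rng.normal(size=10)
        expr = frame(np.column_stack([g1, -g1]), genes=["a", "b"])
        assert coexpression_network(expr, 0.0).edges[("a", "b")] == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        expr = frame(rng.normal(size=(10, 4)))
        net = coexpression_network(expr, cutoff=0.0)
        for (a, b), w in net.edges.items():
            x, y = expr[a].to_numpy(), expr[b].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert w == pytest.approx(abs(r), abs=1e-12)

    def test_constant_gene_gets_no_edges(self, rng):
        expr = frame(np.column_stack([np.ones(8), rng.normal(size=8)]), genes=["c", "d"])
        assert coexpression_network(expr, 0.0).n_edges == 0


class TestBuildPenalty:
    def test_single_edge_graph_closed_form(self):
        net = MINetwork(genes=("a", "b"), edges={("a", "b"): 0.7})
        pen = build_penalty(net, alpha=0.5)
        np.testing.assert_allclose(pen.S, [[0, 1], [1, 0]])
        np.testing.assert_allclose(pen.L, [[1, -1], [-1, 1]])
        np.testing.assert_allclose(pen.Gamma, [[1, -0.5], [-0.5, 1]])

    def test_alpha_one_is_identity(self, rng):
        net = _random_net(rng, 6, 8)
        pen = build_penalty(net, alpha=1.0)
        np.testing.assert_allclose(pen.Gamma, np.eye(6))

    def test_quadratic_form_entrywise_oracle(self, rng):
        net = _random_net(rng, 6, 9)
        pen = build_penalty(net, alpha=0.3)
        beta = rng.normal(size=6)
        # direct expansion: beta' Gamma beta = alpha sum b_i^2
        #   + (1-alpha) [sum_i b_i^2 - sum_ij S_ij b_i b_j]
        direct = 0.3 * np.sum(beta**2)
        cross = 0.0
        for i in range(6):
            for j in range(6):
                cross += pen.S[i, j] * beta[i] * beta[j]
        direct += (1 - 0.3) * (np.sum(beta**2) - cross)
        assert pen.quad_form(beta) == pytest.approx(direct, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    def test_spectrum_bounded_below_by_alpha(self, rng, alpha):
        net = _random_net(rng, 8, 12)
        pen = build_penalty(net, alpha)
        assert np.linalg.eigvalsh(pen.Gamma).min() >= alpha - 1e-8

    def test_symmetric_input_gives_symmetric_s(self, rng):
        net = _random_net(rng, 7, 10)
        pen = build_penalty(net, 0.5)
        np.testing.assert_allclose(pen.S, pen.S.T)
        np.testing.assert_array_equal(pen.row_sums, pen.col_sums)

    def test_isolated_gene_zero_row(self):
        net = MINetwork(genes=("a", "b", "c"), edges={("a", "b"): 1.0})
        pen = build_penalty(net, 0.5)
        assert np.all(pen.S[2] == 0) and np.all(pen.S[:, 2] == 0)
        assert pen.L[2, 2] == 1.0

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_alpha_out_of_range(self, alpha):
        net = MINetwork(genes=("a", "b"), edges={("a", "b"): 1.0})
        with pytest.raises(ValueError, match="alpha"):
            build_penalty(net, alpha)


def _random_net(rng, p, n_edges):
    genes = tuple(f"g{j}" for j in range(p))
    pairs = [(genes[i], genes[j]) for i in range(p - 1) for j in range(i + 1, p)]
    chosen = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    return MINetwork(genes=genes, edges={pairs[k]: float(rng.uniform(0.1, 1)) for k in chosen})


def _bfs_components(genes, edges):
    adj = {g: set() for g in genes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), 0
    for g in genes:
        if g in seen or not adj[g]:
            continue
        comps += 1
        stack = [g]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v] - seen)
    return comps


class TestNetworkStats:
    def test_single_edge(self):
        net = MINetwork(genes=("a", "b", "c"), edges={("a", "b"): 1.0})
        s = network_stats(net)
        assert s == {
            "n_nodes": 2,
            "n_edges": 1,
            "n_components": 1,
            "density": 1.0,
            "average_neighbors": 1.0,
        }

    def test_two_disjoint_edges(self):
        net = MINetwork(
            genes=("a", "b", "c", "d"), edges={("a", "b"): 1.0, ("c", "d"): 1.0}
        )
        s = network_stats(net)
        assert s["n_nodes"] == 4 and s["n_components"] == 2

    def test_empty_network(self):
        s = network_stats(MINetwork(genes=("a", "b"), edges={}))
        assert s["n_nodes"] == 0 and s["n_components"] == 0

    def test_components_match_bfs_oracle(self, rng):
        net = _random_net(rng, 20, 15)
        s = network_stats(net)
        assert s["n_components"] == _bfs_components(net.genes, net.edges)


class TestPlantedRecovery:
    def test_planted_pairs_survive_sigma_zero(self):
        """Planted XOR pairs should clear the permutation cutoff at
        sigma = 0 in nearly every seeded replicate (scaled-down check;
        the full 20-seed version runs in the acceptance suite)."""
        hits = 0
        for seed in range(6):
            spec = SimulationSpec(
                n_samples=300, n_genes=22, n_modules=0, module_size=0,
                n_interaction_pairs=1, seed=seed,
            )
            ds = simulate(spec)
            out = binarize_outcome(ds.survival)
            net = complete_mi_network(ds.expression, out)
            theta = permutation_threshold(ds.expression, out, n_perm=50, seed=seed)
            kept = filter_network(net, theta, 0.0)
            pair = ds.interaction_pairs[0]
            hits += pair in kept.edges or (pair[1], pair[0]) in kept.edges
        assert hits >= 5


class TestEstimator:
    def test_fit_exposes_network_and_theta(self):
        spec = SimulationSpec(n_samples=120, n_genes=8, n_modules=0, module_size=0,
                              n_interaction_pairs=1, seed=2)
        ds = simulate(spec)
        est = OutcomeGuidedMINetwork(n_perm=10, sigma=0.0, random_state=0)
        est.fit(ds.expression, ds.survival)
        assert est.theta_ > 0
        assert est.complete_network_.n_edges == 28
        assert est.network_.n_edges <= 28
        # re-filtering is pure thresholding
        assert est.filtered(10.0).n_edges <= est.network_.n_edges

    def test_sklearn_params_roundtrip(self):
        est = OutcomeGuidedMINetwork(n_bins=4, sigma=0.2)
        params = est.get_params()
        assert params["n_bins"] == 4
        est.set_params(sigma=0.1)
        assert est.sigma == 0.1
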