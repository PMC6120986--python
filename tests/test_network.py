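"""Adjacency construction, scale-free scan, culling, dynamic-hybrid module
detection and connectivity, against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from coexdiff import network, preprocess, simulate
from coexdiff.evaluation import adjusted_rand_index
from coexdiff.network import Adjacency, ConnectivityProfile, ModulePartition, UNASSIGNED

from conftest import make_expr


def _orthonormal_pair(n, rng):
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=0)
    y = rng.standard_normal(n)
    y = y - y.mean() - np.dot(y - y.mean(), x) / np.dot(x, x) * x
    y = y / y.std(ddof=0)
    return x, y


class TestAdjacency:
    def test_perfect_copy_gives_weight_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        expr = make_expr(np.vstack([x, x, -x]))
        adj = network.adjacency(expr)
        assert adj.weights[0, 1] == pytest.approx(1.0)
        assert adj.weights[0, 2] == pytest.approx(1.0)  # unsigned: |r|

    def test_closed_form_for_r_half(self):
        rng = np.random.default_rng(1)
        x, z = _orthonormal_pair(12, rng)
        y = -0.5 * x + np.sqrt(1 - 0.25) * z  # sample correlation exactly -0.5
        adj = network.adjacency(make_expr(np.vstack([x, y])), beta=6)
        assert adj.weights[0, 1] == pytest.approx(0.5**6, abs=1e-12)

    def test_five_gene_matrix_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((5, 9))
        adj = network.adjacency(make_expr(vals), beta=6)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert adj.weights[i, j] == 0.0
                    continue
                # brute-force Pearson correlation from its definition
                a, b = vals[i], vals[j]
                r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
                    np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
                )
                assert adj.weights[i, j] == pytest.approx(abs(r) ** 6, rel=1e-10)

    def test_constant_gene_dropped_with_warning(self):
        vals = np.vstack([np.ones(8), np.arange(8.0), np.arange(8.0)[::-1]])
        with pytest.warns(UserWarning, match="constant"):
            adj = network.adjacency(make_expr(vals))
        assert len(adj.genes) == 2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            network.adjacency(make_expr(np.random.default_rng(0).standard_normal((3, 3))))


class TestSoftPowerScan:
    def test_power_law_degrees_fit_near_one(self):
        rng = np.random.default_rng(3)
        k = (1.0 / rng.uniform(0.02, 1.0, size=2000)) ** 1.2  # heavy-tailed degrees
        assert network.scale_free_fit(k) > 0.8

    def test_noise_expression_low_fit_but_argmax_returned(self):
        rng = np.random.default_rng(4)
        expr = make_expr(rng.standard_normal((80, 20)))
        chosen, table = network.soft_power_scan(expr, powers=(2, 4, 6), fit_target=0.95)
        assert chosen in {2.0, 4.0, 6.0}
        assert len(table) == 3

    def test_chosen_beta_stable_across_seeds(self):
        chosen = []
        for seed in range(5):
            cfg = simulate.SimulationConfig(seed=seed, n_genes=150, module_size=40,
                                            n_samples_per_line=30)
            counts = simulate.simulate_expression(simulate.generate_truth(cfg))
            expr = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))
            beta, _ = network.soft_power_scan(expr, powers=(2, 4, 6, 8))
            chosen.append(beta)
        most_common = max(set(chosen), key=chosen.count)
        assert chosen.count(most_common) >= 4

    def test_single_power_rejected(self, default_expr):
        with pytest.raises(ValueError):
            network.soft_power_scan(default_expr, powers=(6,))


class TestCullNetwork:
    def test_fraction_one_keeps_everything(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0, 1, size=(6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        adj = Adjacency([f"g{i}" for i in range(6)], w)
        for mode in ("cumulative", "quantile"):
            assert network.cull_network(adj, mode=mode, fraction=1.0).genes == adj.genes

    def test_cumulative_sum_oracle(self):
        w = np.array(
            [
                [0.0, 0.8, 0.6, 0.4, 0.2],
                [0.8, 0.0, 0.1, 0.05, 0.05],
                [0.6, 0.1, 0.0, 0.05, 0.05],
                [0.4, 0.05, 0.05, 0.0, 0.0],
                [0.2, 0.05, 0.05, 0.0, 0.0],
            ]
        )
        adj = Adjacency([f"g{i}" for i in range(5)], w, beta=1)
        k = adj.k_total()
        assert k.tolist() == pytest.approx([2.0, 1.0, 0.8, 0.5, 0.3])
        kept = network.cull_network(adj, mode="cumulative", fraction=0.8).genes
        # brute-force: smallest prefix of descending k reaching 0.8 * total
        order = sorted(adj.genes, key=lambda g: -k[g])
        csum, expect = 0.0, []
        for g in order:
            expect.append(g)
            csum += k[g]
            if csum >= 0.8 * k.sum():
                break
        assert sorted(kept) == sorted(expect)

    def test_quantile_uniform_tiebreak_by_gene_id(self):
        n = 10
        w = np.full((n, n), 0.5)
        np.fill_diagonal(w, 0.0)
        adj = Adjacency([f"g{i}" for i in range(n)], w)
        kept = network.cull_network(adj, mode="quantile", fraction=0.8).genes
        assert kept == [f"g{i}" for i in range(int(np.ceil(0.8 * n)))]


class TestDetectModules:
    def test_two_perfect_blocks_recovered(self):
        n_block = 30
        w = np.zeros((2 * n_block, 2 * n_block))
        w[:n_block, :n_block] = 1.0
        w[n_block:, n_block:] = 1.0
        np.fill_diagonal(w, 0.0)
        adj = Adjacency([f"g{i:03d}" for i in range(2 * n_block)], w)
        part = network.detect_modules(adj, min_cluster_size=30)
        labels = part.assignment
        assert len(part.modules) == 2
        assert labels.iloc[:n_block].nunique() == 1
        assert labels.iloc[n_block:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_zero_adjacency_all_unassigned(self):
        n = 40
        adj = Adjacency([f"g{i}" for i in range(n)], np.zeros((n, n)))
        part = network.detect_modules(adj, min_cluster_size=10)
        assert (part.assignment == UNASSIGNED).all()

    def test_planted_modules_recovered_with_high_ari(self):
        cfg = simulate.SimulationConfig(seed=11, latent_factor_loading=0.8)
        truth = simulate.generate_truth(cfg)
        counts = simulate.simulate_expression(truth)
        expr = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))
        adj = network.adjacency(expr)
        part = network.detect_modules(adj, min_cluster_size=30)
        planted = [truth.module_assignment[g] for g in adj.genes]
        assert adjusted_rand_index(planted, part.assignment.loc[adj.genes]) >= 0.9

    def test_gene_order_invariance(self):
        cfg = simulate.SimulationConfig(seed=12, n_genes=200, module_size=50,
                                        n_samples_per_line=30)
        counts = simulate.simulate_expression(simulate.generate_truth(cfg))
        expr = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))
        adj = network.adjacency(expr)
        part = network.detect_modules(adj, min_cluster_size=20)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(expr.genes))
        shuffled = preprocess.ExprMatrix(expr.values.iloc[perm],
                                         expr.normalization_factors, expr.metadata)
        part2 = network.detect_modules(network.adjacency(shuffled), min_cluster_size=20)
        joined = part2.assignment.loc[part.assignment.index]
        assert adjusted_rand_index(part.assignment, joined) == pytest.approx(1.0)

    def test_small_network_warns_and_unassigns(self):
        adj = Adjacency(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            part = network.detect_modules(adj, min_cluster_size=100)
        assert (part.assignment == UNASSIGNED).all()


class TestIntramodularConnectivity:
    def _partition(self, labels, genes):
        return ModulePartition(pd.Series(labels, index=genes))

    def test_uniform_module_all_knorm_one(self):
        n = 5
        w = np.full((n, n), 0.4)
        np.fill_diagonal(w, 0.0)
        genes = [f"g{i}" for i in range(n)]
        adj = Adjacency(genes, w)
        prof = network.intramodular_connectivity(adj, self._partition(["m"] * n, genes))
        np.testing.assert_allclose(prof.table["k_norm"], 1.0)

    def test_hand_summed_k_within(self):
        w = np.array(
            [
                [0.0, 0.2, 0.3, 0.1],
                [0.2, 0.0, 0.4, 0.0],
                [0.3, 0.4, 0.0, 0.5],
                [0.1, 0.0, 0.5, 0.0],
            ]
        )
        genes = list("abcd")
        adj = Adjacency(genes, w)
        prof = network.intramodular_connectivity(adj, self._partition(["m"] * 4, genes))
        expected = [0.6, 0.6, 1.2, 0.6]  # row sums by hand
        assert prof.table["k_within"].tolist() == pytest.approx(expected)
        assert prof.table["k_norm"].tolist() == pytest.approx([0.5, 0.5, 1.0, 0.5])

    def test_isolated_gene_zero_knorm_others_unchanged(self):
        w = np.array(
            [
                [0.0, 0.5, 0.0],
                [0.5, 0.0, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )
        genes = list("abc")
        adj = Adjacency(genes, w)
        prof = network.intramodular_connectivity(adj, self._partition(["m"] * 3, genes))
        assert prof.table.loc["c", "k_norm"] == 0.0
        assert prof.table.loc["a", "k_norm"] == 1.0


class TestHubGenes:
    def _profile(self, k_norm, modules=None):
        genes = [f"g{i}" for i in range(len(k_norm))]
        table = pd.DataFrame(
            {
                "module": modules or ["m"] * len(k_norm),
                "k_total": k_norm,
                "k_within": k_norm,
                "k_norm": k_norm,
            },
            index=genes,
        )
        return ConnectivityProfile(table)

    def test_threshold_one_empty(self):
        prof = self._profile([0.5, 1.0, 0.9])
        assert network.hub_genes(prof, threshold=1.0) == set()

    def test_reported_connectivity_values_classify(self):
        # normalized intramodular connectivities 0.821 vs 0.197 straddle 0.8
        prof = self._profile([0.821, 0.197])
        assert network.hub_genes(prof, threshold=0.8) == {"g0"}

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(9)
        k = rng.uniform(0, 1, 50)
        modules = ["m" if i % 3 else UNASSIGNED for i in range(50)]
        prof = self._profile(k, modules)
        expected = {
            f"g{i}" for i in range(50) if k[i] > 0.8 and modules[i] != UNASSIGNED
        }
        assert network.hub_genes(prof, threshold=0.8) == expected
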