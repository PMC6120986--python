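"""DE/DV/DW statistics and SGoF adjustment against independent oracles:
literal SGoF re-implementation, exact binomial tail summation, brute-force
per-pair correlation recomputation, and parameter-recovery simulations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexdiff import differential
from coexdiff.differential import EdgeChangeSet

from conftest import make_count_matrix, make_expr


class TestDeTest:
    def test_identical_counts_no_signal(self):
        arr = np.full((3, 8), 50)
        res = differential.de_test(make_count_matrix(arr))
        assert res["log2fc"].tolist() == pytest.approx([0.0] * 3)
        assert res["pvalue"].tolist() == pytest.approx([1.0] * 3)

    def test_planted_log2fc_recovered(self):
        rng = np.random.default_rng(42)
        n, phi = 30, 0.1
        n_null, n_de = 1800, 200
        mu = rng.lognormal(np.log(100), 1.0, size=n_null + n_de)
        lam = np.tile(mu[:, None], (1, 2 * n))
        lam[n_null:, :n] *= 2.0  # +1 log2FC in the High line
        counts = rng.negative_binomial(1 / phi, 1 / (1 + phi * lam))
        cm = make_count_matrix(counts, lines=["High"] * n + ["Low"] * n)
        res = differential.de_test(cm)
        assert abs(res["log2fc"].iloc[n_null:].median() - 1.0) < 0.2

    def test_line_with_one_sample_rejected(self):
        cm = make_count_matrix(np.full((2, 3), 5), lines=["High", "Low", "Low"])
        with pytest.raises(ValueError):
            differential.de_test(cm)


class TestDvTest:
    def test_identical_lines_unit_f(self):
        rng = np.random.default_rng(0)
        block = rng.standard_normal((4, 6))
        expr = make_expr(np.hstack([block, block]),
                         lines=["High"] * 6 + ["Low"] * 6)
        res = differential.dv_test(expr)
        assert res["f_statistic"].tolist() == pytest.approx([1.0] * 4)
        assert res["pvalue"].tolist() == pytest.approx([1.0] * 4)

    def test_label_swap_inverts_f_and_keeps_p(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((10, 16))
        lines = ["High"] * 8 + ["Low"] * 8
        res = differential.dv_test(make_expr(vals, lines=lines))
        swapped = differential.dv_test(
            make_expr(vals, lines=["Low"] * 8 + ["High"] * 8)
        )
        np.testing.assert_allclose(swapped["f_statistic"], 1.0 / res["f_statistic"])
        np.testing.assert_allclose(swapped["pvalue"], res["pvalue"], rtol=1e-10)

    def test_zero_variance_gene_excluded(self):
        vals = np.vstack([np.ones(12), np.random.default_rng(2).standard_normal(12)])
        res = differential.dv_test(make_expr(vals, lines=["High"] * 6 + ["Low"] * 6))
        assert bool(res["excluded"].iloc[0]) and np.isnan(res["pvalue"].iloc[0])
        assert not res["excluded"].iloc[1]

    def test_direction_is_larger_variance_line(self):
        rng = np.random.default_rng(3)
        hi = rng.normal(0, 3.0, size=(1, 10))
        lo = rng.normal(0, 1.0, size=(1, 10))
        res = differential.dv_test(
            make_expr(np.hstack([hi, lo]), lines=["High"] * 10 + ["Low"] * 10)
        )
        assert res["direction"].iloc[0] == "High"


def _sgof_literal(pvalues, gamma=0.05, alpha=0.05):
    """Independent literal implementation of the sequential binomial rule:
    repeatedly run the one-sided binomial metatest, discard one discovery,
    and shrink both the below-threshold count and the sample size."""
    p = sorted(pvalues)
    n = len(p)
    f = sum(1 for x in p if x <= gamma)
    r = 0
    while f - r > 0:
        test = stats.binomtest(f - r, n - r, gamma, alternative="greater")
        if test.pvalue <= alpha:
            r += 1
        else:
            break
    return r


class TestSgof:
    def test_all_ones_nothing_discovered(self):
        r, flags = differential.sgof_adjust(np.ones(200))
        assert r == 0 and not flags.any()

    def test_all_tiny_pvalues_all_discovered(self):
        p = np.full(100, 1e-10)
        r, flags = differential.sgof_adjust(p)
        assert r == _sgof_literal(p) == 100
        assert flags.all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_literal_implementation_on_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate([
            rng.uniform(0, 1, 300),
            rng.uniform(0, 1e-3, rng.integers(0, 60)),
        ])
        rng.shuffle(p)
        r, flags = differential.sgof_adjust(p)
        assert r == _sgof_literal(p)
        assert flags.sum() == r
        # flags mark exactly the R smallest p-values (ties by index)
        order = np.argsort(p, kind="stable")
        assert set(np.where(flags)[0]) == set(order[:r])

    def test_r_nonincreasing_in_alpha_strictness(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(0, 0.01, 40), rng.uniform(0, 1, 400)])
        rs = [differential.sgof_adjust(p, alpha=a)[0] for a in (0.1, 0.05, 0.01)]
        assert rs[0] >= rs[1] >= rs[2]

    def test_weak_fwer_control_under_global_null(self):
        rng = np.random.default_rng(11)
        n, reps = 1000, 1000
        hits = 0
        for _ in range(reps):
            r, _ = differential.sgof_adjust(rng.uniform(0, 1, n))
            hits += r > 0
        assert hits / reps <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / reps)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            differential.sgof_adjust([0.1, 1.2])


class TestEdgeChanges:
    def test_identical_lines_no_changes(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((10, 12))
        eh = make_expr(vals, lines=["High"] * 12)
        el = make_expr(vals, lines=["Low"] * 12)
        changes = differential.edge_changes(eh, el, list(eh.genes))
        assert changes.changed.sum() == 0

    def test_delta_below_threshold_never_changed(self):
        # sample correlations exactly 0.0 (Low) and 0.4 (High): the Fisher z
        # p-value is significant at n = 500 but the 0.5 screen fails
        rng = np.random.default_rng(1)
        n = 500
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=0)
        e = rng.standard_normal(n)
        e = e - e.mean() - np.dot(e - e.mean(), x) / np.dot(x, x) * x
        e = e / e.std(ddof=0)
        y_high = 0.4 * x + math.sqrt(1 - 0.16) * e
        y_low = e
        eh = make_expr(np.vstack([x, y_high]), lines=["High"] * n)
        el = make_expr(np.vstack([x, y_low]), lines=["Low"] * n)
        changes = differential.edge_changes(eh, el, ["g0", "g1"])
        assert changes.z_pvalue[0] < 1e-4 and not changes.changed[0]

    def test_fifty_gene_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        n_genes, nh, nl = 50, 20, 25
        vh = rng.standard_normal((n_genes, nh))
        vl = rng.standard_normal((n_genes, nl))
        eh = make_expr(vh, lines=["High"] * nh)
        el = make_expr(vl, lines=["Low"] * nl)
        changes = differential.edge_changes(eh, el, list(eh.genes),
                                            delta_min=0.3, p_max=0.05)
        frame = changes.to_frame().set_index(["gene_a", "gene_b"])
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                r_h = stats.pearsonr(vh[i], vh[j]).statistic
                r_l = stats.pearsonr(vl[i], vl[j]).statistic
                z = (math.atanh(r_h) - math.atanh(r_l)) / math.sqrt(
                    1 / (nh - 3) + 1 / (nl - 3)
                )
                p = 2 * stats.norm.sf(abs(z))
                row = frame.loc[(f"g{i}", f"g{j}")]
                assert row["r_high"] == pytest.approx(r_h, abs=1e-10)
                assert row["r_low"] == pytest.approx(r_l, abs=1e-10)
                assert row["z_pvalue"] == pytest.approx(p, rel=1e-8)
                assert bool(row["changed"]) == (abs(r_h - r_l) > 0.3 and p < 0.05)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(3)
        eh = make_expr(rng.standard_normal((4, 4)), lines=["High"] * 4)
        el = make_expr(rng.standard_normal((4, 10)), lines=["Low"] * 10)
        with pytest.raises(ValueError):
            differential.edge_changes(eh, el, ["g0", "g1", "g2", "g3"])


def _changeset(n_genes, changed_mask):
    iu, ju = np.triu_indices(n_genes, k=1)
    return EdgeChangeSet(
        [f"g{i}" for i in range(n_genes)], iu, ju,
        np.zeros(len(iu)), np.zeros(len(iu)), np.ones(len(iu)),
        np.asarray(changed_mask, dtype=bool), 30, 30,
    )


class TestDwTest:
    def test_zero_changed_edges_p_one(self):
        n = 10
        res = differential.dw_test(_changeset(n, np.zeros(n * (n - 1) // 2)))
        assert res["pvalue"].tolist() == pytest.approx([1.0] * n)

    def test_pvalues_match_direct_tail_summation(self):
        rng = np.random.default_rng(5)
        n = 40
        n_edges = n * (n - 1) // 2
        changed = np.zeros(n_edges, dtype=bool)
        changed[rng.choice(n_edges, size=25, replace=False)] = True
        res = differential.dw_test(_changeset(n, changed))
        rate = 25 / n_edges
        for gene, row in res.iterrows():
            s, trials = int(row["changed_edges"]), int(row["trials"])
            # direct summation of the upper binomial tail
            tail = sum(
                math.comb(trials, k) * rate**k * (1 - rate) ** (trials - k)
                for k in range(s, trials + 1)
            )
            assert row["pvalue"] == pytest.approx(tail, rel=1e-9)

    def test_changed_edge_sum_is_twice_total(self):
        rng = np.random.default_rng(6)
        n = 30
        n_edges = n * (n - 1) // 2
        changed = rng.uniform(size=n_edges) < 0.1
        res = differential.dw_test(_changeset(n, changed))
        assert res["changed_edges"].sum() == 2 * changed.sum()

    def test_tiny_network_rejected(self):
        with pytest.raises(ValueError):
            differential.dw_test(_changeset(2, [False]))


class TestOverlapSets:
    def test_disjoint_sets_empty_common(self):
        out = differential.overlap_sets({"A": {"x"}, "B": {"y"}, "C": {"z"}})
        assert out["common"] == []
        assert out["cells"]["A"]["members"] == ["x"]

    def test_identical_sets_full_common(self):
        s = {"a", "b", "c"}
        out = differential.overlap_sets({"A": set(s), "B": set(s)})
        assert out["common"] == sorted(s)
        assert out["cells"]["A&B"]["count"] == 3
        assert out["cells"]["A"]["count"] == 0

    def test_random_sets_match_bruteforce_algebra(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(60)]
        sets = {
            r: {g for g in universe if rng.uniform() < 0.4} for r in ("A", "B", "C")
        }
        out = differential.overlap_sets(sets)
        for g in universe:
            membership = [r for r in ("A", "B", "C") if g in sets[r]]
            if membership:
                key = "&".join(membership)
                assert g in out["cells"][key]["members"]
        total = sum(c["count"] for c in out["cells"].values())
        assert total == len(set().union(*sets.values()))
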