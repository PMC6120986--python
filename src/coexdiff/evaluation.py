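"""Simulation-study evaluations of the pipeline's statistical behaviour.

Each function generates its own inputs (null simulations or planted-truth
fixtures), runs the corresponding pipeline stage, and returns the measured
quantity: type-I error rates, power against closed forms, planted-structure
recovery, module-preservation behaviour and rerun determinism.  Problem
sizes follow the study conditions documented in docs/methods.md.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import differential, network, pipeline, preprocess, preservation, screen, simulate
from .preprocess import CountMatrix, ExprMatrix


def _seeds(seed: int, n: int, salt: int) -> list[int]:
    """n child seeds below 2**31, derived from one root seed."""
    ss = np.random.SeedSequence([int(seed), salt])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _gaussian_expr(rng, n_genes: int, n_per_line: int, sd_high=1.0, sd_low=1.0) -> ExprMatrix:
    cols = [f"High_{i}" for i in range(n_per_line)] + [f"Low_{i}" for i in range(n_per_line)]
    vals = np.hstack(
        [
            rng.normal(0.0, sd_high, size=(n_genes, n_per_line)),
            rng.normal(0.0, sd_low, size=(n_genes, n_per_line)),
        ]
    )
    meta = pd.DataFrame(
        {
            "line": ["High"] * n_per_line + ["Low"] * n_per_line,
            "region": "R1",
            "sex": "F",
        },
        index=cols,
    )
    values = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return ExprMatrix(values, pd.Series(1.0, index=cols), meta)


# ---------------------------------------------------------------------------
# Type-I error of the four tests (null simulations)
# ---------------------------------------------------------------------------

def de_null_type1(seed: int, n_genes: int = 10000, n_per_line: int = 30,
                  dispersion: float = 0.1, alpha: float = 0.05) -> dict:
    """Rejection rate of the NB exact DE test on an all-null NB simulation."""
    rng = np.random.default_rng(_seeds(seed, 1, 11)[0])
    mu = rng.lognormal(np.log(100), 1.0, size=n_genes)
    lam = np.tile(mu[:, None], (1, 2 * n_per_line))
    counts = rng.negative_binomial(1.0 / dispersion, 1.0 / (1.0 + dispersion * lam))
    cols = [f"s{i}" for i in range(2 * n_per_line)]
    meta = pd.DataFrame(
        {"line": ["High"] * n_per_line + ["Low"] * n_per_line, "region": "R1", "sex": "F"},
        index=cols,
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=cols), meta
    )
    res = differential.de_test(cm)
    return {"value": float((res["pvalue"] < alpha).mean()), "n": n_genes}


def dv_null_type1(seed: int, n_genes: int = 10000, n_per_line: int = 30,
                  alpha: float = 0.05) -> dict:
    """Rejection rate of the variance-ratio F test on null Gaussian data."""
    rng = np.random.default_rng(_seeds(seed, 1, 12)[0])
    expr = _gaussian_expr(rng, n_genes, n_per_line)
    res = differential.dv_test(expr)
    return {"value": float((res["pvalue"] < alpha).mean()), "n": n_genes}


def dw_null_type1(seed: int, n_genes: int = 500, rate: float = 0.05,
                  n_sims: int = 200, alpha: float = 0.05) -> dict:
    """Mean fraction of genes with binomial p < alpha under uniform random
    changed-edge placement at a fixed network-wide rate.

    The test is exact and discrete, so its true rejection probability sits
    just below alpha at these sizes rather than exactly on it.
    """
    rng = np.random.default_rng(_seeds(seed, 1, 13)[0])
    iu, ju = np.triu_indices(n_genes, k=1)
    n_edges = len(iu)
    n_changed = int(round(rate * n_edges))
    genes = [f"g{i}" for i in range(n_genes)]
    fracs = []
    for _ in range(n_sims):
        changed = np.zeros(n_edges, dtype=bool)
        changed[rng.choice(n_edges, size=n_changed, replace=False)] = True
        cs = differential.EdgeChangeSet(
            genes, iu, ju, np.zeros(n_edges), np.zeros(n_edges),
            np.ones(n_edges), changed, 30, 30,
        )
        res = differential.dw_test(cs)
        fracs.append(float((res["pvalue"] < alpha).mean()))
    return {"value": float(np.mean(fracs)), "n": n_sims}


def shift_null_type1(seed: int, n_reps: int = 1000, n_genes: int = 50,
                     alpha: float = 0.05) -> dict:
    """Rejection rate of the paired connectivity-shift test on noise."""
    rng = np.random.default_rng(_seeds(seed, 1, 14)[0])
    rejected = 0
    for _ in range(n_reps):
        kh = rng.uniform(0, 1, n_genes)
        kl = kh + rng.normal(0, 0.1, n_genes)
        p = stats.wilcoxon(kh, kl, zero_method="wilcox", mode="auto").pvalue
        rejected += p < alpha
    return {"value": rejected / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# Power against closed forms
# ---------------------------------------------------------------------------

def dv_power_analytic(ratio: float = 4.0, n_per_line: int = 30, alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided F test at a true variance ratio."""
    d = n_per_line - 1
    hi = stats.f.ppf(1 - alpha / 2, d, d)
    lo = stats.f.ppf(alpha / 2, d, d)
    return float(stats.f.sf(hi / ratio, d, d) + stats.f.cdf(lo / ratio, d, d))


def dv_power_empirical(seed: int, ratio: float = 4.0, n_per_line: int = 30,
                       n_genes: int = 5000, alpha: float = 0.05) -> dict:
    rng = np.random.default_rng(_seeds(seed, 1, 15)[0])
    expr = _gaussian_expr(rng, n_genes, n_per_line, sd_high=np.sqrt(ratio), sd_low=1.0)
    res = differential.dv_test(expr)
    return {"value": float((res["pvalue"] < alpha).mean()), "n": n_genes}


def edge_flag_analytic(r_low: float = 0.0, r_high: float = 0.9, n_per_line: int = 35,
                       delta_min: float = 0.5, p_max: float = 0.01,
                       grid: int = 4001) -> float:
    """Probability that a pair is flagged as changed, via the Fisher-z
    normal approximation of both sample correlations (numerical 2D
    integration on the atanh scale)."""
    se = 1.0 / np.sqrt(n_per_line - 3)
    zl0, zh0 = np.arctanh(r_low), np.arctanh(r_high)
    z = np.linspace(-6 * se, 6 * se, grid)
    wl = stats.norm.pdf(z, 0, se) * (z[1] - z[0])
    zh = zh0 + z  # grid of sampled atanh(r_high)
    zl = zl0 + z
    rh = np.tanh(zh)[:, None]
    rl = np.tanh(zl)[None, :]
    se_diff = np.sqrt(2.0) * se
    zstat = (zh[:, None] - zl[None, :]) / se_diff
    pz = 2.0 * stats.norm.sf(np.abs(zstat))
    flag = (np.abs(rh - rl) > delta_min) & (pz < p_max)
    w2 = wl[:, None] * wl[None, :]
    return float((flag * w2).sum())


def edge_flag_empirical(seed: int, r_low: float = 0.0, r_high: float = 0.9,
                        n_per_line: int = 35, n_reps: int = 1000,
                        delta_min: float = 0.5, p_max: float = 0.01) -> dict:
    """Monte-Carlo flag rate for a bivariate-normal pair via edge_changes."""
    rng = np.random.default_rng(_seeds(seed, 1, 16)[0])
    flags = 0
    for _ in range(n_reps):
        def draw(r):
            x = rng.standard_normal(n_per_line)
            y = r * x + np.sqrt(1 - r * r) * rng.standard_normal(n_per_line)
            return np.vstack([x, y])
        vh, vl = draw(r_high), draw(r_low)
        cols_h = [f"High_{i}" for i in range(n_per_line)]
        cols_l = [f"Low_{i}" for i in range(n_per_line)]
        eh = ExprMatrix(pd.DataFrame(vh, index=["a", "b"], columns=cols_h),
                        pd.Series(1.0, index=cols_h), None)
        el = ExprMatrix(pd.DataFrame(vl, index=["a", "b"], columns=cols_l),
                        pd.Series(1.0, index=cols_l), None)
        cs = differential.edge_changes(eh, el, ["a", "b"], delta_min, p_max)
        flags += int(cs.changed[0])
    return {"value": flags / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# Planted-structure recovery on synthetic fixtures
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a, labels_b) -> float:
    """Pair-counting adjusted Rand index between two labelings."""
    a = pd.Categorical(list(labels_a)).codes
    b = pd.Categorical(list(labels_b)).codes
    table = pd.crosstab(a, b).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    total = comb(table.sum())
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def module_recovery_ari(seed: int, n_seeds: int = 10, loading: float = 0.8,
                        n_per_line: int = 50) -> dict:
    """Median ARI of detected vs planted modules over seeded fixtures.

    Detection runs on the full (un-culled) adjacency with min_cluster_size
    scaled to the fixture (30); planted background corresponds to the
    "unassigned" label.
    """
    aris = []
    for s in _seeds(seed, n_seeds, 21):
        cfg = simulate.SimulationConfig(
            seed=s, latent_factor_loading=loading, n_samples_per_line=n_per_line
        )
        truth = simulate.generate_truth(cfg)
        counts = simulate.simulate_expression(truth)
        expr = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))
        adj = network.adjacency(expr)
        part = network.detect_modules(adj, min_cluster_size=30)
        planted = [truth.module_assignment[g] for g in adj.genes]
        aris.append(adjusted_rand_index(planted, part.assignment.loc[adj.genes]))
    return {"value": float(np.median(aris)), "n": n_seeds, "all": aris}


def dv_recovery(seed: int, n_seeds: int = 10, n_genes: int = 1200) -> dict:
    """Pooled sensitivity and FDP for planted DV genes after SGoF."""
    tp = fp = fn = 0
    for s in _seeds(seed, n_seeds, 22):
        cfg = simulate.SimulationConfig(seed=s, n_genes=n_genes)
        truth = simulate.generate_truth(cfg)
        counts = simulate.simulate_expression(truth)
        expr = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))
        res = differential.dv_test(expr)
        _, flags = differential.sgof_adjust(res["pvalue"].fillna(1.0))
        called = set(res.index[flags])
        planted = set(truth.dv_genes)
        tp += len(called & planted)
        fp += len(called - planted)
        fn += len(planted - called)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    fdp = fp / (tp + fp) if tp + fp else 0.0
    return {"sensitivity": float(sens), "fdp": float(fdp), "n": n_seeds}


def dw_decile_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Planted rewired genes ranking in the top dw_pvalue decile.

    Returns the per-seed fraction of planted rewired genes (that survive
    culling) inside the top decile, the pooled fraction, and the count of
    seeds where the majority of planted genes make the decile.
    """
    fracs = []
    pooled_in = pooled_tot = 0
    for s in _seeds(seed, n_seeds, 23):
        cfg = simulate.SimulationConfig(seed=s)
        truth = simulate.generate_truth(cfg)
        counts = simulate.simulate_expression(truth)
        expr = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))
        adj = network.cull_network(network.adjacency(expr))
        genes = adj.genes
        eh, el = expr.line_split()
        sub = lambda e: ExprMatrix(e.values.loc[genes], e.normalization_factors, e.metadata)
        changes = differential.edge_changes(sub(eh), sub(el), genes)
        dw = differential.dw_test(changes)
        decile = set(dw.sort_values("pvalue", kind="stable").index[: max(1, len(genes) // 10)])
        kept = [g for g in truth.dw_genes if g in set(genes)]
        in_decile = sum(g in decile for g in kept)
        fracs.append(in_decile / len(kept) if kept else float("nan"))
        pooled_in += in_decile
        pooled_tot += len(kept)
    majority_seeds = int(sum(f > 0.5 for f in fracs))
    return {
        "per_seed": fracs,
        "pooled_fraction": pooled_in / pooled_tot if pooled_tot else float("nan"),
        "majority_seeds": majority_seeds,
        "n": n_seeds,
    }


def _region_tables(truth, counts, min_cluster_size=30):
    expr = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))
    adj = network.cull_network(network.adjacency(expr))
    part = network.detect_modules(adj, min_cluster_size=min_cluster_size)
    prof = network.intramodular_connectivity(adj, part)
    dv = differential.dv_test(expr)
    _, flags = differential.sgof_adjust(dv["pvalue"].fillna(1.0))
    table = pd.DataFrame(
        {"dv_pvalue": dv["pvalue"], "dv_sig": flags, "de_sig": False, "dw_sig": False},
        index=dv.index,
    )
    return table, prof, part


def screen_recovery(seed: int, n_seeds: int = 10, n_genes: int = 1200,
                    n_hubs: int = 6) -> dict:
    """Pooled sensitivity/FDP of the priority screen for planted
    cross-region DV hub genes on three-region fixtures."""
    tp = fp = fn = 0
    for s in _seeds(seed, n_seeds, 24):
        cfg = simulate.SimulationConfig(seed=s, n_genes=n_genes, n_hub_genes=n_hubs)
        fixture = simulate.multi_region_fixture(cfg)
        diffs, profs, parts = {}, {}, {}
        for region, (truth, counts) in fixture.items():
            diffs[region], profs[region], parts[region] = _region_tables(truth, counts)
        result = screen.priority_screen(diffs, profs, parts)
        planted = set(next(iter(fixture.values()))[0].hub_genes)
        got = set(result.priority_genes)
        tp += len(got & planted)
        fp += len(got - planted)
        fn += len(planted - got)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    fdp = fp / (tp + fp) if tp + fp else 0.0
    return {"sensitivity": float(sens), "fdp": float(fdp), "n": n_seeds}


# ---------------------------------------------------------------------------
# Module preservation behaviour
# ---------------------------------------------------------------------------

def preservation_behaviour(seed: int, n_seeds: int = 5) -> dict:
    """Zsummary on identical networks (expect highly preserved) and against
    independently simulated unstructured networks (expect not preserved)."""
    self_min = []
    null_below2 = null_total = 0
    for i, s in enumerate(_seeds(seed, n_seeds, 25)):
        cfg = simulate.SimulationConfig(seed=s, latent_factor_loading=0.8)
        truth = simulate.generate_truth(cfg)
        counts = simulate.simulate_expression(truth)
        expr = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts))
        adj = network.cull_network(network.adjacency(expr))
        part = network.detect_modules(adj, min_cluster_size=30)
        if not part.modules:
            continue
        z_self = preservation.zsummary_preservation(adj, adj, part, seed=s)
        self_min.append(float(z_self["z_summary"].min()))
        cfg0 = simulate.SimulationConfig(seed=s + 1_000_003, latent_factor_loading=0.0)
        truth0 = simulate.generate_truth(cfg0)
        counts0 = simulate.simulate_expression(truth0)
        expr0 = preprocess.upper_quartile_normalize(preprocess.filter_by_cpm(counts0))
        adj0 = network.adjacency(expr0)
        shared = [g for g in adj.genes if g in set(adj0.genes)]
        z_null = preservation.zsummary_preservation(
            adj, adj0.subset(shared), part, seed=s
        )
        null_below2 += int((z_null["z_summary"] < 2).sum())
        null_total += len(z_null)
    return {
        "self_min_zsummary": float(min(self_min)) if self_min else float("nan"),
        "null_fraction_below_2": null_below2 / null_total if null_total else float("nan"),
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# Pipeline determinism
# ---------------------------------------------------------------------------

def _tree_digest(directory: Path) -> dict[str, str]:
    return {
        str(p.relative_to(directory)): hashlib.md5(p.read_bytes()).hexdigest()
        for p in sorted(Path(directory).rglob("*"))
        if p.is_file()
    }


def pipeline_determinism(seed: int, workdir, n_regions: int = 2) -> dict:
    """Run the full pipeline twice with identical config; 1.0 if the output
    trees are byte-identical."""
    workdir = Path(workdir)
    regions = ("SH", "CeA", "PL")[:n_regions]
    cfg = simulate.SimulationConfig(seed=_seeds(seed, 1, 26)[0], n_hub_genes=6)
    fixture = simulate.multi_region_fixture(cfg, regions=regions)
    region_paths = {}
    for region, (truth, counts) in fixture.items():
        paths = simulate.write_fixture(truth, counts, workdir / "fixture" / region)
        region_paths[region] = {
            "counts": str(paths["counts"]),
            "metadata": str(paths["metadata"]),
        }
    out = workdir / "run"
    pconf = pipeline.PipelineConfig(
        regions=region_paths, out_dir=str(out), min_cluster_size=30,
        n_permutations=25, seed=_seeds(seed, 1, 27)[0],
    )
    pipeline.run_pipeline(pconf)
    first = _tree_digest(out)
    pipeline.run_pipeline(pconf)
    second = _tree_digest(out)
    return {"value": 1.0 if first == second else 0.0, "n": len(first)}
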