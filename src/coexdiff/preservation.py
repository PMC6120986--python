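"""Module enrichment, cross-region module preservation and gene-set tests.

Module x gene-set enrichment uses the 2x2 Fisher exact test (both one-sided
tails reported: enrichment and depletion) with Bonferroni correction over
modules.  Cross-region preservation is scored two ways: tabulation-based
(-log10 Fisher p of the overlap of every module pair) and a permutation
Zsummary composite (median of a density Z and a connectivity Z against
random same-size gene sets), interpreted as not preserved (<= 2), preserved
(> 2) or highly preserved (> 10).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import Adjacency, ModulePartition, UNASSIGNED


def _fisher_tails(overlap: int, module_size: int, set_size: int, background: int):
    """(enrichment p, depletion p, odds ratio) for one 2x2 table."""
    p_enrich = float(stats.hypergeom.sf(overlap - 1, background, set_size, module_size))
    p_deplete = float(stats.hypergeom.cdf(overlap, background, set_size, module_size))
    a = overlap
    b = module_size - overlap
    c = set_size - overlap
    d = background - module_size - set_size + overlap
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b * c)
    return p_enrich, p_deplete, odds


def module_gene_set_enrichment(
    partition: ModulePartition, gene_set, background=None
) -> pd.DataFrame:
    """Per-module Fisher enrichment/depletion of a gene set.

    The background defaults to the network genes (the partition's gene
    universe); the gene set is intersected with it.  Bonferroni correction
    multiplies by the number of modules ("unassigned" is background only).
    """
    if background is None:
        background = partition.genes
    background = sorted(set(background))
    if not background:
        raise ValueError("empty background")
    gene_set = set(gene_set) & set(background)
    n = len(background)
    modules = partition.modules
    rows = []
    for label in modules:
        members = set(partition.members(label)) & set(background)
        overlap = len(members & gene_set)
        expected = len(members) * len(gene_set) / n
        p_enrich, p_deplete, odds = _fisher_tails(
            overlap, len(members), len(gene_set), n
        )
        rows.append(
            {
                "module": label,
                "module_size": len(members),
                "set_size": len(gene_set),
                "overlap": overlap,
                "expected": expected,
                "odds_ratio": odds,
                "p_enrich": p_enrich,
                "p_deplete": p_deplete,
                "bonferroni_enrich": min(1.0, p_enrich * len(modules)),
                "bonferroni_deplete": min(1.0, p_deplete * len(modules)),
            }
        )
    return pd.DataFrame(rows).set_index("module")


def tabulation_preservation(
    partition_a: ModulePartition, partition_b: ModulePartition
) -> pd.DataFrame:
    """-log10 Fisher overlap p for every (A-module, B-module) pair.

    Computed on the shared gene universe ("unassigned" stays in the
    background but is not a module).  Returns a long-form table; pivot on
    (module_a, module_b) for the matrix view.
    """
    shared = sorted(set(partition_a.genes) & set(partition_b.genes))
    if not shared:
        raise ValueError("no shared genes between partitions")
    a = partition_a.assignment.loc[shared]
    b = partition_b.assignment.loc[shared]
    n = len(shared)
    rows = []
    for ma in sorted(set(a) - {UNASSIGNED}):
        set_a = set(a.index[a == ma])
        for mb in sorted(set(b) - {UNASSIGNED}):
            set_b = set(b.index[b == mb])
            overlap = len(set_a & set_b)
            p_enrich, _, _ = _fisher_tails(overlap, len(set_a), len(set_b), n)
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "size_a": len(set_a),
                    "size_b": len(set_b),
                    "overlap": overlap,
                    "fisher_p": p_enrich,
                    "neg_log10_p": -np.log10(max(p_enrich, 1e-300)),
                }
            )
    return pd.DataFrame(rows)


def zsummary_preservation(
    adj_a: Adjacency,
    adj_b: Adjacency,
    partition_a: ModulePartition,
    n_permutations: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation Zsummary of region-A modules inside region-B's network.

    Per module: density = mean within-module adjacency in B; connectivity =
    Pearson correlation of within-module connectivity between A and B over
    the module's genes.  Each statistic is standardized against random
    same-size gene sets drawn from all shared network genes; z_summary is
    the median of the two Z scores.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations for the null")
    shared = sorted(set(adj_a.genes) & set(adj_b.genes))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    sub_a = adj_a.subset(shared)
    sub_b = adj_b.subset(shared)
    pos = {g: i for i, g in enumerate(shared)}
    rng = np.random.default_rng(seed)
    rows = []
    for label in partition_a.modules:
        members = [g for g in partition_a.members(label) if g in pos]
        if len(members) < 3:
            warnings.warn(f"module {label!r} has <3 shared genes; skipped")
            continue
        idx = np.array([pos[g] for g in members])
        obs_density, obs_conn = _module_stats(sub_a.weights, sub_b.weights, idx)
        null_density = np.empty(n_permutations)
        null_conn = np.empty(n_permutations)
        for p in range(n_permutations):
            ridx = rng.choice(len(shared), size=len(idx), replace=False)
            null_density[p], null_conn[p] = _module_stats(
                sub_a.weights, sub_b.weights, ridx
            )
        z_density = _zscore(obs_density, null_density)
        z_conn = _zscore(obs_conn, null_conn)
        z_summary = float(np.median([z_density, z_conn]))
        rows.append(
            {
                "module": label,
                "size": len(members),
                "density_b": obs_density,
                "connectivity_cor": obs_conn,
                "z_density": z_density,
                "z_connectivity": z_conn,
                "z_summary": z_summary,
                "interpretation": (
                    "highly_preserved"
                    if z_summary > 10
                    else "preserved" if z_summary > 2 else "not_preserved"
                ),
            }
        )
    return pd.DataFrame(rows).set_index("module")


def _module_stats(wa: np.ndarray, wb: np.ndarray, idx: np.ndarray):
    sub_b = wb[np.ix_(idx, idx)]
    m = len(idx)
    density = float(sub_b.sum() / (m * (m - 1)))
    ka = wa[np.ix_(idx, idx)].sum(axis=1)
    kb = sub_b.sum(axis=1)
    if ka.std() == 0 or kb.std() == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(ka, kb)[0, 1])
    return density, conn


def _zscore(obs: float, null: np.ndarray) -> float:
    sd = float(null.std(ddof=1))
    if sd < 1e-12:
        return 0.0
    return float((obs - null.mean()) / sd)


# ---------------------------------------------------------------------------
# Generic gene-set (GMT) enrichment
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected >= 3 fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"malformed GMT line {lineno}: duplicate set {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def gmt_enrichment(gene_list, gmt, background) -> pd.DataFrame:
    """Fisher enrichment of a gene list in each GMT set, BH-corrected.

    ``gmt`` is a path or a pre-parsed {name: members} mapping; sets are
    trimmed to the background before testing.
    """
    if not isinstance(gmt, dict):
        gmt = read_gmt(gmt)
    background = sorted(set(background))
    if not background:
        raise ValueError("empty background")
    bg = set(background)
    query = set(gene_list) & bg
    rows = []
    for name in sorted(gmt):
        members = set(gmt[name]) & bg
        overlap = len(members & query)
        p_enrich, _, odds = _fisher_tails(overlap, len(members), len(query), len(bg))
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "query_size": len(query),
                "overlap": overlap,
                "expected": len(members) * len(query) / len(bg),
                "odds_ratio": odds,
                "pvalue": p_enrich,
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["fdr_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    else:
        out["fdr_bh"] = []
    return out.sort_values(["pvalue", "set"], kind="stable")
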