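"""Line-wise connectivity, hub transitions and the priority gene screen.

Selection effects on wiring are summarized per line: adjacency is
recomputed within each line's samples under the module assignment of the
combined-sample network, normalized intramodular connectivity is compared
(paired Wilcoxon), genes crossing the 0.8 hub threshold between lines are
classified, and the final screen intersects cross-region hubs, common
differentially variable genes and the cross-region core module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import (
    Adjacency,
    ConnectivityProfile,
    ModulePartition,
    UNASSIGNED,
    adjacency,
    intramodular_connectivity,
)
from .preprocess import ExprMatrix


def line_connectivity(
    expr_high: ExprMatrix,
    expr_low: ExprMatrix,
    partition: ModulePartition,
    beta: float = 6.0,
    signed: bool = False,
) -> tuple[ConnectivityProfile, ConnectivityProfile]:
    """Per-line connectivity profiles under a shared module assignment.

    Adjacency is recomputed from each line's samples alone at the same soft
    power; k_norm is normalized within each line separately.
    """
    for name, e in (("High", expr_high), ("Low", expr_low)):
        if e.values.shape[1] < 5:
            raise ValueError(f"{name} line has fewer than 5 samples")
    genes = partition.genes
    adj_high = adjacency(_subset(expr_high, genes), beta=beta, signed=signed)
    adj_low = adjacency(_subset(expr_low, genes), beta=beta, signed=signed)
    return (
        intramodular_connectivity(adj_high, partition),
        intramodular_connectivity(adj_low, partition),
    )


def _subset(expr: ExprMatrix, genes) -> ExprMatrix:
    return ExprMatrix(
        expr.values.loc[list(genes)], expr.normalization_factors, expr.metadata
    )


def connectivity_shift_test(
    profile_high: ConnectivityProfile,
    profile_low: ConnectivityProfile,
    gene_set,
) -> tuple[float, float, float]:
    """(mean_high, mean_low, p) for a k_norm shift over a gene set.

    Paired two-sided Wilcoxon signed-rank on per-gene k_norm; for fewer than
    5 genes an exact sign-flip permutation test of the mean difference is
    used instead (with a warning).  Genes are correlated, so the p-value
    overstates certainty; it is reported as a descriptive index.
    """
    genes = sorted(gene_set)
    missing = [g for g in genes if g not in profile_high.table.index or g not in profile_low.table.index]
    if missing:
        raise ValueError(f"genes absent from profiles: {missing[:5]}")
    kh = profile_high.table.loc[genes, "k_norm"].to_numpy()
    kl = profile_low.table.loc[genes, "k_norm"].to_numpy()
    diff = kh - kl
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if np.allclose(diff, 0.0):
        return float(kh.mean()), float(kl.mean()), 1.0
    if len(genes) < 5:
        warnings.warn("fewer than 5 genes; using exact sign-flip permutation test")
        obs = abs(diff.mean())
        flips = np.array(list(itertools.product([1.0, -1.0], repeat=len(diff))))
        null = np.abs((flips * diff).mean(axis=1))
        p = float((null >= obs - 1e-12).mean())
    else:
        p = float(stats.wilcoxon(kh, kl, zero_method="wilcox", mode="auto").pvalue)
    return float(kh.mean()), float(kl.mean()), p


def hub_transitions(
    profile_high: ConnectivityProfile,
    profile_low: ConnectivityProfile,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Genes crossing the hub threshold between lines.

    gained_hub: k_low <= threshold < k_high; lost_hub symmetric.  Sorted by
    |k_high - k_low| descending (ties by gene id).
    """
    shared = [g for g in profile_high.table.index if g in profile_low.table.index]
    kh = profile_high.table.loc[shared, "k_norm"]
    kl = profile_low.table.loc[shared, "k_norm"]
    gained = (kl <= threshold) & (threshold < kh)
    lost = (kh <= threshold) & (threshold < kl)
    rows = []
    for g in shared:
        if gained[g] or lost[g]:
            rows.append(
                {
                    "gene": g,
                    "k_low": float(kl[g]),
                    "k_high": float(kh[g]),
                    "class": "gained_hub" if gained[g] else "lost_hub",
                }
            )
    out = pd.DataFrame(rows, columns=["gene", "k_low", "k_high", "class"])
    if len(out):
        out["abs_shift"] = (out["k_high"] - out["k_low"]).abs()
        out = out.sort_values(["abs_shift", "gene"], ascending=[False, True]).drop(
            columns="abs_shift"
        )
    return out.reset_index(drop=True)


def core_module_grouping(
    partitions: dict[str, ModulePartition],
    affected_module_per_region: dict[str, str],
) -> tuple[set[str], dict[str, float]]:
    """Core gene set: the smallest designated module, restricted to genes
    that belong to the designated module of every other region.

    Returns (core set, per-region fraction of the reference module's genes
    found in that region's designated module).
    """
    missing = [r for r in partitions if r not in affected_module_per_region]
    if missing:
        raise ValueError(f"missing module designation for regions: {missing}")
    member_sets = {
        r: set(partitions[r].members(affected_module_per_region[r]))
        for r in partitions
    }
    ref_region = min(member_sets, key=lambda r: (len(member_sets[r]), r))
    ref = member_sets[ref_region]
    core = set(ref)
    fractions = {}
    for r, members in member_sets.items():
        if r == ref_region:
            fractions[r] = 1.0
            continue
        inter = ref & members
        fractions[r] = len(inter) / len(ref) if ref else 0.0
        core &= members
    return core, fractions


@dataclass
class ScreenResult:
    """Priority screen output with its three documented parent sets."""

    common_affected: dict[str, set[str]]  # per statistic (DE/DV/DW)
    cross_region_hubs: set[str]
    core_module_genes: set[str]
    core_fractions: dict[str, float]
    designated_modules: dict[str, str]
    priority_genes: list[str]
    evidence: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        parents = (
            self.common_affected.get("DV", set()),
            self.cross_region_hubs,
            self.core_module_genes,
        )
        for parent in parents:
            if not set(self.priority_genes) <= set(parent):
                raise ValueError("priority genes must lie in every parent set")


def priority_screen(
    diff_tables: dict[str, pd.DataFrame],
    profiles: dict[str, ConnectivityProfile],
    partitions: dict[str, ModulePartition],
    designated_modules: dict[str, str] | None = None,
    hub_threshold: float = 0.8,
) -> ScreenResult:
    """Intersect cross-region evidence into an ordered priority gene list.

    ``diff_tables`` carries per-region boolean columns de_sig/dv_sig/dw_sig.
    The designated "affected" module per region defaults to the module with
    the smallest Bonferroni DV-enrichment p (DV genes at unadjusted
    p < 0.01).  priority = common DV  x  hubs in every region  x  core
    module, ordered by max k_norm across regions (descending), then gene id.
    """
    regions = sorted(diff_tables)
    for name, mapping in (
        ("profiles", profiles),
        ("partitions", partitions),
    ):
        missing = [r for r in regions if r not in mapping]
        if missing:
            raise ValueError(f"{name} missing regions: {missing}")
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")

    common_affected = {}
    for stat in ("de", "dv", "dw"):
        col = f"{stat}_sig"
        sets = []
        for r in regions:
            t = diff_tables[r]
            if col in t:
                mask = t[col].fillna(False).astype(bool)
                sets.append(set(t.index[mask]))
            else:
                sets.append(set())
        common_affected[stat.upper()] = set.intersection(*sets)

    hub_sets = []
    for r in regions:
        t = profiles[r].table
        hub_sets.append(set(t.index[(t["k_norm"] > hub_threshold) & (t["module"] != UNASSIGNED)]))
    cross_hubs = set.intersection(*hub_sets)

    if designated_modules is None:
        from .preservation import module_gene_set_enrichment

        designated_modules = {}
        for r in regions:
            t = diff_tables[r]
            dv_col = "dv_pvalue" if "dv_pvalue" in t else None
            if dv_col is None:
                raise ValueError(f"region {r}: no dv_pvalue column to designate a module")
            dv_input = set(t.index[t[dv_col] < 0.01])
            enr = module_gene_set_enrichment(partitions[r], dv_input)
            if not len(enr):
                raise ValueError(f"region {r}: no modules to designate")
            best = enr.sort_values(["bonferroni_enrich", "p_enrich"]).index[0]
            designated_modules[r] = str(best)

    core, fractions = core_module_grouping(partitions, designated_modules)

    priority = common_affected["DV"] & cross_hubs & core
    max_knorm = {
        g: max(profiles[r].table.at[g, "k_norm"] for r in regions if g in profiles[r].table.index)
        for g in priority
    }
    ordered = sorted(priority, key=lambda g: (-max_knorm[g], g))

    rows = []
    for g in ordered:
        row = {"gene": g, "max_k_norm": max_knorm[g]}
        for r in regions:
            t = diff_tables[r]
            row[f"{r}_dv_p"] = float(t.at[g, "dv_pvalue"]) if g in t.index else np.nan
            row[f"{r}_k_norm"] = (
                float(profiles[r].table.at[g, "k_norm"])
                if g in profiles[r].table.index
                else np.nan
            )
            row[f"{r}_module"] = (
                str(partitions[r].assignment.get(g, UNASSIGNED))
            )
        rows.append(row)
    evidence = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()

    return ScreenResult(
        common_affected=common_affected,
        cross_region_hubs=cross_hubs,
        core_module_genes=core,
        core_fractions=fractions,
        designated_modules=designated_modules,
        priority_genes=ordered,
        evidence=evidence,
    )
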