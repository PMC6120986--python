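"""End-to-end orchestration: preprocess -> network -> DE/DV/DW -> preservation
-> screen, per region, with deterministic TSV/JSON outputs and a summary
report.  All stage parameters default to the study thresholds (CPM > 1,
beta = 6, cumulative 0.8 culling, cutHeight 0.9995, minClusterSize 100,
deepSplit 4, hub 0.8, |delta r| > 0.5 with edge p < 0.01, SGoF
gamma = alpha = 0.05, Zsummary thresholds 2/10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, network, preprocess, preservation, screen

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    regions: dict = field(default_factory=dict)  # region -> {counts, metadata}
    out_dir: str = "results/pipeline"
    min_cpm: float = 1.0
    beta: float = 6.0
    signed: bool = False
    cull_mode: str = "cumulative"
    cull_fraction: float = 0.8
    cut_height: float = 0.9995
    min_cluster_size: int = 100
    deep_split: int = 4
    hub_threshold: float = 0.8
    delta_min: float = 0.5
    edge_p: float = 0.01
    sgof_gamma: float = 0.05
    sgof_alpha: float = 0.05
    adjust_dw: bool = True  # apply SGoF to the DW binomial p-values too
    enrich_p: float = 0.01  # unadjusted-p cutoff feeding module enrichment
    fold_threshold: float = 10.0
    n_permutations: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not self.regions:
            raise ValueError("config lists no regions")
        for region, paths in self.regions.items():
            for key in ("counts", "metadata"):
                if key not in paths:
                    raise ValueError(f"region {region!r} lacks a {key!r} path")
                if not Path(paths[key]).exists():
                    raise ValueError(f"region {region!r}: missing file {paths[key]}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every region and write the report bundle.

    Returns the in-memory report dict; artifacts land under config.out_dir
    (per-region TSVs plus venn.json, preservation tables, report.json and
    report.md).  Reruns with identical config and inputs are byte-identical.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = sorted(config.regions)

    per_region: dict[str, dict] = {}
    for region in regions:
        per_region[region] = _run_region(config, region, out)

    report = {
        "parameters": {k: v for k, v in asdict(config).items() if k != "regions"},
        "regions": {},
    }

    # cross-region summaries need >= 2 regions
    sig_sets = {stat: {} for stat in ("DE", "DV", "DW")}
    for region in regions:
        res = per_region[region]
        table = res["diff"]
        sig_sets["DE"][region] = set(table.index[table["de_sig"]])
        sig_sets["DV"][region] = set(table.index[table["dv_sig"]])
        sig_sets["DW"][region] = set(table.index[table["dw_sig"]])
        report["regions"][region] = {
            "n_genes_expressed": res["n_expressed"],
            "n_genes_network": res["n_network"],
            "modules": res["module_sizes"],
            "n_de": len(sig_sets["DE"][region]),
            "n_dv": len(sig_sets["DV"][region]),
            "n_dw": len(sig_sets["DW"][region]),
            "n_hubs": len(res["hubs"]),
            "connectivity_shift": res["shift"],
        }

    if len(regions) >= 2:
        venn = {
            stat: differential.overlap_sets(sig_sets[stat]) for stat in sig_sets
        }
        (out / "venn.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
        report["overlaps"] = {
            stat: {k: v["count"] for k, v in venn[stat]["cells"].items()}
            for stat in venn
        }

        tab_rows, z_rows = [], []
        for i, ra in enumerate(regions):
            for rb in regions:
                if ra == rb:
                    continue
                tab = preservation.tabulation_preservation(
                    per_region[ra]["partition"], per_region[rb]["partition"]
                )
                tab.insert(0, "region_a", ra)
                tab.insert(1, "region_b", rb)
                tab_rows.append(tab)
                z = preservation.zsummary_preservation(
                    per_region[ra]["adjacency"],
                    per_region[rb]["adjacency"],
                    per_region[ra]["partition"],
                    n_permutations=config.n_permutations,
                    seed=config.seed + 7919 * (1 + i),
                )
                z = z.reset_index()
                z.insert(0, "region_a", ra)
                z.insert(1, "region_b", rb)
                z_rows.append(z)
        tab_all = pd.concat(tab_rows, ignore_index=True)
        z_all = pd.concat(z_rows, ignore_index=True)
        _write_tsv(tab_all, out / "preservation_tabulation.tsv", index_label="row")
        _write_tsv(z_all, out / "preservation_z.tsv", index_label="row")
        report["preservation"] = {
            "n_pairs": int(len(z_all)),
            "n_preserved": int((z_all["z_summary"] > 2).sum()),
            "n_highly_preserved": int((z_all["z_summary"] > 10).sum()),
        }

        expr_by_region = {r: per_region[r]["expr"] for r in regions}
        folds = preprocess.region_fold_differences(
            expr_by_region, fold=config.fold_threshold
        )
        _write_tsv(folds, out / "region_fold_differences.tsv", index_label="row")
        report["n_region_fold_flagged"] = int(folds["gene"].nunique())

        result = screen.priority_screen(
            {r: per_region[r]["diff"] for r in regions},
            {r: per_region[r]["profile"] for r in regions},
            {r: per_region[r]["partition"] for r in regions},
            hub_threshold=config.hub_threshold,
        )
        if len(result.evidence):
            _write_tsv(result.evidence, out / "priority_genes.tsv")
        report["screen"] = {
            "designated_modules": result.designated_modules,
            "core_module_size": len(result.core_module_genes),
            "core_fractions": {k: round(v, 6) for k, v in result.core_fractions.items()},
            "n_common_dv": len(result.common_affected["DV"]),
            "n_cross_region_hubs": len(result.cross_region_hubs),
            "priority_genes": result.priority_genes,
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "report.md").write_text(_render_report(report))
    return report


def _run_region(config: PipelineConfig, region: str, out: Path) -> dict:
    paths = config.regions[region]
    rdir = out / region
    rdir.mkdir(parents=True, exist_ok=True)

    counts = _stage(f"{region}/read")(preprocess.read_counts)(
        paths["counts"], paths["metadata"]
    )
    filtered = _stage(f"{region}/filter")(preprocess.filter_by_cpm)(
        counts, config.min_cpm
    )
    expr = _stage(f"{region}/normalize")(preprocess.upper_quartile_normalize)(filtered)

    adj_full = _stage(f"{region}/adjacency")(network.adjacency)(
        expr, beta=config.beta, signed=config.signed
    )
    adj = _stage(f"{region}/cull")(network.cull_network)(
        adj_full, mode=config.cull_mode, fraction=config.cull_fraction
    )
    partition = _stage(f"{region}/modules")(network.detect_modules)(
        adj,
        cut_height=config.cut_height,
        min_cluster_size=config.min_cluster_size,
        deep_split=config.deep_split,
    )
    profile = network.intramodular_connectivity(adj, partition)
    hubs = network.hub_genes(profile, config.hub_threshold)

    de = _stage(f"{region}/de")(differential.de_test)(filtered)
    dv = _stage(f"{region}/dv")(differential.dv_test)(expr)
    expr_high, expr_low = expr.line_split()
    net_genes = adj.genes
    changes = _stage(f"{region}/edges")(differential.edge_changes)(
        _sub_expr(expr_high, net_genes),
        _sub_expr(expr_low, net_genes),
        net_genes,
        delta_min=config.delta_min,
        p_max=config.edge_p,
    )
    dw = differential.dw_test(changes)

    table = pd.DataFrame(index=filtered.genes)
    table["de_log2fc"] = de["log2fc"]
    table["de_pvalue"] = de["pvalue"]
    table["dv_f_statistic"] = dv["f_statistic"]
    table["dv_pvalue"] = dv["pvalue"]
    table["dv_direction"] = dv["direction"]
    table["dw_changed_edges"] = dw["changed_edges"].reindex(table.index)
    table["dw_trials"] = dw["trials"].reindex(table.index)
    table["dw_pvalue"] = dw["pvalue"].reindex(table.index)

    _, de_flags = differential.sgof_adjust(
        table["de_pvalue"].fillna(1.0), config.sgof_gamma, config.sgof_alpha
    )
    table["de_sig"] = de_flags
    _, dv_flags = differential.sgof_adjust(
        table["dv_pvalue"].fillna(1.0), config.sgof_gamma, config.sgof_alpha
    )
    table["dv_sig"] = dv_flags
    dw_p = dw["pvalue"]
    if config.adjust_dw:
        _, dw_flags = differential.sgof_adjust(
            dw_p, config.sgof_gamma, config.sgof_alpha
        )
    else:
        dw_flags = (dw_p < 0.05).to_numpy()
    dw_sig = pd.Series(list(dw_flags), index=dw_p.index, dtype=bool)
    table["dw_sig"] = dw_sig.reindex(table.index, fill_value=False).astype(bool)

    ph, pl = screen.line_connectivity(
        _sub_expr(expr_high, net_genes),
        _sub_expr(expr_low, net_genes),
        partition,
        beta=config.beta,
        signed=config.signed,
    )
    assigned = [g for g in net_genes if partition.assignment[g] != network.UNASSIGNED]
    shift = screen.connectivity_shift_test(ph, pl, assigned) if len(assigned) >= 2 else (0, 0, 1)
    transitions = screen.hub_transitions(ph, pl, config.hub_threshold)

    _write_tsv(table, rdir / "diff_results.tsv")
    _write_tsv(profile.table, rdir / "connectivity.tsv")
    partition.assignment.rename("module").to_frame().to_csv(
        rdir / "modules.tsv", sep="\t", index_label="gene"
    )
    _write_tsv(transitions, rdir / "hub_transitions.tsv", index_label="row")
    _write_tsv(
        changes.to_frame()[lambda d: d["changed"]],
        rdir / "changed_edges.tsv",
        index_label="row",
    )

    module_sizes = {
        m: len(partition.members(m)) for m in partition.modules
    }
    module_sizes[network.UNASSIGNED] = int(
        (partition.assignment == network.UNASSIGNED).sum()
    )
    return {
        "expr": expr,
        "adjacency": adj,
        "partition": partition,
        "profile": profile,
        "hubs": hubs,
        "diff": table,
        "n_expressed": len(filtered.genes),
        "n_network": len(net_genes),
        "module_sizes": module_sizes,
        "shift": {
            "mean_high": round(float(shift[0]), 6),
            "mean_low": round(float(shift[1]), 6),
            "pvalue": float(shift[2]),
        },
        "profiles_by_line": (ph, pl),
    }


def _sub_expr(expr, genes):
    return screen._subset(expr, genes)


def _render_report(report: dict) -> str:
    lines = ["# Differential coexpression pipeline report", ""]
    lines.append("## Parameters")
    for k in sorted(report["parameters"]):
        lines.append(f"- {k}: {report['parameters'][k]}")
    lines.append("")
    for region in sorted(report["regions"]):
        r = report["regions"][region]
        lines.append(f"## Region {region}")
        lines.append(
            f"- expressed genes: {r['n_genes_expressed']}; network genes: {r['n_genes_network']}"
        )
        sizes = ", ".join(f"{m}={s}" for m, s in sorted(r["modules"].items()))
        lines.append(f"- modules: {sizes}")
        lines.append(
            f"- significant genes: DE={r['n_de']}, DV={r['n_dv']}, DW={r['n_dw']}; hubs={r['n_hubs']}"
        )
        s = r["connectivity_shift"]
        lines.append(
            f"- intramodular connectivity (assigned genes): High {s['mean_high']:.3f} vs "
            f"Low {s['mean_low']:.3f} (p={s['pvalue']:.3g}; genes are correlated, "
            "treat as descriptive)"
        )
        lines.append("")
    if "overlaps" in report:
        lines.append("## Cross-region overlaps (Venn cells)")
        for stat in sorted(report["overlaps"]):
            cells = ", ".join(
                f"{k}:{v}" for k, v in sorted(report["overlaps"][stat].items())
            )
            lines.append(f"- {stat}: {cells}")
        lines.append("")
    if "preservation" in report:
        p = report["preservation"]
        lines.append("## Module preservation")
        lines.append(
            f"- {p['n_preserved']}/{p['n_pairs']} region-pair modules preserved "
            f"(Zsummary > 2), {p['n_highly_preserved']} highly preserved (> 10)"
        )
        lines.append("")
    if "screen" in report:
        s = report["screen"]
        lines.append("## Priority gene screen")
        lines.append(f"- designated affected modules: {s['designated_modules']}")
        lines.append(
            f"- core module genes: {s['core_module_size']} "
            f"(overlap fractions {s['core_fractions']})"
        )
        lines.append(
            f"- common DV genes: {s['n_common_dv']}; cross-region hubs: {s['n_cross_region_hubs']}"
        )
        lines.append(f"- priority genes: {', '.join(s['priority_genes']) or '(none)'}")
        lines.append("")
    return "\n".join(lines)
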