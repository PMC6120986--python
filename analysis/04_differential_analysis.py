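#!/usr/bin/env python
"""Per-region DE / DV / DW statistics with SGoF adjustment and the
cross-region overlap (Venn) summary, scored against the planted truth."""

import json

import pandas as pd

from coexdiff import differential
from coexdiff.preprocess import ExprMatrix

from _common import RESULTS, load_fixture, network_region, preprocess_region


def main() -> None:
    fixture = load_fixture()
    out = RESULTS / "differential"
    out.mkdir(parents=True, exist_ok=True)
    sig_sets = {"DE": {}, "DV": {}, "DW": {}}
    for region, (truth, counts) in fixture.items():
        filtered, expr = preprocess_region(counts)
        _, adj, _, _ = network_region(expr)

        de = differential.de_test(filtered)
        dv = differential.dv_test(expr)
        eh, el = expr.line_split()
        genes = adj.genes
        sub = lambda e: ExprMatrix(e.values.loc[genes], e.normalization_factors,
                                   e.metadata)
        changes = differential.edge_changes(sub(eh), sub(el), genes)
        dw = differential.dw_test(changes)

        table = pd.DataFrame(index=filtered.genes)
        table["de_log2fc"], table["de_pvalue"] = de["log2fc"], de["pvalue"]
        table["dv_f"], table["dv_pvalue"] = dv["f_statistic"], dv["pvalue"]
        table["dv_direction"] = dv["direction"]
        table["dw_changed"] = dw["changed_edges"].reindex(table.index)
        table["dw_pvalue"] = dw["pvalue"].reindex(table.index)
        for stat, pcol in (("de", "de_pvalue"), ("dv", "dv_pvalue")):
            _, flags = differential.sgof_adjust(table[pcol].fillna(1.0))
            table[f"{stat}_sig"] = flags
        _, dw_flags = differential.sgof_adjust(dw["pvalue"])
        table["dw_sig"] = pd.Series(list(dw_flags), index=dw.index).reindex(
            table.index, fill_value=False)
        table.to_csv(out / f"{region}_diff_results.tsv", sep="\t",
                     float_format="%.6g", index_label="gene")

        for stat in ("DE", "DV", "DW"):
            sig_sets[stat][region] = set(table.index[table[f"{stat.lower()}_sig"]])
        planted_dv = set(truth.dv_genes)
        called_dv = sig_sets["DV"][region]
        sens = len(called_dv & planted_dv) / len(planted_dv)
        dv_dir = table.loc[sorted(called_dv & planted_dv), "dv_direction"]
        print(f"{region}: DE={len(sig_sets['DE'][region])}, "
              f"DV={len(called_dv)} (planted sensitivity {sens:.2f}, "
              f"direction High in {(dv_dir == 'High').mean():.0%}), "
              f"DW={len(sig_sets['DW'][region])}; "
              f"changed edges {int(changes.changed.sum())} "
              f"of {len(changes.changed)}")

    venn = {stat: differential.overlap_sets(sig_sets[stat]) for stat in sig_sets}
    (out / "venn.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
    for stat in ("DE", "DV", "DW"):
        print(f"{stat} common to all regions: {len(venn[stat]['common'])}")


if __name__ == "__main__":
    main()
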