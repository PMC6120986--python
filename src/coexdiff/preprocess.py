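"""Count-matrix ingestion, expression filtering and normalization.

The pipeline starts from a gene x sample matrix of read counts with a
sample-metadata table (selection line High/Low, brain region, sex).  Genes
are kept when their mean counts-per-million (CPM) across all samples exceeds
a threshold (default: 1 CPM), and expression values entering all correlation
and variance analyses are upper-quartile-normalized log2 CPM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_META_COLUMNS = ("line", "region", "sex")
LINES = ("High", "Low")


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema."""


@dataclass
class CountMatrix:
    """Integer gene x sample read counts plus per-sample metadata.

    ``counts`` is indexed by gene id with sample ids as columns; ``metadata``
    is indexed by sample id and carries at least line/region/sex columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise SchemaError(f"duplicate gene id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise SchemaError(f"duplicate sample id: {dup!r}")
        missing = [s for s in c.columns if s not in self.metadata.index]
        if missing:
            raise SchemaError(f"samples missing from metadata: {missing}")
        for col in REQUIRED_META_COLUMNS:
            if col not in self.metadata.columns:
                raise SchemaError(f"metadata lacks required column {col!r}")
        vals = c.to_numpy()
        if not np.isfinite(vals).all():
            gene = c.index[np.where(~np.isfinite(vals))[0][0]]
            raise SchemaError(f"non-finite count for gene {gene!r}")
        if (vals < 0).any():
            gene = c.index[np.where((vals < 0).any(axis=1))[0][0]]
            raise SchemaError(f"negative count for gene {gene!r}")
        if not np.allclose(vals, np.round(vals)):
            gene = c.index[np.where(~np.isclose(vals, np.round(vals)).all(axis=1))[0][0]]
            raise SchemaError(f"non-integer count for gene {gene!r}")
        bad = set(self.metadata.loc[list(c.columns), "line"]) - set(LINES)
        if bad:
            raise SchemaError(f"unknown line labels {sorted(bad)}; expected {LINES}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def line_samples(self, line: str) -> list[str]:
        meta = self.metadata.loc[list(self.counts.columns)]
        return [s for s in self.counts.columns if meta.at[s, "line"] == line]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.metadata)


@dataclass
class ExprMatrix:
    """Normalized log2 CPM expression values with per-sample factors."""

    values: pd.DataFrame
    normalization_factors: pd.Series
    metadata: pd.DataFrame = field(default=None)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def line_samples(self, line: str) -> list[str]:
        meta = self.metadata.loc[list(self.values.columns)]
        return [s for s in self.values.columns if meta.at[s, "line"] == line]

    def line_split(self) -> tuple["ExprMatrix", "ExprMatrix"]:
        """Return (high, low) ExprMatrix views split on the line label."""
        out = []
        for line in LINES:
            cols = self.line_samples(line)
            out.append(
                ExprMatrix(
                    self.values[cols],
                    self.normalization_factors.loc[cols],
                    self.metadata,
                )
            )
        return tuple(out)


def read_counts(path_counts, path_metadata) -> CountMatrix:
    """Read a counts TSV (first column gene id) and a metadata TSV.

    Sample order is taken from the counts file.  Schema violations raise
    :class:`SchemaError` naming the offending row.
    """
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    counts.index.name = None
    meta = pd.read_csv(path_metadata, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise SchemaError(f"duplicate metadata sample id: {dup!r}")
    return CountMatrix(counts, meta)


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: counts / library size x 1e6, per sample."""
    totals = counts.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero library size")
    return counts.counts / totals * 1e6


def filter_by_cpm(counts: CountMatrix, threshold: float = 1.0) -> CountMatrix:
    """Keep genes whose mean CPM across all samples is strictly > threshold."""
    if threshold < 0:
        raise ValueError("CPM threshold must be non-negative")
    mean_cpm = cpm(counts).mean(axis=1)
    keep = mean_cpm.index[mean_cpm > threshold]
    return CountMatrix(counts.counts.loc[keep], counts.metadata)


def upper_quartile_factors(counts: CountMatrix) -> pd.Series:
    """Per-sample upper-quartile normalization factors, geometric mean 1.

    The 75th percentile (linear interpolation) of each sample's counts is
    taken over genes with nonzero total count, divided by the library size,
    and rescaled so the factors multiply to 1.
    """
    c = counts.counts
    totals = c.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    nonzero = c.loc[c.sum(axis=1) > 0]
    if nonzero.shape[0] == 0:
        raise ValueError("no genes with nonzero total count")
    uq = nonzero.quantile(0.75, axis=0, interpolation="linear")
    if (uq <= 0).any():
        bad = uq.index[uq <= 0][0]
        raise ValueError(f"sample {bad!r} has zero upper quartile; filter first")
    rel = uq / totals
    factors = rel / np.exp(np.log(rel).mean())
    factors.name = "factor"
    return factors


def upper_quartile_normalize(counts: CountMatrix, pseudocount: float = 0.5) -> ExprMatrix:
    """Upper-quartile-normalized log2 CPM.

    values = log2((count + p_s) / (factor_s x library_s) x 1e6) where p_s is
    the pseudocount scaled by the sample's effective library size relative to
    the mean, which keeps the transform exactly invariant to rescaling whole
    samples.
    """
    factors = upper_quartile_factors(counts)
    totals = counts.counts.sum(axis=0)
    eff_lib = factors * totals
    pseudo = pseudocount * eff_lib / eff_lib.mean()
    values = np.log2((counts.counts + pseudo) / eff_lib * 1e6)
    return ExprMatrix(values, factors, counts.metadata.copy())


def region_fold_differences(
    expr_by_region: dict[str, ExprMatrix], fold: float = 10.0
) -> pd.DataFrame:
    """Genes with >= fold difference in mean linear expression between regions.

    Means are taken on the linear (2**log2) scale over each region's samples;
    every unordered region pair is scanned and flagged rows report the higher
    region and the ratio.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    regions = sorted(expr_by_region)
    shared = None
    for r in regions:
        g = set(expr_by_region[r].genes)
        shared = g if shared is None else shared & g
    if not shared:
        raise ValueError("no genes shared across regions")
    shared = sorted(shared)
    means = {
        r: np.power(2.0, expr_by_region[r].values.loc[shared]).mean(axis=1)
        for r in regions
    }
    rows = []
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            ratio = means[a] / means[b]
            for gene in shared:
                rr = ratio[gene]
                if rr >= fold or rr <= 1.0 / fold:
                    rows.append(
                        {
                            "gene": gene,
                            "region_pair": f"{a}/{b}",
                            "higher_region": a if rr >= fold else b,
                            "ratio": float(max(rr, 1.0 / rr)),
                        }
                    )
    out = pd.DataFrame(rows, columns=["gene", "region_pair", "higher_region", "ratio"])
    return out.sort_values(["region_pair", "gene"]).reset_index(drop=True)
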