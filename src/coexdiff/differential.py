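"""Per-gene differential expression, variability and wiring statistics.

DE: a self-contained negative-binomial exact-style test on counts,
conditional on the High+Low group totals after rescaling samples to a
common library size, with per-gene method-of-moments dispersions shrunk
50/50 toward the trimmed mean of all genewise dispersions (an approximation
of empirical-Bayes "tagwise" shrinkage; numerical parity with edgeR is not a
goal).

DV: the classical two-sided variance-ratio F test on log expression
(High variance over Low variance), as in R's var.test.

DW: every unordered gene pair is screened for a correlation change between
lines (|delta r| > 0.5 and Fisher-z p < 0.01); each gene's count of changed
edges is then tested against an exact upper-tail binomial whose rate is the
network-wide incidence of changed edges.

Multiple testing uses the binomial sequential-goodness-of-fit (SGoF)
procedure: a binomial metatest of how many p-values fall below gamma,
declaring the R smallest p-values significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .preprocess import CountMatrix, ExprMatrix


# ---------------------------------------------------------------------------
# DE: conditional negative-binomial exact test
# ---------------------------------------------------------------------------

def _mom_dispersions(scaled: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Pooled method-of-moments NB dispersion per gene, shrunk 50/50."""
    num = np.zeros(scaled.shape[0])
    den = np.zeros(scaled.shape[0])
    for idx in groups:
        sub = scaled[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (v - m)
        den += w * np.maximum(m, 1e-8) ** 2
    phi = np.maximum(num / den, 0.0)
    trimmed = stats.trim_mean(phi, 0.1)
    return np.maximum(0.5 * phi + 0.5 * trimmed, 1e-6)


def _nb_exact_pvalue(s1: float, s2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided doubled-tail p for group sums under a common NB mean.

    Group sums of n iid NB(mu, phi) are NB(n*mu, phi/n).  Conditioning on
    t = s1 + s2, the two-sided p doubles the smaller tail of the conditional
    law of the first group's sum.  The summation window is clipped to
    +/- 12 conditional standard deviations (the mass outside is negligible
    at any reportable p).
    """
    t = int(round(s1 + s2))
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    r1, r2 = n1 / phi, n2 / phi  # NB size parameters of the group sums
    m1, m2 = n1 * mu, n2 * mu
    v1 = m1 * (1.0 + phi * mu)
    v2 = m2 * (1.0 + phi * mu)
    sd = np.sqrt(v1 * v2 / (v1 + v2)) if (v1 + v2) > 0 else 1.0
    center = t * n1 / (n1 + n2)
    lo = max(0, int(np.floor(center - 12 * sd - 8)))
    hi = min(t, int(np.ceil(center + 12 * sd + 8)))
    y1 = int(round(s1))
    ks = np.arange(lo, hi + 1)
    # both group sums share the NB success probability, so the conditional
    # law given t is negative-hypergeometric; the shared p-terms cancel and
    # the unnormalized log-weights need only the gamma-function parts
    logw = (
        gammaln(ks + r1)
        - gammaln(ks + 1.0)
        + gammaln(t - ks + r2)
        - gammaln(t - ks + 1.0)
    )
    logz = logsumexp(logw)
    probs = np.exp(logw - logz)
    if y1 < lo:
        lower, upper = 0.0, 1.0
    elif y1 > hi:
        lower, upper = 1.0, 0.0
    else:
        pos = y1 - lo
        lower = float(probs[: pos + 1].sum())
        upper = float(probs[pos:].sum())
    return float(min(1.0, 2.0 * min(lower, upper)))


def de_test(
    counts: CountMatrix,
    line_labels: pd.Series | None = None,
    dispersion: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-group NB exact-style DE test (High vs Low) per gene.

    Returns a DataFrame with log2fc (High over Low, computed on normalized
    group means with a 0.5 prior count) and a two-sided p-value.
    """
    if line_labels is None:
        line_labels = counts.metadata.loc[list(counts.samples), "line"]
    labels = pd.Series(line_labels).loc[list(counts.samples)]
    hi = np.where(labels.to_numpy() == "High")[0]
    lo = np.where(labels.to_numpy() == "Low")[0]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("each line needs at least 2 samples")
    raw = counts.counts.to_numpy(dtype=float)
    libs = raw.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("zero library size")
    # upper-quartile effective library sizes: robust to composition shifts
    # when a minority of genes move between lines
    from .preprocess import upper_quartile_factors

    eff = (upper_quartile_factors(counts) * libs).to_numpy()
    common = np.exp(np.mean(np.log(eff)))
    scaled = raw * (common / eff)[None, :]
    if dispersion is None:
        phi = _mom_dispersions(scaled, [hi, lo])
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (raw.shape[0],)).copy()
        phi = np.maximum(phi, 1e-6)
    s_hi = scaled[:, hi].sum(axis=1)
    s_lo = scaled[:, lo].sum(axis=1)
    m_hi = s_hi / len(hi)
    m_lo = s_lo / len(lo)
    log2fc = np.log2((m_hi + 0.5) / (m_lo + 0.5))
    pvals = np.array(
        [
            _nb_exact_pvalue(s_hi[g], s_lo[g], len(hi), len(lo), phi[g])
            for g in range(raw.shape[0])
        ]
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "dispersion": phi},
        index=counts.genes,
    )


# ---------------------------------------------------------------------------
# DV: variance-ratio F test
# ---------------------------------------------------------------------------

def dv_test(expr: ExprMatrix, line_labels: pd.Series | None = None) -> pd.DataFrame:
    """Two-sided F test of High-line vs Low-line variance per gene.

    F = var(High)/var(Low) on log expression, p from F(n_high-1, n_low-1).
    Genes with zero variance in either line get NaN statistics and are
    flagged excluded.
    """
    if line_labels is None:
        line_labels = expr.metadata.loc[list(expr.samples), "line"]
    labels = pd.Series(line_labels).loc[list(expr.samples)]
    hi_cols = labels.index[labels == "High"]
    lo_cols = labels.index[labels == "Low"]
    if len(hi_cols) < 3 or len(lo_cols) < 3:
        raise ValueError("each line needs at least 3 samples")
    v_hi = expr.values[hi_cols].var(axis=1, ddof=1)
    v_lo = expr.values[lo_cols].var(axis=1, ddof=1)
    d1, d2 = len(hi_cols) - 1, len(lo_cols) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = v_hi / v_lo
    valid = (v_hi > 0) & (v_lo > 0)
    cdf = stats.f.cdf(f.where(valid), d1, d2)
    p = np.minimum(1.0, 2.0 * np.minimum(cdf, 1.0 - cdf))
    out = pd.DataFrame(
        {
            "f_statistic": f,
            "pvalue": p,
            "direction": np.where(f >= 1.0, "High", "Low"),
            "excluded": ~valid,
        },
        index=expr.genes,
    )
    out.loc[~valid, ["f_statistic", "pvalue"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# SGoF multiple-testing adjustment
# ---------------------------------------------------------------------------

def sgof_adjust(
    pvalues, gamma: float = 0.05, alpha: float = 0.05
) -> tuple[int, np.ndarray]:
    """Binomial SGoF: returns (R, boolean flags for the R smallest p-values).

    F = #{p <= gamma} is compared against Binomial(n, gamma).  Discoveries
    accumulate sequentially: at step j the upper tail P(X >= F - j) under
    Binomial(n - j, gamma) is tested at alpha; R is the first j that fails
    (so R = 0 when the initial metatest is not significant).  Ties among
    p-values break by input index.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return 0, np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    n = p.size
    f_count = int((p <= gamma).sum())
    if f_count == 0:
        return 0, np.zeros(n, dtype=bool)
    js = np.arange(f_count)
    tail = stats.binom.sf(f_count - js - 1, n - js, gamma)
    ok = tail <= alpha
    r = f_count if ok.all() else int(np.argmin(ok))
    flags = np.zeros(n, dtype=bool)
    if r > 0:
        order = np.argsort(p, kind="stable")
        flags[order[:r]] = True
    return r, flags


# ---------------------------------------------------------------------------
# DW: edge-change screen + per-gene binomial
# ---------------------------------------------------------------------------

@dataclass
class EdgeChangeSet:
    """All unordered network-gene pairs with per-line correlations.

    Arrays are condensed (upper triangle, row-major); ``changed`` is the
    conjunction |delta_r| > delta_min and Fisher-z p < p_max.
    """

    genes: list[str]
    i: np.ndarray
    j: np.ndarray
    r_low: np.ndarray
    r_high: np.ndarray
    z_pvalue: np.ndarray
    changed: np.ndarray
    n_low: int
    n_high: int
    delta_min: float = 0.5
    p_max: float = 0.01

    @property
    def delta_r(self) -> np.ndarray:
        return self.r_high - self.r_low

    def to_frame(self) -> pd.DataFrame:
        g = np.asarray(self.genes)
        return pd.DataFrame(
            {
                "gene_a": g[self.i],
                "gene_b": g[self.j],
                "r_low": self.r_low,
                "r_high": self.r_high,
                "delta_r": self.delta_r,
                "z_pvalue": self.z_pvalue,
                "changed": self.changed,
            }
        )


def fisher_z_pvalue(r1: np.ndarray, r2: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-sided p for the difference of two independent correlations."""
    eps = 1e-12
    z1 = np.arctanh(np.clip(r1, -1 + eps, 1 - eps))
    z2 = np.arctanh(np.clip(r2, -1 + eps, 1 - eps))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return 2.0 * stats.norm.sf(np.abs(z))


def edge_changes(
    expr_high: ExprMatrix,
    expr_low: ExprMatrix,
    genes: list[str] | None = None,
    delta_min: float = 0.5,
    p_max: float = 0.01,
) -> EdgeChangeSet:
    """Per-line Pearson correlations and changed-edge flags for all pairs."""
    if genes is None:
        genes = [g for g in expr_high.genes if g in set(expr_low.genes)]
    n_high = expr_high.values.shape[1]
    n_low = expr_low.values.shape[1]
    if n_high <= 4 or n_low <= 4:
        raise ValueError("need more than 4 samples per line for the Fisher z test")
    vh = expr_high.values.loc[genes].to_numpy()
    vl = expr_low.values.loc[genes].to_numpy()
    rh = np.clip(np.corrcoef(vh), -1.0, 1.0)
    rl = np.clip(np.corrcoef(vl), -1.0, 1.0)
    iu, ju = np.triu_indices(len(genes), k=1)
    r_high = rh[iu, ju]
    r_low = rl[iu, ju]
    p = fisher_z_pvalue(r_high, r_low, n_high, n_low)
    changed = (np.abs(r_high - r_low) > delta_min) & (p < p_max)
    return EdgeChangeSet(
        list(genes), iu, ju, r_low, r_high, p, changed, n_low, n_high, delta_min, p_max
    )


def dw_test(changes: EdgeChangeSet) -> pd.DataFrame:
    """Per-gene exact upper-tail binomial test on changed-edge counts.

    The binomial rate is the network-wide incidence of changed edges
    (changed / all pairs); each gene has N-1 trials and its incident changed
    edges as successes; p = P(X >= successes) includes the observed count.
    """
    n = len(changes.genes)
    if n < 3:
        raise ValueError("need at least 3 network genes")
    total_edges = n * (n - 1) // 2
    if total_edges == 0:
        raise ValueError("network has no edges")
    rate = float(changes.changed.sum()) / total_edges
    successes = np.bincount(changes.i, weights=changes.changed, minlength=n) + np.bincount(
        changes.j, weights=changes.changed, minlength=n
    )
    successes = successes.astype(int)
    trials = n - 1
    p = stats.binom.sf(successes - 1, trials, rate)
    return pd.DataFrame(
        {"changed_edges": successes, "trials": trials, "pvalue": p, "rate": rate},
        index=changes.genes,
    )


# ---------------------------------------------------------------------------
# Cross-region overlap summaries
# ---------------------------------------------------------------------------

def overlap_sets(sets_by_region: dict[str, set]) -> dict:
    """Venn cells, pairwise intersections and the full intersection.

    Cells are the 2^R - 1 disjoint membership patterns keyed by
    "&"-joined region names (regions sorted alphabetically).
    """
    regions = sorted(sets_by_region)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    sets = {r: set(sets_by_region[r]) for r in regions}
    universe = set().union(*sets.values())
    cells: dict[str, dict] = {}
    for mask in range(1, 2 ** len(regions)):
        inside = [r for b, r in enumerate(regions) if mask >> b & 1]
        outside = [r for r in regions if r not in inside]
        members = set(universe)
        for r in inside:
            members &= sets[r]
        for r in outside:
            members -= sets[r]
        key = "&".join(inside)
        cells[key] = {"count": len(members), "members": sorted(members)}
    pairwise = {
        f"{a}&{b}": sorted(sets[a] & sets[b])
        for i, a in enumerate(regions)
        for b in regions[i + 1 :]
    }
    common = sorted(set.intersection(*sets.values()))
    return {"regions": regions, "cells": cells, "pairwise": pairwise, "common": common}
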