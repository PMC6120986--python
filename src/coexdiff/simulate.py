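"""Synthetic two-line RNA-seq count simulator with planted network effects.

Emulates the study design being analysed: two selection lines (High/Low
ethanol preference), one brain region per call, correlated gene modules, and
planted line effects on gene means (DE), log-scale variances (DV) and
pairwise correlations (DW).

Model
-----
Each gene g carries a latent log2 expression for sample s of line L

    z_gs = mu_g + delta_g[L] + s_g[L] * (a_g[L] * f_{m(g),s} + sqrt(1 - a_g[L]^2) * e_gs)

with module factor f ~ N(0,1) shared within a module, idiosyncratic noise
e ~ N(0,1), baseline mu_g, DE shift delta (log2FC in the High line), latent
scale s (inflated by sqrt(dv_ratio) for DV genes in the High line) and
loading a.  Counts are negative binomial with mean proportional to 2**z and
a per-gene dispersion.  Within-module latent correlation between genes g, h
is a_g[L] * a_h[L]; "rewired" (DW) genes have line-specific loadings so their
correlations differ between lines while module membership is intact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CountMatrix

BACKGROUND = 0  # module id for unstructured genes


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 600
    n_modules: int = 3
    module_size: int = 150
    n_samples_per_line: int = 50
    de_fraction: float = 0.05
    de_effect: float = 1.0  # |log2 fold-change| planted in the High line
    dv_fraction: float = 0.15
    dv_ratio: float = 4.0  # High/Low latent variance ratio
    dw_fraction: float = 0.002  # fraction of within-module pairs rewired
    dv_module_concentration: float = 0.7  # fraction of DV genes from module 1
    latent_factor_loading: float = 0.7
    nb_dispersion: float = 0.02
    seed: int = 0
    # second-tier knobs (kept at the study conditions; see docs/methods.md)
    latent_sd: float = 0.8  # per-gene log2 biological scale
    baseline_log2_mean: float = 7.2
    baseline_log2_sd: float = 1.5
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    dw_loading_shift: float = 0.25  # High +shift / Low -shift on dw-gene loadings
    n_hub_genes: int = 0  # genes of module 1 given hub_loading in both lines
    hub_loading: float = 0.95
    region: str = "R1"

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module_size x n_modules exceeds n_genes")
        for name in ("de_fraction", "dv_fraction", "dw_fraction", "dv_module_concentration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_samples_per_line < 4:
            raise ValueError("need at least 4 samples per line")
        if not 0.0 <= self.latent_factor_loading < 1.0:
            raise ValueError("latent_factor_loading must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.library_size_range[0] <= 0 or self.library_size_range[1] < self.library_size_range[0]:
            raise ValueError("invalid library_size_range")
        if self.n_hub_genes > self.module_size:
            raise ValueError("n_hub_genes exceeds module_size")


@dataclass
class SyntheticTruth:
    """Planted ground truth: everything needed to score downstream stages."""

    genes: list[str]
    module_assignment: dict[str, int]  # gene -> module id (0 = background)
    de_genes: dict[str, float]  # gene -> planted log2FC (High - Low)
    dv_genes: dict[str, float]  # gene -> planted High/Low variance ratio
    dw_edges: list[tuple[str, str, float, float]]  # (a, b, r_low, r_high)
    dw_genes: list[str]  # rewired genes (line-specific loadings)
    hub_genes: list[str]
    baseline_log2: dict[str, float]
    loading_low: dict[str, float]  # signed loadings (sign fixed across lines)
    loading_high: dict[str, float]
    nb_dispersion: dict[str, float]
    latent_sd: float
    library_size_range: tuple[int, int]
    n_samples_per_line: int
    seed: int
    region: str = "R1"

    def __post_init__(self) -> None:
        assigned = set(self.module_assignment)
        if assigned != set(self.genes):
            raise ValueError("every gene must appear in exactly one module or background")
        for g, ratio in self.dv_genes.items():
            if ratio <= 0:
                raise ValueError(f"variance ratio for {g} must be > 0")
        for a, b, r_low, r_high in self.dw_edges:
            if not (abs(r_low) < 1 and abs(r_high) < 1):
                raise ValueError(f"|r| must be < 1 for edge ({a}, {b})")
            if r_low == r_high:
                raise ValueError(f"planted r_low == r_high for edge ({a}, {b})")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["library_size_range"] = list(d["library_size_range"])
        d["dw_edges"] = [list(e) for e in d["dw_edges"]]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["library_size_range"] = tuple(d["library_size_range"])
        d["dw_edges"] = [tuple(e) for e in d["dw_edges"]]
        return cls(**d)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` proportional to `weights` (exact sum)."""
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw the planted ground truth for one region (deterministic in seed)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_genes
    width = max(4, len(str(n)))
    genes = [f"G{i:0{width}d}" for i in range(n)]

    assignment: dict[str, int] = {}
    for i, g in enumerate(genes):
        m = i // config.module_size + 1
        assignment[g] = m if m <= config.n_modules else BACKGROUND

    module_genes = {
        m: [g for g in genes if assignment[g] == m]
        for m in range(1, config.n_modules + 1)
    }
    hub_genes = module_genes[1][: config.n_hub_genes] if config.n_modules else []

    # DE: any non-hub gene, random sign on the planted log2FC (a mean shift
    # would attenuate a hub's pooled-sample correlations, contradicting its
    # planted role)
    hub_idx = {genes.index(g) for g in hub_genes}
    n_de = round(config.de_fraction * n)
    candidates = np.array([i for i in range(n) if i not in hub_idx])
    de_pick = sorted(rng.choice(candidates, size=n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_de)
    de_genes = {genes[i]: float(s * config.de_effect) for i, s in zip(de_pick, signs)}

    # DW: exactly round(dw_fraction x within-module pairs) edges, sampled
    # among pairs of per-module "rewired" gene sets (line-specific loadings)
    pair_counts = np.array(
        [math.comb(len(module_genes[m]), 2) for m in range(1, config.n_modules + 1)]
    )
    dw_total = round(config.dw_fraction * pair_counts.sum()) if config.n_modules else 0
    per_module = (
        _largest_remainder(dw_total, pair_counts)
        if dw_total
        else np.zeros(len(pair_counts), dtype=int)
    )
    a = config.latent_factor_loading
    a_hi = min(0.99, a + config.dw_loading_shift)
    a_lo = max(0.01, a - config.dw_loading_shift)
    dw_genes: list[str] = []
    dw_edges: list[tuple[str, str, float, float]] = []
    loading_low = {g: (a if assignment[g] != BACKGROUND else 0.0) for g in genes}
    loading_high = dict(loading_low)
    for g in hub_genes:
        loading_low[g] = loading_high[g] = config.hub_loading
    for m_idx, m in enumerate(range(1, config.n_modules + 1)):
        e_m = int(per_module[m_idx])
        if e_m == 0:
            continue
        candidates = [g for g in module_genes[m] if g not in hub_genes]
        k = 2
        while math.comb(k, 2) < e_m:
            k += 1
        if k > len(candidates):
            raise ValueError(f"module {m} too small for {e_m} rewired edges")
        chosen = sorted(rng.choice(len(candidates), size=k, replace=False))
        mod_dw = [candidates[i] for i in chosen]
        for g in mod_dw:
            loading_low[g] = a_lo
            loading_high[g] = a_hi
        pairs = [
            (mod_dw[i], mod_dw[j])
            for i in range(k)
            for j in range(i + 1, k)
        ]
        take = sorted(rng.choice(len(pairs), size=e_m, replace=False))
        for t in take:
            ga, gb = pairs[t]
            dw_edges.append(
                (ga, gb, float(a_lo * a_lo), float(a_hi * a_hi))
            )
        dw_genes.extend(mod_dw)

    # Alternate loading signs within each module so coherent factor swings
    # cancel in the per-sample aggregate (keeps quantile normalization from
    # coupling unrelated genes); unsigned adjacency is indifferent to sign.
    # Hub and rewired genes keep +1 so planted edge correlations stay
    # positive and easy to reason about.
    fixed_sign = set(hub_genes) | set(dw_genes)
    for m in range(1, config.n_modules + 1):
        flip = False
        for g in module_genes[m]:
            if g in fixed_sign:
                continue
            if flip:
                loading_low[g] = -loading_low[g]
                loading_high[g] = -loading_high[g]
            flip = not flip

    # DV: module genes, excluding rewired genes (keeps variance vs wiring
    # effects orthogonal); hub genes are included first so multi-region
    # fixtures can plant cross-region DV hubs, and the remainder is drawn
    # mostly from module 1 (differential variability concentrates in a
    # single module per region in the data this emulates)
    n_dv = round(config.dv_fraction * n)
    pool_m1 = [
        g for g in module_genes.get(1, [])
        if g not in dw_genes and g not in hub_genes
    ]
    pool_rest = [
        g
        for m in range(2, config.n_modules + 1)
        for g in module_genes[m]
        if g not in dw_genes and g not in hub_genes
    ]
    dv_list = list(hub_genes)[: n_dv]
    remaining = n_dv - len(dv_list)
    n_from_m1 = min(round(config.dv_module_concentration * remaining), len(pool_m1))
    n_from_rest = remaining - n_from_m1
    if n_from_rest > len(pool_rest):
        raise ValueError("dv_fraction too large for the available module genes")
    if n_from_m1 > 0:
        picked = sorted(rng.choice(len(pool_m1), size=n_from_m1, replace=False))
        dv_list += [pool_m1[i] for i in picked]
    if n_from_rest > 0:
        picked = sorted(rng.choice(len(pool_rest), size=n_from_rest, replace=False))
        dv_list += [pool_rest[i] for i in picked]
    dv_genes = {g: float(config.dv_ratio) for g in dv_list}

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    # planted hubs are solidly expressed: low-abundance draws would let
    # count noise attenuate exactly the correlations they are planted for
    for i in hub_idx:
        baseline[i] = max(baseline[i], config.baseline_log2_mean)

    return SyntheticTruth(
        genes=genes,
        module_assignment=assignment,
        de_genes=de_genes,
        dv_genes=dv_genes,
        dw_edges=dw_edges,
        dw_genes=sorted(dw_genes),
        hub_genes=list(hub_genes),
        baseline_log2={g: float(b) for g, b in zip(genes, baseline)},
        loading_low=loading_low,
        loading_high=loading_high,
        nb_dispersion={g: float(config.nb_dispersion) for g in genes},
        latent_sd=float(config.latent_sd),
        library_size_range=tuple(config.library_size_range),
        n_samples_per_line=config.n_samples_per_line,
        seed=config.seed,
        region=config.region,
    )


def simulate_expression(truth: SyntheticTruth, seed: int | None = None) -> CountMatrix:
    """Sample a two-line count matrix (High then Low samples) from the truth.

    Random streams are split deterministically from one root seed
    (default: the truth's recorded seed): one child per (line, purpose) with
    purposes factors / idiosyncratic noise / counts, plus one for library
    sizes, so partial reruns reproduce each block.
    """
    root = truth.seed if seed is None else seed
    ss = np.random.SeedSequence([root, 202])
    children = ss.spawn(7)
    streams = {
        ("High", "factors"): np.random.default_rng(children[0]),
        ("High", "noise"): np.random.default_rng(children[1]),
        ("High", "counts"): np.random.default_rng(children[2]),
        ("Low", "factors"): np.random.default_rng(children[3]),
        ("Low", "noise"): np.random.default_rng(children[4]),
        ("Low", "counts"): np.random.default_rng(children[5]),
    }
    lib_rng = np.random.default_rng(children[6])

    genes = truth.genes
    n = len(genes)
    n_s = truth.n_samples_per_line
    modules = np.array([truth.module_assignment[g] for g in genes])
    mu = np.array([truth.baseline_log2[g] for g in genes])
    phi = np.array([truth.nb_dispersion[g] for g in genes])
    norm = np.sum(np.power(2.0, mu))  # expected-total normalizer, shared by lines

    blocks = []
    sample_ids, meta_rows = [], []
    module_ids = sorted(set(modules) - {BACKGROUND})
    for line in ("High", "Low"):
        loading = truth.loading_high if line == "High" else truth.loading_low
        a = np.array([loading[g] for g in genes])
        scale = np.full(n, truth.latent_sd)
        delta = np.zeros(n)
        if line == "High":
            for g, fc in truth.de_genes.items():
                delta[genes.index(g)] = fc
            for g, ratio in truth.dv_genes.items():
                scale[genes.index(g)] *= math.sqrt(ratio)
        f = streams[(line, "factors")].standard_normal((len(module_ids), n_s))
        # whiten realized factors (zero mean, identity sample covariance):
        # keeps the planted correlation structure exact instead of convolving
        # it with the sampling spread of shared factors, which would shift a
        # whole module's statistics coherently between lines or couple
        # distinct modules through a chance factor correlation
        if len(module_ids):
            f = f - f.mean(axis=1, keepdims=True)
            if n_s > len(module_ids) + 1:
                cov = f @ f.T / n_s
                f = np.linalg.solve(np.linalg.cholesky(cov), f)
            else:
                f = f / f.std(axis=1, ddof=0, keepdims=True)
        e = streams[(line, "noise")].standard_normal((n, n_s))
        # idiosyncratic noise orthogonal to the factors: a gene's realized
        # noise-factor covariance would otherwise shift its effective
        # loading, which the soft power beta amplifies into large spurious
        # connectivity differences among equally-loaded genes
        if len(module_ids) and n_s > len(module_ids) + 1:
            e = e - e.mean(axis=1, keepdims=True)
            e = e - (e @ f.T / n_s) @ f
        factor_rows = np.zeros((n, n_s))
        for row, m in enumerate(module_ids):
            factor_rows[modules == m] = f[row]
        z = (
            mu[:, None]
            + delta[:, None]
            + scale[:, None] * (a[:, None] * factor_rows + np.sqrt(1 - a[:, None] ** 2) * e)
        )
        libs = lib_rng.integers(
            truth.library_size_range[0], truth.library_size_range[1] + 1, size=n_s
        )
        lam = libs[None, :] * np.power(2.0, z) / norm
        crng = streams[(line, "counts")]
        if np.all(phi == 0):
            counts = crng.poisson(lam)
        else:
            phi_col = np.where(phi == 0, 1e-12, phi)[:, None]
            counts = crng.negative_binomial(1.0 / phi_col, 1.0 / (1.0 + phi_col * lam))
        blocks.append(counts.astype(np.int64))
        for i in range(n_s):
            sid = f"{truth.region}_{line}_{i:03d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "line": line,
                    "region": truth.region,
                    "sex": "F" if i % 2 == 0 else "M",
                }
            )

    counts = pd.DataFrame(np.hstack(blocks), index=genes, columns=sample_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(counts, meta)


def write_fixture(truth: SyntheticTruth, counts: CountMatrix, directory) -> dict[str, Path]:
    """Write counts.tsv, metadata.tsv and truth.json; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    counts.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    paths["truth"].write_text(truth.to_json())
    return paths


def read_fixture(directory) -> tuple[SyntheticTruth, CountMatrix]:
    directory = Path(directory)
    truth = SyntheticTruth.from_json((directory / "truth.json").read_text())
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col=0)
    counts.index.name = None
    meta = pd.read_csv(directory / "metadata.tsv", sep="\t", index_col=0)
    return truth, CountMatrix(counts, meta)


def multi_region_fixture(
    config: SimulationConfig, regions: tuple[str, ...] = ("SH", "CeA", "PL")
) -> dict[str, tuple[SyntheticTruth, CountMatrix]]:
    """Shared planted truth realized independently per region.

    One :func:`generate_truth` call fixes the module labels and the planted
    DE/DV/DW gene and edge sets; each region then gets its own expression
    draw from a region-specific seed, mirroring per-region analyses of lines
    selected once.
    """
    base = generate_truth(config)
    out: dict[str, tuple[SyntheticTruth, CountMatrix]] = {}
    for i, region in enumerate(regions):
        truth = SyntheticTruth(**{**asdict(base), "region": region})
        truth.library_size_range = tuple(truth.library_size_range)
        truth.dw_edges = [tuple(e) for e in truth.dw_edges]
        counts = simulate_expression(truth, seed=config.seed * 1000 + 11 * (i + 1))
        out[region] = (truth, counts)
    return out
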