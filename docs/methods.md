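# Methods

`coexdiff` re-implements, as a tested pipeline, a differential
coexpression-network analysis for comparing two bidirectionally selected
lines (High vs Low ethanol preference) across brain regions, and ships a
synthetic-data generator with planted ground truth so that every stage can
be validated by recovery rather than by eyeballing. This note records the
models, the parameter choices and their rationale, the numerical decisions,
and what the simulation studies do and do not demonstrate about real data.

## Pipeline model

The analysis starts from a gene x sample matrix of RNA-seq read counts per
brain region, with each sample labelled by selection line (High/Low),
region and sex.

**Preprocessing.** Genes are kept when their mean counts-per-million across
all samples exceeds 1 (strictly). Expression entering all correlation and
variance analyses is upper-quartile-normalized log2 CPM: the per-sample
factor is the 75th percentile (linear interpolation) of counts over genes
with nonzero total, divided by library size and rescaled to geometric mean
1. The log2 transform uses pseudocount 0.5 scaled by each sample's relative
effective library size, which makes the transform exactly invariant to
rescaling whole samples; Pearson correlations on the count scale would be
dominated by abundance.

**Network.** Unsigned weighted adjacency `|r|^beta` from Pearson
correlations of log2 CPM, with beta = 6 (a scale-free-fit scan across
powers is provided; the signed variant `((1+r)/2)^beta` is an option). The
network is culled to its high-connectivity core; the default "cumulative"
mode keeps the smallest prefix of genes, ranked by whole-network
connectivity, whose summed connectivity reaches 80% of the total (this
reproduces the roughly 15,000 -> 6,500 gene reduction such analyses
report, whereas keeping the top 80% *of genes* would not). A "quantile"
mode keeping the top fraction of genes is available as a config switch.

**Module detection.** Average-linkage hierarchical clustering of
1 − adjacency, cut by a re-implementation of the dynamic hybrid tree cut
with the standard parameters (cutHeight 0.9995, minClusterSize 100,
deepSplit 4; fixture-scale runs scale minClusterSize with module size):

1. static cut: maximal subtrees entirely below cutHeight;
2. recursive splitting inside each static branch when the relative height
   gap between a branch and its taller child exceeds a deep-split-indexed
   threshold (deepSplit 0..4 -> minimum relative gap 0.25, 0.20, 0.15,
   0.10, 0.05; 4 splits most aggressively) and both children could carry a
   module;
3. clusters below minClusterSize dissolve into "unassigned";
4. a PAM-like pass reassigns an unassigned gene to the module with highest
   mean adjacency when that exceeds its mean adjacency to the unassigned
   pool **and** the corresponding mean dissimilarity is below cutHeight.
   The cap mirrors the reference implementation's maxPamDist behaviour;
   without it, genes with no correlation to anything are assigned to
   modules on noise, since comparing two near-zero means is a coin flip.

Exact equivalence with the reference hybrid cut is a non-goal; the three
exposed parameters and the observable behaviour (separable blocks split,
structureless input unassigned, planted modules recovered) are preserved.
Module labels are colors assigned by decreasing size; ties everywhere
break by ascending gene id for determinism.

**Differential statistics.** Three per-gene statistics compare the lines:

- *DE (means)*: a self-contained negative-binomial exact-style test.
  Samples are rescaled to a common library size using upper-quartile
  effective libraries (robust to composition shifts when a minority of
  genes move); group sums are modelled as NB with per-gene dispersion
  estimated by method of moments, pooled across lines, and shrunk 50/50
  toward the 10%-trimmed mean of all genewise dispersions — a deliberately
  simple stand-in for tagwise empirical-Bayes shrinkage. Because both
  group sums share the NB success probability, the conditional law of one
  group's sum given the total is negative-hypergeometric; the two-sided
  p-value doubles the smaller conditional tail, summed over a window of
  ±12 conditional standard deviations (truncation error is negligible at
  any reportable p). Numerical parity with edgeR is a non-goal; the test
  is validated by calibration (type-I error 0.048–0.056 at alpha 0.05 over
  null simulations) and by log2FC recovery.
- *DV (variances)*: the classical two-sided variance-ratio F test on log2
  expression, F = var(High)/var(Low) with (n_H−1, n_L−1) degrees of
  freedom, as in R's `var.test`. Genes with zero variance in either line
  are excluded and flagged.
- *DW (wiring)*: every unordered pair of network genes is screened for a
  correlation change: changed ⇔ |r_High − r_Low| > 0.5 **and** two-sided
  Fisher-z p < 0.01 (the z statistic divides the atanh difference by
  sqrt(1/(n_H−3) + 1/(n_L−3)); the threshold-only description in the
  source analysis does not name a test, so Fisher z is the documented
  choice). Each gene's count of changed edges is then tested with an exact
  upper-tail binomial: rate = changed edges / all pairs, trials = N−1,
  successes include the observed count. Trials use all pairs among culled
  network genes (the network is treated as a complete weighted graph).

**Multiple testing.** Binomial sequential-goodness-of-fit (SGoF) with
gamma = alpha = 0.05. F = #{p ≤ gamma} is compared against
Binomial(n, gamma); discoveries accumulate sequentially — at step j the
upper tail P(X ≥ F−j) under Binomial(n−j, gamma) is tested at alpha, and R
is the first failing j — so R = 0 whenever the initial metatest is not
significant, and the R smallest p-values (ties by input index) are the
discoveries. This sequential-shrinking rule is the one under which a set
of uniformly tiny p-values is rejected in full (R = n). Headline gene
lists use SGoF-adjusted significance; module-enrichment input lists use
unadjusted p < 0.01. DW p-values receive the same SGoF adjustment by
default (switchable); note that at fixture scale this leaves few
"significant DW genes" even when planted rewired genes are cleanly
top-ranked — the binomial p-value *ranking*, not the adjusted call, is
what the recovery studies score.

**Preservation and enrichment.** Module x gene-set enrichment is the 2x2
Fisher exact test with both one-sided tails reported (enrichment and
depletion — depletion supports "conserved module" claims) and Bonferroni
correction over modules. Cross-region module preservation is scored two
ways: (i) tabulation-based — −log10 Fisher p of the overlap of every
module pair on the shared gene universe; (ii) a permutation Zsummary —
per module, a density statistic (mean within-module adjacency in the test
network) and a connectivity statistic (correlation of within-module
connectivity between reference and test network over module genes), each
standardized against permutation nulls of random same-size gene sets drawn
from all shared network genes, combined as z_summary = median of the two;
interpreted as not preserved (≤ 2), preserved (> 2), highly preserved
(> 10). This composite is a simplification of the reference
implementation's larger statistic menu; agreement is directional
(classification behaviour), never numeric. Generic gene-set enrichment
accepts GMT files, trims sets to the background, and controls FDR across
sets by Benjamini–Hochberg.

**Screen.** Line-specific adjacency is recomputed within each line's
samples at the same beta under the combined-sample module assignment, and
normalized intramodular connectivity (k_norm: within-module connectivity
over the module maximum) is compared per line. The connectivity-shift
p-value is a paired two-sided Wilcoxon signed-rank over the gene set
(exact sign-flip permutation below 5 genes); because genes are correlated
the p-value overstates certainty and is reported as descriptive. Hub =
k_norm > 0.8; hub transitions classify genes crossing that threshold
between lines. The cross-region screen designates per region the module
most enriched in DV genes (smallest Bonferroni p; overridable), takes the
core = genes of the smallest designated module present in all other
designated modules, and returns priority genes = common-DV ∩ cross-region
hubs ∩ core, ordered by maximal k_norm then gene id.

## Synthetic-data generator

Each gene carries a latent log2 expression per sample,

    z = mu_g + delta_g[line] + s_g[line] * ( a_g[line] * f_module + sqrt(1 − a^2) * e ),

with module factor f shared within a module, idiosyncratic noise e,
baseline mu_g ~ N(7.2, 1.5^2) log2 units, and library sizes drawn
uniformly from 0.8–1.2 million reads; counts are negative binomial with
mean proportional to 2^z and dispersion 0.02 (on top of the log-normal
biological layer, whose log2 scale is 0.8). Planted effects:

- *DE*: delta = ±1 log2 units in the High line for 5% of genes;
- *DV*: s multiplied by sqrt(4) in the High line for 15% of genes
  (variance ratio 4, always High > Low, as observed in the data this
  emulates), concentrated 70% in module 1 so each region has one clearly
  DV-enriched module;
- *DW*: per module, a small set of "rewired" genes whose loading is
  a + 0.25 in the High line and a − 0.25 in the Low line; the recorded
  rewired edges are exactly round(dw_fraction x within-module pairs)
  pairs sampled among rewired-gene pairs, with achieved (r_low, r_high)
  from the loading products. Rewiring via gene loadings (rather than a
  factor per edge) keeps module membership intact while giving each
  rewired gene many moderately changed edges — the footprint the per-gene
  binomial screen detects. A gene is never both DV- and DW-planted.
- *hubs* (optional, for multi-region screen fixtures): n_hub_genes of
  module 1 get loading 0.95 in both lines, are planted as DV genes first,
  are excluded from DE planting (a planted mean shift would attenuate
  their pooled-sample correlations) and have baseline abundance floored at
  the baseline mean (low-abundance draws would let count noise attenuate
  exactly the correlations and variance ratio they are planted for).

Defaults are 600 genes = 3 modules x 150 + 150 unstructured background,
50 samples per line (the emulated regions have 54–71 samples total),
loading 0.7. Alternating loading signs within each module keep coherent
factor swings out of the per-sample aggregate so that quantile
normalization does not couple unrelated genes; unsigned adjacency is
indifferent to the sign. Multi-region fixtures reuse one truth (module
memberships and planted sets) with independent expression draws per
region, mirroring per-region assays of lines selected once.

**Conditioned randomness.** The generator's purpose is analytic control of
the planted structure, so two realized-sampling artifacts are removed by
conditioning: module factors are whitened per line (zero mean, identity
sample covariance), and each gene's idiosyncratic noise is projected
orthogonal to the factors. Without the first, the realized
factor-variance ratio between lines — an F(n−1, n−1) spread — shifts a
whole module's correlations and variances coherently, manufacturing
module-wide DV false positives and drowning planted rewiring; without the
second, a gene's realized noise-factor covariance perturbs its effective
loading by ±0.04, which `|r|^6` amplifies into ±30% connectivity spreads
among equally-loaded genes. Gene-level variance noise (what the DV test
sees under the null) is retained: noise norms are not rescaled.

**What the generator does not emulate.** Real data keeps the
shared-factor sampling variability removed above, so real DV/DW analyses
face module-wide correlated fluctuations that these fixtures deliberately
exclude; passing recovery tests therefore demonstrates correctness of the
statistics and plumbing at controlled effect sizes, not field performance
on real tissue. Planted loadings are equal within a module, so
within-module connectivity carries no gene-level signal; one consequence,
visible in the worked example, is that the Zsummary *connectivity*
component is uninformative between independently drawn regions (and its
permutation null is itself inflated, because a random gene set's
module composition induces the same connectivity pattern in both
networks), leaving cross-region preservation to rest on the density
component. Sex effects, batch effects, region-specific expression and
read-level artifacts are out of scope.

## Study-condition and parameter summary

| Parameter | Default | Why |
|---|---|---|
| CPM threshold | mean CPM > 1 | stated inclusion rule for network analyses |
| beta (soft power) | 6 | stated network power; scan provided |
| culling | cumulative 0.8 | matches the reported ~43% gene retention |
| cutHeight / minClusterSize / deepSplit | 0.9995 / 100 / 4 | stated tree-cut parameters |
| hub threshold | k_norm > 0.8 | stated hub definition |
| edge screen | \|dr\| > 0.5, p < 0.01 | stated rewiring thresholds |
| SGoF gamma, alpha | 0.05, 0.05 | procedure defaults |
| Zsummary permutations | 200 | null sd stable to ~5% |
| fixture size | 600 genes, 50/line | desk-scale mirror of 3x(54–71)-sample regions |
| recovery fixtures (DV, screen) | 1,200 genes | SGoF's O(sqrt n) critical-value overhead caps sensitivity at small n; see below |

Simulation-study problem sizes (10 seeds each): module-recovery ARI at
loading 0.8 on 600-gene fixtures; DV recovery and the three-region
priority screen on 1,200-gene fixtures (at 600 genes the binomial SGoF
metatest's critical value, ~39 of 600 at gamma = alpha = 0.05, caps DV
sensitivity near 0.79 regardless of power — an O(sqrt n) overhead of the
procedure that amortizes at larger gene counts); DW decile ranking on
600-gene fixtures; preservation behaviour on 5 seeds; type-I calibration
on 10,000-gene null simulations and 200–1,000 replicate draws.

## Numerical decisions

- Ties break by ascending gene id everywhere (culling order, SGoF flag
  order via stable sort, module label assignment, screen ordering).
- Correlations are clipped to [−1, 1] before powering; atanh arguments to
  ±(1 − 1e−12).
- The DE conditional tail is summed in log space (logsumexp) over a
  ±12-sd window; dispersions are floored at 1e−6.
- Zero-variance genes are dropped from adjacency with a warning; modules
  of size 1 get k_norm 0; "unassigned" genes are never hub candidates.
- Z-scores against permutation nulls floor the null sd at 1e−12 and
  return 0 for degenerate (constant) nulls — the self-comparison case,
  where the density component alone carries the (large) signal.
- Pipeline outputs are written with fixed float formatting and sorted
  keys; reruns with identical configuration are byte-identical.

## Known limitations

- The DE test approximates tagwise empirical-Bayes dispersion shrinkage
  with a two-group moment estimator; heteroskedastic genes (planted DV)
  leak into DE calls at a few percent, as any common-dispersion exact
  test would allow.
- SGoF's discovery count is a global-excess rule: per-region sensitivity
  is capped at (F − critical)/F no matter how strong individual effects
  are, and intersecting calls across regions compounds that attrition.
- The Wilcoxon connectivity-shift p-value ignores gene–gene correlation;
  it is reported as a descriptive index, never as calibrated inference.
- The Zsummary composite is a two-statistic simplification; only its
  classification behaviour (identity -> highly preserved, unstructured
  counterpart -> not preserved) is claimed, and its connectivity
  component is uninformative under the generator's equal loadings.
- Module detection is validated against planted block structure, not
  against the reference hybrid-cut implementation output.
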