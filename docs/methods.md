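# Methods

## Data model and normalization

Input is a genes × cells matrix of non-negative integer UMI counts with
unique gene symbols and cell barcodes, plus per-cell metadata (condition,
animal, cluster). Cluster labels are an input: clustering itself (t-SNE /
density-based or biclustering approaches) is upstream of this package.

Quality control keeps cells with ≥ `min_genes` detected genes **and**
≥ `min_transcripts` total UMIs; both boundaries are inclusive ("at least").
Defaults are 500 genes / 900 transcripts, appropriate for real Drop-seq
depth; the demo analyses scale them down with their shallower simulated
depth.

Normalization is counts-per-cell scaled to 10,000 and natural-log
transformed with pseudocount 1: `ln(1 + c·10⁴/total)`. Natural log and
pseudocount 1 are the convention of the standard single-cell toolchains;
zeros map exactly to zero and within-cell rank order is preserved. Base,
pseudocount and scale are recorded in the matrix provenance and
configurable. "Expressed/detected" always means value > 0 (equivalently raw
count > 0).

## Two-part (bimodal) likelihood-ratio test

For groups *a* and *b* the likelihood factorizes into a Bernoulli detection
part and a Gaussian magnitude part over detected cells with a shared
variance. The LRT statistic is the sum of

* the binomial LRT on detection fractions (1 df), always computed;
* the equal-variance Gaussian LRT on positive values,
  `n_pos · ln(σ̂₀²/σ̂₁²)` (1 df), computed only when both groups have ≥ 2
  positive values (below that the within-group variance is not estimable;
  the df drops accordingly).

p comes from the χ² upper tail at the realized df. The statistic equals the
difference of the numerically maximized full two-part likelihoods (the test
suite verifies this against an independent Nelder-Mead oracle to 1e-6).

Numerical edge cases: when the positive values are constant within groups
but differ between them the Gaussian LRT is +∞; the p-value is floored at
the smallest positive float and flagged (`p_floored`) rather than reported
as 0. When they are constant and identical the contribution is 0.

`logfc` is the difference of group means of the ln-scale normalized values
*including zeros* (so it blends detection-rate and magnitude effects), and
the 0.25 threshold applies to |logfc|. The expression prefilter reads
"detected in ≥ 30% of the cells of one group" as max(frac_a, frac_b) ≥ 0.3.
BH runs within each contrast (per cluster), matching per-cell-type
reporting. Markers contrast a cluster against all remaining cells; a relaxed
reporting mode (unadjusted p < 0.01) exists for rare cell types whose cell
counts cannot support FDR-level discoveries.

Under a shared zero-inflated lognormal null at n = 200/group the test's
type-I error at α = 0.05 measures ≈ 0.05 (the suite accepts [0.02, 0.07]).
At very small n (a handful of cells) the χ² reference is anticonservative —
visible in the pseudobulk tables built on 3 + 3 animal profiles, which is
one more reason rare-cell-type results use the suggestive p < 0.01 label.

## Cluster identity annotation

Cluster markers are overlapped with reference marker sets by the one-sided
hypergeometric (Fisher) test. The query is the cluster's *enriched* genes
(logfc > 0): depleted genes largely echo other clusters' markers and would
swamp the overlap with the largest cluster's reference. Bonferroni corrects
across all cluster × reference tests; a cluster with no significant
reference at adjusted p < 0.05 is labeled "unknown". Best assignment is the
smallest adjusted p, ties broken by larger overlap then lexicographic name.
The default universe is the genes detected (count > 0 somewhere) in the
analyzed matrix — the background the markers were derived from — and is
configurable. Pathway over-representation uses the same exact test with BH
across sets. Cluster-proportion shifts between conditions use a two-sided
Fisher test per cluster (cluster vs rest × condition); the output carries a
standing caveat that droplet capture rates confound composition, so these
results are descriptive.

## Transcriptome-shift permutation test

The statistic is the Euclidean distance between the per-condition mean
profiles ("representative cells") of a cluster over all genes (no gene
prefilter; configurable). The null permutes condition labels within the
cluster preserving group sizes — the exchangeability-respecting reading that
keeps the null statistic on the group-mean scale; a literal "distance
between randomly sampled cells" null is available as `cell-pairs` but its
statistic lives on the single-cell scale. Empirical p is add-one smoothed,
so min p = 1/(n_perm + 1) and never 0; Bonferroni applies across the
clusters tested in one run. Default 1000 permutations.

## Cell–cell crosstalk scoring

Sources are cell types whose markers intersect a secreted-peptide list (a
static file; a glutamate-secretion list turns the machinery into the
trisynaptic benchmark). Expression is summarized to genes × animals means
per cell type, per condition (sham network from sham animals, injured
network from injured animals); with 3 animals per condition that n is
marginal, so the module enforces a configurable minimum (default 3) and the
validation studies use 10–12 synthetic animals. A `--pool-conditions`-style
pooled reading is available by summarizing without the condition split.

For peptide *g* (source) and target cell type *T*:
`S = Σ_{t ∈ T} min(−log₁₀ p_t, cap)` where p_t is the two-sided t-test p of
the Pearson correlation between the peptide's and the target gene's animal
profiles, and cap = 15 keeps S finite under numerically zero p. Target genes
with undefined correlation (constant profiles) are excluded and counted; a
constant peptide is an error. The null shuffles every target gene's animal
values independently (peptide fixed) and recomputes S; empirical p is
add-one smoothed.

A property worth knowing: when target genes are mutually correlated (true of
any planted block, and of co-regulated modules in real data), independent
shuffling destroys that coherence, so *any* peptide with a chance
correlation to the module's shared factor can reach very small empirical p —
the null is anticonservative for such targets. Several matrix cells can
therefore saturate the minimum attainable p; the trisynaptic benchmark
returns the observed scores alongside the p matrix and rankings break p-ties
by score, which is how the validation studies score topology recovery.
Calibration claims are made only for targets without planted structure,
where the empirical p is uniform on the permutation grid (KS-checked in the
suite).

## Single-cell vs in-silico bulk

Bulk profiles are per-animal means over all cells (clusters pooled) of the
normalized matrix; the same two-part test and thresholds run with animals as
observations. Single-cell DEGs found in the bulk table are "shared", the
rest "masked"; the overlap is Fisher-tested against the detected-gene
universe. DEGs confined to rare clusters are expected to be masked — the
validation study plants DEGs in a 2%-abundance cluster and measures both
their single-cell detection and their absence from bulk at identical
thresholds.

## Treatment reversal

Two DE tables (disease vs control; treated vs disease) are intersected at
p < `p_cut` (default 0.05). Overlap genes with opposite logfc signs are
"reversed", same signs "concordant"; overlap significance is a one-sided
Fisher test against a configurable universe (default: union of genes in both
tables — pass the detected-gene universe for a meaningful background when
the inputs are pre-filtered). The negative-binomial bulk fit that produces
such tables is standard-package territory and out of scope; the analysis
consumes its output columns (gene, logfc, p).

## RNAscope spot-count quantification

The marker gate is the knee of the sorted-descending spot-count curve:
the point of maximum perpendicular distance from the chord joining the
curve's endpoints, returned as an integer threshold (cells pass at
marker_count ≥ threshold). No knee algorithm is canonical; the chord rule is
the common "Kneedle-style" choice, and published manual gates (e.g.
microglia 11, ependymal 15, DG 20) can be supplied directly to reproduce a
specific figure's partition. All-equal counts have no knee (error advising a
manual gate); curves without an elbow put the knee next to an endpoint and
are logged. The gated comparison runs the two-part LRT on ln(1 + counts per
cell) — the pseudocount keeps zero-target cells usable, a detail the
ln(counts) axis label of typical figures leaves open.

## Synthetic-data generator

`generate_experiment` emulates a 6-animal (3 per condition) droplet
experiment: unequal cluster abundances (default geometric decay 40% → 1%
over 12 clusters), gamma-Poisson (negative binomial) counts around lognormal
per-gene baselines, and an independent per-entry dropout whose probability
is a decreasing logistic function of the underlying mean. Planted structure:

* **markers** — elevated in their own cluster either by a fold
  (`marker_logfc`, ln units) or by solving the count model for target
  detection fractions (`marker_frac_in`/`out`, e.g. 0.8 vs 0.1);
* **DEGs** — condition effects (alternating signs, default 1.5 ln units,
  emulating strongly induced injury-response genes) applied only in their
  restricted clusters, planted on genes whose baseline detection is
  0.4–0.6 so the planted truth is testable under the 30% prefilter;
* **animal effects** — a global lognormal depth factor per animal
  (σ = 0.15), which cancels under per-cell normalization, as real
  capture-depth variation largely does;
* **crosstalk blocks** — a per-animal latent factor shared between the
  source peptide and the target genes (the peptide is made a marker of its
  source cluster if it is not already).

All randomness flows from one root seed through named
`numpy.random.SeedSequence` child streams (baseline, assignment, animal,
crosstalk, counts, dropout); identical config + seed is bit-identical.

`generate_animal_summaries` plants couplings directly at the animal-summary
level with *exact* population correlation r (the scale at which the
crosstalk statistics operate), which is what the crosstalk validation
studies use; blocks sharing a source peptide reuse its latent profile.
`generate_spot_counts` draws a two-component Poisson marker mixture (modes
2 and 30 by default) and applies the target-gene effect only to injured
cells of the marker-high component.

What the generator does **not** emulate: doublets, ambient RNA,
batch/chemistry effects, gene–gene correlation beyond the planted blocks,
mean–variance trends fitted from real data, or realistic gene-symbol
structure. Passing validation therefore establishes internal statistical
correctness (calibration, power against planted truth, exactness against
oracles), not performance on any particular tissue.

## Problem sizes used by the validation studies

Chosen for single-CPU desk scale: LRT type-I error at 2000 replicates of
n = 200/group; marker recovery over 20 seeds of a 5-cluster, 500-gene,
900-cell experiment at detection 0.8/0.1; rare-cluster masking over 20 seeds
with a 2% cluster in 4800 cells (~48 rare cells per condition); shift
calibration 200 replicates × 200 permutations and power 50 seeds × 1000
permutations (0.5 ln-units on 50 of 200 genes, 100 cells/group); crosstalk
recovery 50 seeds × 1000 permutations (r = 0.9, 30 target genes, 12
animals); trisynaptic recovery 25 seeds × 500 permutations; knee separation
100 seeds. The hypergeometric enumeration sweep covers every 2×2 table with
universe ≤ 12.

## Known limitations

* The Gaussian magnitude component assumes rough log-normality of detected
  expression; heavy zero-inflation plus strong multimodality within the
  positives is not modeled.
* The χ² reference is anticonservative for very few observations (pseudobulk
  on 3 + 3 animals); treat those tables as descriptive.
* The crosstalk null is anticonservative for mutually correlated target
  genes (see above); interaction p-values identify candidate couplings, not
  causal or even directional links — "source/target" is a labeling
  convention driven by secretion annotations.
* Proportion tests inherit droplet capture-rate confounding.
* The knee gate is heuristic; published manual thresholds take precedence
  when reproducing specific analyses.
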