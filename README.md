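# dropcell

Cell-type-resolved statistics for droplet single-cell RNA-seq (Drop-seq)
experiments comparing two animal groups — e.g. sham-operated vs concussively
injured mice — with a synthetic-data generator that plants known truth so the
whole pipeline can be validated end to end.

The package is aimed at analysts who already have a digital gene expression
(DGE) matrix, cluster labels and per-cell metadata, and want the downstream
statistics: which genes mark each cell cluster, which cell types shift their
transcriptome after injury, which genes respond within each cell type, which
of those responses a bulk analysis would have missed, how cell types
co-regulate each other's genes through secreted peptides, whether a treatment
reverses the injury signature, and how to quantify validation smFISH
(RNAscope) spot counts.

## The statistics

**Two-part ("bimodal") likelihood-ratio test.** Single-cell expression of a
gene is modeled in two parts: a Bernoulli part for whether the gene is
detected (value > 0) and a Gaussian part for the log-normalized magnitude
among detected cells. For groups *a*, *b* the statistic is

    LRT = 2·[ℓ_binom(p̂_a, p̂_b) − ℓ_binom(p̂)] + n_pos·ln(σ̂₀²/σ̂₁²)

with the continuous term computed only when both groups have ≥ 2 detected
cells; the statistic is referred to χ² with df = number of computed parts.
Markers test one cluster against all remaining cells; DEGs test conditions
within a cluster. Genes enter testing only if detected in ≥ 30% of the cells
of one group and |logFC| ≥ 0.25 (natural-log units of counts-per-10k,
ln(1 + c·10⁴/total)); Benjamini–Hochberg FDR < 0.05 per contrast, with a
relaxed unadjusted p < 0.01 mode for rare cell types.

**Transcriptome shift.** Per cluster, the Euclidean distance between the two
condition-mean "representative cells" is compared with a label-permutation
null (group sizes preserved); empirical p = (1 + exceedances)/(1 + n_perm),
Bonferroni across clusters.

**Cell–cell crosstalk.** Marker genes encoding secreted peptides define
source cell types. Expression is summarized to genes × animals means per cell
type; a peptide's interaction score with a target cell type is
S = Σ_genes −log₁₀ p(Pearson correlation across animals). Significance comes
from shuffling every target gene's animal values independently. A benchmark
mode uses glutamate-secretion genes as sources to recover the hippocampal
trisynaptic circuit (DG ↔ CA3 → CA1) as a positive control.

**Pseudobulk masking.** In-silico bulk profiles (per-animal means over all
cells) are tested with the same two-part machinery; cluster-restricted DEGs
absent from the bulk table are "masked" — the measurable advantage of
single-cell resolution.

**RNAscope quantification.** Cells are gated by the knee of the sorted
marker-gene spot-count curve (max distance from the chord), then the target
gene's ln(1 + counts per cell) is compared between groups with the two-part
test.

## Worked example

The numbered scripts under `analysis/` run a complete desk-scale study on a
simulated experiment (6 clusters at 35%…2% abundance, 3 animals per
condition, 400 genes, planted markers / DEGs / one crosstalk block), writing
tables under `results/analysis/`:

```sh
python analysis/01_simulate.py
python analysis/03_markers_annotate.py
python analysis/05_de_bulk_compare.py
```

prints (abridged):

```
simulated 400 genes x 1200 cells (6 animals, 6 clusters) -> results/analysis/data
planted: 73 markers, 24 DEGs, 1 crosstalk block(s)
...
cluster00: 36 markers (up: 17); planted recovered 13/13
identity assignment: 6/6 clusters matched their own (noise-corrupted) reference set
...
cluster05: 10 suggestive DEGs at p<0.01; planted recovered 4/4
bulk comparison: 2 shared, 36 masked in bulk (overlap Fisher p 0.0248)
rare cluster cluster05: 4/4 recovered planted DEGs are masked in the bulk analysis
```

Every planted marker is recovered and all clusters are re-identified from
noise-corrupted reference sets; the DEGs planted in the 2%-abundance cluster
are found at single-cell resolution (relaxed p < 0.01 mode, as appropriate
for a rare cell type) yet invisible to the in-silico bulk analysis — the
masking phenomenon the single-cell design exists to overcome. Script
`06_crosstalk.py` prints the trisynaptic benchmark matrix, where exactly the
planted DG→CA3, CA3→DG and CA3→CA1 cells reach the minimum attainable
empirical p (0.005 at 200 permutations).

The same stages are available as a CLI (`dropcell run --config cfg.yaml`,
or individual subcommands `simulate | qc | normalize | markers | annotate |
de | shift | crosstalk | bulk-compare | reversal | ish`). Runs are
deterministic: one config + seed gives byte-identical output tables.

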