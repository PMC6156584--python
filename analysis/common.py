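"""Shared paths and the demo experiment configuration for the analysis scripts.

The demo emulates the study design: two conditions (sham vs tbi), three
animals each, unequal cluster abundances, planted markers, cluster-restricted
DEGs and one cross-cell-type crosstalk block, at desk scale.
"""
import os

from dropcell.syndata import CrosstalkBlock, SynthConfig

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(ROOT, "results", "analysis")
DATA = os.path.join(RESULTS, "data")

SEED = 1
N_PERM = 200

# QC thresholds scaled to the demo's sequencing depth (the study-scale
# defaults of 500 genes / 900 transcripts assume real Drop-seq depth)
MIN_GENES = 10
MIN_TRANSCRIPTS = 20

DEMO = SynthConfig(
    n_clusters=6,
    cluster_abundances=(0.35, 0.25, 0.15, 0.13, 0.10, 0.02),
    n_genes=400,
    cells_per_animal=200,
    animals_per_condition=3,
    markers_per_cluster=12,
    marker_frac_in=0.8,
    marker_frac_out=0.1,
    degs_per_cluster=4,
    crosstalk_blocks=(
        CrosstalkBlock("cluster00", "g0000", "cluster01",
                       tuple(f"g{i:04d}" for i in range(300, 320)), 0.9),
    ),
    seed=SEED,
)

CONDS = ("tbi", "sham")


def outdir(*parts):
    path = os.path.join(RESULTS, *parts)
    os.makedirs(path, exist_ok=True)
    return path
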