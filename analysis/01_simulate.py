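"""Generate the demo Drop-seq-like experiment with planted ground truth.

Writes the DGE matrix (MTX), per-cell metadata, reference marker sets (GMT),
a secreted-peptide list, and the truth registries under results/analysis/data.
"""
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import DATA, DEMO, outdir  # noqa: E402

from dropcell import io_qc, syndata
from dropcell.annotate import write_gmt


def main():
    out = outdir("data")
    m, meta, truth = syndata.generate_experiment(DEMO)
    io_qc.write_dge(m, os.path.join(out, "dge"), format="mtx")
    io_qc.write_meta(meta, os.path.join(out, "meta.tsv"))

    refs = syndata.generate_reference_sets(truth, noise=0.3, seed=DEMO.seed,
                                           universe=list(m.genes))
    write_gmt(refs, os.path.join(out, "references.gmt"))

    secreted = sorted({b.peptide_gene for b in truth.crosstalk}
                      | {g for cl in truth.markers for g in truth.markers[cl][:3]})
    with open(os.path.join(out, "secreted.txt"), "w") as fh:
        fh.write("\n".join(secreted) + "\n")

    pd.DataFrame([{"cluster": cl, "gene": g} for cl in sorted(truth.markers)
                  for g in truth.markers[cl]]).to_csv(
        os.path.join(out, "truth_markers.tsv"), sep="\t", index=False)
    degs = truth.degs.assign(clusters=truth.degs["clusters"].map(",".join))
    degs.to_csv(os.path.join(out, "truth_degs.tsv"), sep="\t", index=False)

    print(f"simulated {m.n_genes} genes x {m.n_cells} cells "
          f"({meta['animal'].nunique()} animals, "
          f"{meta['cluster'].nunique()} clusters) -> {out}")
    print(f"planted: {sum(len(v) for v in truth.markers.values())} markers, "
          f"{len(truth.degs)} DEGs, {len(truth.crosstalk)} crosstalk block(s)")


if __name__ == "__main__":
    main()
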