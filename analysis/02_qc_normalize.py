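"""Quality-filter cells and normalize the demo experiment.

Applies the inclusive detected-genes / total-UMIs thresholds, then
counts-per-10k natural-log normalization; writes the normalized matrix.
"""
import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import DATA, MIN_GENES, MIN_TRANSCRIPTS, outdir  # noqa: E402

from dropcell import io_qc


def load_normalized():
    m = io_qc.read_dge(os.path.join(DATA, "dge"), "mtx")
    meta = io_qc.read_meta(os.path.join(DATA, "meta.tsv"))
    kept = io_qc.filter_cells(m, MIN_GENES, MIN_TRANSCRIPTS)
    meta = meta.loc[kept.cells]
    return kept, io_qc.normalize(kept), meta, m.n_cells


def main():
    out = outdir("qc")
    kept, norm, meta, n_before = load_normalized()
    norm.to_frame().rename_axis("GENE").to_csv(
        os.path.join(out, "normalized.tsv"), sep="\t", float_format="%.6g")
    io_qc.write_meta(meta, os.path.join(out, "meta_qc.tsv"))
    print(f"QC kept {kept.n_cells}/{n_before} cells "
          f"(>= {MIN_GENES} genes and >= {MIN_TRANSCRIPTS} UMIs)")
    print(f"normalization: ln(1 + count/total x {norm.provenance['scale']:g})")


if __name__ == "__main__":
    main()
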