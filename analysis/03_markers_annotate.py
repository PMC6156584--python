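"""Discover cluster markers, annotate cluster identities, compare proportions.

Markers come from the two-part LRT (cluster vs rest, 30%/0.25 prefilters,
FDR < 0.05); identities from Bonferroni-corrected Fisher overlap with the
reference sets; per-cluster composition shifts from two-sided Fisher tests.
"""
import importlib
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import DATA, outdir  # noqa: E402

from dropcell import de
from dropcell.annotate import annotate_clusters, proportion_test, read_gmt

qc = importlib.import_module("02_qc_normalize")


def main():
    out = outdir("markers")
    kept, norm, meta, _ = qc.load_normalized()
    refs = read_gmt(os.path.join(DATA, "references.gmt"))
    universe = set(np.asarray(kept.genes)[(kept.values > 0).any(axis=1)])
    truth = pd.read_csv(os.path.join(DATA, "truth_markers.tsv"), sep="\t")

    markers = {}
    for cl in sorted(meta["cluster"].unique()):
        tbl = de.find_markers(norm, meta, cl)
        markers[cl] = tbl
        tbl.to_csv(os.path.join(out, f"markers_{cl}.tsv"), sep="\t",
                   index=False, float_format="%.6g")
        planted = set(truth.loc[truth["cluster"] == cl, "gene"])
        up = set(tbl.loc[tbl["logfc"] > 0, "gene"])
        print(f"{cl}: {len(tbl)} markers (up: {len(up)}); "
              f"planted recovered {len(up & planted)}/{len(planted)}")

    adj, assigned = annotate_clusters(
        {cl: t for cl, t in markers.items() if len(t)}, refs, universe)
    adj.rename_axis("cluster").to_csv(os.path.join(out, "annotation_adj_p.tsv"),
                                      sep="\t", float_format="%.4g")
    correct = sum(assigned[cl] == f"ref_{cl}" for cl in assigned)
    print(f"identity assignment: {correct}/{len(assigned)} clusters matched "
          f"their own (noise-corrupted) reference set")

    props = proportion_test(meta, "tbi", "sham")
    props.to_csv(os.path.join(out, "proportions.tsv"), sep="\t", index=False,
                 float_format="%.4g")
    sig = props[props["fdr"] < 0.05]
    print(f"proportion shifts at FDR<0.05: "
          f"{', '.join(sig['cluster']) if len(sig) else 'none'} "
          f"(interpret with caution: capture rates confound composition)")


if __name__ == "__main__":
    main()
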