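"""smFISH spot-count quantification: knee gate, then gated group comparison.

Simulates a bimodal marker mixture with a planted target-gene elevation in
injured cells of the marker-high component, finds the knee gate, and compares
ln(1 + counts per cell) between groups with the two-part LRT.
"""
import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import SEED, outdir  # noqa: E402

import pandas as pd

from dropcell.ish import gate_and_compare, knee_threshold
from dropcell.syndata import generate_spot_counts


def main():
    out = outdir("ish")
    spots = generate_spot_counts(600, marker_low=2, marker_high=30,
                                 deg_effect=0.7, seed=SEED)
    spots.to_csv(os.path.join(out, "spot_counts.tsv"), sep="\t", index=False)
    thr = knee_threshold(spots["marker_count"])
    res = gate_and_compare(spots, thr)
    pd.DataFrame([{"threshold": res.threshold, "logfc": res.logfc,
                   "stat": res.stat, "df": res.df, "p": res.p,
                   **{f"n_gated_{g}": n for g, n in res.n_gated.items()}}]).to_csv(
        os.path.join(out, "gate_result.tsv"), sep="\t", index=False,
        float_format="%.6g")
    print(f"knee gate at {thr} marker spots "
          f"(modes planted at 2 and 30); gated "
          f"{res.n_gated['tbi']} tbi / {res.n_gated['sham']} sham cells")
    print(f"target gene: logFC {res.logfc:.3f} (ln units), two-part LRT "
          f"stat {res.stat:.1f}, df {res.df}, p {res.p:.3g}")


if __name__ == "__main__":
    main()
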