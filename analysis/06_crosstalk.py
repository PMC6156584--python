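"""Cell-cell co-expression networks per condition and the trisynaptic benchmark.

Secreted-peptide markers define source cell types; animal-level summaries are
correlated peptide-vs-target-gene; interaction scores get permutation p values
by independent target-gene shuffling. The trisynaptic benchmark reruns the
machinery on summaries with planted DG<->CA3 / CA3->CA1 couplings.
"""
import importlib
import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import DATA, N_PERM, SEED, outdir  # noqa: E402

from dropcell import crosstalk as ct
from dropcell import de, io_qc
from dropcell.syndata import CrosstalkBlock, generate_animal_summaries

qc = importlib.import_module("02_qc_normalize")


def condition_summaries(norm, meta, cond, min_animals=3):
    sub = meta[meta["condition"] == cond]
    out = {}
    for cl in sorted(sub["cluster"].unique()):
        sel = norm.cells.isin(sub.index[sub["cluster"] == cl])
        sub_norm = io_qc.NormMatrix(norm.values[:, sel], norm.genes,
                                    norm.cells[sel], norm.provenance)
        summ = io_qc.summarize_by_animal(sub_norm, meta.loc[norm.cells[sel]])
        if summ.shape[1] >= min_animals:
            out[cl] = summ
    return out


def main():
    out = outdir("crosstalk")
    _, norm, meta, _ = qc.load_normalized()
    with open(os.path.join(DATA, "secreted.txt")) as fh:
        secreted = [line.strip() for line in fh if line.strip()]

    markers = {cl: de.find_markers(norm, meta, cl)
               for cl in sorted(meta["cluster"].unique())}
    sources = ct.select_source_genes(markers, secreted)
    print(f"source cell types: {sorted(sources)} "
          f"({sum(map(len, sources.values()))} secreted peptide markers)")

    all_summaries = {cond: condition_summaries(norm, meta, cond)
                     for cond in ("sham", "tbi")}
    common = sorted(set(all_summaries["sham"]) & set(all_summaries["tbi"]))
    skipped = {cl for s in all_summaries.values() for cl in s} - set(common)
    if skipped:
        print(f"clusters without >= 3 animals in every condition skipped: "
              f"{sorted(skipped)}")
    scores = {}
    for i, cond in enumerate(("sham", "tbi")):
        summaries = {cl: all_summaries[cond][cl] for cl in common}
        usable = {cl: g for cl, g in sources.items() if cl in summaries}
        tbl = ct.score_pairs(summaries, usable, n_perm=N_PERM, seed=SEED + i)
        tbl.to_csv(os.path.join(out, f"scores_{cond}.tsv"), sep="\t",
                   index=False, float_format="%.6g")
        scores[cond] = tbl
        print(f"{cond}: {int((tbl['p_empirical'] < 0.05).sum())}/{len(tbl)} "
              f"triples significant at p<0.05")

    nets = ct.build_networks(scores, alpha=0.05)
    nets["differential"].to_csv(os.path.join(out, "differential_edges.tsv"),
                                sep="\t", index=False)
    print(f"differential edges (significant in exactly one condition): "
          f"{len(nets['differential'])}")

    # trisynaptic positive control on animal-level summaries
    blocks = [
        CrosstalkBlock("DG", "g0000", "CA3",
                       tuple(f"g{i:04d}" for i in range(10, 40)), 0.9),
        CrosstalkBlock("CA3", "g0001", "DG",
                       tuple(f"g{i:04d}" for i in range(40, 70)), 0.9),
        CrosstalkBlock("CA3", "g0001", "CA1",
                       tuple(f"g{i:04d}" for i in range(40, 70)), 0.9),
    ]
    summ = generate_animal_summaries(["DG", "CA3", "CA1"], 100, 10, blocks,
                                     seed=SEED)
    mat = ct.trisynaptic_benchmark(summ, ["g0000", "g0001", "g0002"],
                                   n_perm=N_PERM, seed=SEED)
    mat.to_csv(os.path.join(out, "trisynaptic_p.tsv"), sep="\t",
               float_format="%.6g")
    print("trisynaptic empirical-p matrix (rows = source, cols = target):")
    print(mat.round(4).to_string())


if __name__ == "__main__":
    main()
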