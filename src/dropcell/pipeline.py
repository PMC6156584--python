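"""End-to-end orchestration of the analysis stages.

Stage order: simulate/load -> qc -> normalize -> markers -> annotate
(identities + proportions) -> de -> shift -> crosstalk -> bulk-compare
[-> ish, reversal when inputs are given]. Every table is written as TSV with
a fixed float format, and a manifest (JSON) records artifact paths, the full
parameter set and the seed, so a run is reproducible from its manifest alone:
identical config + seed gives byte-identical TSV outputs.
"""
from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from . import annotate as ann
from . import crosstalk as ct
from . import de
from . import io_qc
from . import ish as ish_mod
from . import shift as shift_mod
from . import syndata
from .config import PipelineConfig

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: str, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return path


def _sidecar(path: str, params: dict) -> None:
    with open(path + ".params.json", "w") as fh:
        json.dump(params, fh, sort_keys=True, indent=1, default=str)


def _load_inputs(cfg: PipelineConfig):
    m = io_qc.read_dge(cfg.inputs["dge"], cfg.inputs.get("format", "auto"))
    meta = io_qc.read_meta(cfg.inputs["meta"])
    io_qc.validate_meta(meta, m)
    meta = meta.loc[m.cells]
    refs = ann.read_gmt(cfg.inputs["references"]) if cfg.inputs.get("references") else None
    secreted = None
    if cfg.inputs.get("secreted"):
        with open(cfg.inputs["secreted"]) as fh:
            secreted = [line.strip() for line in fh if line.strip()]
    return m, meta, refs, secreted, None


def _simulate(cfg: PipelineConfig, outdir: str, manifest: dict):
    m, meta, truth = syndata.generate_experiment(cfg.syndata)
    io_qc.write_dge(m, os.path.join(outdir, "dge"), format="mtx")
    io_qc.write_meta(meta, os.path.join(outdir, "meta.tsv"))
    marker_rows = [{"cluster": cl, "gene": g}
                   for cl in sorted(truth.markers) for g in truth.markers[cl]]
    _write(pd.DataFrame(marker_rows), os.path.join(outdir, "truth_markers.tsv"))
    degs = truth.degs.copy()
    degs["clusters"] = degs["clusters"].map(lambda t: ",".join(t))
    _write(degs, os.path.join(outdir, "truth_degs.tsv"))
    refs = syndata.generate_reference_sets(
        truth, noise=cfg.params["reference_noise"], seed=cfg.seed,
        universe=list(m.genes))
    ann.write_gmt(refs, os.path.join(outdir, "references.gmt"))
    # demo secreted list: a few planted markers per cluster (plus any
    # crosstalk peptides), standing in for a curated secreted-peptide list
    secreted = sorted({b.peptide_gene for b in truth.crosstalk}
                      | {g for cl in truth.markers for g in truth.markers[cl][:3]})
    with open(os.path.join(outdir, "secreted.txt"), "w") as fh:
        fh.write("\n".join(secreted) + "\n")
    manifest["stages"]["simulate"] = {
        "n_genes": m.n_genes, "n_cells": m.n_cells,
        "dge": os.path.join(outdir, "dge"),
        "meta": os.path.join(outdir, "meta.tsv"),
    }
    return m, meta, refs, secreted, truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    p = cfg.params
    manifest = {"seed": cfg.seed, "outdir": outdir, "params": p,
                "version": __version__, "stages": {}}

    try:
        if cfg.syndata is not None:
            m, meta, refs, secreted, truth = _simulate(cfg, outdir, manifest)
        else:
            m, meta, refs, secreted, truth = _load_inputs(cfg)

        conditions = list(pd.unique(meta["condition"]))
        cond_a, cond_b = (conditions + [None, None])[:2]

        if cfg.stages["qc"]:
            m = io_qc.filter_cells(m, p["min_genes"], p["min_transcripts"])
            meta = meta.loc[m.cells]
            manifest["stages"]["qc"] = {"n_cells": m.n_cells}

        norm = io_qc.normalize(m, scale=p["scale"])
        manifest["stages"]["normalize"] = dict(norm.provenance)

        clusters = sorted(pd.unique(meta["cluster"]))
        markers = {}
        if cfg.stages["markers"]:
            for cl in clusters:
                n_in = int((meta["cluster"] == cl).sum())
                if n_in < 2 or m.n_cells - n_in < 2:
                    log.warning("markers: skipping cluster %s (too few cells)", cl)
                    continue
                markers[cl] = de.find_markers(norm, meta, cl, p["min_frac"],
                                              p["min_logfc"], p["fdr"])
                _write(markers[cl], os.path.join(outdir, f"markers_{cl}.tsv"))
            manifest["stages"]["markers"] = {cl: len(t) for cl, t in markers.items()}

        if cfg.stages["annotate"] and refs is not None and markers:
            universe = set(np.asarray(m.genes)[(m.values > 0).any(axis=1)])
            nonempty = {cl: t for cl, t in markers.items() if len(t)}
            if nonempty:
                adj, assigned = ann.annotate_clusters(nonempty, refs, universe,
                                                      alpha=p["alpha"])
                _write(adj.rename_axis("cluster"),
                       os.path.join(outdir, "annotation_adj_p.tsv"), index=True)
                _write(pd.DataFrame(sorted(assigned.items()),
                                    columns=["cluster", "identity"]),
                       os.path.join(outdir, "annotation.tsv"))
                manifest["stages"]["annotate"] = assigned
            props = ann.proportion_test(meta, cond_a, cond_b)
            _write(props, os.path.join(outdir, "proportions.tsv"))

        degs = {}
        if cfg.stages["de"] and cond_b is not None:
            for cl in clusters:
                sub = meta[meta["cluster"] == cl]
                if ((sub["condition"] == cond_a).sum() < 2
                        or (sub["condition"] == cond_b).sum() < 2):
                    log.warning("de: skipping cluster %s (too few cells)", cl)
                    continue
                degs[cl] = de.find_degs(norm, meta, cl, cond_a, cond_b,
                                        p["min_frac"], p["min_logfc"],
                                        p["fdr"], p_cut=p["p_cut"])
                _write(degs[cl], os.path.join(outdir, f"degs_{cl}.tsv"))
            manifest["stages"]["de"] = {cl: len(t) for cl, t in degs.items()}

        if cfg.stages["shift"] and cond_b is not None:
            shifts = shift_mod.transcriptome_shift_all(
                norm, meta, cond_a, cond_b, n_perm=p["n_perm"], seed=cfg.seed)
            _write(shifts, os.path.join(outdir, "shift.tsv"))
            manifest["stages"]["shift"] = {
                "n_clusters": len(shifts),
                "significant": int((shifts["p_bonferroni"] < p["alpha"]).sum()),
            }

        if cfg.stages["crosstalk"] and secreted and markers:
            sources = ct.select_source_genes(markers, secreted)
            # summarize per condition, then score the common cluster inventory
            # (a cluster must have >= min_animals animals in every condition)
            summaries_by_cond = {}
            for cond in [c for c in (cond_a, cond_b) if c is not None]:
                sub = meta[meta["condition"] == cond]
                summaries = {}
                for cl in clusters:
                    if (sub["cluster"] == cl).any():
                        sel = norm.cells.isin(sub.index[sub["cluster"] == cl])
                        sub_norm = io_qc.NormMatrix(norm.values[:, sel], norm.genes,
                                                    norm.cells[sel], norm.provenance)
                        summ = io_qc.summarize_by_animal(sub_norm, meta.loc[norm.cells[sel]])
                        if summ.shape[1] >= p["min_animals"]:
                            summaries[cl] = summ
                summaries_by_cond[cond] = summaries
            common = sorted(set.intersection(
                *[set(s) for s in summaries_by_cond.values()])) \
                if summaries_by_cond else []
            dropped = {c: sorted(set(s) - set(common))
                       for c, s in summaries_by_cond.items()}
            if any(dropped.values()):
                log.warning("crosstalk: clusters without >= %d animals in every "
                            "condition excluded: %s", p["min_animals"], dropped)
            scores_by_cond = {}
            for ci, (cond, summaries) in enumerate(summaries_by_cond.items()):
                summaries = {cl: summaries[cl] for cl in common}
                usable_sources = {cl: g for cl, g in sources.items()
                                  if cl in summaries}
                if not (usable_sources and summaries):
                    continue
                try:
                    tbl = ct.score_pairs(summaries, usable_sources,
                                         n_perm=p["n_perm"],
                                         seed=cfg.seed + ci, cap=p["cap"],
                                         min_animals=p["min_animals"])
                except ValueError as exc:
                    log.warning("crosstalk (%s): %s", cond, exc)
                    continue
                scores_by_cond[cond] = tbl
                _write(tbl, os.path.join(outdir, f"crosstalk_{cond}.tsv"))
            if len(scores_by_cond) == 2:
                nets = ct.build_networks(scores_by_cond, alpha=p["alpha"])
                _write(nets["differential"],
                       os.path.join(outdir, "crosstalk_differential.tsv"))
                manifest["stages"]["crosstalk"] = {
                    c: int(len(e)) for c, e in nets["edges"].items()}

        if cfg.stages["bulk_compare"] and degs and cond_b is not None:
            cmp = de.bulk_vs_sc_comparison(norm, meta, degs, cond_a, cond_b,
                                           p["min_frac"], p["min_logfc"], p["fdr"])
            _write(cmp["bulk_table"], os.path.join(outdir, "bulk_degs.tsv"))
            _write(pd.DataFrame({"gene": cmp["shared"] + cmp["sc_only"],
                                 "status": ["shared"] * len(cmp["shared"])
                                 + ["sc_only"] * len(cmp["sc_only"])}),
                   os.path.join(outdir, "bulk_vs_sc.tsv"))
            manifest["stages"]["bulk_compare"] = {
                "shared": len(cmp["shared"]), "sc_only": len(cmp["sc_only"]),
                "fisher_p": cmp["fisher_p"],
            }

        if cfg.stages["ish"]:
            if cfg.syndata is not None:
                spots = syndata.generate_spot_counts(400, deg_effect=0.7,
                                                     seed=cfg.seed)
            else:
                spots = pd.read_csv(cfg.inputs["spots"], sep="\t")
            ish_mod.validate_spot_table(spots)
            thr = ish_mod.knee_threshold(spots["marker_count"])
            gate = ish_mod.gate_and_compare(spots, thr)
            _write(pd.DataFrame([{
                "threshold": gate.threshold, "logfc": gate.logfc,
                "stat": gate.stat, "df": gate.df, "p": gate.p,
                **{f"n_gated_{g}": n for g, n in gate.n_gated.items()},
            }]), os.path.join(outdir, "ish.tsv"))
            manifest["stages"]["ish"] = {"threshold": gate.threshold, "p": gate.p}

        if cfg.stages["reversal"]:
            dis = pd.read_csv(cfg.inputs["reversal_disease"], sep="\t")
            trt = pd.read_csv(cfg.inputs["reversal_treatment"], sep="\t")
            rev = de.reversal_analysis(dis, trt)
            _write(pd.DataFrame({
                "gene": rev.overlap,
                "status": ["reversed" if g in set(rev.reversed_genes)
                           else "concordant" for g in rev.overlap]}),
                os.path.join(outdir, "reversal.tsv"))
            manifest["stages"]["reversal"] = {
                "overlap": len(rev.overlap), "reversed": len(rev.reversed_genes),
                "fisher_p": rev.fisher_p,
            }
    except Exception:
        manifest["status"] = "failed"
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1, default=str)
        raise

    manifest["status"] = "ok"
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1, default=str)
    _sidecar(os.path.join(outdir, "manifest.json"), p)
    return manifest
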