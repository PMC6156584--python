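"""Pipeline configuration: a strict YAML schema with centralized defaults.

Exactly one of ``inputs`` (paths to real data) or ``syndata`` (synthetic
experiment parameters) must be present. Unknown keys are rejected with a
spelling suggestion. All stage parameters default to the study conventions:
min_genes 500, min_transcripts 900, scale 10,000, min_frac 0.3,
min_logfc 0.25, fdr 0.05, n_perm 1000.
"""
from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields as dc_fields

import yaml

from .syndata import SynthConfig, CrosstalkBlock

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "DEFAULT_PARAMS",
           "DEFAULT_STAGES"]


class ConfigError(ValueError):
    pass


DEFAULT_PARAMS = {
    "min_genes": 500,
    "min_transcripts": 900,
    "scale": 10_000.0,
    "min_frac": 0.3,
    "min_logfc": 0.25,
    "fdr": 0.05,
    "alpha": 0.05,
    "n_perm": 1000,
    "cap": 15.0,
    "p_cut": None,          # rare-cell-type relaxed DEG mode, e.g. 0.01
    "min_animals": 3,
    "reference_noise": 0.0,
}

DEFAULT_STAGES = {
    "qc": True, "normalize": True, "markers": True, "annotate": True,
    "de": True, "shift": True, "crosstalk": True, "bulk_compare": True,
    "ish": False, "reversal": False,
}

_INPUT_KEYS = {"dge", "format", "meta", "references", "secreted", "pathways",
               "spots", "reversal_disease", "reversal_treatment"}
_PARAM_BOUNDS = {
    "min_genes": (0, None), "min_transcripts": (0, None), "scale": (1e-12, None),
    "min_frac": (0.0, 1.0), "min_logfc": (0.0, None), "fdr": (0.0, 1.0),
    "alpha": (0.0, 1.0), "n_perm": (1, None), "cap": (0.0, None),
    "min_animals": (2, None), "reference_noise": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/run"
    syndata: SynthConfig | None = None
    inputs: dict | None = None
    stages: dict = field(default_factory=lambda: dict(DEFAULT_STAGES))
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))


def _reject_unknown(given: dict, allowed, where: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(str(key), [str(a) for a in allowed], n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {where}{suffix}")


def _check_bounds(params: dict) -> None:
    for key, (lo, hi) in _PARAM_BOUNDS.items():
        v = params.get(key)
        if v is None:
            continue
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"params.{key} must be a number, got {v!r}")
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            raise ConfigError(f"params.{key}={v} outside allowed range "
                              f"[{lo}, {hi if hi is not None else 'inf'}]")


def _build_syndata(block: dict) -> SynthConfig:
    allowed = {f.name for f in dc_fields(SynthConfig)}
    _reject_unknown(block, allowed, "syndata")
    block = dict(block)
    if "crosstalk_blocks" in block:
        block["crosstalk_blocks"] = tuple(
            CrosstalkBlock(b["source_cluster"], b["peptide_gene"],
                           b["target_cluster"], tuple(b["target_genes"]),
                           float(b["r"]))
            for b in block["crosstalk_blocks"]
        )
    for key in ("cluster_abundances", "cluster_names", "conditions"):
        if key in block and block[key] is not None:
            block[key] = tuple(block[key])
    cfg = SynthConfig(**block)
    try:
        cfg.validate()
    except ValueError as exc:
        raise ConfigError(f"syndata: {exc}") from None
    return cfg


def validate_config(source) -> PipelineConfig:
    """Normalize a config file path, YAML string, or dict into a PipelineConfig."""
    if isinstance(source, dict):
        raw = source
    else:
        try:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        except (OSError, TypeError):
            raw = yaml.safe_load(source)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(raw, {"seed", "outdir", "syndata", "inputs", "stages", "params"},
                    "config")
    has_syn = raw.get("syndata") is not None
    has_inputs = raw.get("inputs") is not None
    if has_syn == has_inputs:
        raise ConfigError("exactly one of 'syndata' and 'inputs' must be given")

    stages = dict(DEFAULT_STAGES)
    _reject_unknown(raw.get("stages", {}) or {}, stages, "stages")
    stages.update(raw.get("stages", {}) or {})
    for k, v in stages.items():
        if not isinstance(v, bool):
            raise ConfigError(f"stages.{k} must be a boolean, got {v!r}")

    params = dict(DEFAULT_PARAMS)
    _reject_unknown(raw.get("params", {}) or {}, params, "params")
    params.update(raw.get("params", {}) or {})
    _check_bounds(params)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed must be an integer, got {seed!r}")

    inputs = None
    if has_inputs:
        inputs = dict(raw["inputs"])
        _reject_unknown(inputs, _INPUT_KEYS, "inputs")
        if "dge" not in inputs or "meta" not in inputs:
            raise ConfigError("inputs requires at least 'dge' and 'meta' paths")

    syndata = None
    if has_syn:
        block = dict(raw["syndata"])
        block.setdefault("seed", seed)  # the root seed drives the generator
        syndata = _build_syndata(block)

    return PipelineConfig(
        seed=seed,
        outdir=str(raw.get("outdir", "results/run")),
        syndata=syndata,
        inputs=inputs,
        stages=stages,
        params=params,
    )
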