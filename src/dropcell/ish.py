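"""RNAscope / smFISH spot-count quantification.

Input is a per-segmented-cell table of integer spot counts for a cell-type
marker gene and a target gene, with group labels (e.g. sham vs tbi). Cells of
the type of interest are gated by a marker spot-count threshold found at the
knee of the sorted count curve (max perpendicular distance from the chord
joining its endpoints); published manual gates can be supplied instead. The
target gene is then compared between groups on ln(1 + counts per cell) with
the same two-part likelihood-ratio test used for the sequencing data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import two_part_lrt

log = logging.getLogger(__name__)

__all__ = ["GateResult", "knee_threshold", "gate_and_compare",
           "validate_spot_table"]

SPOT_COLUMNS = ("group", "marker_count", "target_count")


@dataclass
class GateResult:
    threshold: int
    n_gated: dict
    n_total: dict
    logfc: float
    stat: float
    df: int
    p: float


def validate_spot_table(table: pd.DataFrame, groups=None) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spot-count table missing columns: {missing}")
    for col in ("marker_count", "target_count"):
        v = table[col].to_numpy()
        if len(v) and ((v < 0).any() or (v != np.floor(v)).any()):
            raise ValueError(f"{col} must be non-negative integers")
    if groups is not None:
        bad = set(table["group"]) - set(groups)
        if bad:
            raise ValueError(f"unexpected group labels: {sorted(bad)}")


def knee_threshold(marker_counts) -> int:
    """Integer gate at the knee of the sorted-descending count curve.

    The knee is the point of maximum perpendicular distance from the chord
    joining the first and last points of the curve. Cells with
    ``marker_count >= threshold`` pass the gate. Degenerate curves (no
    curvature — e.g. linear counts) place the knee next to an endpoint and
    are logged as such; all-equal counts are an error (supply a manual gate).
    """
    y = np.sort(np.asarray(marker_counts, dtype=float))[::-1]
    n = y.size
    if n < 10:
        raise ValueError(f"need >= 10 cells to locate a knee (got {n})")
    if y[0] == y[-1]:
        raise ValueError("all marker counts are equal: no knee; "
                         "supply a manual threshold")
    x = np.arange(n, dtype=float)
    # perpendicular distance from the chord (x0,y0)-(x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    knee = int(np.argmax(dist))
    if knee <= 1 or knee >= n - 2:
        log.warning("knee_threshold: knee at position %d of %d is endpoint-adjacent; "
                    "the curve may lack an elbow", knee, n)
    return int(y[knee])


def gate_and_compare(table: pd.DataFrame, threshold: int,
                     group_a: str = "tbi", group_b: str = "sham") -> GateResult:
    """Gate cells by marker count, compare target counts between groups.

    Comparison is on ln(1 + target_count) of gated cells via the two-part
    LRT; ``logfc`` is mean(group_a) - mean(group_b) on that scale.
    """
    validate_spot_table(table)
    gated = table[table["marker_count"] >= threshold]
    n_total = table["group"].value_counts().to_dict()
    n_gated = gated["group"].value_counts().to_dict()
    vals = {}
    for g in (group_a, group_b):
        v = gated.loc[gated["group"] == g, "target_count"].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(
                f"group {g!r} has {v.size} gated cells at threshold {threshold} "
                f"(needs >= 2)"
            )
        vals[g] = np.log1p(v)
    res = two_part_lrt(vals[group_a], vals[group_b])
    logfc = float(vals[group_a].mean() - vals[group_b].mean())
    return GateResult(threshold=int(threshold),
                      n_gated={g: int(n_gated.get(g, 0)) for g in (group_a, group_b)},
                      n_total={g: int(n_total.get(g, 0)) for g in (group_a, group_b)},
                      logfc=logfc, stat=res.stat, df=res.df, p=res.p)
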