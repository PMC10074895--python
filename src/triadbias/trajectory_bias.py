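"""Asymmetry fractions along ordered pseudotime segments.

Cells are grouped into segments — either labels provided by an upstream
trajectory tool or equal-count pseudotime bins — and each segment is
pseudobulked and classified; the reported statistic is the fraction of
expressed triads with a non-Balance category, ordered start -> terminal
per branch.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .bias_pipeline import classify_groups, pseudobulk_means
from .io import CountMatrix
from .triad_core import NOT_EXPRESSED, CentroidSet, TriadTable

logger = logging.getLogger(__name__)

_DEFAULT_BRANCH = "branch0"


class TrajectoryError(ValueError):
    """Invalid trajectory annotation or segmentation request."""


def _require_columns(annotation: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in annotation.columns]
    if missing:
        raise TrajectoryError(f"annotation missing column(s): {missing}")


def segment_cells(
    annotation: pd.DataFrame, mode: str = "labels"
) -> pd.DataFrame:
    """Assign each cell to an ordered trajectory segment.

    ``mode='labels'`` passes the ``segment`` column through (branch defaults
    to a single branch; segment order is first-appearance order within each
    branch unless pseudotime is present, in which case segments are ordered
    by median pseudotime). ``mode='bins:K'`` splits each branch into K
    equal-count pseudotime bins, breaking boundary ties by cell id.

    Returns a frame ``cell_id, branch, segment, segment_order``.
    """
    ann = annotation.copy()
    if "branch" not in ann.columns:
        ann["branch"] = _DEFAULT_BRANCH
    if mode == "labels":
        _require_columns(ann, ["cell_id", "segment"])
        out = ann[["cell_id", "branch", "segment"]].copy()
        orders = {}
        for branch, sub in ann.groupby("branch", sort=False):
            if "pseudotime" in sub.columns and sub["pseudotime"].notna().all():
                med = sub.groupby("segment", sort=False)["pseudotime"].median()
                ordered = list(med.sort_values(kind="stable").index)
            else:
                ordered = list(dict.fromkeys(sub["segment"]))
            orders.update({(branch, seg): i for i, seg in enumerate(ordered)})
        out["segment_order"] = [
            orders[(b, s)] for b, s in zip(out["branch"], out["segment"])
        ]
        return out
    if mode.startswith("bins:"):
        try:
            k = int(mode.split(":", 1)[1])
        except ValueError as exc:
            raise TrajectoryError(f"bad binning spec {mode!r}") from exc
        if k <= 0:
            raise TrajectoryError("bin count must be positive")
        _require_columns(ann, ["cell_id", "pseudotime"])
        rows = []
        for branch, sub in ann.groupby("branch", sort=False):
            if k > len(sub):
                raise TrajectoryError(
                    f"branch {branch!r}: {k} bins requested for {len(sub)} cells"
                )
            ordered = sub.sort_values(
                ["pseudotime", "cell_id"], kind="stable"
            ).reset_index(drop=True)
            # equal-count split: first (len % k) bins get one extra cell
            edges = np.linspace(0, len(ordered), k + 1).round().astype(int)
            for i in range(k):
                for cell in ordered["cell_id"].iloc[edges[i] : edges[i + 1]]:
                    rows.append((cell, branch, f"bin{i}", i))
        return pd.DataFrame(rows, columns=["cell_id", "branch", "segment", "segment_order"])
    raise TrajectoryError(f"unknown segmentation mode {mode!r}")


def asymmetry_along_trajectory(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    triads: TriadTable,
    min_total_expr: float = 0.5,
    normalization: str = "cp10k",
    mode: str = "labels",
    centroids: CentroidSet | None = None,
) -> pd.DataFrame:
    """Unbalanced-triad fraction per ordered trajectory segment.

    Returns ``branch, segment, segment_order, n_cells, n_expressed_triads,
    unbalanced_fraction`` sorted start -> terminal within each branch.
    Segments without cells are impossible by construction (they would not
    appear); empty expressed sets yield NaN fractions and a log entry.
    """
    seg = segment_cells(annotation, mode=mode)
    seg_ann = seg.rename(columns={"segment": "cluster"})[["cell_id", "cluster"]]
    expr = pseudobulk_means(cm, seg_ann, normalization=normalization)
    calls = classify_groups(expr, triads, min_total_expr, centroids)
    meta = (
        seg.groupby(["branch", "segment", "segment_order"], sort=False)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    rows = []
    for _, m in meta.iterrows():
        segment_calls = calls[m["segment"]]
        expressed = [c for c in segment_calls if c.category != NOT_EXPRESSED]
        n_expr = len(expressed)
        if n_expr == 0:
            logger.warning(
                "segment %s/%s has no expressed triads", m["branch"], m["segment"]
            )
            frac = np.nan
        else:
            frac = sum(1 for c in expressed if c.category != "Balance") / n_expr
        rows.append(
            (m["branch"], m["segment"], int(m["segment_order"]), int(m["n_cells"]), n_expr, frac)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "branch",
            "segment",
            "segment_order",
            "n_cells",
            "n_expressed_triads",
            "unbalanced_fraction",
        ],
    )
    return out.sort_values(["branch", "segment_order"], kind="stable").reset_index(
        drop=True
    )
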