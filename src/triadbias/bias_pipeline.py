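"""Pseudobulk aggregation and bulk-vs-cluster bias summaries.

Implements the per-group classification workflow: average single cells into
group-level expression, classify every triad per group, and derive the
summary tables — category proportions per group, the breakdown of
bulk-balanced triads within clusters, suppressed/dominant ratios per
subgenome, and marker-gene bias summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix
from .triad_core import (
    CATEGORIES,
    NOT_EXPRESSED,
    BiasCall,
    CentroidSet,
    TriadTable,
    classify_matrix,
)

logger = logging.getLogger(__name__)

_SUBGENOMES = ("A", "B", "D")


class PipelineError(ValueError):
    """Inconsistent inputs to a pipeline stage."""


def pseudobulk_means(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    normalization: str = "cp10k",
    group_col: str = "cluster",
) -> pd.DataFrame:
    """Gene-by-group matrix of mean expression.

    ``cp10k`` scales each cell to 10,000 total counts before averaging
    (zero-total cells stay zero, with a warning); ``raw_mean`` averages raw
    counts. Column order follows first appearance of groups in the
    annotation.
    """
    if normalization not in ("cp10k", "raw_mean"):
        raise ValueError(f"unknown normalization {normalization!r}")
    ann = annotation.set_index("cell_id")
    missing = [b for b in cm.barcodes if b not in ann.index]
    if missing:
        raise PipelineError(
            f"{len(missing)} cell(s) missing annotation: {missing[:10]}"
        )
    groups_per_cell = ann.loc[cm.barcodes, group_col]
    group_order = list(dict.fromkeys(groups_per_cell))

    X = cm.matrix.astype(np.float64)
    if normalization == "cp10k":
        totals = np.asarray(X.sum(axis=0)).ravel()
        zero = totals == 0
        if zero.any():
            logger.warning("pseudobulk_means: %d zero-count cells left at zero", zero.sum())
        scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=~zero)
        X = X @ sp.diags(scale)

    cols = {}
    codes = groups_per_cell.to_numpy()
    for g in group_order:
        idx = np.flatnonzero(codes == g)
        if idx.size == 0:
            raise PipelineError(f"group {g!r} has no cells")
        cols[g] = np.asarray(X[:, idx].mean(axis=1)).ravel()
    return pd.DataFrame(cols, index=pd.Index(cm.genes, name="gene"))


def classify_groups(
    expr: pd.DataFrame,
    triads: TriadTable,
    min_total_expr: float = 0.5,
    centroids: CentroidSet | None = None,
) -> dict[str, list[BiasCall]]:
    """Run the nearest-centroid classifier on every column of ``expr``."""
    return {
        group: classify_matrix(expr, triads, group, min_total_expr, centroids)
        for group in expr.columns
    }


def calls_to_frame(calls_by_group: Mapping[str, Sequence[BiasCall]]) -> pd.DataFrame:
    """Long table of calls: triad_id, group, fa, fb, fd, category, distance."""
    rows = []
    for group, calls in calls_by_group.items():
        for c in calls:
            if c.composition is None:
                rows.append((c.triad_id, group, np.nan, np.nan, np.nan, c.category, np.nan))
            else:
                rows.append(
                    (
                        c.triad_id,
                        group,
                        c.composition.fa,
                        c.composition.fb,
                        c.composition.fd,
                        c.category,
                        c.distance,
                    )
                )
    return pd.DataFrame(
        rows, columns=["triad_id", "group", "fa", "fb", "fd", "category", "distance"]
    )


@dataclass(frozen=True)
class BiasSummary:
    """Per-group category counts and proportions over expressed triads.

    ``table`` columns: ``group, category, count, proportion`` with one row
    per group for each of the seven categories plus ``not_expressed``
    (whose proportion is NaN — it is excluded from the denominator).
    """

    table: pd.DataFrame

    def counts(self, group: str) -> pd.Series:
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise KeyError(f"no summary rows for group {group!r}")
        return sub.set_index("category")["count"]

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))


def category_proportions(
    calls_by_group: Mapping[str, Sequence[BiasCall]],
) -> BiasSummary:
    """Stacked-histogram-ready counts/proportions of the seven categories."""
    if not calls_by_group:
        raise PipelineError("no groups supplied")
    rows = []
    for group, calls in calls_by_group.items():
        cats = pd.Series([c.category for c in calls])
        counts = cats.value_counts()
        n_expr = int(counts.reindex(CATEGORIES).fillna(0).sum())
        for cat in CATEGORIES:
            cnt = int(counts.get(cat, 0))
            prop = cnt / n_expr if n_expr > 0 else np.nan
            rows.append((group, cat, cnt, prop))
        rows.append((group, NOT_EXPRESSED, int(counts.get(NOT_EXPRESSED, 0)), np.nan))
    return BiasSummary(pd.DataFrame(rows, columns=["group", "category", "count", "proportion"]))


def suppressed_dominant_ratio(
    summary: BiasSummary, subgenome: str, group: str
) -> float:
    """count(g.suppressed) / count(g.dominant) for one subgenome and group.

    A zero dominant count yields ``inf`` with a warning rather than an
    exception (small clusters routinely hit it).
    """
    if subgenome not in _SUBGENOMES:
        raise ValueError(f"subgenome must be one of {_SUBGENOMES}")
    counts = summary.counts(group)
    supp = counts.get(f"{subgenome}.suppressed", 0)
    dom = counts.get(f"{subgenome}.dominant", 0)
    if dom == 0:
        warnings.warn(
            f"group {group!r}: no {subgenome}.dominant triads; ratio is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(supp) / float(dom)


def ratio_table(summary: BiasSummary) -> pd.DataFrame:
    """Suppressed/dominant ratios for all subgenomes and groups."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for group in summary.groups():
            for g in _SUBGENOMES:
                rows.append((group, g, suppressed_dominant_ratio(summary, g, group)))
    return pd.DataFrame(rows, columns=["group", "subgenome", "suppressed_dominant_ratio"])


def balanced_breakdown(
    bulk_calls: Sequence[BiasCall],
    cluster_calls: Mapping[str, Sequence[BiasCall]],
) -> pd.DataFrame:
    """Cluster-level category distribution of the bulk-balanced triads.

    Restricted to triads classified ``Balance`` in bulk. Per cluster, two
    denominators are reported: ``proportion`` uses bulk-balanced triads
    expressed in that cluster; ``proportion_all`` uses all bulk-balanced
    triads (the cluster's ``not_expressed`` row carries only the latter).
    """
    bulk_ids = {c.triad_id for c in bulk_calls}
    balanced = {c.triad_id for c in bulk_calls if c.category == "Balance"}
    rows = []
    for group, calls in cluster_calls.items():
        ids = {c.triad_id for c in calls}
        if ids != bulk_ids:
            raise PipelineError(
                f"cluster {group!r} calls cover a different triad set than bulk"
            )
        sub = [c for c in calls if c.triad_id in balanced]
        cats = pd.Series([c.category for c in sub])
        counts = cats.value_counts()
        n_all = len(sub)
        n_expr = int(counts.reindex(CATEGORIES).fillna(0).sum())
        for cat in CATEGORIES:
            cnt = int(counts.get(cat, 0))
            rows.append(
                (
                    group,
                    cat,
                    cnt,
                    cnt / n_expr if n_expr else np.nan,
                    cnt / n_all if n_all else np.nan,
                )
            )
        ne = int(counts.get(NOT_EXPRESSED, 0))
        rows.append((group, NOT_EXPRESSED, ne, np.nan, ne / n_all if n_all else np.nan))
    return pd.DataFrame(
        rows, columns=["group", "category", "count", "proportion", "proportion_all"]
    )


def unbalanced_fraction(breakdown: pd.DataFrame) -> pd.Series:
    """Per-group 1 - proportion(Balance) from a breakdown/proportions table."""
    bal = breakdown[breakdown["category"] == "Balance"].set_index("group")["proportion"]
    return (1.0 - bal).rename("unbalanced_fraction")


def marker_bias_summary(
    cluster_calls: Mapping[str, Sequence[BiasCall]],
    marker_sets: Mapping[str, Iterable[str]],
    triads: TriadTable,
) -> pd.DataFrame:
    """Fraction of marker-containing triads that are non-Balance per group.

    A triad counts as a marker triad for a group when any member gene is in
    that group's marker list. Markers outside any triad are counted in
    ``n_markers_unmapped``. Groups with no expressed marker triads get NaN.
    """
    gene_to_triad: dict[str, str] = {}
    table = triads.data
    for role in ("gene_a", "gene_b", "gene_d"):
        gene_to_triad.update(dict(zip(table[role], table["triad_id"])))
    rows = []
    for group, markers in marker_sets.items():
        markers = list(markers)
        if group not in cluster_calls:
            raise PipelineError(f"no calls for marker group {group!r}")
        marker_triads = {gene_to_triad[m] for m in markers if m in gene_to_triad}
        n_unmapped = sum(1 for m in markers if m not in gene_to_triad)
        if n_unmapped:
            logger.info(
                "marker_bias_summary[%s]: %d markers not in any triad", group, n_unmapped
            )
        expressed = [
            c
            for c in cluster_calls[group]
            if c.triad_id in marker_triads and c.category != NOT_EXPRESSED
        ]
        n = len(expressed)
        n_unb = sum(1 for c in expressed if c.category != "Balance")
        rows.append(
            (group, len(marker_triads), n, n_unb, n_unb / n if n else np.nan, n_unmapped)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_marker_triads",
            "n_expressed_marker_triads",
            "n_unbalanced",
            "fraction_unbalanced",
            "n_markers_unmapped",
        ],
    )


def audit_denominators(
    summary: BiasSummary, n_triads: int
) -> None:
    """Assert category counts + not_expressed = triad-table size per group."""
    for group in summary.groups():
        total = int(summary.counts(group).sum())
        if total != n_triads:
            raise PipelineError(
                f"group {group!r}: counts sum to {total}, expected {n_triads}"
            )
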