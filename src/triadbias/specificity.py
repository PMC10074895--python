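"""Expression-specificity scoring and cross-species cluster comparison.

The specificity index of a gene's cross-group profile is
``S = 1 - H / log2(n_groups)`` where H is the Shannon entropy (bits) of the
profile normalized to sum to 1: 0 for a uniform profile, 1 for one-hot.
Cross-species cluster similarity is Spearman correlation over orthologous
genes with Benjamini-Hochberg adjustment across all cluster pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class SpecificityError(ValueError):
    """Invalid input to a specificity or correlation operation."""


@dataclass(frozen=True)
class SpecificityScore:
    gene: str
    s: float
    h: float
    n_groups: int


def shannon_specificity(
    x: Sequence[float], gene: str = "", normalized: bool = True
) -> SpecificityScore:
    """Entropy-based specificity of one expression profile.

    With ``normalized=False`` the raw information deficit
    ``log2(n) - H`` is reported instead of ``1 - H/log2(n)``.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise SpecificityError("profile must be a vector over >= 2 groups")
    if (arr < 0).any():
        raise SpecificityError("profile must be nonnegative")
    total = arr.sum()
    if total == 0:
        raise SpecificityError("profile sums to zero; specificity undefined")
    p = arr / total
    h = float(stats.entropy(p, base=2))  # 0*log0 handled as 0
    hmax = float(np.log2(arr.size))
    s = (1.0 - h / hmax) if normalized else (hmax - h)
    # clamp float fuzz at the boundaries
    if normalized:
        s = min(max(s, 0.0), 1.0)
    return SpecificityScore(gene=gene, s=s, h=h, n_groups=int(arr.size))


def specificity_table(
    expr: pd.DataFrame, genes: Iterable[str] | None = None, normalized: bool = True
) -> pd.DataFrame:
    """Per-gene specificity over the columns of a gene-by-group matrix.

    Zero-total genes get NaN scores (logged), matching the domain
    restriction of the index.
    """
    if expr.shape[1] < 2:
        raise SpecificityError("need >= 2 groups to score specificity")
    sub = expr.loc[list(genes)] if genes is not None else expr
    rows = []
    n_zero = 0
    for gene, profile in sub.iterrows():
        if profile.sum() == 0:
            n_zero += 1
            rows.append((gene, np.nan, np.nan, expr.shape[1]))
            continue
        sc = shannon_specificity(profile.to_numpy(), gene=str(gene), normalized=normalized)
        rows.append((gene, sc.s, sc.h, sc.n_groups))
    if n_zero:
        logger.info("specificity_table: %d zero-total genes scored NaN", n_zero)
    return pd.DataFrame(rows, columns=["gene", "S", "H", "n_groups"])


def top_specific_per_group(
    expr: pd.DataFrame, gene_subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """For each group, the highest-specificity gene among genes peaking there.

    A gene peaks in the group of its maximal mean (first column on exact
    ties); per-group winners break score ties by gene id order. Groups with
    no peaking gene get an NA row.
    """
    sub = expr.loc[list(gene_subset)] if gene_subset is not None else expr
    sub = sub[sub.sum(axis=1) > 0]
    scores = specificity_table(sub).set_index("gene")["S"]
    peaks = sub.idxmax(axis=1)
    rows = []
    for group in expr.columns:
        candidates = sorted(peaks.index[peaks == group])
        if not candidates:
            rows.append((group, None, np.nan))
            continue
        smax = max(scores[g] for g in candidates)
        best = sorted(g for g in candidates if scores[g] == smax)[0]
        rows.append((group, best, float(scores[best])))
    return pd.DataFrame(rows, columns=["group", "gene", "S"])


def _validate_ortholog_map(omap: pd.DataFrame) -> pd.DataFrame:
    if not {"gene1", "gene2"}.issubset(omap.columns):
        raise SpecificityError("ortholog map needs columns gene1, gene2")
    omap = omap[["gene1", "gene2"]].astype(str).drop_duplicates()
    if (omap["gene1"] == omap["gene2"]).any():
        raise SpecificityError("ortholog map contains self-pairs")
    return omap.reset_index(drop=True)


def collapse_orthologs(
    expr: pd.DataFrame,
    omap: pd.DataFrame,
    side: int = 1,
    policy: str = "one_to_one",
) -> pd.DataFrame:
    """Reindex a gene-by-group matrix onto ortholog-pair ids.

    ``side`` picks which column of the map (1 or 2) indexes ``expr``.
    ``one_to_one`` keeps only pairs whose genes are uniquely mapped on both
    sides; ``mean`` keeps every pair and averages rows that share a pair id.
    Pairs referencing genes absent from ``expr`` are dropped and counted.
    """
    if side not in (1, 2):
        raise SpecificityError("side must be 1 or 2")
    if policy not in ("one_to_one", "mean"):
        raise SpecificityError(f"unknown policy {policy!r}")
    omap = _validate_ortholog_map(omap)
    key = f"gene{side}"
    present = omap[key].isin(expr.index)
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("collapse_orthologs: %d pairs dropped (gene not in matrix)", n_dropped)
    omap = omap[present]
    if omap.empty:
        raise SpecificityError("no ortholog pairs map into the expression matrix")
    if policy == "one_to_one":
        unique1 = ~omap["gene1"].duplicated(keep=False)
        unique2 = ~omap["gene2"].duplicated(keep=False)
        omap = omap[unique1 & unique2]
        if omap.empty:
            raise SpecificityError("no one-to-one ortholog pairs remain")
    pair_id = omap["gene1"] + "|" + omap["gene2"]
    out = expr.loc[omap[key]].set_index(pd.Index(pair_id, name="pair"))
    out = out.groupby(level=0, sort=True).mean()
    return out


@dataclass(frozen=True)
class ClusterCorrelation:
    """Cluster-by-cluster rank correlations with BH-adjusted significance."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    padj: pd.DataFrame
    significant: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        long = self.rho.stack(future_stack=True).rename("rho").reset_index()
        long.columns = ["cluster1", "cluster2", "rho"]
        long["pvalue"] = self.pvalue.stack(future_stack=True).to_numpy()
        long["padj"] = self.padj.stack(future_stack=True).to_numpy()
        long["significant"] = self.significant.stack(future_stack=True).to_numpy()
        return long


def pairwise_cluster_correlation(
    m1: pd.DataFrame,
    m2: pd.DataFrame,
    genes: Iterable[str] | None = None,
    alpha: float = 0.05,
    n_permutations: int | None = None,
    seed: int = 0,
) -> ClusterCorrelation:
    """Spearman correlation of every cluster pair over shared gene rows.

    Rows are intersected (optionally restricted to ``genes``, e.g. an
    orthologous-marker union); p-values are two-sided (asymptotic, or
    permutation when ``n_permutations`` is set) and BH-adjusted across all
    pairs. Constant profiles yield NaN cells and are logged.
    """
    shared = m1.index.intersection(m2.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) == 0:
        raise SpecificityError("no shared gene rows between the two matrices")
    a = m1.loc[shared]
    b = m2.loc[shared]
    rho = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    pval = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    rng = np.random.default_rng(seed)
    for c1 in a.columns:
        for c2 in b.columns:
            x, y = a[c1].to_numpy(), b[c2].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                logger.warning("constant profile for pair (%s, %s); rho is NaN", c1, c2)
                continue
            if n_permutations:
                res = stats.permutation_test(
                    (x,),
                    lambda xs: stats.spearmanr(xs, y).statistic,
                    permutation_type="pairings",
                    n_resamples=n_permutations,
                    rng=rng,
                )
                rho.loc[c1, c2] = stats.spearmanr(x, y).statistic
                pval.loc[c1, c2] = res.pvalue
            else:
                r, p = stats.spearmanr(x, y)
                rho.loc[c1, c2] = r
                pval.loc[c1, c2] = p
    flat = pval.to_numpy().ravel()
    ok = ~np.isnan(flat)
    padj_flat = np.full_like(flat, np.nan)
    if ok.any():
        padj_flat[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    padj = pd.DataFrame(
        padj_flat.reshape(pval.shape), index=pval.index, columns=pval.columns
    )
    sig = (padj < alpha).fillna(False)
    return ClusterCorrelation(rho=rho, pvalue=pval, padj=padj, significant=sig)


def overlapped_marker_counts(
    markers1: Mapping[str, Iterable[str]],
    markers2: Mapping[str, Iterable[str]],
    omap: pd.DataFrame,
) -> pd.DataFrame:
    """Count cluster1 marker genes whose orthologs are cluster2 markers.

    Sankey-ready long table ``cluster1, cluster2, n_overlap``.
    """
    omap = _validate_ortholog_map(omap)
    partners: dict[str, set[str]] = {}
    for g1, g2 in zip(omap["gene1"], omap["gene2"]):
        partners.setdefault(g1, set()).add(g2)
    rows = []
    for c1, genes1 in markers1.items():
        set1 = set(genes1)
        for c2, genes2 in markers2.items():
            set2 = set(genes2)
            n = sum(1 for g in set1 if partners.get(g, set()) & set2)
            rows.append((c1, c2, n))
    return pd.DataFrame(rows, columns=["cluster1", "cluster2", "n_overlap"])
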