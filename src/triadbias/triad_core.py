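"""Triads, simplex normalization, and nearest-centroid bias classification.

A *triad* is a set of three homoeologous genes, one from each of the A, B,
and D subgenomes of an allohexaploid. Given expression values for the three
members, the triad is projected onto the 2-simplex (fractions summing to 1)
and assigned to one of seven bias categories by Euclidean distance to a set
of ideal centroids:

========================  =====================
category                  centroid (fA, fB, fD)
========================  =====================
``Balance``               (1/3, 1/3, 1/3)
``A.dominant``            (1, 0, 0)
``B.dominant``            (0, 1, 0)
``D.dominant``            (0, 0, 1)
``A.suppressed``          (0, 1/2, 1/2)
``B.suppressed``          (1/2, 0, 1/2)
``D.suppressed``          (1/2, 1/2, 0)
========================  =====================

Triads whose total expression falls at or below a caller-chosen floor are
labelled with the sentinel ``not_expressed`` and carry no composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven bias categories, in tie-breaking preference order.
CATEGORIES: tuple[str, ...] = (
    "Balance",
    "A.dominant",
    "B.dominant",
    "D.dominant",
    "A.suppressed",
    "B.suppressed",
    "D.suppressed",
)

#: Sentinel category for triads below the expression floor.
NOT_EXPRESSED = "not_expressed"

#: Roles of the three triad members.
ROLES: tuple[str, str, str] = ("gene_a", "gene_b", "gene_d")

_COMP_TOL = 1e-9
# Ties between centroids are measure-zero but reachable (e.g. exact
# midpoints); resolved by preference order within this absolute slack.
_TIE_TOL = 1e-12


class TriadFormatError(ValueError):
    """An input file does not match the expected triad-table schema."""


class TriadValidationError(ValueError):
    """Triad table content violates a structural invariant."""


class NotExpressedError(ValueError):
    """Normalization was requested for a triad with zero total expression."""


@dataclass(frozen=True)
class TriadComposition:
    """A point on the 2-simplex: per-subgenome expression fractions."""

    fa: float
    fb: float
    fd: float

    def __post_init__(self) -> None:
        total = self.fa + self.fb + self.fd
        if min(self.fa, self.fb, self.fd) < 0:
            raise TriadValidationError(
                f"composition has negative component: ({self.fa}, {self.fb}, {self.fd})"
            )
        if abs(total - 1.0) > _COMP_TOL:
            raise TriadValidationError(
                f"composition does not sum to 1 (got {total!r})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.fa, self.fb, self.fd], dtype=float)


@dataclass(frozen=True)
class BiasCall:
    """Classification result for a single triad in a single group."""

    triad_id: str
    category: str
    distance: float
    composition: TriadComposition | None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES and self.category != NOT_EXPRESSED:
            raise TriadValidationError(f"unknown category {self.category!r}")


def _default_centroids() -> dict[str, TriadComposition]:
    third, half = 1.0 / 3.0, 0.5
    return {
        "Balance": TriadComposition(third, third, third),
        "A.dominant": TriadComposition(1.0, 0.0, 0.0),
        "B.dominant": TriadComposition(0.0, 1.0, 0.0),
        "D.dominant": TriadComposition(0.0, 0.0, 1.0),
        "A.suppressed": TriadComposition(0.0, half, half),
        "B.suppressed": TriadComposition(half, 0.0, half),
        "D.suppressed": TriadComposition(half, half, 0.0),
    }


@dataclass(frozen=True)
class CentroidSet:
    """The seven ideal simplex points used by the classifier.

    Category order doubles as the deterministic tie-breaking order
    (``Balance`` first, then dominants, then suppressed).
    """

    centroids: Mapping[str, TriadComposition] = field(
        default_factory=_default_centroids
    )

    def __post_init__(self) -> None:
        if tuple(self.centroids) != CATEGORIES:
            raise TriadValidationError(
                "centroid set must contain exactly the seven categories "
                f"{CATEGORIES} in order; got {tuple(self.centroids)}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.centroids)

    def matrix(self) -> np.ndarray:
        """(7, 3) array of centroid coordinates in category order."""
        return np.stack([c.as_array() for c in self.centroids.values()])


class TriadTable:
    """Validated table of A/B/D homoeolog triples.

    Parameters
    ----------
    data
        Frame with columns ``triad_id``, ``gene_a``, ``gene_b``, ``gene_d``.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        required = ["triad_id", *ROLES]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise TriadFormatError(f"triad table missing columns: {missing}")
        data = data.loc[:, required].reset_index(drop=True)
        dup_ids = data["triad_id"][data["triad_id"].duplicated()]
        if not dup_ids.empty:
            raise TriadValidationError(
                f"duplicate triad_id values: {sorted(set(dup_ids))[:10]}"
            )
        genes = pd.concat([data[r] for r in ROLES], ignore_index=True)
        dup_genes = genes[genes.duplicated()]
        if not dup_genes.empty:
            raise TriadValidationError(
                "gene identifiers appear in more than one triad or role: "
                f"{sorted(set(dup_genes))[:10]}"
            )
        self._data = data

    @property
    def data(self) -> pd.DataFrame:
        return self._data.copy()

    @property
    def triad_ids(self) -> pd.Series:
        return self._data["triad_id"]

    @property
    def genes(self) -> pd.Index:
        """All member genes (3 per triad), A genes first, then B, then D."""
        return pd.Index(
            pd.concat([self._data[r] for r in ROLES], ignore_index=True)
        )

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TriadTable) and self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"TriadTable(n_triads={len(self)})"


def load_triad_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> TriadTable:
    """Read a tab-separated triad table, keeping only complete triples.

    ``column_map`` maps the roles ``triad_id``/``gene_a``/``gene_b``/``gene_d``
    to the actual column names in the file (defaults: ``triad_id``, ``A``,
    ``B``, ``D``). Rows missing any member are dropped and logged; duplicate
    triad_ids keep the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    defaults = {"triad_id": "triad_id", "gene_a": "A", "gene_b": "B", "gene_d": "D"}
    colmap = {**defaults, **(column_map or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise TriadFormatError(
            f"{path}: missing required column(s) {missing}; found {list(raw.columns)}"
        )
    frame = pd.DataFrame({role: raw[src] for role, src in colmap.items()})
    n_input = len(frame)
    frame = frame.replace("", np.nan)
    complete = frame.dropna(subset=["triad_id", *ROLES])
    n_incomplete = n_input - len(complete)
    deduped = complete.drop_duplicates(subset="triad_id", keep="first")
    n_duplicate = len(complete) - len(deduped)
    logger.info(
        "load_triad_table: %d rows read, %d incomplete dropped, "
        "%d duplicate triad_ids dropped, %d kept",
        n_input, n_incomplete, n_duplicate, len(deduped),
    )
    return TriadTable(deduped.reset_index(drop=True))


def normalize_triad(a: float, b: float, d: float) -> TriadComposition:
    """Scale the three homoeolog expression values to sum to 1.

    Raises :class:`NotExpressedError` when the total is zero and
    :class:`TriadValidationError` for negative inputs.
    """
    if min(a, b, d) < 0:
        raise TriadValidationError(
            f"expression values must be nonnegative, got ({a}, {b}, {d})"
        )
    total = a + b + d
    if total == 0:
        raise NotExpressedError("triad not expressed (zero total expression)")
    return TriadComposition(a / total, b / total, d / total)


def euclidean_distance(p: TriadComposition, q: TriadComposition) -> float:
    """Euclidean distance between two compositions in 3-component space."""
    return float(np.linalg.norm(p.as_array() - q.as_array()))


def _nearest_centroid(points: np.ndarray, centroids: CentroidSet):
    """Vectorized nearest-centroid assignment.

    Parameters
    ----------
    points
        (n, 3) array of simplex points.

    Returns
    -------
    idx, dist
        Winning centroid index (position in :data:`CATEGORIES`) and its
        distance, per point. Near-exact ties go to the earliest category.
    """
    cmat = centroids.matrix()  # (7, 3)
    diffs = points[:, None, :] - cmat[None, :, :]
    dists = np.sqrt((diffs**2).sum(axis=2))  # (n, 7)
    dmin = dists.min(axis=1, keepdims=True)
    # first index within tie tolerance of the minimum
    idx = (dists <= dmin + _TIE_TOL).argmax(axis=1)
    return idx, dists[np.arange(len(points)), idx]


def classify_composition(
    comp: TriadComposition,
    centroids: CentroidSet | None = None,
    triad_id: str = "",
) -> BiasCall:
    """Assign a composition to the bias category with the nearest centroid."""
    centroids = centroids or CentroidSet()
    idx, dist = _nearest_centroid(comp.as_array()[None, :], centroids)
    return BiasCall(
        triad_id=triad_id,
        category=centroids.names[int(idx[0])],
        distance=float(dist[0]),
        composition=comp,
    )


def classify_matrix(
    expr: pd.DataFrame,
    triads: TriadTable,
    group: str,
    min_total_expr: float = 0.5,
    centroids: CentroidSet | None = None,
) -> list[BiasCall]:
    """Classify every triad from one column of a gene-by-group matrix.

    Genes absent from ``expr`` contribute 0. Triads whose A+B+D total is
    ``<= min_total_expr`` are returned as ``not_expressed`` (NaN distance,
    no composition). Output order and length match the triad table.
    """
    if group not in expr.columns:
        raise KeyError(f"group {group!r} not in expression matrix columns")
    centroids = centroids or CentroidSet()
    col = expr[group]
    if (col < 0).any():
        raise TriadValidationError(f"negative expression values in group {group!r}")
    table = triads.data
    vals = np.column_stack(
        [col.reindex(table[r]).fillna(0.0).to_numpy(dtype=float) for r in ROLES]
    )
    totals = vals.sum(axis=1)
    expressed = totals > min_total_expr
    calls: list[BiasCall] = []
    if expressed.any():
        points = vals[expressed] / totals[expressed, None]
        idx, dist = _nearest_centroid(points, centroids)
    pos = 0
    for i, tid in enumerate(table["triad_id"]):
        if expressed[i]:
            comp = TriadComposition(*points[pos])
            calls.append(
                BiasCall(tid, centroids.names[int(idx[pos])], float(dist[pos]), comp)
            )
            pos += 1
        else:
            calls.append(BiasCall(tid, NOT_EXPRESSED, float("nan"), None))
    n_ne = int((~expressed).sum())
    if n_ne:
        logger.info(
            "classify_matrix[%s]: %d/%d triads below min_total_expr=%g",
            group, n_ne, len(table), min_total_expr,
        )
    return calls


def ternary_coordinates(calls: Iterable[BiasCall]) -> pd.DataFrame:
    """Plot-ready table of simplex coordinates for expressed triads.

    Columns: ``triad_id, fa, fb, fd, category``. ``not_expressed`` calls are
    skipped.
    """
    rows = [
        (c.triad_id, c.composition.fa, c.composition.fb, c.composition.fd, c.category)
        for c in calls
        if c.category != NOT_EXPRESSED
    ]
    return pd.DataFrame(rows, columns=["triad_id", "fa", "fb", "fd", "category"])
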