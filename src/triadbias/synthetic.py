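"""Synthetic allopolyploid single-cell count data with planted triad bias.

The generator plants, for every cluster x triad, a bias category and a
latent simplex composition drawn from a Dirichlet around that category's
centroid; per-cell counts then arise from a negative-binomial triad total,
a multinomial A/B/D split, and independent Bernoulli dropout. An optional
branching trajectory plants a monotone gradient of unbalanced triads along
ordered segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix
from .triad_core import CATEGORIES, CentroidSet, TriadTable

logger = logging.getLogger(__name__)

# Dirichlet parameters must be positive; zero centroid coordinates get this
# floor before scaling by the concentration. Kept small enough that the
# Dirichlet mean stays within 1e-3 of every centroid coordinate.
EPS_FLOOR = 1e-4

_STAGES = ("truth", "gene_means", "counts", "dropout")


class SimulationError(ValueError):
    """Invalid simulation configuration or inconsistent inputs."""


@dataclass(frozen=True)
class TrajectoryConfig:
    """Ordered trajectory segments and their target unbalanced fractions.

    ``branches`` maps a branch label to its ordered segment labels
    (start -> terminal); ``unbalanced_targets`` gives, per segment, the
    fraction of triads planted with a non-Balance category.
    """

    branches: Mapping[str, Sequence[str]]
    unbalanced_targets: Mapping[str, float]

    def __post_init__(self) -> None:
        segments = [s for segs in self.branches.values() for s in segs]
        if len(segments) != len(set(segments)):
            raise SimulationError("segment labels must be unique across branches")
        for seg in segments:
            if seg not in self.unbalanced_targets:
                raise SimulationError(f"no unbalanced target for segment {seg!r}")
            t = self.unbalanced_targets[seg]
            if not 0.0 <= t <= 1.0:
                raise SimulationError(f"unbalanced target for {seg!r} not in [0,1]: {t}")
        for branch, segs in self.branches.items():
            targets = [self.unbalanced_targets[s] for s in segs]
            if any(b < a for a, b in zip(targets, targets[1:])):
                logger.warning(
                    "trajectory branch %r has non-monotone unbalanced targets %s",
                    branch, targets,
                )

    @property
    def segments(self) -> list[str]:
        return [s for segs in self.branches.values() for s in segs]


def _default_category_probs() -> tuple[float, ...]:
    # mildly Balance-heavy mixture over the seven categories
    return (0.4, 0.08, 0.08, 0.08, 0.12, 0.12, 0.12)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; every stochastic element derives from ``seed``."""

    n_triads: int = 1000
    n_clusters: int = 5
    cells_per_cluster: int = 200
    category_probs: Sequence[float] | Sequence[Sequence[float]] = field(
        default_factory=_default_category_probs
    )
    dirichlet_concentration: float = 200.0
    mean_total_expr: float = 10.0
    gamma_shape: float = 2.0
    nb_dispersion: float = 1.0
    dropout_rate: float = 0.3
    trajectory: TrajectoryConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_triads <= 0 or self.n_clusters <= 0 or self.cells_per_cluster <= 0:
            raise SimulationError("n_triads, n_clusters, cells_per_cluster must be positive")
        if self.dirichlet_concentration <= 0:
            raise SimulationError("dirichlet_concentration must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise SimulationError("dropout_rate must be in [0, 1]")
        if self.mean_total_expr <= 0 or self.gamma_shape <= 0 or self.nb_dispersion <= 0:
            raise SimulationError("expression parameters must be positive")
        probs = self.probs_matrix()
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
            raise SimulationError("category_probs rows must sum to 1")
        if (probs < 0).any():
            raise SimulationError("category_probs must be nonnegative")

    def probs_matrix(self) -> np.ndarray:
        """(n_groups, 7) per-cluster category probabilities."""
        probs = np.asarray(self.category_probs, dtype=float)
        n = len(self.cluster_labels())
        if probs.ndim == 1:
            probs = np.tile(probs, (n, 1))
        if probs.shape != (n, len(CATEGORIES)):
            raise SimulationError(
                f"category_probs must be a 7-vector or a ({n}, 7) matrix; "
                f"got shape {probs.shape}"
            )
        return probs

    def cluster_labels(self) -> list[str]:
        """Group labels: trajectory segments if configured, else cluster0..N."""
        if self.trajectory is not None:
            return list(self.trajectory.segments)
        return [f"cluster{i}" for i in range(self.n_clusters)]

    def child_rngs(self) -> dict[str, np.random.Generator]:
        """Deterministic per-stage generators derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimulationConfig":
        payload = dict(payload)
        traj = payload.pop("trajectory", None)
        if traj is not None and not isinstance(traj, TrajectoryConfig):
            traj = TrajectoryConfig(
                branches=traj["branches"],
                unbalanced_targets=traj["unbalanced_targets"],
            )
        if "category_probs" in payload and payload["category_probs"] is not None:
            payload["category_probs"] = payload["category_probs"]
        else:
            payload.pop("category_probs", None)
        return cls(trajectory=traj, **payload)


def make_triad_table(n_triads: int) -> TriadTable:
    """Deterministic triad table naming 3*n_triads synthetic genes."""
    ids = [f"tri{i:05d}" for i in range(n_triads)]
    return TriadTable(
        pd.DataFrame(
            {
                "triad_id": ids,
                "gene_a": [f"g{i:05d}A" for i in range(n_triads)],
                "gene_b": [f"g{i:05d}B" for i in range(n_triads)],
                "gene_d": [f"g{i:05d}D" for i in range(n_triads)],
            }
        )
    )


def plant_truth(config: SimulationConfig) -> pd.DataFrame:
    """Draw the planted category and latent composition per cluster x triad.

    Returns a frame with columns ``cluster, triad_id, category, fa, fb, fd``
    (one row per cluster x triad, cluster-major, triad order within cluster).
    With a trajectory configured, each segment plants exactly
    ``round(target * n_triads)`` non-Balance triads, nested along each
    branch so monotone targets produce monotone planted fractions.
    """
    rng = config.child_rngs()["truth"]
    labels = config.cluster_labels()
    probs = config.probs_matrix()
    n = config.n_triads
    triad_ids = [f"tri{i:05d}" for i in range(n)]
    centroid_mat = CentroidSet().matrix()
    kappa = config.dirichlet_concentration

    cat_idx_by_cluster: dict[str, np.ndarray] = {}
    if config.trajectory is None:
        for label, p in zip(labels, probs):
            cat_idx_by_cluster[label] = rng.choice(len(CATEGORIES), size=n, p=p)
    else:
        # One global ordering of triads + one non-Balance category per triad:
        # segment targets carve nested prefixes so gradients are monotone in
        # the planted assignment, not only in expectation.
        order = rng.permutation(n)
        nonbal = probs[0][1:]
        if nonbal.sum() == 0:
            nonbal = np.ones(len(CATEGORIES) - 1)
        nonbal = nonbal / nonbal.sum()
        per_triad_nonbal = rng.choice(
            np.arange(1, len(CATEGORIES)), size=n, p=nonbal
        )
        for label in labels:
            target = config.trajectory.unbalanced_targets[label]
            n_unb = int(round(target * n))
            cats = np.zeros(n, dtype=int)  # Balance
            unb = order[:n_unb]
            cats[unb] = per_triad_nonbal[unb]
            cat_idx_by_cluster[label] = cats

    frames = []
    for label in labels:
        cats = cat_idx_by_cluster[label]
        comps = np.empty((n, 3))
        for k in range(len(CATEGORIES)):
            mask = cats == k
            cnt = int(mask.sum())
            if cnt:
                alpha = kappa * (centroid_mat[k] + EPS_FLOOR)
                comps[mask] = rng.dirichlet(alpha, size=cnt)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": label,
                    "triad_id": triad_ids,
                    "category": [CATEGORIES[k] for k in cats],
                    "fa": comps[:, 0],
                    "fb": comps[:, 1],
                    "fd": comps[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_counts(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame, TriadTable]:
    """Generate the gene-by-cell count matrix implied by a truth table.

    Per cell, each triad's total count is negative-binomial around a
    triad-level gamma mean, split A/B/D multinomially with the planted
    cluster composition, then thinned by dropout. Gene rows are ordered
    A/B/D within each triad.
    """
    labels = config.cluster_labels()
    if set(truth["cluster"]) != set(labels):
        raise SimulationError(
            f"truth clusters {sorted(set(truth['cluster']))} do not match config "
            f"labels {labels}"
        )
    if (truth.groupby("cluster").size() != config.n_triads).any():
        raise SimulationError("truth must contain one row per cluster x triad")

    rngs = config.child_rngs()
    n = config.n_triads
    ncells = config.cells_per_cluster
    triads = make_triad_table(n)

    mu = rngs["gene_means"].gamma(
        shape=config.gamma_shape,
        scale=config.mean_total_expr / config.gamma_shape,
        size=n,
    )
    r = config.nb_dispersion
    p_nb = r / (r + mu)  # per-triad NB success prob

    rng_c = rngs["counts"]
    rng_d = rngs["dropout"]
    blocks = []
    barcodes: list[str] = []
    ann_rows = []
    for label in labels:
        sub = truth[truth["cluster"] == label].set_index("triad_id")
        comp = sub.loc[[f"tri{i:05d}" for i in range(n)], ["fa", "fb", "fd"]].to_numpy()
        totals = rng_c.negative_binomial(r, p_nb[:, None], size=(n, ncells))
        pa = comp[:, [0]]
        a = rng_c.binomial(totals, pa)
        rem = totals - a
        pbd = comp[:, 1] + comp[:, 2]
        pb = np.divide(comp[:, 1], pbd, out=np.zeros(n), where=pbd > 0)
        b = rng_c.binomial(rem, pb[:, None])
        d = rem - b
        block = np.empty((3 * n, ncells), dtype=np.int64)
        block[0::3] = a
        block[1::3] = b
        block[2::3] = d
        if config.dropout_rate > 0:
            keep = rng_d.random(block.shape) >= config.dropout_rate
            block *= keep
        blocks.append(sp.csr_matrix(block))
        for j in range(ncells):
            cell = f"{label}-c{j:04d}"
            barcodes.append(cell)
            ann_rows.append((cell, label))

    # row order: triad-major A/B/D to match make_triad_table gene triples
    genes = [
        g
        for i in range(n)
        for g in (f"g{i:05d}A", f"g{i:05d}B", f"g{i:05d}D")
    ]
    matrix = sp.hstack(blocks, format="csr")
    annotation = pd.DataFrame(ann_rows, columns=["cell_id", "cluster"])
    return CountMatrix(matrix, genes, barcodes), annotation, triads


def simulate_trajectory(
    truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Cell annotation with pseudotime/branch/segment for a trajectory run.

    Cells match :func:`simulate_counts` exactly (same ids, same order).
    Pseudotime spreads cells evenly within their segment's slot on the
    branch; a single-segment branch pins pseudotime to 0.
    """
    if config.trajectory is None:
        raise SimulationError("config.trajectory is not set")
    rows = []
    for branch, segs in config.trajectory.branches.items():
        k = len(segs)
        for i, seg in enumerate(segs):
            for j in range(config.cells_per_cluster):
                if k == 1:
                    pt = 0.0
                else:
                    pt = (i + (j + 0.5) / config.cells_per_cluster) / k
                rows.append((f"{seg}-c{j:04d}", seg, branch, seg, pt))
    return pd.DataFrame(
        rows, columns=["cell_id", "cluster", "branch", "segment", "pseudotime"]
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, TriadTable, pd.DataFrame]:
    """Convenience wrapper: plant truth, draw counts, attach trajectory columns.

    Returns ``(counts, annotation, triads, truth)``.
    """
    truth = plant_truth(config)
    cm, annotation, triads = simulate_counts(truth, config)
    if config.trajectory is not None:
        traj = simulate_trajectory(truth, config)
        annotation = annotation.merge(
            traj[["cell_id", "branch", "segment", "pseudotime"]],
            on="cell_id",
            validate="one_to_one",
        )
    return cm, annotation, triads, truth
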