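import numpy as np
import pandas as pd
import pytest

from triadbias.synthetic import SimulationConfig, simulate_dataset
from triadbias.triad_core import CATEGORIES, CentroidSet, TriadTable


@pytest.fixture
def centroids() -> CentroidSet:
    return CentroidSet()


@pytest.fixture
def centroid_matrix(centroids) -> np.ndarray:
    return centroids.matrix()


def brute_force_classify(point, centroid_matrix):
    """Independent oracle: exhaustive 7-way argmin over centroid distances.

    Returns (category, distance). Ties resolve to the earliest category,
    matching the documented preference order.
    """
    point = np.asarray(point, dtype=float)
    dists = [float(np.sqrt(((point - c) ** 2).sum())) for c in centroid_matrix]
    dmin = min(dists)
    best = next(i for i, d in enumerate(dists) if d <= dmin + 1e-12)
    return CATEGORIES[best], dists[best]


@pytest.fixture
def oracle():
    return brute_force_classify


def make_triads(n: int) -> TriadTable:
    return TriadTable(
        pd.DataFrame(
            {
                "triad_id": [f"t{i}" for i in range(n)],
                "gene_a": [f"a{i}" for i in range(n)],
                "gene_b": [f"b{i}" for i in range(n)],
                "gene_d": [f"d{i}" for i in range(n)],
            }
        )
    )


@pytest.fixture
def triads3() -> TriadTable:
    return make_triads(3)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted dataset shared across pipeline tests."""
    config = SimulationConfig(
        n_triads=150, n_clusters=3, cells_per_cluster=60, seed=11
    )
    cm, annotation, triads, truth = simulate_dataset(config)
    return config, cm, annotation, triads, truth
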