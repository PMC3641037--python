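import numpy as np
import pandas as pd
import pytest

from phylogeokit.distances import DistanceMatrix
from phylogeokit.io import BinaryMarkerMatrix, CodingAlignment, SampleTable
from phylogeokit.simulate import (
    SimulationConfig,
    simulate_aflp,
    simulate_landscape,
    simulate_sequences,
)


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic dataset shared by read-only tests."""
    conf = SimulationConfig(
        seed=7, n_individuals=40, n_loci=120, n_localities=20, n_clusters=3,
        seq_length=300, theta=10.0,
    )
    land = simulate_landscape(conf)
    markers, samples, truth = simulate_aflp(land, conf)
    alignment = simulate_sequences(land, conf, samples)
    return {
        "config": conf,
        "landscape": land,
        "markers": markers,
        "samples": samples,
        "truth": truth,
        "alignment": alignment,
        "env": land.env,
    }


@pytest.fixture
def toy_markers():
    values = np.array(
        [
            [1, 1, 0, 0, 1],
            [1, 0, 1, 0, 1],
            [0, 0, 1, 1, 0],
        ],
        dtype=np.int8,
    )
    return BinaryMarkerMatrix(["a", "b", "c"], [f"l{i}" for i in range(5)], values)


@pytest.fixture
def toy_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "individual_id": ["a", "b", "c"],
                "locality_id": ["p1", "p2", "p3"],
                "latitude": [35.0, 35.2, 35.4],
                "longitude": [24.0, 24.3, 24.9],
            }
        )
    )


def two_cluster_markers(
    n_per: int = 20, n_loci: int = 100, p_high: float = 0.9, seed: int = 1
):
    """Strongly differentiated two-cluster binary matrix with known truth."""
    rng = np.random.default_rng(seed)
    p = np.where(rng.random(n_loci) < 0.5, p_high, 1 - p_high)
    x = np.vstack(
        [
            (rng.random((n_per, n_loci)) < p).astype(np.int8),
            (rng.random((n_per, n_loci)) < (1 - p)).astype(np.int8),
        ]
    )
    ids = [f"i{i:02d}" for i in range(2 * n_per)]
    truth = np.array([1] * n_per + [2] * n_per)
    return (
        BinaryMarkerMatrix(ids, [f"l{j}" for j in range(n_loci)], x),
        truth,
    )


def distance_matrix_from_points(points: np.ndarray, labels=None) -> DistanceMatrix:
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    labels = labels or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(list(labels), d)


def alignment_from_strings(seqs, outgroup=(), frame=0) -> CodingAlignment:
    ids = list(seqs)
    mat = np.array(
        [np.frombuffer(s.encode(), dtype="S1") for s in seqs.values()]
    )
    flags = np.array([i in set(outgroup) for i in ids])
    return CodingAlignment(ids, mat, frame, flags)
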