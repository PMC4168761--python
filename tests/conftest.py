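import numpy as np
import pytest
from skbio import DistanceMatrix

from cophylospace import AlignedSequenceSet


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    """Labelled Euclidean distance matrix of a point configuration."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(d, ids)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_alignment():
    return AlignedSequenceSet(
        ("a", "b", "c"),
        ("ACGTACGT", "ACGAACGT", "A-GAACGT"),
    )
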