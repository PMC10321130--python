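import numpy as np
import pytest

from eegclust.bonn_io import EEGSegment, LabeledDataset
from eegclust.synthetic import SynthParams, generate_dataset


def two_blob(seed: int, n_per_blob: int = 20, gap: float = 8.0) -> np.ndarray:
    """Two well-separated Gaussian blobs in the plane."""
    rng = np.random.default_rng(seed)
    return np.vstack(
        [rng.normal(0.0, 1.0, (n_per_blob, 2)), rng.normal(gap, 1.0, (n_per_blob, 2))]
    )


def exhaustive_sse_optimum(X: np.ndarray) -> float:
    """Global optimum of the k=2 SSE objective by assignment enumeration.

    Every 2-partition of the points is tried with per-group mean centroids;
    independent of any clustering code under test.
    """
    n = len(X)
    best = np.inf
    for mask_bits in range(1, 2**n - 1):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        sse = 0.0
        for group in (X[mask], X[~mask]):
            sse += ((group - group.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """40 short two-class segments; session-scoped for speed."""
    return generate_dataset(20, SynthParams(n_samples=512), seed=11)


@pytest.fixture()
def short_segment() -> EEGSegment:
    rng = np.random.default_rng(5)
    return EEGSegment(rng.normal(0, 1, 256), fs=173.61, segment_id="s", label="normal")
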