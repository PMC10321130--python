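"""Optional signal conditioning before clustering.

The reference pipeline standardizes each segment (zero mean, unit sd);
component-based artifact suppression -- stacking same-class segments as
pseudo-channels, decomposing with ICA, and zeroing high-kurtosis
components -- is available as an opt-in step.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA

from .bonn_io import EEGSegment, LabeledDataset


class DegenerateInputError(ValueError):
    """Raised when an operation receives an input it is undefined for."""


def standardize_segment(segment: EEGSegment) -> EEGSegment:
    """Return the segment rescaled to mean 0 and sd 1 (n-1 denominator)."""
    x = segment.samples
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError(
            f"segment {segment.segment_id!r} is constant; cannot standardize"
        )
    z = (x - x.mean()) / sd
    return EEGSegment(z, fs=segment.fs, segment_id=segment.segment_id, label=segment.label)


def standardize_dataset(dataset: LabeledDataset) -> LabeledDataset:
    return LabeledDataset([standardize_segment(s) for s in dataset.segments])


def remove_artifact_components(
    dataset: LabeledDataset,
    n_components: int,
    kurtosis_threshold: float = 5.0,
    seed: int = 0,
) -> LabeledDataset:
    """Suppress high-kurtosis independent components, per class.

    Same-class segments are stacked as pseudo-channels of a multivariate
    record, decomposed into ``n_components`` maximally non-Gaussian
    components (FastICA), components with absolute excess kurtosis above
    ``kurtosis_threshold`` are zeroed, and the segments reconstructed.
    With an infinite threshold this is an identity up to reconstruction
    tolerance.  Off by default in the pipeline: the source corpus never
    specifies how single-channel segments map onto ICA inputs.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    cleaned: dict[str, list[EEGSegment]] = {}
    for label in dataset.labels:
        group = dataset.by_label(label)
        if n_components > len(group):
            raise ValueError(
                f"n_components={n_components} exceeds the {len(group)} segments "
                f"of class {label!r}"
            )
        X = np.stack([s.samples for s in group]).T  # (n_samples, n_segments)
        ica = FastICA(
            n_components=n_components, random_state=seed, whiten="unit-variance",
            max_iter=1000,
        )
        S = ica.fit_transform(X)  # (n_samples, n_components)
        kurt = stats.kurtosis(S, axis=0, fisher=True, bias=True)
        keep = np.abs(kurt) <= kurtosis_threshold
        S_clean = S * keep
        X_rec = S_clean @ ica.mixing_.T + ica.mean_
        cleaned[label] = [
            EEGSegment(X_rec[:, j], fs=s.fs, segment_id=s.segment_id, label=s.label)
            for j, s in enumerate(group)
        ]
    ordered = [
        cleaned[s.label].pop(0) for s in dataset.segments
    ]
    return LabeledDataset(ordered)
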