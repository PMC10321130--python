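"""Reading and writing EEG segments in the Bonn ASCII dialect.

The Bonn university corpus distributes each single-channel EEG segment as a
plain ASCII file with one integer amplitude per line: 4097 samples per
segment at ~173.61 Hz (23.6 s).  This module parses that dialect (slightly
liberally: decimal tokens and blank lines are tolerated) and assembles
labeled datasets from a ``path,label`` manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: Nominal Bonn sampling rate in Hz.
DEFAULT_FS = 173.61
#: Canonical Bonn segment length in samples (23.6 s at 173.61 Hz).
DEFAULT_SEGMENT_LENGTH = 4097

#: Bonn subset tags plus the two synthetic class tags.
KNOWN_LABELS = frozenset({"A", "B", "C", "D", "E", "normal", "ictal"})


class DialectError(ValueError):
    """Raised when a file violates the one-amplitude-per-line dialect."""


class ParseError(DialectError):
    """Raised when a line cannot be parsed as a number."""


@dataclass(frozen=True)
class EEGSegment:
    """One fixed-length single-channel EEG amplitude series.

    Parameters
    ----------
    samples : numpy array
        Amplitude series, arbitrary units (nominally microvolts).
    fs : float
        Sampling rate in Hz.
    segment_id : str
        Unique identifier within a dataset.
    label : str or None
        Class tag, e.g. a Bonn subset letter in ``A``-``E`` or
        ``normal``/``ictal`` for synthetic data.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    segment_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("segment needs at least 2 samples in a 1-d series")
        if not np.all(np.isfinite(samples)):
            raise ValueError("segment samples must be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class LabeledDataset:
    """A collection of equal-length labeled segments.

    ``class_index`` maps each label to the segment ids carrying it, in
    manifest order.
    """

    segments: list[EEGSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {s.n_samples for s in self.segments}
        if len(lengths) > 1:
            raise DialectError(f"mixed segment lengths in dataset: {sorted(lengths)}")
        for s in self.segments:
            if s.label is None:
                raise ValueError(f"segment {s.segment_id!r} has no label")

    @property
    def class_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for s in self.segments:
            index.setdefault(s.label, []).append(s.segment_id)
        return index

    @property
    def labels(self) -> list[str]:
        return sorted(self.class_index)

    def __len__(self) -> int:
        return len(self.segments)

    def by_label(self, label: str) -> list[EEGSegment]:
        return [s for s in self.segments if s.label == label]

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack segments as a (n_segments, n_samples) matrix plus labels."""
        X = np.stack([s.samples for s in self.segments])
        y = np.asarray([s.label for s in self.segments])
        return X, y


def read_segment(
    path: str | Path,
    expected_length: int | None = None,
    fs: float = DEFAULT_FS,
    label: str | None = None,
) -> EEGSegment:
    """Read one Bonn-dialect ASCII segment (one amplitude per line).

    Blank lines are ignored; integer and decimal tokens are both accepted.
    If ``expected_length`` is given the sample count must match it exactly.
    """
    path = Path(path)
    values: list[float] = []
    with path.open("r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: cannot parse {token!r} as a number"
                ) from exc
    if expected_length is not None and len(values) != expected_length:
        raise DialectError(
            f"{path}: expected {expected_length} samples, found {len(values)}"
        )
    return EEGSegment(np.asarray(values), fs=fs, segment_id=path.stem, label=label)


def write_segment(segment: EEGSegment, path: str | Path) -> None:
    """Write a segment in the Bonn dialect: one ASCII sample per line.

    Integer-valued samples are written without a decimal point so a
    write/read round trip of canonical Bonn data is byte-identical.
    """
    path = Path(path)
    with path.open("w", encoding="ascii") as fh:
        for v in segment.samples:
            if float(v).is_integer():
                fh.write(f"{int(v)}\n")
            else:
                fh.write(f"{float(v)!r}\n")


def load_labeled_dataset(
    manifest: str | Path | Sequence[tuple[str, str]] | Mapping[str, str],
    expected_length: int | None = None,
    fs: float = DEFAULT_FS,
    label_set: frozenset[str] | set[str] = KNOWN_LABELS,
    base_dir: str | Path | None = None,
) -> LabeledDataset:
    """Assemble a LabeledDataset from a ``(path, label)`` manifest.

    ``manifest`` may be a CSV file with columns ``path,label`` (header row
    optional) or an in-memory sequence of pairs.  Duplicate paths are loaded
    twice with disambiguated segment ids.  All segments must share one
    length; labels must come from ``label_set``.
    """
    if isinstance(manifest, (str, Path)):
        rows = _read_manifest_csv(Path(manifest))
        if base_dir is None:
            base_dir = Path(manifest).parent
    elif isinstance(manifest, Mapping):
        rows = list(manifest.items())
    else:
        rows = [(p, l) for p, l in manifest]

    base = Path(base_dir) if base_dir is not None else None
    segments: list[EEGSegment] = []
    seen_ids: dict[str, int] = {}
    for raw_path, label in rows:
        if label not in label_set:
            raise ValueError(f"unknown label {label!r}; expected one of {sorted(label_set)}")
        p = Path(raw_path)
        if base is not None and not p.is_absolute():
            p = base / p
        seg = read_segment(p, expected_length=expected_length, fs=fs, label=label)
        count = seen_ids.get(seg.segment_id, 0)
        seen_ids[seg.segment_id] = count + 1
        seg_id = seg.segment_id if count == 0 else f"{seg.segment_id}#{count}"
        segments.append(
            EEGSegment(seg.samples, fs=seg.fs, segment_id=seg_id, label=label)
        )
    return LabeledDataset(segments)


def write_manifest(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write a ``path,label`` manifest CSV with a header row."""
    with Path(path).open("w", newline="", encoding="ascii") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(rows)


def _read_manifest_csv(path: Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with path.open("r", newline="", encoding="ascii") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            if i == 0 and [c.strip().lower() for c in row[:2]] == ["path", "label"]:
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: manifest row {i + 1} needs path,label")
            rows.append((row[0].strip(), row[1].strip()))
    return rows
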