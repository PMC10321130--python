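"""Seeded synthetic two-class EEG generator in the Bonn dialect.

Emulates the geometry of the Bonn A-vs-E problem without downloading data:
"normal" segments are band-limited alpha-range rhythms over colored AR(1)
background noise; "ictal" segments are higher-amplitude ~3 Hz spike-wave
trains (a narrow Gaussian spike followed by a slow half-sine wave per
cycle) with harmonics and noise.  Everything is deterministic given
(class, params, seed); per-segment seeds are derived from the master seed
so datasets are reproducible independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bonn_io import (
    DEFAULT_FS,
    DEFAULT_SEGMENT_LENGTH,
    EEGSegment,
    LabeledDataset,
    write_manifest,
    write_segment,
)

CLASSES = ("normal", "ictal")


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters.

    Defaults mirror the Bonn segment geometry (4097 samples at 173.61 Hz)
    and give the ictal class the higher amplitude and stronger regularity
    that separate Bonn subsets A and E: an 8-12 Hz rhythm band for normal
    activity, a 3 Hz spike-wave fundamental for seizures, and a 4x ictal
    amplitude ratio.
    """

    n_samples: int = DEFAULT_SEGMENT_LENGTH
    fs: float = DEFAULT_FS
    normal_rhythm_hz: tuple[float, float] = (8.0, 12.0)
    normal_amp: float = 1.0
    ictal_spike_hz: float = 3.0
    ictal_amp: float = 4.0
    noise_sd: float = 0.3
    ar_coeff: float = 0.6

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.fs <= 0:
            raise ValueError("need n_samples >= 2 and fs > 0")
        if self.normal_amp <= 0 or self.ictal_amp <= 0:
            raise ValueError("amplitudes must be positive")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        lo, hi = self.normal_rhythm_hz
        if not 0 < lo <= hi:
            raise ValueError("rhythm band must satisfy 0 < lo <= hi")


def _segment_seed(master_seed: int, cls: str, index: int) -> np.random.SeedSequence:
    # Stable derivation: order of generation never changes a segment.
    return np.random.SeedSequence(master_seed, spawn_key=(CLASSES.index(cls), index))


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    white = rng.normal(0.0, sd * np.sqrt(max(1.0 - phi**2, 1e-12)), size=n)
    out = np.empty(n)
    out[0] = white[0]
    for i in range(1, n):
        out[i] = phi * out[i - 1] + white[i]
    return out


def _normal_waveform(rng: np.random.Generator, p: SynthParams) -> np.ndarray:
    t = np.arange(p.n_samples) / p.fs
    lo, hi = p.normal_rhythm_hz
    n_components = 3
    freqs = rng.uniform(lo, hi, size=n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
    amps = p.normal_amp * rng.uniform(0.5, 1.0, size=n_components)
    x = np.zeros(p.n_samples)
    for f, ph, a in zip(freqs, phases, amps):
        x += a * np.sin(2.0 * np.pi * f * t + ph)
    return x


def _ictal_waveform(rng: np.random.Generator, p: SynthParams) -> np.ndarray:
    """Periodic spike-wave train: Gaussian spike + slow half-sine per cycle."""
    n, fs = p.n_samples, p.fs
    period = fs / p.ictal_spike_hz
    spike_width = period / 20.0  # spike much narrower than the cycle
    t_idx = np.arange(n, dtype=float)
    x = np.zeros(n)
    start = rng.uniform(0.0, period)
    pos = start
    while pos < n + period:
        amp = p.ictal_amp * (1.0 + 0.1 * rng.standard_normal())  # 10% jitter
        x += amp * np.exp(-0.5 * ((t_idx - pos) / spike_width) ** 2)
        # slow half-wave occupying the back 60% of the cycle, opposite sign
        wave_start = pos + 0.25 * period
        wave_len = 0.6 * period
        phase = (t_idx - wave_start) / wave_len
        mask = (phase >= 0.0) & (phase < 1.0)
        x[mask] -= 0.5 * amp * np.sin(np.pi * phase[mask])
        pos += period
    return x


def generate_segment(cls: str, params: SynthParams | None = None, seed: int = 0) -> EEGSegment:
    """Generate one synthetic segment of class ``normal`` or ``ictal``."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
    p = params or SynthParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(CLASSES.index(cls),)))
    if cls == "normal":
        x = _normal_waveform(rng, p)
    else:
        x = _ictal_waveform(rng, p)
    x = x + _ar1_noise(rng, p.n_samples, p.noise_sd, p.ar_coeff)
    return EEGSegment(x, fs=p.fs, segment_id=f"{cls}-{seed}", label=cls)


def generate_dataset(
    n_per_class: int, params: SynthParams | None = None, seed: int = 0
) -> LabeledDataset:
    """Generate a balanced two-class dataset of 2*n_per_class segments."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    p = params or SynthParams()
    segments: list[EEGSegment] = []
    for cls in CLASSES:
        for i in range(n_per_class):
            ss = _segment_seed(seed, cls, i)
            rng = np.random.default_rng(ss)
            if cls == "normal":
                x = _normal_waveform(rng, p)
            else:
                x = _ictal_waveform(rng, p)
            x = x + _ar1_noise(rng, p.n_samples, p.noise_sd, p.ar_coeff)
            segments.append(
                EEGSegment(x, fs=p.fs, segment_id=f"{cls}-{i:03d}", label=cls)
            )
    return LabeledDataset(segments)


def write_dataset(
    dataset: LabeledDataset, out_dir: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write a dataset as Bonn-dialect files plus a path,label manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: list[tuple[str, str]] = []
    for seg in dataset.segments:
        fname = f"{seg.segment_id}.txt"
        write_segment(seg, out / fname)
        rows.append((fname, seg.label))
    manifest_path = out / manifest_name
    write_manifest(rows, manifest_path)
    return manifest_path
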