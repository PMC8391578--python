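"""Signal conditioning for multichannel scalp EEG.

Pipeline order: artifact-interval removal -> integer-factor downsampling
(500 -> 250 Hz by default) -> zero-phase Butterworth band-pass 0.5-48 Hz.
Artifact intervals are an input (device annotations or config); automatic
artifact detection is out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import ANALYSIS_BAND
from .filters import DEFAULT_ORDER, bandpass_sos, filtfilt, lowpass_sos

ClassLabel = str  # one of "AD", "FTD", "CN"


@dataclass
class Recording:
    """A multichannel recording with subject/class provenance.

    samples is a C x T array in microvolts; artifact_intervals are
    [start_s, end_s) spans to be excised before analysis.
    """

    subject_id: str
    class_label: ClassLabel
    fs_hz: float
    channel_names: list[str]
    samples: np.ndarray
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} signal rows but {len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class CleanSegment:
    """A contiguous artifact-free stretch of a recording."""

    subject_id: str
    class_label: ClassLabel
    fs_hz: float
    channel_names: list[str]
    samples: np.ndarray
    start_offset_s: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def _normalize_intervals(
    intervals: list[tuple[float, float]], duration_s: float
) -> list[tuple[float, float]]:
    """Sort, merge and validate artifact spans against the recording length."""
    checked = []
    for start, end in intervals:
        if start >= end:
            raise ValueError(f"empty or inverted artifact interval [{start}, {end})")
        if start < 0 or end > duration_s + 1e-9:
            raise ValueError(
                f"artifact interval [{start}, {end}) outside recording of {duration_s:.3f} s"
            )
        checked.append((float(start), min(float(end), duration_s)))
    checked.sort()
    merged: list[tuple[float, float]] = []
    for start, end in checked:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def remove_artifacts(rec: Recording) -> list[CleanSegment]:
    """Split a recording into maximal artifact-free segments, in temporal order.

    Sample n (time n/fs) is removed iff it falls inside a marked
    [start_s, end_s) span. A fully marked recording yields an empty list.
    """
    intervals = _normalize_intervals(rec.artifact_intervals, rec.duration_s)
    edges = [0]
    for start, end in intervals:
        edges.append(int(round(start * rec.fs_hz)))
        edges.append(int(round(end * rec.fs_hz)))
    edges.append(rec.n_samples)

    segments = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi > lo:
            segments.append(
                CleanSegment(
                    subject_id=rec.subject_id,
                    class_label=rec.class_label,
                    fs_hz=rec.fs_hz,
                    channel_names=list(rec.channel_names),
                    samples=rec.samples[:, lo:hi],
                    start_offset_s=lo / rec.fs_hz,
                )
            )
    return segments


def downsample(seg: CleanSegment, target_fs_hz: float) -> CleanSegment:
    """Decimate to target_fs_hz (integer factor) with zero-phase anti-aliasing.

    The anti-alias filter is an order-8 Butterworth low-pass at 0.8x the new
    Nyquist, applied forward-backward before taking every factor-th sample.
    """
    ratio = seg.fs_hz / target_fs_hz
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"fs {seg.fs_hz} Hz is not an integer multiple of target {target_fs_hz} Hz"
        )
    if factor == 1:
        return replace(seg, samples=seg.samples.copy())
    sos = lowpass_sos(0.8 * target_fs_hz / 2.0, seg.fs_hz)
    filtered = filtfilt(sos, seg.samples)
    return replace(seg, samples=filtered[:, ::factor], fs_hz=float(target_fs_hz))


def butterworth_bandpass(
    seg: CleanSegment,
    low_hz: float = ANALYSIS_BAND[0],
    high_hz: float = ANALYSIS_BAND[1],
    order: int = DEFAULT_ORDER,
) -> CleanSegment:
    """Zero-phase Butterworth band-pass per channel; length is unchanged.

    With the 0.5-48 Hz defaults this removes drift and 50 Hz mains
    interference while keeping the five rhythm bands intact.
    """
    sos = bandpass_sos(low_hz, high_hz, seg.fs_hz, order=order)
    return replace(seg, samples=filtfilt(sos, seg.samples))


def preprocess_recording(
    rec: Recording,
    target_fs_hz: float = 250.0,
    low_hz: float = ANALYSIS_BAND[0],
    high_hz: float = ANALYSIS_BAND[1],
    order: int = DEFAULT_ORDER,
    min_segment_s: float = 0.0,
) -> list[CleanSegment]:
    """Full conditioning chain: artifacts -> downsample -> band-pass.

    Segments shorter than min_segment_s (typically one epoch) are dropped.
    """
    out = []
    for seg in remove_artifacts(rec):
        if seg.duration_s < min_segment_s:
            continue
        seg = downsample(seg, target_fs_hz)
        out.append(butterworth_bandpass(seg, low_hz, high_hz, order=order))
    return out
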