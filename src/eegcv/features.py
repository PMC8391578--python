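"""Epoching and per-channel feature extraction.

Clean segments are cut into overlapping fixed-length epochs (5 s windows
every 2.5 s by default). For every epoch and channel, eight features are
computed: the energies of the five rhythm bands (sum of squared samples of
the zero-phase band-filtered signal) and three time-domain statistics of
the broadband-conditioned signal (mean, population variance, interquartile
range). With C channels the classification table has 8C + 1 columns, the
last being the class label; for the default 17-channel montage that is 137
columns. The subject id is carried out-of-band as grouping metadata and is
never one of the predictors.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, Band
from .filters import DEFAULT_ORDER, bandpass_sos, filtfilt
from .preprocess import CleanSegment

FEATURE_SUFFIXES = ("energy_delta", "energy_theta", "energy_alpha",
                    "energy_beta", "energy_gamma", "mean", "variance", "iqr")
LABEL_COLUMN = "class"
SUBJECT_COLUMN = "subject_id"


@dataclass
class Epoch:
    subject_id: str
    class_label: str
    samples: np.ndarray  # C x L
    fs_hz: float
    start_time_s: float
    duration_s: float
    channel_names: list[str]


def extract_epochs(seg: CleanSegment, duration_s: float, stride_s: float) -> list[Epoch]:
    """Cut a segment into overlapping epochs on a fixed stride grid.

    Epoch k covers [k*stride_s, k*stride_s + duration_s) relative to the
    segment start; the trailing partial window is discarded. A segment
    shorter than one epoch yields an empty list.
    """
    if not 0 < stride_s <= duration_s:
        raise ValueError("need 0 < stride_s <= duration_s")
    win = int(round(duration_s * seg.fs_hz))
    step = int(round(stride_s * seg.fs_hz))
    if step < 1:
        raise ValueError("stride shorter than one sample")
    n = seg.n_samples
    if n < win:
        return []
    count = (n - win) // step + 1
    return [
        Epoch(
            subject_id=seg.subject_id,
            class_label=seg.class_label,
            samples=seg.samples[:, k * step: k * step + win],
            fs_hz=seg.fs_hz,
            start_time_s=seg.start_offset_s + k * step / seg.fs_hz,
            duration_s=duration_s,
            channel_names=list(seg.channel_names),
        )
        for k in range(count)
    ]


def band_energy(x: np.ndarray, band: Band, fs_hz: float, order: int = DEFAULT_ORDER) -> np.ndarray:
    """Energy of one rhythm band: sum of squared band-filtered samples.

    x may be a single channel (length L) or a C x L matrix; returns a
    scalar or length-C vector accordingly, in uV^2 * samples.
    """
    sos = bandpass_sos(band.low_hz, band.high_hz, fs_hz, order=order)
    xf = filtfilt(sos, np.asarray(x, dtype=float))
    return np.sum(xf * xf, axis=-1)


def time_domain_features(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, population variance (divisor L) and IQR (Q3 - Q1) per channel."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least two samples per channel")
    mean = np.mean(x, axis=-1)
    var = np.var(x, axis=-1)  # ddof=0: population variance
    q1, q3 = np.percentile(x, [25, 75], axis=-1)
    return mean, var, q3 - q1


@dataclass
class FeatureTable:
    """Per-epoch feature rows with the class label as the final column.

    ``data`` holds the 8C feature columns plus the label; ``subject_ids``
    is index-aligned grouping metadata kept outside the predictors.
    """

    data: pd.DataFrame
    subject_ids: pd.Series

    def __post_init__(self) -> None:
        if list(self.data.columns)[-1:] != [LABEL_COLUMN] and len(self.data.columns):
            raise ValueError(f"last column must be {LABEL_COLUMN!r}")
        if len(self.subject_ids) != len(self.data):
            raise ValueError("subject_ids misaligned with data")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != LABEL_COLUMN]

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data[LABEL_COLUMN].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.data.loc[mask].reset_index(drop=True),
            self.subject_ids.loc[mask].reset_index(drop=True),
        )

    def restrict_classes(self, classes: tuple[str, ...]) -> "FeatureTable":
        return self.subset(self.data[LABEL_COLUMN].isin(classes).to_numpy())

    def groups(self) -> dict[str, str]:
        """subject id -> class label mapping for grouped validation."""
        pairs = pd.DataFrame({SUBJECT_COLUMN: self.subject_ids, LABEL_COLUMN: self.y})
        return dict(pairs.drop_duplicates().itertuples(index=False))

    # -- CSV round trip ---------------------------------------------------
    def write_csv(self, features_path: str | Path, groups_path: str | Path) -> None:
        self.data.to_csv(features_path, index=False)
        pd.DataFrame({SUBJECT_COLUMN: self.subject_ids}).to_csv(groups_path, index=False)

    @classmethod
    def read_csv(cls, features_path: str | Path, groups_path: str | Path) -> "FeatureTable":
        data = pd.read_csv(features_path)
        groups = pd.read_csv(groups_path)[SUBJECT_COLUMN]
        return cls(data, groups)


def feature_column_names(channel_names: list[str]) -> list[str]:
    return [f"{ch}_{suf}" for ch in channel_names for suf in FEATURE_SUFFIXES]


def epoch_features(epoch: Epoch, bands: tuple[Band, ...] = DEFAULT_BANDS) -> np.ndarray:
    """The 8C feature vector of one epoch, channel-major."""
    energies = np.stack([band_energy(epoch.samples, b, epoch.fs_hz) for b in bands])  # 5 x C
    mean, var, iqr = time_domain_features(epoch.samples)
    per_channel = np.vstack([energies, mean[None], var[None], iqr[None]])  # 8 x C
    return per_channel.T.reshape(-1)


def build_feature_table(epochs: list[Epoch], bands: tuple[Band, ...] = DEFAULT_BANDS) -> FeatureTable:
    """Assemble the classification table: one row per epoch, label last.

    Band filters are applied to each epoch in isolation; for epochs cut
    from a longer clean segment prefer :func:`segment_feature_table`,
    which filters the continuous segment before windowing and so avoids
    edge transients in the low bands.
    """
    if len(bands) != 5:
        raise ValueError("expected the five rhythm bands")
    if not epochs:
        return FeatureTable(pd.DataFrame(columns=[LABEL_COLUMN]),
                            pd.Series([], dtype=object, name=SUBJECT_COLUMN))
    schema = epochs[0].channel_names
    fs = epochs[0].fs_hz
    for e in epochs:
        if e.channel_names != schema or e.fs_hz != fs:
            raise ValueError("epochs have mixed channel schemas or sampling rates")
    rows = np.stack([epoch_features(e, bands) for e in epochs])
    data = pd.DataFrame(rows, columns=feature_column_names(schema))
    data[LABEL_COLUMN] = [e.class_label for e in epochs]
    subjects = pd.Series([e.subject_id for e in epochs], name=SUBJECT_COLUMN)
    return FeatureTable(data, subjects)


def segment_feature_table(
    segments: list[CleanSegment],
    duration_s: float,
    stride_s: float,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> FeatureTable:
    """Feature table with stream-style band filtering.

    Each rhythm filter runs over the whole clean segment once and the
    resulting band signals are windowed on the epoch grid, so an epoch's
    band energy sees the segment's true continuation instead of a
    reflective-padding guess. A zero-phase filter on a 5 s window alone
    leaks substantial broadband energy into delta (the filter's impulse
    response spans several delta cycles); filtering before windowing
    removes that bias. The epoch grid restarts in every segment, so no
    window spans a removed artifact interval.
    """
    if len(bands) != 5:
        raise ValueError("expected the five rhythm bands")
    if not segments:
        return FeatureTable(pd.DataFrame(columns=[LABEL_COLUMN]),
                            pd.Series([], dtype=object, name=SUBJECT_COLUMN))
    schema = segments[0].channel_names
    rows, labels, subjects = [], [], []
    for seg in segments:
        if seg.channel_names != schema:
            raise ValueError("segments have mixed channel schemas")
        win = int(round(duration_s * seg.fs_hz))
        step = int(round(stride_s * seg.fs_hz))
        if seg.n_samples < win:
            continue
        band_sq = {}
        for b in bands:
            sos = bandpass_sos(b.low_hz, b.high_hz, seg.fs_hz)
            xf = filtfilt(sos, seg.samples.astype(float))
            band_sq[b.name] = xf * xf
        count = (seg.n_samples - win) // step + 1
        for k in range(count):
            sl = slice(k * step, k * step + win)
            energies = np.stack([band_sq[b.name][:, sl].sum(axis=-1) for b in bands])
            mean, var, iqr = time_domain_features(seg.samples[:, sl])
            rows.append(np.vstack([energies, mean[None], var[None], iqr[None]]).T.reshape(-1))
            labels.append(seg.class_label)
            subjects.append(seg.subject_id)
    if not rows:
        return FeatureTable(pd.DataFrame(columns=[LABEL_COLUMN]),
                            pd.Series([], dtype=object, name=SUBJECT_COLUMN))
    data = pd.DataFrame(np.stack(rows), columns=feature_column_names(schema))
    data[LABEL_COLUMN] = labels
    return FeatureTable(data, pd.Series(subjects, name=SUBJECT_COLUMN))
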