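"""Minimal EDF (European Data Format) I/O for cohort exchange.

Implements the classic 16-bit EDF layout with 1-second data records: the
256-byte global header, ns x 256 signal headers, then little-endian int16
records. Subject id and class label are stored in the patient-id field as
``<subject_id> class=<label>`` so a cohort round-trips without relying on
the sidecar table. Signals are scaled per channel to the full digital
range, so quantization error is ~1/65000 of the channel's peak amplitude.

Limitations: integer sampling rates only, recordings are truncated to
whole seconds, and EDF+ annotation streams are not written; artifact
intervals travel in a sidecar CSV instead.
"""
from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from .preprocess import Recording

_DIG_MAX = 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(v: float) -> str:
    s = f"{v:.6g}"
    if len(s) > 8:
        s = f"{v:.2e}"
    return s[:8]


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write one recording as a 16-bit EDF file."""
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record (1 s)")
    if n_records * spr != rec.n_samples:
        warnings.warn("recording truncated to whole seconds for EDF export")
    ns = rec.n_channels
    data = np.asarray(rec.samples[:, : n_records * spr], dtype=float)

    # per-channel symmetric physical range; re-parse the 8-char header text
    # so the scale used for quantization matches what a reader will see
    phys_max_txt, gains = [], []
    for ch in range(ns):
        pm = float(np.max(np.abs(data[ch]))) or 1.0
        txt = _fmt_float(pm * 1.0001)  # headroom so no sample clips
        phys_max_txt.append(txt)
        gains.append(float(txt) / _DIG_MAX)
    digital = np.empty_like(data, dtype="<i2")
    for ch in range(ns):
        digital[ch] = np.round(data[ch] / gains[ch]).astype("<i2")

    header = b"".join([
        _ascii("0", 8),
        _ascii(f"{rec.subject_id} class={rec.class_label}", 80),
        _ascii("Startdate 01-JAN-2000 synthetic", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (1 + ns), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii("1", 8),
        _ascii(ns, 4),
    ])
    sig = b"".join([
        b"".join(_ascii(name, 16) for name in rec.channel_names),
        b"".join(_ascii("synthetic", 80) for _ in range(ns)),
        b"".join(_ascii("uV", 8) for _ in range(ns)),
        b"".join(_ascii("-" + t, 8) for t in phys_max_txt),
        b"".join(_ascii(t, 8) for t in phys_max_txt),
        b"".join(_ascii(-_DIG_MAX, 8) for _ in range(ns)),
        b"".join(_ascii(_DIG_MAX, 8) for _ in range(ns)),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii(spr, 8) for _ in range(ns)),
        b"".join(_ascii("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records are interleaved: for each second, each signal's block
        fh.write(np.ascontiguousarray(
            digital.reshape(ns, n_records, spr).transpose(1, 0, 2)).tobytes())


def _read_field(fh, width: int) -> str:
    return fh.read(width).decode("ascii", errors="replace").strip()


def read_edf(path: str | Path) -> Recording:
    """Read a 16-bit EDF file back into a Recording (physical units)."""
    with open(path, "rb") as fh:
        fh.read(8)  # version
        patient = _read_field(fh, 80)
        fh.read(80 + 8 + 8)
        fh.read(8)  # header bytes
        fh.read(44)
        n_records = int(_read_field(fh, 8))
        record_dur = float(_read_field(fh, 8))
        ns = int(_read_field(fh, 4))

        labels = [_read_field(fh, 16) for _ in range(ns)]
        fh.read(80 * ns)  # transducer
        fh.read(8 * ns)   # physical dimension
        phys_min = [float(_read_field(fh, 8)) for _ in range(ns)]
        phys_max = [float(_read_field(fh, 8)) for _ in range(ns)]
        dig_min = [int(float(_read_field(fh, 8))) for _ in range(ns)]
        dig_max = [int(float(_read_field(fh, 8))) for _ in range(ns)]
        fh.read(80 * ns)  # prefiltering
        spr = [int(_read_field(fh, 8)) for _ in range(ns)]
        fh.read(32 * ns)

        if len(set(spr)) != 1:
            raise ValueError("channels with differing sampling rates are unsupported")
        raw = np.frombuffer(fh.read(2 * sum(spr) * n_records), dtype="<i2")

    spr0 = spr[0]
    fs = spr0 / record_dur
    digital = raw.reshape(n_records, ns, spr0).transpose(1, 0, 2).reshape(ns, -1)
    samples = np.empty(digital.shape, dtype=float)
    for ch in range(ns):
        gain = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
        samples[ch] = (digital[ch].astype(float) - dig_min[ch]) * gain + phys_min[ch]

    subject_id, class_label = patient, "unknown"
    parts = patient.split()
    if parts and parts[-1].startswith("class="):
        class_label = parts[-1].split("=", 1)[1]
        subject_id = " ".join(parts[:-1])
    return Recording(
        subject_id=subject_id,
        class_label=class_label,
        fs_hz=fs,
        channel_names=labels,
        samples=samples,
    )


def write_cohort(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write one EDF per subject plus a sidecar subjects.csv; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "subjects.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "class", "duration_s", "fs_hz", "n_channels", "file"])
        for rec in recordings:
            fname = f"{rec.subject_id}.edf"
            write_edf(rec, out / fname)
            w.writerow([rec.subject_id, rec.class_label, rec.duration_s,
                        rec.fs_hz, rec.n_channels, fname])
    return out


def read_cohort(in_dir: str | Path) -> list[Recording]:
    """Read every EDF listed in a cohort directory's subjects.csv."""
    in_dir = Path(in_dir)
    recs = []
    with open(in_dir / "subjects.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            rec = read_edf(in_dir / row["file"])
            rec.subject_id = row["subject_id"]
            rec.class_label = row["class"]
            recs.append(rec)
    return recs
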