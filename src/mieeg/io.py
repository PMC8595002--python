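"""Readers and writers: delimited trial dumps, EDF, feature tables.

The delimited dump is the primary text interchange format: a commented
header carrying (rate, n_channels, n_samples, channel names) followed by one
CSV row per trial x channel.  EDF support is a minimal self-contained
implementation of the 16-bit European Data Format: one data record per
trial, plus an extra integer-valued "LABEL" signal because EDF has no native
per-record class label (subject codes travel in a JSON sidecar).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    FEATURE_NAMES,
    N_FEATURES,
    VALID_LABELS,
    EEGDataset,
    EEGSegment,
    FeatureMatrix,
    ValidationError,
)

__all__ = ["read_segments", "write_segments",
           "read_feature_table", "write_feature_table"]

_MAGIC = "# mieeg-trials v1"


# ---------------------------------------------------------------------------
# delimited trial dump
# ---------------------------------------------------------------------------

def _write_delimited(dataset: EEGDataset, path: Path) -> None:
    n_samples = dataset.segments[0].n_samples
    for i, seg in enumerate(dataset.segments):
        if seg.n_samples != n_samples:
            raise ValidationError(
                f"segment {i}: {seg.n_samples} samples, expected {n_samples}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"# rate={dataset.rate!r}\n")
        fh.write(f"# n_channels={dataset.n_channels}\n")
        fh.write(f"# n_samples={n_samples}\n")
        fh.write(f"# channels={','.join(dataset.channel_names)}\n")
        cols = ["trial", "subject", "label", "channel"] + [
            f"s{i}" for i in range(n_samples)]
        fh.write(",".join(cols) + "\n")
        for t, seg in enumerate(dataset.segments):
            for c, name in enumerate(seg.channel_names):
                row = seg.samples[c]
                fh.write(f"{t},{seg.subject},{seg.label},{name},")
                fh.write(",".join(f"{v:.17g}" for v in row))
                fh.write("\n")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(dataset.metadata, fh, indent=1, sort_keys=True, default=str)


def _read_delimited(path: Path) -> EEGDataset:
    header: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise ValidationError(f"{path}: not a mieeg trial dump")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("# "):
                fh.seek(pos)
                break
            key, _, val = line[2:].rstrip("\n").partition("=")
            header[key] = val
            pos = fh.tell()
        table = pd.read_csv(fh, float_precision="round_trip")
    rate = float(header["rate"])
    n_channels = int(header["n_channels"])
    n_samples = int(header["n_samples"])
    channels = tuple(header["channels"].split(","))
    sample_cols = [f"s{i}" for i in range(n_samples)]
    segments = []
    for trial, grp in table.groupby("trial", sort=True):
        if len(grp) != n_channels:
            raise ValidationError(
                f"trial {trial}: {len(grp)} channel rows, "
                f"expected {n_channels}")
        grp = grp.set_index("channel").loc[list(channels)]
        label = int(grp["label"].iloc[0])
        if label not in VALID_LABELS:
            raise ValidationError(
                f"trial {trial}: label {label} not in {sorted(VALID_LABELS)}")
        segments.append(EEGSegment(
            samples=grp[sample_cols].to_numpy(dtype=float),
            rate=rate,
            label=label,
            subject=str(grp["subject"].iloc[0]),
            channel_names=channels,
        ))
    metadata = {}
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            metadata = json.load(fh)
    return EEGDataset(segments, metadata)


# ---------------------------------------------------------------------------
# EDF (16-bit European Data Format)
# ---------------------------------------------------------------------------

_LABEL_CHANNEL = "LABEL"


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(dataset: EEGDataset, path: Path) -> None:
    n_trials = len(dataset)
    n_samples = dataset.segments[0].n_samples
    for i, seg in enumerate(dataset.segments):
        if seg.n_samples != n_samples:
            raise ValidationError(
                f"segment {i}: {seg.n_samples} samples, expected {n_samples}")
    duration = n_samples / dataset.rate
    names = list(dataset.channel_names) + [_LABEL_CHANNEL]
    ns = len(names)

    data = np.stack([seg.samples for seg in dataset.segments])  # trials x ch x t
    phys_min = data.min(axis=(0, 2))
    phys_max = data.max(axis=(0, 2))
    # guard flat channels: EDF requires phys_min != phys_max
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    phys_min = np.append(phys_min, 0.0)
    phys_max = np.append(phys_max, 255.0)
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))                      # patient
        fh.write(_edf_field("Startdate X mieeg", 80))            # recording
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(256 * (1 + ns), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_trials, 8))
        fh.write(_edf_field(f"{duration:g}", 8))
        fh.write(_edf_field(ns, 4))
        for n in names:
            fh.write(_edf_field(n, 16))
        for _ in names:
            fh.write(_edf_field("", 80))                         # transducer
        for n in names:
            fh.write(_edf_field("uV" if n != _LABEL_CHANNEL else "", 8))
        for v in phys_min:
            fh.write(_edf_field(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_edf_field(f"{v:.8g}"[:8], 8))
        fh.write(_edf_field(dig_min, 8) * ns)
        fh.write(_edf_field(dig_max, 8) * ns)
        for _ in names:
            fh.write(_edf_field("", 80))                         # prefiltering
        for n in names:
            fh.write(_edf_field(n_samples if n != _LABEL_CHANNEL else 1, 8))
        fh.write(_edf_field("", 32) * ns)

        scale = (phys_max - phys_min) / (dig_max - dig_min)
        offset = phys_min - dig_min * scale
        for seg in dataset.segments:
            for c in range(len(dataset.channel_names)):
                dig = np.round((seg.samples[c] - offset[c]) / scale[c])
                dig = np.clip(dig, dig_min, dig_max).astype("<i2")
                fh.write(dig.tobytes())
            lab = np.round((float(seg.label) - offset[-1]) / scale[-1])
            fh.write(np.array([lab], dtype="<i2").tobytes())

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump({"subjects": dataset.subjects, "rate": dataset.rate,
                   "metadata": dataset.metadata},
                  fh, indent=1, sort_keys=True, default=str)


def _read_edf(path: Path) -> EEGDataset:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise ValidationError(f"{path}: truncated EDF header")
        n_records = int(hdr[236:244].decode("ascii"))
        duration = float(hdr[244:252].decode("ascii"))
        ns = int(hdr[252:256].decode("ascii"))
        sig = fh.read(256 * ns)

        def fields(offset, width):
            base = offset * ns
            return [sig[base + i * width: base + (i + 1) * width]
                    .decode("ascii").strip() for i in range(ns)]

        names = fields(0, 16)
        pos = ns * (16 + 80 + 8)
        phys_min = [float(v) for v in fields(pos // ns, 8)]
        pos += ns * 8
        phys_max = [float(v) for v in fields(pos // ns, 8)]
        pos += ns * 8
        dig_min = [int(v) for v in fields(pos // ns, 8)]
        pos += ns * 8
        dig_max = [int(v) for v in fields(pos // ns, 8)]
        pos += ns * (8 + 80)
        n_per_rec = [int(v) for v in fields(pos // ns, 8)]
        payload = fh.read()

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    subjects, metadata, rate = None, {}, None
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            extra = json.load(fh)
        subjects = extra.get("subjects")
        metadata = extra.get("metadata", {})
        rate = extra.get("rate")

    try:
        label_idx = names.index(_LABEL_CHANNEL)
    except ValueError as exc:
        raise ValidationError(f"{path}: no {_LABEL_CHANNEL} signal") from exc
    eeg_idx = [i for i in range(ns) if i != label_idx]
    if rate is None:
        rate = n_per_rec[eeg_idx[0]] / duration

    scale = [(phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
             for i in range(ns)]
    offset = [phys_min[i] - dig_min[i] * scale[i] for i in range(ns)]
    rec_len = sum(n_per_rec)
    raw = np.frombuffer(payload, dtype="<i2")
    if len(raw) != rec_len * n_records:
        raise ValidationError(f"{path}: payload size mismatch")
    raw = raw.reshape(n_records, rec_len)

    bounds = np.cumsum([0] + n_per_rec)
    segments = []
    channel_names = tuple(names[i] for i in eeg_idx)
    for r in range(n_records):
        chans = []
        for i in eeg_idx:
            dig = raw[r, bounds[i]:bounds[i + 1]].astype(float)
            chans.append(dig * scale[i] + offset[i])
        lab_dig = float(raw[r, bounds[label_idx]])
        label = int(round(lab_dig * scale[label_idx] + offset[label_idx]))
        if label not in VALID_LABELS:
            raise ValidationError(
                f"record {r}: label {label} not in {sorted(VALID_LABELS)}")
        subject = subjects[r] if subjects else "S1"
        segments.append(EEGSegment(
            samples=np.vstack(chans), rate=float(rate), label=label,
            subject=subject, channel_names=channel_names))
    return EEGDataset(segments, metadata)


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def write_segments(dataset: EEGDataset, path, format: str = "delimited"):
    """Write a dataset; ``format`` is ``delimited`` or ``edf``."""
    if not isinstance(dataset, EEGDataset):
        raise ValidationError("write_segments expects an EEGDataset")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        _write_delimited(dataset, path)
    elif format == "edf":
        _write_edf(dataset, path)
    else:
        raise ValidationError(f"unknown format {format!r}")
    return path


def read_segments(path, format: str | None = None) -> EEGDataset:
    """Read a dataset written by :func:`write_segments`.

    ``format`` defaults to sniffing: ``.edf`` suffix means EDF, anything
    else is treated as a delimited dump.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "delimited":
        return _read_delimited(path)
    if format == "edf":
        return _read_edf(path)
    raise ValidationError(f"unknown format {format!r}")


def write_feature_table(matrix: FeatureMatrix, path):
    """Write a feature matrix as CSV: canonical 95 columns + label + subject."""
    if not isinstance(matrix, FeatureMatrix):
        raise ValidationError("write_feature_table expects a FeatureMatrix")
    if matrix.values.shape[1] != N_FEATURES:
        raise ValidationError(
            f"feature matrix must have {N_FEATURES} columns")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(matrix.values, columns=list(FEATURE_NAMES))
    df["label"] = matrix.labels
    df["subject"] = matrix.subject_ids
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path) -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing[:3]}...")
    return FeatureMatrix(
        df[list(FEATURE_NAMES)].to_numpy(dtype=float),
        df["label"].to_numpy(dtype=int),
        [str(s) for s in df["subject"]],
    )
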