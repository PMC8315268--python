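"""Readers and writers for the pipeline's external file formats.

Three formats are handled:

- **Utterance tier tables**: a tab-separated dialect modelled on ELAN tier
  exports (``speaker_id<TAB>onset_ms<TAB>offset_ms<TAB>transcript``), plus an
  optional reader for ELAN's native EAF (XML) format. The TSV dialect is the
  normative interchange format.
- **OpenFace 2.0 landmark CSVs**: ``frame``, ``timestamp``, ``success`` and
  per-landmark coordinate columns (``X_i``/``Y_i`` for the 3-D millimetre
  set, ``x_i``/``y_i`` for the 2-D pixel set). OpenFace writes a space after
  each comma in its header; both dialects are accepted.
- **Tidy epoch tables**: long-format CSV with one row per (utterance, epoch
  frame), the input to the slice models.

Annotations use integer milliseconds throughout; OpenFace timestamps in
seconds are converted to milliseconds at read time so the whole pipeline
shares one time base.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from prespeech.core import LIP_LANDMARKS, AreaTrajectory, FaceTrack, UtteranceRecord
from prespeech.errors import FormatError, ParseError, ValidationError

_TSV_HEADER = ["speaker_id", "onset_ms", "offset_ms", "transcript"]

EPOCH_COLUMNS = [
    "utterance_id",
    "speaker_id",
    "slice_offset_ms",
    "area",
    "missing",
    "word_count",
    "first_word",
    "constraint",
    "utterance_type",
]


# ---------------------------------------------------------------------------
# utterance tiers


def read_utterance_tier(path, dialect: str = "tsv") -> list[UtteranceRecord]:
    """Read an utterance-tier annotation export.

    ``dialect="tsv"`` expects the normative header
    ``speaker_id<TAB>onset_ms<TAB>offset_ms<TAB>transcript``;
    ``dialect="eaf"`` reads ELAN's XML format, taking each tier's
    ``PARTICIPANT`` (or tier id) as the speaker label. Records are returned
    in file order (EAF: sorted by onset), with millisecond fields as
    integers and transcripts verbatim.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "eaf":
        return _read_eaf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> list[UtteranceRecord]:
    records: list[UtteranceRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file: missing header", line=1) from None
        if [h.strip() for h in header] != _TSV_HEADER:
            raise ParseError(
                f"bad header {header!r}; expected {_TSV_HEADER!r}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ParseError(f"expected 4 fields, got {len(row)}", line=lineno)
            speaker, onset_s, offset_s, transcript = row
            try:
                onset, offset = int(onset_s), int(offset_s)
            except ValueError:
                raise ParseError(
                    f"non-integer millisecond field in {row!r}", line=lineno
                ) from None
            try:
                records.append(UtteranceRecord(speaker, onset, offset, transcript))
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
    return records


def _read_eaf(path: Path) -> list[UtteranceRecord]:
    tree = ET.parse(path)
    root = tree.getroot()
    slots: dict[str, int] = {}
    for ts in root.iter("TIME_SLOT"):
        value = ts.get("TIME_VALUE")
        if value is not None:
            slots[ts.get("TIME_SLOT_ID")] = int(value)
    records = []
    for tier in root.iter("TIER"):
        speaker = tier.get("PARTICIPANT") or tier.get("TIER_ID")
        for ann in tier.iter("ALIGNABLE_ANNOTATION"):
            t1 = slots.get(ann.get("TIME_SLOT_REF1"))
            t2 = slots.get(ann.get("TIME_SLOT_REF2"))
            value = ann.findtext("ANNOTATION_VALUE") or ""
            if t1 is None or t2 is None:
                raise FormatError(
                    f"annotation {ann.get('ANNOTATION_ID')!r} references an "
                    "unaligned time slot"
                )
            if value.strip():
                records.append(UtteranceRecord(speaker, t1, t2, value))
    records.sort(key=lambda r: (r.onset_ms, r.speaker_id))
    return records


def write_utterance_tier(records: Iterable[UtteranceRecord], path) -> None:
    """Write records in the normative TSV dialect (lossless round trip)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for r in records:
            writer.writerow([r.speaker_id, r.onset_ms, r.offset_ms, r.transcript])


# ---------------------------------------------------------------------------
# OpenFace landmark CSVs


def read_openface_csv(
    path, speaker_id: str | None = None, coordinate_set: str = "3d_mm", fps: float = 30.0
) -> FaceTrack:
    """Read an OpenFace 2.0 output CSV into a :class:`FaceTrack`.

    ``coordinate_set="3d_mm"`` selects the millimetre ``X_i``/``Y_i``
    columns (the default: lip areas are reported in mm^2);
    ``"2d_pixel"`` selects the camera-frame ``x_i``/``y_i`` columns.
    Frames with ``success == 0`` are retained but flagged unsuccessful.
    """
    if coordinate_set == "3d_mm":
        xf, yf = "X_{}", "Y_{}"
    elif coordinate_set == "2d_pixel":
        xf, yf = "x_{}", "y_{}"
    else:
        raise ValueError(f"unknown coordinate_set {coordinate_set!r}")

    df = pd.read_csv(path)
    # OpenFace emits ", " separated headers; normalize.
    df.columns = [c.strip() for c in df.columns]
    for col in ("frame", "timestamp", "success"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    missing = [
        name
        for i in LIP_LANDMARKS
        for name in (xf.format(i), yf.format(i))
        if name not in df.columns
    ]
    if missing:
        raise FormatError(f"missing lip landmark columns: {', '.join(missing)}")

    frame_raw = df["frame"].to_numpy(dtype=np.int64)
    if frame_raw.size and np.any(np.diff(frame_raw) <= 0):
        raise ValidationError("non-monotonic frame index")
    frame = frame_raw - (frame_raw[0] if frame_raw.size else 0)  # OpenFace counts from 1

    ts = df["timestamp"].to_numpy(dtype=float)
    # OpenFace reports seconds; annotation time base is ms. Detect by the
    # median inter-frame step: ~1/fps => seconds, ~1000/fps => already ms.
    if ts.size > 1 and np.median(np.diff(ts)) < 100.0 / fps:
        ts = ts * 1000.0

    points = {
        i: np.column_stack(
            [df[xf.format(i)].to_numpy(float), df[yf.format(i)].to_numpy(float)]
        )
        for i in LIP_LANDMARKS
    }
    return FaceTrack(
        speaker_id=speaker_id or Path(path).stem,
        fps=fps,
        frame=frame,
        timestamp_ms=ts,
        success=df["success"].to_numpy() != 0,
        points=points,
    )


def write_openface_csv(
    track: FaceTrack, path, coordinate_set: str = "3d_mm", spaced_header: bool = False
) -> None:
    """Write a track in the OpenFace 2.0 CSV layout.

    ``spaced_header=True`` reproduces OpenFace's own ``, ``-separated
    header dialect; parsing is insensitive to the choice.
    """
    xf, yf = ("X_{}", "Y_{}") if coordinate_set == "3d_mm" else ("x_{}", "y_{}")
    data = {
        "frame": track.frame + 1,
        "timestamp": track.timestamp_ms / 1000.0,
        "success": track.success.astype(int),
    }
    for i in LIP_LANDMARKS:
        pts = track.points[i]
        data[xf.format(i)] = pts[:, 0]
        data[yf.format(i)] = pts[:, 1]
    df = pd.DataFrame(data)
    if spaced_header:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(", ".join(df.columns) + "\n")
            df.to_csv(fh, index=False, header=False, lineterminator="\n")
    else:
        df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# tidy epoch tables


def epochs_to_table(
    epochs: Sequence[AreaTrajectory], metadata: Sequence[dict]
) -> pd.DataFrame:
    """Assemble epochs plus per-utterance metadata into the tidy long table.

    One row per (utterance, epoch frame); ``slice_offset_ms`` is the frame's
    signed offset from acoustic onset. All epochs must share a length.
    """
    if len(epochs) != len(metadata):
        raise ValidationError("epochs and metadata lengths differ")
    if not epochs:
        return pd.DataFrame(columns=EPOCH_COLUMNS)
    n = epochs[0].n_frames
    if any(e.n_frames != n for e in epochs):
        raise ValidationError("ragged epochs: all epochs must share a length")
    frames = []
    for epoch, meta in zip(epochs, metadata):
        frames.append(
            pd.DataFrame(
                {
                    "utterance_id": epoch.utterance_id,
                    "speaker_id": meta["speaker_id"],
                    "slice_offset_ms": epoch.frame_offsets_ms(),
                    "area": epoch.areas,
                    "missing": epoch.missing_mask,
                    "word_count": meta["word_count"],
                    "first_word": meta["first_word"],
                    "constraint": meta["constraint"],
                    "utterance_type": meta["utterance_type"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[EPOCH_COLUMNS]


def write_epoch_table(
    epochs: Sequence[AreaTrajectory], metadata: Sequence[dict], path
) -> pd.DataFrame:
    """Write the tidy epoch CSV; returns the table that was written."""
    table = epochs_to_table(epochs, metadata)
    table.to_csv(path, index=False, lineterminator="\n")
    return table


def read_epoch_table(path) -> pd.DataFrame:
    """Read a tidy epoch CSV written by :func:`write_epoch_table`."""
    df = pd.read_csv(
        path,
        dtype={
            "utterance_id": str,
            "speaker_id": str,
            "first_word": str,
            "constraint": str,
            "utterance_type": str,
            "word_count": np.int64,
        },
    )
    missing_cols = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"epoch table missing columns: {', '.join(missing_cols)}")
    df["missing"] = df["missing"].astype(bool)
    return df[EPOCH_COLUMNS]
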