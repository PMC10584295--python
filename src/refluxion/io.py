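"""Data model and text-format I/O for 24-hour pH/impedance studies.

A study is a multichannel intraluminal impedance (MII) recording: six
impedance channels ordered distal to proximal (channels 1-2 distal, 3-6
proximal) plus two pH channels (channel 1 distal, positioned 5 cm above the
upper border of the lower esophageal sphincter; channel 2 proximal).
Patient-marked annotations (meals, supine periods, symptoms) travel in a
sidecar CSV, and event lists (reader marks, detector candidates, model
scores, gold-standard labels) in a second CSV dialect.

Formats are plain text so that studies round-trip bit-exactly:

* study file — TSV; ``#``-prefixed header lines carry study_id,
  sampling_rate_hz, duration_s and metadata; a column header
  ``time_s imp1..imp6 ph1 ph2``; one row per sample, floats serialized
  with full round-trip precision (``%.17g``).
* annotations file — CSV with header ``kind,start_s,end_s,label``.
* events file — CSV with header
  ``onset_s,end_s,proximal_extent,source,score,is_event``; empty ``score``
  (and ``is_event``) fields are allowed.

All times are seconds from recording start; intervals are half-open
``[start_s, end_s)``.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationInterval",
    "EventRecord",
    "ImpedanceStudy",
    "StudyFormatError",
    "SchemaError",
    "ValidationError",
    "EVENT_SOURCES",
    "read_study",
    "write_study",
    "read_annotations",
    "write_annotations",
    "read_events",
    "write_events",
    "merge_intervals",
]

N_IMPEDANCE_CHANNELS = 6
N_PH_CHANNELS = 2

ANNOTATION_KINDS = ("meal", "supine", "symptom")
EVENT_SOURCES = ("reader_A", "reader_B", "reader_C", "software", "model", "gold")

_STUDY_COLUMNS = ["time_s"] + [f"imp{i}" for i in range(1, 7)] + ["ph1", "ph2"]


class StudyFormatError(ValueError):
    """A file does not conform to the study/annotation/event dialect."""


class SchemaError(StudyFormatError):
    """The file parses but has the wrong shape (e.g. channel count)."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


@dataclass(frozen=True)
class AnnotationInterval:
    """A patient-marked interval: a meal, a supine period, or a symptom."""

    kind: str
    start_s: float
    end_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValidationError(
                f"annotation kind {self.kind!r} not in {ANNOTATION_KINDS}"
            )
        if not (self.start_s < self.end_s):
            raise ValidationError(
                f"annotation start_s={self.start_s} must be < end_s={self.end_s}"
            )
        if self.start_s < 0:
            raise ValidationError("annotation start_s must be >= 0")


@dataclass(frozen=True)
class EventRecord:
    """A time-localized reflux event, candidate, or mark with provenance.

    ``score`` is present iff ``source == "model"``.  ``is_event`` carries the
    adjudicated truth for gold records (True = reflux event, False =
    confirmed nonevent); for raw marks and candidates it may be None.
    """

    onset_s: float
    end_s: float
    proximal_extent: int = 1
    source: str = "gold"
    score: Optional[float] = None
    is_event: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (self.onset_s < self.end_s):
            raise ValidationError(
                f"event onset_s={self.onset_s} must be < end_s={self.end_s}"
            )
        if self.onset_s < 0:
            raise ValidationError("event onset_s must be >= 0")
        if not (1 <= int(self.proximal_extent) <= 6):
            raise ValidationError(
                f"proximal_extent must be in 1..6, got {self.proximal_extent}"
            )
        if self.source not in EVENT_SOURCES:
            raise ValidationError(f"unknown event source {self.source!r}")
        if (self.score is not None) != (self.source == "model"):
            raise ValidationError(
                "score must be present iff source == 'model' "
                f"(source={self.source!r}, score={self.score!r})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score must be in [0, 1], got {self.score}")


@dataclass
class ImpedanceStudy:
    """One pH/impedance recording.

    Attributes
    ----------
    study_id : str
        Identifier; also used to guard against patient leakage across splits.
    sampling_rate_hz : float
        Samples per second, shared by all channels.
    impedance : ndarray, shape (6, T)
        Impedance in ohms, channel order distal (row 0) to proximal (row 5).
    ph : ndarray, shape (2, T)
        pH traces; row 0 is the distal sensor used for acid exposure time.
    annotations : list of AnnotationInterval
    metadata : dict
        Must carry ``duration_s``; conventionally also ``on_ppi`` (bool) and
        ``indication`` (str).
    """

    study_id: str
    sampling_rate_hz: float
    impedance: np.ndarray
    ph: np.ndarray
    annotations: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(self.metadata["duration_s"])

    @property
    def n_samples(self) -> int:
        return int(self.impedance.shape[1])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def meals(self) -> list:
        return [a for a in self.annotations if a.kind == "meal"]

    def validate(self) -> "ImpedanceStudy":
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if "duration_s" not in self.metadata:
            raise ValidationError("metadata must carry duration_s")
        imp = np.asarray(self.impedance, dtype=float)
        ph = np.asarray(self.ph, dtype=float)
        if imp.ndim != 2 or imp.shape[0] != N_IMPEDANCE_CHANNELS:
            raise SchemaError(
                f"impedance must have {N_IMPEDANCE_CHANNELS} channels, "
                f"got shape {imp.shape}"
            )
        if ph.ndim != 2 or ph.shape[0] != N_PH_CHANNELS:
            raise SchemaError(
                f"ph must have {N_PH_CHANNELS} channels, got shape {ph.shape}"
            )
        if imp.shape[1] != ph.shape[1]:
            raise ValidationError(
                "impedance and ph must have identical sample counts "
                f"({imp.shape[1]} != {ph.shape[1]})"
            )
        t_expected = int(round(self.duration_s * self.sampling_rate_hz))
        if imp.shape[1] != t_expected:
            raise ValidationError(
                f"sample count {imp.shape[1]} != round(duration_s * rate) = "
                f"{t_expected}"
            )
        if np.any(imp < 0) or not np.all(np.isfinite(imp)):
            raise ValidationError("impedance values must be finite and >= 0")
        if np.any(ph < 0) or np.any(ph > 14) or not np.all(np.isfinite(ph)):
            raise ValidationError("pH values must be finite and in [0, 14]")
        for a in self.annotations:
            if a.end_s > self.duration_s + 1e-9:
                raise ValidationError(
                    f"annotation [{a.start_s}, {a.end_s}) exceeds study "
                    f"duration {self.duration_s}"
                )
        return self


def merge_intervals(intervals: Sequence[tuple]) -> list:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    out: list = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# study file


def _parse_header_value(key: str, raw: str, line_no: int):
    raw = raw.strip()
    try:
        if key in ("sampling_rate_hz", "duration_s"):
            return float(raw)
        if key == "on_ppi":
            return raw.lower() in ("true", "1", "yes")
        return raw
    except ValueError as exc:  # pragma: no cover - float() rarely fails here
        raise StudyFormatError(f"line {line_no}: bad header value {raw!r}") from exc


def read_study(study_path, annotations_path=None) -> ImpedanceStudy:
    """Read a study TSV (and optional sidecar annotations CSV).

    Parsing is locale-independent (decimal point).  Overlapping meal
    annotations are merged with a warning; other invariant violations raise
    :class:`SchemaError` / :class:`ValidationError` naming the offending
    line where possible.
    """
    study_path = Path(study_path)
    header: dict = {}
    data_lines: list = []
    with open(study_path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    col_line_idx = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" not in body:
                raise StudyFormatError(
                    f"{study_path.name} line {i + 1}: malformed header line "
                    f"{line.rstrip()!r} (expected '# key: value')"
                )
            key, _, val = body.partition(":")
            key = key.strip()
            header[key] = _parse_header_value(key, val, i + 1)
        else:
            col_line_idx = i
            break
    if col_line_idx is None:
        raise StudyFormatError(f"{study_path.name}: no column header found")
    for key in ("study_id", "sampling_rate_hz", "duration_s"):
        if key not in header:
            raise StudyFormatError(
                f"{study_path.name}: missing required header field {key!r}"
            )
    columns = lines[col_line_idx].rstrip("\n").split("\t")
    if columns != _STUDY_COLUMNS:
        raise SchemaError(
            f"{study_path.name}: column header {columns} != expected "
            f"{_STUDY_COLUMNS}"
        )
    body = "".join(lines[col_line_idx:])
    try:
        df = pd.read_csv(_stdio.StringIO(body), sep="\t", dtype=float,
                         float_precision="round_trip")
    except ValueError as exc:
        raise StudyFormatError(f"{study_path.name}: non-numeric cell ({exc})") from exc
    bad = df.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise StudyFormatError(
            f"{study_path.name}: non-numeric or missing cell in data row {row}"
        )

    metadata = {k: v for k, v in header.items() if k not in ("study_id", "sampling_rate_hz")}
    annotations: list = []
    if annotations_path is not None:
        annotations = read_annotations(annotations_path)

    study = ImpedanceStudy(
        study_id=str(header["study_id"]),
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        impedance=df[[f"imp{i}" for i in range(1, 7)]].to_numpy().T.copy(),
        ph=df[["ph1", "ph2"]].to_numpy().T.copy(),
        annotations=annotations,
        metadata=metadata,
    )
    return study.validate()


def write_study(study: ImpedanceStudy, study_path, annotations_path=None) -> None:
    """Write a study (validated first) with full round-trip float precision."""
    study.validate()
    study_path = Path(study_path)
    t = study.times
    mat = np.vstack([t, study.impedance, study.ph]).T
    with open(study_path, "w", encoding="utf-8") as fh:
        fh.write(f"# study_id: {study.study_id}\n")
        fh.write(f"# sampling_rate_hz: {study.sampling_rate_hz:.17g}\n")
        fh.write(f"# duration_s: {study.duration_s:.17g}\n")
        for key, val in study.metadata.items():
            if key == "duration_s":
                continue
            fh.write(f"# {key}: {val}\n")
        fh.write("\t".join(_STUDY_COLUMNS) + "\n")
        np.savetxt(fh, mat, fmt="%.17g", delimiter="\t")
    if annotations_path is not None:
        write_annotations(study.annotations, annotations_path)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path) -> list:
    path = Path(path)
    df = pd.read_csv(path, dtype={"kind": str, "label": str}, keep_default_na=False)
    expected = ["kind", "start_s", "end_s", "label"]
    if list(df.columns) != expected:
        raise SchemaError(f"{path.name}: annotation columns {list(df.columns)} != {expected}")
    out: list = []
    meal_rows: list = []
    for i, row in df.iterrows():
        try:
            ann = AnnotationInterval(
                kind=row["kind"],
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                label=str(row["label"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
        if ann.kind == "meal":
            meal_rows.append(ann)
        else:
            out.append(ann)
    # merge overlapping meals, keeping the first non-empty label per group
    meal_rows.sort(key=lambda m: (m.start_s, m.end_s))
    merged_meals: list = []
    for m in meal_rows:
        if merged_meals and m.start_s <= merged_meals[-1].end_s:
            prev = merged_meals[-1]
            merged_meals[-1] = AnnotationInterval(
                "meal", prev.start_s, max(prev.end_s, m.end_s),
                prev.label or m.label)
        else:
            merged_meals.append(m)
    if len(merged_meals) < len(meal_rows):
        warnings.warn(
            f"{path.name}: overlapping meal intervals merged "
            f"({len(meal_rows)} -> {len(merged_meals)})",
            stacklevel=2,
        )
    out.extend(merged_meals)
    out.sort(key=lambda a: (a.start_s, a.end_s, a.kind))
    return out


def write_annotations(annotations: Sequence[AnnotationInterval], path) -> None:
    rows = [
        {"kind": a.kind, "start_s": a.start_s, "end_s": a.end_s, "label": a.label}
        for a in sorted(annotations, key=lambda a: (a.start_s, a.end_s, a.kind))
    ]
    pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "label"]).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# events


def read_events(path) -> list:
    """Read an events CSV; records are returned sorted by onset."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"source": str}, keep_default_na=False, na_values=[""])
    expected = ["onset_s", "end_s", "proximal_extent", "source", "score", "is_event"]
    if list(df.columns) != expected:
        raise SchemaError(f"{path.name}: event columns {list(df.columns)} != {expected}")
    out: list = []
    for i, row in df.iterrows():
        score = row["score"]
        score = None if pd.isna(score) else float(score)
        is_event = row["is_event"]
        if pd.isna(is_event):
            is_event = None
        elif isinstance(is_event, str):
            is_event = is_event.strip().lower() in ("true", "1", "yes")
        else:
            is_event = bool(is_event)
        try:
            rec = EventRecord(
                onset_s=float(row["onset_s"]),
                end_s=float(row["end_s"]),
                proximal_extent=int(row["proximal_extent"]),
                source=row["source"],
                score=score,
                is_event=is_event,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
        out.append(rec)
    out.sort(key=lambda e: (e.onset_s, e.end_s))
    return out


def write_events(events: Sequence[EventRecord], path) -> None:
    rows = []
    for e in sorted(events, key=lambda e: (e.onset_s, e.end_s)):
        rows.append(
            {
                "onset_s": e.onset_s,
                "end_s": e.end_s,
                "proximal_extent": e.proximal_extent,
                "source": e.source,
                "score": "" if e.score is None else f"{e.score:.17g}",
                "is_event": "" if e.is_event is None else e.is_event,
            }
        )
    pd.DataFrame(
        rows,
        columns=["onset_s", "end_s", "proximal_extent", "source", "score", "is_event"],
    ).to_csv(path, index=False, float_format="%.17g")
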