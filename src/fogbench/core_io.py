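"""Domain types and readers/writers for the competition CSV dialects.

The benchmark datasets come in two labeled dialects — ``tdcsfog`` (lab
protocol, 128 Hz, acceleration already in m/s^2) and ``defog`` (home
protocol, 100 Hz, with per-sample ``Valid`` and ``Task`` masks) — plus an
unlabeled ``daily`` dialect for week-long 24/7 recordings.  All sample
intervals in this package are 0-based and half-open ``[start, end)``.

Acceleration is normalized to m/s^2 in memory.  Dialects whose files are
in units of g are converted on read (and back on write) with a configurable
standard-gravity constant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, FormatError, SchemaError, ValidationError

STANDARD_GRAVITY = 9.80665

FOG_CLASSES = ("start_hesitation", "turn", "walking")

#: CSV column name per FOG class, in submission/file order.
CLASS_COLUMNS = {
    "start_hesitation": "StartHesitation",
    "turn": "Turn",
    "walking": "Walking",
}

ACC_COLUMNS = ("AccV", "AccML", "AccAP")


class Dialect(str, Enum):
    tdcsfog = "tdcsfog"
    defog = "defog"
    daily = "daily"


@dataclass(frozen=True)
class DialectSpec:
    """Declarative schema for one CSV dialect.

    ``time_is_seconds`` selects whether the Time column holds seconds or a
    sample index; either way it must advance uniformly and is converted to a
    sample index on load.
    """

    name: str
    sampling_rate: float
    units_in: str  # "m_per_s2" | "g"
    time_is_seconds: bool = False
    has_valid_task: bool = False
    has_labels: bool = True
    g_constant: float = STANDARD_GRAVITY

    def required_columns(self) -> tuple[str, ...]:
        cols = ["Time", *ACC_COLUMNS]
        if self.has_labels:
            cols += list(CLASS_COLUMNS.values())
        if self.has_valid_task:
            cols += ["Valid", "Task"]
        return tuple(cols)

    def optional_columns(self) -> tuple[str, ...]:
        # Notype carries FOG-of-unknown-class samples; present only when any.
        return ("Notype",) if self.has_labels else ()


DEFAULT_DIALECTS: dict[Dialect, DialectSpec] = {
    Dialect.tdcsfog: DialectSpec("tdcsfog", 128.0, "m_per_s2"),
    Dialect.defog: DialectSpec("defog", 100.0, "g", has_valid_task=True),
    Dialect.daily: DialectSpec("daily", 100.0, "g", has_labels=False),
}


def dialect_spec(dialect: Dialect | str, **overrides) -> DialectSpec:
    spec = DEFAULT_DIALECTS[Dialect(dialect)]
    return replace(spec, **overrides) if overrides else spec


def load_dialect_config(path) -> dict[Dialect, DialectSpec]:
    """Read dialect overrides from a YAML mapping {dialect: {field: value}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(DEFAULT_DIALECTS)
    for name, overrides in raw.items():
        d = Dialect(name)
        out[d] = replace(DEFAULT_DIALECTS[d], **(overrides or {}))
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """One sensor session: uniform-rate 3-axis lower-back acceleration.

    ``acc`` is an (N, 3) float array ordered (vertical, mediolateral,
    anteroposterior), in m/s^2 regardless of the file's native units.
    """

    subject_id: str
    session_id: str
    dialect: Dialect
    sampling_rate: float
    acc: np.ndarray
    start_clock: Optional[datetime] = None
    units_in: str = "m_per_s2"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3 or self.acc.shape[0] < 1:
            raise ValidationError("acc must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(self.acc)):
            raise ValidationError("acceleration values must be finite")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.dialect == Dialect.daily and self.start_clock is None:
            raise ValidationError("daily recordings require start_clock")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class LabelSeries:
    """Per-sample ground truth: one boolean channel per FOG class.

    ``notype`` marks samples known to be FOG but of unknown class; at most
    one of the four FOG channels is true per sample.  ``valid`` and ``task``
    are the evaluation masks of the defog dialect (all-true elsewhere).
    """

    start_hesitation: np.ndarray
    turn: np.ndarray
    walking: np.ndarray
    notype: np.ndarray
    valid: np.ndarray
    task: np.ndarray

    def __post_init__(self):
        arrs = [self.start_hesitation, self.turn, self.walking, self.notype,
                self.valid, self.task]
        n = len(arrs[0])
        for name in ("start_hesitation", "turn", "walking", "notype", "valid", "task"):
            a = np.asarray(getattr(self, name), dtype=bool)
            if a.shape != (n,):
                raise AlignmentError(f"label channel {name!r} length mismatch")
            setattr(self, name, a)
        stacked = (self.start_hesitation.astype(int) + self.turn.astype(int)
                   + self.walking.astype(int) + self.notype.astype(int))
        if stacked.max(initial=0) > 1:
            raise ValidationError("FOG class channels must be mutually exclusive")

    @classmethod
    def all_false(cls, n: int) -> "LabelSeries":
        z = np.zeros(n, dtype=bool)
        t = np.ones(n, dtype=bool)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), t.copy(), t.copy())

    def __len__(self) -> int:
        return len(self.turn)

    @property
    def any_fog(self) -> np.ndarray:
        """Binary all-FOG indicator: any class or notype."""
        return self.start_hesitation | self.turn | self.walking | self.notype

    def class_channel(self, fog_class: str) -> np.ndarray:
        if fog_class == "any":
            return self.any_fog
        return getattr(self, fog_class)


@dataclass
class ScoreSeries:
    """Per-sample real-valued detector confidences, one channel per class."""

    start_hesitation: np.ndarray
    turn: np.ndarray
    walking: np.ndarray

    def __post_init__(self):
        n = len(np.asarray(self.start_hesitation))
        for name in FOG_CLASSES:
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (n,):
                raise AlignmentError(f"score channel {name!r} length mismatch")
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"score channel {name!r} contains non-finite values")
            setattr(self, name, a)

    def __len__(self) -> int:
        return len(self.turn)

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.start_hesitation, self.turn, self.walking])

    @property
    def max_over_classes(self) -> np.ndarray:
        return self.as_matrix().max(axis=1)

    def class_channel(self, fog_class: str) -> np.ndarray:
        return getattr(self, fog_class)


@dataclass(frozen=True)
class Episode:
    """One contiguous FOG event over half-open sample interval [start, end)."""

    fog_class: str  # one of FOG_CLASSES or "any"
    start: int
    end: int
    sampling_rate: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError("episode requires 0 <= start < end")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class WalkingBouts:
    """Sorted, non-overlapping half-open sample intervals of detected gait."""

    intervals: list[tuple[int, int]]

    def __post_init__(self):
        iv = sorted((int(a), int(b)) for a, b in self.intervals)
        for (a, b) in iv:
            if not 0 <= a < b:
                raise ValidationError("bout intervals must satisfy 0 <= start < end")
        for (_, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValidationError("bout intervals must not overlap")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def membership(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for a, b in self.intervals:
            mask[a:min(b, n)] = True
        return mask


def make_mask(labels: LabelSeries, bouts: Optional[WalkingBouts] = None,
              pad_s: float = 0.0, sampling_rate: Optional[float] = None) -> np.ndarray:
    """Evaluation mask: valid AND task (AND padded-bout membership if given).

    Only samples labeled both Valid and Task are scored; daily-living
    analyses additionally restrict to walking bouts padded by ``pad_s``.
    """
    mask = labels.valid & labels.task
    if bouts is not None:
        if pad_s and sampling_rate is None:
            raise ValidationError("pad_s > 0 requires sampling_rate")
        from .daily import expand_bouts  # local import to avoid a cycle
        bout_mask = expand_bouts(bouts, pad_s=pad_s, n=len(labels),
                                 sampling_rate=sampling_rate or 1.0)
        if len(bout_mask) != len(mask):
            raise AlignmentError("bout mask length mismatch")
        mask = mask & bout_mask
    return mask


# ---------------------------------------------------------------------------
# Session CSV I/O
# ---------------------------------------------------------------------------


def _check_columns(columns: Sequence[str], spec: DialectSpec) -> None:
    required = spec.required_columns()
    got = list(columns)
    for col in required:
        if col not in got:
            raise SchemaError(f"missing mandatory column {col!r} for dialect {spec.name!r}")
    allowed = set(required) | set(spec.optional_columns())
    for col in got:
        if col not in allowed:
            raise SchemaError(f"unexpected column {col!r} for dialect {spec.name!r}")


def _time_to_index(time: np.ndarray, spec: DialectSpec) -> None:
    """Validate the time column advances uniformly by one sample."""
    if len(time) > 1:
        step = np.diff(time.astype(float))
        expected = (1.0 / spec.sampling_rate) if spec.time_is_seconds else 1.0
        if not np.allclose(step, expected, rtol=1e-6, atol=1e-9):
            raise FormatError("non-uniform time index")


def read_recording(path, dialect: Dialect | str,
                   spec: Optional[DialectSpec] = None,
                   subject_id: str = "", session_id: str = "",
                   start_clock: Optional[datetime] = None,
                   ) -> tuple[Recording, LabelSeries]:
    """Read one session CSV, returning an aligned (Recording, LabelSeries).

    For unlabeled dialects the LabelSeries is all-false with all-true masks.
    """
    dialect = Dialect(dialect)
    spec = spec or dialect_spec(dialect)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc
    if len(df) == 0:
        raise FormatError(f"file has a header but no samples: {path}")
    _check_columns(df.columns, spec)
    _time_to_index(df["Time"].to_numpy(), spec)

    acc = df[list(ACC_COLUMNS)].to_numpy(dtype=float)
    if spec.units_in == "g":
        acc = acc * spec.g_constant
    elif spec.units_in != "m_per_s2":
        raise ValidationError(f"unknown units_in {spec.units_in!r}")

    n = len(df)
    if spec.has_labels:
        def col(name):
            return df[name].to_numpy(dtype=float).astype(bool) if name in df else np.zeros(n, bool)
        labels = LabelSeries(
            start_hesitation=col("StartHesitation"),
            turn=col("Turn"),
            walking=col("Walking"),
            notype=col("Notype"),
            valid=(df["Valid"].to_numpy(dtype=float).astype(bool)
                   if spec.has_valid_task else np.ones(n, bool)),
            task=(df["Task"].to_numpy(dtype=float).astype(bool)
                  if spec.has_valid_task else np.ones(n, bool)),
        )
    else:
        labels = LabelSeries.all_false(n)

    rec = Recording(
        subject_id=subject_id or str(path),
        session_id=session_id or str(path),
        dialect=dialect,
        sampling_rate=spec.sampling_rate,
        acc=acc,
        start_clock=start_clock,
        units_in=spec.units_in,
        provenance={"path": str(path), "g_constant": spec.g_constant},
    )
    return rec, labels


def write_recording(recording: Recording, labels: LabelSeries, path,
                    spec: Optional[DialectSpec] = None) -> None:
    """Write a session back to its dialect CSV (inverse of read_recording)."""
    spec = spec or dialect_spec(recording.dialect)
    if len(labels) != recording.n_samples:
        raise AlignmentError("labels/recording length mismatch")
    acc = recording.acc
    if spec.units_in == "g":
        acc = acc / spec.g_constant
    out = {"Time": np.arange(recording.n_samples)
           if not spec.time_is_seconds
           else np.arange(recording.n_samples) / spec.sampling_rate}
    for name, a in zip(ACC_COLUMNS, acc.T):
        out[name] = a
    if spec.has_labels:
        out["StartHesitation"] = labels.start_hesitation.astype(int)
        out["Turn"] = labels.turn.astype(int)
        out["Walking"] = labels.walking.astype(int)
        if labels.notype.any():
            out["Notype"] = labels.notype.astype(int)
    if spec.has_valid_task:
        out["Valid"] = labels.valid.astype(int)
        out["Task"] = labels.task.astype(int)
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Submission I/O
# ---------------------------------------------------------------------------

SUBMISSION_COLUMNS = ("Id", "StartHesitation", "Turn", "Walking")


def write_submission(scores: Mapping[str, ScoreSeries], path) -> None:
    """Write per-sample class confidences, one row per (session, sample).

    Row order is session order then sample order; Id is "<session>_<sample>".
    """
    frames = []
    for session_id, series in scores.items():
        m = series.as_matrix()
        if not np.all(np.isfinite(m)):
            raise ValidationError(f"NaN/inf confidence in session {session_id!r}")
        frames.append(pd.DataFrame({
            "Id": [f"{session_id}_{i}" for i in range(len(series))],
            "StartHesitation": series.start_hesitation,
            "Turn": series.turn,
            "Walking": series.walking,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=list(SUBMISSION_COLUMNS)))
    if df["Id"].duplicated().any():
        dup = df.loc[df["Id"].duplicated(), "Id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r}")
    # repr-precision floats so read(write(x)) is value-exact
    with open(path, "w") as fh:
        fh.write(",".join(SUBMISSION_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.Id},{row.StartHesitation!r},{row.Turn!r},{row.Walking!r}\n")


def read_submission(path) -> dict[str, ScoreSeries]:
    """Read a submission CSV back into per-session ScoreSeries."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty submission file: {path}") from exc
    for col in SUBMISSION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"submission missing column {col!r}")
    if df["Id"].duplicated().any():
        raise FormatError("duplicate sample ids in submission")
    if len(df) == 0:
        return {}
    ids = df["Id"].astype(str)
    split = ids.str.rsplit("_", n=1)
    sessions = split.str[0]
    sample_idx = split.str[1].astype(int)
    if df[["StartHesitation", "Turn", "Walking"]].isna().to_numpy().any():
        raise ValidationError("NaN confidence in submission")
    out: dict[str, ScoreSeries] = {}
    for session in sessions.unique():
        sel = sessions == session
        sub = df.loc[sel].iloc[np.argsort(sample_idx[sel].to_numpy(), kind="stable")]
        out[session] = ScoreSeries(
            start_hesitation=sub["StartHesitation"].to_numpy(float),
            turn=sub["Turn"].to_numpy(float),
            walking=sub["Walking"].to_numpy(float),
        )
    return out
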