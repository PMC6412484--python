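"""Domain types and file I/O for bilateral gyro / sEMG recordings.

A recording session holds one uniformly sampled :class:`SignalTrace` per
(side, muscle, channel) key — e.g. the z-axis angular velocity of the right
shank device mounted over the tibialis anterior, plus the raw sEMG of that
muscle — together with interval annotations (the ground-truth statement of
where regular gait, shuffling / trembling freezing episodes and rest lie).

File dialect: comma-delimited UTF-8 text with one header row.  Trace files
carry a time column ``t_s`` (seconds) followed by one column per trace named
``<side>_<muscle>_<channel>``; annotation files carry ``start_s,end_s,label``.
Floats are written with 17 significant digits so that write -> read is an
exact round trip.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FormatError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "Channel",
    "Side",
    "Muscle",
    "SignalTrace",
    "Interval",
    "IntervalAnnotationSet",
    "RecordingSession",
    "normalize_abs_max",
    "read_trace_file",
    "write_trace_file",
    "read_annotation_file",
    "write_annotation_file",
    "ANNOTATION_LABELS",
    "FOG_LABELS",
]


class Channel(str, enum.Enum):
    GYRO_Z = "gyro_z"
    SEMG_RAW = "semg_raw"
    SEMG_ENVELOPE = "semg_envelope"
    SEMG_TYPE = "semg_type"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Muscle(str, enum.Enum):
    TA = "TA"
    GC = "GC"
    NONE = "none"


#: Closed annotation vocabulary.
ANNOTATION_LABELS = ("regular_gait", "shuffling_fog", "trembling_fog", "rest", "turning")
#: Labels that denote a freezing-of-gait state.
FOG_LABELS = ("shuffling_fog", "trembling_fog")

@dataclass
class SignalTrace:
    """One uniformly sampled channel.

    Parameters
    ----------
    values
        Sample values in ``units``; converted to a float64 array.
    fs
        Sampling rate in Hz, strictly positive.
    channel, side, muscle
        Identity of the trace within a session.
    units
        Free-form unit string ("dps", "V", "normalized", ...).
    t0
        Time of the first sample in seconds.
    normalized
        True only if ``max(|values|)`` is exactly 1 (set by
        :func:`normalize_abs_max`).
    """

    values: np.ndarray
    fs: float
    channel: Channel
    side: Side = Side.RIGHT
    muscle: Muscle = Muscle.NONE
    units: str = ""
    t0: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.channel = Channel(self.channel)
        self.side = Side(self.side)
        self.muscle = Muscle(self.muscle)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError("trace values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("trace contains NaN or infinite samples")
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.channel is Channel.SEMG_ENVELOPE:
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValidationError("sEMG envelope values must lie in [0, 1]")
        if self.normalized and np.max(np.abs(self.values)) != 1.0:
            raise ValidationError(
                "a trace flagged normalized must have max(|values|) == 1"
            )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (must be inside the domain)."""
        i = int(round((t - self.t0) * self.fs))
        if i < 0 or i >= self.n:
            raise ValidationError(f"time {t} s outside trace domain")
        return i

    def key(self) -> tuple[Side, Muscle, Channel]:
        return (self.side, self.muscle, self.channel)

    def column_name(self) -> str:
        return f"{self.side.value}_{self.muscle.value}_{self.channel.value}"

    def slice_time(self, start_s: float, end_s: float) -> "SignalTrace":
        """Sub-trace covering ``[start_s, end_s)``."""
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.fs - 1e-9)))
        i1 = min(self.n, int(np.ceil((end_s - self.t0) * self.fs - 1e-9)))
        if i1 <= i0:
            raise ValidationError(f"empty slice [{start_s}, {end_s})")
        return replace(
            self,
            values=self.values[i0:i1].copy(),
            t0=self.t0 + i0 / self.fs,
            normalized=False,
        )


def normalize_abs_max(trace: SignalTrace) -> SignalTrace:
    """Rescale a trace by its absolute maximum so that max(|values|) == 1.

    The sign pattern is preserved; the result carries ``normalized=True`` and
    unit string "normalized".  All-zero traces are rejected: the rescaling is
    undefined and downstream threshold comparisons would be meaningless.
    """
    m = float(np.max(np.abs(trace.values)))
    if m == 0.0:
        raise DegenerateInputError("cannot normalize an all-zero trace")
    return replace(
        trace, values=trace.values / m, units="normalized", normalized=True
    )


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"interval start {self.start_s} must precede end {self.end_s}"
            )
        if self.label not in ANNOTATION_LABELS:
            raise ValidationError(
                f"unknown annotation label {self.label!r}; "
                f"expected one of {ANNOTATION_LABELS}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class IntervalAnnotationSet:
    """Sorted, non-overlapping labelled intervals (the reference statement)."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s - 1e-12:
                raise ValidationError(
                    f"annotation intervals overlap: {a} and {b}"
                )
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def label_at(self, t: float) -> str | None:
        """Label of the interval containing time ``t``, or None."""
        for iv in self.intervals:
            if iv.contains(t):
                return iv.label
        return None

    def with_label(self, *labels: str) -> "IntervalAnnotationSet":
        return IntervalAnnotationSet(
            [iv for iv in self.intervals if iv.label in labels]
        )


@dataclass
class RecordingSession:
    """The bilateral, multi-muscle set of traces plus annotations."""

    traces: dict[tuple[Side, Muscle, Channel], SignalTrace] = field(
        default_factory=dict
    )
    annotations: IntervalAnnotationSet = field(default_factory=IntervalAnnotationSet)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fs = None
        n = None
        for key, tr in self.traces.items():
            if key != tr.key():
                raise ValidationError(f"trace stored under wrong key {key}")
            if fs is None:
                fs, n = tr.fs, tr.n
            elif tr.fs != fs or tr.n != n:
                raise ValidationError(
                    "all traces in a session must share fs and length"
                )

    @property
    def fs(self) -> float:
        return next(iter(self.traces.values())).fs

    @property
    def n(self) -> int:
        return next(iter(self.traces.values())).n

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def add(self, trace: SignalTrace) -> None:
        key = trace.key()
        if key in self.traces:
            raise ValidationError(f"duplicate trace for key {key}")
        if self.traces:
            first = next(iter(self.traces.values()))
            if trace.fs != first.fs or trace.n != first.n:
                raise ValidationError(
                    "all traces in a session must share fs and length"
                )
        self.traces[key] = trace

    def get(self, side: Side, muscle: Muscle, channel: Channel) -> SignalTrace:
        key = (Side(side), Muscle(muscle), Channel(channel))
        if key not in self.traces:
            raise ValidationError(f"session has no trace for {key}")
        return self.traces[key]

    def has(self, side: Side, muscle: Muscle, channel: Channel) -> bool:
        return (Side(side), Muscle(muscle), Channel(channel)) in self.traces

    def sides(self) -> list[Side]:
        return sorted({k[0] for k in self.traces}, key=lambda s: s.value)


def _parse_column(name: str) -> tuple[Side, Muscle, Channel]:
    parts = name.split("_", 2)
    if len(parts) != 3:
        raise SchemaError(
            f"column {name!r} does not match '<side>_<muscle>_<channel>'"
        )
    side_s, muscle_s, channel_s = parts
    try:
        return (Side(side_s), Muscle(muscle_s), Channel(channel_s))
    except ValueError as exc:
        raise SchemaError(f"column {name!r}: {exc}") from exc


def read_trace_file(
    path,
    schema: Mapping[str, tuple] | None = None,
    fs: float | None = None,
    target_fs: float | None = None,
) -> RecordingSession:
    """Read a delimited trace file into a :class:`RecordingSession`.

    Parameters
    ----------
    path
        CSV file with a ``t_s`` time column (or no time column if ``fs`` is
        given) and one column per trace.
    schema
        Optional mapping from column name to ``(side, muscle, channel)``;
        columns not in the mapping are parsed from the default
        ``<side>_<muscle>_<channel>`` naming.
    fs
        Sampling rate to assume when the file has no ``t_s`` column.
    target_fs
        If given, every channel is resampled (linear interpolation) onto a
        uniform grid at this rate at load time.
    """
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# fogsense-meta:"):
                try:
                    meta = json.loads(line.split(":", 1)[1])
                except json.JSONDecodeError as exc:
                    raise FormatError(f"broken meta line in {path}: {exc}")
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if len(df.columns) != len(set(df.columns)):
        raise SchemaError(f"duplicate column names in {path}")
    if df.isna().any().any():
        bad = int(np.argmax(df.isna().any(axis=1).to_numpy()))
        raise FormatError(f"NaN cell in {path} at data row {bad}")
    if df.shape[0] < 1:
        raise FormatError(f"{path} contains no data rows")

    if "t_s" in df.columns:
        t = df["t_s"].to_numpy(dtype=float)
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise FormatError(f"non-monotone time column in {path}")
            step = np.median(dt)
            if np.max(np.abs(dt - step)) > 1e-6 * max(step, 1e-12):
                raise FormatError(f"non-uniform time grid in {path}")
            file_fs = 1.0 / step
            # snap away the float dust of 1/median(diff)
            if abs(file_fs - round(file_fs)) < 1e-6 * file_fs:
                file_fs = float(round(file_fs))
        else:
            if fs is None:
                raise FormatError("single-row file needs an explicit fs")
            file_fs = fs
        t0 = float(t[0])
        data_cols = [c for c in df.columns if c != "t_s"]
    else:
        if fs is None:
            raise SchemaError(f"{path} has no 't_s' column and no fs was given")
        file_fs = float(fs)
        t0 = 0.0
        t = np.arange(df.shape[0]) / file_fs
        data_cols = list(df.columns)

    if not data_cols:
        raise SchemaError(f"{path} contains no signal columns")

    session = RecordingSession(
        meta={**meta, "source": str(path), "column_order": data_cols}
    )
    for col in data_cols:
        if schema is not None and col in schema:
            side, muscle, channel = schema[col]
            side, muscle, channel = Side(side), Muscle(muscle), Channel(channel)
        else:
            side, muscle, channel = _parse_column(col)
        values = df[col].to_numpy(dtype=float)
        out_fs, out_t0 = file_fs, t0
        if target_fs is not None and abs(target_fs - file_fs) > 1e-9:
            n_new = max(2, int(round(values.size * target_fs / file_fs)))
            t_new = t0 + np.arange(n_new) / target_fs
            values = np.interp(t_new, t, values)
            out_fs, out_t0 = float(target_fs), t0
        session.add(
            SignalTrace(
                values=values,
                fs=out_fs,
                channel=channel,
                side=side,
                muscle=muscle,
                t0=out_t0,
            )
        )
    return session


def write_trace_file(session: RecordingSession, path) -> None:
    """Write all session traces to one CSV (``t_s`` + one column per trace)."""
    if not session.traces:
        raise ValidationError("cannot write a session with no traces")
    first = next(iter(session.traces.values()))
    data = {"t_s": first.times()}
    order = session.meta.get("column_order")
    traces = list(session.traces.values())
    if order:
        by_name = {tr.column_name(): tr for tr in traces}
        traces = [by_name[c] for c in order if c in by_name] + [
            tr for tr in traces if tr.column_name() not in order
        ]
    for tr in traces:
        data[tr.column_name()] = tr.values
    meta = {
        k: v for k, v in session.meta.items()
        if k not in ("source", "column_order")
        and isinstance(v, (str, int, float, bool))
    }
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# fogsense-meta: {json.dumps(meta, sort_keys=True)}\n")
        # pandas' default float formatting is the shortest exact repr, which
        # guarantees a bit-faithful round trip
        pd.DataFrame(data).to_csv(fh, index=False)


def read_annotation_file(path) -> IntervalAnnotationSet:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"annotation file {path} must have columns {sorted(required)}"
        )
    if df[["start_s", "end_s"]].isna().any().any():
        raise FormatError(f"NaN cell in annotation file {path}")
    intervals = [
        Interval(float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples(index=False)
    ]
    return IntervalAnnotationSet(intervals)


def write_annotation_file(annotations: IntervalAnnotationSet, path) -> None:
    pd.DataFrame(
        [(iv.start_s, iv.end_s, iv.label) for iv in annotations],
        columns=["start_s", "end_s", "label"],
    ).to_csv(path, index=False)


def gyro_norm_constant(session: RecordingSession, side: Side, muscle: Muscle) -> float:
    """Session normalization constant for one gyro channel.

    The absolute maximum of the raw angular velocity over the whole
    recording.  If the session carries a full-scale reference
    (``meta['gyro_full_scale_dps']``) and the recorded maximum stays below
    20% of it — i.e. the recording contains no locomotion at all, only
    sensor noise — the reference is used instead, so rest-only recordings
    are not blown up to full scale.
    """
    raw = session.get(side, muscle, Channel.GYRO_Z)
    m = float(np.max(np.abs(raw.values)))
    ref = float(session.meta.get("gyro_full_scale_dps", 0.0))
    if ref > 0 and m < 0.2 * ref:
        m = ref
    if m == 0.0:
        raise DegenerateInputError("all-zero gyro trace cannot be normalized")
    return m


def iter_devices(session: RecordingSession) -> Iterable[tuple[Side, Muscle]]:
    """(side, muscle) pairs that have both a gyro and a raw sEMG trace."""
    for side, muscle, channel in sorted(
        session.traces, key=lambda k: (k[0].value, k[1].value, k[2].value)
    ):
        if channel is Channel.GYRO_Z and session.has(side, muscle, Channel.SEMG_RAW):
            yield (side, muscle)
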