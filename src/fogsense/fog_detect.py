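"""Step-window segmentation and the R index for freezing-of-gait detection.

The detector operates on the normalized, moving-averaged angular velocity
(gyro-bar) and its absolute value (ABS).  Whenever ABS rises above the
threshold T1 a step (or step attempt) window opens; it closes when ABS falls
back below T1.  Windows whose gyro-bar minimum dips at or below the negative
threshold T2 are the stance halves of regular steps and are skipped (no R).
For every remaining window the index

    R = max(ABS in window) / sEMG envelope at the time of that maximum

separates vigorous, low-effort regular swings (high R) from shuffled or
attempted steps where weak rotation coincides with substantial muscle
activity (low R).  R at or above the demarcation level (3) labels the window
regular, below it FOG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ContractViolation, ValidationError
from .signal_model import (
    Channel,
    FOG_LABELS,
    IntervalAnnotationSet,
    SignalTrace,
)

__all__ = [
    "DetectorConfig",
    "StepWindow",
    "StepClassification",
    "FogEpisode",
    "ConfusionCounts",
    "abs_trace",
    "detect_step_windows",
    "compute_R",
    "classify_windows",
    "aggregate_episodes",
    "evaluate_step_level",
    "StreamingDetector",
]

LABEL_REGULAR = "regular"
LABEL_FOG = "fog"
LABEL_STANCE = "stance_skip"


@dataclass
class DetectorConfig:
    """Thresholds of the detection algorithm (normalized gyro scale).

    T1: window opening/closing level on ABS (subject-independent, 0.01).
    T2: stance rejection level on gyro-bar (-0.4); windows dipping to or
        below it are the deep negative stance lobes of regular steps.
    R_demarcation: regular/FOG decision level on R (3).
    min_win_s: windows shorter than this are threshold chatter and dropped.
    envelope_floor: lower bound on the envelope denominator of R.
    episode_gap_s / min_episode_windows: aggregation of consecutive FOG
        windows into episodes.
    """

    T1: float = 0.01
    T2: float = -0.4
    R_demarcation: float = 3.0
    min_win_s: float = 0.05
    envelope_floor: float = 1e-6
    episode_gap_s: float = 1.0
    min_episode_windows: int = 2

    def validate(self) -> None:
        if not (0 < self.T1 < 1):
            raise ValidationError("T1 must lie in (0, 1)")
        if not (-1 < self.T2 < 0):
            raise ValidationError("T2 must lie in (-1, 0)")
        if self.R_demarcation <= 0:
            raise ValidationError("R_demarcation must be positive")
        if self.envelope_floor <= 0:
            raise ValidationError("envelope_floor must be positive")
        if self.min_episode_windows < 1:
            raise ValidationError("min_episode_windows must be >= 1")


@dataclass(frozen=True)
class StepWindow:
    """A supra-threshold interval of ABS: one step or step attempt.

    Half-open sample range [start_idx, end_idx); ``t_max_abs`` is the time of
    the ABS maximum inside the window, ``min_gyro`` the gyro-bar minimum.
    """

    start_idx: int
    end_idx: int
    t_max_abs: float
    max_abs: float
    min_gyro: float

    def __post_init__(self) -> None:
        if not self.start_idx < self.end_idx:
            raise ValidationError("window must satisfy start_idx < end_idx")

    def start_s(self, fs: float, t0: float = 0.0) -> float:
        return t0 + self.start_idx / fs

    def end_s(self, fs: float, t0: float = 0.0) -> float:
        return t0 + self.end_idx / fs


@dataclass(frozen=True)
class StepClassification:
    window: StepWindow
    R: float | None
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if (self.label == LABEL_STANCE) != (self.R is None):
            raise ContractViolation("R is absent exactly for stance_skip windows")


@dataclass(frozen=True)
class FogEpisode:
    start_s: float
    end_s: float
    windows: tuple[StepClassification, ...]


def abs_trace(gyro_smoothed: SignalTrace) -> SignalTrace:
    """ABS: pointwise absolute value of the normalized gyro-bar trace."""
    if gyro_smoothed.channel is not Channel.GYRO_Z:
        raise ValidationError("abs_trace expects a gyro_z trace")
    return replace(gyro_smoothed, values=np.abs(gyro_smoothed.values),
                   normalized=False)


def detect_step_windows(
    abs_tr: SignalTrace,
    gyro_smoothed: SignalTrace,
    cfg: DetectorConfig | None = None,
) -> list[StepWindow]:
    """Segment ABS into step windows by T1 crossings.

    A window opens at the first sample with ABS > T1 following a sample with
    ABS <= T1 (or at sample 0 if the trace starts above T1) and closes at the
    next sample with ABS <= T1 (half-open).  An unterminated trailing window
    is dropped.  Windows shorter than ``min_win_s`` are discarded.  If ABS
    never exceeds T1 (voluntary rest) the result is empty.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate()
    a = abs_tr.values
    g = gyro_smoothed.values
    if a.size != g.size or abs_tr.fs != gyro_smoothed.fs:
        raise ContractViolation("ABS and gyro-bar traces must share the grid")
    fs = abs_tr.fs
    above = a > cfg.T1
    # rising/falling edges of the supra-threshold mask
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    # drop an unterminated final window (still open at end of trace)
    k = min(starts.size, ends.size)
    starts, ends = starts[:k], ends[:k]
    min_len = int(np.ceil(cfg.min_win_s * fs))
    out: list[StepWindow] = []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        seg = a[s:e]
        imax = int(np.argmax(seg))
        out.append(
            StepWindow(
                start_idx=int(s),
                end_idx=int(e),
                t_max_abs=abs_tr.t0 + (s + imax) / fs,
                max_abs=float(seg[imax]),
                min_gyro=float(g[s:e].min()),
            )
        )
    return out


def compute_R(
    window: StepWindow,
    abs_tr: SignalTrace,
    envelope: SignalTrace,
    cfg: DetectorConfig | None = None,
) -> float:
    """R = max(ABS in window) / envelope at the time of that maximum.

    The denominator is floored at ``cfg.envelope_floor`` so a silent muscle
    yields a finite, very large R rather than a division by zero.
    """
    cfg = cfg or DetectorConfig()
    if envelope.fs != abs_tr.fs or envelope.n != abs_tr.n:
        raise ContractViolation("envelope must share the ABS grid")
    idx = envelope.index_at(window.t_max_abs)
    denom = max(float(envelope.values[idx]), cfg.envelope_floor)
    return window.max_abs / denom


def classify_windows(
    windows: Sequence[StepWindow],
    gyro_smoothed: SignalTrace,
    abs_tr: SignalTrace,
    envelope: SignalTrace,
    cfg: DetectorConfig | None = None,
) -> list[StepClassification]:
    """Apply stance rejection and the R demarcation to every window.

    min_gyro <= T2 -> stance_skip (deep stance lobe of a regular step; R not
    computed).  Otherwise R >= R_demarcation -> regular (ties regular),
    R < R_demarcation -> fog.
    """
    cfg = cfg or DetectorConfig()
    fs, t0 = abs_tr.fs, abs_tr.t0
    out = []
    for w in windows:
        if w.min_gyro <= cfg.T2:
            label, r = LABEL_STANCE, None
        else:
            r = compute_R(w, abs_tr, envelope, cfg)
            label = LABEL_REGULAR if r >= cfg.R_demarcation else LABEL_FOG
        out.append(
            StepClassification(
                window=w, R=r, label=label,
                start_s=w.start_s(fs, t0), end_s=w.end_s(fs, t0),
            )
        )
    return out


def aggregate_episodes(
    classifications: Sequence[StepClassification],
    cfg: DetectorConfig | None = None,
) -> list[FogEpisode]:
    """Group FOG-labelled windows into episodes.

    Maximal runs of fog windows whose successive gaps (previous end to next
    start) do not exceed ``episode_gap_s`` and that contain at least
    ``min_episode_windows`` members; episode bounds are the first window's
    start and the last window's end.
    """
    cfg = cfg or DetectorConfig()
    fog = [c for c in classifications if c.label == LABEL_FOG]
    episodes: list[FogEpisode] = []
    run: list[StepClassification] = []

    def flush() -> None:
        if len(run) >= cfg.min_episode_windows:
            episodes.append(
                FogEpisode(run[0].start_s, run[-1].end_s, tuple(run))
            )

    for c in fog:
        if run and c.start_s - run[-1].end_s > cfg.episode_gap_s:
            flush()
            run = []
        run.append(c)
    if run:
        flush()
    return episodes


@dataclass
class ConfusionCounts:
    """Step-level confusion between detector labels and annotations.

    FOG-annotated windows: fog -> tp, regular -> fn.  Regular-gait-annotated:
    fog -> fp, regular -> tn.  Stance-skip windows are excluded (they are the
    stance halves of regular steps, not steps in their own right); windows
    falling in rest/turning annotations or outside every annotation are
    tallied as unassigned.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    unassigned: int = 0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
            self.unassigned + other.unassigned,
        )


def evaluate_step_level(
    classifications: Sequence[StepClassification],
    annotations: IntervalAnnotationSet,
) -> ConfusionCounts:
    """Count detector labels against reference annotations, step by step.

    Each non-stance window is assigned to the annotation interval containing
    its ABS-maximum time (windows straddling a boundary therefore follow
    their peak).
    """
    counts = ConfusionCounts()
    for c in classifications:
        if c.label == LABEL_STANCE:
            continue
        ann = annotations.label_at(c.window.t_max_abs)
        if ann in FOG_LABELS:
            if c.label == LABEL_FOG:
                counts.tp += 1
            else:
                counts.fn += 1
        elif ann == "regular_gait":
            if c.label == LABEL_FOG:
                counts.fp += 1
            else:
                counts.tn += 1
        else:
            counts.unassigned += 1
    return counts


@dataclass
class StreamingDetector:
    """Sample-by-sample detector over normalized (ABS, gyro-bar, envelope).

    Consumes chunks of already-normalized samples and emits a
    :class:`StepClassification` whenever a window closes.  Because every
    per-window quantity uses only samples inside the window (always on the
    order of 200 ms during FOG), streamed results are identical to the
    offline path on the same normalized input.
    """

    cfg: DetectorConfig = field(default_factory=DetectorConfig)
    fs: float = 200.0
    t0: float = 0.0
    _i: int = 0
    _prev_above: bool = False
    _start: int | None = None
    _max_abs: float = 0.0
    _imax: int = 0
    _min_gyro: float = float("inf")

    def process(self, abs_chunk, gyro_chunk, env_chunk) -> list[StepClassification]:
        """Feed one chunk of samples; return windows closed within it."""
        self.cfg.validate()
        out: list[StepClassification] = []
        a = np.atleast_1d(np.asarray(abs_chunk, dtype=float))
        g = np.atleast_1d(np.asarray(gyro_chunk, dtype=float))
        e = np.atleast_1d(np.asarray(env_chunk, dtype=float))
        if not (a.size == g.size == e.size):
            raise ContractViolation("chunks must have equal length")
        for av, gv, ev in zip(a, g, e):
            above = av > self.cfg.T1
            if above:
                if self._start is None:
                    self._start = self._i
                    self._max_abs = -np.inf
                    self._min_gyro = np.inf
                if av > self._max_abs:
                    self._max_abs = float(av)
                    self._imax = self._i
                    self._env_at_max = float(ev)
                self._min_gyro = min(self._min_gyro, float(gv))
            elif self._start is not None:
                out.extend(self._close(self._i))
                self._start = None
            self._i += 1
        return out

    def _close(self, end: int) -> list[StepClassification]:
        start = self._start
        assert start is not None
        if end - start < int(np.ceil(self.cfg.min_win_s * self.fs)):
            return []
        w = StepWindow(
            start_idx=start, end_idx=end,
            t_max_abs=self.t0 + self._imax / self.fs,
            max_abs=self._max_abs, min_gyro=self._min_gyro,
        )
        if w.min_gyro <= self.cfg.T2:
            label, r = LABEL_STANCE, None
        else:
            denom = max(self._env_at_max, self.cfg.envelope_floor)
            r = w.max_abs / denom
            label = LABEL_REGULAR if r >= self.cfg.R_demarcation else LABEL_FOG
        return [
            StepClassification(
                window=w, R=r, label=label,
                start_s=w.start_s(self.fs, self.t0),
                end_s=w.end_s(self.fs, self.t0),
            )
        ]
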