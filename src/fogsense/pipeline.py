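"""End-to-end orchestration: detection, phenotype and muscle stages combined.

``run_pipeline`` produces the per-episode "agenda" a clinician would review:
episode bounds, window counts, median R, the phenotype index with its label,
and the gastrocnemius stretching fraction, plus session totals (episode
count, fraction of time frozen).  ``evaluate_session`` scores step-level
detection against reference annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import TooShortError, ValidationError
from .fog_detect import (
    ConfusionCounts,
    LABEL_STANCE,
    StepClassification,
    StreamingDetector,
    abs_trace,
    aggregate_episodes,
    classify_windows,
    detect_step_windows,
    evaluate_step_level,
)
from .muscle_activity import STRETCHING, activity_type
from .phenotype import phenotype_episode
from .preprocess import gyro_smooth, semg_envelope
from .signal_model import (
    Channel,
    IntervalAnnotationSet,
    Muscle,
    RecordingSession,
    Side,
    SignalTrace,
    gyro_norm_constant,
)

logger = logging.getLogger("fogsense")

__all__ = [
    "DeviceSignals",
    "AgendaReport",
    "preprocess_device",
    "detect_device",
    "detect_session",
    "run_pipeline",
    "evaluate_session",
]


@dataclass
class DeviceSignals:
    """Preprocessed traces of one (side, muscle) device."""

    side: Side
    muscle: Muscle
    gyro_smoothed: SignalTrace
    abs: SignalTrace
    envelope: SignalTrace


def preprocess_device(
    session: RecordingSession,
    side: Side,
    muscle: Muscle,
    cfg: PipelineConfig,
    norm_const: float | None = None,
) -> DeviceSignals:
    """Normalize + smooth the gyro and extract the sEMG envelope."""
    gyro = session.get(side, muscle, Channel.GYRO_Z)
    raw = session.get(side, muscle, Channel.SEMG_RAW)
    if norm_const is None:
        norm_const = gyro_norm_constant(session, side, muscle)
    sm = gyro_smooth(gyro, cfg.preprocess, norm_const=norm_const)
    env = semg_envelope(raw, cfg.preprocess)
    return DeviceSignals(side=side, muscle=muscle, gyro_smoothed=sm,
                         abs=abs_trace(sm), envelope=env)


def detect_device(
    session: RecordingSession,
    side: Side,
    cfg: PipelineConfig | None = None,
    muscle: Muscle = Muscle.TA,
) -> list[StepClassification]:
    """Full detection chain for one leg (TA device by default)."""
    cfg = cfg or PipelineConfig()
    dev = preprocess_device(session, side, muscle, cfg)
    windows = detect_step_windows(dev.abs, dev.gyro_smoothed, cfg.detector)
    return classify_windows(windows, dev.gyro_smoothed, dev.abs, dev.envelope,
                            cfg.detector)


def detect_session(
    session: RecordingSession,
    cfg: PipelineConfig | None = None,
    muscle: Muscle = Muscle.TA,
) -> dict[Side, list[StepClassification]]:
    """Detection on every leg present in the session."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    out: dict[Side, list[StepClassification]] = {}
    for side in session.sides():
        if session.has(side, muscle, Channel.GYRO_Z):
            out[side] = detect_device(session, side, cfg, muscle)
            logger.info("detect %s/%s: %d windows", side.value, muscle.value,
                        len(out[side]))
    return out


def detect_session_streaming(
    session: RecordingSession,
    cfg: PipelineConfig | None = None,
    muscle: Muscle = Muscle.TA,
    chunk_s: float = 0.5,
) -> dict[Side, list[StepClassification]]:
    """Chunk-by-chunk replay of the detection stage.

    The gyro normalization constant is frozen on the calibration prefix
    (``cfg.calibration_s``, floored at the generator full-scale reference
    when present) instead of the whole recording, and the windowing / R state
    machine consumes the session in ``chunk_s`` chunks.  With identical
    normalization the emitted windows and R values match the offline path
    exactly, which is what makes the ~200 ms per-window computation feasible
    in real time.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    out: dict[Side, list[StepClassification]] = {}
    chunk = max(1, int(round(chunk_s * session.fs)))
    for side in session.sides():
        if not session.has(side, muscle, Channel.GYRO_Z):
            continue
        gyro = session.get(side, muscle, Channel.GYRO_Z)
        n_cal = min(gyro.n, int(round(cfg.calibration_s * gyro.fs)))
        norm = float(np.max(np.abs(gyro.values[:n_cal])))
        ref = float(session.meta.get("gyro_full_scale_dps", 0.0))
        if ref > 0 and norm < 0.2 * ref:
            norm = ref
        dev = preprocess_device(session, side, muscle, cfg, norm_const=norm)
        det = StreamingDetector(cfg=cfg.detector, fs=gyro.fs, t0=gyro.t0)
        got: list[StepClassification] = []
        for i0 in range(0, gyro.n, chunk):
            sl = slice(i0, min(i0 + chunk, gyro.n))
            got.extend(det.process(dev.abs.values[sl],
                                   dev.gyro_smoothed.values[sl],
                                   dev.envelope.values[sl]))
        out[side] = got
    return out


@dataclass
class AgendaReport:
    """Per-episode summary plus session totals."""

    episodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    episode_count: int = 0
    fog_time_fraction: float = 0.0
    duration_s: float = 0.0
    confusion: ConfusionCounts | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.episodes


_EPISODE_COLUMNS = ["start_s", "end_s", "n_windows", "median_R", "PI",
                    "phenotype", "gc_fraction_stretching"]


def run_pipeline(
    session: RecordingSession,
    cfg: PipelineConfig | None = None,
) -> AgendaReport:
    """Detection -> episode aggregation -> phenotype -> muscle summary.

    FOG windows from both legs are pooled in time before aggregation (a
    freeze is a bilateral event); each episode long enough for a stable
    spectrum gets a phenotype index and, when GC devices are present, the
    gastrocnemius stretching fraction over the episode.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    per_side = detect_session(session, cfg)
    pooled = sorted(
        (c for clas in per_side.values() for c in clas),
        key=lambda c: (c.start_s, c.end_s),
    )
    episodes = aggregate_episodes(pooled, cfg.detector)
    logger.info("aggregated %d FOG episodes", len(episodes))

    envs: dict[Side, SignalTrace] = {}
    gyros: dict[Side, SignalTrace] = {}
    for side in (Side.RIGHT, Side.LEFT):
        if session.has(side, Muscle.TA, Channel.GYRO_Z):
            dev = preprocess_device(session, side, Muscle.TA, cfg)
            envs[side], gyros[side] = dev.envelope, dev.gyro_smoothed

    gc_activity = {}
    for side in (Side.RIGHT, Side.LEFT):
        if session.has(side, Muscle.GC, Channel.SEMG_RAW):
            gc_activity[side] = activity_type(
                session.get(side, Muscle.GC, Channel.SEMG_RAW), cfg.preprocess
            )

    rows = []
    for ep in episodes:
        rs = [c.R for c in ep.windows if c.R is not None]
        pi, label = np.nan, None
        if len(envs) == 2:
            try:
                res = phenotype_episode(
                    envs[Side.RIGHT].slice_time(ep.start_s, ep.end_s),
                    gyros[Side.RIGHT].slice_time(ep.start_s, ep.end_s),
                    envs[Side.LEFT].slice_time(ep.start_s, ep.end_s),
                    gyros[Side.LEFT].slice_time(ep.start_s, ep.end_s),
                    cfg.phenotype,
                )
                pi, label = res.PI, res.label
            except TooShortError:
                logger.info("episode %.1f-%.1f s too short for a phenotype",
                            ep.start_s, ep.end_s)
        frac = np.nan
        if gc_activity:
            fracs = []
            for act in gc_activity.values():
                i0 = max(0, int(round((ep.start_s - act.t0) * act.fs)))
                i1 = min(act.n, int(round((ep.end_s - act.t0) * act.fs)))
                if i1 > i0:
                    fracs.append(float(np.mean(act.labels[i0:i1] == STRETCHING)))
            if fracs:
                frac = float(np.mean(fracs))
        rows.append((ep.start_s, ep.end_s, len(ep.windows),
                     float(np.median(rs)) if rs else np.nan, pi, label, frac))

    df = pd.DataFrame(rows, columns=_EPISODE_COLUMNS)
    fog_time = float((df["end_s"] - df["start_s"]).sum()) if len(df) else 0.0
    return AgendaReport(
        episodes=df,
        episode_count=len(df),
        fog_time_fraction=fog_time / session.duration_s,
        duration_s=session.duration_s,
    )


def evaluate_session(
    session: RecordingSession,
    annotations: IntervalAnnotationSet | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[ConfusionCounts, pd.DataFrame]:
    """Step-level confusion counts plus a scatter table (one row per window).

    The scatter table (window index, time of ABS max, R, detector label,
    annotation label) is what an R-vs-step scatter or box plot is drawn
    from; stance-skip windows are excluded.
    """
    cfg = cfg or PipelineConfig()
    if annotations is None:
        annotations = session.annotations
    if len(annotations) == 0:
        raise ValidationError("evaluation requires a non-empty annotation set")
    per_side = detect_session(session, cfg)
    counts = ConfusionCounts()
    rows = []
    idx = 0
    for side, clas in sorted(per_side.items(), key=lambda kv: kv[0].value):
        counts = counts + evaluate_step_level(clas, annotations)
        for c in clas:
            if c.label == LABEL_STANCE:
                continue
            rows.append((idx, side.value, c.window.t_max_abs, c.R, c.label,
                         annotations.label_at(c.window.t_max_abs)))
            idx += 1
    scatter = pd.DataFrame(
        rows, columns=["step", "side", "t_max_abs", "R", "label", "annotation"]
    )
    return counts, scatter
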