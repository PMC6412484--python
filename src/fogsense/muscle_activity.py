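"""Antagonist-muscle activity decoding: type, intensity, ensemble averages.

The linear envelope quantifies how *much* a muscle is active but not *how*:
the same envelope can come from a concentric contraction or from a stretch.
The low-frequency portion of the raw sEMG (below 10 Hz) carries that missing
sign — positive excursions correspond to contraction, negative to stretching.
This module extracts the signed "type" trace, pairs it with the envelope
"intensity", labels samples through a small deadband, and ensemble-averages
step-aligned one-second segments so recurring activation patterns (or their
absence, as in the gastrocnemius toe-off deficit during trembling freezes)
become visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ContractViolation, DegenerateInputError, ValidationError
from .preprocess import PreprocessConfig, semg_envelope
from .signal_model import Channel, IntervalAnnotationSet, Muscle, Side, SignalTrace

__all__ = [
    "ActivityTrace",
    "EnsembleConfig",
    "activity_type",
    "extract_step_segments",
    "ensemble_average",
    "gc_deficit_summary",
    "CONTRACTION",
    "STRETCHING",
    "QUIESCENT",
]

CONTRACTION = 1
QUIESCENT = 0
STRETCHING = -1

_LABEL_NAMES = {CONTRACTION: "contraction", QUIESCENT: "quiescent",
                STRETCHING: "stretching"}


@dataclass
class ActivityTrace:
    """Signed activity type plus envelope intensity for one muscle.

    ``type_values`` is the 10 Hz low-passed raw sEMG normalized by its
    session absolute maximum; ``labels`` holds +1 (contraction), -1
    (stretching) or 0 (quiescent, inside the deadband).  ``intensity_values``
    is the linear envelope of the same raw trace.
    """

    type_values: np.ndarray
    intensity_values: np.ndarray
    labels: np.ndarray
    muscle: Muscle
    side: Side
    fs: float
    t0: float = 0.0
    deadband: float = 0.05

    def __post_init__(self) -> None:
        if not (
            self.type_values.size == self.intensity_values.size == self.labels.size
        ):
            raise ContractViolation("type, intensity and labels must share length")

    @property
    def n(self) -> int:
        return self.type_values.size

    def label_names(self) -> list[str]:
        return [_LABEL_NAMES[int(v)] for v in self.labels]


@dataclass
class EnsembleConfig:
    """Step-aligned ensemble-averaging settings.

    segment_s: analysis window per step (1 s covers a full cycle at
    pathological cadence).  resample_len: common length the time-normalized
    segments are interpolated to.  alignment: which event anchors segments.
    """

    segment_s: float = 1.0
    resample_len: int = 200
    alignment: str = "window_start"

    def validate(self) -> None:
        if self.segment_s <= 0:
            raise ValidationError("segment_s must be positive")
        if self.resample_len < 10:
            raise ValidationError("resample_len must be >= 10")
        if self.alignment not in ("window_start", "gyro_peak"):
            raise ValidationError("alignment must be window_start or gyro_peak")


def activity_type(
    raw: SignalTrace,
    pre_cfg: PreprocessConfig | None = None,
    lp_hz: float = 10.0,
    deadband: float = 0.05,
) -> ActivityTrace:
    """Decode activity type and intensity from one raw sEMG trace.

    The raw trace must not be high-pass filtered: the sub-10 Hz content that
    conventional preprocessing throws away is the signal here.  The type
    trace is the zero-phase low-passed raw signal normalized to its absolute
    maximum; samples above +deadband are contraction, below -deadband
    stretching, in between quiescent.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    if raw.channel is not Channel.SEMG_RAW:
        raise ValidationError("activity_type expects a semg_raw trace")
    if raw.fs <= 2 * lp_hz:
        raise ValidationError("sampling rate too low for the 10 Hz type filter")
    if not np.any(raw.values):
        raise DegenerateInputError("all-zero sEMG trace: activity undefined")
    sos = signal.butter(pre_cfg.filter_order, lp_hz, btype="lowpass",
                        fs=raw.fs, output="sos")
    low = signal.sosfiltfilt(sos, raw.values)
    # normalize on the interior so filter edge transients cannot set the scale
    k = int(round(0.25 * raw.fs)) if raw.n > raw.fs else 0
    core = low[k : raw.n - k] if k else low
    m = float(np.max(np.abs(core)))
    if m == 0.0:
        raise DegenerateInputError("sEMG trace vanishes below the type cut-off")
    tv = np.clip(low / m, -1.0, 1.0)
    # If the sub-cutoff band carries under 1% of the signal power there is no
    # physiological low-frequency component to sign — only filtered noise,
    # which normalization would blow up past any deadband.  Such a trace is
    # quiescent throughout.
    lf_power_fraction = float(np.mean(core**2) / np.mean(raw.values**2))
    if lf_power_fraction < 0.01:
        labels = np.zeros(raw.n, dtype=np.int8)
    else:
        labels = np.where(tv > deadband, CONTRACTION,
                          np.where(tv < -deadband, STRETCHING, QUIESCENT)
                          ).astype(np.int8)
    env = semg_envelope(raw, pre_cfg)
    return ActivityTrace(
        type_values=tv, intensity_values=env.values, labels=labels,
        muscle=raw.muscle, side=raw.side, fs=raw.fs, t0=raw.t0,
        deadband=deadband,
    )


def extract_step_segments(
    values: np.ndarray,
    fs: float,
    anchors: Sequence[float],
    cfg: EnsembleConfig | None = None,
    t0: float = 0.0,
) -> tuple[list[np.ndarray], int]:
    """Cut ``[anchor, anchor + segment_s)`` slices and time-normalize them.

    Each slice is linearly resampled to ``resample_len`` points.  Anchors too
    close to the end of the trace (or before its start) are skipped; the
    second return value counts the skips.
    """
    cfg = cfg or EnsembleConfig()
    cfg.validate()
    x = np.asarray(values, dtype=float)
    seg_n = int(round(cfg.segment_s * fs))
    out: list[np.ndarray] = []
    skipped = 0
    for a in anchors:
        i0 = int(round((a - t0) * fs))
        if i0 < 0 or i0 + seg_n > x.size:
            skipped += 1
            continue
        seg = x[i0 : i0 + seg_n]
        grid = np.linspace(0.0, seg_n - 1, cfg.resample_len)
        out.append(np.interp(grid, np.arange(seg_n), seg))
    return out, skipped


def ensemble_average(
    segments: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation across equal-length segments."""
    if len(segments) == 0:
        raise ContractViolation("ensemble_average needs at least one segment")
    lengths = {len(s) for s in segments}
    if len(lengths) != 1:
        raise ContractViolation("all segments must have the same length")
    stack = np.vstack(segments)
    return stack.mean(axis=0), stack.std(axis=0)


def gc_deficit_summary(
    gc_activity: ActivityTrace,
    intervals: IntervalAnnotationSet,
) -> dict[str, dict[str, float]]:
    """Per-annotation-label stretching fraction and mean intensity of the GC.

    For every annotation label with at least one sample: the fraction of
    samples whose type label is stretching and the mean envelope intensity.
    A persistently high stretching fraction with low intensity over
    trembling episodes is the toe-off deficit signature.
    """
    t = gc_activity.t0 + np.arange(gc_activity.n) / gc_activity.fs
    out: dict[str, dict[str, float]] = {}
    for label in sorted({iv.label for iv in intervals}):
        mask = np.zeros(gc_activity.n, dtype=bool)
        for iv in intervals:
            if iv.label == label:
                mask |= (t >= iv.start_s) & (t < iv.end_s)
        if not mask.any():
            continue
        out[label] = {
            "fraction_stretching": float(
                np.mean(gc_activity.labels[mask] == STRETCHING)
            ),
            "mean_intensity": float(np.mean(gc_activity.intensity_values[mask])),
        }
    return out
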