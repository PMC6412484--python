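"""Conventional sEMG envelope extraction and gyro conditioning.

The envelope chain is the standard linear-envelope recipe: high-pass at 3 Hz
(removes hum, motion artifact and the low-frequency "type" component),
full-wave rectification, normalization to the rectified maximum, low-pass at
10 Hz.  The gyro is smoothed with a short centered moving average and
normalized by the session constant; its absolute value drives the step-window
detector downstream.

Offline mode uses zero-phase (forward-backward) 4th-order Butterworth
filters so that envelope maxima stay time-aligned with gyro events; streaming
mode uses the same designs causally (single pass).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, ValidationError
from .signal_model import Channel, SignalTrace

__all__ = ["PreprocessConfig", "semg_envelope", "gyro_smooth", "gyro_gait_view"]


@dataclass
class PreprocessConfig:
    """Filter settings for the preprocessing stage.

    hp_cutoff_hz / lp_envelope_hz: envelope band edges (Hz).
    gyro_ma_window_s: moving-average width for the smoothed gyro (s).
    gyro_view_lp_hz: cut-off of the 0-3 Hz gait inspection filter (Hz).
    filter_order: Butterworth order for every recursive filter.
    causal: single-pass filters (streaming) instead of zero-phase (offline).
    """

    hp_cutoff_hz: float = 3.0
    lp_envelope_hz: float = 10.0
    gyro_ma_window_s: float = 0.1
    gyro_view_lp_hz: float = 3.0
    filter_order: int = 4
    causal: bool = False

    def validate(self, fs: float | None = None) -> None:
        if not (0 < self.hp_cutoff_hz < self.lp_envelope_hz):
            raise ValidationError("need 0 < hp_cutoff_hz < lp_envelope_hz")
        if fs is not None and not (self.lp_envelope_hz < fs / 2):
            raise ValidationError("lp_envelope_hz must be below Nyquist")
        if self.gyro_ma_window_s <= 0:
            raise ValidationError("gyro_ma_window_s must be positive")
        if self.filter_order < 1:
            raise ValidationError("filter_order must be >= 1")


def _butter_apply(x: np.ndarray, fs: float, cutoff, btype: str, order: int,
                  causal: bool) -> np.ndarray:
    sos = signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    if causal:
        return signal.sosfilt(sos, x)
    return signal.sosfiltfilt(sos, x)


def semg_envelope(raw: SignalTrace, cfg: PreprocessConfig | None = None,
                  ) -> SignalTrace:
    """Linear envelope of a raw sEMG trace.

    Pipeline: HP(3 Hz) -> |.| -> normalize to rectified max -> LP(10 Hz).
    The output shares grid and rate with the input and lies in [0, 1]
    (low-pass ringing below zero is clipped; overshoot above one likewise).
    """
    cfg = cfg or PreprocessConfig()
    if raw.channel is not Channel.SEMG_RAW:
        raise ValidationError("semg_envelope expects a semg_raw trace")
    cfg.validate(raw.fs)
    if not np.any(raw.values):
        raise DegenerateInputError("all-zero sEMG trace: envelope undefined")
    hp = _butter_apply(raw.values, raw.fs, cfg.hp_cutoff_hz, "highpass",
                       cfg.filter_order, cfg.causal)
    rect = np.abs(hp)
    m = rect.max()
    # A signal that vanishes after the high-pass (pure DC / sub-3 Hz drift)
    # carries no muscle activity; normalizing would only amplify numerical
    # dust, so the near-zero rectified trace is smoothed as-is.
    if m > 1e-9 * np.max(np.abs(raw.values)):
        rect = rect / m
    env = _butter_apply(rect, raw.fs, cfg.lp_envelope_hz, "lowpass",
                        cfg.filter_order, cfg.causal)
    env = np.clip(env, 0.0, 1.0)
    return replace(raw, values=env, channel=Channel.SEMG_ENVELOPE,
                   units="normalized", normalized=False)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrink-to-valid edges.

    For even ``window`` the kernel extends one sample further into the past
    than into the future.  Near the edges the mean is taken over however much
    of the kernel support lies inside the trace.
    """
    n = x.size
    if window < 1:
        raise ValidationError("moving-average window must be >= 1 sample")
    if window > n:
        raise DegenerateInputError("moving-average window longer than trace")
    back = window // 2          # samples of past included (even kernels lean back)
    fwd = window - back - 1     # samples of future included
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.clip(np.arange(n) - back, 0, n)
    hi = np.clip(np.arange(n) + fwd + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def gyro_smooth(gyro: SignalTrace, cfg: PreprocessConfig | None = None,
                norm_const: float | None = None) -> SignalTrace:
    """Moving-averaged, session-normalized angular velocity (the gyro-bar trace).

    ``norm_const`` is the session's gyro normalization constant (absolute
    maximum of the raw trace by default), applied after smoothing so the
    output is on the normalized scale the detector thresholds expect.
    """
    cfg = cfg or PreprocessConfig()
    if gyro.channel is not Channel.GYRO_Z:
        raise ValidationError("gyro_smooth expects a gyro_z trace")
    window = max(1, int(round(cfg.gyro_ma_window_s * gyro.fs)))
    sm = moving_average(gyro.values, window)
    if norm_const is None:
        norm_const = float(np.max(np.abs(gyro.values)))
    if norm_const <= 0:
        raise DegenerateInputError("gyro normalization constant must be positive")
    return replace(gyro, values=sm / norm_const, units="normalized",
                   normalized=False)


def gyro_gait_view(gyro: SignalTrace, cfg: PreprocessConfig | None = None,
                   ) -> SignalTrace:
    """0-3 Hz low-passed gyro trace for visual inspection of gait content.

    Not used by the detector; zero-phase regardless of mode so plots stay
    aligned with the raw trace.
    """
    cfg = cfg or PreprocessConfig()
    if gyro.channel is not Channel.GYRO_Z:
        raise ValidationError("gyro_gait_view expects a gyro_z trace")
    if gyro.fs <= 2 * cfg.gyro_view_lp_hz:
        raise ValidationError("sampling rate too low for the 3 Hz gait view")
    out = _butter_apply(gyro.values, gyro.fs, cfg.gyro_view_lp_hz, "lowpass",
                        cfg.filter_order, causal=False)
    return replace(gyro, values=out)
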