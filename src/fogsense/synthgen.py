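"""Script-driven generator of bilateral gyro + sEMG gait recordings.

The generator encodes the signal morphology the analysis stack consumes, not
a biomechanical forward model:

* regular gait — per cycle (~1.2 s) one positive raised-cosine swing lobe of
  the shank angular velocity followed by a deep negative stance lobe
  (>= half the swing amplitude, so stance minima survive session
  normalization below the stance-rejection threshold); tibialis anterior
  (TA) sEMG bursts at swing onset and termination with a quiet mid-swing,
  gastrocnemius (GC) bursts at toe-off; legs half a cycle out of phase;
* shuffling freeze — shallow quasi-sinusoidal gyro oscillation (~15% of the
  regular swing amplitude, minima well above the stance threshold), one
  sEMG burst per shuffle peaking at the gyro minimum, left/right antiphase;
* trembling freeze — band-limited (2-6 Hz) aperiodic zero-mean gyro noise at
  <= 10% of full scale with no bilateral phase relation; TA shows an
  alternating-sign low-frequency activity component while GC stays mildly
  negative (stretched) at very low envelope intensity;
* rest — sensor noise floor only.

Raw sEMG is synthesized as an amplitude-modulated 20-80 Hz noise carrier
plus an additive low-frequency "type" component, so the conventional
envelope chain recovers the modulation and the 10 Hz type filter recovers
the signed component.  Everything is deterministic given the script seed,
and the emitted annotations coincide exactly with the segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ValidationError
from .signal_model import (
    Channel,
    Interval,
    IntervalAnnotationSet,
    Muscle,
    RecordingSession,
    Side,
    SignalTrace,
)

__all__ = [
    "SegmentSpec",
    "GaitScript",
    "generate_session",
    "default_tug_script",
    "mixed_fog_script",
    "regular_walk_script",
    "FULL_SCALE_DPS",
]

#: Nominal full-scale shank angular velocity (regular swing peak), in dps.
FULL_SCALE_DPS = 250.0

#: RMS gyro sensor noise, dps (typical MEMS low-power figure).
GYRO_NOISE_DPS = 0.12

KINDS = ("rest", "regular_gait", "shuffling_fog", "trembling_fog")

_DEFAULTS: dict[str, dict[str, float | bool | tuple]] = {
    "regular_gait": {
        "cycle_s": 1.2,           # full gait cycle
        "swing_amp_dps": FULL_SCALE_DPS,
        "swing_width_s": 0.35,
        "stance_depth_frac": 0.65,  # stance lobe depth / swing amplitude
        "stance_width_s": 0.40,
        "swing_stance_gap_s": 0.10,
        "amp_jitter": 0.10,       # per-cycle relative amplitude spread
        "ta_burst_amp": 1.0,
        "ta_burst_width_s": 0.10,
        "ta_dip_level": 0.05,     # TA modulation floor mid-swing
        "ta_stance_amp": 0.5,     # toe-off TA activity under the stance lobe
        "gc_burst_amp": 0.9,
        "gc_base": 0.05,
        "type_amp": 0.30,         # signed low-frequency component amplitude
    },
    "shuffling_fog": {
        "rate_hz": 1.6,           # shuffle repetition rate
        "gyro_frac": 0.15,        # peak amplitude / full scale
        "amp_jitter": 0.10,
        "ta_burst_peak": 0.70,    # sEMG modulation at the gyro minimum
        "ta_burst_base": 0.35,    # sustained activity between bursts
        "gc_level": 0.15,
        "gc_mod": 0.10,
        "ta_type_amp": 0.30,      # positive-oscillating TA type component
        "gc_type_level": -0.12,   # mildly stretched GC
        "antiphase": True,
    },
    "trembling_fog": {
        "gyro_frac": 0.08,        # peak amplitude / full scale
        "band_hz": (2.0, 6.0),    # knee-tremor band
        "amp_jitter": 0.10,
        "ta_level": 0.30,
        "ta_mod": 0.10,
        "gc_level": 0.04,         # defective toe-off: very low GC intensity
        "ta_type_amp": 0.20,
        "ta_type_hz": 1.5,        # alternation rate of the TA type component
        "gc_type_level": -0.15,   # tonically stretched GC
    },
    "rest": {
        "semg_level": 0.01,
    },
}

_KIND_TO_LABEL = {
    "rest": "rest",
    "regular_gait": "regular_gait",
    "shuffling_fog": "shuffling_fog",
    "trembling_fog": "trembling_fog",
}


@dataclass(frozen=True)
class SegmentSpec:
    """One scripted gait segment: a kind, a duration and kind parameters."""

    kind: str
    duration_s: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if not self.duration_s > 0:
            raise ValidationError("segment duration must be positive")
        unknown = set(self.params) - set(_DEFAULTS[self.kind])
        if unknown:
            raise ValidationError(
                f"unknown parameters for {self.kind}: {sorted(unknown)}"
            )

    def resolved(self) -> dict:
        p = dict(_DEFAULTS[self.kind])
        p.update(self.params)
        _validate_params(self.kind, p)
        return p


def _validate_params(kind: str, p: dict) -> None:
    positive = {
        "regular_gait": ("cycle_s", "swing_amp_dps", "swing_width_s",
                         "stance_width_s", "ta_burst_amp", "gc_burst_amp"),
        "shuffling_fog": ("rate_hz", "gyro_frac", "ta_burst_peak"),
        "trembling_fog": ("gyro_frac", "ta_level"),
        "rest": ("semg_level",),
    }[kind]
    for name in positive:
        if not p[name] > 0:
            raise ValidationError(f"{kind}.{name} must be positive")
    if kind == "regular_gait":
        if not (0 < p["stance_depth_frac"] <= 1.5):
            raise ValidationError("stance_depth_frac out of range (0, 1.5]")
        total = p["swing_width_s"] + p["swing_stance_gap_s"] + p["stance_width_s"]
        if total > p["cycle_s"]:
            raise ValidationError("swing + gap + stance must fit in one cycle")
    if kind in ("shuffling_fog", "trembling_fog") and not (0 < p["gyro_frac"] < 0.5):
        raise ValidationError("gyro_frac must lie in (0, 0.5)")


@dataclass
class GaitScript:
    """Ordered synthetic segment plan with its sampling rate and seed."""

    segments: list[SegmentSpec]
    fs: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("script must contain at least one segment")
        if self.fs < 50:
            raise ValidationError("script fs must be >= 50 Hz")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-peak raised-cosine bump of n samples (zero at both ends)."""
    return np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Zero-mean band-limited Gaussian noise, normalized to unit peak."""
    x = rng.standard_normal(n + 2 * int(fs))  # pad to suppress filter edges
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)[int(fs) : int(fs) + n]
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def _smooth_noise(rng: np.random.Generator, n: int, fs: float,
                  cutoff_hz: float = 1.0) -> np.ndarray:
    """Slowly varying unit-RMS noise for amplitude jitter."""
    x = rng.standard_normal(n + 2 * int(fs))
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)[int(fs) : int(fs) + n]
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _edge_taper(n: int, fs: float, ramp_s: float = 0.05) -> np.ndarray:
    """Cosine ramps at both segment ends to avoid boundary discontinuities."""
    w = np.ones(n)
    r = min(int(round(ramp_s * fs)), n // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        w[:r] = ramp
        w[-r:] = ramp[::-1]
    return w


class _SideBuffers:
    """Per-leg accumulation buffers while a script is rendered."""

    def __init__(self, n: int):
        self.gyro = np.zeros(n)
        self.mod = {Muscle.TA: np.full(n, 0.01), Muscle.GC: np.full(n, 0.01)}
        self.type = {Muscle.TA: np.zeros(n), Muscle.GC: np.zeros(n)}


def _render_regular(buf: _SideBuffers, sl: slice, fs: float, p: dict,
                    rng: np.random.Generator, phase_offset_s: float) -> None:
    n = sl.stop - sl.start
    dur = n / fs
    cyc = p["cycle_s"]
    t_first = phase_offset_s
    k = 0
    while t_first + k * cyc + cyc <= dur + 1e-9:
        c0 = t_first + k * cyc
        j_sw = 1.0 + p["amp_jitter"] * rng.uniform(-1, 1)
        j_st = 1.0 + p["amp_jitter"] * rng.uniform(-1, 1)
        j_emg = 1.0 + p["amp_jitter"] * rng.uniform(-1, 1)

        def put(arr: np.ndarray, start_s: float, width_s: float,
                amp: float) -> None:
            i0 = sl.start + int(round((c0 + start_s) * fs))
            m = int(round(width_s * fs))
            i1 = min(i0 + m, sl.stop)
            if i1 > i0:
                arr[i0:i1] += amp * _raised_cosine(m)[: i1 - i0]

        sw_w, st_w = p["swing_width_s"], p["stance_width_s"]
        st_0 = sw_w + p["swing_stance_gap_s"]
        put(buf.gyro, 0.0, sw_w, p["swing_amp_dps"] * j_sw)
        put(buf.gyro, st_0, st_w,
            -p["swing_amp_dps"] * p["stance_depth_frac"] * j_st)
        # TA: biphasic swing bursts framing a quiet mid-swing, toe-off burst
        bw = p["ta_burst_width_s"]
        put(buf.mod[Muscle.TA], 0.0, bw, p["ta_burst_amp"] * j_emg)
        put(buf.mod[Muscle.TA], sw_w - bw, bw, p["ta_burst_amp"] * j_emg)
        put(buf.mod[Muscle.TA], st_0 + 0.05, 0.15, p["ta_stance_amp"] * j_emg)
        # GC: single toe-off burst under the stance lobe
        put(buf.mod[Muscle.GC], st_0 + 0.05, 0.20, p["gc_burst_amp"] * j_emg)
        k += 1
    tau = np.arange(n) / fs - phase_offset_s
    buf.mod[Muscle.TA][sl] = np.maximum(buf.mod[Muscle.TA][sl], p["ta_dip_level"])
    buf.mod[Muscle.GC][sl] = np.maximum(buf.mod[Muscle.GC][sl], p["gc_base"])
    # periodic signed type component: TA positive in swing, GC in antiphase
    buf.type[Muscle.TA][sl] = p["type_amp"] * np.cos(2 * np.pi * tau / cyc)
    buf.type[Muscle.GC][sl] = -p["type_amp"] * np.cos(2 * np.pi * tau / cyc)


def _render_shuffling(buf: _SideBuffers, sl: slice, fs: float, p: dict,
                      rng: np.random.Generator, side: Side) -> None:
    n = sl.stop - sl.start
    t = np.arange(n) / fs
    phase = np.pi if (p["antiphase"] and side is Side.LEFT) else 0.0
    theta = 2 * np.pi * p["rate_hz"] * t + phase
    amp = p["gyro_frac"] * FULL_SCALE_DPS * (
        1.0 + p["amp_jitter"] * 0.5 * _smooth_noise(rng, n, fs)
    )
    taper = _edge_taper(n, fs)
    buf.gyro[sl] += amp * np.sin(theta) * taper
    burst = 0.5 * (1.0 - np.sin(theta))  # peaks at the gyro minimum
    buf.mod[Muscle.TA][sl] = p["ta_burst_base"] + (
        p["ta_burst_peak"] - p["ta_burst_base"]
    ) * burst
    buf.mod[Muscle.GC][sl] = p["gc_level"] + p["gc_mod"] * burst
    buf.type[Muscle.TA][sl] = p["ta_type_amp"] * burst
    buf.type[Muscle.GC][sl] = p["gc_type_level"] * (
        0.8 + 0.2 * np.sin(2 * np.pi * 0.7 * t)
    )


def _render_trembling(buf: _SideBuffers, sl: slice, fs: float, p: dict,
                      rng: np.random.Generator) -> None:
    n = sl.stop - sl.start
    t = np.arange(n) / fs
    amp = p["gyro_frac"] * FULL_SCALE_DPS * (
        1.0 + p["amp_jitter"] * rng.uniform(-1, 1)
    )
    taper = _edge_taper(n, fs)
    buf.gyro[sl] += amp * _band_noise(rng, n, fs, p["band_hz"]) * taper
    buf.mod[Muscle.TA][sl] = np.clip(
        p["ta_level"] * (1.0 + 0.5 * p["ta_mod"] * _smooth_noise(rng, n, fs)),
        0.05, None,
    )
    buf.mod[Muscle.GC][sl] = p["gc_level"]
    phi = rng.uniform(0, 2 * np.pi)
    buf.type[Muscle.TA][sl] = p["ta_type_amp"] * np.sin(
        2 * np.pi * p["ta_type_hz"] * t + phi
    )
    buf.type[Muscle.GC][sl] = p["gc_type_level"] * (
        0.8 + 0.2 * np.sin(2 * np.pi * 0.7 * t + phi)
    )


def _render_rest(buf: _SideBuffers, sl: slice, p: dict) -> None:
    buf.mod[Muscle.TA][sl] = p["semg_level"]
    buf.mod[Muscle.GC][sl] = p["semg_level"]


def generate_session(script: GaitScript) -> RecordingSession:
    """Render a script into a full bilateral recording session.

    Returns a session with eight traces — gyro_z and semg_raw for every
    (side, muscle in {TA, GC}) device — plus annotations that exactly match
    the segment boundaries.  Deterministic given ``script.seed``.
    """
    fs = script.fs
    n_total = int(round(script.duration_s * fs))
    rng = np.random.default_rng(script.seed)
    bufs = {Side.RIGHT: _SideBuffers(n_total), Side.LEFT: _SideBuffers(n_total)}

    intervals: list[Interval] = []
    t_cursor = 0.0
    for seg in script.segments:
        p = seg.resolved()
        i0 = int(round(t_cursor * fs))
        i1 = min(int(round((t_cursor + seg.duration_s) * fs)), n_total)
        sl = slice(i0, i1)
        for side in (Side.RIGHT, Side.LEFT):
            buf = bufs[side]
            if seg.kind == "regular_gait":
                offset = 0.0 if side is Side.RIGHT else p["cycle_s"] / 2
                _render_regular(buf, sl, fs, p, rng, offset)
            elif seg.kind == "shuffling_fog":
                _render_shuffling(buf, sl, fs, p, rng, side)
            elif seg.kind == "trembling_fog":
                _render_trembling(buf, sl, fs, p, rng)
            else:
                _render_rest(buf, sl, p)
        intervals.append(
            Interval(t_cursor, t_cursor + seg.duration_s, _KIND_TO_LABEL[seg.kind])
        )
        t_cursor += seg.duration_s

    session = RecordingSession(
        annotations=IntervalAnnotationSet(intervals),
        meta={
            "seed": script.seed,
            "fs": fs,
            "gyro_full_scale_dps": FULL_SCALE_DPS,
            "generator": "fogsense.synthgen",
        },
    )
    carrier_sos = signal.butter(4, (20.0, min(80.0, fs / 2 * 0.95)),
                                btype="bandpass", fs=fs, output="sos")
    for side in (Side.RIGHT, Side.LEFT):
        buf = bufs[side]
        for muscle in (Muscle.TA, Muscle.GC):
            gyro = buf.gyro + GYRO_NOISE_DPS * rng.standard_normal(n_total)
            session.add(
                SignalTrace(values=gyro, fs=fs, channel=Channel.GYRO_Z,
                            side=side, muscle=muscle, units="dps")
            )
            carrier = signal.sosfiltfilt(
                carrier_sos, rng.standard_normal(n_total)
            )
            carrier /= max(np.sqrt(np.mean(carrier**2)), 1e-12)
            raw = buf.mod[muscle] * carrier + buf.type[muscle]
            session.add(
                SignalTrace(values=raw, fs=fs, channel=Channel.SEMG_RAW,
                            side=side, muscle=muscle, units="a.u.")
            )
    return session


def default_tug_script(seed: int = 0) -> GaitScript:
    """A ~1 min timed-up-and-go-like plan: rest, regular walking, two
    shuffling episodes, one trembling episode, closing rest.

    Segment durations are jittered upward by up to 15% so different seeds
    give different but comparable sessions (total always within 50-70 s).
    """
    rng = np.random.default_rng(seed)
    base = [
        ("rest", 4.0),
        ("regular_gait", 14.4),
        ("shuffling_fog", 10.0),
        ("rest", 3.0),
        ("shuffling_fog", 8.0),
        ("trembling_fog", 12.0),
        ("rest", 4.0),
    ]
    segs = [
        SegmentSpec(kind, dur * float(rng.uniform(1.0, 1.15)))
        for kind, dur in base
    ]
    return GaitScript(segments=segs, seed=seed)


def mixed_fog_script(seed: int = 0, shuffle_s: float = 16.0,
                     tremble_s: float = 10.0) -> GaitScript:
    """A freeze-heavy session: a short regular walk to anchor the session
    normalization scale, then shuffling and trembling episodes."""
    return GaitScript(
        segments=[
            SegmentSpec("rest", 2.0),
            SegmentSpec("regular_gait", 7.2),
            SegmentSpec("shuffling_fog", shuffle_s),
            SegmentSpec("rest", 2.0),
            SegmentSpec("trembling_fog", tremble_s),
            SegmentSpec("rest", 2.0),
        ],
        seed=seed,
    )


def regular_walk_script(seed: int = 0, walk_s: float = 60.0) -> GaitScript:
    """A freeze-free session: sustained regular gait between two rests."""
    return GaitScript(
        segments=[
            SegmentSpec("rest", 2.0),
            SegmentSpec("regular_gait", walk_s),
            SegmentSpec("rest", 2.0),
        ],
        seed=seed,
    )
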