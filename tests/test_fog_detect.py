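"""Step-window segmentation, the R index, episode aggregation, evaluation."""

import numpy as np
import pytest

import fogsense as fg
from fogsense.errors import ContractViolation
from fogsense.fog_detect import (
    LABEL_FOG,
    LABEL_REGULAR,
    LABEL_STANCE,
    StepClassification,
    StepWindow,
    StreamingDetector,
    abs_trace,
    aggregate_episodes,
    classify_windows,
    compute_R,
    detect_step_windows,
    evaluate_step_level,
)
from fogsense.pipeline import detect_session, detect_session_streaming
from fogsense.signal_model import Channel, Interval, IntervalAnnotationSet, Side

from conftest import make_trace

FS = 200.0


def brute_force_windows(a, g, cfg, fs=FS, t0=0.0):
    """Independent per-sample linear scan re-deriving the step windows."""
    wins = []
    i = 0
    n = len(a)
    while i < n:
        if a[i] > cfg.T1 and (i == 0 or a[i - 1] <= cfg.T1):
            j = i
            while j < n and a[j] > cfg.T1:
                j += 1
            if j < n and (j - i) >= int(np.ceil(cfg.min_win_s * fs)):
                seg = list(a[i:j])
                imax = seg.index(max(seg))
                wins.append(
                    StepWindow(i, j, t0 + (i + imax) / fs, max(seg),
                               min(g[i:j]))
                )
            i = j
        else:
            i += 1
    return wins


def random_abs_pair(rng, n=600):
    """A smoothed random trace pair (gyro-bar, ABS) with realistic crossings."""
    g = np.convolve(rng.normal(size=n), np.ones(9) / 9, mode="same") * 0.3
    return np.abs(g), g


def traces_from(a, g):
    abs_tr = make_trace(a, channel=Channel.GYRO_Z)
    gs = make_trace(g, channel=Channel.GYRO_Z)
    return abs_tr, gs


class TestDetectStepWindows:
    def test_rest_below_threshold_gives_no_windows(self, cfg):
        a = np.full(1000, 0.005)
        wins = detect_step_windows(*traces_from(a, a), cfg.detector)
        assert wins == []

    def test_single_crossing_pair(self, cfg):
        a = np.concatenate([np.zeros(200), np.full(200, 0.5), np.zeros(200)])
        wins = detect_step_windows(*traces_from(a, a), cfg.detector)
        assert len(wins) == 1
        w = wins[0]
        assert (w.start_idx, w.end_idx) == (200, 400)
        assert w.max_abs == 0.5

    def test_unterminated_final_window_dropped(self, cfg):
        a = np.concatenate([np.zeros(200), np.full(300, 0.5)])
        assert detect_step_windows(*traces_from(a, a), cfg.detector) == []

    def test_short_chatter_pruned(self, cfg):
        a = np.zeros(500)
        a[100:103] = 0.5  # 15 ms, below the 50 ms minimum
        assert detect_step_windows(*traces_from(a, a), cfg.detector) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed, cfg):
        rng = np.random.default_rng(seed)
        a, g = random_abs_pair(rng)
        fast = detect_step_windows(*traces_from(a, g), cfg.detector)
        slow = brute_force_windows(a, g, cfg.detector)
        assert fast == slow


class TestComputeR:
    def make_inputs(self, env_value):
        a = np.zeros(400)
        a[100:200] = np.linspace(0.1, 0.8, 100)
        a[200:300] = 0.05
        env = np.full(400, float(env_value))
        abs_tr = make_trace(a, channel=Channel.GYRO_Z)
        envelope = make_trace(env, channel=Channel.SEMG_ENVELOPE)
        w = detect_step_windows(abs_tr, abs_tr, fg.DetectorConfig())[0]
        return w, abs_tr, envelope

    def test_direct_formula(self, cfg):
        w, abs_tr, env = self.make_inputs(0.1)
        assert compute_R(w, abs_tr, env, cfg.detector) == pytest.approx(8.0)

    def test_zero_envelope_floored(self, cfg):
        w, abs_tr, env = self.make_inputs(0.0)
        r = compute_R(w, abs_tr, env, cfg.detector)
        assert r == pytest.approx(0.8 / cfg.detector.envelope_floor)
        assert np.isfinite(r)

    def test_unity_ratio(self, cfg):
        w, abs_tr, env = self.make_inputs(0.8)
        assert compute_R(w, abs_tr, env, cfg.detector) == pytest.approx(1.0)


class TestClassifyWindows:
    def build(self, min_gyro, env_value):
        a = np.zeros(400)
        a[100:300] = 0.8
        g = np.where(a > 0, min_gyro, 0.0)
        env = np.full(400, env_value)
        abs_tr = make_trace(a, channel=Channel.GYRO_Z)
        gs = make_trace(g, channel=Channel.GYRO_Z)
        envelope = make_trace(env, channel=Channel.SEMG_ENVELOPE)
        wins = detect_step_windows(abs_tr, gs, fg.DetectorConfig())
        return classify_windows(wins, gs, abs_tr, envelope, fg.DetectorConfig())

    def test_deep_stance_is_skipped(self):
        (c,) = self.build(min_gyro=-0.6, env_value=0.5)
        assert c.label == LABEL_STANCE and c.R is None

    def test_high_r_is_regular(self):
        (c,) = self.build(min_gyro=-0.1, env_value=0.1)
        assert c.R == pytest.approx(8.0)
        assert c.label == LABEL_REGULAR

    def test_low_r_is_fog(self):
        (c,) = self.build(min_gyro=-0.1, env_value=0.667)
        assert c.R < 3
        assert c.label == LABEL_FOG

    def test_tie_at_demarcation_is_regular(self):
        cfg = fg.DetectorConfig()
        (c,) = self.build(min_gyro=-0.1, env_value=0.8 / cfg.R_demarcation)
        assert c.R == pytest.approx(cfg.R_demarcation)
        assert c.label == LABEL_REGULAR


def _fake_classification(start_s, end_s, label):
    w = StepWindow(int(start_s * FS), int(end_s * FS),
                   (start_s + end_s) / 2, 0.5, -0.1)
    r = None if label == LABEL_STANCE else (5.0 if label == LABEL_REGULAR else 1.0)
    return StepClassification(w, r, label, start_s, end_s)


class TestAggregateEpisodes:
    def test_no_fog_no_episodes(self, cfg):
        clas = [_fake_classification(i, i + 0.2, LABEL_REGULAR) for i in range(5)]
        assert aggregate_episodes(clas, cfg.detector) == []

    def test_single_run(self, cfg):
        clas = [_fake_classification(0.3 * i, 0.3 * i + 0.2, LABEL_FOG)
                for i in range(5)]
        eps = aggregate_episodes(clas, cfg.detector)
        assert len(eps) == 1
        assert eps[0].start_s == 0.0
        assert eps[0].end_s == pytest.approx(1.4)

    def test_gap_splits_runs(self, cfg):
        clas = [_fake_classification(0.3 * i, 0.3 * i + 0.2, LABEL_FOG)
                for i in range(3)]
        clas += [_fake_classification(3.0 + 0.3 * i, 3.2 + 0.3 * i, LABEL_FOG)
                 for i in range(3)]
        assert len(aggregate_episodes(clas, cfg.detector)) == 2

    def test_min_windows_filter(self, cfg):
        clas = [_fake_classification(0.0, 0.2, LABEL_FOG)]
        assert aggregate_episodes(clas, cfg.detector) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_gap_partition_oracle(self, seed, cfg):
        rng = np.random.default_rng(seed)
        t = 0.0
        clas = []
        for _ in range(40):
            t += rng.uniform(0.05, 2.0)
            dur = rng.uniform(0.1, 0.4)
            label = rng.choice([LABEL_FOG, LABEL_REGULAR, LABEL_STANCE])
            clas.append(_fake_classification(t, t + dur, label))
            t += dur
        got = aggregate_episodes(clas, cfg.detector)
        # oracle: brute-force partition of fog windows by the gap rule
        fog = [c for c in clas if c.label == LABEL_FOG]
        runs, cur = [], []
        for c in fog:
            if cur and c.start_s - cur[-1].end_s > cfg.detector.episode_gap_s:
                runs.append(cur)
                cur = []
            cur.append(c)
        if cur:
            runs.append(cur)
        runs = [r for r in runs if len(r) >= cfg.detector.min_episode_windows]
        assert [(e.start_s, e.end_s) for e in got] == [
            (r[0].start_s, r[-1].end_s) for r in runs
        ]


class TestEvaluateStepLevel:
    def annotations(self):
        return IntervalAnnotationSet(
            [Interval(0.0, 50.0, "regular_gait"), Interval(50.0, 100.0, "shuffling_fog")]
        )

    def test_perfect_labels(self):
        clas = [_fake_classification(t, t + 0.2, LABEL_REGULAR) for t in range(0, 40, 2)]
        clas += [_fake_classification(t, t + 0.2, LABEL_FOG) for t in range(51, 99, 2)]
        c = evaluate_step_level(clas, self.annotations())
        assert c.fp == 0 and c.fn == 0
        assert c.tp == 24 and c.tn == 20

    def test_98_of_100_sensitivity(self):
        clas = [_fake_classification(50.0 + 0.4 * i, 50.2 + 0.4 * i,
                                     LABEL_FOG if i < 98 else LABEL_REGULAR)
                for i in range(100)]
        c = evaluate_step_level(clas, self.annotations())
        assert c.sensitivity == pytest.approx(0.98)

    def test_stance_windows_excluded(self):
        clas = [_fake_classification(10.0, 10.2, LABEL_STANCE)]
        c = evaluate_step_level(clas, self.annotations())
        assert c.tp == c.fp == c.tn == c.fn == c.unassigned == 0

    def test_outside_annotation_counts_unassigned(self):
        clas = [_fake_classification(200.0, 200.2, LABEL_FOG)]
        c = evaluate_step_level(clas, self.annotations())
        assert c.unassigned == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_independent_recount(self, seed):
        rng = np.random.default_rng(seed)
        ann = self.annotations()
        clas = []
        for _ in range(200):
            t = rng.uniform(0, 110)
            label = rng.choice([LABEL_FOG, LABEL_REGULAR, LABEL_STANCE])
            clas.append(_fake_classification(t, t + 0.1, label))
        c = evaluate_step_level(clas, ann)
        tp = fp = tn = fn = un = 0
        for cl in clas:
            if cl.label == LABEL_STANCE:
                continue
            mid = cl.window.t_max_abs
            if 50.0 <= mid < 100.0:
                tp += cl.label == LABEL_FOG
                fn += cl.label == LABEL_REGULAR
            elif 0.0 <= mid < 50.0:
                fp += cl.label == LABEL_FOG
                tn += cl.label == LABEL_REGULAR
            else:
                un += 1
        assert (c.tp, c.fp, c.tn, c.fn, c.unassigned) == (tp, fp, tn, fn, un)


class TestOnSyntheticGait:
    def test_rest_only_session_has_no_windows(self, cfg):
        script = fg.GaitScript([fg.SegmentSpec("rest", 10.0)], seed=3)
        session = fg.generate_session(script)
        per_side = detect_session(session, cfg)
        assert all(len(v) == 0 for v in per_side.values())

    def test_regular_gait_has_zero_fog_labels(self, cfg):
        session = fg.generate_session(fg.regular_walk_script(5, walk_s=24.0))
        per_side = detect_session(session, cfg)
        labels = [c.label for clas in per_side.values() for c in clas]
        assert labels.count(LABEL_FOG) == 0
        assert labels.count(LABEL_REGULAR) > 0
        assert labels.count(LABEL_STANCE) > 0

    def test_r_is_scale_free(self, cfg):
        session = fg.generate_session(fg.mixed_fog_script(2, 6.0, 4.0))
        r1 = [c.R for c in detect_session(session, cfg)[Side.RIGHT]
              if c.R is not None]
        for tr in session.traces.values():
            if tr.channel is Channel.GYRO_Z:
                tr.values *= 7.5
        session.meta["gyro_full_scale_dps"] *= 7.5
        r2 = [c.R for c in detect_session(session, cfg)[Side.RIGHT]
              if c.R is not None]
        np.testing.assert_allclose(r1, r2, rtol=1e-9)


class TestStreaming:
    @pytest.mark.parametrize("chunk", [1, 7, 64, 100000])
    def test_streaming_equals_offline_on_same_normalized_input(self, cfg, chunk):
        rng = np.random.default_rng(11)
        a, g = random_abs_pair(rng, n=2000)
        env = np.clip(np.abs(np.convolve(rng.normal(size=2000),
                                         np.ones(20) / 20, "same")), 0, 1)
        abs_tr, gs = traces_from(a, g)
        envelope = make_trace(env, channel=Channel.SEMG_ENVELOPE)
        wins = detect_step_windows(abs_tr, gs, cfg.detector)
        offline = classify_windows(wins, gs, abs_tr, envelope, cfg.detector)
        det = StreamingDetector(cfg=cfg.detector, fs=FS)
        streamed = []
        for i in range(0, 2000, chunk):
            streamed.extend(det.process(a[i:i + chunk], g[i:i + chunk],
                                        env[i:i + chunk]))
        assert len(streamed) == len(offline)
        for s, o in zip(streamed, offline):
            assert (s.window.start_idx, s.window.end_idx) == (
                o.window.start_idx, o.window.end_idx)
            assert s.label == o.label
            if o.R is not None:
                assert abs(s.R - o.R) < 1e-9

    def test_streaming_pipeline_matches_offline_normalization_aside(self, cfg):
        session = fg.generate_session(fg.mixed_fog_script(4, 8.0, 6.0))
        offline = detect_session(session, cfg)
        streamed = detect_session_streaming(session, cfg, chunk_s=0.25)
        for side in offline:
            # calibration prefix covers the regular walk, so the constants
            # coincide with the full-recording maximum and windows agree
            assert [c.label for c in streamed[side]] == [
                c.label for c in offline[side]]
            for s, o in zip(streamed[side], offline[side]):
                if o.R is not None:
                    assert abs(s.R - o.R) < 1e-9

    def test_mismatched_chunks_rejected(self, cfg):
        det = StreamingDetector(cfg=cfg.detector, fs=FS)
        with pytest.raises(ContractViolation):
            det.process([0.1, 0.2], [0.1], [0.5, 0.5])
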