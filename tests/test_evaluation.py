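import numpy as np
import pytest

from gaitcue import (
    FogEpisode,
    MotionPhase,
    PulseTrain,
    ValidationError,
    classification_metrics,
    cueing_coverage,
    delay_stats,
    gait_report,
    label_detected,
    match_phases,
    mean_percent,
    round_half_up,
)

from _oracles import brute_force_label, brute_force_match, rasterized_coverage


def _mp(s, e, **kw):
    return MotionPhase(start=s, end=e, **kw)


def _random_disjoint(rng, n, lo=0.0, hi=100.0, max_dur=1.0):
    starts = np.sort(rng.uniform(lo, hi, n))
    out = []
    cursor = lo
    for s in starts:
        s = max(s, cursor + 1e-3)
        e = s + rng.uniform(0.05, max_dur)
        if e >= hi:
            break
        out.append(_mp(round(s, 4), round(e, 4)))
        cursor = e
    return out


class TestMatchPhases:
    def test_worked_example(self):
        annotated = [_mp(1, 2, source="annotated"), _mp(3, 4, source="annotated")]
        detected = [_mp(1.5, 2.5), _mp(1.9, 3.2), _mp(3.3, 3.9)]
        m = match_phases(annotated, detected)
        assert (m.n_correct, m.n_missed, m.n_false) == (2, 0, 1)
        # the spanning detection (1.9, 3.2) is the single false detection
        assert m.false_detections[0].start == 1.9

    def test_identical_lists_all_correct(self):
        phases = [_mp(i, i + 0.4) for i in range(5)]
        m = match_phases(phases, phases)
        assert m.n_correct == 5 and m.n_false == 0 and m.n_missed == 0
        d = delay_stats(m)
        assert np.all(d.start_delays == 0) and np.all(d.end_delays == 0)

    def test_empty_detection_all_missed(self):
        annotated = [_mp(i, i + 0.4) for i in range(4)]
        m = match_phases(annotated, [])
        assert m.n_correct == 0 and m.n_missed == 4

    def test_shared_endpoint_is_not_overlap(self):
        m = match_phases([_mp(1.0, 2.0)], [_mp(2.0, 3.0)])
        assert m.n_correct == 0 and m.n_false == 1

    def test_first_exclusive_match_is_kept(self):
        annotated = [_mp(1.0, 2.0)]
        detected = [_mp(1.1, 1.3), _mp(1.5, 1.8)]
        m = match_phases(annotated, detected)
        assert m.n_correct == 1
        assert m.correct[0][1].start == 1.1   # earliest
        assert m.n_false == 0                 # extras are neglected, not false

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValidationError):
            match_phases([_mp(0, 2), _mp(1, 3)], [])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ann = _random_disjoint(rng, rng.integers(0, 15))
            det = _random_disjoint(rng, rng.integers(0, 15))
            m = match_phases(ann, det)
            assert (m.n_correct, m.n_missed, m.n_false) == brute_force_match(ann, det)


class TestDelayStats:
    def test_hand_arithmetic(self):
        m = match_phases([_mp(1.0, 2.0, source="annotated")], [_mp(1.05, 2.01)])
        d = delay_stats(m)
        assert d.start_delays[0] == pytest.approx(0.05)
        assert d.end_delays[0] == pytest.approx(0.01)
        assert d.duration_diffs[0] == pytest.approx(-0.04)

    def test_median_of_two(self):
        m = match_phases([_mp(1, 2, source="annotated"), _mp(4, 5, source="annotated")],
                         [_mp(1.02, 2.0), _mp(4.08, 5.0)])
        s = delay_stats(m).summary()
        assert s["start_delay_s"]["median"] == pytest.approx(0.05)

    def test_no_matches_empty(self):
        m = match_phases([_mp(1, 2)], [])
        s = delay_stats(m).summary()
        assert s["n_pairs"] == 0 and np.isnan(s["start_delay_s"]["median"])


class TestCoverage:
    def test_trains_equal_phases(self):
        mps = [_mp(0.0, 0.5), _mp(2.0, 2.5)]
        trains = [PulseTrain(start=0.0, end=0.5), PulseTrain(start=2.0, end=2.5)]
        cov = cueing_coverage(mps, trains, [(0.0, 3.0)])
        assert cov["pct_mp_time_stimulated"] == pytest.approx(100.0)
        assert cov["pct_nonmp_time_stimulated"] == pytest.approx(0.0)

    def test_train_overhang_counts_as_nonmp(self):
        mps = [_mp(0.0, 0.5)]
        trains = [PulseTrain(start=0.0, end=1.0)]
        cov = cueing_coverage(mps, trains, [(0.0, 1.0)])
        assert cov["pct_mp_time_stimulated"] == pytest.approx(100.0)
        assert cov["pct_nonmp_time_stimulated"] == pytest.approx(100.0)

    def test_no_mp_time_reported_as_none(self):
        cov = cueing_coverage([], [PulseTrain(start=0, end=1)], [(0.0, 2.0)])
        assert cov["pct_mp_time_stimulated"] is None

    def test_matches_rasterized_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mps = _random_disjoint(rng, 10, hi=20.0, max_dur=0.5)
            trains = [PulseTrain(start=s.start + 0.01, end=s.end + 0.15)
                      for s in mps[::2]]
            intervals = [(0.0, 10.0), (12.0, 18.0)]
            cov = cueing_coverage(mps, trains, intervals)
            # snap everything to the 1 ms grid for the rasterized reference
            mps_q = [_mp(round(p.start, 3), round(p.end, 3)) for p in mps]
            trains_q = [PulseTrain(start=round(t.start, 3), end=round(t.end, 3))
                        for t in trains]
            cov_q = cueing_coverage(mps_q, trains_q, intervals)
            o_mp, o_non = rasterized_coverage(mps_q, trains_q, intervals)
            assert cov_q["pct_mp_time_stimulated"] == pytest.approx(o_mp, abs=0.1)
            assert cov_q["pct_nonmp_time_stimulated"] == pytest.approx(o_non, abs=0.1)
            # 1 ms re-quantization moves coverage by < 0.1 pp
            assert cov["pct_mp_time_stimulated"] == pytest.approx(
                cov_q["pct_mp_time_stimulated"], abs=0.1)


class TestLabeling:
    def test_end_inside_episode_is_fog(self):
        eps = [FogEpisode(start=1.0, end=2.0)]
        assert label_detected([_mp(0.5, 1.5)], eps) == ["fog"]

    def test_end_after_episode_is_normal(self):
        eps = [FogEpisode(start=1.0, end=2.0)]
        assert label_detected([_mp(1.5, 2.5)], eps) == ["normal"]

    def test_episode_start_inclusive_end_exclusive(self):
        eps = [FogEpisode(start=1.0, end=2.0)]
        assert label_detected([_mp(0.5, 1.0)], eps) == ["fog"]
        assert label_detected([_mp(1.5, 2.0)], eps) == ["normal"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        phases = _random_disjoint(rng, 1000, hi=2000.0)
        eps = [FogEpisode(start=p.start, end=p.end, subtype="shuffling")
               for p in _random_disjoint(rng, 50, hi=2000.0, max_dur=10.0)]
        assert label_detected(phases, eps) == brute_force_label(phases, eps)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = ["fog", "normal", "fog", "normal"]
        m = classification_metrics(y, y)
        assert (m["sensitivity"], m["specificity"], m["accuracy"]) == (100, 100, 100)

    def test_hand_arithmetic(self):
        truth = ["fog"] * 10 + ["normal"] * 10
        pred = (["fog"] * 8 + ["normal"] * 2) + (["fog"] * 4 + ["normal"] * 6)
        m = classification_metrics(pred, truth)
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(60.0)
        assert m["accuracy"] == pytest.approx(70.0)
        assert m["confusion"] == {"tp": 8, "fn": 2, "tn": 6, "fp": 4}

    def test_all_normal_predictor(self):
        m = classification_metrics(["normal"] * 4, ["fog", "normal", "fog", "normal"])
        assert m["sensitivity"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics([], [])


class TestGaitReport:
    def test_empty_session(self):
        rep = gait_report([], [], duration_s=10.0)
        assert rep.n_mps == rep.n_fog_mps == rep.n_cued_mps == 0
        assert rep.cueing_s == 0.0

    def test_counting(self):
        phases = ([_mp(i, i + 0.4, class_label="fog") for i in range(3)]
                  + [_mp(i, i + 0.4, class_label="normal") for i in range(3, 10)])
        trains = [PulseTrain(start=p.start, end=p.end) for p in phases[:5]]
        rep = gait_report(phases, trains, duration_s=20.0)
        assert rep.n_mps == 10 and rep.n_fog_mps == 3 and rep.n_cued_mps == 5
        assert rep.cueing_s == pytest.approx(2.0)
        assert rep.percent_cueing_active == pytest.approx(10.0)
        assert rep.percent_fog == pytest.approx(30.0)

    def test_train_at_phase_end_counts_as_cued(self):
        phases = [_mp(1.0, 1.4, class_label="fog")]
        trains = [PulseTrain(start=1.4, end=1.6)]
        rep = gait_report(phases, trains, duration_s=5.0)
        assert rep.n_cued_mps == 1


class TestRounding:
    @pytest.mark.parametrize("num,den,want", [
        (283, 301, 94.0), (18, 301, 6.0), (162, 170, 95.3), (8, 170, 4.7),
    ])
    def test_printed_rate_style(self, num, den, want):
        assert round_half_up(100.0 * num / den) == want

    def test_half_up_not_bankers(self):
        assert round_half_up(52.55) == 52.6
        assert round_half_up(52.45) == 52.5

    def test_mean_percent(self):
        assert mean_percent([61.2, 43.9]) == 52.6
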