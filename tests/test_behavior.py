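import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from engramkit import (
    EpochSet, FreezingLabels, PosthocParams, classify_freezing_online,
    classify_freezing_posthoc, compute_speeds, freezing_metrics,
)
from conftest import make_track


class TestSpeeds:
    def test_stationary_track_zero_speed(self):
        sm = compute_speeds(make_track(np.zeros(10)))
        assert np.all(sm.speeds == 0)

    @pytest.mark.parametrize("step,rate,expected", [
        (0.1, 15.0, 1.5),          # 0.1 cm per frame at 15 Hz
        (0.5, 30.0, 15.0),         # diagonal (0.3, 0.4) step at 30 Hz
    ])
    def test_constant_step_speed(self, step, rate, expected):
        sm = compute_speeds(make_track(np.full(10, step), frame_rate=rate))
        assert sm.speeds[0] == pytest.approx(0)
        assert np.allclose(sm.speeds[1:], expected)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_speeds(make_track([0.0]))


class TestOnline:
    def test_all_immobile_every_frame_freezing(self):
        sm = compute_speeds(make_track(np.zeros(20)))
        labels = classify_freezing_online(sm, min_immobile_parts=7)
        assert labels.per_frame.all()

    def test_six_of_ten_parts_distinguishes_criteria(self):
        """Exactly 6 immobile parts: freezing under the 6-part rule only."""
        track = make_track(np.zeros(20))
        pos = track.positions.copy()
        # parts 6..9 step 0.1 cm/frame -> 1.5 cm/s, mobile; parts 0..5 still
        pos[:, 6:, 0] += 0.1 * np.arange(20)[:, None]
        track.positions = pos
        sm = compute_speeds(track)
        frz6 = classify_freezing_online(sm, min_immobile_parts=6)
        frz7 = classify_freezing_online(sm, min_immobile_parts=7)
        assert frz6.per_frame[1:].all()
        assert not frz7.per_frame[1:].any()

    def test_all_mobile_never_freezing(self):
        sm = compute_speeds(make_track(np.full(20, 1.0 / 15)))  # 1.0 cm/s
        for parts in (6, 7):
            labels = classify_freezing_online(sm, min_immobile_parts=parts)
            assert not labels.per_frame[1:].any()

    def test_lower_min_parts_never_shrinks_freezing(self, rng):
        speeds = compute_speeds(make_track(rng.uniform(0, 0.1, 200), jitter=0.02, rng=rng))
        frz6 = classify_freezing_online(speeds, min_immobile_parts=6)
        frz7 = classify_freezing_online(speeds, min_immobile_parts=7)
        assert np.all(frz6.per_frame >= frz7.per_frame)


class TestPosthoc:
    def test_stationary_track_is_one_bout(self):
        track = make_track(np.zeros(300), frame_rate=30.0)
        labels = classify_freezing_posthoc(track)
        assert labels.per_frame.all()
        assert len(labels.bouts) == 1

    def test_fast_track_has_no_bouts(self):
        track = make_track(np.full(300, 5.0 / 30), frame_rate=30.0)  # 5 cm/s
        labels = classify_freezing_posthoc(track)
        assert not labels.per_frame.any()

    def test_short_still_interval_rejected_by_min_duration(self):
        # 0.4 s of stillness (12 frames at 30 Hz) flanked by fast motion
        steps = np.full(300, 5.0 / 30)
        steps[150:162] = 0.0
        track = make_track(steps, frame_rate=30.0)
        labels = classify_freezing_posthoc(track)
        assert not labels.per_frame.any()

    def test_track_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            classify_freezing_posthoc(make_track(np.zeros(10), frame_rate=30.0))

    def test_translation_invariance(self, rng):
        steps = rng.uniform(0, 0.3, 300)
        track = make_track(steps, frame_rate=30.0, jitter=0.05, rng=rng)
        shifted = make_track(steps, frame_rate=30.0)
        shifted.positions = track.positions + np.array([123.4, -56.7])
        a = classify_freezing_posthoc(track)
        b = classify_freezing_posthoc(shifted)
        assert np.array_equal(a.per_frame, b.per_frame)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            PosthocParams(count_threshold=40, window_width=32)
        with pytest.raises(ValueError):
            PosthocParams(velocity_threshold=-1)


class TestLabelsAndMetrics:
    def test_bouts_match_per_frame_exactly(self, rng):
        per_frame = rng.random(500) < 0.3
        labels = FreezingLabels(per_frame, 15.0)
        assert np.array_equal(labels.bouts.mask(15.0, 500), per_frame)

    def test_always_frozen_all_epochs_100(self):
        labels = FreezingLabels(np.ones(600, bool), 15.0)
        eps = EpochSet([("ON", 0, 10), ("OFF", 10, 20), ("ON", 20, 30), ("OFF", 30, 40)])
        rep = freezing_metrics(labels, eps)
        assert all(r[3] == pytest.approx(100.0) for r in rep.per_epoch)
        assert rep.delta == pytest.approx(0.0)

    def test_frozen_only_during_on_gives_delta_100(self):
        rate, n = 10.0, 400
        eps = EpochSet([("ON", 0, 10), ("OFF", 10, 20), ("ON", 20, 30), ("OFF", 30, 40)])
        per_frame = eps.select("ON").mask(rate, n)
        rep = freezing_metrics(FreezingLabels(per_frame, rate), eps)
        assert rep.delta == pytest.approx(100.0)

    def test_half_on_quarter_off_gives_delta_25(self):
        rate, n = 10.0, 400
        frozen = EpochSet([("f", 0, 5), ("f", 20, 25),      # half of each ON
                           ("f", 10, 12.5), ("f", 30, 32.5)])  # quarter of each OFF
        per_frame = frozen.mask(rate, n)
        eps = EpochSet([("ON", 0, 10), ("OFF", 10, 20), ("ON", 20, 30), ("OFF", 30, 40)])
        rep = freezing_metrics(FreezingLabels(per_frame, rate), eps)
        assert rep.delta == pytest.approx(25.0)

    def test_zero_length_epoch_rejected(self):
        labels = FreezingLabels(np.ones(600, bool), 15.0)
        with pytest.raises(ValueError):
            freezing_metrics(labels, EpochSet([("ON", 5, 5)]))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2 ** 31 - 1))
def test_online_monotone_in_min_parts(seed):
    """The frame set can only grow as the immobile-part requirement drops."""
    rng = np.random.default_rng(seed)
    speeds = compute_speeds(make_track(rng.uniform(0, 0.08, 100), jitter=0.03, rng=rng))
    prev = None
    for parts in range(10, 0, -1):
        cur = classify_freezing_online(speeds, min_immobile_parts=parts).per_frame
        if prev is not None:
            assert np.all(cur >= prev)
        prev = cur
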