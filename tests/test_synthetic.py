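import numpy as np
import pytest

from engramkit import (
    EpochSet, GroundTruth, SessionSpec, generate_behavior, generate_experiment,
    generate_registration, generate_session, generate_traces,
)
from engramkit.behavior import classify_freezing_online, compute_speeds
from engramkit.synthetic import BACKGROUND, plant_membership


class TestBehaviorGeneration:
    def test_seeded_determinism(self):
        spec = SessionSpec(duration_s=60.0, shock_onsets_s=(), seed=5)
        truth = GroundTruth()
        t1, l1 = generate_behavior(spec, truth, seed=5)
        t2, l2 = generate_behavior(spec, truth, seed=5)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(l1.per_frame, l2.per_frame)

    def test_speeds_encode_labels(self):
        """All parts < 0.5 cm/s in frozen frames; all parts above outside."""
        spec = SessionSpec(duration_s=120.0, shock_onsets_s=(), seed=2)
        track, labels = generate_behavior(spec, GroundTruth(), seed=2)
        speeds = compute_speeds(track).speeds[1:]           # frame 0 is 0 by definition
        frozen = labels.per_frame[1:]
        assert np.all(speeds[frozen] < 0.5)
        assert np.all((speeds[~frozen] > 0.5).sum(axis=1) >= 8)

    def test_online_classifier_recovers_generated_labels(self):
        spec = SessionSpec(duration_s=120.0, shock_onsets_s=(), seed=9)
        track, labels = generate_behavior(spec, GroundTruth(), seed=9)
        got = classify_freezing_online(compute_speeds(track))
        assert np.array_equal(got.per_frame[1:], labels.per_frame[1:])

    def test_stationary_freezing_fraction(self):
        """Mean-bout 4 s / inter-bout 16 s -> frozen ~20% of the time."""
        spec = SessionSpec(duration_s=420.0, shock_onsets_s=())
        truth = GroundTruth(freezing_mean_bout_s=4.0, freezing_mean_interbout_s=16.0)
        fracs = [generate_behavior(spec, truth, seed=s)[1].per_frame.mean()
                 for s in range(100)]
        assert np.mean(fracs) == pytest.approx(0.2, rel=0.1)

    def test_zero_bout_mean_never_freezes(self):
        spec = SessionSpec(duration_s=60.0, shock_onsets_s=(), seed=1)
        truth = GroundTruth(freezing_mean_bout_s=0.0)
        _, labels = generate_behavior(spec, truth, seed=1)
        assert not labels.per_frame.any()

    def test_negative_dwell_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(freezing_mean_bout_s=-1.0)
        with pytest.raises(ValueError):
            GroundTruth(freezing_mean_interbout_s=0.0)


class TestTraceGeneration:
    def test_planted_cells_more_active_in_their_epochs(self):
        """In-epoch trace mean exceeds out-epoch mean for >= 95% of seeds."""
        eps = EpochSet([("g", 100, 140)])
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            spec = SessionSpec(duration_s=420.0, n_cells=2, shock_onsets_s=(), seed=seed)
            truth = GroundTruth(planted_membership={0: "g", 1: BACKGROUND})
            trace, _ = generate_traces(spec, truth, eps, seed=seed)
            mask = eps.mask(spec.sample_rate_trace, trace.n_samples)
            if trace.values[0, mask].mean() > trace.values[0, ~mask].mean():
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_missing_epoch_for_planted_group_rejected(self):
        spec = SessionSpec(duration_s=120.0, n_cells=2, shock_onsets_s=())
        truth = GroundTruth(planted_membership={0: "freezing"})
        with pytest.raises(ValueError):
            generate_traces(spec, truth, EpochSet([("other", 0, 10)]), seed=0)

    def test_ground_truth_events_returned(self):
        spec = SessionSpec(duration_s=120.0, n_cells=3, shock_onsets_s=(), seed=4)
        trace, ev = generate_traces(spec, GroundTruth(), EpochSet(), seed=4)
        assert set(ev) == {0, 1, 2}
        for times in ev.values():
            assert np.all((times >= 0) & (times <= 120.0))

    def test_seeded_determinism(self):
        spec = SessionSpec(duration_s=90.0, n_cells=4, shock_onsets_s=(), seed=8)
        a, _ = generate_traces(spec, GroundTruth(), EpochSet(), seed=8)
        b, _ = generate_traces(spec, GroundTruth(), EpochSet(), seed=8)
        assert np.array_equal(a.values, b.values)


class TestRegistration:
    def test_keep_prob_one_is_complete(self):
        reg = generate_registration(50, 1.0, seed=0)
        assert len(reg) == 50 and reg.a_ids == set(range(50))

    def test_keep_prob_zero_is_empty(self):
        assert len(generate_registration(50, 0.0, seed=0)) == 0

    def test_binomial_tracked_count(self):
        counts = [len(generate_registration(100, 0.7, seed=s)) for s in range(1000)]
        assert np.mean(counts) == pytest.approx(70, abs=3)

    def test_per_group_keep_probabilities(self):
        membership = {c: ("g" if c < 50 else BACKGROUND) for c in range(100)}
        counts_g = []
        for s in range(200):
            reg = generate_registration(100, 0.2, seed=s, membership=membership,
                                        keep_prob_by_group={"g": 0.9})
            counts_g.append(len(reg.a_ids & set(range(50))))
        assert np.mean(counts_g) == pytest.approx(45, abs=2)


class TestSessions:
    def test_fc_preset_shapes(self):
        b = generate_session("fc", seed=0)
        assert b.spec.duration_s == 420.0
        assert set(b.condition_epochs) == {"pre-shock", "shock", "freezing", "no-freezing"}
        assert b.traces.n_cells == 90
        assert len(b.positions.cell_ids) == 90

    def test_session_determinism_bytewise(self):
        a = generate_session("fc", seed=3)
        b = generate_session("fc", seed=3)
        assert np.array_equal(a.traces.values, b.traces.values)
        assert np.array_equal(a.track.positions, b.track.positions)
        assert a.truth.planted_membership == b.truth.planted_membership

    def test_planted_groups_disjoint(self):
        mem = plant_membership(90, seed=0)
        groups = {}
        for c, g in mem.items():
            groups.setdefault(g, set()).add(c)
        groups.pop(BACKGROUND)
        all_cells = [c for s in groups.values() for c in s]
        assert len(all_cells) == len(set(all_cells)) == 64

    def test_experiment_links_sessions(self):
        exp = generate_experiment(seed=2)
        a2b = exp.registration.a_to_b()
        # tuned identity carried through the map for freezing conditions
        for a, b in exp.registration.pairs:
            g = exp.fc.truth.planted_membership[a]
            if g in ("freezing", "no-freezing"):
                assert exp.recall.truth.planted_membership[b] == g
        assert exp.recall.preset == "recall"
        assert len(a2b) <= exp.fc.spec.n_cells
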