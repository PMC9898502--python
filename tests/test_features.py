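"""Feature extraction: closed-form examples, rule checks, and equivalence
with the brute-force oracle on randomised simulated sessions."""

import math

import numpy as np
import pytest

from conftest import make_bubble, make_trace, minimal_record, random_small_session
from oracle_features import o_extract_features
from popkin.features import (
    FEATURE_COLUMNS,
    applied_force,
    associate_targets,
    detect_double_touches,
    detect_pops,
    exploration_percentage,
    extract_features,
    features_table,
    popping_accuracy,
    touch_kinematics,
)
from popkin.session import AccelSample, GameConfig
from popkin.simulate import (
    IMPULSE_SIGMA_S,
    AgentProfile,
    simulate_session,
    synthesize_accel,
)


class TestTouchKinematics:
    def test_three_four_five_triangle(self):
        tr = make_trace("T0", [(0, 0), (3, 4)], t0=1.0, dt=0.1)
        k = touch_kinematics(tr)
        assert k.duration_s == pytest.approx(0.1)
        assert k.length_mm == pytest.approx(5.0)
        assert k.velocity_mm_s == pytest.approx(50.0)

    def test_single_sample_has_no_velocity(self):
        k = touch_kinematics(make_trace("T0", [(5, 5)]))
        assert k.duration_s == 0 and k.length_mm == 0
        assert math.isnan(k.velocity_mm_s)

    def test_out_and_back_path_sums_steps(self):
        tr = make_trace("T0", [(0, 0), (3, 4), (0, 0)], t0=1.0, dt=0.1)
        k = touch_kinematics(tr)
        assert k.length_mm == pytest.approx(10.0)
        assert k.velocity_mm_s == pytest.approx(50.0)

    def test_empty_trace_rejected(self):
        from popkin.session import TouchTrace
        with pytest.raises(ValueError):
            touch_kinematics(TouchTrace(touch_id="T0", samples=[]))


class TestDoubleTouches:
    def test_quick_nearby_pair_flagged(self, config):
        traces = [make_trace("T0", [(50, 50)], t0=1.0),
                  make_trace("T1", [(52, 50)], t0=1.1)]
        assert detect_double_touches(traces, config) == [False, True]

    def test_slow_pair_not_flagged(self, config):
        traces = [make_trace("T0", [(50, 50)], t0=1.0),
                  make_trace("T1", [(50, 50)], t0=2.0)]
        assert detect_double_touches(traces, config) == [False, False]

    def test_three_rapid_same_spot_touches_flag_two(self, config):
        traces = [make_trace(f"T{i}", [(50, 50)], t0=1.0 + 0.15 * i)
                  for i in range(3)]
        flags = detect_double_touches(traces, config)
        assert flags == [False, True, True]
        assert sum(flags) / len(flags) == pytest.approx(2 / 3)

    def test_far_apart_fast_pair_not_flagged(self, config):
        traces = [make_trace("T0", [(50, 50)], t0=1.0),
                  make_trace("T1", [(80, 50)], t0=1.1)]
        assert detect_double_touches(traces, config) == [False, False]


class TestDetectPops:
    def test_boundary_inclusive_exclusive(self, config):
        bubble = make_bubble(end_t=10.0)  # center (80, 120) at t=5
        inside = make_trace("T0", [(80 + 18.5, 120.0)], t0=5.0)
        assert len(detect_pops([inside], [bubble], config)) == 1
        outside = make_trace("T0", [(80 + 18.6, 120.0)], t0=5.0)
        assert len(detect_pops([outside], [bubble], config)) == 0

    def test_nearest_of_two_pops_exactly_once(self, config):
        b1 = make_bubble("B1", lane=1, center_x_mm=48.0, end_t=10.0)
        b2 = make_bubble("B2", lane=2, center_x_mm=80.0, end_t=10.0)
        # at t=5 both centers at y=120; touch 10 mm from B2, ~22 from B1
        tr = make_trace("T0", [(70.0, 120.0)], t0=5.0)
        pops = detect_pops([tr], [b1, b2], config)
        assert len(pops) == 1
        assert pops[0].bubble_id == "B2"
        assert pops[0].distance_to_center_mm == pytest.approx(10.0)

    def test_matches_simulator_log(self):
        for seed in range(10):
            rec = random_small_session(seed)
            redone = detect_pops(rec.touches, rec.bubbles, rec.config)
            logged = [(p.touch_id, p.bubble_id) for p in rec.pops]
            assert [(p.touch_id, p.bubble_id) for p in redone] == logged


class TestAssociateTargets:
    def test_three_touches_then_pop_is_one_episode(self, config):
        bubble = make_bubble(end_t=5.4, end_reason="popped")
        traces = [make_trace(f"T{i}", [(80.0, 120.0 + i)], t0=5.0 + 0.2 * i)
                  for i in range(3)]
        eps = associate_targets(traces, [bubble], config)
        assert len(eps) == 1
        assert eps[0].n_touches == 3

    def test_interleaved_bubbles_make_three_episodes(self, config):
        bA = make_bubble("A", lane=1, center_x_mm=48.0, end_t=10.0)
        bB = make_bubble("B", lane=3, center_x_mm=112.0, end_t=10.0)
        xs = [48.0, 48.0, 112.0, 48.0]
        traces = [make_trace(f"T{i}", [(x, 220 - 20 * (1 + 0.3 * i))],
                             t0=1.0 + 0.3 * i) for i, x in enumerate(xs)]
        eps = associate_targets(traces, [bA, bB], config)
        assert [e.bubble_id for e in eps] == ["A", "B", "A"]

    def test_touch_beyond_targeting_radius_unassigned(self, config):
        bubble = make_bubble(end_t=10.0)
        tr = make_trace("T0", [(80.0 + 30.0, 120.0)], t0=5.0)
        assert associate_targets([tr], [bubble], config) == []


class TestPoppingAccuracy:
    def test_inside_disc_is_100(self, config):
        bubble = make_bubble(end_t=10.0)
        tr = make_trace("T0", [(80 + 10.0, 120.0)], t0=5.0)
        prof = popping_accuracy(tr, bubble, config)
        assert prof.per_sample_accuracy == [100.0]

    def test_midpoint_of_decay_is_50(self, config):
        bubble = make_bubble(end_t=10.0)
        tr = make_trace("T0", [(80 + 27.75, 120.0)], t0=5.0)
        prof = popping_accuracy(tr, bubble, config)
        assert prof.per_sample_accuracy[0] == pytest.approx(50.0)

    def test_far_sample_floors_at_zero(self, config):
        bubble = make_bubble(end_t=10.0)
        tr = make_trace("T0", [(80 + 40.0, 120.0)], t0=5.0)
        prof = popping_accuracy(tr, bubble, config)
        assert prof.per_sample_accuracy[0] == 0.0


class TestAppliedForce:
    def test_isolated_spikes_hand_integral(self, config):
        """Three 0.2 m/s^2 single-sample spikes inside a [5, 5.5] s touch:
        the piecewise-linear squared signal integrates to v^2/60 for an
        interior spike and v^2/120 for spikes at the window endpoints."""
        spikes = {300, 315, 330}  # t = 5.0, 5.25, 5.5
        accel = [AccelSample(t=k / 60, ax=0.2 if k in spikes else 0.0,
                             ay=0.0, az=9.81) for k in range(1200)]
        tr = make_trace("T0", [(10, 10), (10, 10.1)], t0=5.0, dt=0.5)
        f = applied_force(tr, accel, config)
        expected = 0.2 ** 2 * (1 / 120 + 1 / 60 + 1 / 120)
        assert f == pytest.approx(expected, rel=1e-9)

    def test_zero_acceleration_gives_zero(self, config):
        accel = [AccelSample(t=k / 60, ax=0, ay=0, az=0) for k in range(1200)]
        tr = make_trace("T0", [(10, 10), (11, 10)], t0=5.0, dt=0.3)
        assert applied_force(tr, accel, config) == 0.0

    def test_synthesized_impulse_matches_analytic_integral(self, config):
        """A Gaussian impulse of peak A and scale s integrates (squared) to
        A^2 * s * sqrt(pi)."""
        profile = AgentProfile(force_scale=1.5, accel_noise_sd=0.0)
        tr = make_trace("T0", [(10, 10)] * 31, t0=10.0)  # covers +-0.25 s
        accel = synthesize_accel([tr], profile, config, seed=0)
        f = applied_force(tr, accel, config)
        expected = 1.5 ** 2 * IMPULSE_SIGMA_S * math.sqrt(math.pi)
        # half the impulse precedes the onset; the touch window captures the
        # second half, and the median filter slightly dents the peak
        assert f == pytest.approx(expected / 2, rel=0.02)

    def test_uncovered_touch_window_raises(self, config):
        accel = [AccelSample(t=k / 60, ax=0, ay=0, az=0) for k in range(60)]
        tr = make_trace("T0", [(10, 10), (11, 10)], t0=10.0, dt=0.3)
        with pytest.raises(ValueError, match="cover"):
            applied_force(tr, accel, config)


class TestExploration:
    def test_counting_distinct_cells(self):
        cfg = GameConfig(screen_width_mm=100, screen_height_mm=100)
        pts = [(5, 5), (15, 5), (25, 5), (35, 5), (45, 5)]
        traces = [make_trace(f"T{i}", [p], t0=1 + i) for i, p in enumerate(pts)]
        assert exploration_percentage(traces, cfg) == pytest.approx(0.05)

    def test_no_touches_zero(self, config):
        assert exploration_percentage([], config) == 0.0

    def test_single_cell(self):
        cfg = GameConfig(screen_width_mm=100, screen_height_mm=100)
        traces = [make_trace("T0", [(5, 5), (6, 6)], t0=1.0)]
        assert exploration_percentage(traces, cfg) == pytest.approx(1 / 100)


class TestExtractFeatures:
    def test_popping_rate_ratio(self):
        rec = random_small_session(1)
        f = extract_features(rec)
        assert f["number_of_touches"] == rec.n_touches
        assert f["number_of_pops"] == len(rec.pops)
        if rec.n_touches:
            assert f["bubble_popping_rate"] == pytest.approx(
                len(rec.pops) / rec.n_touches)

    def test_repeat_and_transition_counting(self, config):
        """Pop sequence (lane2,charA),(lane2,charA),(lane3,charB):
        repeat 1/2, transitions 1."""
        b1 = make_bubble("B1", lane=2, character_id=1, spawn_t=0.0,
                         center_x_mm=80.0, end_t=2.0, end_reason="popped")
        b2 = make_bubble("B2", lane=2, character_id=1, spawn_t=2.5,
                         center_x_mm=80.0, end_t=5.0, end_reason="popped")
        b3 = make_bubble("B3", lane=3, character_id=4, spawn_t=0.0,
                         center_x_mm=112.0, end_t=8.0, end_reason="popped")
        traces = [
            make_trace("T0", [(80.0, b1.y_at(2.0))], t0=2.0),
            make_trace("T1", [(80.0, b2.y_at(5.0))], t0=5.0),
            make_trace("T2", [(112.0, b3.y_at(8.0))], t0=8.0),
        ]
        rec = minimal_record(touches=traces, bubbles=[b1, b2, b3], pops=[])
        rec.pops = detect_pops(traces, rec.bubbles, config)
        assert len(rec.pops) == 3
        f = extract_features(rec)
        assert f["repeat_percentage"] == pytest.approx(0.5)
        assert f["number_of_transitions"] == 1.0

    def test_distance_summaries_hand_arithmetic(self, config):
        b1 = make_bubble("B1", lane=1, center_x_mm=48.0, end_t=4.0,
                         end_reason="popped")
        b2 = make_bubble("B2", lane=3, center_x_mm=112.0, end_t=8.0,
                         end_reason="popped")
        traces = [
            make_trace("T0", [(48.0 + 3.0, b1.y_at(4.0))], t0=4.0),
            make_trace("T1", [(112.0 + 5.0, b2.y_at(8.0))], t0=8.0),
        ]
        rec = minimal_record(touches=traces, bubbles=[b1, b2], pops=[])
        rec.pops = detect_pops(traces, rec.bubbles, config)
        f = extract_features(rec)
        assert f["distance_to_center_mean"] == pytest.approx(4.0)
        assert f["distance_to_center_median"] == pytest.approx(4.0)
        assert f["distance_to_center_std"] == pytest.approx(math.sqrt(2))

    def test_std_features_nan_below_two_observations(self):
        rec = minimal_record()  # one touch, one pop
        f = extract_features(rec)
        assert math.isnan(f["distance_to_center_std"])
        assert math.isnan(f["touch_duration_std"])

    def test_zero_touch_record(self, config):
        rec = minimal_record(touches=[], pops=[])
        f = extract_features(rec)
        assert f["number_of_touches"] == 0
        assert math.isnan(f["bubble_popping_rate"])
        assert f["screen_exploratory_percentage"] == 0.0


class TestOracleEquivalence:
    COUNT_FEATURES = {
        "number_of_touches", "number_of_pops", "number_of_transitions",
        "number_of_targeted_bubbles",
    }

    @pytest.mark.parametrize("seed", range(15))
    def test_features_equal_brute_force(self, seed):
        """Every feature matches an independently coded recomputation."""
        rec = random_small_session(seed)
        ours = extract_features(rec)
        oracle = o_extract_features(rec)
        assert set(ours) == set(oracle) == set(FEATURE_COLUMNS)
        for name in FEATURE_COLUMNS:
            a, b = ours[name], oracle[name]
            if math.isnan(a) or math.isnan(b):
                assert math.isnan(a) and math.isnan(b), name
            elif name in self.COUNT_FEATURES:
                assert a == b, name
            else:
                assert math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-9), (
                    name, a, b)


class TestMonotonicity:
    def test_more_aim_error_hurts_accuracy(self):
        """Raising aim error must not shrink distance-to-center nor raise the
        popping rate (paired seeds, 20-seed averages)."""
        lo = AgentProfile(aim_sd_mm=8.0)
        hi = AgentProfile(aim_sd_mm=16.0)
        stats = {"lo": [], "hi": []}
        for seed in range(20):
            for name, prof in (("lo", lo), ("hi", hi)):
                f = extract_features(simulate_session(prof, 27.0, seed=seed))
                stats[name].append((f["distance_to_center_mean"],
                                    f["bubble_popping_rate"]))
        d_lo, r_lo = np.nanmean(np.array(stats["lo"]), axis=0)
        d_hi, r_hi = np.nanmean(np.array(stats["hi"]), axis=0)
        assert d_hi >= d_lo
        assert r_hi <= r_lo


class TestFeaturesTable:
    def test_rows_and_stable_columns(self):
        recs = [random_small_session(s) for s in range(3)]
        table = features_table(recs)
        assert len(table) == 3
        assert list(table.columns[-len(FEATURE_COLUMNS):]) == FEATURE_COLUMNS

    def test_duplicate_session_id_rejected(self):
        rec = random_small_session(0)
        with pytest.raises(ValueError, match="duplicate"):
            features_table([rec, rec])

    def test_csv_round_trip_preserves_missingness(self, tmp_path):
        import pandas as pd

        table = features_table([random_small_session(s) for s in range(3)])
        p = tmp_path / "f.csv"
        table.to_csv(p, index=False)
        back = pd.read_csv(p)
        for col in FEATURE_COLUMNS:
            assert back[col].isna().equals(table[col].isna())
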