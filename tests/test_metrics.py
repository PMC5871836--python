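import math

import numpy as np
import pytest

from larvataxis.metrics import (BinaryRate, MetricsError, UndefinedIndexError,
                                acceptance_rate, binary_sem,
                                combined_away_steering, compute_report,
                                first_sweep_direction, first_sweep_left_rate,
                                head_sweep_size, mean_run_heading_change,
                                mean_sweep_size_by_outcome, mirror_tracks,
                                navigation_index, run_heading_change, run_speed,
                                steering_magnitude_by_phase, turn_direction,
                                turn_rate, turn_size, turn_size_by_phase,
                                turn_size_delta)
from larvataxis.segmentation import (HeadSweep, Reorientation, Run,
                                     SegmentationParams, segment_track)
from larvataxis.simulator import (AgentParams, SimConfig, simulate_experiment,
                                  straight_track)
from larvataxis.stimulus import DirectionalField, TemporalRamp


def _arena(compass_deg, field=None):
    """Arena-frame heading for a given compass angle (default light angle 180)."""
    la = field.light_angle_deg if field else 180.0
    return compass_deg + la


def _run(start_c, end_c, field, t_start=0.0, t_end=10.0, speed=0.05,
         mean_c=None):
    mean_c = mean_c if mean_c is not None else 0.5 * (start_c + end_c)
    return Run(t_start=t_start, t_end=t_end, i_start=0, i_end=0,
               start_heading=_arena(start_c, field), end_heading=_arena(end_c, field),
               mean_heading=_arena(mean_c, field), path_length_cm=speed * (t_end - t_start),
               mean_speed=speed, mean_velocity=(0.0, 0.0), n_frames=10)


def _turn(prior_c, new_c, field, side="left", t_start=0.0, t_end=1.0,
          outcome="accepted", max_heading_c=None):
    sweeps = [HeadSweep(t_start=t_start, t_end=t_end, side=side, max_bend_deg=40.0,
                        outcome=outcome, ordinal=1,
                        heading_before=_arena(prior_c, field),
                        max_heading=_arena(max_heading_c if max_heading_c is not None
                                           else new_c, field))]
    return Reorientation(t_start=t_start, t_end=t_end, i_start=0, i_end=0,
                         sweeps=sweeps, prior_heading=_arena(prior_c, field),
                         new_heading=_arena(new_c, field))


class TestBinarySem:
    def test_closed_form(self):
        assert binary_sem(50.0, 100) == pytest.approx(5.0)
        assert binary_sem(60.0, 10) == pytest.approx(15.4919, abs=1e-3)

    def test_degenerate(self):
        assert binary_sem(0.0, 10) == 0.0
        assert binary_sem(100.0, 10) == 0.0

    def test_binary_rate(self):
        br = BinaryRate(6, 10)
        assert br.p == pytest.approx(60.0)
        assert br.sem == pytest.approx(math.sqrt(60 * 40) / math.sqrt(10))
        with pytest.raises(MetricsError):
            BinaryRate(11, 10)


class TestNavigationIndex:
    def _straight_runs(self, field, compass_deg_list, seg_params):
        runs = []
        for i, c in enumerate(compass_deg_list):
            tr = straight_track((12, 12), _arena(c, field), 0.05, 30.0,
                                track_id=f"r{i}")
            events = segment_track(tr, seg_params, threshold=0.02)
            runs += [e for e in events if isinstance(e, Run)]
        return runs

    def test_all_toward_is_plus_one(self, field, seg_params):
        runs = self._straight_runs(field, [0, 0, 0], seg_params)
        assert navigation_index(runs, field) == pytest.approx(1.0, abs=1e-12)

    def test_all_away_is_minus_one(self, field, seg_params):
        runs = self._straight_runs(field, [180, 180], seg_params)
        assert navigation_index(runs, field) == pytest.approx(-1.0, abs=1e-12)

    def test_isotropic_is_zero(self, field, seg_params):
        runs = self._straight_runs(field, [0, 90, 180, -90], seg_params)
        assert navigation_index(runs, field) == pytest.approx(0.0, abs=1e-12)

    def test_bounds(self, field, seg_params):
        runs = self._straight_runs(field, [30, -120, 75], seg_params)
        assert -1.0 <= navigation_index(runs, field) <= 1.0

    def test_time_rescale_invariant(self, field, seg_params):
        runs = self._straight_runs(field, [30, -120], seg_params)
        scaled = [Run(r.t_start * 2, r.t_end * 2, r.i_start, r.i_end,
                      r.start_heading, r.end_heading, r.mean_heading,
                      r.path_length_cm, r.mean_speed / 2,
                      (r.mean_velocity[0] / 2, r.mean_velocity[1] / 2), r.n_frames)
                  for r in runs]
        assert navigation_index(scaled, field) == pytest.approx(
            navigation_index(runs, field), abs=1e-9)

    def test_zero_speed_error(self, field):
        r = Run(0, 10, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, (0.0, 0.0), 10)
        with pytest.raises(UndefinedIndexError):
            navigation_index([r], field)


class TestFirstSweepDirection:
    def test_plus90_left_is_away(self, field):
        rate, skipped = first_sweep_direction([_turn(90, 150, field, side="left")], field)
        assert (rate.k, rate.n, skipped) == (1, 1, 0)

    def test_minus90_left_is_toward(self, field):
        rate, _ = first_sweep_direction([_turn(-90, -60, field, side="left")], field)
        assert (rate.k, rate.n) == (0, 1)

    def test_symmetric_is_fifty(self, field):
        events = [_turn(90, 150, field, side=s) for s in ("left", "right")]
        events += [_turn(-90, -150, field, side=s) for s in ("left", "right")]
        rate, _ = first_sweep_direction(events, field)
        assert rate.p == pytest.approx(50.0)

    def test_outside_bins_skipped(self, field):
        rate, skipped = first_sweep_direction([_turn(0, 40, field)], field)
        assert rate.n == 0 and skipped == 1

    def test_half_disks(self, field):
        rate, _ = first_sweep_direction([_turn(30, 90, field, side="left")], field,
                                        bin_mode="half_disks")
        assert (rate.k, rate.n) == (1, 1)
        rate, _ = first_sweep_direction([_turn(-30, -90, field, side="left")], field,
                                        bin_mode="half_disks")
        assert (rate.k, rate.n) == (0, 1)

    def test_accounting_identity(self, field):
        events = [_turn(c, c + 30, field) for c in (0, 45, 90, -90, 170, -20)]
        rate, skipped = first_sweep_direction(events, field)
        assert rate.n + skipped == len(events)


class TestTurnDirection:
    def test_plus_bin_ccw_away(self, field):
        rate, _ = turn_direction([_turn(92, 150, field)], field)
        assert (rate.k, rate.n) == (1, 1)

    def test_minus_bin_cw_away(self, field):
        rate, _ = turn_direction([_turn(-90, -150, field)], field)
        assert (rate.k, rate.n) == (1, 1)

    def test_zero_change_excluded(self, field):
        rate, skipped = turn_direction([_turn(90, 90, field)], field)
        assert rate.n == 0 and skipped == 1

    def test_toward_bin_left_rate(self, field):
        events = [_turn(0, 40, field), _turn(10, -30, field)]
        rate, _ = turn_direction(events, field, prior_bin="toward")
        assert (rate.k, rate.n) == (1, 2)

    def test_first_sweep_left_rate(self, field):
        events = [_turn(0, 40, field, side="left"), _turn(5, -40, field, side="right"),
                  _turn(90, 130, field, side="left")]
        rate, skipped = first_sweep_left_rate(events, field, prior_bin="toward")
        assert (rate.k, rate.n, skipped) == (1, 2, 1)


class TestRunHeadingChange:
    def test_simple(self, field):
        assert run_heading_change(_run(90, 110, field)) == pytest.approx(20.0)

    def test_straight(self, field):
        assert run_heading_change(_run(45, 45, field)) == pytest.approx(0.0)

    def test_wraparound(self, field):
        assert run_heading_change(_run(170, -170, field)) == pytest.approx(20.0)


class TestSteering:
    def test_mean_in_plus90_bin(self, field):
        runs = [_run(90, 100, field, mean_c=95), _run(80, 110, field, mean_c=95)]
        mean, n = mean_run_heading_change(runs, field, "plus90")
        assert mean == pytest.approx(20.0) and n == 2

    def test_mirror_symmetric_combined_zero(self, field):
        runs = [_run(90, 110, field, mean_c=100), _run(90, 70, field, mean_c=80),
                _run(-90, -110, field, mean_c=-100), _run(-90, -70, field, mean_c=-80)]
        mean, n = combined_away_steering(runs, field)
        assert mean == pytest.approx(0.0) and n == 4

    def test_magnitude_by_phase(self, ramp, field):
        runs = [_run(0, 10, field, t_start=5.0, t_end=15.0),
                _run(0, -30, field, t_start=16.0, t_end=24.0)]
        out = steering_magnitude_by_phase(runs, ramp)
        assert out["increase"][0] == pytest.approx(20.0)
        assert out["increase"][1] == 2


class TestAcceptanceRate:
    def _sweep_turn(self, t_start, outcome, field):
        return _turn(90, 130, field, t_start=t_start, t_end=t_start + 0.7,
                     outcome=outcome)

    def test_six_of_ten_in_decrease(self, ramp, field):
        events = []
        # decrease segment of cycle 0 spans (31, 54.5) after margin exclusion
        for i in range(10):
            events.append(self._sweep_turn(32.0 + i, "accepted" if i < 6 else "rejected",
                                           field))
        rates = acceptance_rate(events, ramp)
        assert (rates["decrease"].k, rates["decrease"].n) == (6, 10)
        assert rates["decrease"].p == pytest.approx(60.0)
        assert rates["decrease"].sem == pytest.approx(15.4919, abs=1e-3)

    def test_zero_accepted(self, ramp, field):
        events = [self._sweep_turn(5.0 + i, "rejected", field) for i in range(5)]
        rates = acceptance_rate(events, ramp)
        assert rates["increase"].p == 0.0 and rates["increase"].sem == 0.0

    def test_hold_sweeps_excluded(self, ramp, field):
        events = [self._sweep_turn(27.0, "accepted", field)]  # inside the high hold
        rates = acceptance_rate(events, ramp)
        assert rates["increase"].n == 0 and rates["decrease"].n == 0

    def test_truncated_excluded(self, ramp, field):
        events = [self._sweep_turn(10.0, "truncated", field)]
        rates = acceptance_rate(events, ramp)
        assert rates["increase"].n == 0


class TestTurnSize:
    def test_simple(self, field):
        assert turn_size(_turn(10, 70, field)) == pytest.approx(60.0)

    def test_delta_zero_for_identical(self, ramp, field):
        events = [_turn(0, 50, field, t_start=10.0), _turn(0, 50, field, t_start=40.0)]
        assert turn_size_delta(events, ramp) == pytest.approx(0.0)

    def test_delta_arithmetic(self, ramp, field):
        events = [_turn(0, 80, field, t_start=10.0), _turn(0, 50, field, t_start=40.0)]
        by = turn_size_by_phase(events, ramp)
        assert by["increase"][0] == pytest.approx(80.0)
        assert by["decrease"][0] == pytest.approx(50.0)
        assert turn_size_delta(events, ramp) == pytest.approx(30.0)

    def test_bounds(self, field):
        for prior, new in ((0, 179), (0, -179), (10, 200)):
            assert 0.0 <= turn_size(_turn(prior, new, field)) <= 180.0


class TestTurnRate:
    def test_arithmetic(self, ramp, field):
        # 3 tracks spanning the whole protocol; 12 turns in increase phases
        tracks = [straight_track((2, 5 + i), 0.0, 0.01, ramp.total_s - 1.0,
                                 track_id=f"tr{i}") for i in range(3)]
        events = [_turn(90, 130, field, t_start=5.0 + k * ramp.period_s)
                  for k in range(11)] + [_turn(90, 130, field, t_start=10.0)]
        rate = turn_rate(events, tracks, ramp, "increase")
        phase_min = 11 * (ramp.t_ramp_s - 2.0) / 60.0
        assert rate == pytest.approx(12 / phase_min / 3, rel=0.02)

    def test_zero_turns(self, ramp, field):
        tracks = [straight_track((2, 5), 0.0, 0.01, 300.0)]
        assert turn_rate([], tracks, ramp, "increase") == 0.0


class TestHeadSweepSize:
    def test_simple(self, field):
        turn = _turn(0, 35, field, max_heading_c=35)
        assert head_sweep_size(turn.sweeps[0]) == pytest.approx(35.0)

    def test_no_head_movement(self, field):
        turn = _turn(0, 0, field, max_heading_c=0)
        assert head_sweep_size(turn.sweeps[0]) == pytest.approx(0.0)

    def test_pooled_by_outcome(self, field):
        events = [_turn(0, 30, field, outcome="accepted", max_heading_c=30),
                  _turn(0, 20, field, outcome="rejected", max_heading_c=20)]
        out = mean_sweep_size_by_outcome(events)
        assert out["accepted"] == (pytest.approx(30.0), 1)
        assert out["rejected"] == (pytest.approx(20.0), 1)


class TestRunSpeed:
    def test_simple(self):
        r = Run(0, 30, 0, 0, 0, 0, 0, path_length_cm=2.0, mean_speed=2 / 30,
                mean_velocity=(0, 0), n_frames=390)
        assert run_speed(r) == pytest.approx(0.0667, abs=1e-4)

    def test_agent_speed_recovered(self, seg_params, clean_agent_params, field):
        cfg = SimConfig(n_agents=3, duration_s=300.0, stimulus=field, seed=5)
        tracks, _ = simulate_experiment(cfg, clean_agent_params)
        runs = []
        for tr in tracks:
            runs += [e for e in segment_track(tr, seg_params) if isinstance(e, Run)]
        mean = np.mean([run_speed(r) for r in runs])
        assert mean == pytest.approx(4.0 / 60.0, rel=0.05)


class TestMirrorSymmetry:
    def test_mirrored_metrics(self, seg_params, field):
        params = AgentParams(spatial_dir_gain=0.002, steer_gain=15.0)
        cfg = SimConfig(n_agents=6, duration_s=400.0, stimulus=field, seed=11)
        tracks, _ = simulate_experiment(cfg, params)
        mirrored = mirror_tracks(tracks, field)

        def analyze(trs):
            evs = [segment_track(t, seg_params) for t in trs]
            return compute_report(trs, evs, field)

        a, b = analyze(tracks), analyze(mirrored)
        assert b.navigation_index == pytest.approx(a.navigation_index, abs=1e-6)
        # away-rate and away-steering are chirality-free
        assert b.first_sweep_away.k == a.first_sweep_away.k
        assert b.first_sweep_away.n == a.first_sweep_away.n
        assert b.steering_away[0] == pytest.approx(a.steering_away[0], abs=1e-6)
        # signed per-bin steering swaps and negates
        assert b.steering_plus90[0] == pytest.approx(-a.steering_minus90[0], abs=1e-6)
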