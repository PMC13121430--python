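"""Success-criteria evaluation for the three surgical sub-tasks."""

import numpy as np
import pandas as pd
import pytest

from podosim.fixtures import TrajectoryProfile, script_trajectory
from podosim.tasks import (
    AttemptResult,
    CutRecord,
    PierceEvent,
    RemovalEvent,
    TaskCriteria,
    angle_to_plane,
    evaluate_cut_removal_attempt,
    evaluate_elevation_attempt,
    evaluate_injection_attempt,
    find_ready_exit,
    record_cut,
    run_trial,
    strip_severed,
)
from taskcases import chain_cuts, injection_rows, make_trajectory, removal_event


class TestAngleConvention:
    @pytest.mark.parametrize(
        "axis, expected",
        [([0, 1, 0], 90.0), ([1, 0, 0], 0.0), ([1, 1, 0], 45.0), ([0, -1, 0], 90.0)],
    )
    def test_angle_to_plane_acute(self, axis, expected):
        assert angle_to_plane(axis, [0, 1, 0]) == pytest.approx(expected)


class TestInjection:
    def test_four_good_insertions_pass(self, toe_frame):
        traj = make_trajectory(
            injection_rows(toe_frame, sorted(toe_frame.injection_sites), angle_deg=80.0)
        )
        result = evaluate_injection_attempt(traj, toe_frame)
        assert result.passed and result.reason == "ok"

    def test_shallow_angle_fails(self, toe_frame):
        traj = make_trajectory(
            injection_rows(toe_frame, sorted(toe_frame.injection_sites), angle_deg=60.0)
        )
        result = evaluate_injection_attempt(traj, toe_frame)
        assert not result.passed and result.reason == "angle"

    def test_three_sites_fail(self, toe_frame):
        sites = sorted(toe_frame.injection_sites)[:3]
        traj = make_trajectory(injection_rows(toe_frame, sites))
        result = evaluate_injection_attempt(traj, toe_frame)
        assert not result.passed and result.reason == "site_count"

    def test_shallow_depth_does_not_count(self, toe_frame):
        traj = make_trajectory(
            injection_rows(toe_frame, sorted(toe_frame.injection_sites), depth_frac=0.5)
        )
        result = evaluate_injection_attempt(traj, toe_frame)
        assert not result.passed and result.reason == "site_count"

    def test_no_insertion_fails(self, toe_frame):
        rows = [(0.0, "syringe", 0, 50, 0, 0, -1, 0, 0, 0)]
        result = evaluate_injection_attempt(make_trajectory(rows), toe_frame)
        assert not result.passed and result.reason == "no_insertion"

    def test_tightening_depth_fraction_never_flips_fail_to_pass(self, toe_frame):
        traj = make_trajectory(
            injection_rows(toe_frame, sorted(toe_frame.injection_sites), depth_frac=0.82)
        )
        loose = evaluate_injection_attempt(traj, toe_frame, TaskCriteria(depth_fraction=0.8))
        tight = evaluate_injection_attempt(traj, toe_frame, TaskCriteria(depth_fraction=0.9))
        assert loose.passed and not tight.passed


class TestElevation:
    def test_both_volumes_good_angles_pass(self, toe_frame):
        events = [("hyponychium", 75.0), ("eponychium", 88.0)]
        result = evaluate_elevation_attempt(events, toe_frame)
        assert result.passed

    def test_missing_volume_fails(self, toe_frame):
        result = evaluate_elevation_attempt([("hyponychium", 80.0)], toe_frame)
        assert not result.passed and result.reason == "missing_volume"

    def test_bad_angle_fails_even_with_both_pierced(self, toe_frame):
        events = [("hyponychium", 75.0), ("eponychium", 65.0)]
        result = evaluate_elevation_attempt(events, toe_frame)
        assert not result.passed and result.reason == "angle"

    def test_accepts_event_objects(self, toe_frame):
        events = [
            PierceEvent("hyponychium", 80.0, 100.0),
            PierceEvent("eponychium", 82.0, 200.0),
        ]
        assert evaluate_elevation_attempt(events, toe_frame).passed


class TestCutRecords:
    def test_on_nail_good_angle_valid(self, toe_frame):
        pose = toe_frame.nail_world_point(0.0, toe_frame.strip_v0, 0.5)
        axis = toe_frame.nail_normal
        cut = record_cut(pose, axis, toe_frame)
        assert cut.valid and cut.angle_deg == pytest.approx(90.0)

    def test_shallow_angle_invalid(self, toe_frame):
        pose = toe_frame.nail_world_point(0.0, toe_frame.strip_v0, 0.5)
        tilted = np.cos(np.radians(30)) * toe_frame.nail_normal + np.sin(
            np.radians(30)
        ) * toe_frame.nail_u  # 60° to the plane
        cut = record_cut(pose, tilted, toe_frame)
        assert not cut.valid and cut.reason == "angle"
        assert cut.angle_deg == pytest.approx(60.0, abs=1e-6)

    def test_off_nail_invalid(self, toe_frame):
        pose = toe_frame.nail_world_point(0.0, 0.0, 10.0)  # 10 mm above the nail
        cut = record_cut(pose, toe_frame.nail_normal, toe_frame)
        assert not cut.valid and cut.reason == "off_nail"

    def test_angles_always_within_quarter_turn(self, toe_frame, rng):
        for _ in range(50):
            axis = rng.normal(size=3)
            if np.linalg.norm(axis) < 1e-9:
                continue
            cut = record_cut(
                toe_frame.nail_world_point(0, 0, 0.5), axis, toe_frame
            )
            assert 0.0 <= cut.angle_deg <= 90.0


class TestCutRemoval:
    def removal(self, frame, t=10_000.0):
        return removal_event(frame, t)

    def test_three_chained_cuts_plus_removal_pass(self, toe_frame):
        result = evaluate_cut_removal_attempt(
            chain_cuts(toe_frame), self.removal(toe_frame), toe_frame
        )
        assert result.passed

    def test_two_cuts_fail(self, toe_frame):
        cuts = chain_cuts(toe_frame)[:2]
        result = evaluate_cut_removal_attempt(cuts, self.removal(toe_frame), toe_frame)
        assert not result.passed and result.reason == "cut_count"

    def test_no_removal_fails(self, toe_frame):
        result = evaluate_cut_removal_attempt(chain_cuts(toe_frame), None, toe_frame)
        assert not result.passed and result.reason == "not_removed"

    def test_removal_before_any_cut_fails(self, toe_frame):
        result = evaluate_cut_removal_attempt([], self.removal(toe_frame), toe_frame)
        assert not result.passed and result.reason == "premature_removal"

    def test_removal_before_last_cut_fails(self, toe_frame):
        result = evaluate_cut_removal_attempt(
            chain_cuts(toe_frame), self.removal(toe_frame, t=50.0), toe_frame
        )
        assert not result.passed and result.reason == "premature_removal"

    def test_bad_angle_cut_fails_attempt(self, toe_frame):
        cuts = chain_cuts(toe_frame)
        tilted = np.cos(np.radians(40)) * toe_frame.nail_normal + np.sin(
            np.radians(40)
        ) * toe_frame.nail_u
        bad = record_cut(
            toe_frame.nail_world_point(0, toe_frame.strip_v0, 0.5),
            tilted,
            toe_frame,
            t_ms=350.0,
        )
        result = evaluate_cut_removal_attempt(
            cuts + [bad], self.removal(toe_frame), toe_frame
        )
        assert not result.passed and result.reason == "angle"

    def test_disconnected_cuts_do_not_sever(self, toe_frame):
        hu, _ = toe_frame.nail_half_extents
        criteria = TaskCriteria(blade_half_extents=(1.0, 1.0))  # too short to chain
        cuts = [
            record_cut(
                toe_frame.nail_world_point(u, toe_frame.strip_v0, 0.5),
                toe_frame.nail_normal,
                toe_frame,
                criteria,
                t_ms=i * 100.0,
            )
            for i, u in enumerate(np.linspace(-hu + 1, hu - 1, 3))
        ]
        assert not strip_severed(cuts, toe_frame)
        result = evaluate_cut_removal_attempt(
            cuts, self.removal(toe_frame), toe_frame, criteria
        )
        assert not result.passed and result.reason == "not_severed"

    def test_chained_cuts_sever(self, toe_frame):
        assert strip_severed(chain_cuts(toe_frame), toe_frame)


class TestReadyGate:
    def test_hands_below_level_never_ready(self, toe_frame):
        rows = [
            (t, tool, 0.0, 5.0, 0.0, 0, -1, 0, 0, 0)
            for t in (0.0, 100.0, 200.0)
            for tool in ("syringe", "hand")
        ]
        assert find_ready_exit(make_trajectory(rows), toe_frame.ready_height_mm) is None
        result = run_trial("anesthesia", make_trajectory(rows), toe_frame)
        assert not result.passed and result.reason == "no_ready"
        assert result.duration_s is None

    def test_ready_exit_at_first_descent(self, toe_frame):
        rows = []
        for t, y in [(0.0, 40.0), (100.0, 40.0), (200.0, 10.0), (300.0, 10.0)]:
            rows.append((t, "syringe", 0.0, y, 0.0, 0, -1, 0, 0, 0))
            rows.append((t, "hand", 0.0, 40.0, 0.0, 0, -1, 0, 0, 0))
        assert find_ready_exit(
            make_trajectory(rows), toe_frame.ready_height_mm
        ) == pytest.approx(200.0)

    def test_unknown_task_rejected(self, toe_frame):
        with pytest.raises(ValueError):
            run_trial("debridement", make_trajectory([]), toe_frame)


class TestTrialDeterminism:
    def test_same_inputs_same_result(self, toe_frame):
        traj = script_trajectory(
            "anesthesia", toe_frame, TrajectoryProfile.novice(seed=3)
        )
        r1 = run_trial("anesthesia", traj, toe_frame)
        r2 = run_trial("anesthesia", traj, toe_frame)
        assert r1 == r2

    def test_batch_order_preserved(self, toe_frame):
        results = []
        for seed in range(3):
            traj = script_trajectory(
                "elevation", toe_frame, TrajectoryProfile.expert(seed=seed)
            )
            results.append(run_trial("elevation", traj, toe_frame))
        assert [r.task for r in results] == ["elevation"] * 3
        assert all(r.duration_s is not None for r in results)


class TestAttemptResultInvariant:
    def test_pass_requires_ok_reason(self):
        with pytest.raises(ValueError):
            AttemptResult(task="anesthesia", passed=True, reason="angle")
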