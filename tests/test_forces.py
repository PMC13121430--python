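"""Stylus force laws: surface contact, needle model, springs, vibration."""

import numpy as np
import pytest

from podosim.forces import (
    DEFAULT_TOOL_PROPERTIES,
    DEVICE_MAX_FORCE_N,
    ContactStatus,
    NeedleState,
    SpringBinding,
    SurfaceProperties,
    begin_insertion,
    check_pierce,
    clamp_force,
    emit_vibration,
    needle_force,
    perceptually_distinct,
    spring_force,
    surface_contact_force,
)
from podosim.geometry import PlaneCollider


@pytest.fixture()
def plane():
    return PlaneCollider(point=[0, 0, 0], normal=[0, 1, 0])


def _rotation_about(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestSurfaceContact:
    def test_free_side_zero_force(self, plane):
        f, status = surface_contact_force(
            plane, [0, 1, 0], [0, 0, 0], DEFAULT_TOOL_PROPERTIES["syringe"]
        )
        assert status == ContactStatus.FREE
        np.testing.assert_array_equal(f, [0, 0, 0])

    def test_frictionless_elevator_force_along_normal(self, plane):
        # the freer-elevator row has zero static and dynamic friction
        props = DEFAULT_TOOL_PROPERTIES["freer_elevator"]
        f, status = surface_contact_force(plane, [3, -1.0, 7], [0.5, 0, -0.2], props)
        assert status == ContactStatus.CONTACT
        assert f[0] == 0.0 and f[2] == 0.0
        assert f[1] == pytest.approx(props.stiffness * 1.0)

    def test_syringe_pop_through_threshold(self, plane):
        props = DEFAULT_TOOL_PROPERTIES["syringe"]
        threshold = props.pop_through * DEVICE_MAX_FORCE_N  # ≈ 0.112 N
        depth_at_threshold = threshold / props.stiffness
        f, status = surface_contact_force(
            plane, [0, -(depth_at_threshold - 1e-6), 0], [0, 0, 0], props
        )
        assert status == ContactStatus.CONTACT
        f, status = surface_contact_force(
            plane, [0, -(depth_at_threshold + 1e-6), 0], [0, 0, 0], props
        )
        assert status == ContactStatus.POPPED
        np.testing.assert_array_equal(f, [0, 0, 0])

    def test_friction_opposes_tangential_motion(self, plane):
        props = DEFAULT_TOOL_PROPERTIES["english_anvil"]
        f, _ = surface_contact_force(plane, [0, -1.0, 0], [1.0, 0, 0], props)
        assert f[0] < 0  # dynamic friction against +X sliding
        assert abs(f[0]) == pytest.approx(props.dynamic_friction * f[1])

    def test_force_clamped_to_device_max(self, plane):
        props = SurfaceProperties(1.0, 0, 0, 0.0, 0.0)
        f, _ = surface_contact_force(plane, [0, -100.0, 0], [0, 0, 0], props)
        assert np.linalg.norm(f) <= DEVICE_MAX_FORCE_N + 1e-12

    def test_non_unit_normal_rejected(self):
        class BadPlane:
            point = np.zeros(3)
            normal = np.array([0, 2.0, 0])

        with pytest.raises(ValueError):
            surface_contact_force(
                BadPlane(), [0, -1, 0], [0, 0, 0], DEFAULT_TOOL_PROPERTIES["syringe"]
            )

    def test_property_magnitudes_validated(self):
        with pytest.raises(ValueError):
            SurfaceProperties(1.2, 0, 0, 0, 0)


class TestNeedleModel:
    def test_begin_normalizes_direction_and_is_idempotent(self):
        s1 = begin_insertion([0, 0, 0], [0, -2.0, 0])
        s2 = begin_insertion([0, 0, 0], [0, -2.0, 0])
        np.testing.assert_allclose(s1.direction, [0, -1, 0])
        np.testing.assert_array_equal(s1.origin, s2.origin)
        np.testing.assert_array_equal(s1.direction, s2.direction)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            begin_insertion([0, 0, 0], [0, 0, 0])

    def test_rest_on_path_zero_net_force(self):
        state = begin_insertion([0, 0, 0], [0, -1, 0])
        np.testing.assert_array_equal(needle_force(state), [0, 0, 0])

    def test_quasistatic_on_path_below_limit_zero_force(self):
        state = begin_insertion([0, 0, 0], [0, -1, 0])
        state.tip = np.array([0.0, -20.0, 0.0])
        np.testing.assert_allclose(needle_force(state), [0, 0, 0], atol=1e-12)

    def test_viscous_branch_magnitude(self):
        # depth 10 mm, axial speed 1.0 → |F| = b·10·1 = 2.0 opposing insertion
        state = begin_insertion([0, 0, 0], [0, -1, 0])
        state.tip = np.array([0.0, -10.0, 0.0])
        state.velocity = np.array([0.0, -1.0, 0.0])
        f = needle_force(state)
        assert np.linalg.norm(f) == pytest.approx(2.0)
        assert f[1] == pytest.approx(2.0)  # opposes the −Y insertion motion

    def test_stiffness_branch_magnitude(self):
        # depth 35 mm quasi-static → |F| = k1·(35−30) = 3.0 pushing back out
        state = begin_insertion([0, 0, 0], [0, -1, 0])
        state.tip = np.array([0.0, -35.0, 0.0])
        f = needle_force(state)
        assert np.linalg.norm(f) == pytest.approx(3.0)
        assert f[1] > 0  # toward the surface, against −Y insertion

    def test_path_force_restores_toward_axis(self):
        # 1 mm off-axis at depth 5: |F_path| = k2·1·1 = 7.9 along −X
        state = begin_insertion([0, 0, 0], [0, -1, 0])
        state.tip = np.array([1.0, -5.0, 0.0])
        f = needle_force(state)
        assert f[0] == pytest.approx(-7.9)
        assert f[2] == pytest.approx(0.0)

    def test_path_force_quadratic_in_offset(self):
        state = begin_insertion([0, 0, 0], [0, -1, 0])
        state.tip = np.array([2.0, -5.0, 0.0])
        f = needle_force(state)
        assert f[0] == pytest.approx(-7.9 * 2.0 * 2.0)
        state.linear_path_spring = True
        f_lin = needle_force(state)
        assert f_lin[0] == pytest.approx(-7.9 * 2.0)

    def test_as_printed_flips_spring_signs(self):
        state = begin_insertion([0, 0, 0], [0, -1, 0], as_printed=True)
        state.tip = np.array([1.0, -5.0, 0.0])
        f = needle_force(state)
        assert f[0] == pytest.approx(+7.9)

    @pytest.mark.parametrize("angle", [0.3, 1.2, 2.9])
    def test_path_force_symmetric_under_rotation_about_axis(self, angle):
        d = np.array([0.0, -1.0, 0.0])
        state = begin_insertion([0, 0, 0], d)
        state.tip = np.array([1.3, -7.0, 0.4])
        state.velocity = np.array([0.2, -0.5, -0.1])
        f_ref = needle_force(state)
        rot = _rotation_about(d, angle)
        state2 = begin_insertion([0, 0, 0], d)
        state2.tip = rot @ state.tip
        state2.velocity = rot @ state.velocity
        np.testing.assert_allclose(needle_force(state2), rot @ f_ref, atol=1e-9)

    def test_restoring_component_never_points_off_path(self):
        rng = np.random.default_rng(5)
        d = np.array([0.0, -1.0, 0.0])
        for _ in range(50):
            state = begin_insertion([0, 0, 0], d)
            state.tip = rng.normal(0, 8, 3)
            f = needle_force(state)  # zero velocity → pure spring part
            perp = state.depth_vector - np.dot(state.depth_vector, d) * d
            assert np.dot(f - np.dot(f, d) * d, perp) <= 1e-9

    def test_inactive_state_rejected(self):
        state = begin_insertion([0, 0, 0], [0, -1, 0])
        state.active = False
        with pytest.raises(RuntimeError):
            needle_force(state)


class TestSprings:
    def test_zero_at_anchor(self):
        b = SpringBinding(anchor=[1, 2, 3], stiffness=1.5)
        np.testing.assert_array_equal(spring_force(b, [1, 2, 3]), [0, 0, 0])

    def test_hooke_magnitude_toward_anchor(self):
        b = SpringBinding(anchor=[0, 0, 0], stiffness=1.5)
        f = spring_force(b, [2.0, 0, 0])
        assert np.linalg.norm(f) == pytest.approx(3.0)
        assert f[0] < 0  # toward the anchor

    def test_elevation_pierce_displacement(self):
        # k = 2: the 1.815 N pierce force corresponds to 0.9075 mm
        b = SpringBinding(anchor=[0, 0, 0], stiffness=2.0, pierce_threshold_n=1.815)
        f = spring_force(b, [0.9075, 0, 0])
        assert np.linalg.norm(f) == pytest.approx(1.815)

    def test_as_printed_points_away(self):
        b = SpringBinding(anchor=[0, 0, 0], stiffness=2.0, as_printed=True)
        assert spring_force(b, [1.0, 0, 0])[0] > 0

    def test_free_relaxation_contracts_under_damping(self):
        b = SpringBinding(anchor=[0, 0, 0], stiffness=2.0)
        p = np.array([3.0, 0, 0])
        v = np.zeros(3)
        dt, damping = 1.0, 6.0  # overdamped at k = 2 with this timestep
        last = np.linalg.norm(p)
        for _ in range(200):
            f = spring_force(b, p)
            v = (v + f * dt) / (1.0 + damping * dt)
            p = p + v * dt
            assert np.linalg.norm(p) <= last + 1e-12
            last = np.linalg.norm(p)


class TestPierceLatch:
    def test_below_threshold_not_pierced(self):
        b = SpringBinding(anchor=[0, 0, 0], stiffness=2.0, pierce_threshold_n=1.815)
        assert not check_pierce(b, [0.5, 0, 0])  # force 1.0 < 1.815

    def test_at_threshold_pierced(self):
        b = SpringBinding(anchor=[0, 0, 0], stiffness=2.0, pierce_threshold_n=1.815)
        assert check_pierce(b, [0.9075, 0, 0])

    def test_latch_never_reverts_and_force_vanishes(self):
        b = SpringBinding(anchor=[0, 0, 0], stiffness=2.0, pierce_threshold_n=1.815)
        check_pierce(b, [2.0, 0, 0])
        assert b.pierced
        assert check_pierce(b, [0.01, 0, 0])  # tiny displacement: still pierced
        np.testing.assert_array_equal(spring_force(b, [5, 0, 0]), [0, 0, 0])

    def test_missing_threshold_rejected(self):
        b = SpringBinding(anchor=[0, 0, 0], stiffness=2.0)
        with pytest.raises(RuntimeError):
            check_pierce(b, [1, 0, 0])

    def test_exact_boundary_sweep(self):
        # piercing happens exactly when k·‖P−P0‖ reaches the threshold
        for disp in np.linspace(0.85, 0.95, 21):
            b = SpringBinding(anchor=[0, 0, 0], stiffness=2.0, pierce_threshold_n=1.815)
            pierced = check_pierce(b, [disp, 0, 0])
            assert pierced == (2.0 * disp >= 1.815)


class TestVibration:
    def test_ui_confirmation_defaults(self):
        ev = emit_vibration()
        assert (ev.frequency_hz, ev.duration_ms, ev.magnitude) == (200.0, 100.0, 0.25)

    def test_just_noticeable_difference_flag(self):
        assert not perceptually_distinct(0.25, 0.27)  # Δ = 0.02 < 0.045
        assert perceptually_distinct(0.25, 0.30)

    def test_silent_event_valid(self):
        assert emit_vibration(magnitude=0.0).magnitude == 0.0

    def test_out_of_range_magnitude_rejected(self):
        with pytest.raises(ValueError):
            emit_vibration(magnitude=1.5)

    def test_event_appended_to_log(self):
        log = []
        emit_vibration(log=log)
        assert len(log) == 1


class TestClamp:
    def test_overlimit_force_rescaled(self):
        f = clamp_force([10.0, 0, 0])
        assert np.linalg.norm(f) == pytest.approx(DEVICE_MAX_FORCE_N)

    def test_inside_limit_untouched(self):
        np.testing.assert_array_equal(clamp_force([1.0, 1.0, 0]), [1.0, 1.0, 0])
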