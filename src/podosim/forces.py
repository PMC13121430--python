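"""Force laws felt through the haptic stylus.

Four families of forces drive the simulated tools:

* **surface contact** — penalty response against the proxy plane, with
  per-tool stiffness / friction / damping / pop-through magnitudes in
  [0, 1] (the unitless effect style of commercial haptic toolkits),
  bridged to Newtons by a
  device calibration constant;
* **needle insertion** — a piecewise model: viscous resistance
  ``b·‖D‖·v_axial`` while the depth ``‖D‖`` is under the 30 mm limit, a
  stiffness wall ``k1·(‖D‖−30)`` beyond it, plus a restoring path force
  ``k2·(⊥distance)·(D − proj_d D)`` with off-axis damping ``c`` that keeps
  the needle on the line locked at the moment of penetration;
* **Hooke springs** — tissue-pierce bindings, grasp restraint and anvil
  restraint, with an optional pierce threshold that latches once the
  spring magnitude reaches it (1.815 N for the elevation tissue at k=2);
* **vibration events** — 200 Hz / 100 ms tactile confirmations, with a
  0.045 just-noticeable-difference flag between magnitudes.

Positions are mm, velocities mm/ms, forces N.  The device can command at
most 3.3 N; :func:`clamp_force` applies that cap at the command stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEVICE_MAX_FORCE_N",
    "PERCEPTIBLE_VIBRATION_DELTA",
    "SurfaceProperties",
    "DEFAULT_TOOL_PROPERTIES",
    "NeedleState",
    "SpringBinding",
    "VibrationEvent",
    "ContactStatus",
    "clamp_force",
    "surface_contact_force",
    "begin_insertion",
    "needle_force",
    "spring_force",
    "check_pierce",
    "emit_vibration",
    "ForceLog",
]

DEVICE_MAX_FORCE_N = 3.3
PERCEPTIBLE_VIBRATION_DELTA = 0.045


def _unit(v, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{name} must be non-zero")
    return v / n


def clamp_force(force, f_max: float = DEVICE_MAX_FORCE_N) -> np.ndarray:
    """Scale the commanded force down to the device's maximum magnitude."""
    force = np.asarray(force, dtype=np.float64)
    mag = np.linalg.norm(force)
    if mag > f_max > 0:
        return force * (f_max / mag)
    return force


# ---------------------------------------------------------------------------
# Surface contact


@dataclass(frozen=True)
class SurfaceProperties:
    """Unitless tool-to-skin contact magnitudes in [0, 1]."""

    stiffness: float
    static_friction: float
    dynamic_friction: float
    damping: float
    pop_through: float

    def __post_init__(self) -> None:
        for name in (
            "stiffness",
            "static_friction",
            "dynamic_friction",
            "damping",
            "pop_through",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


#: Expert-tuned contact property rows, one per surgical tool.
DEFAULT_TOOL_PROPERTIES: dict[str, SurfaceProperties] = {
    "syringe": SurfaceProperties(0.2, 0.5, 0.35, 0.1, 0.034),
    "freer_elevator": SurfaceProperties(0.2, 0.0, 0.0, 0.1, 0.0),
    "english_anvil": SurfaceProperties(0.2, 0.3, 0.3, 0.1, 0.0),
    "straight_hemostat": SurfaceProperties(0.2, 0.25, 0.25, 0.1, 0.0),
}


class ContactStatus:
    FREE = "free"
    CONTACT = "contact"
    POPPED = "popped"


def surface_contact_force(
    plane,
    tool_point,
    tool_velocity,
    props: SurfaceProperties,
    f_max: float = DEVICE_MAX_FORCE_N,
    device_stiffness: float = 1.0,
    device_damping: float = 1.0,
    slip_speed: float = 1e-3,
) -> tuple[np.ndarray, str]:
    """Penalty contact force against the proxy plane.

    Returns ``(force_N, status)``.  Zero force on the free side of the
    plane.  In contact: normal force = stiffness-scaled penetration depth
    minus damping on the normal velocity; Coulomb friction opposes the
    tangential velocity (static regularization below ``slip_speed``,
    dynamic above).  If ``pop_through`` > 0 and the normal force reaches
    ``pop_through × f_max``, the tool pops through and the force drops to
    zero.  The returned force magnitude is clamped to ``f_max``.

    ``device_stiffness`` (N/mm) and ``device_damping`` (N·ms/mm) bridge
    the unitless property magnitudes to physical units.
    """
    n = np.asarray(plane.normal, dtype=np.float64)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("plane normal must be unit length")
    p = np.asarray(tool_point, dtype=np.float64)
    v = np.asarray(tool_velocity, dtype=np.float64)
    depth = -float(np.dot(p - np.asarray(plane.point, dtype=np.float64), n))
    if depth <= 0:
        return np.zeros(3), ContactStatus.FREE

    v_n = float(np.dot(v, n))
    normal_mag = props.stiffness * device_stiffness * depth
    normal_mag -= props.damping * device_damping * v_n
    normal_mag = max(normal_mag, 0.0)

    if props.pop_through > 0 and normal_mag >= props.pop_through * f_max:
        return np.zeros(3), ContactStatus.POPPED

    force = normal_mag * n
    v_t = v - v_n * n
    speed_t = float(np.linalg.norm(v_t))
    if speed_t > 0:
        if speed_t < slip_speed:  # static: regularized hold
            force -= props.static_friction * normal_mag * (v_t / slip_speed)
        else:
            force -= props.dynamic_friction * normal_mag * (v_t / speed_t)
    return clamp_force(force, f_max), ContactStatus.CONTACT


# ---------------------------------------------------------------------------
# Needle insertion


@dataclass
class NeedleState:
    """Penetration origin, locked direction and current tip kinematics.

    ``b`` (viscous, N·ms/mm²), ``k1`` (over-depth stiffness, N/mm),
    ``k2`` (path spring, N/mm²), ``c`` (off-axis damping, N·ms/mm) and the
    30 mm depth limit are the expert-tuned defaults.
    """

    origin: np.ndarray
    direction: np.ndarray
    tip: np.ndarray = field(default=None)  # type: ignore[assignment]
    velocity: np.ndarray = field(default=None)  # type: ignore[assignment]
    b: float = 0.2
    k1: float = 0.6
    k2: float = 7.9
    c: float = 0.15
    depth_limit_mm: float = 30.0
    active: bool = True
    as_printed: bool = False
    linear_path_spring: bool = False

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.direction = _unit(self.direction, "insertion direction")
        if self.tip is None:
            self.tip = self.origin.copy()
        else:
            self.tip = np.asarray(self.tip, dtype=np.float64)
        if self.velocity is None:
            self.velocity = np.zeros(3)
        else:
            self.velocity = np.asarray(self.velocity, dtype=np.float64)
        for name in ("b", "k1", "k2", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def depth_vector(self) -> np.ndarray:
        """D = tip − origin."""
        return self.tip - self.origin

    @property
    def depth(self) -> float:
        return float(np.linalg.norm(self.depth_vector))

    def path_point(self, t: float) -> np.ndarray:
        """p(t) = origin + direction·t."""
        return self.origin + self.direction * t


def begin_insertion(contact_point, approach_direction, **coeffs) -> NeedleState:
    """Lock the penetration origin and insertion direction for an insertion."""
    return NeedleState(
        origin=np.asarray(contact_point, dtype=np.float64),
        direction=approach_direction,
        **coeffs,
    )


def needle_force(state: NeedleState) -> np.ndarray:
    """Net needle force: penetration resistance plus path restoration.

    Piecewise penetration force: below the depth limit a viscous drag
    ``−b·‖D‖·v_axial`` opposes axial motion; at or beyond the limit a
    stiffness force of magnitude ``k1·(‖D‖ − limit)`` pushes back out.
    The path force is a restoring spring, quadratic in the off-path
    offset as modeled (``linear_path_spring`` switches to plain Hooke),
    with damping ``c`` on the off-axis velocity.  ``as_printed`` flips
    the spring signs to the literal (non-restoring) convention for
    comparison studies.
    """
    if not state.active:
        raise RuntimeError("needle_force on inactive insertion")
    d = state.direction
    D = state.depth_vector
    depth = float(np.linalg.norm(D))
    v = state.velocity
    v_axial = float(np.dot(v, d))
    sign = -1.0 if not state.as_printed else 1.0

    if depth < state.depth_limit_mm:
        f_pen = -state.b * depth * v_axial * d
    else:
        f_pen = sign * state.k1 * (depth - state.depth_limit_mm) * d
        if state.as_printed:
            # as printed: −k1·(‖D‖−30) along the insertion axis
            f_pen = -state.k1 * (depth - state.depth_limit_mm) * d

    perp = D - np.dot(D, d) * d
    perp_dist = float(np.linalg.norm(perp))
    if state.linear_path_spring:
        spring = state.k2 * perp
    else:
        spring = state.k2 * perp_dist * perp
    if not state.as_printed:
        spring = -spring
    v_perp = v - v_axial * d
    f_path = spring - state.c * v_perp
    return f_pen + f_path


# ---------------------------------------------------------------------------
# Hooke spring bindings


@dataclass
class SpringBinding:
    """Anchored Hooke spring, optionally piercing past a force threshold.

    Restores the held point toward the anchor with magnitude k·‖P − P0‖.
    When a pierce threshold is configured, the binding latches ``pierced``
    once the spring magnitude reaches the threshold; a pierced binding
    exerts no further force and never un-pierces within an attempt.
    """

    anchor: np.ndarray
    stiffness: float = 2.0
    pierce_threshold_n: float | None = None
    pierced: bool = False
    as_printed: bool = False

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=np.float64)
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")


def spring_force(binding: SpringBinding, point) -> np.ndarray:
    """Spring force at ``point``: k·‖P−P0‖ directed toward the anchor.

    (The literal printed convention −k·(P0 − P) points *away* from the
    anchor; the restoring orientation is the default, ``as_printed``
    preserves the literal sign.)  A pierced binding returns zero.
    """
    p = np.asarray(point, dtype=np.float64)
    if binding.pierced:
        return np.zeros(3)
    f = binding.stiffness * (binding.anchor - p)
    return -f if binding.as_printed else f


def check_pierce(binding: SpringBinding, point) -> bool:
    """Latch ``pierced`` once the spring magnitude reaches the threshold."""
    if binding.pierce_threshold_n is None:
        raise RuntimeError("binding has no pierce threshold configured")
    if binding.pierced:
        return True
    p = np.asarray(point, dtype=np.float64)
    mag = binding.stiffness * float(np.linalg.norm(p - binding.anchor))
    if mag >= binding.pierce_threshold_n:
        binding.pierced = True
    return binding.pierced


# ---------------------------------------------------------------------------
# Vibration events


@dataclass(frozen=True)
class VibrationEvent:
    frequency_hz: float
    duration_ms: float
    magnitude: float
    timestamp_ms: float = 0.0


def perceptually_distinct(
    magnitude_a: float, magnitude_b: float, jnd: float = PERCEPTIBLE_VIBRATION_DELTA
) -> bool:
    """Whether two vibration magnitudes differ by at least the measured JND."""
    return abs(magnitude_a - magnitude_b) >= jnd


def emit_vibration(
    frequency_hz: float = 200.0,
    duration_ms: float = 100.0,
    magnitude: float = 0.25,
    timestamp_ms: float = 0.0,
    log: list | None = None,
) -> VibrationEvent:
    """Create a vibration event (UI confirmation default: 200 Hz, 100 ms, 0.25)."""
    if not 0.0 <= magnitude <= 1.0:
        raise ValueError("vibration magnitude must lie in [0, 1]")
    event = VibrationEvent(frequency_hz, duration_ms, magnitude, timestamp_ms)
    if log is not None:
        log.append(event)
    return event


# ---------------------------------------------------------------------------
# Force log


class ForceLog:
    """CSV force log: tick, tool, Fx, Fy, Fz, regime tag."""

    COLUMNS = ("tick", "tool", "fx", "fy", "fz", "regime")

    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def append(self, tick: int, tool: str, force, regime: str) -> None:
        f = np.asarray(force, dtype=np.float64)
        self.rows.append((int(tick), tool, float(f[0]), float(f[1]), float(f[2]), regime))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.rows, columns=self.COLUMNS).to_csv(path, index=False)
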