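"""Surgical sub-task state machines and pass/fail evaluation.

Three sub-tasks are scored against explicit success criteria:

* **anesthesia (digital ring block)** — four injections, one per site
  region around the digit, each to at least 80% of the needle length at
  an insertion angle of 70–90° to the skin surface;
* **elevation** — piercing of the soft-tissue bindings at the
  hyponychium and the eponychium, each at 70–90° to the nail plane;
* **cutting & removal** — at least three cuts at ≥70° to the nail plane
  whose footprints, projected onto the nail plane, form a connected
  chain severing the ingrown strip from distal edge to proximal fold,
  followed by a grasp-and-release removal with the hemostat.

Angles are reported as acute angles between the tool axis and the
relevant plane (90° = perpendicular insertion).  Each trial begins with
a ready gesture: both tools raised above a configured virtual height.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, box as shapely_box
from shapely.ops import unary_union

from .forces import SpringBinding, check_pierce
from .trajectory import Trajectory

__all__ = [
    "TASKS",
    "SphereRegion",
    "ToeFrame",
    "TaskCriteria",
    "InsertionEvent",
    "PierceEvent",
    "CutRecord",
    "RemovalEvent",
    "AttemptResult",
    "angle_to_plane",
    "extract_insertions",
    "extract_pierce_events",
    "extract_cuts",
    "extract_removal",
    "evaluate_injection_attempt",
    "evaluate_elevation_attempt",
    "record_cut",
    "evaluate_cut_removal_attempt",
    "strip_severed",
    "find_ready_exit",
    "run_trial",
]

TASKS = ("anesthesia", "elevation", "cutting_removal")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def angle_to_plane(axis, plane_normal) -> float:
    """Acute angle (degrees) between a tool axis and a plane; 90° = normal."""
    a = _unit(axis)
    n = _unit(plane_normal)
    return float(np.degrees(np.arcsin(np.clip(abs(float(np.dot(a, n))), 0.0, 1.0))))


# ---------------------------------------------------------------------------
# Frame & criteria


@dataclass(frozen=True)
class SphereRegion:
    """Named spherical tolerance region (injection site or pierce volume)."""

    name: str
    center: tuple
    radius: float

    def contains(self, point) -> bool:
        return self.distance(point) <= 0.0

    def distance(self, point) -> float:
        p = np.asarray(point, dtype=np.float64)
        return float(np.linalg.norm(p - np.asarray(self.center))) - self.radius


@dataclass
class ToeFrame:
    """Geometric bookkeeping of the toe: nail plane, sites, pierce volumes.

    The nail plane carries an in-plane frame (``nail_u`` along the toe
    axis toward the distal edge, ``nail_v`` lateral toward the ingrown
    side) and half extents; the ingrown strip is the lateral band
    ``v ∈ [strip_v0, hv]``.  ``ellipsoid`` (center, semi-axes) supplies
    local skin normals for the parametric toe; when absent the nail
    normal is used.
    """

    nail_point: np.ndarray
    nail_normal: np.ndarray
    nail_u: np.ndarray
    nail_v: np.ndarray
    nail_half_extents: tuple  # (hu, hv) mm
    strip_v0: float
    injection_sites: dict  # name -> SphereRegion (four of them)
    hyponychium: SphereRegion
    eponychium: SphereRegion
    needle_length_mm: float = 30.0
    ready_height_mm: float = 25.0
    ellipsoid: tuple | None = None  # (center (3,), semi_axes (3,))

    def __post_init__(self) -> None:
        self.nail_point = np.asarray(self.nail_point, dtype=np.float64)
        self.nail_normal = _unit(self.nail_normal)
        self.nail_u = _unit(self.nail_u)
        self.nail_v = _unit(self.nail_v)

    def skin_normal_at(self, point) -> np.ndarray:
        if self.ellipsoid is None:
            return self.nail_normal
        center, semi = self.ellipsoid
        p = np.asarray(point, dtype=np.float64) - np.asarray(center)
        grad = p / np.asarray(semi, dtype=np.float64) ** 2
        n = np.linalg.norm(grad)
        return grad / n if n > 0 else self.nail_normal

    def nail_plane_coords(self, point) -> tuple[float, float]:
        """Project a world point into (u, v) nail-plane coordinates."""
        r = np.asarray(point, dtype=np.float64) - self.nail_point
        return float(np.dot(r, self.nail_u)), float(np.dot(r, self.nail_v))

    def nail_world_point(self, u: float, v: float, height: float = 0.0) -> np.ndarray:
        return (
            self.nail_point
            + u * self.nail_u
            + v * self.nail_v
            + height * self.nail_normal
        )

    def nearest_site(self, point) -> str:
        return min(self.injection_sites.values(), key=lambda s: s.distance(point)).name


@dataclass(frozen=True)
class TaskCriteria:
    """The pass/fail thresholds, all configurable."""

    angle_min_deg: float = 70.0
    angle_max_deg: float = 90.0
    depth_fraction: float = 0.8
    required_sites: int = 4
    min_cuts: int = 3
    pierce_threshold_n: float = 1.815
    pierce_stiffness: float = 2.0
    blade_half_extents: tuple = (4.0, 1.2)  # cut footprint on the nail (mm)
    nail_proximity_mm: float = 5.0  # max tool distance from nail plane for a cut
    grasp_radius_mm: float = 6.0


# ---------------------------------------------------------------------------
# Events & results


@dataclass(frozen=True)
class InsertionEvent:
    site: str
    depth_mm: float
    angle_deg: float
    t_press_ms: float
    t_release_ms: float


@dataclass(frozen=True)
class PierceEvent:
    volume: str
    angle_deg: float
    t_ms: float = 0.0


@dataclass(frozen=True)
class CutRecord:
    """One cut: tool pose, projected mask footprint and the 70° validity rule."""

    position: tuple
    axis: tuple
    center_uv: tuple
    half_extents: tuple
    angle_deg: float
    valid: bool
    reason: str = "ok"
    t_ms: float = 0.0

    def footprint(self) -> Polygon:
        u, v = self.center_uv
        hu, hv = self.half_extents
        return shapely_box(u - hu, v - hv, u + hu, v + hv)


@dataclass(frozen=True)
class RemovalEvent:
    t_press_ms: float
    t_release_ms: float
    position: tuple


@dataclass(frozen=True)
class AttemptResult:
    task: str
    passed: bool
    reason: str
    duration_s: float | None = None
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.passed and self.reason != "ok":
            raise ValueError("passing attempts must have reason 'ok'")

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "passed": self.passed,
            "reason": self.reason,
            "duration_s": self.duration_s,
            "metrics": self.metrics,
        }


# ---------------------------------------------------------------------------
# Event extraction from trajectories


def extract_insertions(
    trajectory: Trajectory,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
    tool: str = "syringe",
) -> list[InsertionEvent]:
    """Syringe btn1 press→release intervals as insertion events.

    The entry pose is the sample at the press; depth is the maximum
    displacement along the locked insertion axis during the hold; the
    angle is measured between the axis and the skin surface at entry;
    the event is assigned to the nearest injection-site region.
    """
    if not trajectory.has_tool(tool):
        return []
    sub = trajectory.for_tool(tool)
    t = sub["t_ms"].to_numpy(dtype=float)
    pos = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    axes = sub[["ax", "ay", "az"]].to_numpy(dtype=float)
    events = []
    for t0, t1 in trajectory.button_intervals(tool, button=1):
        i0 = int(np.searchsorted(t, t0))
        i1 = int(np.searchsorted(t, t1, side="right"))
        entry = pos[i0]
        axis = axes[i0]
        if np.linalg.norm(axis) == 0:
            continue
        direction = _unit(axis)
        depth = float(np.max((pos[i0:i1] - entry) @ direction)) if i1 > i0 else 0.0
        normal = frame.skin_normal_at(entry)
        events.append(
            InsertionEvent(
                site=frame.nearest_site(entry),
                depth_mm=max(depth, 0.0),
                angle_deg=angle_to_plane(direction, normal),
                t_press_ms=t0,
                t_release_ms=t1,
            )
        )
    return events


def extract_pierce_events(
    trajectory: Trajectory,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
    tool: str = "freer_elevator",
) -> list[PierceEvent]:
    """Drive a pierce SpringBinding per volume with the elevator tip.

    A binding anchors where the tip first enters the volume; while inside,
    the spring magnitude grows with displacement from the anchor and the
    binding latches pierced at the force threshold (tip exit before the
    latch re-arms the anchor).  The recorded angle is the tool-axis angle
    to the nail plane at the moment of piercing.
    """
    criteria = criteria or TaskCriteria()
    if not trajectory.has_tool(tool):
        return []
    sub = trajectory.for_tool(tool)
    t = sub["t_ms"].to_numpy(dtype=float)
    pos = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    axes = sub[["ax", "ay", "az"]].to_numpy(dtype=float)
    events = []
    for region in (frame.hyponychium, frame.eponychium):
        binding: SpringBinding | None = None
        for i in range(len(t)):
            inside = region.contains(pos[i])
            if not inside:
                binding = None
                continue
            if binding is None:
                binding = SpringBinding(
                    anchor=pos[i],
                    stiffness=criteria.pierce_stiffness,
                    pierce_threshold_n=criteria.pierce_threshold_n,
                )
            if check_pierce(binding, pos[i]):
                axis = axes[i] if np.linalg.norm(axes[i]) > 0 else frame.nail_normal
                events.append(
                    PierceEvent(
                        volume=region.name,
                        angle_deg=angle_to_plane(axis, frame.nail_normal),
                        t_ms=float(t[i]),
                    )
                )
                break
    return events


def record_cut(
    position,
    axis,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
    t_ms: float = 0.0,
    blade_direction=None,
) -> CutRecord:
    """Instantiate a cut-mask record at the tool pose and judge its validity.

    The mask footprint is an axis-aligned rectangle in nail-plane
    coordinates centered at the projected tool position (the blade's long
    side runs along ``blade_direction``, default the nail ``u`` axis).
    A cut is valid when it lands on the nail and its axis meets the nail
    plane at >= the angle floor.
    """
    criteria = criteria or TaskCriteria()
    p = np.asarray(position, dtype=np.float64)
    angle = angle_to_plane(axis, frame.nail_normal)
    u, v = frame.nail_plane_coords(p)
    hu, hv = frame.nail_half_extents
    height = abs(float(np.dot(p - frame.nail_point, frame.nail_normal)))
    on_nail = (
        abs(u) <= hu + criteria.nail_proximity_mm
        and abs(v) <= hv + criteria.nail_proximity_mm
        and height <= criteria.nail_proximity_mm
    )
    if not on_nail:
        valid, reason = False, "off_nail"
    elif not (criteria.angle_min_deg <= angle <= criteria.angle_max_deg):
        valid, reason = False, "angle"
    else:
        valid, reason = True, "ok"
    return CutRecord(
        position=tuple(float(x) for x in p),
        axis=tuple(float(x) for x in np.asarray(axis, dtype=float)),
        center_uv=(u, v),
        half_extents=tuple(criteria.blade_half_extents),
        angle_deg=angle,
        valid=valid,
        reason=reason,
        t_ms=t_ms,
    )


def extract_cuts(
    trajectory: Trajectory,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
    tool: str = "english_anvil",
) -> list[CutRecord]:
    """One CutRecord per anvil btn1 press (pose sampled at the press)."""
    if not trajectory.has_tool(tool):
        return []
    sub = trajectory.for_tool(tool)
    t = sub["t_ms"].to_numpy(dtype=float)
    pos = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    axes = sub[["ax", "ay", "az"]].to_numpy(dtype=float)
    cuts = []
    for t0, _ in trajectory.button_intervals(tool, button=1):
        i = int(np.searchsorted(t, t0))
        cuts.append(record_cut(pos[i], axes[i], frame, criteria, t_ms=t0))
    return cuts


def extract_removal(
    trajectory: Trajectory,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
    tool: str = "straight_hemostat",
) -> RemovalEvent | None:
    """The first hemostat grasp+release near the ingrown strip, if any."""
    criteria = criteria or TaskCriteria()
    if not trajectory.has_tool(tool):
        return None
    sub = trajectory.for_tool(tool)
    t = sub["t_ms"].to_numpy(dtype=float)
    pos = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    hu, hv = frame.nail_half_extents
    strip_center = frame.nail_world_point(0.0, (frame.strip_v0 + hv) / 2.0)
    for t0, t1 in trajectory.button_intervals(tool, button=1):
        i = int(np.searchsorted(t, t0))
        if np.linalg.norm(pos[i] - strip_center) <= criteria.grasp_radius_mm + hu:
            return RemovalEvent(t0, t1, tuple(float(x) for x in pos[i]))
    return None


# ---------------------------------------------------------------------------
# Evaluators


def evaluate_injection_attempt(
    trajectory: Trajectory,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
    duration_s: float | None = None,
) -> AttemptResult:
    """Digital-block anesthesia: four sites, ≥80% needle depth, 70–90°."""
    criteria = criteria or TaskCriteria()
    events = extract_insertions(trajectory, frame, criteria)
    metrics = {"n_insertions": len(events)}
    if not events:
        return AttemptResult("anesthesia", False, "no_insertion", duration_s, metrics)
    for ev in events:
        if not (criteria.angle_min_deg <= ev.angle_deg <= criteria.angle_max_deg):
            metrics["bad_angle_deg"] = ev.angle_deg
            return AttemptResult("anesthesia", False, "angle", duration_s, metrics)
    min_depth = criteria.depth_fraction * frame.needle_length_mm
    covered = {ev.site for ev in events if ev.depth_mm >= min_depth}
    metrics["sites_covered"] = sorted(covered)
    if len(covered) < criteria.required_sites:
        return AttemptResult("anesthesia", False, "site_count", duration_s, metrics)
    return AttemptResult("anesthesia", True, "ok", duration_s, metrics)


def evaluate_elevation_attempt(
    pierce_events,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
    duration_s: float | None = None,
) -> AttemptResult:
    """Elevation: both volumes pierced at 70–90° to the nail plane."""
    criteria = criteria or TaskCriteria()
    events = [
        ev if isinstance(ev, PierceEvent) else PierceEvent(volume=ev[0], angle_deg=ev[1])
        for ev in pierce_events
    ]
    metrics = {"pierced": [ev.volume for ev in events]}
    for ev in events:
        if not (criteria.angle_min_deg <= ev.angle_deg <= criteria.angle_max_deg):
            metrics["bad_angle_deg"] = ev.angle_deg
            return AttemptResult("elevation", False, "angle", duration_s, metrics)
    pierced = {ev.volume for ev in events}
    if not {frame.hyponychium.name, frame.eponychium.name} <= pierced:
        return AttemptResult("elevation", False, "missing_volume", duration_s, metrics)
    return AttemptResult("elevation", True, "ok", duration_s, metrics)


def strip_severed(cuts, frame: ToeFrame) -> bool:
    """2-D connectivity test: do the valid cut footprints sever the strip?

    Footprints are unioned in nail-plane coordinates and clipped to a
    margin around the nail; the strip counts as severed when one
    connected component of the union touches the distal-edge line, the
    proximal-fold line, and the ingrown-strip polygon.
    """
    valid = [c for c in cuts if c.valid]
    if not valid:
        return False
    hu, hv = frame.nail_half_extents
    margin = 4.0
    nail_region = shapely_box(-hu - margin, -hv - margin, hu + margin, hv + margin)
    union = unary_union([c.footprint() for c in valid]).intersection(nail_region)
    if union.is_empty:
        return False
    distal = LineString([(hu, -hv - margin), (hu, hv + margin)])
    proximal = LineString([(-hu, -hv - margin), (-hu, hv + margin)])
    strip = shapely_box(-hu, frame.strip_v0, hu, hv)
    components = union.geoms if hasattr(union, "geoms") else [union]
    for comp in components:
        if (
            comp.intersects(distal)
            and comp.intersects(proximal)
            and comp.intersects(strip)
        ):
            return True
    return False


def evaluate_cut_removal_attempt(
    cuts,
    removal_event: RemovalEvent | None,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
    duration_s: float | None = None,
) -> AttemptResult:
    """Cutting & removal: ≥3 valid cuts, strip severed, then grasped off."""
    criteria = criteria or TaskCriteria()
    cuts = list(cuts)
    valid = [c for c in cuts if c.valid]
    metrics = {"n_cuts": len(cuts), "n_valid_cuts": len(valid)}

    if removal_event is not None and not cuts:
        return AttemptResult(
            "cutting_removal", False, "premature_removal", duration_s, metrics
        )
    if any(c.reason == "angle" for c in cuts):
        return AttemptResult("cutting_removal", False, "angle", duration_s, metrics)
    if len(valid) < criteria.min_cuts:
        return AttemptResult("cutting_removal", False, "cut_count", duration_s, metrics)
    if not strip_severed(valid, frame):
        return AttemptResult("cutting_removal", False, "not_severed", duration_s, metrics)
    if removal_event is None:
        return AttemptResult("cutting_removal", False, "not_removed", duration_s, metrics)
    last_cut_t = max(c.t_ms for c in valid)
    if removal_event.t_press_ms < last_cut_t:
        return AttemptResult(
            "cutting_removal", False, "premature_removal", duration_s, metrics
        )
    return AttemptResult("cutting_removal", True, "ok", duration_s, metrics)


# ---------------------------------------------------------------------------
# Trial runner


def _device_of(tool: str) -> str:
    """Physical stylus a virtual tool is held in: left hand vs right tool."""
    return "left" if tool in ("hand", "left_hand") else "right"


def find_ready_exit(trajectory: Trajectory, ready_height_mm: float) -> float | None:
    """Time the trial starts: both devices raised above the level, then dropped.

    Device heights (the left virtual hand and whichever tool the right
    stylus holds) are stepwise-interpolated on the merged timeline.  The
    ready phase is the first span with every device above the level; the
    exit (timing origin) is the first instant a device descends again,
    or the ready instant itself if the trajectory ends raised.
    """
    if trajectory.data.empty:
        return None
    t_all = np.unique(trajectory.data["t_ms"].to_numpy(dtype=float))
    df = trajectory.data
    device_col = df["tool"].map(_device_of)
    heights = []
    for _, sub in df.groupby(device_col):
        sub = sub.sort_values("t_ms", kind="stable")
        t_dev = sub["t_ms"].to_numpy(dtype=float)
        y_dev = sub["y_mm"].to_numpy(dtype=float)
        idx = np.clip(np.searchsorted(t_dev, t_all, side="right") - 1, 0, len(t_dev) - 1)
        h = y_dev[idx]
        h[t_all < t_dev[0]] = -np.inf  # device not yet observed
        heights.append(h)
    all_above = np.all(np.vstack(heights) > ready_height_mm, axis=0)
    if not all_above.any():
        return None
    i_ready = int(np.argmax(all_above))
    below_after = np.flatnonzero(~all_above[i_ready:])
    if len(below_after) == 0:
        return float(t_all[i_ready])
    return float(t_all[i_ready + below_after[0]])


def run_trial(
    task: str,
    trajectory: Trajectory,
    frame: ToeFrame,
    criteria: TaskCriteria | None = None,
) -> AttemptResult:
    """Ready-gate a trajectory, dispatch to the task evaluator, time it."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    criteria = criteria or TaskCriteria()
    ready_exit = find_ready_exit(trajectory, frame.ready_height_mm)
    if ready_exit is None:
        return AttemptResult(task, False, "no_ready", None)
    work = trajectory.slice_time(ready_exit)

    if task == "anesthesia":
        events = extract_insertions(work, frame, criteria)
        end_t = max((ev.t_release_ms for ev in events), default=work.t_end)
        result = evaluate_injection_attempt(work, frame, criteria)
    elif task == "elevation":
        pierces = extract_pierce_events(work, frame, criteria)
        end_t = max((ev.t_ms for ev in pierces), default=work.t_end)
        result = evaluate_elevation_attempt(pierces, frame, criteria)
    else:
        cuts = extract_cuts(work, frame, criteria)
        removal = extract_removal(work, frame, criteria)
        end_t = removal.t_release_ms if removal is not None else work.t_end
        result = evaluate_cut_removal_attempt(cuts, removal, frame, criteria)

    if not result.passed:
        end_t = work.t_end
    duration = max(end_t - ready_exit, 0.0) / 1000.0
    metrics = dict(result.metrics)
    metrics["ready_exit_ms"] = ready_exit
    return replace(result, duration_s=duration, metrics=metrics)
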