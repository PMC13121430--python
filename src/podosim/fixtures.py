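"""Deterministic generators for every input the engine needs.

No external dataset ships with the package: the canonical toe is a
parametric ellipsoid (semi-axes 15 × 7.5 × 7.5 mm, long axis X, distal
end at +X) built from a subdivided icosahedron, carrying a labeled
:class:`~podosim.tasks.ToeFrame` (nail patch on the dorsal surface,
digital-ring-block injection sites around the proximal base, pierce
volumes at the hyponychium and eponychium, and the ingrown strip as a
lateral band of the nail).  Scripted expert trajectories satisfy every
task criterion by construction; novice trajectories add seeded
Ornstein–Uhlenbeck positional jitter, Gaussian tool-angle error and
wandering detours.  The sphere-drop scene reproduces the octree query
benchmark: a rigid sphere dropped on a 4,356-vertex terrain proxy,
collided through the plane-collider mapping until it rolls off.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    Octree,
    PlaneCollider,
    TriangleMesh,
    build_octree,
    nearest_triangle,
    update_plane_collider,
)
from .tasks import SphereRegion, ToeFrame
from .trajectory import TRAJECTORY_COLUMNS, Trajectory

__all__ = [
    "TrajectoryProfile",
    "make_icosahedron",
    "subdivide",
    "make_ellipsoid_mesh",
    "make_toe_mesh",
    "SphereDropScene",
    "make_sphere_drop_scene",
    "script_trajectory",
]


# ---------------------------------------------------------------------------
# Meshes


def make_icosahedron(radius: float = 1.0) -> TriangleMesh:
    """Regular icosahedron: 12 vertices, 20 triangles."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    raw = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    verts = raw / np.linalg.norm(raw, axis=1, keepdims=True) * radius
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return TriangleMesh(vertices=verts, triangles=faces)


def subdivide(mesh: TriangleMesh, project_radius: float | None = None) -> TriangleMesh:
    """Midpoint 4-split of every triangle; optionally re-project to a sphere."""
    verts = [tuple(v) for v in mesh.vertices]
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = (np.array(verts[i]) + np.array(verts[j])) / 2.0
            if project_radius is not None:
                m = m / np.linalg.norm(m) * project_radius
            cache[key] = len(verts)
            verts.append(tuple(m))
        return cache[key]

    faces = []
    for a, b, c in mesh.triangles:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
    return TriangleMesh(vertices=np.array(verts), triangles=np.array(faces))


def make_ellipsoid_mesh(semi_axes, subdivision: int = 2) -> TriangleMesh:
    """Unit-sphere subdivision scaled to an ellipsoid."""
    mesh = make_icosahedron(radius=1.0)
    for _ in range(subdivision):
        mesh = subdivide(mesh, project_radius=1.0)
    verts = mesh.vertices * np.asarray(semi_axes, dtype=np.float64)
    return TriangleMesh(vertices=verts, triangles=mesh.triangles)


TOE_SEMI_AXES = (15.0, 7.5, 7.5)


def make_toe_mesh(subdivision: int = 2) -> tuple[TriangleMesh, ToeFrame]:
    """Parametric toe plus its labeled anatomical frame.

    Triangle count grows 4× per subdivision level (base 20).  The frame
    is independent of the resolution: nail patch centered dorsally near
    the distal end, four 3 mm injection-site spheres encircling the
    proximal base (medial/lateral × dorsal/plantar), 2.5 mm pierce
    volumes at the distal nail edge (hyponychium) and proximal nail fold
    (eponychium), and the ingrown strip as the lateral nail band.
    """
    if subdivision < 0:
        raise ValueError("subdivision must be non-negative")
    a, b, c = TOE_SEMI_AXES
    mesh = make_ellipsoid_mesh(TOE_SEMI_AXES, subdivision)

    # nail patch around x = 9 on the dorsal (+Y) surface
    x_nail = 9.0
    y_nail = b * math.sqrt(1.0 - (x_nail / a) ** 2)
    nail_point = np.array([x_nail, y_nail, 0.0])
    normal = np.array([x_nail / a**2, y_nail / b**2, 0.0])
    normal /= np.linalg.norm(normal)
    u = np.array([1.0, 0.0, 0.0]) - np.dot([1.0, 0.0, 0.0], normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)

    hu, hv = 4.0, 4.0
    hypo_center = nail_point + hu * u  # distal nail edge
    epo_center = nail_point - hu * u  # proximal nail fold

    # digital ring block: four sites around the proximal phalanx base
    x_ring = -10.0
    r_ring = b * math.sqrt(1.0 - (x_ring / a) ** 2)
    offset = r_ring / math.sqrt(2.0)
    sites = {}
    for name, (sy, sz) in {
        "medial_dorsal": (+1, +1),
        "medial_plantar": (-1, +1),
        "lateral_dorsal": (+1, -1),
        "lateral_plantar": (-1, -1),
    }.items():
        sites[name] = SphereRegion(
            name=name, center=(x_ring, sy * offset, sz * offset), radius=3.0
        )

    frame = ToeFrame(
        nail_point=nail_point,
        nail_normal=normal,
        nail_u=u,
        nail_v=v,
        nail_half_extents=(hu, hv),
        strip_v0=2.0,
        injection_sites=sites,
        hyponychium=SphereRegion("hyponychium", tuple(hypo_center), 2.5),
        eponychium=SphereRegion("eponychium", tuple(epo_center), 2.5),
        needle_length_mm=30.0,
        ready_height_mm=25.0,
        ellipsoid=(np.zeros(3), np.array(TOE_SEMI_AXES)),
    )
    return mesh, frame


# ---------------------------------------------------------------------------
# Sphere-drop octree benchmark scene


def _heightfield_mesh(n: int = 66, extent: float = 50.0) -> TriangleMesh:
    """n×n terrain grid (n² vertices): gentle +X slope with bumps."""
    xs = np.linspace(-extent, extent, n)
    zs = np.linspace(-extent, extent, n)
    xx, zz = np.meshgrid(xs, zs, indexing="ij")
    yy = -0.15 * xx + 2.0 * np.sin(xx / 8.0) * np.cos(zz / 8.0)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            bq = a + 1
            cq = a + n
            dq = a + n + 1
            faces.append((a, bq, cq))
            faces.append((bq, dq, cq))
    return TriangleMesh(vertices=verts, triangles=np.array(faces, dtype=np.int64))


@dataclass
class SphereDropScene:
    """Rigid sphere dropped on the terrain proxy through the plane collider.

    Deterministic: no randomness anywhere.  ``run(depth)`` integrates the
    sphere at the physics rate, maps the plane collider to the nearest
    triangle each step via an octree of the requested depth, and logs the
    query cost (cells visited + triangles examined) per step until the
    sphere rolls off the mesh.
    """

    mesh: TriangleMesh
    sphere_radius: float = 5.0
    start_position: tuple = (0.0, 30.0, 0.0)
    gravity_mm_per_ms2: float = 9.81e-3
    timestep_ms: float = 1.0
    restitution: float = 0.3

    def run(self, depth: int, max_steps: int = 4000) -> dict:
        tree: Octree = build_octree(self.mesh, depth)
        pos = np.array(self.start_position, dtype=np.float64)
        vel = np.zeros(3)
        lo, hi = self.mesh.bounds()
        collider: PlaneCollider | None = None
        contact_events: list[tuple[int, int]] = []
        query_costs: list[int] = []
        dt = self.timestep_ms
        steps = 0
        for step_i in range(max_steps):
            steps = step_i + 1
            vel[1] -= self.gravity_mm_per_ms2 * dt
            pos = pos + vel * dt
            stats: dict = {}
            tri = nearest_triangle(tree, self.mesh, pos, stats)
            query_costs.append(stats["cells_visited"] + stats["triangles_examined"])
            corners = self.mesh.triangle_corners()[tri]
            centroid = corners.mean(axis=0)
            n = np.cross(corners[1] - corners[0], corners[2] - corners[0])
            n /= np.linalg.norm(n)
            if np.dot(n, pos - centroid) < 0:
                n = -n
            if collider is None:
                collider = PlaneCollider(point=centroid, normal=n)
            else:
                update_plane_collider(collider, (centroid, n), dt)
            dist = collider.signed_distance(pos)
            if dist < self.sphere_radius:
                pos = pos + (self.sphere_radius - dist) * collider.normal
                v_n = float(np.dot(vel, collider.normal))
                if v_n < 0:
                    vel = vel - (1.0 + self.restitution) * v_n * collider.normal
                contact_events.append((step_i, tri))
            if (
                pos[0] > hi[0] + self.sphere_radius
                or pos[0] < lo[0] - self.sphere_radius
                or pos[2] > hi[2] + self.sphere_radius
                or pos[2] < lo[2] - self.sphere_radius
                or pos[1] < lo[1] - 10 * self.sphere_radius
            ):
                break
        return {
            "depth": depth,
            "steps": steps,
            "contact_events": contact_events,
            "query_costs": query_costs,
            "mean_query_cost": float(np.mean(query_costs)) if query_costs else 0.0,
        }

    def depth_sweep(self, depths=range(0, 9), max_steps: int = 4000) -> dict:
        """Per-depth mean query cost table (depth -> mean visited nodes)."""
        return {
            int(d): self.run(int(d), max_steps=max_steps)["mean_query_cost"]
            for d in depths
        }


def make_sphere_drop_scene() -> SphereDropScene:
    """The benchmark scene: a 4,356-vertex terrain proxy and a rigid sphere."""
    mesh = _heightfield_mesh(n=66)
    assert mesh.n_vertices == 4356
    return SphereDropScene(mesh=mesh)


# ---------------------------------------------------------------------------
# Scripted trajectories


@dataclass
class TrajectoryProfile:
    """Behavioral profile of a scripted operator."""

    skill: str
    jitter_mm: float
    angle_sd_deg: float
    dwell_ms: float
    seed: int = 0

    @classmethod
    def expert(cls, seed: int = 0) -> "TrajectoryProfile":
        return cls(skill="expert", jitter_mm=0.2, angle_sd_deg=0.0, dwell_ms=0.0, seed=seed)

    @classmethod
    def novice(cls, seed: int = 0, angle_sd_deg: float = 15.0) -> "TrajectoryProfile":
        return cls(
            skill="novice", jitter_mm=2.0, angle_sd_deg=angle_sd_deg, dwell_ms=400.0, seed=seed
        )


class _Builder:
    """Accumulates per-tick tool samples on a shared clock."""

    def __init__(self, dt_ms: float = 10.0):
        self.dt = dt_ms
        self.t = 0.0
        self.rows: list[tuple] = []

    def emit(self, tool: str, pos, axis, btn1: int = 0, btn2: int = 0) -> None:
        p = np.asarray(pos, dtype=float)
        a = np.asarray(axis, dtype=float)
        self.rows.append(
            (self.t, tool, p[0], p[1], p[2], a[0], a[1], a[2], int(btn1), int(btn2))
        )

    def tick(self) -> None:
        self.t += self.dt

    def move(
        self,
        tool: str,
        start,
        end,
        duration_ms: float,
        axis,
        btn1: int = 0,
        other: tuple | None = None,
    ) -> np.ndarray:
        """Linear move of one tool; optionally hold a second tool in place."""
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        n = max(int(round(duration_ms / self.dt)), 1)
        for k in range(1, n + 1):
            p = start + (end - start) * (k / n)
            self.emit(tool, p, axis, btn1=btn1)
            if other is not None:
                o_tool, o_pos, o_axis = other
                self.emit(o_tool, o_pos, o_axis)
            self.tick()
        return end

    def trajectory(self) -> Trajectory:
        return Trajectory(pd.DataFrame(self.rows, columns=TRAJECTORY_COLUMNS))


def _rotate_axis(axis: np.ndarray, angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``axis`` by ``angle_deg`` about a random perpendicular axis."""
    axis = axis / np.linalg.norm(axis)
    if angle_deg == 0.0:
        return axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    perp1 = np.cross(axis, helper)
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    k = math.cos(phi) * perp1 + math.sin(phi) * perp2
    th = math.radians(angle_deg)
    return axis * math.cos(th) + np.cross(k, axis) * math.sin(th)


def _apply_jitter(
    traj: Trajectory, tools: list[str], jitter_mm: float, rng: np.random.Generator,
    dt_ms: float = 10.0, tau_ms: float = 100.0,
) -> Trajectory:
    """Ornstein–Uhlenbeck positional jitter per tool (stationary SD = jitter)."""
    if jitter_mm <= 0:
        return traj
    df = traj.data.copy()
    alpha = math.exp(-dt_ms / tau_ms)
    sigma = jitter_mm * math.sqrt(1.0 - alpha**2)
    for tool in tools:
        mask = df["tool"] == tool
        n = int(mask.sum())
        if n == 0:
            continue
        noise = np.zeros((n, 3))
        for i in range(1, n):
            noise[i] = alpha * noise[i - 1] + sigma * rng.standard_normal(3)
        df.loc[mask, ["x_mm", "y_mm", "z_mm"]] += noise
    return Trajectory(df)


_RAISED_RIGHT = np.array([30.0, 40.0, 20.0])
_RAISED_LEFT = np.array([-30.0, 40.0, 20.0])
_LEFT_PARK = np.array([-30.0, 15.0, 20.0])
_UP_AXIS = np.array([0.0, -1.0, 0.0])


def _ready_phase(b: _Builder, right_tool: str) -> None:
    n = max(int(round(300.0 / b.dt)), 1)
    for _ in range(n):
        b.emit(right_tool, _RAISED_RIGHT, _UP_AXIS)
        b.emit("hand", _RAISED_LEFT, _UP_AXIS)
        b.tick()


def _wander(b: _Builder, tool: str, pos, rng, dwell_ms: float) -> np.ndarray:
    """Novice detour: drift to a random nearby point, dwelling a random while."""
    if dwell_ms <= 0:
        return np.asarray(pos, dtype=float)
    detour = np.asarray(pos, dtype=float) + rng.uniform(-25.0, 25.0, 3)
    detour[1] = max(detour[1], 5.0)
    duration = float(rng.uniform(0.5, 2.0)) * dwell_ms
    pos = b.move(tool, pos, detour, duration, _UP_AXIS, other=("hand", _LEFT_PARK, _UP_AXIS))
    return pos


def script_trajectory(
    task: str, frame: ToeFrame, profile: TrajectoryProfile, dt_ms: float = 10.0
) -> Trajectory:
    """Scripted attempt for one task under a skill profile.

    Expert profiles satisfy all success criteria by construction
    (correct angles, depths, site coverage, ≥3 chained valid cuts plus a
    removal grasp); novices add seeded angle error, positional jitter
    and wandering.  Every trajectory opens with the raise-above-level
    ready gesture on both hands.
    """
    rng = np.random.default_rng(profile.seed)
    b = _Builder(dt_ms=dt_ms)

    if task == "anesthesia":
        tool = "syringe"
        _ready_phase(b, tool)
        pos = _RAISED_RIGHT
        for name in sorted(frame.injection_sites):
            site = frame.injection_sites[name]
            center = np.asarray(site.center, dtype=float)
            normal = frame.skin_normal_at(center)
            err = abs(rng.normal(0.0, profile.angle_sd_deg)) if profile.angle_sd_deg else 0.0
            direction = _rotate_axis(-normal, err, rng)
            hover = center + 8.0 * normal
            pos = _wander(b, tool, pos, rng, profile.dwell_ms)
            pos = b.move(tool, pos, hover, 400.0, direction, other=("hand", _LEFT_PARK, _UP_AXIS))
            pos = b.move(tool, pos, center, 150.0, direction, other=("hand", _LEFT_PARK, _UP_AXIS))
            depth = 0.85 * frame.needle_length_mm
            inserted = center + depth * direction
            pos = b.move(tool, pos, inserted, 300.0, direction, btn1=1,
                         other=("hand", _LEFT_PARK, _UP_AXIS))
            pos = b.move(tool, pos, center, 300.0, direction, btn1=1,
                         other=("hand", _LEFT_PARK, _UP_AXIS))
            pos = b.move(tool, pos, hover, 150.0, direction, other=("hand", _LEFT_PARK, _UP_AXIS))
        traj = b.trajectory()
        return _apply_jitter(traj, [tool], profile.jitter_mm, rng, dt_ms)

    if task == "elevation":
        tool = "freer_elevator"
        _ready_phase(b, tool)
        pos = _RAISED_RIGHT
        for region in (frame.hyponychium, frame.eponychium):
            center = np.asarray(region.center, dtype=float)
            err = abs(rng.normal(0.0, profile.angle_sd_deg)) if profile.angle_sd_deg else 0.0
            tilted = _rotate_axis(frame.nail_normal, 10.0, rng)  # 80° to the plane
            direction = -_rotate_axis(tilted, err, rng)
            start = center - 6.0 * direction
            pos = _wander(b, tool, pos, rng, profile.dwell_ms)
            pos = b.move(tool, pos, start, 400.0, direction, other=("hand", _LEFT_PARK, _UP_AXIS))
            pos = b.move(tool, pos, center + 1.5 * direction, 500.0, direction,
                         other=("hand", _LEFT_PARK, _UP_AXIS))
            pos = b.move(tool, pos, start, 300.0, direction, other=("hand", _LEFT_PARK, _UP_AXIS))
        traj = b.trajectory()
        return _apply_jitter(traj, [tool], profile.jitter_mm, rng, dt_ms)

    if task == "cutting_removal":
        anvil = "english_anvil"
        _ready_phase(b, anvil)
        pos = _RAISED_RIGHT
        hu, hv = frame.nail_half_extents
        n_cuts = 3
        span = np.linspace(-hu + 1.0, hu - 1.0, n_cuts)
        for u in span:
            target = frame.nail_world_point(float(u), frame.strip_v0, 0.5)
            err = abs(rng.normal(0.0, profile.angle_sd_deg)) if profile.angle_sd_deg else 0.0
            axis = _rotate_axis(-frame.nail_normal, err, rng)
            hover = target + 6.0 * frame.nail_normal
            pos = _wander(b, anvil, pos, rng, profile.dwell_ms)
            pos = b.move(anvil, pos, hover, 300.0, axis, other=("hand", _LEFT_PARK, _UP_AXIS))
            pos = b.move(anvil, pos, target, 200.0, axis, other=("hand", _LEFT_PARK, _UP_AXIS))
            pos = b.move(anvil, pos, target, 100.0, axis, btn1=1,
                         other=("hand", _LEFT_PARK, _UP_AXIS))
            pos = b.move(anvil, pos, hover, 200.0, axis, other=("hand", _LEFT_PARK, _UP_AXIS))
        hemostat = "straight_hemostat"
        strip_center = frame.nail_world_point(0.0, (frame.strip_v0 + hv) / 2.0, 0.5)
        grab_axis = -frame.nail_normal
        pos = b.move(hemostat, pos, strip_center, 400.0, grab_axis,
                     other=("hand", _LEFT_PARK, _UP_AXIS))
        lifted = strip_center + 15.0 * frame.nail_normal + 5.0 * frame.nail_v
        pos = b.move(hemostat, pos, lifted, 400.0, grab_axis, btn1=1,
                     other=("hand", _LEFT_PARK, _UP_AXIS))
        b.move(hemostat, pos, lifted + np.array([0.0, 5.0, 0.0]), 100.0, grab_axis,
               other=("hand", _LEFT_PARK, _UP_AXIS))
        traj = b.trajectory()
        return _apply_jitter(traj, [anvil, hemostat], profile.jitter_mm, rng, dt_ms)

    raise ValueError(f"unknown task {task!r}")
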