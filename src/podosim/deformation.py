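"""Mass-spring-damper skin deformation with inverse-square force dispersal.

On tool contact the force is applied to the three vertices of the touched
triangle and dispersed outward through the vertex adjacency graph under an
inverse-square law of the accumulated rest-space distance from the contact
point.  A vertex relays force to its neighbours only while its own
received magnitude stays above a threshold, which bounds the displaced
region.  Displaced vertices enter an update queue where a restoring spring
plus viscous damping pulls them back to rest at a 1 kHz physics rate;
vertices marginally close to rest are snapped back exactly and dequeued.

Integration is semi-implicit Euler with the damping term evaluated
implicitly, which keeps the default stiff, overdamped parameter set stable
at the 1 ms timestep (see docs/methods.md).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import TriangleMesh, write_obj

__all__ = [
    "DeformationParams",
    "DeformableState",
    "dispersal_weight",
    "apply_contact_force",
    "step",
    "is_settled",
    "affected_vertices",
    "export_snapshot",
    "DeformationLog",
]


@dataclass
class DeformationParams:
    """Tunable constants of the skin model.

    stiffness : restoring spring constant k (force/mm)
    damping : viscous coefficient (force·ms/mm); the default 6.0 is
        overdamped at k = 2 so vertices return to rest without oscillation
    mass : per-vertex mass (force·ms²/mm)
    force_threshold : minimum received force magnitude for a vertex to
        relay force onward (F_min)
    min_dispersal_distance : clamp on the inverse-square distance (d_min, mm)
    settle_tolerance : displacement below which a slow vertex snaps to rest (mm)
    speed_tolerance : speed below which a near-rest vertex snaps (mm/ms)
    timestep_ms : physics step; 1 ms (1 kHz haptic rate)
    """

    stiffness: float = 2.0
    damping: float = 6.0
    mass: float = 1.0
    force_threshold: float = 0.01
    min_dispersal_distance: float = 0.1
    settle_tolerance: float = 0.01
    speed_tolerance: float = 0.01
    timestep_ms: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "stiffness",
            "damping",
            "mass",
            "force_threshold",
            "min_dispersal_distance",
            "settle_tolerance",
            "speed_tolerance",
            "timestep_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.settle_tolerance >= self.min_dispersal_distance:
            raise ValueError("settle_tolerance must be < min_dispersal_distance")


@dataclass
class DeformableState:
    """Mesh plus per-vertex velocities and the active update queue."""

    mesh: TriangleMesh
    params: DeformationParams = field(default_factory=DeformationParams)
    velocities: np.ndarray = field(default=None)  # type: ignore[assignment]
    active: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.mesh.n_vertices
        if self.velocities is None:
            self.velocities = np.zeros((n, 3), dtype=np.float64)
        if self.active is None:
            self.active = np.zeros(n, dtype=bool)

    @property
    def queue(self) -> np.ndarray:
        """Indices of currently displaced vertices, ascending."""
        return np.flatnonzero(self.active)

    def displacements(self) -> np.ndarray:
        return self.mesh.vertices - self.mesh.rest_positions

    def max_displacement(self) -> float:
        if not self.active.any():
            return 0.0
        d = self.displacements()[self.active]
        return float(np.linalg.norm(d, axis=1).max())


def dispersal_weight(distance: float, d_min: float) -> float:
    """Inverse-square dispersal weight 1/max(d, d_min)²; finite everywhere."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / max(distance, d_min) ** 2


def affected_vertices(
    mesh: TriangleMesh,
    contact_triangle: int,
    force_magnitude: float,
    contact_point,
    params: DeformationParams,
) -> dict:
    """Multi-source Dijkstra dispersal: vertex -> accumulated distance (mm).

    Sources are the contact triangle's vertices at their rest-space
    Euclidean distance from the contact point; edges add rest-space edge
    length.  A vertex relays only while its own received force
    (``force_magnitude * dispersal_weight(d)``) is at least F_min.  Since
    the weight decreases monotonically with distance, the gate is a pure
    distance cutoff for non-source vertices.
    """
    if not (0 <= contact_triangle < mesh.n_triangles):
        raise ValueError(f"invalid triangle index {contact_triangle}")
    contact_point = np.asarray(contact_point, dtype=np.float64)
    rest = mesh.rest_positions
    sources = [int(v) for v in mesh.triangles[contact_triangle]]
    dist: dict[int, float] = {}
    pq: list[tuple[float, int]] = []
    for v in sources:
        d0 = float(np.linalg.norm(rest[v] - contact_point))
        if d0 < dist.get(v, np.inf):
            dist[v] = d0
            heapq.heappush(pq, (d0, v))
    source_set = set(sources)
    fmin = params.force_threshold
    dmin = params.min_dispersal_distance
    while pq:
        d, v = heapq.heappop(pq)
        if d > dist.get(v, np.inf):
            continue
        # relay gate: the vertex's own received force must reach F_min
        if force_magnitude * dispersal_weight(d, dmin) < fmin:
            continue
        for u in mesh.vertex_adjacency[v]:
            u = int(u)
            nd = d + float(np.linalg.norm(rest[u] - rest[v]))
            if nd < dist.get(u, np.inf):
                dist[u] = nd
                heapq.heappush(pq, (nd, u))
    # keep sources unconditionally; others only if they actually received
    # force at or above threshold (otherwise they were merely scanned)
    out = {}
    for v, d in dist.items():
        if v in source_set or force_magnitude * dispersal_weight(d, dmin) >= fmin:
            out[v] = d
    return out


def apply_contact_force(
    state: DeformableState,
    contact_triangle: int,
    force,
    contact_point,
) -> DeformableState:
    """Disperse a contact force into vertex impulses and enqueue the vertices.

    Every affected vertex receives the full contact force scaled by the
    inverse-square weight of its accumulated distance, applied as a
    velocity impulse over one physics timestep.  The state is modified in
    place and returned.
    """
    force = np.asarray(force, dtype=np.float64)
    if not np.all(np.isfinite(force)):
        raise ValueError("force must be finite")
    fmag = float(np.linalg.norm(force))
    if fmag == 0.0:
        return state
    params = state.params
    reached = affected_vertices(
        state.mesh, contact_triangle, fmag, contact_point, params
    )
    dt = params.timestep_ms
    scale = dt / params.mass
    for v in sorted(reached):  # fixed order: deterministic accumulation
        w = dispersal_weight(reached[v], params.min_dispersal_distance)
        state.velocities[v] += force * w * scale
        state.active[v] = True
    return state


def step(state: DeformableState, dt_ms: float | None = None) -> DeformableState:
    """Advance every queued vertex one physics tick toward rest.

    Semi-implicit Euler with implicit damping:
        v' = (v - k·x·dt/m) / (1 + c·dt/m),   x' = x + v'·dt
    then snap-and-dequeue vertices within the settle tolerances.
    """
    p = state.params
    dt = p.timestep_ms if dt_ms is None else dt_ms
    if abs(dt - p.timestep_ms) > 1e-12:
        raise ValueError("step must use the configured timestep")
    idx = state.queue
    if len(idx) == 0:
        return state
    x = state.mesh.vertices[idx] - state.mesh.rest_positions[idx]
    v = state.velocities[idx]
    v_new = (v - p.stiffness * x * dt / p.mass) / (1.0 + p.damping * dt / p.mass)
    x_new = x + v_new * dt
    settled = (np.linalg.norm(x_new, axis=1) < p.settle_tolerance) & (
        np.linalg.norm(v_new, axis=1) < p.speed_tolerance
    )
    x_new[settled] = 0.0
    v_new[settled] = 0.0
    state.mesh.vertices[idx] = state.mesh.rest_positions[idx] + x_new
    state.velocities[idx] = v_new
    state.active[idx[settled]] = False
    return state


def is_settled(state: DeformableState) -> bool:
    """True iff the queue is empty and every vertex sits exactly at rest."""
    return (not state.active.any()) and bool(
        np.array_equal(state.mesh.vertices, state.mesh.rest_positions)
    )


def export_snapshot(state: DeformableState, path) -> None:
    """Write the current (deformed) mesh as an OBJ snapshot."""
    write_obj(state.mesh, path)


class DeformationLog:
    """JSONL event log: one record per (tick, vertex, displacement)."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def capture(self, tick: int, state: DeformableState) -> None:
        disp = state.displacements()
        for v in state.queue:
            self.records.append(
                {
                    "tick": int(tick),
                    "vertex": int(v),
                    "displacement_mm": float(np.linalg.norm(disp[v])),
                }
            )

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")
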