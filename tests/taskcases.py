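"""Hand-built task scenarios shared across test modules."""

import numpy as np
import pandas as pd

from podosim.tasks import RemovalEvent, record_cut
from podosim.trajectory import TRAJECTORY_COLUMNS, Trajectory


def make_trajectory(rows):
    return Trajectory(pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS))


def injection_rows(frame, sites, angle_deg=90.0, depth_frac=0.85, t0=0.0):
    """Hand-built syringe insertions: one press/hold/release per site."""
    rows = []
    t = t0
    for name in sites:
        center = np.asarray(frame.injection_sites[name].center, dtype=float)
        normal = frame.skin_normal_at(center)
        # tilt the needle away from the normal by (90 − angle)
        tilt = np.radians(90.0 - angle_deg)
        perp = np.cross(normal, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(normal, [1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        direction = -(np.cos(tilt) * normal - np.sin(tilt) * perp)
        depth = depth_frac * frame.needle_length_mm
        for frac, btn in [(0.0, 0), (0.0, 1), (0.5, 1), (1.0, 1), (0.5, 1), (0.0, 0)]:
            p = center + frac * depth * direction
            rows.append((t, "syringe", *p, *direction, btn, 0))
            t += 50.0
    return rows


def chain_cuts(frame, n=3, t0=0.0, criteria=None):
    """Valid collinear cuts spanning the nail along the severance line."""
    hu, _ = frame.nail_half_extents
    cuts = []
    for i, u in enumerate(np.linspace(-hu + 1, hu - 1, n)):
        pose = frame.nail_world_point(float(u), frame.strip_v0, 0.5)
        cuts.append(
            record_cut(pose, frame.nail_normal, frame, criteria, t_ms=t0 + 100.0 * i)
        )
    return cuts


def removal_event(frame, t=10_000.0):
    """A hemostat grasp+release at the center of the ingrown strip."""
    _, hv = frame.nail_half_extents
    pos = frame.nail_world_point(0.0, (frame.strip_v0 + hv) / 2)
    return RemovalEvent(t, t + 500.0, tuple(pos))
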