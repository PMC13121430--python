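# Methods

`podosim` is a headless re-implementation of the computational core of a
bimanual VR-haptic trainer for ingrown-toenail (paronychia) removal.  It
contains no renderer and talks to no device: tool motion enters as
timestamped pose trajectories, and the engine computes what the haptic
and scoring layers of such a trainer would compute — contact and
insertion forces, skin deformation, task pass/fail marks and skill
metrics.  This note records the models, the parameter choices, the
numerical decisions, and what the synthetic fixtures do and do not show.

Units throughout: millimetres, milliseconds, Newtons; right-handed
coordinates with +Y up.  The physics rate is 1 kHz (1 ms steps), the
haptic-loop rate of the stylus devices being emulated; the simulated
device force ceiling is 3.3 N.

## Plane-proxy collision (geometry)

Tools never collide with the deformable mesh directly.  Each tick the
triangle nearest the tool tip is located and a single infinite plane
collider is mapped onto its position and normal; the plane is the only
object the force laws see.  Re-mapping between adjacent triangles is
interpolated over a 25 ms window — linear in the plane point,
normalized-linear (nlerp) in the normal — to avoid force oscillation
when the nearest triangle flips.  nlerp was chosen over slerp because it
is cheap, monotone in the angle for the small rotations involved, and
its non-constant angular rate is irrelevant over 25 ms.  The plane's
extent is treated as infinite; proximity re-mapping keeps the contact
local.

Nearest-triangle queries go through an octree realized as a fixed-depth
uniform subdivision of the mesh bounding box (8^depth conceptual leaves,
only non-empty buckets stored), with triangles bucketed by centroid.
The index is not rebuilt during deformation on the assumption that
deformed triangles stay within their octant; `rebuild_octree` exists for
cases that violate it.  A naive "search only the query's octant" rule
can return the wrong triangle near octant boundaries, so the query runs
in two phases: (1) find the nearest non-empty Chebyshev ring of leaves
around the query's leaf and score its triangles for a best-distance
bound; (2) re-score every leaf that could contain a triangle within that
bound, padding the search radius by the mesh's maximum centroid-to-corner
distance (a triangle's closest point can be that far from the centroid
it was bucketed under).  Phase 2 makes the query *exact*: it must and
does agree with a brute-force linear scan on every query, with ties
broken toward the lowest triangle index in both paths.  Point-triangle
distance is computed exactly as the minimum of the in-plane projection
(when its barycentric coordinates are interior) and the three edge-segment
distances.

The reported query cost (cells visited + triangles examined) counts the
cells an expanding pointer-based search would touch, not the vectorized
shortcut actually executed, so the depth benchmark reflects the data
structure rather than the implementation trick.

## Skin deformation

The skin is a mass-spring-damper system on the mesh vertices.  A contact
force applied at a point on a triangle is given to that triangle's three
vertices and dispersed outward through the vertex adjacency graph under
an inverse-square law w(d) = 1/max(d, d_min)² of the distance d from the
contact point.  d is accumulated along the propagation frontier
(multi-source shortest-path distance in rest coordinates, seeded at the
three contact vertices with their Euclidean distance to the contact
point).  Each reached vertex receives the full contact force scaled by
w(d) as a velocity impulse over one timestep; a vertex relays onward
only while its own received magnitude is at least F_min, which bounds
the displaced region.  Because w is monotone in d, the gate is a pure
distance cutoff, so the affected set is exactly reproducible by an
exhaustive graph walk — the test suite checks this against an
independent Dijkstra oracle.  An alternative reading — dispersing a
per-vertex *share* of the force rather than the full force scaled by
w — would only rescale the effective F_min; the full-force form matches
the inverse-square description most directly.

Displaced vertices sit in an update queue.  Each tick a restoring spring
of stiffness k toward the rest position plus viscous damping c acts on
every queued vertex; a vertex within ε of rest moving slower than the
speed tolerance is snapped exactly to rest and dequeued, so a settled
mesh is bit-identical to its rest state.  Iteration order is fixed by
vertex index: identical inputs give bit-identical states.

Parameters (all configurable, defaults chosen once):

| parameter | default | units | why |
|---|---|---|---|
| stiffness k | 2.0 | N/mm | matches the elevation-spring stiffness scale used elsewhere in the engine |
| damping c | 6.0 | N·ms/mm | overdamped at k = 2, m = 1, dt = 1 ms (see below) |
| mass m | 1.0 | N·ms²/mm | unit mass; only the ratios matter |
| F_min | 0.01 | N | keeps the displaced patch local (tens of vertices for ~1 N) |
| d_min | 0.1 | mm | caps the inverse-square singularity at contact |
| ε | 0.01 | mm | sub-visual snap distance, < d_min |
| speed tolerance | 0.01 | mm/ms | paired with ε for the settle rule |

Integration is semi-implicit Euler with the damping term evaluated
implicitly: v′ = (v − k·x·dt/m)/(1 + c·dt/m), x′ = x + v′·dt.  Plain
semi-implicit Euler is unstable at this stiffness for any damping large
enough to be overdamped (the update map's spectral radius exceeds 1);
with implicit damping the map's eigenvalues at the defaults are real,
0.63 and 0.23, giving stable, oscillation-free, strictly monotone decay
— displacement peaks one tick after an impulse and then decreases
strictly until the snap.  Relaxation from a 1 N impulse settles in ~10
ticks.

## Haptic force laws

**Surface contact.**  Per-tool contact properties (stiffness, static and
dynamic friction, damping, pop-through) are unitless magnitudes in
[0, 1], in the style of commercial haptic toolkits; the defaults are the
expert-tuned rows for the syringe (0.2, 0.5, 0.35, 0.1, 0.034), freer
elevator (0.2, 0, 0, 0.1, 0), English anvil (0.2, 0.3, 0.3, 0.1, 0) and
straight hemostat (0.2, 0.25, 0.25, 0.1, 0).  The penalty force is
stiffness × penetration depth along the plane normal, minus damping on
the normal velocity, plus Coulomb friction on the tangential velocity
(a regularized static hold below a slip speed, dynamic sliding above) —
the standard proxy model a haptic toolkit would apply.  Unit bridging:
the unitless magnitudes are multiplied by a device calibration constant
(default 1 N/mm stiffness, 1 N·ms/mm damping), configurable.
Pop-through fires when the normal force reaches pop_through × 3.3 N
(zero disables it); a popped contact exerts no force.  The commanded
surface force is clamped to the 3.3 N device maximum.

**Needle insertion.**  At penetration the origin p0 and unit direction d
are locked, defining the path p(t) = p0 + d·t.  With depth vector
D = p_c − p0 the net force is F_pen + F_path.  F_pen is piecewise: for
‖D‖ < 30 mm a viscous drag of magnitude b·‖D‖·v_axial opposing axial
motion (b = 0.2), beyond 30 mm a stiffness wall of magnitude
k1·(‖D‖ − 30) pushing back out (k1 = 0.6).  The 30 is taken as mm —
the plausible scale for an anesthesia needle.  The piecewise law is
implemented verbatim, so with non-zero axial velocity the force is
discontinuous at ‖D‖ = 30; no blending is applied.  F_path restores the
tip toward the path with magnitude k2 × (perpendicular distance) ×
‖D − proj_d D‖ — quadratic in the off-path offset as modeled
(`linear_path_spring` switches to plain Hooke) — minus damping c = 0.15
on the velocity component orthogonal to d.  "Axial velocity" and
"off-axis velocity" are the projections onto and orthogonal to d; the
one-dimensional v_y / (v_x, 0, v_z) notation of the source model is
interpreted in the frame of the insertion axis.  Sign convention: the
literal printed spring expressions point *away* from the anchor/path;
they are implemented as restoring forces (toward anchor/path), which is
what "return to the point of contact" and "maintain the needle on path"
require; an `as_printed` flag preserves the literal signs for
comparison.  The needle model returns the unclamped model force (its
own worked values exceed 3.3 N); the clamp is applied at the
device-command stage by `clamp_force`.

**Springs and piercing.**  Soft-tissue attachment, grasping (k = 1.5)
and anvil restraint use a Hooke spring of magnitude k·‖P − P0‖ toward
the anchor.  The elevation tissue binding (k = 2) latches "pierced" the
moment the spring magnitude reaches 1.815 N — equivalently 0.9075 mm of
displacement — after which it exerts no force and never un-pierces
within an attempt.

**Vibration.**  Tactile confirmations are events (frequency, duration,
magnitude); the UI default is 200 Hz for 100 ms at magnitude 0.25.
Magnitude pairs closer than 0.045 — the measured just-noticeable
difference — are flagged perceptually indistinct.

## Task evaluation

Angles are acute angles between a tool axis and a plane (90° =
perpendicular): the injection angle is measured against the local skin
tangent plane (skin normals come from the analytic ellipsoid of the toe
fixture), the elevation and cutting angles against the nail plane.

*Anesthesia* passes iff each of the four ring-block site regions (3 mm
tolerance spheres) receives at least one insertion reaching ≥ 80% of
the 30 mm needle length, and every insertion angle lies in [70°, 90°];
any out-of-range insertion fails the attempt outright.  Insertions are
the syringe's button-hold intervals; depth is the maximum displacement
along the axis locked at the press; each insertion is assigned to the
nearest site region, and a site must be distinct to count (repeating a
region does not cover another — the stricter of the two possible
readings; the alternative would only relax the site-count check).

*Elevation* passes iff both the hyponychium and eponychium volumes are
pierced at angles in [70°, 90°].  Pierce events are generated by
driving the k = 2 / 1.815 N spring binding with the elevator tip: the
anchor is set at first entry into the volume, and exit before the latch
re-arms it.

*Cutting & removal* passes iff at least three valid cuts (on the nail,
≥ 70°) are recorded, their mask footprints sever the ingrown strip, and
a hemostat grasp-and-release near the strip happens after the last cut.
Since the visual system being emulated only *masks* the cut, severance
is made computable geometrically: cut footprints (rectangles of the
anvil blade's footprint, default 8 × 2.4 mm, configurable) are
projected onto the nail plane and unioned; the strip counts as severed
when one connected component of the union touches the distal-edge line,
the proximal-fold line and the strip polygon — i.e. the cuts chain
across the nail.  Both the cut count and the severance test are
enforced and exposed separately.  Failure reasons are reported in a
fixed precedence: premature_removal, angle, cut_count, not_severed,
not_removed.

Every trial is gated by a ready gesture: both physical styluses (the
left virtual hand and whichever tool the right stylus holds) must rise
above a configured height (default 25 mm); timing runs from the first
descent after the gate to the completing event.  Trials that never gate
are reported as not started (`no_ready`) with undefined duration.

## Skill metrics and statistics

Path length is the summed Euclidean segment length of a tool's samples,
reported in cm, computed on raw samples (no smoothing).  The success
score of an attempt block is the pass fraction.  Improvement across a
block is 100·(first − last)/last — the ratio-to-final convention, under
which halving one's time reads as +100%; the (first − last)/first
alternative is available via a switch.  Group comparisons use Welch's
unequal-variance t-test with Welch–Satterthwaite degrees of freedom and
a one-tailed p-value by default, computable from raw samples or from
printed summary statistics (mean, SD, n).  Per-subject means are the
default aggregation unit for group tests, the conservative choice when
attempts within a subject are correlated.  Plot-data export decimates a
trajectory by a uniform temporal factor, preserving endpoints.

## Adaptive staircase

A 1-up/1-down staircase: the comparison level starts at 0.3 (reference
0.5), steps down on "detected" and up on "not detected", clamped to
[0, 1].  Coarse 0.1 steps run until three reversals; fine 0.025 steps
until twelve further reversals; the step change applies from the
reversal trial onward.  The threshold estimate is the mean of the
fine-phase reversal levels — the conventional estimator for a sawtooth
of this shape; the underlying up/down rule is identical whether the
judgment was "detected" or "stronger than reference".  Simulated
observers carry a threshold, a logistic slope and a seed (slope 0 =
deterministic); for ideal observers with thresholds in [0.03, 0.3] the
estimator recovers the truth within one fine step in well over 90% of
seeded runs.

## Synthetic fixtures: what they show and what they do not

The toe is an ellipsoid (15 × 7.5 × 7.5 mm semi-axes) built by midpoint
subdivision of an icosahedron (triangle count ×4 per level), with the
nail patch on the dorsal surface near the distal end, 3 mm injection
spheres encircling the proximal base at ±45°, and 2.5 mm pierce volumes
at the distal nail edge and proximal fold.  It is a geometric stand-in,
not an anatomical model: it exercises every code path (curved skin
normals, distinct site regions, a planar nail with a lateral strip)
without claiming anatomical fidelity.  Any OBJ/STL mesh can replace it
via configuration.

The sphere-drop benchmark scene is a 66 × 66 height-field terrain proxy
(66² = 4,356 vertices) with a gentle slope and sinusoidal bumps; a 5 mm
rigid sphere falls from a fixed pose, collides through the
plane-collider mapping at 1 kHz, and rolls off — a fully deterministic,
repeatable workload for the octree depth sweep.  The sweep reports
query node-visit counts, not frame rates: frame rates are
hardware-dependent and intentionally out of scope.  On this scene the
cost is minimized at an intermediate depth (3–4) and grows at both
extremes, the qualitative behavior that motivates choosing a shallow
tree for real-time use.

Scripted trajectories encode skill profiles.  The expert profile
executes each task's criteria by construction: exact angles (90°
injections, 80° elevations and cuts), 85% needle depth, three chained
cuts along the severance line, a post-cut grasp, and the ready gesture
first.  The novice profile adds Ornstein–Uhlenbeck positional jitter
(stationary SD 2 mm, correlation time 100 ms), Gaussian tool-angle
error (SD 15°) and random wandering detours; the expert carries 0.2 mm
jitter and no angle error.  These parameters are behavioral choices,
set once to produce a qualitative skill gap — experts pass everything
and travel less; novices fail often and travel more.  They are not fit
to human data: passing the skill-gap checks shows the *direction* of
the metric separation, not that the simulator discriminates real
expertise.  Likewise, human headline numbers (completion times, path
lengths in the tens of cm, improvement percentages, p-values) arise
from human motor behavior and are not reproducible from synthetic
scripts; the statistics module is instead verified on the printed group
summaries (t ≈ 1.39, df ≈ 30.3 for the anesthesia-time comparison) and
against an independent reference implementation.  The one-tailed
p = 0.018 reported for that comparison is not recoverable from the
printed summaries under any standard convention — it was presumably
computed on unpublished per-trial data — and is therefore recorded but
not asserted.

## Degenerate inputs and edge rules

Zero-area triangles are dropped at load; OBJ faces are strictly
validated (index 0 and out-of-range indices are parse errors with line
context).  Empty meshes build an empty index whose queries are
rejected.  Equidistant nearest-triangle ties break toward the lowest
index in both the octree and the brute-force path.  A zero contact
force is a no-op; a zero-length plane normal or insertion direction is
an argument error.  The pop-through and pierce comparisons both use ≥
at the threshold boundary.  Staircase levels clamp to [0, 1]; an update
after completion is a state error.  Reported angles are always in
[0°, 90°] by the acute-angle convention.

## Problem sizes

Default test and acceptance workloads use the subdivision-3 toe (1,280
triangles), 1,000 random octree queries at depths 0–4, 20 scripted
trials per skill profile, 100 staircase seeds, and a few hundred steps
of the sphere-drop scene — sizes chosen so the full suite runs in well
under a minute while exercising every branch; all scale up linearly via
parameters.
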