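# podosim

A headless Python engine implementing the computational core of a
bimanual VR-haptic trainer for ingrown-toenail (paronychia) removal —
the first surgical procedure podiatric students learn.  Physical
practice models and cadavers convey the kinesthetic side of the skill
poorly or expensively; haptic simulators fill that gap, but their
interesting parts (tissue mechanics, force rendering, objective skill
scoring) are usually welded to a game engine and a device driver.
`podosim` extracts exactly those parts so they can be run, tested and
extended on any machine: no headset, no stylus, no GPU.  Tool motion
enters as timestamped pose trajectories (recorded or scripted) and the
engine computes everything downstream of them.

It is aimed at surgical-simulation researchers and engineers who want
reproducible force models and scoring logic, and at anyone needing a
worked example of proxy-based haptic rendering on a deformable mesh.

## What's inside

- **`podosim.geometry`** — triangle meshes (OBJ/STL in, OBJ out), an
  octree nearest-triangle index that provably agrees with brute force,
  and the moving plane-proxy collider interpolated over 25 ms.
- **`podosim.deformation`** — mass-spring-damper skin: a contact force
  **F** is dispersed over neighbouring vertices as **F**/d² of the
  distance d from the contact point, gated by a minimum-force
  threshold; queued vertices relax back to rest at 1 kHz and snap
  exactly onto their rest positions.
- **`podosim.forces`** — the stylus force laws.  Needle insertion about
  the locked path p(t) = p₀ + **d**t with depth **D** = p_c − p₀:

      F_pen = −b‖D‖·v_axial                (‖D‖ < 30 mm, b = 0.2)
      F_pen = −k₁(‖D‖ − 30)·d              (‖D‖ ≥ 30 mm, k₁ = 0.6)
      F_path = −k₂‖D⊥‖·D⊥ − c·v⊥           (k₂ = 7.9, c = 0.15)
      F_net = F_pen + F_path

  plus penalty plane contact with per-tool [0, 1] surface properties
  and pop-through, Hooke springs F = −k(P − P₀) for tissue piercing
  (k = 2, latching at 1.815 N), grasping (k = 1.5), and 200 Hz/100 ms
  vibration events with a 0.045 perceptibility flag.  Commanded forces
  cap at the 3.3 N device maximum.
- **`podosim.tasks`** — pass/fail state machines for the three
  sub-tasks: digital-block anesthesia (4 sites, ≥ 80% needle depth,
  70–90° to the skin), soft-tissue elevation (hyponychium + eponychium
  pierced at 70–90° to the nail), and cutting & removal (≥ 3 cuts at
  ≥ 70° whose footprints sever the ingrown strip, then a forceps
  grasp), each behind a raise-both-hands ready gate.
- **`podosim.assessment`** — completion time, tool path length (cm),
  success scores, improvement percentages and Welch's unequal-variance
  one-tailed t-test.
- **`podosim.staircase`** — the 1-up/1-down adaptive staircase used to
  calibrate perceptible vibration magnitude (0.1 steps for 3 reversals,
  then 0.025 for 12; threshold = mean of fine-phase reversals).
- **`podosim.fixtures`** — deterministic generators: a parametric toe
  with labeled anatomy, scripted expert/novice trajectories per task,
  and the 4,356-vertex sphere-drop octree benchmark scene.

## Worked example

Generate fixtures, replay an expert and a novice through the anesthesia
evaluator, and score them:

```sh
podosim gen-fixtures --out fx --seed 3 --trials 2
podosim simulate fx/anesthesia_expert_00.csv fx/anesthesia_expert_01.csv \
        --task anesthesia --out expert.jsonl
podosim simulate fx/anesthesia_novice_00.csv fx/anesthesia_novice_01.csv \
        --task anesthesia --out novice.jsonl
podosim score expert.jsonl --compare novice.jsonl --out report.json
```

which prints (seed 3):

```
2 attempts, 2 passed -> expert.jsonl
2 attempts, 0 passed -> novice.jsonl
{
  "n_attempts": 2,
  "success_score": 1.0,
  "mean_completion_time_s": 5.05,
  "improvement_percent": 0.0,
  "welch_completion_time": {
    "t": -24.222222222222147,
    "df": 1.0,
    "p_one_tail": 0.9868662245226695
  }
}
```

The expert passes both attempts in ~5 s of simulated task time; the
novice's angle errors fail the 70–90° criterion.  The Welch block
compares completion times (expert minus novice, one-tailed): the
negative t says the expert group was faster; with n = 2 per group the
degrees of freedom and tail probability are of course not meaningful —
they become so over full 10-attempt blocks.

The same machinery is scriptable directly:

```python
from podosim.fixtures import make_toe_mesh, script_trajectory, TrajectoryProfile
from podosim.tasks import run_trial
from podosim.assessment import path_length

mesh, frame = make_toe_mesh(subdivision=3)
traj = script_trajectory("anesthesia", frame, TrajectoryProfile.expert(seed=7))
result = run_trial("anesthesia", traj, frame)
print(result.passed, result.reason, result.duration_s,
      path_length(traj, "syringe"))
# True ok 5.05 39.9506949640921
```

Other entry points: `podosim benchmark-octree` (deterministic per-depth
query-cost sweep on the sphere-drop scene) and `podosim staircase`
(simulated threshold-estimation session).

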