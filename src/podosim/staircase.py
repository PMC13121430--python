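"""Adaptive 1-up/1-down staircase for 1-D perceptual threshold estimation.

Calibrates the minimally perceptible vibration magnitude: the comparison
stimulus starts at 0.3 against a fixed 0.5 reference, steps down on a
"detected" answer and up on "not detected".  The first phase uses coarse
0.1 steps until three reversals have occurred, the second fine 0.025
steps for twelve further reversals; the threshold estimate is the mean
of the fine-phase reversal levels.  Levels are clamped to [0, 1].

Responses come through an observer interface so recorded human answers
and simulated observers (threshold + logistic slope + seed) are
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "SimulatedObserver",
    "staircase_update",
    "staircase_threshold",
    "run_staircase",
    "session_log_rows",
]


@dataclass(frozen=True)
class StaircaseConfig:
    reference_level: float = 0.5
    start_level: float = 0.3
    coarse_step: float = 0.1
    fine_step: float = 0.025
    coarse_reversals: int = 3
    fine_reversals: int = 12


@dataclass
class StaircaseState:
    config: StaircaseConfig = field(default_factory=StaircaseConfig)
    level: float = None  # type: ignore[assignment]
    history: list = field(default_factory=list)  # (level, response) per trial
    reversal_levels: list = field(default_factory=list)  # (level, phase)
    last_direction: int | None = None  # -1 down, +1 up
    finished: bool = False

    def __post_init__(self) -> None:
        if self.level is None:
            self.level = self.config.start_level

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels)

    @property
    def phase(self) -> int:
        """1 while coarse-stepping, 2 once the coarse reversals are spent."""
        return 1 if self.n_reversals < self.config.coarse_reversals else 2

    @property
    def current_step(self) -> float:
        return self.config.coarse_step if self.phase == 1 else self.config.fine_step


def staircase_update(state: StaircaseState, response: bool) -> StaircaseState:
    """Advance one trial: ``response`` True = detected (level steps down).

    A direction change records a reversal at the pre-move level; after
    the coarse reversal budget the step shrinks, and after the fine
    budget the staircase finishes.  Modifies ``state`` in place.
    """
    if state.finished:
        raise RuntimeError("staircase already finished")
    cfg = state.config
    direction = -1 if response else +1
    if state.last_direction is not None and direction != state.last_direction:
        state.reversal_levels.append((state.level, state.phase))
        fine_revs = sum(1 for _, ph in state.reversal_levels if ph == 2)
        if fine_revs >= cfg.fine_reversals:
            state.finished = True
    state.history.append((state.level, bool(response)))
    if not state.finished:
        state.level = float(np.clip(state.level + direction * state.current_step, 0.0, 1.0))
    state.last_direction = direction
    return state


def staircase_threshold(state: StaircaseState) -> float:
    """Threshold estimate: mean of the fine-phase reversal levels."""
    if not state.finished:
        raise RuntimeError("staircase not finished")
    fine = [lvl for lvl, ph in state.reversal_levels if ph == 2]
    return float(np.mean(fine))


@dataclass
class SimulatedObserver:
    """Ideal-to-noisy observer: detects a stimulus above its threshold.

    With ``slope`` > 0 the detection probability is logistic in
    (level − threshold)/slope; slope 0 gives a deterministic observer.
    """

    threshold: float
    slope: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def respond(self, level: float) -> bool:
        if self.slope <= 0:
            return level >= self.threshold
        p = 1.0 / (1.0 + np.exp(-(level - self.threshold) / self.slope))
        return bool(self._rng.random() < p)


def run_staircase(
    observer,
    config: StaircaseConfig | None = None,
    max_trials: int = 10_000,
) -> StaircaseState:
    """Run a full session against an observer; returns the finished state."""
    state = StaircaseState(config=config or StaircaseConfig())
    for _ in range(max_trials):
        if state.finished:
            return state
        staircase_update(state, observer.respond(state.level))
    if not state.finished:
        raise RuntimeError(f"staircase did not finish within {max_trials} trials")
    return state


def session_log_rows(state: StaircaseState) -> list[dict]:
    """Per-trial rows (trial, level, response, reversal flag) for CSV export."""
    reversal_trials = set()
    last_dir = None
    for i, (_, resp) in enumerate(state.history):
        direction = -1 if resp else +1
        if last_dir is not None and direction != last_dir:
            reversal_trials.add(i)
        last_dir = direction
    return [
        {
            "trial": i,
            "level": lvl,
            "response": int(resp),
            "reversal": int(i in reversal_trials),
        }
        for i, (lvl, resp) in enumerate(state.history)
    ]
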