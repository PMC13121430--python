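"""Objective skill metrics and group statistics.

Per-attempt measures are completion time (s) and tool path length (cm);
per-subject measures are the success score over an attempt block and the
attempt-over-attempt improvement percentage; group comparisons use the
heteroscedastic (Welch) two-sample t-test with the Welch–Satterthwaite
degrees of freedom and a one-tailed p-value by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .trajectory import Trajectory, TRAJECTORY_COLUMNS  # re-export: spec surface

__all__ = [
    "Trajectory",
    "TRAJECTORY_COLUMNS",
    "GroupStats",
    "path_length",
    "completion_time",
    "success_score",
    "improvement_percent",
    "welch_t_test",
    "export_trajectory_plot_data",
]


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics of one group: mean, sample SD, size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")

    @classmethod
    def from_samples(cls, samples) -> "GroupStats":
        x = np.asarray(samples, dtype=float)
        if len(x) < 2:
            raise ValueError("need at least 2 samples")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


def path_length(trajectory: Trajectory, tool: str) -> float:
    """Distance traveled by one tool: sum of segment lengths, in cm."""
    try:
        pos = trajectory.positions(tool)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    if len(pos) < 2:
        return 0.0
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(seg.sum()) / 10.0  # mm → cm


def completion_time(attempt) -> float:
    """Attempt duration in seconds (ready-exit to task completion).

    Accepts any object exposing ``duration_s`` (an AttemptResult).
    Raises if the trial never started.
    """
    duration = getattr(attempt, "duration_s", attempt)
    if duration is None:
        raise ValueError("trial did not start; completion time undefined")
    return float(duration)


def success_score(attempts) -> float:
    """Fraction of passing attempts in a block."""
    attempts = list(attempts)
    if not attempts:
        raise ValueError("success_score of an empty attempt list")
    passes = sum(1 for a in attempts if getattr(a, "passed", a))
    return passes / len(attempts)


def improvement_percent(per_attempt_times, relative_to: str = "final") -> float:
    """Improvement from the first to the last attempt, in percent.

    Default convention: 100·(first − last)/last (ratio to the final
    time, so halving the time reads as +100%).  ``relative_to="first"``
    gives the alternative 100·(first − last)/first.
    """
    times = np.asarray(list(per_attempt_times), dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 attempts")
    if np.any(times <= 0):
        raise ValueError("attempt times must be positive")
    first, last = times[0], times[-1]
    denom = last if relative_to == "final" else first
    return 100.0 * (first - last) / denom


def _as_stats(group) -> GroupStats:
    if isinstance(group, GroupStats):
        return group
    return GroupStats.from_samples(group)


def welch_t_test(a, b, tail: str = "one") -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from samples or summary statistics.

    Returns ``(t, df, p)`` where t = (mean_a − mean_b)/SE, df is the
    Welch–Satterthwaite approximation and p is the upper-tail probability
    (alternative: mean_a > mean_b) for ``tail="one"``, two-sided for
    ``tail="two"``.
    """
    ga, gb = _as_stats(a), _as_stats(b)
    va, vb = ga.sd**2 / ga.n, gb.sd**2 / gb.n
    se = np.sqrt(va + vb)
    if se == 0:
        raise ValueError("zero variance in both groups")
    t = (ga.mean - gb.mean) / se
    df = (va + vb) ** 2 / (va**2 / (ga.n - 1) + vb**2 / (gb.n - 1))
    if tail == "one":
        p = float(_stats.t.sf(t, df))
    elif tail == "two":
        p = float(2.0 * _stats.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return float(t), float(df), p


def export_trajectory_plot_data(
    trajectory: Trajectory, tool: str | None = None, factor: int = 10
) -> np.ndarray:
    """Temporally decimated 3-D point series for plotting; endpoints kept."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if tool is None:
        tools = trajectory.tools()
        if not tools:
            return np.empty((0, 3))
        tool = tools[0]
    try:
        pos = trajectory.positions(tool)
    except KeyError:
        return np.empty((0, 3))
    if factor == 1 or len(pos) <= 2:
        return pos
    idx = np.arange(0, len(pos), factor)
    if idx[-1] != len(pos) - 1:
        idx = np.append(idx, len(pos) - 1)
    return pos[idx]
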