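"""Timestamped tool-pose trajectories with button events.

The on-disk format is CSV with columns
``t_ms,tool,x_mm,y_mm,z_mm,ax,ay,az,btn1,btn2``: per-sample timestamp,
tool identifier, tip position (mm), tool axis (unit vector, pointing
along the working direction of the instrument) and the two stylus
buttons (0/1).  Timestamps must be strictly increasing per tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "TRAJECTORY_COLUMNS"]

TRAJECTORY_COLUMNS = [
    "t_ms",
    "tool",
    "x_mm",
    "y_mm",
    "z_mm",
    "ax",
    "ay",
    "az",
    "btn1",
    "btn2",
]


@dataclass
class Trajectory:
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory missing columns: {missing}")
        df = self.data.reset_index(drop=True)
        pos = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError("trajectory positions must be finite")
        for tool, sub in df.groupby("tool"):
            t = sub["t_ms"].to_numpy(dtype=float)
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"timestamps not strictly increasing for tool {tool!r}")
        self.data = df

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise ValueError(f"cannot parse trajectory CSV {path}: {exc}") from exc
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, columns=TRAJECTORY_COLUMNS)

    # -- access ------------------------------------------------------------
    def tools(self) -> list[str]:
        return sorted(self.data["tool"].unique())

    def for_tool(self, tool: str) -> pd.DataFrame:
        sub = self.data[self.data["tool"] == tool]
        if sub.empty:
            raise KeyError(f"no samples for tool {tool!r}")
        return sub.reset_index(drop=True)

    def has_tool(self, tool: str) -> bool:
        return bool((self.data["tool"] == tool).any())

    def positions(self, tool: str) -> np.ndarray:
        return self.for_tool(tool)[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    def axes(self, tool: str) -> np.ndarray:
        return self.for_tool(tool)[["ax", "ay", "az"]].to_numpy(dtype=float)

    def times(self, tool: str) -> np.ndarray:
        return self.for_tool(tool)["t_ms"].to_numpy(dtype=float)

    @property
    def t_start(self) -> float:
        return float(self.data["t_ms"].min())

    @property
    def t_end(self) -> float:
        return float(self.data["t_ms"].max())

    def slice_time(self, t_from: float, t_to: float | None = None) -> "Trajectory":
        mask = self.data["t_ms"] >= t_from
        if t_to is not None:
            mask &= self.data["t_ms"] <= t_to
        return Trajectory(self.data[mask].reset_index(drop=True))

    def button_intervals(self, tool: str, button: int = 1) -> list[tuple[float, float]]:
        """Press→release intervals [(t_press, t_release), ...] for a button.

        A press still held at the last sample closes at that sample's time.
        """
        sub = self.for_tool(tool)
        col = f"btn{button}"
        state = sub[col].to_numpy(dtype=int)
        t = sub["t_ms"].to_numpy(dtype=float)
        intervals: list[tuple[float, float]] = []
        press_t: float | None = None
        for i in range(len(state)):
            if state[i] and press_t is None:
                press_t = t[i]
            elif not state[i] and press_t is not None:
                intervals.append((press_t, t[i]))
                press_t = None
        if press_t is not None:
            intervals.append((press_t, t[-1]))
        return intervals

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(pd.concat([self.data, other.data], ignore_index=True))
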