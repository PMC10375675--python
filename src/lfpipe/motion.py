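"""Locomotion quantification from markerless pose-estimation output.

Consumes the DeepLabCut CSV dialect (3-row header: scorer / bodyparts /
coords; per bodypart columns x, y, likelihood). Traveled distance is the
cumulative sum of Euclidean distances between successive positions, after
dropping low-likelihood frames and linearly interpolating across them.
Distances are in pixels unless a px→cm scale is applied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "load_pose",
    "write_dlc_csv",
    "cumulative_distance",
    "speed",
    "speed_at",
]


@dataclass
class Trajectory:
    times: np.ndarray        # s, strictly increasing
    x: np.ndarray            # px
    y: np.ndarray
    likelihood: np.ndarray   # [0, 1] per frame
    bodypart: str = "back"
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.likelihood) == n):
            raise ValueError("times, x, y, likelihood must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if n and (np.min(self.likelihood) < 0 or np.max(self.likelihood) > 1):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def write_dlc_csv(traj: Trajectory, path: str | Path,
                  scorer: str = "lfpipe") -> Path:
    """Write a trajectory in the DeepLabCut CSV dialect."""
    path = Path(path)
    cols = pd.MultiIndex.from_product([[scorer], [traj.bodypart],
                                       ["x", "y", "likelihood"]],
                                      names=["scorer", "bodyparts", "coords"])
    df = pd.DataFrame(np.column_stack([traj.x, traj.y, traj.likelihood]),
                      columns=cols)
    df.to_csv(path, index_label=None)
    return path


def load_pose(path: str | Path, bodypart: str,
              frame_rate: float) -> Trajectory:
    """Load one bodypart's trajectory from a DeepLabCut-dialect CSV."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    bodyparts = df.columns.get_level_values(1)
    if bodypart not in set(bodyparts):
        raise ValueError(f"bodypart {bodypart!r} not found; file has "
                         f"{sorted(set(bodyparts))}")
    sub = df.loc[:, df.columns.get_level_values(1) == bodypart]
    sub.columns = sub.columns.get_level_values(2)
    for col in ("x", "y", "likelihood"):
        if col not in sub.columns:
            raise ValueError(f"missing column {col!r} for bodypart {bodypart!r}")
    n = len(sub)
    return Trajectory(times=np.arange(n) / frame_rate,
                      x=sub["x"].to_numpy(float), y=sub["y"].to_numpy(float),
                      likelihood=sub["likelihood"].to_numpy(float),
                      bodypart=bodypart, frame_rate=frame_rate)


def _clean_positions(traj: Trajectory, likelihood_min: float,
                     median_filter_frames: int = 0) -> tuple[np.ndarray, np.ndarray]:
    good = traj.likelihood >= likelihood_min
    if not good.any():
        raise ValueError("all frames below the likelihood cutoff")
    idx = np.arange(traj.n_frames)
    x = np.interp(idx, idx[good], traj.x[good])
    y = np.interp(idx, idx[good], traj.y[good])
    if median_filter_frames > 1:
        from scipy.ndimage import median_filter

        x = median_filter(x, size=median_filter_frames, mode="nearest")
        y = median_filter(y, size=median_filter_frames, mode="nearest")
    return x, y


def cumulative_distance(traj: Trajectory, likelihood_min: float = 0.9,
                        median_filter_frames: int = 0,
                        scale: float = 1.0) -> np.ndarray:
    """Cumulative traveled distance per frame (px, or scaled units).

    Frames with likelihood below the cutoff are removed and linearly
    interpolated before differencing; the result is monotone non-decreasing
    with element 0 equal to 0.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    x, y = _clean_positions(traj, likelihood_min, median_filter_frames)
    steps = np.hypot(np.diff(x), np.diff(y)) * scale
    return np.concatenate([[0.0], np.cumsum(steps)])


def speed(traj: Trajectory, bin_s: float, likelihood_min: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """Mean speed (px/s) in consecutive bins of width ``bin_s``.

    Returns (bin center times, speeds).
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    n_bins = int(traj.times[-1] // bin_s) + 1
    centers = (np.arange(n_bins) + 0.5) * bin_s
    return centers, speed_at(traj, centers, bin_s, likelihood_min=likelihood_min)


def speed_at(traj: Trajectory, times: np.ndarray, window_s: float,
             likelihood_min: float = 0.9) -> np.ndarray:
    """Mean speed (px/s) in windows of width ``window_s`` centered at
    ``times`` — used to align motion to spectrogram bins."""
    x, y = _clean_positions(traj, likelihood_min)
    step = np.hypot(np.diff(x), np.diff(y))
    # speed attributed to the interval's left frame
    t = traj.times[:-1]
    dt = np.diff(traj.times)
    inst = step / dt
    out = np.empty(len(times))
    for i, tc in enumerate(np.asarray(times, dtype=float)):
        mask = (t >= tc - window_s / 2) & (t < tc + window_s / 2)
        out[i] = inst[mask].mean() if mask.any() else 0.0
    return out
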