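"""Assignment-time analysis of categorical trajectories.

An atom's *assignment time* is the earliest grid time after which its
categorical state never changes along a sampled trajectory. Measured
separately for the state x_t and for the denoiser prediction, the gap
between the two quantifies how long a flow variant takes to commit a
decision the denoiser has already made: continuous embeddings only approach
their one-hot vertex as t -> 1, so their states lag the denoiser, while CTMC
tokens can jump straight to the predicted class. Mid-trajectory continuous
states are discretized by argmax before this analysis (done at recording
time by the sampler).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .samplers import GenerationTrajectory

__all__ = [
    "CategoricalTrajectory",
    "assignment_time",
    "assignment_cdf",
    "assignment_gap",
    "trajectory_assignment_times",
    "mean_assignment_gap",
]


@dataclass
class CategoricalTrajectory:
    """One token's discrete state at each grid time; the grid ends at t = 1."""

    grid: np.ndarray  # (K+1,) strictly increasing, grid[-1] == 1
    states: np.ndarray  # (K+1,) int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).reshape(-1)
        self.states = np.asarray(self.states, dtype=int).reshape(-1)
        if self.grid.size == 0:
            raise ValueError("trajectory must be non-empty")
        if self.grid.shape != self.states.shape:
            raise ValueError("grid and states must be aligned")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if abs(self.grid[-1] - 1.0) > 1e-9:
            raise ValueError("grid must end at t = 1")

    @property
    def final_state(self) -> int:
        return int(self.states[-1])


def assignment_time(traj: CategoricalTrajectory, mask_index: Optional[int] = None) -> float:
    """Smallest grid time t* with state(t) = final state for all t >= t*."""
    if mask_index is not None and traj.final_state == mask_index:
        raise ValueError("final state is the mask class; trajectory is unresolved")
    differs = np.nonzero(traj.states != traj.final_state)[0]
    if differs.size == 0:
        return float(traj.grid[0])
    return float(traj.grid[differs[-1] + 1])


def assignment_cdf(times: Sequence[float], eval_grid: Sequence[float]) -> np.ndarray:
    """Empirical CDF of assignment times evaluated on a grid."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("no assignment times given")
    if np.any((times < 0) | (times > 1)):
        raise ValueError("assignment times must lie in [0, 1]")
    eval_grid = np.asarray(eval_grid, dtype=float)
    srt = np.sort(times)
    return np.searchsorted(srt, eval_grid, side="right") / times.size


def assignment_gap(
    state_times: Sequence[float],
    pred_times: Sequence[float],
    t_query: float,
) -> tuple[float, float]:
    """Fractions of atoms assigned by t_query in the state and the prediction.

    The two time lists are paired per atom; the gap statistic is the
    difference of the returned fractions.
    """
    state_times = np.asarray(state_times, dtype=float)
    pred_times = np.asarray(pred_times, dtype=float)
    if state_times.shape != pred_times.shape:
        raise ValueError("state and prediction time lists must be paired (equal length)")
    if state_times.size == 0:
        raise ValueError("empty time lists")
    return (
        float(np.mean(state_times <= t_query)),
        float(np.mean(pred_times <= t_query)),
    )


def trajectory_assignment_times(
    trajs: Sequence[GenerationTrajectory],
    modality: str = "atoms",
    mask_index: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-token (state, prediction) assignment times over molecules."""
    state_times: list[float] = []
    pred_times: list[float] = []
    for traj in trajs:
        grid = traj.grid
        for row_s, row_p in zip(traj.states[modality], traj.preds[modality]):
            state_times.append(assignment_time(CategoricalTrajectory(grid, row_s), mask_index))
            pred_times.append(assignment_time(CategoricalTrajectory(grid, row_p)))
    return np.asarray(state_times), np.asarray(pred_times)


def mean_assignment_gap(
    trajs: Sequence[GenerationTrajectory],
    modality: str = "atoms",
    mask_index: Optional[int] = None,
) -> float:
    """Mean over tokens of (state assignment time - prediction assignment time)."""
    s, p = trajectory_assignment_times(trajs, modality, mask_index)
    return float(np.mean(s - p))
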