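"""Macroscopic order parameters of the swarm and time-series summaries.

Two scalars characterize the group at each instant:

* polarization ``O_p`` — the norm of the mean unit heading, 1 for a
  perfectly aligned group and ~1/sqrt(N) for random headings;
* elongation ``O_e = L / W`` — length-to-width ratio of the bounding
  rectangle whose long axis is forced to the centroid's direction of
  motion.  ``O_e >> 1`` is the signature of a longitudinal queue.

The centroid's motion direction is estimated by finite differencing the
centroid track, falling back to the last valid direction (the mean
heading at t = 0) whenever the centroid barely moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

W_MIN = 1.0  # floor on the transverse width, one body length

__all__ = [
    "W_MIN",
    "MetricsSeries",
    "Summary",
    "polarization",
    "elongation",
    "centroid_direction",
    "detect_success",
    "summarize",
    "early_peak_polarization",
]


def polarization(headings: np.ndarray) -> float:
    """Norm of the mean unit-heading vector, in [0, 1]."""
    headings = np.asarray(headings, dtype=float)
    if headings.size == 0:
        raise ValueError("polarization of an empty group is undefined")
    return float(np.linalg.norm(headings.mean(axis=0)))


def elongation(positions: np.ndarray, motion_direction: np.ndarray, w_min: float = W_MIN) -> float:
    """Length/width of the motion-aligned bounding rectangle.

    Positions are projected onto the motion direction (length axis) and
    its perpendicular (width axis); the width is floored at ``w_min`` so
    a perfectly collinear group has a finite, large ratio.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("elongation needs at least 2 points")
    d = np.asarray(motion_direction, dtype=float)
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0]])
    lon = positions @ d
    tra = positions @ perp
    length = lon.max() - lon.min()
    width = tra.max() - tra.min()
    return float(length / max(width, w_min))


def centroid_direction(
    previous_centroid: np.ndarray,
    current_centroid: np.ndarray,
    fallback: np.ndarray,
) -> np.ndarray:
    """Unit displacement of the centroid, or ``fallback`` if it barely moved."""
    disp = np.asarray(current_centroid, dtype=float) - np.asarray(previous_centroid, dtype=float)
    norm = np.linalg.norm(disp)
    if norm < 1e-9:
        return np.asarray(fallback, dtype=float)
    return disp / norm


@dataclass
class MetricsSeries:
    """Per-step group metrics of one episode (index 0 is the initial state)."""

    t: np.ndarray
    polarization: np.ndarray
    elongation: np.ndarray
    centroid: np.ndarray  # (T, 2)
    direction: np.ndarray  # (T, 2) centroid-motion unit direction
    dist_to_target: np.ndarray  # centroid-to-target distance

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("polarization", "elongation", "dist_to_target"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match t")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "O_p": self.polarization,
                "O_e": self.elongation,
                "centroid_x": self.centroid[:, 0],
                "centroid_y": self.centroid[:, 1],
                "dist_to_target": self.dist_to_target,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def detect_success(series: MetricsSeries, success_radius: float) -> tuple[bool, int | None]:
    """Did the centroid ever come within ``success_radius`` of the target?

    Returns the flag and the first step at which it happened (None if never).
    """
    hits = np.flatnonzero(series.dist_to_target <= success_radius)
    if hits.size == 0:
        return False, None
    return True, int(series.t[hits[0]])


def early_peak_polarization(series: MetricsSeries, horizon: int = 100) -> float:
    """Maximum polarization attained within the first ``horizon`` steps."""
    mask = series.t <= horizon
    return float(series.polarization[mask].max())


@dataclass(frozen=True)
class Summary:
    """Derived per-episode summary of a metrics series."""

    peak_elongation: float
    peak_elongation_step: int
    mean_polarization: float  # over the steady navigation window
    alignment_step: int | None  # first step with O_p >= threshold
    success: bool
    success_step: int | None
    window: tuple[int, int]  # [start, stop) of the steady window used


def summarize(
    series: MetricsSeries,
    alignment_threshold: float = 0.9,
    success_radius: float = 100.0,
) -> Summary:
    """Collapse a series into its headline numbers.

    The steady navigation window runs from first alignment
    (``O_p >= alignment_threshold``) to the first target hit; if the
    group never aligns the whole series is used, and if it never hits
    the target the window extends to the end.
    """
    aligned = np.flatnonzero(series.polarization >= alignment_threshold)
    alignment_step = int(series.t[aligned[0]]) if aligned.size else None
    success, success_step = detect_success(series, success_radius)

    start = aligned[0] if aligned.size else 0
    stop = len(series.t)
    if success_step is not None:
        hit_idx = int(np.flatnonzero(series.t == success_step)[0])
        if hit_idx > start:
            stop = hit_idx
    peak_idx = int(np.argmax(series.elongation))
    return Summary(
        peak_elongation=float(series.elongation[peak_idx]),
        peak_elongation_step=int(series.t[peak_idx]),
        mean_polarization=float(series.polarization[start:stop].mean()),
        alignment_step=alignment_step,
        success=success,
        success_step=success_step,
        window=(int(series.t[start]), int(series.t[stop - 1]) + 1),
    )
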