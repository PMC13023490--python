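"""Weighted Vicsek baseline: fixed linear alignment/target arbitration.

Each agent's new heading is the direction of a fixed convex combination
of its topological neighbors' mean heading and the target bearing,

    theta_i(t+1) = arg[(1 - omega) * v_avg / |v_avg| + omega * v_t / |v_t|] + xi,

with uniform angular noise xi ~ U[-noise_halfwidth, +noise_halfwidth]
(radians).  Unlike the learned PS policy, the trade-off between social
alignment and goal seeking is the same constant in every state, which is
exactly why this baseline navigates as a compact cluster rather than a
longitudinal queue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env import EnvConfig, SwarmState, _neighbor_matrix, init_swarm
from .metrics import MetricsSeries, centroid_direction, elongation, polarization

__all__ = ["VicsekConfig", "vicsek_step", "run_vicsek_experiment"]


@dataclass(frozen=True)
class VicsekConfig:
    """Weights and noise of the baseline update."""

    omega: float = 0.5  # target weight; 0 = pure alignment, 1 = pure pursuit
    noise_halfwidth: float = 0.25  # radians
    k_neighbors: int = 6
    speed: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if self.noise_halfwidth < 0:
            raise ValueError("noise_halfwidth must be >= 0")


def _safe_unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.where(norm > 1e-12, v / np.where(norm > 0, norm, 1.0), 0.0)


def vicsek_step(state: SwarmState, config: VicsekConfig, rng: np.random.Generator) -> SwarmState:
    """One synchronous weighted-Vicsek update of every agent.

    A vanishing resultant vector (no alignment nor bearing information)
    keeps the previous heading.
    """
    pos, head = state.positions, state.headings
    nbr = _neighbor_matrix(pos, config.k_neighbors)
    v_avg = head[nbr].mean(axis=1)
    v_t = state.target - pos
    resultant = (1.0 - config.omega) * _safe_unit(v_avg) + config.omega * _safe_unit(v_t)
    res_norm = np.linalg.norm(resultant, axis=1)
    theta = np.arctan2(resultant[:, 1], resultant[:, 0])
    if config.noise_halfwidth > 0:
        theta = theta + rng.uniform(-config.noise_halfwidth, config.noise_halfwidth, len(theta))
    new_head = np.column_stack((np.cos(theta), np.sin(theta)))
    degenerate = res_norm < 1e-12
    if np.any(degenerate):
        new_head[degenerate] = head[degenerate]
    return SwarmState(
        pos + config.speed * new_head,
        new_head,
        t=state.t + 1,
        target=state.target + state.target_velocity,
        target_velocity=state.target_velocity.copy(),
    )


def run_vicsek_experiment(
    config: VicsekConfig,
    env_config: EnvConfig,
    rng: np.random.Generator,
    *,
    state: SwarmState | None = None,
) -> MetricsSeries:
    """Full baseline episode with the same initializer and metrics as the PS runs."""
    if state is None:
        state = init_swarm(env_config, rng)
    n_rec = env_config.max_steps + 1
    pol = np.empty(n_rec)
    elo = np.empty(n_rec)
    cen = np.empty((n_rec, 2))
    dirs = np.empty((n_rec, 2))
    dist = np.empty(n_rec)

    mean_head = state.headings.mean(axis=0)
    mh_norm = np.linalg.norm(mean_head)
    direction = mean_head / mh_norm if mh_norm > 1e-9 else np.array([1.0, 0.0])

    for i in range(n_rec):
        if i > 0:
            prev_centroid = cen[i - 1]
            state = vicsek_step(state, config, rng)
            direction = centroid_direction(prev_centroid, state.positions.mean(axis=0), direction)
        pol[i] = polarization(state.headings)
        elo[i] = elongation(state.positions, direction)
        c = state.positions.mean(axis=0)
        cen[i] = c
        dirs[i] = direction
        dist[i] = np.linalg.norm(state.target - c)

    return MetricsSeries(
        t=np.arange(n_rec),
        polarization=pol,
        elongation=elo,
        centroid=cen,
        direction=dirs,
        dist_to_target=dist,
    )
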