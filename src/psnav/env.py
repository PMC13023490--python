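"""Two-dimensional unbounded navigation environment for the PS swarm.

Agents move at constant speed in an open plane and steer by discrete
angles.  Each agent perceives exactly two signed angles, both measured
from its own heading with positive = counter-clockwise (to its left):

* ``theta_neighbor`` — to the mean heading of its k topological nearest
  neighbors (metric-free interaction: k nearest regardless of distance);
* ``theta_target``  — to the bearing of the global target.

Both angles are discretized into three cues (0 = right of heading,
1 = aligned within ±30°, 2 = left), giving the 9-state percept
``3 * neighbor_cue + target_cue``.  The per-step reward combines the
distance shortened toward the target with the clipped heading/target
alignment, weighted by ``lambda_d`` and ``lambda_r``.

All agents update synchronously: percepts are taken from the common
time-t snapshot, then every heading rotates and every position advances
together, so the outcome is independent of agent ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecm import (
    ActionSpace,
    GlowMemory,
    PolicyMemory,
    policy_table,
    update_experience,
    update_glow,
)
from .metrics import W_MIN, MetricsSeries, centroid_direction, elongation, polarization

ALIGN_HALFWIDTH = np.pi / 6  # half-width of the "aligned" cue interval

__all__ = [
    "EnvConfig",
    "RewardWeights",
    "RewardSignal",
    "SwarmState",
    "StepRecord",
    "EpisodeResult",
    "init_swarm",
    "topological_neighbors",
    "neighbor_angle",
    "target_angle",
    "discretize_angle",
    "percept_index",
    "apply_sensor_noise",
    "turn",
    "compute_reward",
    "env_step",
    "run_episode",
]


@dataclass(frozen=True)
class EnvConfig:
    """Environment geometry and episode bookkeeping.

    Distances are in body lengths (one unit = one step at speed 1);
    ``sensor_noise_sigma_deg`` is the s.d. of the Gaussian perturbation
    added to both perceived angles before discretization (0 = noiseless).
    """

    n_agents: int = 30
    k_neighbors: int = 6
    init_radius: float = 300.0
    speed: float = 1.0
    max_steps: int = 10_000
    target: tuple[float, float] = (3000.0, 3000.0)
    target_velocity: tuple[float, float] = (0.0, 0.0)
    sensor_noise_sigma_deg: float = 0.0
    success_radius: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if not 1 <= self.k_neighbors < self.n_agents:
            raise ValueError("k_neighbors must satisfy 1 <= k < n_agents")
        if self.init_radius <= 0:
            raise ValueError("init_radius must be positive")
        if self.sensor_noise_sigma_deg < 0:
            raise ValueError("sensor noise sigma must be >= 0")


@dataclass(frozen=True)
class RewardWeights:
    """Coefficients of the composite reward: distance (λd) and orientation (λr)."""

    lambda_d: float = 0.5
    lambda_r: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda_d < 0 or self.lambda_r < 0:
            raise ValueError("reward weights must be non-negative")


@dataclass(frozen=True)
class RewardSignal:
    """Per-agent reward components (arrays) for one synchronous step."""

    r_dis: np.ndarray
    r_dir: np.ndarray
    r_total: np.ndarray


@dataclass
class SwarmState:
    """Positions/headings of all agents plus the (possibly moving) target."""

    positions: np.ndarray  # (N, 2)
    headings: np.ndarray  # (N, 2), unit rows
    t: int = 0
    target: np.ndarray = field(default_factory=lambda: np.array([3000.0, 3000.0]))
    target_velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        self.target_velocity = np.asarray(self.target_velocity, dtype=float)
        if self.positions.shape != self.headings.shape or self.positions.ndim != 2:
            raise ValueError("positions and headings must both be (N, 2)")
        norms = np.linalg.norm(self.headings, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("headings must be unit vectors")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SwarmState":
        return SwarmState(
            self.positions.copy(),
            self.headings.copy(),
            t=self.t,
            target=self.target.copy(),
            target_velocity=self.target_velocity.copy(),
        )


@dataclass(frozen=True)
class StepRecord:
    """What each agent perceived, chose, and was rewarded in one step."""

    percepts: np.ndarray
    actions: np.ndarray
    reward: RewardSignal


def init_swarm(config: EnvConfig, rng: np.random.Generator) -> SwarmState:
    """Random start: positions area-uniform in a disk, headings uniform on the circle."""
    n = config.n_agents
    radii = config.init_radius * np.sqrt(rng.random(n))
    pos_angles = rng.uniform(0.0, 2 * np.pi, n)
    positions = np.column_stack((radii * np.cos(pos_angles), radii * np.sin(pos_angles)))
    head_angles = rng.uniform(0.0, 2 * np.pi, n)
    headings = np.column_stack((np.cos(head_angles), np.sin(head_angles)))
    return SwarmState(
        positions,
        headings,
        t=0,
        target=np.asarray(config.target, dtype=float),
        target_velocity=np.asarray(config.target_velocity, dtype=float),
    )


def _neighbor_matrix(positions: np.ndarray, k: int) -> np.ndarray:
    """Indices (N, k) of each agent's k nearest neighbors, ties to smaller index."""
    diff = positions[:, None, :] - positions[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, -1.0)  # self always sorts first, then gets dropped
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, 1 : k + 1]


def topological_neighbors(positions: np.ndarray, i: int, k: int) -> np.ndarray:
    """The k nearest neighbors of agent ``i`` (self excluded)."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < N")
    d2 = np.einsum("jk,jk->j", positions - positions[i], positions - positions[i])
    d2[i] = -1.0
    return np.argsort(d2, kind="stable")[1 : k + 1]


def _signed_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed angle from u to v in (−π, π]; positive = v counter-clockwise of u.

    Exactly antiparallel vectors map to +π (a convention for the
    measure-zero degenerate case).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    ang = np.arctan2(cross, dot)
    return np.where(ang == -np.pi, np.pi, ang)


def neighbor_angle(heading_i: np.ndarray, neighbor_headings: np.ndarray) -> float:
    """Signed angle from an agent's heading to its neighbors' mean heading.

    A vanishing neighbor average (< 1e-9) carries no directional
    information and is treated as perfect alignment (angle 0).
    """
    v_avg = np.mean(np.asarray(neighbor_headings, dtype=float), axis=0)
    if np.linalg.norm(v_avg) < 1e-9:
        return 0.0
    return float(_signed_angle(np.asarray(heading_i, dtype=float), v_avg))


def target_angle(heading_i: np.ndarray, position_i: np.ndarray, target: np.ndarray) -> float:
    """Signed angle from an agent's heading to the target bearing (0 if at target)."""
    v = np.asarray(target, dtype=float) - np.asarray(position_i, dtype=float)
    if np.linalg.norm(v) < 1e-12:
        return 0.0
    return float(_signed_angle(np.asarray(heading_i, dtype=float), v))


def discretize_angle(theta) -> np.ndarray:
    """Map a signed angle to a cue: 0 = right (θ < −π/6), 1 = aligned (|θ| ≤ π/6), 2 = left."""
    theta = np.asarray(theta, dtype=float)
    cue = np.where(np.abs(theta) <= ALIGN_HALFWIDTH, 1, np.where(theta < -ALIGN_HALFWIDTH, 0, 2))
    return cue if cue.ndim else cue[()]


def percept_index(s_n, s_t) -> np.ndarray:
    """Combine cues into the percept index 3·s_n + s_t ∈ {0, …, 8}."""
    s_n = np.asarray(s_n)
    s_t = np.asarray(s_t)
    if np.any((s_n < 0) | (s_n > 2) | (s_t < 0) | (s_t > 2)):
        raise ValueError("cues must lie in {0, 1, 2}")
    idx = 3 * s_n + s_t
    return idx if idx.ndim else idx[()]


def apply_sensor_noise(theta, sigma_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Add Gaussian angular noise (s.d. ``sigma_deg``) and wrap into (−π, π]."""
    if sigma_deg < 0:
        raise ValueError("sigma must be >= 0")
    theta = np.asarray(theta, dtype=float)
    if sigma_deg == 0:
        return theta
    noisy = theta + rng.normal(0.0, np.radians(sigma_deg), size=theta.shape)
    wrapped = np.mod(noisy + np.pi, 2 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def turn(heading: np.ndarray, angle_deg) -> np.ndarray:
    """Rotate heading(s) counter-clockwise by ``angle_deg`` (positive = left turn)."""
    heading = np.asarray(heading, dtype=float)
    a = np.radians(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    x, y = heading[..., 0], heading[..., 1]
    return np.stack((c * x - s * y, s * x + c * y), axis=-1)


def compute_reward(
    prev_position: np.ndarray,
    new_position: np.ndarray,
    new_heading: np.ndarray,
    target: np.ndarray,
    weights: RewardWeights,
) -> RewardSignal:
    """Composite navigation reward for one step (vectorized over agents).

    ``r_dis`` is the distance shortened toward the target, ``r_dir`` the
    clipped cosine between the post-move heading and the post-move target
    bearing; the total is their λ-weighted sum.
    """
    prev_position = np.atleast_2d(np.asarray(prev_position, dtype=float))
    new_position = np.atleast_2d(np.asarray(new_position, dtype=float))
    new_heading = np.atleast_2d(np.asarray(new_heading, dtype=float))
    target = np.asarray(target, dtype=float)
    d_prev = np.linalg.norm(target - prev_position, axis=1)
    to_target = target - new_position
    d_new = np.linalg.norm(to_target, axis=1)
    r_dis = d_prev - d_new
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = np.einsum("ij,ij->i", new_heading, to_target) / np.where(d_new > 0, d_new, 1.0)
    r_dir = np.clip(np.where(d_new > 0, cosines, 0.0), 0.0, None)
    r_total = weights.lambda_d * r_dis + weights.lambda_r * r_dir
    return RewardSignal(r_dis=r_dis, r_dir=r_dir, r_total=r_total)


def _percepts(state: SwarmState, config: EnvConfig, rng: np.random.Generator) -> np.ndarray:
    """Percept index of every agent from the common time-t snapshot."""
    pos, head = state.positions, state.headings
    nbr = _neighbor_matrix(pos, config.k_neighbors)
    v_avg = head[nbr].mean(axis=1)
    avg_norm = np.linalg.norm(v_avg, axis=1)
    theta_n = np.where(avg_norm < 1e-9, 0.0, _signed_angle(head, v_avg))
    to_target = state.target - pos
    t_norm = np.linalg.norm(to_target, axis=1)
    theta_t = np.where(t_norm < 1e-12, 0.0, _signed_angle(head, to_target))
    sigma = config.sensor_noise_sigma_deg
    if sigma > 0:
        theta_n = apply_sensor_noise(theta_n, sigma, rng)
        theta_t = apply_sensor_noise(theta_t, sigma, rng)
    return percept_index(discretize_angle(theta_n), discretize_angle(theta_t))


def _resolve_actions(policy, percepts: np.ndarray, rng: np.random.Generator, m: int) -> np.ndarray:
    """Sample (or look up) one action per agent for the given percepts."""
    if callable(policy):
        return np.asarray(policy(percepts), dtype=int)
    if isinstance(policy, PolicyMemory):
        table = policy_table(policy)
    else:
        table = np.asarray(policy, dtype=float)
        table = table / table.sum(axis=1, keepdims=True)
    cum = np.cumsum(table[percepts], axis=1)
    u = rng.random(percepts.shape[0])
    return np.minimum((u[:, None] > cum).sum(axis=1), m - 1)


def env_step(
    state: SwarmState,
    policy,
    action_space: ActionSpace,
    config: EnvConfig,
    weights: RewardWeights,
    rng: np.random.Generator,
    *,
    glow: GlowMemory | None = None,
    learn: bool = False,
    gamma: float = 0.0,
) -> tuple[SwarmState, StepRecord]:
    """One synchronous step of the whole swarm.

    ``policy`` is a :class:`PolicyMemory` (sampled through its normalized
    rows), a fixed (9, m) probability table, or a callable mapping the
    percept array to an action array.  With ``learn=True`` the policy
    must be a ``PolicyMemory`` and ``glow`` must be supplied: glow decays
    and re-lights first, then the shared H-matrix absorbs Σ_i R_i·G_i.
    """
    percepts = _percepts(state, config, rng)
    actions = _resolve_actions(policy, percepts, rng, action_space.m)
    new_headings = turn(state.headings, action_space.angles_deg[actions])
    new_positions = state.positions + config.speed * new_headings
    new_target = state.target + state.target_velocity
    reward = compute_reward(state.positions, new_positions, new_headings, new_target, weights)
    if learn:
        if not isinstance(policy, PolicyMemory) or glow is None:
            raise ValueError("learning requires a PolicyMemory and a GlowMemory")
        update_glow(glow, (percepts, actions))
        update_experience(policy, glow, reward.r_total, gamma)
    new_state = SwarmState(
        new_positions,
        new_headings,
        t=state.t + 1,
        target=new_target,
        target_velocity=state.target_velocity.copy(),
    )
    return new_state, StepRecord(percepts=percepts, actions=actions, reward=reward)


def _run_episode_kernel(
    policy,
    action_space: ActionSpace,
    config: EnvConfig,
    weights: RewardWeights,
    rng: np.random.Generator,
    learn: bool,
    eta: float,
    gamma: float,
    state: SwarmState,
    stop_on_success: bool,
) -> "EpisodeResult | None":
    """Run the episode through the compiled kernel; None if unavailable.

    The kernel consumes the generator in the same order as the stepwise
    path, so results agree with :func:`env_step` iteration up to
    floating-point reduction order.
    """
    try:
        from ._kernel import episode_kernel
    except ImportError:  # numba not installed: stepwise path still works
        return None
    if learn and not isinstance(policy, PolicyMemory):
        raise ValueError("learning requires a PolicyMemory")
    if isinstance(policy, PolicyMemory):
        table = policy.weights  # kernel normalizes rows on the fly
        h_min = policy.h_min
    else:
        table = np.ascontiguousarray(np.asarray(policy, dtype=float))
        h_min = 0.0
    pol, elo, cen, dirs, dist, total_reward = episode_kernel(
        state.positions.copy(),
        state.headings.copy(),
        state.target.astype(float).copy(),
        state.target_velocity.astype(float).copy(),
        table,
        h_min,
        eta,
        gamma,
        learn,
        config.k_neighbors,
        config.speed,
        config.max_steps,
        np.radians(config.sensor_noise_sigma_deg),
        np.radians(action_space.angles_deg),
        weights.lambda_d,
        weights.lambda_r,
        W_MIN,
        config.success_radius if stop_on_success else 0.0,
        rng,
    )
    series = MetricsSeries(
        t=np.arange(len(pol)),
        polarization=pol,
        elongation=elo,
        centroid=cen,
        direction=dirs,
        dist_to_target=dist,
    )
    return EpisodeResult(metrics=series, total_reward=float(total_reward))


@dataclass
class EpisodeResult:
    """Output of one episode: order-parameter series and optional trajectory.

    ``trajectory`` (when recorded) is tidy/long-form with one row per
    agent per recorded step: t, agent_id, x, y, heading_x, heading_y,
    percept, action — the percept seen and action taken in the step
    that produced that pose (-1 at t = 0, before any decision).
    """

    metrics: MetricsSeries
    total_reward: float
    trajectory: "pd.DataFrame | None" = None

    def save_trajectory_csv(self, path) -> None:
        if self.trajectory is None:
            raise ValueError("episode was run without record_trajectory")
        self.trajectory.to_csv(path, index=False)


def run_episode(
    policy,
    action_space: ActionSpace,
    config: EnvConfig,
    weights: RewardWeights,
    rng: np.random.Generator,
    *,
    learn: bool = False,
    eta: float = 0.1,
    gamma: float = 0.0,
    state: SwarmState | None = None,
    stop_on_success: bool = False,
    record_trajectory: bool = False,
    record_every: int = 1,
) -> EpisodeResult:
    """Run one episode of at most ``config.max_steps`` synchronous steps.

    Glow is zeroed at the start (episodic short-term memory); the
    H-matrix, if learning, persists and accumulates across episodes.
    With ``stop_on_success`` the episode ends as soon as the swarm
    centroid comes within ``config.success_radius`` of the target
    (task completion during training); otherwise it always runs the
    full ``max_steps``.  Metrics are recorded every step; positions only
    if requested, thinned by ``record_every``.
    """
    if state is None:
        state = init_swarm(config, rng)

    if not record_trajectory and not callable(policy):
        fast = _run_episode_kernel(
            policy, action_space, config, weights, rng, learn, eta, gamma, state, stop_on_success
        )
        if fast is not None:
            return fast

    glow = None
    if learn:
        glow = GlowMemory(state.n_agents, action_space.m, eta=eta)
        glow.reset()

    n_rec = config.max_steps + 1
    pol = np.empty(n_rec)
    elo = np.empty(n_rec)
    cen = np.empty((n_rec, 2))
    dirs = np.empty((n_rec, 2))
    dist = np.empty(n_rec)

    mean_head = state.headings.mean(axis=0)
    mh_norm = np.linalg.norm(mean_head)
    direction = mean_head / mh_norm if mh_norm > 1e-9 else np.array([1.0, 0.0])

    def record(i: int, st: SwarmState, drn: np.ndarray) -> None:
        pol[i] = polarization(st.headings)
        elo[i] = elongation(st.positions, drn)
        c = st.positions.mean(axis=0)
        cen[i] = c
        dirs[i] = drn
        dist[i] = np.linalg.norm(st.target - c)

    record(0, state, direction)
    n = state.n_agents
    traj_rows = []

    def record_traj(step: int, st: SwarmState, percepts, actions) -> None:
        traj_rows.append(
            {
                "t": np.full(n, step),
                "agent_id": np.arange(n),
                "x": st.positions[:, 0].copy(),
                "y": st.positions[:, 1].copy(),
                "heading_x": st.headings[:, 0].copy(),
                "heading_y": st.headings[:, 1].copy(),
                "percept": percepts,
                "action": actions,
            }
        )

    if record_trajectory:
        record_traj(0, state, np.full(n, -1), np.full(n, -1))

    total_reward = 0.0
    n_done = n_rec
    already_done = stop_on_success and dist[0] <= config.success_radius
    if already_done:
        n_done = 1
    for i in range(1, 0 if already_done else config.max_steps + 1):
        prev_centroid = cen[i - 1]
        state, rec = env_step(
            state, policy, action_space, config, weights, rng, glow=glow, learn=learn, gamma=gamma
        )
        total_reward += float(rec.reward.r_total.sum())
        direction = centroid_direction(prev_centroid, state.positions.mean(axis=0), direction)
        record(i, state, direction)
        if record_trajectory and i % record_every == 0:
            record_traj(i, state, rec.percepts, rec.actions)
        if stop_on_success and dist[i] <= config.success_radius:
            n_done = i + 1
            break

    series = MetricsSeries(
        t=np.arange(n_done),
        polarization=pol[:n_done],
        elongation=elo[:n_done],
        centroid=cen[:n_done],
        direction=dirs[:n_done],
        dist_to_target=dist[:n_done],
    )
    trajectory = None
    if record_trajectory:
        trajectory = pd.concat([pd.DataFrame(r) for r in traj_rows], ignore_index=True)
    return EpisodeResult(metrics=series, total_reward=total_reward, trajectory=trajectory)
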