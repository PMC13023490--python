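"""Training/evaluation protocols, parameter sweeps, and robustness suites.

A run has two stages.  Training: repeated episodes from fresh random
initial conditions, with the shared H-matrix preserved across episodes
(species-level memory) and the per-agent glow reset each episode.
Evaluation: the trained H-matrix is frozen (no updates) and replayed
from new random initial conditions, from which success rate, alignment
time, steady polarization, and peak elongation are aggregated.

The reference protocol (the ``full_plan``) is 30 independent runs of
5000 episodes x 10,000 steps toward a target at (3000, 3000); the
``scaled_plan`` shrinks this to a desk-sized replicate (one run of 300
episodes x 3000 steps toward (600, 600)) that preserves the qualitative
regime: the target starts well outside the initial disk and an episode
leaves time for queue formation, arrival, and post-arrival adjustment.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .ecm import (
    ActionSpace,
    PolicyMemory,
    average_certainty,
    average_entropy,
    policy_table,
)
from .env import EnvConfig, RewardWeights, run_episode
from .metrics import MetricsSeries, early_peak_polarization, summarize
from .vicsek import VicsekConfig, run_vicsek_experiment

logger = logging.getLogger(__name__)

GRANULARITY_GRID = ((5, 7.0), (11, 3.0), (15, 2.0), (19, 1.5), (29, 1.0))
REWARD_GRID = ((0.1, 0.9), (0.3, 0.7), (0.5, 0.5), (0.7, 0.3), (0.9, 0.1))
NOISE_GRID = (0.0, 10.0, 20.0, 30.0)

__all__ = [
    "GRANULARITY_GRID",
    "REWARD_GRID",
    "NOISE_GRID",
    "ExperimentPlan",
    "TrainResult",
    "EvalResult",
    "full_plan",
    "scaled_plan",
    "scale_plan",
    "train",
    "evaluate",
    "sweep_granularity",
    "sweep_rewards",
    "noise_suite",
    "generalization_suite",
    "parameter_count",
    "plan_to_dict",
    "plan_from_dict",
    "save_plan",
    "load_plan",
]


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything needed to reproduce a training/evaluation campaign."""

    name: str = "default"
    env: EnvConfig = field(default_factory=EnvConfig)
    actions: ActionSpace = field(default_factory=ActionSpace)
    weights: RewardWeights = field(default_factory=RewardWeights)
    eta: float = 0.1
    gamma: float = 1e-3  # forgetting rate of the shared memory during training
    episodes: int = 5000
    n_runs: int = 30
    eval_episodes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must lie in (0, 1]")
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")
        if self.episodes < 0 or self.n_runs < 1 or self.eval_episodes < 1:
            raise ValueError("episodes >= 0, n_runs >= 1, eval_episodes >= 1 required")

    def config_hash(self) -> str:
        blob = json.dumps(plan_to_dict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]


def full_plan(seed: int = 0) -> ExperimentPlan:
    """The reference protocol (hours of CPU): 30 runs x 5000 episodes x 10,000 steps."""
    return ExperimentPlan(
        name="full",
        env=EnvConfig(target=(3000.0, 3000.0), max_steps=10_000, seed=seed),
        episodes=5000,
        n_runs=30,
        eval_episodes=30,
        seed=seed,
    )


def scaled_plan(seed: int = 0) -> ExperimentPlan:
    """Desk-sized replicate: one run of 300 episodes x 3000 steps, target (600, 600)."""
    return ExperimentPlan(
        name="scaled",
        env=EnvConfig(target=(600.0, 600.0), max_steps=3000, seed=seed),
        episodes=300,
        n_runs=1,
        eval_episodes=10,
        seed=seed,
    )


def scale_plan(plan: ExperimentPlan, factor: float) -> ExperimentPlan:
    """Shrink target distance, episode count, and episode length by ``factor``."""
    if not 0 < factor <= 1:
        raise ValueError("scale factor must lie in (0, 1]")
    tx, ty = plan.env.target
    env = replace(
        plan.env,
        target=(tx * factor, ty * factor),
        max_steps=max(1, math.ceil(plan.env.max_steps * factor)),
    )
    return replace(
        plan,
        name=f"{plan.name}-x{factor:g}",
        env=env,
        episodes=max(1, math.ceil(plan.episodes * factor)),
    )


@dataclass
class TrainResult:
    """A trained shared policy plus its per-episode learning curve."""

    policy: PolicyMemory
    curve: pd.DataFrame  # episode, total_reward, entropy, certainty


def train(plan: ExperimentPlan, seed: int | None = None, progress: bool = False) -> TrainResult:
    """One training run: ``plan.episodes`` episodes sharing one H-matrix.

    The H-matrix persists across episodes; glow is re-zeroed inside each
    episode.  Training is noiseless regardless of the plan's evaluation
    noise setting.  With ``episodes == 0`` the uniform prior is returned.
    """
    seed = plan.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    logger.info(
        "train run start: plan=%s seed=%d hash=%s episodes=%d",
        plan.name, seed, plan.config_hash(), plan.episodes,
    )
    policy = PolicyMemory.uniform(plan.actions.m)
    train_env = replace(plan.env, sensor_noise_sigma_deg=0.0)
    episodes = range(plan.episodes)
    if progress:
        from tqdm import tqdm

        episodes = tqdm(episodes, desc=f"train[{plan.name}]")
    rows = []
    for ep in episodes:
        result = run_episode(
            policy,
            plan.actions,
            train_env,
            plan.weights,
            rng,
            learn=True,
            eta=plan.eta,
            gamma=plan.gamma,
        )
        table = policy_table(policy)
        rows.append(
            {
                "episode": ep,
                "total_reward": result.total_reward,
                "entropy": average_entropy(table),
                "certainty": average_certainty(table),
            }
        )
    curve = pd.DataFrame(rows, columns=["episode", "total_reward", "entropy", "certainty"])
    return TrainResult(policy=policy, curve=curve)


@dataclass
class EvalResult:
    """Frozen-policy evaluation: per-episode records and their aggregate."""

    episodes: pd.DataFrame
    series: list[MetricsSeries]
    aggregate: dict

    @property
    def success_rate(self) -> float:
        return float(self.aggregate["success_rate"])


def evaluate(
    policy,
    plan: ExperimentPlan,
    *,
    episodes: int | None = None,
    sigma_deg: float | None = None,
    seed: int | None = None,
    keep_series: bool = True,
) -> EvalResult:
    """Replay a frozen policy over fresh random initial conditions.

    Aggregates (means over episodes unless noted): success rate, first
    alignment step, steady-window polarization, per-episode peak
    elongation, and the max polarization reached by step 100.
    """
    episodes = plan.eval_episodes if episodes is None else episodes
    sigma = plan.env.sensor_noise_sigma_deg if sigma_deg is None else sigma_deg
    env = replace(plan.env, sensor_noise_sigma_deg=sigma)
    rng = np.random.default_rng(plan.seed + 1_000_003 if seed is None else seed)
    rows, series_list = [], []
    for ep in range(episodes):
        result = run_episode(policy, plan.actions, env, plan.weights, rng, learn=False)
        s = summarize(result.metrics, success_radius=env.success_radius)
        rows.append(
            {
                "episode": ep,
                "success": s.success,
                "success_step": s.success_step,
                "alignment_step": s.alignment_step,
                "mean_polarization": s.mean_polarization,
                "peak_elongation": s.peak_elongation,
                "early_peak_polarization": early_peak_polarization(result.metrics),
                "total_reward": result.total_reward,
            }
        )
        if keep_series:
            series_list.append(result.metrics)
    df = pd.DataFrame(rows)
    aggregate = {
        "episodes": episodes,
        "sigma_deg": sigma,
        "success_rate": float(df["success"].mean()),
        "mean_alignment_step": float(df["alignment_step"].dropna().mean())
        if df["alignment_step"].notna().any()
        else float("nan"),
        "mean_polarization": float(df["mean_polarization"].mean()),
        "mean_peak_elongation": float(df["peak_elongation"].mean()),
        "max_peak_elongation": float(df["peak_elongation"].max()),
        "mean_early_peak_polarization": float(df["early_peak_polarization"].mean()),
    }
    return EvalResult(episodes=df, series=series_list, aggregate=aggregate)


def _run_setting(plan: ExperimentPlan, run_seeds: list[int]) -> dict:
    """Train/evaluate ``plan`` once per seed and average the run-level metrics."""
    cert, ent, pol, elo, succ = [], [], [], [], []
    for rs in run_seeds:
        trained = train(plan, seed=rs)
        table = policy_table(trained.policy)
        ev = evaluate(trained.policy, plan, seed=rs + 500_009, keep_series=False)
        cert.append(average_certainty(table))
        ent.append(average_entropy(table))
        pol.append(ev.aggregate["mean_polarization"])
        elo.append(ev.aggregate["max_peak_elongation"])
        succ.append(ev.aggregate["success_rate"])
    return {
        "avg_certainty": float(np.mean(cert)),
        "avg_entropy": float(np.mean(ent)),
        "avg_polarization": float(np.mean(pol)),
        "max_elongation": float(np.mean(elo)),
        "success_rate": float(np.mean(succ)),
    }


def _run_seeds(plan: ExperimentPlan, salt: int) -> list[int]:
    ss = np.random.SeedSequence([plan.seed, salt])
    return [int(s) for s in ss.generate_state(plan.n_runs) % (2**31)]


def sweep_granularity(plan: ExperimentPlan, grid=GRANULARITY_GRID) -> pd.DataFrame:
    """Re-train at each (m, Δθ) action-granularity setting and tabulate metrics.

    The grid spans coarse (5 x 7°) to fine (29 x 1°) discretizations
    around a ~14° maximum steering angle.
    """
    rows = []
    for m, dtheta in grid:
        sub = replace(plan, actions=ActionSpace(m=m, delta_theta_deg=dtheta))
        rows.append(
            {"m": m, "delta_theta_deg": dtheta, **_run_setting(sub, _run_seeds(plan, m))}
        )
    return pd.DataFrame(rows)


def sweep_rewards(plan: ExperimentPlan, grid=REWARD_GRID) -> pd.DataFrame:
    """Re-train at each (λd, λr) reward weighting and tabulate metrics."""
    rows = []
    for ld, lr in grid:
        sub = replace(plan, weights=RewardWeights(lambda_d=ld, lambda_r=lr))
        rows.append(
            {
                "lambda_d": ld,
                "lambda_r": lr,
                **_run_setting(sub, _run_seeds(plan, int(1000 * ld))),
            }
        )
    return pd.DataFrame(rows)


def noise_suite(policy, plan: ExperimentPlan, sigmas=NOISE_GRID) -> pd.DataFrame:
    """Evaluate one frozen policy under increasing sensory noise levels."""
    rows = []
    for sigma in sigmas:
        ev = evaluate(policy, plan, sigma_deg=float(sigma), keep_series=False)
        rows.append(
            {
                "sigma_deg": float(sigma),
                "mean_polarization": ev.aggregate["mean_polarization"],
                "mean_peak_elongation": ev.aggregate["mean_peak_elongation"],
                "success_rate": ev.aggregate["success_rate"],
            }
        )
    return pd.DataFrame(rows)


def vicsek_baseline(
    plan: ExperimentPlan,
    vconfig: VicsekConfig | None = None,
    runs: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the weighted-Vicsek comparator under the plan's environment.

    Per run: success flag, peak elongation, and the elongation averaged
    over the navigation phase (start until the first target hit, or the
    whole episode if the target is never reached).
    """
    vconfig = vconfig or VicsekConfig(k_neighbors=plan.env.k_neighbors, speed=plan.env.speed)
    runs = plan.eval_episodes if runs is None else runs
    rng = np.random.default_rng(plan.seed + 77_003 if seed is None else seed)
    rows = []
    for r in range(runs):
        series = run_vicsek_experiment(vconfig, plan.env, rng)
        s = summarize(series, success_radius=plan.env.success_radius)
        stop = s.success_step if s.success_step is not None else len(series.t) - 1
        stop = max(stop, 1)
        rows.append(
            {
                "run": r,
                "success": s.success,
                "success_step": s.success_step,
                "peak_elongation": s.peak_elongation,
                "nav_peak_elongation": float(series.elongation[: stop + 1].max()),
                "nav_mean_elongation": float(series.elongation[: stop + 1].mean()),
                "mean_polarization": s.mean_polarization,
            }
        )
    return pd.DataFrame(rows)


def generalization_suite(policy, plan: ExperimentPlan, sizes=(30, 100, 150)) -> pd.DataFrame:
    """Stress the unmodified trained policy outside its training geometry.

    Scenarios: pursuit of a target moving at (-0.35, 0.35); the target
    rotated onto each coordinate axis at the training distance; and
    larger group sizes re-using the same shared policy.
    """
    rows = []

    def add(name: str, sub: ExperimentPlan) -> None:
        ev = evaluate(policy, sub, keep_series=False)
        rows.append(
            {
                "scenario": name,
                "target_x": sub.env.target[0],
                "target_y": sub.env.target[1],
                "n_agents": sub.env.n_agents,
                "success_rate": ev.aggregate["success_rate"],
                "mean_polarization": ev.aggregate["mean_polarization"],
                "mean_peak_elongation": ev.aggregate["mean_peak_elongation"],
            }
        )

    add("dynamic_target", replace(plan, env=replace(plan.env, target_velocity=(-0.35, 0.35))))
    dist = float(np.hypot(*plan.env.target))
    add("rotated_north", replace(plan, env=replace(plan.env, target=(0.0, dist))))
    add("rotated_east", replace(plan, env=replace(plan.env, target=(dist, 0.0))))
    for n in sizes:
        add(f"scale_N{n}", replace(plan, env=replace(plan.env, n_agents=n)))
    return pd.DataFrame(rows)


def parameter_count(state_count: int, action_count: int) -> int:
    """Number of learnable parameters of the tabular policy (9 x 15 = 135 here)."""
    if state_count < 1 or action_count < 1:
        raise ValueError("counts must be positive")
    return int(state_count) * int(action_count)


# -- configuration files ------------------------------------------------

def plan_to_dict(plan: ExperimentPlan) -> dict:
    return {
        "name": plan.name,
        "group_size": plan.env.n_agents,
        "topological_k": plan.env.k_neighbors,
        "init_radius": plan.env.init_radius,
        "speed": plan.env.speed,
        "target": list(plan.env.target),
        "target_velocity": list(plan.env.target_velocity),
        "m": plan.actions.m,
        "delta_theta_deg": plan.actions.delta_theta_deg,
        "eta": plan.eta,
        "gamma": plan.gamma,
        "lambda_d": plan.weights.lambda_d,
        "lambda_r": plan.weights.lambda_r,
        "episodes": plan.episodes,
        "max_steps": plan.env.max_steps,
        "sigma_deg": plan.env.sensor_noise_sigma_deg,
        "success_radius": plan.env.success_radius,
        "n_runs": plan.n_runs,
        "eval_episodes": plan.eval_episodes,
        "seed": plan.seed,
    }


def plan_from_dict(d: dict) -> ExperimentPlan:
    base = plan_to_dict(ExperimentPlan())
    unknown = set(d) - set(base)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**base, **d}
    env = EnvConfig(
        n_agents=merged["group_size"],
        k_neighbors=merged["topological_k"],
        init_radius=merged["init_radius"],
        speed=merged["speed"],
        max_steps=merged["max_steps"],
        target=tuple(merged["target"]),
        target_velocity=tuple(merged["target_velocity"]),
        sensor_noise_sigma_deg=merged["sigma_deg"],
        success_radius=merged["success_radius"],
        seed=merged["seed"],
    )
    return ExperimentPlan(
        name=merged["name"],
        env=env,
        actions=ActionSpace(m=merged["m"], delta_theta_deg=merged["delta_theta_deg"]),
        weights=RewardWeights(lambda_d=merged["lambda_d"], lambda_r=merged["lambda_r"]),
        eta=merged["eta"],
        gamma=merged["gamma"],
        episodes=merged["episodes"],
        n_runs=merged["n_runs"],
        eval_episodes=merged["eval_episodes"],
        seed=merged["seed"],
    )


def save_plan(plan: ExperimentPlan, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(plan_to_dict(plan), fh, sort_keys=False)


def load_plan(path) -> ExperimentPlan:
    with open(path) as fh:
        return plan_from_dict(yaml.safe_load(fh) or {})
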