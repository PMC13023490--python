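"""Projective-simulation memory: weight table, glow, and policy diagnostics.

The decision model is a two-layer episodic memory.  Nine discrete percepts
(a neighbor-alignment cue paired with a target-bearing cue, each in
{right, aligned, left}) connect to ``m`` discrete steering actions through
non-negative weights ``h[s, a]`` — the H-matrix.  Action selection is a
single random-walk hop over the outgoing edges of the active percept::

    P(a | s) = h[s, a] / sum_k h[s, k]

Learning couples the H-matrix (long-term memory, shared by the whole
swarm) to a per-agent glow table (short-term eligibility, the G-matrix):
every step the glow decays geometrically by ``1 - eta``, the edge the
agent just used is re-lit by +1, and the scalar reward moves every weight
in proportion to its glow.  Because the H-matrix is a plain table, the
learned policy can be read out directly — normalized rows, per-state
entropy/certainty, and an explicit rule list.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

N_PERCEPTS = 9
#: cue semantics shared by both percept dimensions
CUE_LABELS = {0: "right", 1: "aligned", 2: "left"}

__all__ = [
    "N_PERCEPTS",
    "CUE_LABELS",
    "ActionSpace",
    "PolicyMemory",
    "GlowMemory",
    "Rule",
    "action_probabilities",
    "sample_action",
    "update_glow",
    "update_experience",
    "policy_table",
    "average_entropy",
    "average_certainty",
    "extract_rules",
    "save_policy_csv",
    "load_policy_csv",
    "save_rules_json",
]


@dataclass(frozen=True)
class ActionSpace:
    """Symmetric discrete steering angles.

    ``m`` must be odd so that the set contains an exact 0° (straight)
    action with ``(m-1)/2`` left turns mirrored by ``(m-1)/2`` right
    turns.  Action ``k`` steers by ``(k - (m-1)/2) * delta_theta_deg``
    degrees; positive angles are left (counter-clockwise) turns.
    """

    m: int = 15
    delta_theta_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.m % 2 == 0:
            raise ValueError(f"action count must be a positive odd integer, got {self.m}")
        if self.delta_theta_deg <= 0:
            raise ValueError("delta_theta_deg must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return (np.arange(self.m) - (self.m - 1) / 2) * self.delta_theta_deg

    @property
    def theta_max_deg(self) -> float:
        """Largest single-step steering magnitude, ((m-1)/2)·Δθ."""
        return (self.m - 1) / 2 * self.delta_theta_deg

    @property
    def straight_index(self) -> int:
        return (self.m - 1) // 2


class PolicyMemory:
    """The shared H-matrix: 9 percepts × m actions of experience weights.

    Entries are kept ≥ ``h_min`` > 0 so every row stays a valid
    (unnormalized) distribution even under sustained negative reward.
    """

    __slots__ = ("weights", "h_min")

    def __init__(self, weights: np.ndarray, h_min: float = 0.01):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != N_PERCEPTS:
            raise ValueError(f"weights must have shape (9, m), got {weights.shape}")
        if h_min <= 0:
            raise ValueError("h_min must be positive")
        if np.any(weights < h_min):
            raise ValueError("all weights must be >= h_min")
        self.weights = weights
        self.h_min = h_min

    @classmethod
    def uniform(cls, m: int = 15, h_min: float = 0.01) -> "PolicyMemory":
        """Fresh memory: every edge weight exactly 1 (the untrained prior)."""
        return cls(np.ones((N_PERCEPTS, m)), h_min=h_min)

    @property
    def m(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "PolicyMemory":
        return PolicyMemory(self.weights.copy(), h_min=self.h_min)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PolicyMemory)
            and other.h_min == self.h_min
            and np.array_equal(other.weights, self.weights)
        )


class GlowMemory:
    """Per-agent G-matrices, stacked as an (n_agents, 9, m) array.

    Glow entries decay by ``1 - eta`` every step and the activated edge
    gains +1, so no entry can exceed the geometric fixed point ``1/eta``.
    Reset to zero at the start of every episode.
    """

    __slots__ = ("glow", "eta")

    def __init__(self, n_agents: int, m: int, eta: float = 0.1):
        if not 0 < eta <= 1:
            raise ValueError("eta must lie in (0, 1]")
        self.glow = np.zeros((n_agents, N_PERCEPTS, m))
        self.eta = eta

    @property
    def n_agents(self) -> int:
        return self.glow.shape[0]

    def reset(self) -> None:
        self.glow[:] = 0.0


def action_probabilities(memory: PolicyMemory, percept: int) -> np.ndarray:
    """Normalized action distribution of one percept row (a single PS hop)."""
    row = memory.weights[percept]
    total = row.sum()
    if total <= 0:
        raise ValueError("memory row must have a strictly positive sum")
    return row / total


def sample_action(probabilities: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one action index from an explicit probability vector."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("probability vector is empty")
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValueError("probabilities must be non-negative and sum to 1")
    idx = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
    return min(idx, p.size - 1)


def update_glow(glow: GlowMemory, activated=None) -> GlowMemory:
    """Decay every glow entry by (1 - eta), then re-light the used edges.

    ``activated`` is ``None`` (pure decay), a single ``(percept, action)``
    pair (one agent), or a pair of integer arrays with one entry per agent.
    Mutates and returns ``glow``.
    """
    glow.glow *= 1.0 - glow.eta
    if activated is not None:
        percepts, actions = activated
        percepts = np.atleast_1d(np.asarray(percepts, dtype=int))
        actions = np.atleast_1d(np.asarray(actions, dtype=int))
        if percepts.shape != actions.shape or percepts.size != glow.n_agents:
            raise ValueError("activated pair must provide one (percept, action) per agent")
        if np.any((percepts < 0) | (percepts >= N_PERCEPTS)):
            raise IndexError("percept index out of range")
        if np.any((actions < 0) | (actions >= glow.glow.shape[2])):
            raise IndexError("action index out of range")
        glow.glow[np.arange(glow.n_agents), percepts, actions] += 1.0
    return glow


def update_experience(
    memory: PolicyMemory, glow: GlowMemory, reward, gamma: float = 0.0
) -> PolicyMemory:
    """H ← max(h_min, H − γ(H − 1) + Σ_i R_i · G_i); per-step credit assignment.

    ``reward`` is a scalar or one value per agent; each agent's reward is
    spread over its own glow and the contributions summed into the shared
    H-matrix.  ``gamma`` is the forgetting (dissipation) rate that relaxes
    weights back toward the uniform prior of 1; with the default γ=0 the
    update is pure accumulation.  Mutates and returns ``memory``.
    """
    if glow.glow.shape[1:] != memory.weights.shape:
        raise ValueError("glow and memory shapes do not match")
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    r = np.atleast_1d(np.asarray(reward, dtype=float))
    if r.size == 1:
        r = np.full(glow.n_agents, r.item())
    if r.size != glow.n_agents:
        raise ValueError("need one reward per agent (or a scalar)")
    if gamma > 0.0:
        memory.weights -= gamma * (memory.weights - 1.0)
    memory.weights += np.einsum("i,ism->sm", r, glow.glow)
    np.maximum(memory.weights, memory.h_min, out=memory.weights)
    return memory


def policy_table(memory: PolicyMemory) -> np.ndarray:
    """Row-normalize the H-matrix into the full P(a|s) lookup table."""
    w = memory.weights
    return w / w.sum(axis=1, keepdims=True)


def average_entropy(table: np.ndarray) -> float:
    """Mean Shannon entropy (bits) of the 9 per-state action distributions.

    Each perceptual state counts equally, so residual randomness in rare
    (e.g. conflict) states is not washed out by frequent ones.
    """
    p = np.asarray(table, dtype=float)
    terms = np.zeros_like(p)
    mask = p > 0
    terms[mask] = -p[mask] * np.log2(p[mask])
    return float(terms.sum(axis=1).mean())


def average_certainty(table: np.ndarray) -> float:
    """Mean over states of the maximum action probability; 1 ⇔ deterministic."""
    return float(np.asarray(table, dtype=float).max(axis=1).mean())


@dataclass(frozen=True)
class Rule:
    """One extracted behavioral rule: the preferred action of one percept."""

    state: int
    neighbor_cue: int
    target_cue: int
    action_index: int
    angle_deg: float
    probability: float
    deterministic: bool


def extract_rules(
    table: np.ndarray,
    action_space: ActionSpace,
    determinism_threshold: float = 0.9,
) -> list[Rule]:
    """Read the argmax action of every percept out of the policy table.

    A rule is flagged deterministic when its max probability reaches the
    threshold; argmax ties resolve to the smaller action index.
    """
    table = np.asarray(table, dtype=float)
    m = table.shape[1]
    if not 1.0 / m < determinism_threshold <= 1.0:
        raise ValueError("determinism_threshold must lie in (1/m, 1]")
    angles = action_space.angles_deg
    rules = []
    for s in range(N_PERCEPTS):
        a = int(np.argmax(table[s]))  # np.argmax already prefers the smaller index
        p = float(table[s, a])
        rules.append(
            Rule(
                state=s,
                neighbor_cue=s // 3,
                target_cue=s % 3,
                action_index=a,
                angle_deg=float(angles[a]),
                probability=p,
                deterministic=p >= determinism_threshold,
            )
        )
    return rules


def save_policy_csv(path, table: np.ndarray, action_space: ActionSpace) -> None:
    """Write a P(a|s) (or H) table as CSV: 9 rows, one column per angle."""
    cols = [f"{a:g}" for a in action_space.angles_deg]
    pd.DataFrame(np.asarray(table, dtype=float), columns=cols).to_csv(path, index=False)


def load_policy_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a policy CSV back; returns (table, action angles in degrees)."""
    df = pd.read_csv(path)
    angles = np.array([float(c) for c in df.columns])
    table = df.to_numpy(dtype=float)
    if table.shape[0] != N_PERCEPTS:
        raise ValueError(f"policy table must have 9 rows, got {table.shape[0]}")
    return table, angles


def save_rules_json(path, rules: list[Rule]) -> None:
    Path(path).write_text(json.dumps([asdict(r) for r in rules], indent=2))
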