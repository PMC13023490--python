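"""Geometry, percepts, rewards, and the synchronous swarm step."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psnav.ecm import ActionSpace, GlowMemory, PolicyMemory
from psnav.env import (
    EnvConfig,
    RewardWeights,
    SwarmState,
    apply_sensor_noise,
    compute_reward,
    discretize_angle,
    env_step,
    init_swarm,
    neighbor_angle,
    percept_index,
    run_episode,
    target_angle,
    topological_neighbors,
    turn,
)


def small_config(**kw):
    defaults = dict(n_agents=8, k_neighbors=3, target=(400.0, 0.0), max_steps=50)
    defaults.update(kw)
    return EnvConfig(**defaults)


class TestInitSwarm:
    def test_disk_uniform_moments(self):
        cfg = EnvConfig(n_agents=10_000, target=(600, 600))
        state = init_swarm(cfg, np.random.default_rng(0))
        radii = np.linalg.norm(state.positions, axis=1)
        assert radii.max() <= 300.0
        # area-uniform disk: E[r^2] = R^2 / 2
        assert np.mean(radii**2) == pytest.approx(300**2 / 2, rel=0.03)

    def test_initial_polarization_is_low(self):
        """Random headings give O(1/sqrt(N)) polarization, < 0.4 in ~99% of seeds."""
        from psnav.metrics import polarization

        cfg = EnvConfig(n_agents=30, target=(600, 600))
        exceed = sum(
            polarization(init_swarm(cfg, np.random.default_rng(seed)).headings) >= 0.4
            for seed in range(200)
        )
        assert exceed <= 4

    def test_seed_reproducibility(self):
        cfg = small_config()
        s1 = init_swarm(cfg, np.random.default_rng(5))
        s2 = init_swarm(cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(s1.positions, s2.positions)
        np.testing.assert_array_equal(s1.headings, s2.headings)


class TestTopologicalNeighbors:
    def test_collinear_points(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        assert list(topological_neighbors(pos, 0, 1)) == [1]

    def test_hexagon_beats_distant_point(self):
        angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        hexagon = np.column_stack((np.cos(angles), np.sin(angles)))
        pos = np.vstack(([[0.0, 0.0]], hexagon, [[50.0, 0.0]]))
        assert set(topological_neighbors(pos, 0, 6)) == {1, 2, 3, 4, 5, 6}

    def test_tie_goes_to_smaller_index(self):
        pos = np.array([[0.0, 0.0], [0.0, 2.0], [2.0, 0.0]])  # 1 and 2 equidistant from 0
        assert list(topological_neighbors(pos, 0, 1)) == [1]

    def test_k_must_be_less_than_n(self):
        pos = np.zeros((3, 2))
        with pytest.raises(ValueError):
            topological_neighbors(pos, 0, 3)


class TestAngles:
    def test_aligned_neighbors(self):
        assert neighbor_angle([1, 0], [[1, 0], [1, 0]]) == 0.0

    def test_counter_clockwise_positive(self):
        assert neighbor_angle([1, 0], [[0, 1]]) == pytest.approx(np.pi / 2)
        assert target_angle([1, 0], [0, 0], [0, 5]) == pytest.approx(np.pi / 2)

    def test_clockwise_negative(self):
        assert neighbor_angle([1, 0], [[0, -1]]) == pytest.approx(-np.pi / 2)
        assert target_angle([1, 0], [0, 0], [0, -5]) == pytest.approx(-np.pi / 2)

    def test_antiparallel_maps_to_plus_pi(self):
        assert neighbor_angle([1, 0], [[-1, 0]]) == pytest.approx(np.pi)
        assert target_angle([1, 0], [0, 0], [-5, 0]) == pytest.approx(np.pi)

    def test_vanishing_neighbor_average_reads_aligned(self):
        assert neighbor_angle([1, 0], [[0, 1], [0, -1]]) == 0.0

    def test_at_target_defined_as_zero(self):
        assert target_angle([1, 0], [3.0, 4.0], [3.0, 4.0]) == 0.0


class TestDiscretization:
    @pytest.mark.parametrize(
        "theta,cue",
        [
            (0.0, 1),
            (np.pi / 6, 1),
            (-np.pi / 6, 1),  # boundary closed on the aligned side
            (np.pi / 6 + 1e-9, 2),
            (-np.pi / 6 - 1e-9, 0),
            (np.pi, 2),
            (-np.pi + 1e-9, 0),
        ],
    )
    def test_cue_intervals(self, theta, cue):
        assert discretize_angle(theta) == cue

    def test_percept_index_conflict_states(self):
        # neighbors right + target left is conflict state 2; the mirror is 6
        assert percept_index(0, 2) == 2
        assert percept_index(2, 0) == 6
        assert percept_index(1, 1) == 4

    def test_percept_totality(self):
        """Every pair of angles lands in exactly one of the 9 states."""
        thetas = np.linspace(-np.pi + 1e-9, np.pi, 37)
        idx = {int(percept_index(discretize_angle(a), discretize_angle(b))) for a in thetas for b in thetas}
        assert idx == set(range(9))

    def test_invalid_cue_rejected(self):
        with pytest.raises(ValueError):
            percept_index(3, 0)

    def test_mirror_antisymmetry(self):
        """Reflection across the focal heading negates angles and swaps cues 0 and 2."""
        for theta in np.linspace(-np.pi + 0.01, np.pi - 0.01, 25):
            cue, mirrored = int(discretize_angle(theta)), int(discretize_angle(-theta))
            assert mirrored == {0: 2, 1: 1, 2: 0}[cue]


class TestSensorNoise:
    def test_zero_sigma_is_identity(self, rng):
        theta = np.linspace(-3, 3, 11)
        np.testing.assert_array_equal(apply_sensor_noise(theta, 0.0, rng), theta)

    def test_sample_sd_matches_sigma(self, rng):
        out = apply_sensor_noise(np.zeros(100_000), 30.0, rng)
        assert np.std(out) == pytest.approx(np.radians(30.0), rel=0.02)

    def test_wraps_into_principal_interval(self):
        # push pi - eps past pi with a deterministic large draw
        class FakeRng:
            def normal(self, loc, scale, size=None):
                return np.full(size, 0.5)

        out = apply_sensor_noise(np.array([np.pi - 0.1]), 30.0, FakeRng())
        assert -np.pi < out[0] <= np.pi
        assert out[0] < 0  # wrapped onto the negative branch

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_sensor_noise(np.zeros(3), -1.0, rng)


class TestTurn:
    def test_zero_angle_identity(self):
        np.testing.assert_allclose(turn([1.0, 0.0], 0.0), [1.0, 0.0])

    def test_quarter_turn_left(self):
        np.testing.assert_allclose(turn([1.0, 0.0], 90.0), [0.0, 1.0], atol=1e-12)

    def test_composition(self, rng):
        h = rng.normal(size=2)
        h /= np.linalg.norm(h)
        np.testing.assert_allclose(turn(turn(h, 2.0), 2.0), turn(h, 4.0), atol=1e-12)

    def test_norm_preserved(self, rng):
        angles = rng.uniform(0, 7, 20)
        h = np.column_stack((np.cos(angles), np.sin(angles)))
        out = turn(h, rng.uniform(-180, 180, 20))
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-12)


class TestReward:
    def test_step_straight_at_far_target(self):
        w = RewardWeights(0.5, 0.5)
        r = compute_reward([0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [1e7, 0.0], w)
        assert r.r_dis[0] == pytest.approx(1.0)
        assert r.r_dir[0] == pytest.approx(1.0)
        assert r.r_total[0] == pytest.approx(1.0)

    def test_step_directly_away(self):
        w = RewardWeights(0.5, 0.5)
        r = compute_reward([0.0, 0.0], [-1.0, 0.0], [-1.0, 0.0], [1e7, 0.0], w)
        assert r.r_dis[0] == pytest.approx(-1.0)
        assert r.r_dir[0] == 0.0  # clipped at zero
        assert r.r_total[0] == pytest.approx(-0.5)

    def test_perpendicular_step_far_target_limit(self):
        w = RewardWeights(0.5, 0.5)
        r = compute_reward([0.0, 0.0], [0.0, 1.0], [0.0, 1.0], [1e9, 0.0], w)
        assert abs(r.r_dis[0]) < 1e-6
        assert r.r_dir[0] < 1e-6
        assert abs(r.r_total[0]) < 1e-6


def _rotate(points, angle):
    c, s = np.cos(angle), np.sin(angle)
    return points @ np.array([[c, s], [-s, c]]).T


class TestInvariances:
    @given(st.integers(0, 2**31 - 1), st.floats(-np.pi, np.pi))
    def test_rotational_invariance_of_percepts_and_rewards(self, seed, angle):
        """Rotating everything about the origin changes no percept and no reward."""
        from psnav.env import _percepts

        cfg = small_config()
        r = np.random.default_rng(seed)
        state = init_swarm(cfg, r)
        rot = SwarmState(
            _rotate(state.positions, angle),
            _rotate(state.headings, angle),
            target=_rotate(state.target, angle),
        )
        quiet = np.random.default_rng(0)
        np.testing.assert_array_equal(
            _percepts(state, cfg, quiet), _percepts(rot, cfg, quiet)
        )
        w = RewardWeights()
        head = state.headings
        r1 = compute_reward(state.positions, state.positions + head, head, state.target, w)
        r2 = compute_reward(
            rot.positions, rot.positions + _rotate(head, angle), _rotate(head, angle), rot.target, w
        )
        np.testing.assert_allclose(r1.r_dis, r2.r_dis, atol=1e-8)
        np.testing.assert_allclose(r1.r_dir, r2.r_dir, atol=1e-8)

    def test_translation_invariance(self, rng):
        from psnav.env import _percepts

        cfg = small_config()
        state = init_swarm(cfg, rng)
        shift = np.array([123.4, -77.1])
        moved = SwarmState(
            state.positions + shift, state.headings, target=state.target + shift
        )
        quiet = np.random.default_rng(0)
        np.testing.assert_array_equal(_percepts(state, cfg, quiet), _percepts(moved, cfg, quiet))


class TestEnvStep:
    def test_speed_conservation(self, rng):
        cfg = small_config()
        state = init_swarm(cfg, rng)
        new, _ = env_step(state, PolicyMemory.uniform(15), ActionSpace(), cfg, RewardWeights(), rng)
        steps = np.linalg.norm(new.positions - state.positions, axis=1)
        np.testing.assert_allclose(steps, cfg.speed, atol=1e-12)

    def test_single_agent_straight_at_target_closes_distance_by_speed(self):
        cfg = EnvConfig(n_agents=2, k_neighbors=1, target=(100.0, 0.0), max_steps=10)
        state = SwarmState(
            np.array([[0.0, 0.0], [0.0, 1.0]]),
            np.array([[1.0, 0.0], [1.0, 0.0]]),
            target=np.array([100.0, 0.0]),
        )
        straight = ActionSpace().straight_index
        new, rec = env_step(
            state,
            lambda percepts: np.full(len(percepts), straight),
            ActionSpace(),
            cfg,
            RewardWeights(),
            np.random.default_rng(0),
        )
        assert rec.reward.r_dis[0] == pytest.approx(1.0)
        assert np.linalg.norm(new.target - new.positions[0]) == pytest.approx(99.0)

    def test_aligned_swarm_under_straight_policy_stays_polarized(self):
        from psnav.metrics import polarization

        cfg = small_config(target=(1e6, 0.0))
        pos = np.random.default_rng(3).uniform(-50, 50, (8, 2))
        state = SwarmState(pos, np.tile([1.0, 0.0], (8, 1)), target=np.array([1e6, 0.0]))
        straight = ActionSpace().straight_index
        policy = lambda percepts: np.full(len(percepts), straight)
        for _ in range(20):
            state, _ = env_step(state, policy, ActionSpace(), cfg, RewardWeights(), np.random.default_rng(0))
        assert polarization(state.headings) == pytest.approx(1.0)

    def test_learning_requires_glow(self, rng):
        cfg = small_config()
        state = init_swarm(cfg, rng)
        with pytest.raises(ValueError):
            env_step(state, PolicyMemory.uniform(15), ActionSpace(), cfg, RewardWeights(), rng, learn=True)


class TestRunEpisode:
    def test_frozen_policy_bit_identical(self, rng):
        cfg = small_config()
        mem = PolicyMemory.uniform(15)
        before = mem.weights.copy()
        run_episode(mem, ActionSpace(), cfg, RewardWeights(), rng, learn=False)
        np.testing.assert_array_equal(mem.weights, before)

    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        out = []
        for _ in range(2):
            res = run_episode(
                PolicyMemory.uniform(15), ActionSpace(), cfg, RewardWeights(),
                np.random.default_rng(11), learn=True,
            )
            out.append(res.metrics)
        np.testing.assert_array_equal(out[0].polarization, out[1].polarization)
        np.testing.assert_array_equal(out[0].centroid, out[1].centroid)

    @pytest.mark.parametrize("sigma", [0.0, 30.0])
    def test_kernel_matches_stepwise_reference(self, sigma):
        """The compiled episode loop reproduces the explicit env_step loop."""
        cfg = small_config(n_agents=12, k_neighbors=4, max_steps=120,
                           sensor_noise_sigma_deg=sigma, target=(300.0, 200.0))
        asp, w = ActionSpace(), RewardWeights()
        mem_fast = PolicyMemory.uniform(15)
        r_fast = np.random.default_rng(7)
        state0 = init_swarm(cfg, r_fast)
        fast = run_episode(mem_fast, asp, cfg, w, r_fast, learn=True, gamma=1e-3, state=state0)

        mem_ref = PolicyMemory.uniform(15)
        r_ref = np.random.default_rng(7)
        state = init_swarm(cfg, r_ref)
        glow = GlowMemory(cfg.n_agents, 15)
        for _ in range(cfg.max_steps):
            state, _ = env_step(state, mem_ref, asp, cfg, w, r_ref, glow=glow, learn=True, gamma=1e-3)
        np.testing.assert_allclose(mem_fast.weights, mem_ref.weights, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(fast.metrics.centroid[-1], state.positions.mean(axis=0), atol=1e-8)

    def test_stop_on_success_truncates(self):
        cfg = small_config(target=(120.0, 0.0), max_steps=500, success_radius=100.0)
        straight = ActionSpace().straight_index
        state = SwarmState(
            np.array([[0.0, -1.0], [0.0, 1.0], [1.0, 0.0], [-1.0, 0.0],
                      [0.0, -2.0], [0.0, 2.0], [2.0, 0.0], [-2.0, 0.0]]),
            np.tile([1.0, 0.0], (8, 1)),
            target=np.array([120.0, 0.0]),
        )
        table = np.full((9, 15), 1e-12)
        table[:, straight] = 1.0
        res = run_episode(
            table / table.sum(1, keepdims=True), ActionSpace(), cfg, RewardWeights(),
            np.random.default_rng(0), state=state, stop_on_success=True,
        )
        assert len(res.metrics.t) < 501
        assert res.metrics.dist_to_target[-1] <= 100.0
        assert np.all(res.metrics.dist_to_target[:-1] > 100.0)

    def test_trajectory_export_is_tidy(self, tmp_path, rng):
        cfg = small_config(max_steps=9)
        res = run_episode(
            PolicyMemory.uniform(15), ActionSpace(), cfg, RewardWeights(), rng,
            record_trajectory=True, record_every=3,
        )
        df = res.trajectory
        assert list(df.columns) == [
            "t", "agent_id", "x", "y", "heading_x", "heading_y", "percept", "action"
        ]
        assert sorted(df.t.unique()) == [0, 3, 6, 9]
        assert (df.groupby("t").size() == cfg.n_agents).all()
        assert df.loc[df.t == 0, "percept"].eq(-1).all()
        assert df.loc[df.t > 0, "action"].between(0, 14).all()
        out = tmp_path / "traj.csv"
        res.save_trajectory_csv(out)
        assert out.read_text().splitlines()[0] == "t,agent_id,x,y,heading_x,heading_y,percept,action"
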