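"""Episode runner: pre-pose, drop-to-contact, rollout, adjudication."""

from types import SimpleNamespace

import numpy as np
import pytest

from bedfall import humanoid
from bedfall.episodes import (
    EpisodeConfig,
    EpisodeRejected,
    RejectionCounter,
    drop_to_contact,
    generate_batch,
    pre_pose,
    reset_configuration,
    rollout_and_detect,
    run_episode,
)
from bedfall.labels import risk_label
from bedfall.sampling import InitialConfiguration, SamplerConfig, sample_initial_configuration
from bedfall.skeleton import features_from_state
from bedfall.world import (
    CONTACT_HAND_FLOOR,
    CONTACT_HUMANOID_BED,
    CONTACT_HUMANOID_FLOOR,
    ContactEvent,
    SimState,
)


def _hip_mid_height(state):
    pos = state.positions
    i, j = humanoid.KEYPOINT_INDEX["l_hip"], humanoid.KEYPOINT_INDEX["r_hip"]
    return (pos[i, 2] + pos[j, 2]) / 2.0


class TestPrePose:
    def test_identity_target_reproduces_reset_pose(self, world):
        target = reset_configuration(world)
        state = pre_pose(world, target, 1.0, drop_height=2.0)
        assert np.all(state.v == 0.0)
        expected = humanoid.forward_kinematics(
            np.array([0.0, 0.0, world.bed_top_height + 2.0]), target.root_quat, target.joints
        )
        assert np.allclose(state.positions, expected, atol=1e-12)

    def test_final_root_height_is_drop_height(self, world):
        rng = np.random.default_rng(3)
        for _ in range(5):
            target = sample_initial_configuration(rng, SamplerConfig(), world.bed_bounds)
            state = pre_pose(world, target, 1.0, drop_height=2.0)
            # the hip midpoint is the kinematic root
            assert _hip_mid_height(state) == pytest.approx(world.bed_top_height + 2.0, abs=1e-9)

    def test_endpoint_matches_target_joints(self, world):
        rng = np.random.default_rng(4)
        target = sample_initial_configuration(rng, SamplerConfig(), world.bed_bounds)
        state = pre_pose(world, target, 0.5, drop_height=2.0)
        root = np.array([*target.planar_xy, world.bed_top_height + 2.0])
        expected = humanoid.forward_kinematics(root, target.root_quat, target.joints)
        assert np.allclose(state.positions, expected, atol=1e-9)


class TestDropToContact:
    def test_centered_body_reaches_bed_contact(self, world):
        target = reset_configuration(world)
        posed = pre_pose(world, target, 1.0, drop_height=2.0)
        start = drop_to_contact(world, posed, timeout=2.0)
        assert start.t == 0.0
        assert np.all(start.v == 0.0)
        # at least one particle rests on the bed surface inside the footprint
        pos = start.positions
        x_min, x_max, y_min, y_max = world.bed_bounds
        on_surface = (
            (np.abs(pos[:, 2] - world.support_height()) < 1e-6)
            & (pos[:, 0] >= x_min)
            & (pos[:, 0] <= x_max)
            & (pos[:, 1] >= y_min)
            & (pos[:, 1] <= y_max)
        )
        assert on_surface.any()

    def test_body_beyond_footprint_times_out(self, world):
        target = InitialConfiguration(
            planar_xy=np.array([5.0, 5.0]),  # entirely off the bed
            root_quat=np.array([1.0, 0.0, 0.0, 0.0]),
            joints=humanoid.JointState.neutral(),
        )
        posed = pre_pose(world, target, 0.2, drop_height=2.0)
        with pytest.raises(EpisodeRejected) as exc:
            drop_to_contact(world, posed, timeout=1.0)
        assert exc.value.reason == "timeout"


class _StubWorld:
    """Scripted contact stream for testing adjudication without physics."""

    def __init__(self, events_by_step, dt=1 / 60):
        self.config = SimpleNamespace(sim_timestep=dt)
        self._events = events_by_step
        self._step = 0

    def step(self, state):
        self._step += 1
        new = SimState(q=state.q.copy(), v=state.v.copy(), t=state.t + self.config.sim_timestep)
        return new, self._events.get(self._step, [])


def _stub_state():
    return SimState(q=np.zeros(39), v=np.zeros(39), t=0.0)


class TestRolloutAdjudication:
    def test_hand_contact_alone_is_non_terminal(self):
        events = {10: [ContactEvent("l_wrist", "floor", CONTACT_HAND_FLOOR)]}
        stub = _StubWorld(events)
        outcome = rollout_and_detect(stub, _stub_state(), EpisodeConfig())
        assert not outcome.fell

    def test_hand_then_torso_contact_falls_at_torso_step(self):
        events = {
            10: [ContactEvent("l_wrist", "floor", CONTACT_HAND_FLOOR)],
            40: [ContactEvent("l_hip", "floor", CONTACT_HUMANOID_FLOOR)],
        }
        outcome = rollout_and_detect(_StubWorld(events), _stub_state(), EpisodeConfig())
        assert outcome.fell and outcome.fall_step == 40

    def test_full_window_without_contact_is_non_fall(self):
        outcome = rollout_and_detect(_StubWorld({}), _stub_state(), EpisodeConfig())
        assert not outcome.fell and outcome.fall_step is None
        assert len(outcome.contact_log) == 180

    def test_requires_frozen_start(self):
        state = _stub_state()
        state.t = 0.5
        with pytest.raises(ValueError):
            rollout_and_detect(_StubWorld({}), state, EpisodeConfig())

    def test_fall_step_is_first_qualifying_step(self, world):
        # physics episodes: re-scan the contact log for earlier qualifying contacts
        rng = np.random.default_rng(5)
        fallen = 0
        for _ in range(60):
            try:
                _, _, outcome = run_episode(rng, world, SamplerConfig(), EpisodeConfig())
            except EpisodeRejected:
                continue
            if not outcome.fell:
                continue
            fallen += 1
            for s, events in enumerate(outcome.contact_log, start=1):
                qualifying = any(e.kind == CONTACT_HUMANOID_FLOOR for e in events)
                if s < outcome.fall_step:
                    assert not qualifying
                elif s == outcome.fall_step:
                    assert qualifying
        assert fallen > 0


class TestRunEpisode:
    def test_seed_determinism(self, world):
        results = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            _, start, outcome = run_episode(rng, world, SamplerConfig(), EpisodeConfig())
            results.append((start.q.copy(), outcome.fell, outcome.fall_step))
        assert np.array_equal(results[0][0], results[1][0])
        assert results[0][1:] == results[1][1:]

    def test_rejection_counter_accounting(self, world):
        counter = RejectionCounter()
        target = InitialConfiguration(
            planar_xy=np.array([5.0, 5.0]),
            root_quat=np.array([1.0, 0.0, 0.0, 0.0]),
            joints=humanoid.JointState.neutral(),
        )
        posed = pre_pose(world, target, 0.2, drop_height=2.0)
        before = counter.total
        try:
            drop_to_contact(world, posed, timeout=0.5)
        except EpisodeRejected as exc:
            counter.add(exc.reason)
        assert counter.total == before + 1


class TestBatchGeneration:
    def test_batch_matches_single_episode_replay(self, world, label_config):
        seeds = np.arange(100, 140)
        batch = generate_batch(world, SamplerConfig(), EpisodeConfig(), label_config, seeds)
        checked = 0
        for i, seed in enumerate(seeds):
            if not batch.accepted[i]:
                continue
            rng = np.random.default_rng(int(seed))
            _, start, outcome = run_episode(rng, world, SamplerConfig(), EpisodeConfig())
            assert outcome.fell == bool(batch.fell[i])
            if outcome.fell:
                assert outcome.fall_step == batch.fall_step[i]
            u, v = features_from_state(world, start)
            assert np.allclose(u, batch.u[i], atol=1e-12)
            assert np.array_equal(v, batch.validity[i])
            checked += 1
        assert checked >= 30

    def test_accepted_outcomes_satisfy_invariants(self, world, label_config):
        batch = generate_batch(
            world, SamplerConfig(), EpisodeConfig(), label_config, np.arange(200)
        )
        acc = batch.accepted
        n_steps = EpisodeConfig().n_rollout_steps(world.sim_timestep)
        assert np.all((batch.fall_step[acc & batch.fell] >= 0))
        assert np.all((batch.fall_step[acc & batch.fell] <= n_steps))
        assert np.all(batch.y[acc & batch.fell] >= label_config.min_fall_label - 1e-12)
        assert np.all(batch.y[acc & ~batch.fell] == 0.0)
        assert np.all((batch.c[acc] == 1) == (batch.y[acc] > 0))
        assert np.isfinite(batch.u[acc]).all()

    def test_labels_match_risk_labeler(self, world, label_config):
        batch = generate_batch(
            world, SamplerConfig(), EpisodeConfig(), label_config, np.arange(300, 380)
        )
        from bedfall.episodes import EpisodeOutcome

        for i in np.flatnonzero(batch.accepted & batch.fell):
            outcome = EpisodeOutcome(fell=True, fall_step=int(batch.fall_step[i]), unstable=False)
            assert batch.y[i] == risk_label(outcome, 0, label_config)

    def test_forced_modes_pin_the_mode_column(self, world, label_config):
        from bedfall.sampling import PostureMode

        seeds = np.arange(20)
        batch = generate_batch(
            world,
            SamplerConfig(),
            EpisodeConfig(),
            label_config,
            seeds,
            forced_modes=[PostureMode.PRONE] * len(seeds),
        )
        assert all(m == "prone" for m in batch.mode)

    def test_sequence_frames_shape_and_fall_padding(self, world, label_config):
        batch = generate_batch(
            world, SamplerConfig(), EpisodeConfig(), label_config, np.arange(400, 700)
        )
        assert batch.frames.shape == (len(batch), 5, 26)
        early = np.flatnonzero(batch.fell & (batch.fall_step < 8) & batch.accepted)
        for i in early:
            last = int(batch.fall_step[i]) // 2
            for k in range(last + 1, 5):
                assert np.array_equal(batch.frames[i, k], batch.frames[i, last])
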