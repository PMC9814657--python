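"""Reward function, policy-gradient loss, replay/fine-tune updates, shaping."""

import numpy as np
import pytest

from smilesrl.buffer import ReplayBuffer
from smilesrl.chem import parse_and_canonicalize
from smilesrl.policy import (
    Adam,
    PolicyNetwork,
    pretrain_step,
    sample_trajectories,
    trajectory_logprobs,
    weighted_nll_and_grads,
)
from smilesrl.rl import (
    RewardConfig,
    RLConfig,
    ShapingState,
    experience_replay_step,
    finetune_step,
    policy_gradient_loss,
    policy_gradient_step,
    shaping_update,
    threshold_reward,
)
from smilesrl.vocab import build_vocabulary


class TestThresholdReward:
    def test_above_threshold_earns_r_pos(self):
        rc = RewardConfig()
        assert threshold_reward(0.9, ShapingState(p0=0.5), rc) == rc.r_pos

    def test_exactly_at_threshold_earns_r_neg(self):
        """The comparison is strict: p == p0 is a bad example."""
        rc = RewardConfig()
        assert threshold_reward(0.5, ShapingState(p0=0.5), rc) == rc.r_neg

    def test_zero_probability_earns_r_neg(self):
        rc = RewardConfig()
        assert threshold_reward(0.0, ShapingState(p0=0.05), rc) == rc.r_neg

    def test_r_pos_must_exceed_r_neg(self):
        with pytest.raises(ValueError):
            RewardConfig(r_pos=1.0, r_neg=2.0)


class TestPolicyGradientLoss:
    def test_zero_reward_gives_zero_loss(self, tiny_model):
        traj = tiny_model.vocab.encode_trajectory("CC")
        assert policy_gradient_loss(traj, 0.0, 0.97, tiny_model) == 0.0

    def test_gamma_one_reward_one_equals_total_nll(self, tiny_model):
        traj = tiny_model.vocab.encode_trajectory("CO")
        L = policy_gradient_loss(traj, 1.0, 1.0, tiny_model)
        assert L == pytest.approx(-trajectory_logprobs(tiny_model, traj).sum())

    def test_linear_in_reward(self, tiny_model):
        traj = tiny_model.vocab.encode_trajectory("CN")
        L1 = policy_gradient_loss(traj, 1.0, 0.9, tiny_model)
        assert policy_gradient_loss(traj, 3.5, 0.9, tiny_model) == pytest.approx(
            3.5 * L1
        )

    def test_single_step_closed_form(self, tiny_model):
        """N=1: L = -r * gamma^1 * ln q, the discount starting at gamma^1."""
        from smilesrl.vocab import Trajectory

        traj = Trajectory(token_ids=(tiny_model.vocab.stop_id,), terminated=True)
        q = float(np.exp(trajectory_logprobs(tiny_model, traj)[0]))
        r, gamma = 2.0, 0.8
        L = policy_gradient_loss(traj, r, gamma, tiny_model)
        assert L == pytest.approx(-r * gamma * np.log(q))

    def test_empty_trajectory_rejected(self, tiny_model):
        from smilesrl.vocab import Trajectory

        with pytest.raises(ValueError):
            policy_gradient_loss(
                Trajectory(token_ids=(), terminated=False), 1.0, 0.9, tiny_model
            )


class TestGradientOracle:
    def test_analytic_gradient_matches_finite_differences(self, tiny_model):
        """Exact BPTT vs central differences on a <200-parameter policy."""
        model = tiny_model.clone()
        assert model.n_params <= 200
        batch = [
            model.vocab.encode_trajectory("CC"),
            model.vocab.encode_trajectory("CO"),
        ]
        rewards = np.array([2.0, 1.0])
        gamma = 0.9
        T = max(len(t) for t in batch)
        w = rewards[:, None] * gamma ** np.arange(1, T + 1)[None, :]
        _, grads = weighted_nll_and_grads(model, batch, w)
        analytic = np.concatenate([grads[k].ravel() for k in sorted(grads)])
        theta = model.get_flat()
        eps = 1e-6
        fd = np.zeros_like(theta)
        for i in range(theta.size):
            for sign, store in ((+1, "hi"), (-1, "lo")):
                model.set_flat(theta + sign * eps * np.eye(1, theta.size, i)[0])
                val, _ = weighted_nll_and_grads(model, batch, w, compute_grads=False)
                if sign > 0:
                    hi = val
                else:
                    lo = val
            fd[i] = (hi - lo) / (2 * eps)
        model.set_flat(theta)
        scale = np.maximum(np.abs(fd), 1e-3)
        assert np.max(np.abs(analytic - fd) / scale) < 1e-4


class TestPolicyGradientStep:
    def test_zero_rewards_leave_parameters_unchanged(self, tiny_model):
        model = tiny_model.clone()
        before = model.get_flat()
        policy_gradient_step(model, lambda s: 0.0, RLConfig(), seed=0)
        assert np.array_equal(model.get_flat(), before)

    def test_seeded_determinism_on_frozen_copies(self, pretrained_model, oracle):
        rc = RewardConfig()
        shaping = ShapingState()

        def reward_fn(s):
            rec = parse_and_canonicalize(s)
            if not rec.is_valid:
                return rc.r_invalid
            return threshold_reward(oracle(rec.canonical_smiles), shaping, rc)

        m1 = policy_gradient_step(
            pretrained_model.clone(), reward_fn, RLConfig(), seed=4
        )
        m2 = policy_gradient_step(
            pretrained_model.clone(), reward_fn, RLConfig(), seed=4
        )
        assert m1 == m2


def _buffer_of(model, smiles, reward=1.0):
    buf = ReplayBuffer()
    for s in smiles:
        rec = parse_and_canonicalize(s)
        buf.admit(
            rec,
            p=0.9,
            p0=0.05,
            trajectory=model.vocab.encode_trajectory(rec.canonical_smiles),
            reward=reward,
        )
    return buf


class TestReplayAndFinetune:
    def test_replay_on_empty_buffer_is_an_error(self, tiny_model):
        with pytest.raises(ValueError):
            experience_replay_step(tiny_model, ReplayBuffer(), RLConfig(), 1, seed=0)

    def test_finetune_on_empty_buffer_is_an_error(self, tiny_model):
        with pytest.raises(ValueError):
            finetune_step(tiny_model, ReplayBuffer(), 1, seed=0)

    def test_replay_loss_equals_direct_policy_gradient_loss(self, tiny_model):
        model = tiny_model.clone()
        buf = _buffer_of(model, ["CC"], reward=3.0)
        rl = RLConfig(gamma=0.9)
        direct = policy_gradient_loss(buf.entries[0].trajectory, 3.0, 0.9, model)
        metrics = experience_replay_step(
            model.clone(), buf, rl, k=1, seed=0
        )
        assert metrics.mean_loss == pytest.approx(direct)

    def test_zero_reward_entry_gives_zero_update(self, tiny_model):
        model = tiny_model.clone()
        buf = _buffer_of(model, ["CC"], reward=0.0)
        before = model.get_flat()
        experience_replay_step(model, buf, RLConfig(), k=1, seed=0)
        assert np.array_equal(model.get_flat(), before)

    def test_replay_only_training_raises_buffer_likelihood(self, toy_vocab):
        model = PolicyNetwork(toy_vocab, hidden_size=32, embed_dim=16, seed=5)
        smiles = ["CCOc1ccccc1", "CNc1ccncc1", "CCC1CCOCC1"]
        buf = _buffer_of(model, smiles, reward=1.0)
        rl = RLConfig(gamma=1.0, learning_rate=1e-3)
        opt = Adam(model, lr=rl.learning_rate)

        def total_loglik():
            return sum(
                trajectory_logprobs(model, e.trajectory).sum() for e in buf.entries
            )

        before = total_loglik()
        for step in range(200):
            experience_replay_step(model, buf, rl, k=3, seed=step, optimizer=opt)
        assert total_loglik() > before

    def test_finetune_equals_pretrain_on_same_batch(self, tiny_model):
        buf = _buffer_of(tiny_model, ["CC", "CO"])
        drawn = buf.sample_entries(2, seed=12)
        m1, m2 = tiny_model.clone(), tiny_model.clone()
        loss_ft = finetune_step(m1, buf, k=2, seed=12, optimizer=Adam(m1))
        loss_pt = pretrain_step(m2, [e.trajectory for e in drawn], Adam(m2))
        assert loss_ft == pytest.approx(loss_pt)
        assert np.allclose(m1.get_flat(), m2.get_flat())


class TestShaping:
    def test_trigger_at_exactly_fifteen_percent(self):
        s = ShapingState(p0=0.05)
        probs = [0.5] * 450 + [0.0] * 2550  # 450/3000 = 15%
        shaping_update(s, probs)
        assert s.p0 == pytest.approx(0.10)

    def test_no_trigger_just_below_fifteen_percent(self):
        s = ShapingState(p0=0.05)
        probs = [0.5] * 449 + [0.0] * 2551
        shaping_update(s, probs)
        assert s.p0 == pytest.approx(0.05)

    def test_probability_at_threshold_does_not_count(self):
        s = ShapingState(p0=0.5)
        shaping_update(s, [0.5] * 3000)  # equal, not greater
        assert s.p0 == pytest.approx(0.5)

    def test_threshold_capped_below_one(self):
        s = ShapingState(p0=0.90)
        for _ in range(10):
            shaping_update(s, [1.0] * 100)
        assert s.p0 == pytest.approx(0.95)
        assert s.p0 < 1.0

    def test_empty_batch_leaves_state_unchanged(self):
        s = ShapingState(p0=0.25)
        shaping_update(s, [])
        assert s.p0 == 0.25

    def test_monotone_nondecreasing_in_exact_increments(self):
        rng = np.random.default_rng(0)
        s = ShapingState()
        history = [s.p0]
        for _ in range(50):
            shaping_update(s, list(rng.random(200)))
            history.append(s.p0)
        diffs = np.diff(history)
        assert np.all(diffs >= 0)
        assert all(
            d == 0 or d == pytest.approx(s.increment) for d in diffs
        )
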