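"""Policy-gradient training with sparse-reward heuristics.

The core objective is the discounted REINFORCE loss

    L(theta) = - sum_{i=1..N} r(s_N) * gamma^i * log p(s_i | s_{i-1}; theta),

a whole-trajectory reward r(s_N) spread over the token transitions with
a discount counted from the sequence start (gamma^1 on the first token).
Three heuristics combat reward sparsity:

* real-time reward shaping — a probability threshold p0 that starts low
  and ratchets upward as the policy improves (``ShapingState``);
* experience replay — policy-gradient updates teacher-forced along
  stored high-reward trajectories;
* fine-tuning — plain supervised (cross-entropy) updates on buffer
  molecules, identical in form to pretraining.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .buffer import ReplayBuffer, ReplayEntry
from .policy import (
    Adam,
    PolicyNetwork,
    decode_samples,
    pretrain_step,
    sample_trajectories,
    weighted_nll_and_grads,
)
from .vocab import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "RewardConfig",
    "ShapingState",
    "RLConfig",
    "StepMetrics",
    "threshold_reward",
    "policy_gradient_loss",
    "policy_gradient_step",
    "experience_replay_step",
    "finetune_step",
    "shaping_update",
]


@dataclass
class RewardConfig:
    """Two-level threshold reward.

    r_pos goes to molecules the predictor scores above the live
    threshold, r_neg to everything else that parses; unparseable strings
    get r_invalid. Values are not prescribed by the method itself — the
    defaults keep a nonzero signal on valid-but-inactive molecules so an
    unaided policy still optimizes validity.
    """

    r_pos: float = 10.0
    r_neg: float = 1.0
    r_invalid: float = 0.0

    def __post_init__(self) -> None:
        if not self.r_pos > self.r_neg:
            raise ValueError("r_pos must exceed r_neg")


@dataclass
class ShapingState:
    """Dynamic reward threshold p0 and its update rule.

    p0 rises by ``increment`` whenever at least ``trigger_fraction`` of a
    freshly generated evaluation batch scores strictly above the current
    p0; it never decreases and is capped below 1.
    """

    p0: float = 0.05
    increment: float = 0.05
    trigger_fraction: float = 0.15
    eval_batch_size: int = 3000
    p0_history: List[Tuple[int, float]] = field(default_factory=list)
    _step: int = 0


@dataclass
class RLConfig:
    gamma: float = 0.97
    learning_rate: float = 1e-4
    trajectories_per_step: int = 32

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")


@dataclass
class StepMetrics:
    mean_reward: float
    mean_loss: float
    n_trajectories: int


def threshold_reward(p: float, shaping: ShapingState, rc: RewardConfig) -> float:
    """R(s): r_pos iff the predicted active probability strictly exceeds p0.

    A prediction exactly at the threshold earns r_neg. Invalid molecules
    never reach this function — they are assigned rc.r_invalid upstream.
    """
    return rc.r_pos if p > shaping.p0 else rc.r_neg


def _pg_weights(
    batch: List[Trajectory], rewards: np.ndarray, gamma: float
) -> np.ndarray:
    """Weight matrix w[b, i] = reward_b * gamma^(i+1), i 0-based."""
    T = max(len(t) for t in batch)
    disc = gamma ** np.arange(1, T + 1)
    return rewards[:, None] * disc[None, :]


def policy_gradient_loss(
    t: Trajectory, reward: float, gamma: float, model: PolicyNetwork
) -> float:
    """The discounted REINFORCE loss of one trajectory, teacher-forced."""
    if len(t) == 0:
        raise ValueError("empty trajectory")
    w = _pg_weights([t], np.array([reward]), gamma)
    loss, _ = weighted_nll_and_grads(model, [t], w, compute_grads=False)
    return loss


def policy_gradient_step(
    model: PolicyNetwork,
    reward_fn: Callable[[str], float],
    rl: RLConfig,
    seed: int,
    optimizer: Optional[Adam] = None,
) -> StepMetrics:
    """Sample a batch, reward the decoded molecules, apply one update.

    ``reward_fn`` maps a decoded SMILES string to its reward (predictor +
    threshold + invalid handling composed by the caller). The update
    minimizes the batch-mean loss; an all-zero-reward batch leaves the
    parameters untouched.
    """
    if optimizer is None:
        optimizer = Adam(model, lr=rl.learning_rate)
    batch = sample_trajectories(model, rl.trajectories_per_step, seed=seed)
    rewards = np.array([reward_fn(s) for s in decode_samples(model, batch)])
    w = _pg_weights(batch, rewards, rl.gamma) / len(batch)
    loss, grads = weighted_nll_and_grads(model, batch, w)
    if np.any(rewards != 0.0):
        optimizer.step(grads)
    return StepMetrics(
        mean_reward=float(rewards.mean()),
        mean_loss=loss,
        n_trajectories=len(batch),
    )


def experience_replay_step(
    model: PolicyNetwork,
    buffer: ReplayBuffer,
    rl: RLConfig,
    k: int,
    seed: int,
    optimizer: Optional[Adam] = None,
    reward_of: Optional[Callable[[ReplayEntry], float]] = None,
) -> StepMetrics:
    """Policy-gradient update teacher-forced along k stored trajectories.

    Entries are drawn uniformly without replacement. By default each
    replayed trajectory carries its stored admission-time reward;
    ``reward_of`` overrides this (e.g. to recompute against the current
    shaping threshold).
    """
    if len(buffer) == 0:
        raise ValueError("cannot replay from an empty buffer")
    if k < 1:
        raise ValueError("k must be >= 1")
    if optimizer is None:
        optimizer = Adam(model, lr=rl.learning_rate)
    k = min(k, len(buffer))
    entries = buffer.sample_entries(k, seed=seed)
    batch = [e.trajectory for e in entries]
    if any(t is None for t in batch):
        raise ValueError("buffer entry lacks a trajectory; tokenize at admission")
    rewards = np.array(
        [e.reward if reward_of is None else reward_of(e) for e in entries]
    )
    w = _pg_weights(batch, rewards, rl.gamma) / len(batch)
    loss, grads = weighted_nll_and_grads(model, batch, w)
    if np.any(rewards != 0.0):
        optimizer.step(grads)
    return StepMetrics(
        mean_reward=float(rewards.mean()), mean_loss=loss, n_trajectories=k
    )


def finetune_step(
    model: PolicyNetwork,
    buffer: ReplayBuffer,
    k: int,
    seed: int,
    optimizer: Optional[Adam] = None,
) -> float:
    """Transfer-learning update: supervised cross-entropy on k buffer draws.

    Identical to pretraining on the drawn trajectories — no reward
    weighting, no discount.
    """
    if len(buffer) == 0:
        raise ValueError("cannot fine-tune from an empty buffer")
    if optimizer is None:
        optimizer = Adam(model)
    k = min(k, len(buffer))
    entries = buffer.sample_entries(k, seed=seed)
    return pretrain_step(model, [e.trajectory for e in entries], optimizer)


def shaping_update(shaping: ShapingState, probs: List[float]) -> ShapingState:
    """Raise p0 by one increment if the trigger fires on a fresh batch.

    Fires when the fraction of predictions strictly above the current p0
    is at least ``trigger_fraction``. p0 is capped at 1 - increment so
    rewards above it remain attainable. Mutates and returns ``shaping``.
    """
    shaping._step += 1
    if not probs:
        logger.warning("shaping_update called with no probabilities; unchanged")
        return shaping
    frac = sum(1 for p in probs if p > shaping.p0) / len(probs)
    if frac >= shaping.trigger_fraction:
        new_p0 = min(shaping.p0 + shaping.increment, 1.0 - shaping.increment)
        if not math.isclose(new_p0, shaping.p0):
            shaping.p0 = new_p0
            shaping.p0_history.append((shaping._step, new_p0))
    return shaping
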