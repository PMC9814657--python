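"""Shared fixtures: toy corpus, pretrained policy, ablation runs.

Everything is generated programmatically and seeded; the expensive
artifacts (pretrained model, the four-condition ablation) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import statistics

import pytest

from smilesrl import (
    PolicyNetwork,
    ReplayBuffer,
    RunConfig,
    SyntheticConfig,
    TrainingSchedule,
    build_vocabulary,
    evaluate_library,
    generate_toy_corpus,
    pretrain,
    run_training,
    substructure_oracle,
)
from smilesrl.buffer import init_from_generated
from smilesrl.rl import RLConfig
from smilesrl.synthetic import DEFAULT_MOTIF

CORPUS_SEED = 7
PRETRAIN_SEED = 0
PRETRAIN_EPOCHS = 15
PRETRAIN_LR = 2e-3


@pytest.fixture(scope="session")
def toy_corpus():
    """1000 unique valid SMILES; thiophene motif in 0.5% of them."""
    return generate_toy_corpus(SyntheticConfig(corpus_size=1000, seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def oracle():
    return substructure_oracle(DEFAULT_MOTIF)


@pytest.fixture(scope="session")
def toy_vocab(toy_corpus):
    return build_vocabulary(toy_corpus)


@pytest.fixture(scope="session")
def pretrained_model(toy_corpus, toy_vocab):
    """Naive generative model: pretrained on the toy corpus, no RL."""
    model = PolicyNetwork(toy_vocab, hidden_size=128, embed_dim=64, seed=PRETRAIN_SEED)
    pretrain(
        model,
        toy_corpus,
        n_epochs=PRETRAIN_EPOCHS,
        batch_size=64,
        lr=PRETRAIN_LR,
        seed=PRETRAIN_SEED,
    )
    return model


@pytest.fixture(scope="session")
def tiny_model():
    """A <200-parameter policy for exact-gradient and hand-check tests."""
    vocab = build_vocabulary(["CC", "CO", "CN"])
    return PolicyNetwork(vocab, hidden_size=3, embed_dim=2, seed=1)


ABLATION_CONDITIONS = {
    # (policy_iters, replay_iters, finetune_iters); conditions without
    # replay run 25 policy iterations, those with replay run 15
    "pg_only": (25, 0, 0),
    "ft_only": (25, 0, 20),
    "replay_only": (15, 10, 0),
    "both": (15, 10, 20),
}
ABLATION_SEEDS = (0, 1, 2)


def run_ablation_condition(pretrained, oracle, iters, seed):
    """One scaled-down training run; returns final-library metrics."""
    pi, ri, fi = iters
    model = pretrained.clone()
    schedule = TrainingSchedule(
        n_epochs=5,
        policy_iters=pi,
        replay_iters=ri,
        finetune_iters=fi,
        intermediate_gen_size=300,
        final_gen_size=1000,
        snapshot_every=0,
    )
    buffer = None
    if ri or fi:  # trick conditions start from a generated-actives buffer
        buffer = init_from_generated(
            pretrained, oracle, n=3000, p0=0.05, seed=seed + 900
        )
    config = RunConfig(rl=RLConfig())
    artifacts = run_training(
        model, oracle, schedule, config=config, buffer=buffer, seed=seed
    )
    m = evaluate_library(artifacts.final_library)
    return {
        "valid_fraction": m.valid_fraction,
        "active_fraction": m.active_fraction,
        "final_p0": artifacts.shaping.p0,
        "buffer_size": len(artifacts.buffer),
    }


@pytest.fixture(scope="session")
def ablation_results(pretrained_model, oracle):
    """Four Fig-2-style conditions x three seeds at toy scale."""
    out = {}
    for name, iters in ABLATION_CONDITIONS.items():
        out[name] = [
            run_ablation_condition(pretrained_model, oracle, iters, seed)
            for seed in ABLATION_SEEDS
        ]
    return out


def median_of(results, key):
    return statistics.median(r[key] for r in results)
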