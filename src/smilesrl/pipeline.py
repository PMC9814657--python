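"""Training-loop orchestration and library evaluation.

An epoch consists of three phases — policy gradient, experience replay,
fine-tuning — in that order. After each phase that actually ran, an
intermediate batch of molecules is generated, scored by the predictor,
admitted to the replay buffer where the score beats the live threshold,
and fed to the reward-shaping controller. Snapshot libraries are taken
every few epochs and a final library is generated for evaluation.

Two diagnostics track training: the *valid fraction* (valid and unique
SMILES over all generated trajectories — a falling value signals mode
collapse or degraded syntax) and the *active fraction* (predicted
actives at the 0.75 reporting cutoff over the valid-unique set).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .buffer import ReplayBuffer
from .chem import (
    MoleculeRecord,
    compute_fingerprint,
    murcko_scaffold,
    parse_and_canonicalize,
    tanimoto,
    ScaffoldKey,
)
from .policy import Adam, PolicyNetwork, decode_samples, sample_trajectories
from .rl import (
    RewardConfig,
    RLConfig,
    ShapingState,
    experience_replay_step,
    finetune_step,
    policy_gradient_step,
    threshold_reward,
)
from .vocab import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSchedule",
    "RunConfig",
    "EpochMetrics",
    "GeneratedLibrary",
    "RunArtifacts",
    "generate_library",
    "evaluate_library",
    "run_epoch",
    "run_training",
    "scaffold_report",
    "similarity_profile",
]

Scorer = Union[Callable[[str], float], "object"]  # callable or ensemble


@dataclass
class TrainingSchedule:
    """Epoch structure and generation sizes.

    The defaults mirror the full-scale protocol (20 epochs of 15 policy /
    10 replay / 20 fine-tune iterations, 3200-molecule intermediate
    generations, 16,000-molecule final library, snapshots every 2
    epochs); toy runs scale every size down. ``replay_iters=0`` together
    with ``finetune_iters=0`` is the "policy gradient only" condition.
    """

    n_epochs: int = 20
    policy_iters: int = 15
    replay_iters: int = 10
    finetune_iters: int = 20
    intermediate_gen_size: int = 3200
    final_gen_size: int = 16000
    snapshot_every: int = 2
    replay_batch: int = 16
    finetune_batch: int = 16

    def __post_init__(self) -> None:
        for name in ("n_epochs", "policy_iters", "replay_iters", "finetune_iters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RunConfig:
    reward: RewardConfig = field(default_factory=RewardConfig)
    rl: RLConfig = field(default_factory=RLConfig)
    shaping: ShapingState = field(default_factory=ShapingState)
    buffer_capacity: int = 5000
    replay_reward_mode: str = "current"  # or "stored"
    active_cutoff: float = 0.75

    def __post_init__(self) -> None:
        if self.replay_reward_mode not in ("current", "stored"):
            raise ValueError("replay_reward_mode must be 'current' or 'stored'")


@dataclass
class EpochMetrics:
    valid_fraction: float
    active_fraction: float
    current_p0: float
    mean_reward: float
    buffer_size: int


@dataclass
class GeneratedLibrary:
    """A scored generation batch plus its provenance."""

    records: List[MoleculeRecord]
    probabilities: List[float]  # aligned with records; sentinel 0 for invalid
    trajectories: List[Trajectory]
    total_trajectories: int
    metadata: Dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def valid_unique(self) -> List[Tuple[str, float]]:
        """(canonical_smiles, probability) of the first occurrence of each
        unique valid molecule, in generation order."""
        seen = set()
        out = []
        for rec, p in zip(self.records, self.probabilities):
            if rec.is_valid and rec.canonical_smiles not in seen:
                seen.add(rec.canonical_smiles)
                out.append((rec.canonical_smiles, p))
        return out


@dataclass
class RunArtifacts:
    metrics: List[Dict]
    snapshots: List[GeneratedLibrary]
    final_library: GeneratedLibrary
    buffer: ReplayBuffer
    shaping: ShapingState
    epoch_metrics: List[EpochMetrics]


def _as_batch_scorer(predictor: Scorer) -> Callable[[Sequence[str]], np.ndarray]:
    if hasattr(predictor, "predict_batch"):
        return predictor.predict_batch  # ClassifierEnsemble
    return lambda smiles: np.array([predictor(s) for s in smiles], dtype=float)


def generate_library(
    model: PolicyNetwork,
    predictor: Scorer,
    n: int,
    seed: int,
    metadata: Optional[Dict] = None,
) -> GeneratedLibrary:
    """Sample n trajectories, decode, canonicalize and score them."""
    trajs = sample_trajectories(model, n, seed=seed)
    smiles = decode_samples(model, trajs)
    records = [parse_and_canonicalize(s) for s in smiles]
    scorer = _as_batch_scorer(predictor)
    probs = np.zeros(len(records))
    valid_idx = [i for i, r in enumerate(records) if r.is_valid]
    if valid_idx:
        probs[valid_idx] = scorer([records[i].canonical_smiles for i in valid_idx])
    return GeneratedLibrary(
        records=records,
        probabilities=probs.tolist(),
        trajectories=trajs,
        total_trajectories=n,
        metadata=dict(metadata or {}, seed=seed),
    )


def evaluate_library(
    lib: GeneratedLibrary,
    total_trajectories: Optional[int] = None,
    active_cutoff: float = 0.75,
) -> EpochMetrics:
    """Valid fraction and active fraction of a generation batch.

    valid_fraction = |valid and unique| / total trajectories;
    active_fraction = |valid-unique with p > cutoff| / |valid-unique|,
    defined as 0 when there are no valid-unique molecules.
    """
    total = total_trajectories if total_trajectories is not None else lib.total_trajectories
    if total < len(lib.records):
        raise ValueError("total_trajectories smaller than the library itself")
    vu = lib.valid_unique()
    valid_fraction = len(vu) / total if total else 0.0
    if vu:
        n_active = sum(1 for _, p in vu if p > active_cutoff)
        active_fraction = n_active / len(vu)
    else:
        active_fraction = 0.0
    return EpochMetrics(
        valid_fraction=valid_fraction,
        active_fraction=active_fraction,
        current_p0=float("nan"),
        mean_reward=float("nan"),
        buffer_size=0,
    )


def _admit_batch(
    lib: GeneratedLibrary,
    buffer: ReplayBuffer,
    shaping: ShapingState,
    rc: RewardConfig,
    step: int,
) -> int:
    admitted = 0
    for rec, p, traj in zip(lib.records, lib.probabilities, lib.trajectories):
        if buffer.admit(rec, p, shaping.p0, step=step, trajectory=traj, reward=rc.r_pos):
            admitted += 1
    return admitted


def run_epoch(
    model: PolicyNetwork,
    buffer: ReplayBuffer,
    predictor: Scorer,
    shaping: ShapingState,
    schedule: TrainingSchedule,
    rl_config: RLConfig,
    config: Optional[RunConfig] = None,
    optimizer: Optional[Adam] = None,
    seed: int = 0,
    epoch: int = 0,
    step_log: Optional[List[Dict]] = None,
) -> EpochMetrics:
    """One epoch: policy gradient, experience replay, fine-tuning.

    After each phase that has iterations scheduled, an intermediate
    batch is generated, scored, admitted to the buffer and used for a
    shaping update. Replay and fine-tune iterations on an empty buffer
    are skipped with a logged notice (and a bookkeeping row each).
    """
    config = config or RunConfig()
    rc = config.reward
    if optimizer is None:
        optimizer = Adam(model, lr=rl_config.learning_rate)
    scorer = _as_batch_scorer(predictor)

    def reward_fn(smiles: str) -> float:
        rec = parse_and_canonicalize(smiles)
        if not rec.is_valid:
            return rc.r_invalid
        return threshold_reward(float(scorer([rec.canonical_smiles])[0]), shaping, rc)

    def replay_reward(entry) -> float:
        if config.replay_reward_mode == "stored":
            return entry.reward
        return threshold_reward(entry.admission_probability, shaping, rc)

    rng = np.random.default_rng(seed)

    def next_seed() -> int:
        return int(rng.integers(2**31 - 1))

    last_lib: Optional[GeneratedLibrary] = None
    phases = [
        ("policy", schedule.policy_iters),
        ("replay", schedule.replay_iters),
        ("finetune", schedule.finetune_iters),
    ]
    for phase, iters in phases:
        for i in range(iters):
            row: Dict = {"epoch": epoch, "phase": phase, "iter": i}
            if phase == "policy":
                m = policy_gradient_step(
                    model, reward_fn, rl_config, seed=next_seed(), optimizer=optimizer
                )
                row.update(mean_reward=m.mean_reward, mean_loss=m.mean_loss)
            elif len(buffer) == 0:
                logger.info("epoch %d: %s skipped, buffer empty", epoch, phase)
                row["skipped"] = True
            elif phase == "replay":
                m = experience_replay_step(
                    model,
                    buffer,
                    rl_config,
                    k=schedule.replay_batch,
                    seed=next_seed(),
                    optimizer=optimizer,
                    reward_of=replay_reward,
                )
                row.update(mean_reward=m.mean_reward, mean_loss=m.mean_loss)
            else:
                loss = finetune_step(
                    model,
                    buffer,
                    k=schedule.finetune_batch,
                    seed=next_seed(),
                    optimizer=optimizer,
                )
                row.update(mean_loss=loss)
            if step_log is not None:
                step_log.append(row)
        if iters > 0:
            last_lib = generate_library(
                model,
                predictor,
                schedule.intermediate_gen_size,
                seed=next_seed(),
                metadata={"epoch": epoch, "phase": phase},
            )
            _admit_batch(last_lib, buffer, shaping, rc, step=epoch)
            from .rl import shaping_update

            shaping_update(shaping, list(last_lib.probabilities))
    if last_lib is None:  # degenerate (0,0,0) schedule: still measure
        last_lib = generate_library(
            model,
            predictor,
            schedule.intermediate_gen_size,
            seed=next_seed(),
            metadata={"epoch": epoch, "phase": "none"},
        )
    metrics = evaluate_library(last_lib, active_cutoff=config.active_cutoff)
    rewards = [
        rc.r_invalid
        if not rec.is_valid
        else threshold_reward(p, shaping, rc)
        for rec, p in zip(last_lib.records, last_lib.probabilities)
    ]
    return EpochMetrics(
        valid_fraction=metrics.valid_fraction,
        active_fraction=metrics.active_fraction,
        current_p0=shaping.p0,
        mean_reward=float(np.mean(rewards)) if rewards else float("nan"),
        buffer_size=len(buffer),
    )


def run_training(
    model: PolicyNetwork,
    predictor: Scorer,
    schedule: TrainingSchedule,
    config: Optional[RunConfig] = None,
    buffer: Optional[ReplayBuffer] = None,
    seed: int = 0,
    out_dir: Optional[str] = None,
) -> RunArtifacts:
    """Full training run: epochs, periodic snapshots, final library.

    Mutates ``model`` in place (it should be a pretrained checkpoint or
    a clone of one). Every step and epoch appends one metrics row; the
    run is bit-reproducible for a fixed seed.
    """
    config = config or RunConfig()
    if buffer is None:
        buffer = ReplayBuffer(capacity=config.buffer_capacity)
    shaping = config.shaping
    optimizer = Adam(model, lr=config.rl.learning_rate)
    rng = np.random.default_rng(seed)
    metrics: List[Dict] = []
    epoch_metrics: List[EpochMetrics] = []
    snapshots: List[GeneratedLibrary] = []
    for epoch in range(schedule.n_epochs):
        em = run_epoch(
            model,
            buffer,
            predictor,
            shaping,
            schedule,
            config.rl,
            config=config,
            optimizer=optimizer,
            seed=int(rng.integers(2**31 - 1)),
            epoch=epoch,
            step_log=metrics,
        )
        epoch_metrics.append(em)
        metrics.append({"epoch": epoch, "phase": "epoch", **asdict(em)})
        if schedule.snapshot_every and (epoch + 1) % schedule.snapshot_every == 0:
            snapshots.append(
                generate_library(
                    model,
                    predictor,
                    schedule.final_gen_size,
                    seed=int(rng.integers(2**31 - 1)),
                    metadata={"epoch": epoch, "kind": "snapshot"},
                )
            )
    final_library = generate_library(
        model,
        predictor,
        schedule.final_gen_size,
        seed=int(rng.integers(2**31 - 1)),
        metadata={"kind": "final"},
    )
    artifacts = RunArtifacts(
        metrics=metrics,
        snapshots=snapshots,
        final_library=final_library,
        buffer=buffer,
        shaping=shaping,
        epoch_metrics=epoch_metrics,
    )
    if out_dir is not None:
        _persist_run(artifacts, schedule, config, seed, out_dir)
    return artifacts


def _persist_run(
    artifacts: RunArtifacts,
    schedule: TrainingSchedule,
    config: RunConfig,
    seed: int,
    out_dir: str,
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "metrics.jsonl"), "w") as fh:
        for row in artifacts.metrics:
            fh.write(json.dumps(row) + "\n")
    manifest = {
        "seed": seed,
        "schedule": asdict(schedule),
        "reward": asdict(config.reward),
        "rl": asdict(config.rl),
        "shaping_final_p0": artifacts.shaping.p0,
        "replay_reward_mode": config.replay_reward_mode,
        "active_cutoff": config.active_cutoff,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts.buffer.to_csv(os.path.join(out_dir, "replay_buffer.csv"))
    _write_library(artifacts.final_library, os.path.join(out_dir, "final_library"))
    for i, snap in enumerate(artifacts.snapshots):
        _write_library(snap, os.path.join(out_dir, f"snapshot_{i:03d}"))


def _write_library(lib: GeneratedLibrary, stem: str) -> None:
    with open(stem + ".smi", "w") as fh:
        for smi, _ in lib.valid_unique():
            fh.write(smi + "\n")
    with open(stem + ".csv", "w") as fh:
        fh.write("canonical_smiles,probability\n")
        for smi, p in lib.valid_unique():
            fh.write(f"{smi},{p}\n")


def _percent_1dp(count: int, total: int) -> float:
    """count/total as a percentage, one decimal, round-half-up."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def scaffold_report(
    lib: GeneratedLibrary,
    top_k: int = 12,
    active_cutoff: float = 0.75,
) -> List[Tuple[ScaffoldKey, int, float]]:
    """The most common Bemis–Murcko scaffolds among predicted actives.

    Scaffolds are counted over the valid-unique molecules with predicted
    probability above the cutoff and sorted by decreasing count (ties by
    canonical scaffold string); percentages are of all predicted
    actives, rounded half-up to one decimal.
    """
    actives = [(smi, p) for smi, p in lib.valid_unique() if p > active_cutoff]
    if not actives:
        return []
    counts: Dict[ScaffoldKey, int] = {}
    for smi, _ in actives:
        key = murcko_scaffold(smi)
        counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].scaffold_smiles))
    total = len(actives)
    return [
        (key, count, _percent_1dp(count, total)) for key, count in ranked[:top_k]
    ]


def similarity_profile(
    lib: GeneratedLibrary,
    reference: Sequence[str],
    n_bits: int = 2048,
    radius: int = 2,
) -> Dict:
    """Max-Tanimoto-to-reference distribution of the library.

    For every valid-unique library member, the maximum Tanimoto
    similarity of its Morgan fingerprint to any reference molecule.
    Returns the values with their mean, median and a 10-bin histogram
    over [0, 1].
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    ref_fps = [compute_fingerprint(s, n_bits, radius) for s in reference]
    values = []
    for smi, _ in lib.valid_unique():
        fp = compute_fingerprint(smi, n_bits, radius)
        values.append(max(tanimoto(fp, r) for r in ref_fps))
    values = np.array(values)
    hist, edges = np.histogram(values, bins=10, range=(0.0, 1.0))
    return {
        "values": values,
        "mean": float(values.mean()) if len(values) else float("nan"),
        "median": float(np.median(values)) if len(values) else float("nan"),
        "histogram": hist,
        "bin_edges": edges,
    }
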