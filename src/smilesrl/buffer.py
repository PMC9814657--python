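"""Experience replay buffer of high-reward molecules.

A deduplicated (by canonical SMILES) store of trajectories whose
predicted active-class probability exceeded the reward threshold in
force when they were generated. Three initialization strategies are
supported: empty, actives sampled from a pretrained generator, or an
external compound library screened through the predictor and a
scaffold-dissimilarity filter.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

from .chem import MoleculeRecord, ScaffoldKey, murcko_scaffold, parse_and_canonicalize
from .vocab import Trajectory, Vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "ReplayEntry",
    "ReplayBuffer",
    "BufferInit",
    "init_from_external_library",
    "init_from_generated",
]


class BufferInit(enum.Enum):
    EMPTY = "empty"
    GENERATED_ACTIVES = "generated_actives"
    EXTERNAL_LIBRARY = "external_library"


@dataclass
class ReplayEntry:
    canonical_smiles: str
    trajectory: Optional[Trajectory]
    admission_probability: float
    admitted_at: int
    reward: float = 0.0  # reward in force at admission time


@dataclass
class ReplayBuffer:
    """Bounded, deduplicated store of replayable molecules.

    On overflow the entry with the lowest admission probability is
    evicted (ties broken by oldest admission step), so the buffer keeps
    its most convincing experiences.
    """

    capacity: int = 5000
    entries: List[ReplayEntry] = field(default_factory=list)
    _index: Dict[str, ReplayEntry] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, canonical_smiles: str) -> bool:
        return canonical_smiles in self._index

    def admit(
        self,
        mol: MoleculeRecord,
        p: float,
        p0: float,
        step: int = 0,
        trajectory: Optional[Trajectory] = None,
        reward: float = 0.0,
    ) -> bool:
        """Admit a molecule iff it is valid, scores strictly above p0 and
        is not already present. Returns whether it was admitted."""
        if not mol.is_valid or not p > p0:
            return False
        if mol.canonical_smiles in self._index:
            return False
        entry = ReplayEntry(
            canonical_smiles=mol.canonical_smiles,
            trajectory=trajectory,
            admission_probability=p,
            admitted_at=step,
            reward=reward,
        )
        self.entries.append(entry)
        self._index[entry.canonical_smiles] = entry
        if len(self.entries) > self.capacity:
            self._evict()
        return True

    def _evict(self) -> None:
        worst = min(
            self.entries, key=lambda e: (e.admission_probability, e.admitted_at)
        )
        self.entries.remove(worst)
        del self._index[worst.canonical_smiles]

    def sample_entries(self, k: int, seed: int) -> List[ReplayEntry]:
        """Uniform draw of k entries without replacement."""
        if k > len(self.entries):
            raise ValueError(f"cannot draw {k} from a buffer of {len(self.entries)}")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self.entries), size=k, replace=False)
        return [self.entries[i] for i in idx]

    def attach_trajectories(self, vocab: Vocabulary) -> int:
        """Tokenize entries admitted without a trajectory (e.g. from an
        external library). Entries whose SMILES contain symbols unknown
        to the vocabulary are dropped with a logged count."""
        kept: List[ReplayEntry] = []
        dropped = 0
        for e in self.entries:
            if e.trajectory is None:
                try:
                    e.trajectory = vocab.encode_trajectory(e.canonical_smiles)
                except ValueError:
                    dropped += 1
                    del self._index[e.canonical_smiles]
                    continue
            kept.append(e)
        self.entries = kept
        if dropped:
            logger.info("dropped %d buffer entries not tokenizable", dropped)
        return dropped

    # ------------------------------------------------------------------
    # persistence (audit/restart)
    # ------------------------------------------------------------------
    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["canonical_smiles", "admission_probability", "admitted_at"])
            for e in self.entries:
                w.writerow([e.canonical_smiles, e.admission_probability, e.admitted_at])

    @classmethod
    def from_csv(cls, path: str, capacity: int = 5000) -> "ReplayBuffer":
        buf = cls(capacity=capacity)
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                buf.admit(
                    parse_and_canonicalize(row["canonical_smiles"]),
                    p=float(row["admission_probability"]),
                    p0=-1.0,  # stored entries were already admitted once
                    step=int(row["admitted_at"]),
                )
        return buf


def init_from_external_library(
    smiles_list: Iterable[str],
    predict_fn,
    known_scaffolds: Set[ScaffoldKey],
    capacity: int = 5000,
    vocab: Optional[Vocabulary] = None,
) -> ReplayBuffer:
    """Seed a buffer from an external compound library.

    Keeps candidates with a strictly positive predicted active-class
    probability whose Bemis–Murcko scaffold is absent from
    ``known_scaffolds`` (exact membership — the point is dissimilarity
    from the predictor's own training chemistry). ``predict_fn`` maps a
    SMILES string to an active-class probability.
    """
    buf = ReplayBuffer(capacity=capacity)
    for smi in smiles_list:
        mol = parse_and_canonicalize(smi)
        if not mol.is_valid:
            continue
        if murcko_scaffold(mol.canonical_smiles) in known_scaffolds:
            continue
        p = float(predict_fn(mol.canonical_smiles))
        # non-zero probability filter: p0=0 with the strict comparison
        buf.admit(mol, p=p, p0=0.0, step=0)
    if vocab is not None:
        buf.attach_trajectories(vocab)
    return buf


def init_from_generated(
    model,
    predict_fn,
    n: int,
    p0: float,
    seed: int,
    capacity: int = 5000,
    r_pos: float = 10.0,
) -> ReplayBuffer:
    """Seed a buffer with predicted actives sampled from a pretrained model.

    The standard way to initialize training: generate n molecules from
    the (pretrained, unoptimized) policy and admit those whose predicted
    active-class probability strictly exceeds p0. Under sparse rewards
    the resulting buffer is small but it is what bootstraps replay and
    fine-tuning.
    """
    from .policy import decode_samples, sample_trajectories

    buf = ReplayBuffer(capacity=capacity)
    trajs = sample_trajectories(model, n, seed=seed)
    for traj, smi in zip(trajs, decode_samples(model, trajs)):
        rec = parse_and_canonicalize(smi)
        if not rec.is_valid:
            continue
        p = float(predict_fn(rec.canonical_smiles))
        buf.admit(rec, p=p, p0=p0, step=-1, trajectory=traj, reward=r_pos)
    return buf
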