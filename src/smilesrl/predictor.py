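"""Ensemble bioactivity classifier.

Five probabilistic binary classifiers (random forests by default)
trained on the five complements of a stratified 5-fold split of a
fingerprint/label table. The ensemble prediction is either the mean of
the members' active-class probabilities (the default) or the fraction of
members voting "active" — the latter is necessarily quantized to fifths
{0, 0.2, 0.4, 0.6, 0.8, 1.0}.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import List, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .chem import compute_fingerprint, parse_and_canonicalize

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityDataset",
    "ClassifierEnsemble",
    "train_ensemble",
    "predict_active_probability",
]

N_MEMBERS = 5


@dataclass
class ActivityDataset:
    """Deduplicated (canonical_smiles, label) table; label 1 = active."""

    frame: pd.DataFrame  # columns: canonical_smiles, label
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"canonical_smiles", "label"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"frame must have columns {required}")
        if self.frame["canonical_smiles"].duplicated().any():
            raise ValueError("duplicate canonical SMILES in activity dataset")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ClassifierEnsemble:
    members: List[RandomForestClassifier]
    aggregation_mode: str = "mean_probability"  # or "vote_fraction"
    n_bits: int = 2048
    radius: int = 2
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.members) != N_MEMBERS:
            raise ValueError(f"ensemble must have exactly {N_MEMBERS} members")
        if self.aggregation_mode not in ("mean_probability", "vote_fraction"):
            raise ValueError(f"unknown aggregation mode {self.aggregation_mode!r}")

    # --------------------------------------------------------------
    def _features(self, smiles: Sequence[str]) -> np.ndarray:
        return np.stack(
            [compute_fingerprint(s, self.n_bits, self.radius).bits for s in smiles]
        )

    def predict_batch(self, smiles: Sequence[str]) -> np.ndarray:
        """Active-class probability for each SMILES; invalid strings get
        the sentinel 0 (an unparseable molecule cannot be active)."""
        out = np.zeros(len(smiles))
        valid_idx, canon = [], []
        n_invalid = 0
        for i, s in enumerate(smiles):
            rec = parse_and_canonicalize(s)
            if rec.is_valid:
                valid_idx.append(i)
                canon.append(rec.canonical_smiles)
            else:
                n_invalid += 1
        if n_invalid:
            logger.warning("%d invalid SMILES scored as p=0", n_invalid)
        if not valid_idx:
            return out
        X = self._features(canon)
        per_member = np.stack([self._member_scores(m, X) for m in self.members])
        out[valid_idx] = per_member.mean(axis=0)
        return out

    def _member_scores(self, member, X: np.ndarray) -> np.ndarray:
        if self.aggregation_mode == "vote_fraction":
            return member.predict(X).astype(float)
        proba = member.predict_proba(X)
        active_col = list(member.classes_).index(1)
        return proba[:, active_col]

    # --------------------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        for i, m in enumerate(self.members):
            joblib.dump(m, os.path.join(directory, f"member_{i}.joblib"))
        manifest = {
            "aggregation_mode": self.aggregation_mode,
            "n_bits": self.n_bits,
            "radius": self.radius,
            "fold_seed": self.fold_seed,
            "n_members": N_MEMBERS,
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory: str) -> "ClassifierEnsemble":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        members = [
            joblib.load(os.path.join(directory, f"member_{i}.joblib"))
            for i in range(manifest["n_members"])
        ]
        return cls(
            members=members,
            aggregation_mode=manifest["aggregation_mode"],
            n_bits=manifest["n_bits"],
            radius=manifest["radius"],
            fold_seed=manifest["fold_seed"],
        )


def train_ensemble(
    data: ActivityDataset,
    seed: int,
    aggregation_mode: str = "mean_probability",
    n_estimators: int = 100,
    n_bits: int = 2048,
    radius: int = 2,
) -> ClassifierEnsemble:
    """Train the 5-member ensemble on a stratified 5-fold split.

    Member k is fitted on all folds except fold k, so each member has a
    disjoint held-out fold and the ensemble as a whole has seen every
    training molecule exactly four times.
    """
    df = data.frame
    if len(df) < 5 * N_MEMBERS:
        raise ValueError(f"need at least {5 * N_MEMBERS} rows for 5-fold training")
    y = df["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train the ensemble")
    ens = ClassifierEnsemble(
        members=[
            RandomForestClassifier(n_estimators=n_estimators, random_state=seed + i)
            for i in range(N_MEMBERS)
        ],
        aggregation_mode=aggregation_mode,
        n_bits=n_bits,
        radius=radius,
        fold_seed=seed,
    )
    X = ens._features(df["canonical_smiles"].tolist())
    skf = StratifiedKFold(n_splits=N_MEMBERS, shuffle=True, random_state=seed)
    for member, (train_idx, _) in zip(ens.members, skf.split(X, y)):
        member.fit(X[train_idx], y[train_idx])
    return ens


def predict_active_probability(ens: ClassifierEnsemble, smiles: str) -> float:
    """Aggregated active-class probability for one molecule.

    Mean of member probabilities in ``mean_probability`` mode; fraction
    of members voting active in ``vote_fraction`` mode. Invalid SMILES
    return the sentinel 0 with a logged warning.
    """
    return float(ens.predict_batch([smiles])[0])
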