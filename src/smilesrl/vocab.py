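"""SMILES tokenization and the policy network's action vocabulary.

Tokens are learned from a training corpus: bracket atoms (``[nH]``,
``[O-]``, ...) and the two-letter organic-subset halogens ``Cl``/``Br``
are single tokens; everything else is one character per token.
Tokenization is greedy longest-match, so any corpus string round-trips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

__all__ = ["Vocabulary", "Trajectory", "build_vocabulary"]

# Splits a SMILES into chemist-meaningful symbols. Bracket atoms are
# atomic; Cl/Br must win over C/B; all other symbols are 1 char.
_SMILES_TOKEN_RE = re.compile(r"(\[[^\]]+\]|Cl|Br|.)")

PAD = "<pad>"
START = "<start>"
STOP = "<stop>"


def _split_symbols(smiles: str) -> List[str]:
    return _SMILES_TOKEN_RE.findall(smiles)


@dataclass(frozen=True)
class Trajectory:
    """A token-id sequence s_1..s_N as produced/consumed by the policy.

    ``token_ids`` excludes the START prefix; if ``terminated`` the final
    id is STOP and STOP occurs nowhere else.
    """

    token_ids: Tuple[int, ...]
    terminated: bool

    def __len__(self) -> int:
        return len(self.token_ids)


@dataclass
class Vocabulary:
    """Bijective token<->id map over SMILES symbols plus PAD/START/STOP."""

    tokens: List[str]
    token_to_id: dict = field(init=False, repr=False)
    max_length: int = 0

    def __post_init__(self) -> None:
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        if len(self.token_to_id) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for special in (PAD, START, STOP):
            if self.tokens.count(special) != 1:
                raise ValueError(f"special token {special!r} must occur exactly once")
        # greedy longest-match order
        self._by_length = sorted(
            (t for t in self.tokens if t not in (PAD, START, STOP)),
            key=len,
            reverse=True,
        )

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def start_id(self) -> int:
        return self.token_to_id[START]

    @property
    def stop_id(self) -> int:
        return self.token_to_id[STOP]

    def tokenize(self, smiles: str) -> List[int]:
        """Greedy longest-match tokenization into ids (no START/STOP added)."""
        ids: List[int] = []
        i = 0
        while i < len(smiles):
            for tok in self._by_length:
                if smiles.startswith(tok, i):
                    ids.append(self.token_to_id[tok])
                    i += len(tok)
                    break
            else:
                raise ValueError(
                    f"unknown symbol at position {i} in {smiles!r}"
                )
        return ids

    def detokenize(self, ids: Sequence[int]) -> str:
        """Ids back to a SMILES string; PAD/START/STOP are dropped."""
        specials = {self.pad_id, self.start_id, self.stop_id}
        return "".join(self.tokens[i] for i in ids if i not in specials)

    def encode_trajectory(self, smiles: str) -> Trajectory:
        """Tokenize and append STOP — the teacher-forcing target sequence."""
        ids = self.tokenize(smiles) + [self.stop_id]
        return Trajectory(token_ids=tuple(ids), terminated=True)

    def decode_trajectory(self, t: Trajectory) -> str:
        return self.detokenize(t.token_ids)


def build_vocabulary(corpus: Sequence[str]) -> Vocabulary:
    """Learn the symbol set of a SMILES corpus.

    ``max_length`` is set to the longest corpus tokenization plus 2
    (room for the START prefix and the STOP terminator).
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    symbols = set()
    longest = 0
    for s in corpus:
        syms = _split_symbols(s)
        if "".join(syms) != s:
            raise ValueError(f"string does not tokenize cleanly: {s!r}")
        symbols.update(syms)
        longest = max(longest, len(syms))
    vocab = Vocabulary(tokens=[PAD, START, STOP] + sorted(symbols))
    vocab.max_length = longest + 2
    # round-trip guarantee on the training corpus
    for s in corpus:
        if vocab.detokenize(vocab.tokenize(s)) != s:
            raise ValueError(f"tokenization round-trip failed for {s!r}")
    return vocab
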