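"""Chemistry utilities on top of RDKit.

SMILES validity and canonicalization, fixed-length Morgan (ECFP-style)
bit fingerprints, Bemis–Murcko scaffolds and Tanimoto similarity.
Canonical SMILES is the deduplication key everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, TextIO, Union

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

# RDKit is chatty about every malformed SMILES; malformed input is an
# expected, handled case here (is_valid=False), not an event worth logging.
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "FingerprintVector",
    "ScaffoldKey",
    "parse_and_canonicalize",
    "compute_fingerprint",
    "tanimoto",
    "murcko_scaffold",
    "read_smi",
    "write_smi",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """A raw SMILES plus its canonical form and validity verdict.

    ``is_valid`` is true iff RDKit parsed and sanitized the string, in
    which case ``canonical_smiles`` holds RDKit's canonical form.
    """

    raw_smiles: str
    canonical_smiles: Optional[str] = None

    @property
    def is_valid(self) -> bool:
        return self.canonical_smiles is not None


@dataclass(frozen=True)
class FingerprintVector:
    """Fixed-length binary Morgan fingerprint."""

    bits: np.ndarray  # uint8 0/1, length n_bits
    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        if len(self.bits) != self.n_bits:
            raise ValueError(
                f"fingerprint length {len(self.bits)} != n_bits {self.n_bits}"
            )

    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class ScaffoldKey:
    """Canonical Bemis–Murcko scaffold SMILES; empty for acyclic molecules."""

    scaffold_smiles: str
    is_empty: bool


def parse_and_canonicalize(raw_smiles: str) -> MoleculeRecord:
    """Parse a SMILES string, returning a record with its canonical form.

    Never raises on malformed input: an unparseable or unsanitizable
    string yields ``is_valid=False``.
    """
    if not raw_smiles.strip():
        # RDKit parses "" as a zero-atom molecule; an empty string is not one
        return MoleculeRecord(raw_smiles=raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)  # sanitizes by default
    if mol is None:
        return MoleculeRecord(raw_smiles=raw_smiles)
    return MoleculeRecord(raw_smiles=raw_smiles, canonical_smiles=Chem.MolToSmiles(mol))


_FP_GENERATORS: dict = {}


def _fp_generator(n_bits: int, radius: int):
    key = (n_bits, radius)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _FP_GENERATORS[key]


def compute_fingerprint(
    canonical_smiles: str, n_bits: int = 2048, radius: int = 2
) -> FingerprintVector:
    """Morgan bit fingerprint (ECFP-equivalent at diameter 2*radius).

    Raises ``ValueError`` on invalid SMILES: callers are expected to
    pre-validate with :func:`parse_and_canonicalize`.
    """
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES cannot be fingerprinted: {canonical_smiles!r}")
    fp = _fp_generator(n_bits, radius).GetFingerprintAsNumPy(mol)
    return FingerprintVector(bits=fp.astype(np.uint8), n_bits=n_bits, radius=radius)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto (Jaccard) similarity |a∧b| / |a∨b|; 0 if both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 0.0
    return inter / union


def murcko_scaffold(canonical_smiles: str) -> ScaffoldKey:
    """Bemis–Murcko scaffold: ring systems plus linkers, substituents removed.

    Acyclic molecules have no scaffold and map to an empty key.
    """
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES has no scaffold: {canonical_smiles!r}")
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
    return ScaffoldKey(scaffold_smiles=scaffold, is_empty=(scaffold == ""))


def read_smi(source: Union[str, TextIO]) -> Iterator[str]:
    """Yield SMILES from a .smi file: one per line, optional whitespace-
    separated id, blank lines and '#' comments skipped."""
    if isinstance(source, str):
        with open(source) as fh:
            yield from read_smi(fh)
        return
    for line in source:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield line.split()[0]


def write_smi(path: str, smiles: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
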