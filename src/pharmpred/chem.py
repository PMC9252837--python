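"""Small-molecule parsing, canonicalization and fingerprinting.

All structure handling in the pipeline funnels through this module so that
every stage agrees on what "the same molecule" means: the RDKit canonical
isomeric SMILES. Stereochemistry is retained throughout — stereoisomers are
distinct structures for curation and lookup purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Structure",
    "FingerprintConfig",
    "Fingerprint",
    "SmilesParseError",
    "canonicalize",
    "is_salt",
    "fingerprint",
    "largest_fragment",
    "strip_stereo",
    "DEFAULT_COUNTERIONS",
]

#: Common counter-ions that mark a record as a salt even when the table
#: carries only the ion itself (single-fragment records).
DEFAULT_COUNTERIONS = frozenset(
    {
        "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[Cl-]", "[Br-]",
        "[I-]", "O=S(=O)(O)O", "Cl", "Br", "I", "[NH4+]", "O=C(O)C(=O)O",
    }
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; names the input."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"invalid SMILES: {smiles!r}")


@dataclass(frozen=True)
class Structure:
    """A parsed small molecule.

    Attributes
    ----------
    input_smiles:
        The SMILES string as given by the caller.
    canonical_smiles:
        RDKit canonical isomeric SMILES; the identity key used everywhere.
    n_fragments:
        Number of disconnected components ('.'-separated parts after
        parsing); 1 for an ordinary single molecule.
    id:
        Opaque caller-supplied identifier (empty string if none).
    """

    input_smiles: str
    canonical_smiles: str
    n_fragments: int
    id: str = ""

    @property
    def mol(self) -> Chem.Mol:
        """Re-materialized RDKit molecule (not cached; Structure stays picklable)."""
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass(frozen=True)
class FingerprintConfig:
    """Morgan (circular) fingerprint parameters.

    The defaults — 2048 bits, radius 2 (ECFP4-like) — are the published
    model configuration and should not be changed when reproducing it.
    """

    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint."""

    bits: np.ndarray = field(repr=False)
    config: FingerprintConfig = FingerprintConfig()

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return len(self.bits)


def canonicalize(smiles: str, id: str = "") -> Structure:
    """Parse a SMILES string into a :class:`Structure`.

    Canonicalization is a fixed point: feeding the canonical form back in
    returns the identical canonical form. Stereo descriptors are kept.

    Raises
    ------
    SmilesParseError
        If RDKit cannot parse the input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        # a zero-atom molecule (e.g. the empty string) is not a structure
        raise SmilesParseError(smiles)
    canonical = Chem.MolToSmiles(mol)
    n_frag = len(Chem.GetMolFrags(mol))
    return Structure(
        input_smiles=smiles, canonical_smiles=canonical, n_fragments=n_frag, id=id
    )


def is_salt(structure: Structure, counterions: frozenset[str] = DEFAULT_COUNTERIONS) -> bool:
    """Decide whether a record is a salt / multi-component entry.

    A record counts as a salt iff it has more than one disconnected
    fragment, or its canonical SMILES is itself a known counter-ion.
    Salt records are *dropped* during curation (not desalted): keeping the
    parent structure would plant near-duplicates of the free base in the
    training set and inflate validation accuracy.
    """
    if structure.n_fragments > 1:
        return True
    canon_ions = {canonicalize(s).canonical_smiles for s in counterions}
    return structure.canonical_smiles in canon_ions


def largest_fragment(structure: Structure) -> Structure:
    """Return the largest disconnected fragment (by heavy-atom count).

    Used only for *query* structures at prediction time, so users may paste
    salt forms; training-side curation never desalts.
    """
    if structure.n_fragments == 1:
        return structure
    frags = structure.canonical_smiles.split(".")
    best = max(frags, key=lambda s: Chem.MolFromSmiles(s).GetNumHeavyAtoms())
    return canonicalize(best, id=structure.id)


def strip_stereo(structure: Structure) -> str:
    """Canonical SMILES with all stereo descriptors removed.

    Supports the secondary "known for a stereoisomer" lookup in reports.
    """
    mol = Chem.MolFromSmiles(structure.canonical_smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def fingerprint(structure: Structure, config: FingerprintConfig = FingerprintConfig()) -> Fingerprint:
    """Morgan fingerprint of a structure under ``config``.

    Deterministic: identical canonical SMILES and config give bit-identical
    vectors. Bit collisions are accepted as-is (plain binary fingerprints,
    no count vectors).
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits
    )
    bv = gen.GetFingerprint(structure.mol)
    arr = np.zeros(config.n_bits, dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    arr.setflags(write=False)
    return Fingerprint(bits=arr, config=config)


def fingerprint_matrix(structures: list[Structure], config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Stack fingerprints for a list of structures into an (n, n_bits) array."""
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits
    )
    out = np.zeros((len(structures), config.n_bits), dtype=np.uint8)
    for i, s in enumerate(structures):
        for b in gen.GetFingerprint(s.mol).GetOnBits():
            out[i, b] = 1
    return out
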