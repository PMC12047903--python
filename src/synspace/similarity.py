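"""Molecular and string similarity metrics for analog evaluation.

Three fingerprint-based Tanimoto similarities characterise how close an
analog is to its target: 4096-bit Morgan (radius 2, the ECFP4-equivalent
field default), Morgan over Murcko scaffolds (ring systems and linkers only),
and Gobbi 2D pharmacophore fingerprints. A fourth, purely string-level
metric -- one minus normalized Levenshtein distance between canonical SMILES
-- guides product selection during route reconstruction, where chemically
close candidates must be ranked against a predicted product string.

Conventions for degenerate inputs: two empty fingerprints (acyclic molecules
under the scaffold metric, feature-free molecules under the pharmacophore
metric) compare as 1.0 when both are empty and 0.0 when only one is, keeping
every metric total and identity-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import edlib
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator
from rdkit.Chem.Pharm2D import Generate, Gobbi_Pharm2D
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import mol_from_smiles
from .errors import InvalidSmiles

__all__ = [
    "SimilarityProfile",
    "morgan_tanimoto",
    "scaffold_tanimoto",
    "pharmacophore_tanimoto",
    "smiles_string_similarity",
    "profile",
    "mean_profile",
]

DEFAULT_N_BITS = 4096
DEFAULT_RADIUS = 2


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


@lru_cache(maxsize=100_000)
def _morgan_fp(smiles: str, radius: int, n_bits: int):
    return _morgan_generator(radius, n_bits).GetFingerprint(mol_from_smiles(smiles))


@lru_cache(maxsize=100_000)
def _canonical(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def _tanimoto(a, b) -> float:
    # Both-empty convention: identical (similarity 1), not undefined.
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 1.0
    return DataStructs.TanimotoSimilarity(a, b)


def morgan_tanimoto(
    a: str, b: str, n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS
) -> float:
    """Tanimoto similarity of hashed Morgan fingerprints of two molecules."""
    return _tanimoto(_morgan_fp(a, radius, n_bits), _morgan_fp(b, radius, n_bits))


@lru_cache(maxsize=100_000)
def _scaffold_smiles(smiles: str) -> str:
    scaffold = MurckoScaffold.GetScaffoldForMol(mol_from_smiles(smiles))
    return Chem.MolToSmiles(scaffold)


def scaffold_tanimoto(a: str, b: str, n_bits: int = DEFAULT_N_BITS) -> float:
    """Morgan Tanimoto between the Murcko scaffolds of two molecules.

    Acyclic molecules have an empty scaffold: two empty scaffolds score 1.0,
    an empty against a non-empty scaffold scores 0.0.
    """
    sa, sb = _scaffold_smiles(a), _scaffold_smiles(b)
    if not sa or not sb:
        return 1.0 if sa == sb else 0.0
    return morgan_tanimoto(sa, sb, n_bits=n_bits)


@lru_cache(maxsize=20_000)
def _gobbi_fp(smiles: str):
    return Generate.Gen2DFingerprint(mol_from_smiles(smiles), Gobbi_Pharm2D.factory)


def pharmacophore_tanimoto(a: str, b: str) -> float:
    """Tanimoto similarity of Gobbi 2D pharmacophore fingerprints."""
    return _tanimoto(_gobbi_fp(a), _gobbi_fp(b))


def smiles_string_similarity(a: str, b: str) -> float:
    """1 - normalized edit distance between canonical SMILES strings.

    Works on canonical forms when both strings parse (so depictions of the
    same molecule score exactly 1.0) and falls back to the raw strings
    otherwise; always in [0, 1] and symmetric.
    """
    try:
        ca, cb = _canonical(a), _canonical(b)
    except InvalidSmiles:
        ca, cb = a, b
    if ca == cb:
        return 1.0
    longest = max(len(ca), len(cb))
    if longest == 0:
        return 1.0
    distance = edlib.align(ca, cb)["editDistance"]
    return 1.0 - distance / longest


@dataclass(frozen=True)
class SimilarityProfile:
    """The three fingerprint similarities between one molecule pair."""

    morgan: float
    scaffold: float
    pharmacophore: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.morgan, self.scaffold, self.pharmacophore)


def profile(a: str, b: str) -> SimilarityProfile:
    """Full similarity profile between two molecules."""
    return SimilarityProfile(
        morgan=morgan_tanimoto(a, b),
        scaffold=scaffold_tanimoto(a, b),
        pharmacophore=pharmacophore_tanimoto(a, b),
    )


def mean_profile(pairs: Iterable[tuple[str, str]]) -> SimilarityProfile:
    """Component-wise arithmetic mean of profiles over molecule pairs."""
    profiles = [profile(a, b) for a, b in pairs]
    if not profiles:
        raise ValueError("mean_profile needs at least one pair")
    n = len(profiles)
    return SimilarityProfile(
        morgan=sum(p.morgan for p in profiles) / n,
        scaffold=sum(p.scaffold for p in profiles) / n,
        pharmacophore=sum(p.pharmacophore for p in profiles) / n,
    )
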