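"""Deterministic toy chemical spaces for exercising the whole workflow.

Real building-block catalogs (Enamine-scale, hundreds of thousands of
molecules) cannot ship with a toolkit, so this module generates small
catalogs organised into the functional-group families such catalogs are
built around -- carboxylic acids, primary/secondary amines, aryl boronic
acids, aryl halides, sulfonyl chlorides, aldehydes -- together with a
registry of five standard two-component coupling templates (amide coupling,
Suzuki coupling, sulfonamide formation, reductive amination, ester
formation) written as textbook reaction SMARTS.

Members are produced by decorating small scaffolds (benzene, cyclohexane,
short chains) with the family's functional group plus substituents drawn
from a seeded stream; a few substituents are themselves reactive handles
(e.g. an aryl bromide on a benzoic acid) so that multi-step routes such as
amide coupling followed by Suzuki coupling exist in every default space.
Catalog generation is a pure function of the spec: the same spec always
yields a byte-identical catalog.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .chem import (
    BuildingBlock,
    ChemSpace,
    ReactionTemplate,
    canonicalize,
    make_template,
)

__all__ = [
    "FAMILIES",
    "FAMILY_PROBES",
    "FixtureSpec",
    "default_templates",
    "make_toy_catalog",
    "make_toy_space",
    "write_catalog",
    "write_templates",
]

#: Substructure probes that every generated member of a family must match.
FAMILY_PROBES: dict[str, str] = {
    "acid": "[CX3](=O)[OX2H1]",
    "primary_amine": "[NX3;H2;!$(NC=O)]",
    "secondary_amine": "[NX3;H1;!$(NC=O)]",
    "boronic_acid": "c[B]([OX2H1])[OX2H1]",
    "aryl_halide": "c[Cl,Br,I]",
    "sulfonyl_chloride": "[SX4](=O)(=O)Cl",
    "aldehyde": "[CX3H1](=O)[#6]",
}

FAMILIES: tuple[str, ...] = tuple(FAMILY_PROBES)

# Five standard couplings, all 2-slot. Amine slots exclude amide/sulfonamide
# nitrogens so that a coupling product cannot immediately re-react at the bond
# it just formed (keeps forward expansion from chaining on the same nitrogen).
_TEMPLATES: tuple[tuple[str, str, str], ...] = (
    (
        "T1",
        "amide coupling",
        "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(NC=O);!$(NS=O):3]>>[C:1](=[O:2])[N:3]",
    ),
    (
        "T2",
        "Suzuki coupling",
        "[c:1][B]([OX2H1])[OX2H1].[Cl,Br,I][c:2]>>[c:1][c:2]",
    ),
    (
        "T3",
        "sulfonamide formation",
        "[S:1](=[O:2])(=[O:3])[Cl].[NX3;H2,H1;!$(NC=O);!$(NS=O):4]>>[S:1](=[O:2])(=[O:3])[N:4]",
    ),
    (
        "T4",
        "reductive amination",
        "[CX3H1:1](=[OX1])[#6:2].[NX3;H2,H1;!$(NC=O);!$(NS=O):3]>>[CH2:1]([#6:2])[N:3]",
    ),
    (
        "T5",
        "ester formation",
        "[C:1](=[O:2])[OX2H1].[OX2H1][CX4:3]>>[C:1](=[O:2])O[C:3]",
    ),
)


def default_templates() -> list[ReactionTemplate]:
    """The five-template default registry; every SMARTS parses with 2 slots."""
    return [make_template(tid, name, smarts) for tid, name, smarts in _TEMPLATES]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy catalog: families, members per family, and a seed."""

    n_per_family: int = 20
    families: tuple[str, ...] = FAMILIES
    seed: int = 0

    def __post_init__(self):
        if self.n_per_family < 1:
            raise ValueError("n_per_family must be >= 1")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")


# Substituents used to decorate scaffolds. A couple of them are reactive
# handles (Br for Suzuki, aminomethyl/carboxyl for amide) so intermediates can
# recruit further reactions.
_PLAIN_SUBS = ["C", "CC", "F", "Cl", "OC", "C(C)C", "C(F)(F)F", "CCC", "OCC"]
_HANDLE_SUBS = ["Br", "C(=O)O", "CN"]

# Per family: templates with one {x} slot, plus undecorated base molecules.
_GRIDS: dict[str, tuple[list[str], list[str]]] = {
    "acid": (
        [
            "OC(=O)c1ccc({x})cc1",
            "OC(=O)c1cccc({x})c1",
            "OC(=O)C({x})C",
            "OC(=O)CC{x}",
            "OC(=O)C1CCC({x})CC1",
        ],
        ["OC(=O)c1ccccc1", "OC(=O)CC", "OC(=O)C1CCCCC1", "OC(=O)Cc1ccccc1"],
    ),
    "primary_amine": (
        [
            "NCc1ccc({x})cc1",
            "NCc1cccc({x})c1",
            "NCCC{x}",
            "NC1CCC({x})CC1",
        ],
        ["NCc1ccccc1", "NCCC", "NC1CCCCC1", "NCCc1ccccc1"],
    ),
    "secondary_amine": (
        [
            "CNCc1ccc({x})cc1",
            "CNCc1cccc({x})c1",
            "CNCCC{x}",
            "CCNCC{x}",
        ],
        ["CNCc1ccccc1", "CNCCC", "C1CCNCC1", "C1CNCCN1C"],
    ),
    "boronic_acid": (
        [
            "OB(O)c1ccc({x})cc1",
            "OB(O)c1cccc({x})c1",
            "OB(O)c1ccccc1{x}",
        ],
        ["OB(O)c1ccccc1", "OB(O)c1ccc2ccccc2c1"],
    ),
    "aryl_halide": (
        [
            "Brc1ccc({x})cc1",
            "Brc1cccc({x})c1",
            "Clc1ccc({x})cc1",
            "Ic1ccc({x})cc1",
        ],
        ["Brc1ccccc1", "Clc1ccccc1", "Brc1ccc2ccccc2c1", "Brc1ccncc1"],
    ),
    "sulfonyl_chloride": (
        [
            "ClS(=O)(=O)c1ccc({x})cc1",
            "ClS(=O)(=O)c1cccc({x})c1",
            "ClS(=O)(=O)CC{x}",
        ],
        ["ClS(=O)(=O)c1ccccc1", "ClS(=O)(=O)C"],
    ),
    "aldehyde": (
        [
            "O=Cc1ccc({x})cc1",
            "O=Cc1cccc({x})c1",
            "O=CCC{x}",
            "O=CC1CCC({x})CC1",
        ],
        ["O=Cc1ccccc1", "O=CCC", "O=CC1CCCCC1", "O=Cc1ccc2ccccc2c1"],
    ),
}


def _family_candidates(family: str) -> list[str]:
    """Deterministic, deduplicated canonical-SMILES pool for one family."""
    from rdkit import Chem

    sub_templates, bases = _GRIDS[family]
    probe = Chem.MolFromSmarts(FAMILY_PROBES[family])
    seen: set[str] = set()
    pool: list[str] = []
    raw = list(bases)
    for tpl in sub_templates:
        for sub in _PLAIN_SUBS + _HANDLE_SUBS:
            raw.append(tpl.format(x=sub))
    for smiles in raw:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or not mol.HasSubstructMatch(probe):
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen or "." in canon:
            continue
        seen.add(canon)
        pool.append(canon)
    return pool


def make_toy_catalog(spec: FixtureSpec) -> list[BuildingBlock]:
    """Generate ``n_per_family`` members for each requested family.

    Deterministic: the member list is a pure function of the spec. Members
    are drawn without replacement from each family's candidate grid after a
    seeded shuffle, so different seeds give different (overlapping) catalogs.
    """
    blocks: list[BuildingBlock] = []
    for family in spec.families:  # spec order, then per-family seeded order
        pool = _family_candidates(family)
        if spec.n_per_family > len(pool):
            raise ValueError(
                f"family {family!r} has only {len(pool)} distinct members "
                f"(requested {spec.n_per_family})"
            )
        rng = random.Random(f"{spec.seed}:{family}")
        rng.shuffle(pool)
        for i, smiles in enumerate(pool[: spec.n_per_family]):
            blocks.append(
                BuildingBlock(id=f"{family}_{i:03d}", smiles=smiles, source="catalog")
            )
    return blocks


def make_toy_space(
    n_per_family: int = 20,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
) -> ChemSpace:
    """Convenience: toy catalog + default templates + compatibility index."""
    spec = FixtureSpec(n_per_family=n_per_family, families=tuple(families), seed=seed)
    return ChemSpace(make_toy_catalog(spec), default_templates())


def write_catalog(blocks: Iterable[BuildingBlock], path: str | Path) -> None:
    """Write a catalog in the ``SMILES<TAB>id`` format the loaders read."""
    lines = [f"{bb.smiles}\t{bb.id}" for bb in blocks]
    Path(path).write_text("\n".join(lines) + "\n")


def write_templates(registry: Iterable[ReactionTemplate], path: str | Path) -> None:
    """Write a registry in the ``id<TAB>name<TAB>smarts`` TSV the loaders read."""
    lines = ["id\tname\tsmarts"]
    lines += [f"{t.id}\t{t.name}\t{t.smarts}" for t in registry]
    Path(path).write_text("\n".join(lines) + "\n")
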