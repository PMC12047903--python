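"""Building-block catalogs, reaction-template registries, and their compatibility index.

A *chemical space* is the pair (catalog of purchasable building blocks,
registry of reaction SMARTS templates) plus an index recording, for every
reactant slot of every template, which catalog molecules match that slot's
substructure pattern. Everything downstream -- route sampling, nearest-
neighbour candidate search, reconstruction -- is phrased against this index.

Compatibility is deliberately defined as a per-slot substructure match of the
template's reactant pattern, not full joint applicability with all partner
reactants: that is the unit the probabilistic sampler and the constrained
nearest-neighbour search both consume, and it is cheap to verify exhaustively.

All SMILES stored in these containers are RDKit-canonical; equality anywhere
in the toolkit means canonical-SMILES equality. Stereochemistry survives
canonicalization but plays no role in SMARTS matching unless a pattern asks
for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import EmptyCatalog, InvalidSmiles, InvalidTemplate

# Catalog loading and predictor-output parsing both feed arbitrary strings to
# the SMILES parser; keep RDKit's per-molecule error spam off stderr.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "BuildingBlock",
    "ReactionTemplate",
    "CompatibilityIndex",
    "ChemSpace",
    "canonicalize",
    "mol_from_smiles",
    "load_building_blocks",
    "load_reaction_templates",
    "build_compatibility_index",
    "applicable_reactions",
]


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES for ``smiles``.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.

    Raises
    ------
    InvalidSmiles
        If the string does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InvalidSmiles(smiles)
    return Chem.MolToSmiles(mol)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse ``smiles`` or raise :class:`InvalidSmiles` (atom-less counts as invalid)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InvalidSmiles(smiles)
    return mol


@dataclass(frozen=True)
class BuildingBlock:
    """A reactant molecule, either from the purchasable catalog or predicted.

    ``source`` distinguishes catalog members from novel building blocks that a
    predictor proposed but that are absent from the supplied catalog.
    """

    id: str
    smiles: str
    source: str = "catalog"  # "catalog" | "predicted"

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


@dataclass(frozen=True)
class ReactionTemplate:
    """A reaction SMARTS with ordered reactant slots and a single product.

    ``n_slots`` is derived from the SMARTS at load time and is always the
    number of reactant patterns (1-3 for the template sets this toolkit
    targets).
    """

    id: str
    name: str
    smarts: str
    n_slots: int

    def rxn(self) -> AllChem.ChemicalReaction:
        return _reaction_from_smarts(self.smarts)

    def slot_pattern(self, slot: int) -> Chem.Mol:
        """Query molecule for reactant slot ``slot`` (0-based)."""
        return self.rxn().GetReactantTemplate(slot)


# Parsed-reaction cache: ReactionFromSmarts is comparatively expensive and
# templates are reused across every sampling / matching call.
_RXN_CACHE: dict[str, AllChem.ChemicalReaction] = {}


def _reaction_from_smarts(smarts: str) -> AllChem.ChemicalReaction:
    rxn = _RXN_CACHE.get(smarts)
    if rxn is None:
        try:
            rxn = AllChem.ReactionFromSmarts(smarts)
        except Exception as exc:  # RDKit raises ValueError on bad SMARTS
            raise InvalidTemplate(f"unparsable reaction SMARTS {smarts!r}: {exc}") from exc
        if rxn is None:
            raise InvalidTemplate(f"unparsable reaction SMARTS {smarts!r}")
        rxn.Initialize()
        _RXN_CACHE[smarts] = rxn
    return rxn


def make_template(id: str, name: str, smarts: str) -> ReactionTemplate:
    """Validate ``smarts`` and build a :class:`ReactionTemplate`.

    The SMARTS must have at least one reactant pattern and exactly one product
    pattern; slot count is taken from the parsed reaction.
    """
    rxn = _reaction_from_smarts(smarts)
    n_reactants = rxn.GetNumReactantTemplates()
    n_products = rxn.GetNumProductTemplates()
    if n_reactants < 1:
        raise InvalidTemplate(f"template {id!r}: no reactant patterns in {smarts!r}")
    if n_products != 1:
        raise InvalidTemplate(
            f"template {id!r}: expected exactly 1 product pattern, got {n_products}"
        )
    return ReactionTemplate(id=id, name=name, smarts=smarts, n_slots=n_reactants)


@dataclass
class LoadReport:
    """Per-file accounting of rejected catalog lines."""

    n_loaded: int = 0
    rejected: list[tuple[int, str, str]] = field(default_factory=list)  # (lineno, line, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def load_building_blocks(
    path: str | Path, report: LoadReport | None = None
) -> list[BuildingBlock]:
    """Read a ``.smi``-style file into a canonicalized, deduplicated catalog.

    One record per line: ``SMILES`` optionally followed by whitespace and an
    id; lines starting with ``#`` and blank lines are ignored. Invalid SMILES
    and multi-fragment (salt) entries are skipped and recorded in ``report``.
    Duplicate canonical SMILES collapse to the first-seen id.

    Raises
    ------
    EmptyCatalog
        If no valid record remains.
    """
    path = Path(path)
    report = report if report is not None else LoadReport()
    blocks: list[BuildingBlock] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        bb_id = parts[1] if len(parts) > 1 else f"BB{lineno}"
        try:
            canon = canonicalize(smiles)
        except InvalidSmiles:
            report.rejected.append((lineno, line, "invalid SMILES"))
            continue
        if "." in canon:
            report.rejected.append((lineno, line, "multi-fragment (salt)"))
            continue
        if canon in seen:
            continue
        seen.add(canon)
        blocks.append(BuildingBlock(id=bb_id, smiles=canon, source="catalog"))
    report.n_loaded = len(blocks)
    if not blocks:
        raise EmptyCatalog(f"no valid building blocks in {path}")
    return blocks


def load_reaction_templates(path: str | Path) -> list[ReactionTemplate]:
    """Read a TSV (header ``id<TAB>name<TAB>smarts``) into a template registry.

    Raises
    ------
    InvalidTemplate
        On any unparsable row, with the offending row in the message.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise InvalidTemplate(f"empty template file {path}")
    header = lines[0].split("\t")
    if [h.strip().lower() for h in header[:3]] != ["id", "name", "smarts"]:
        raise InvalidTemplate(f"bad header in {path}: {lines[0]!r}")
    registry: list[ReactionTemplate] = []
    for row in lines[1:]:
        cols = row.split("\t")
        if len(cols) < 3:
            raise InvalidTemplate(f"row with <3 columns: {row!r}")
        try:
            registry.append(make_template(cols[0].strip(), cols[1].strip(), cols[2].strip()))
        except InvalidTemplate as exc:
            raise InvalidTemplate(f"{exc} (row: {row!r})") from exc
    return registry


class CompatibilityIndex:
    """Mapping ``(template_id, slot) -> ordered building-block ids``.

    Membership is exactly "the building block has the slot's reactant pattern
    as a substructure"; ids are kept sorted so that rebuilds are bit-exact.
    """

    def __init__(self, entries: Mapping[tuple[str, int], Sequence[str]]):
        self._entries: dict[tuple[str, int], tuple[str, ...]] = {
            key: tuple(sorted(ids)) for key, ids in entries.items()
        }

    def compatible(self, template_id: str, slot: int) -> tuple[str, ...]:
        return self._entries.get((template_id, slot), ())

    def items(self) -> Iterator[tuple[tuple[str, int], tuple[str, ...]]]:
        return iter(sorted(self._entries.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompatibilityIndex):
            return NotImplemented
        return self._entries == other._entries

    def to_json(self) -> str:
        """Serialize as ``{"templateId:slot": [ids...]}`` with sorted keys."""
        payload = {f"{tid}:{slot}": list(ids) for (tid, slot), ids in self._entries.items()}
        return json.dumps(payload, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CompatibilityIndex":
        payload = json.loads(text)
        entries: dict[tuple[str, int], list[str]] = {}
        for key, ids in payload.items():
            tid, _, slot = key.rpartition(":")
            entries[(tid, int(slot))] = list(ids)
        return cls(entries)


def build_compatibility_index(
    catalog: Sequence[BuildingBlock], registry: Sequence[ReactionTemplate]
) -> CompatibilityIndex:
    """Match every catalog molecule against every template slot pattern."""
    mols = [(bb.id, bb.mol()) for bb in catalog]
    entries: dict[tuple[str, int], list[str]] = {}
    for template in registry:
        rxn = template.rxn()
        for slot in range(template.n_slots):
            pattern = rxn.GetReactantTemplate(slot)
            entries[(template.id, slot)] = [
                bb_id for bb_id, mol in mols if mol.HasSubstructMatch(pattern)
            ]
    return CompatibilityIndex(entries)


class ChemSpace:
    """A catalog + registry + compatibility index, with id/SMILES lookups."""

    def __init__(
        self,
        catalog: Sequence[BuildingBlock],
        registry: Sequence[ReactionTemplate],
        index: CompatibilityIndex | None = None,
    ):
        self.catalog: list[BuildingBlock] = list(catalog)
        self.registry: list[ReactionTemplate] = list(registry)
        self.index: CompatibilityIndex = (
            index if index is not None else build_compatibility_index(catalog, registry)
        )
        self.by_id: dict[str, BuildingBlock] = {bb.id: bb for bb in self.catalog}
        self.by_smiles: dict[str, BuildingBlock] = {bb.smiles: bb for bb in self.catalog}
        self.template_by_id: dict[str, ReactionTemplate] = {t.id: t for t in self.registry}
        self.template_by_smarts: dict[str, ReactionTemplate] = {
            _normalize_smarts(t.smarts): t for t in self.registry
        }

    def template(self, template_id: str) -> ReactionTemplate:
        return self.template_by_id[template_id]

    def find_template_by_smarts(self, smarts: str) -> ReactionTemplate | None:
        """Registry template whose SMARTS string-matches ``smarts`` (whitespace-insensitive)."""
        return self.template_by_smarts.get(_normalize_smarts(smarts))

    def compatible_blocks(self, template_id: str, slot: int) -> list[BuildingBlock]:
        return [self.by_id[i] for i in self.index.compatible(template_id, slot)]


def _normalize_smarts(smarts: str) -> str:
    return "".join(smarts.split())


def applicable_reactions(
    space: ChemSpace, smiles: str
) -> list[tuple[str, int]]:
    """Template slots the molecule matches, with every partner slot coverable.

    Returns ``(template_id, slot_index)`` pairs such that the molecule has the
    slot's reactant pattern as a substructure and each *other* slot of the
    template has at least one compatible catalog building block. Order is
    deterministic (registry order, then slot index).
    """
    mol = mol_from_smiles(smiles)
    out: list[tuple[str, int]] = []
    for template in space.registry:
        rxn = template.rxn()
        for slot in range(template.n_slots):
            if not mol.HasSubstructMatch(rxn.GetReactantTemplate(slot)):
                continue
            partners_ok = all(
                space.index.compatible(template.id, other)
                for other in range(template.n_slots)
                if other != slot
            )
            if partners_ok:
                out.append((template.id, slot))
    return out


def enumerate_template_products(
    template: ReactionTemplate, reactant_smiles: Sequence[str]
) -> set[str]:
    """All distinct, valid, canonical products of one template application.

    Reactants must be given in slot order. Products that fail sanitization are
    dropped; the empty set means the template did not fire.
    """
    if len(reactant_smiles) != template.n_slots:
        return set()
    mols = []
    for s in reactant_smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            return set()
        mols.append(mol)
    rxn = template.rxn()
    products: set[str] = set()
    for product_set in rxn.RunReactants(tuple(mols)):
        for product in product_set:
            try:
                Chem.SanitizeMol(product)
            except Exception:
                continue
            products.add(Chem.MolToSmiles(product))
    return products
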