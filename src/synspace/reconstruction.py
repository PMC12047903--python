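"""Turn predicted retrosyntheses into replayable routes, analogs, or both.

Given a parsed predictor response (reaction SMARTS sequence in retrosynthetic
order plus a building-block list) and a chemical space, the reconstructor:

1. recovers forward order and assigns each reaction's reactants to its
   template's slots by exhaustive permutation search;
2. for every building-block position, runs a nearest-neighbour search over
   the catalog blocks *compatible with that slot's reactant pattern*, under
   two representations (canonical-SMILES edit similarity and Morgan Tanimoto),
   merging the per-representation top-k and re-ranking by Morgan similarity;
   a predicted block that is itself valid and slot-matching is additionally
   admitted as a *novel* (non-catalog) candidate;
3. beam-searches over candidate combinations, replaying each forward with the
   real reaction engine; when a template yields several products, the one
   closest to the predicted product by SMILES string similarity is kept;
4. classifies the outcome: **exact** (target reached with catalog blocks
   only), **novel_bb** (target reached but only via at least one non-catalog
   block), **analog** (only structurally similar catalog-constrained products
   were reached), or **failed**.

Every route in any result replays to its claimed product; analog routes use
catalog blocks exclusively. Reactions whose template is not in the registry
are dropped rather than fuzzily matched; if the dropped reaction was the
target-producing step the result is failed by definition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem

from .chem import (
    BuildingBlock,
    ChemSpace,
    ReactionTemplate,
    canonicalize,
    enumerate_template_products,
    mol_from_smiles,
)
from .corpus import ResponseBody, RetroResponse, parse_response
from .errors import (
    CoreNotInTarget,
    EmptyCandidateSet,
    InvalidSmiles,
    NoProducts,
    ReconstructionFailed,
    UnassignableReaction,
)
from .predictors import Predictor, PredictorConfig
from .sampler import SynthesisRoute, SynthesisStep, replay_route
from .similarity import (
    SimilarityProfile,
    morgan_tanimoto,
    profile,
    smiles_string_similarity,
)

__all__ = [
    "Candidate",
    "AssignedReaction",
    "ReconstructedRoute",
    "Analog",
    "ReconstructionResult",
    "assign_slots",
    "candidate_bbs",
    "enumerate_products",
    "select_product",
    "reconstruct",
    "reconstruct_target",
    "hit_expand",
]

DEFAULT_K = 2
DEFAULT_BEAM_WIDTH = 32
_STATUS_RANK = {"failed": 0, "analog": 1, "novel_bb": 2, "exact": 3}


@dataclass(frozen=True)
class Candidate:
    """One building-block candidate for a predicted reactant position."""

    smiles: str
    bb_id: str | None  # None for novel (non-catalog) candidates
    similarity: float  # to the predicted block, under the ranking representation
    representation: str  # "exact" | "smiles" | "morgan" | "novel"

    @property
    def is_novel(self) -> bool:
        return self.bb_id is None


@dataclass(frozen=True)
class AssignedReaction:
    """A forward-order reaction with reactants arranged in template slot order."""

    template: ReactionTemplate
    reactants: tuple[str, ...]  # predicted SMILES, slot order
    predicted_product: str


@dataclass(frozen=True)
class ReconstructedRoute:
    """A replay-valid route plus reconstruction bookkeeping."""

    route: SynthesisRoute
    uses_novel_bb: bool
    novel_bb_smiles: tuple[str, ...]
    score: float  # product of per-block candidate similarities


@dataclass(frozen=True)
class Analog:
    """A catalog-constrained product with its similarity profile and route."""

    smiles: str
    similarity: SimilarityProfile
    route: SynthesisRoute
    is_rediscovery: bool = False


@dataclass
class ReconstructionResult:
    """Outcome of reconstructing one target from one or more responses."""

    target_smiles: str
    status: str  # "exact" | "novel_bb" | "analog" | "failed"
    routes: list[ReconstructedRoute] = field(default_factory=list)
    analogs: list[Analog] = field(default_factory=list)

    @property
    def best_analog(self) -> Analog | None:
        return self.analogs[0] if self.analogs else None

    def exact_routes(self) -> list[ReconstructedRoute]:
        return [
            r
            for r in self.routes
            if r.route.target_smiles == self.target_smiles and not r.uses_novel_bb
        ]


def assign_slots(
    response: ResponseBody,
    registry: Sequence[ReactionTemplate],
    strict: bool = True,
) -> list[AssignedReaction]:
    """Recover forward order and slot assignments from a retrosynthetic response.

    In strict mode an unmemorized template or an unassignable reactant set
    raises; with ``strict=False`` such reactions are dropped (the caller is
    told nothing -- reconstruction handles the consequences).
    """
    by_smarts = {_norm(t.smarts): t for t in registry}
    out: list[AssignedReaction] = []
    for entry in reversed(response.reactions):
        template = by_smarts.get(_norm(entry.template))
        if template is None:
            if strict:
                raise UnassignableReaction(f"template not in registry: {entry.template!r}")
            continue
        assignment = _first_matching_assignment(entry.reactants, template)
        if assignment is None:
            if strict:
                raise UnassignableReaction(
                    f"no reactant permutation matches slots of {template.id}"
                )
            continue
        out.append(AssignedReaction(template, assignment, entry.product))
    return out


def _norm(smarts: str) -> str:
    return "".join(smarts.split())


def _first_matching_assignment(
    reactants: Sequence[str], template: ReactionTemplate
) -> tuple[str, ...] | None:
    if len(reactants) != template.n_slots:
        return None
    mols = [Chem.MolFromSmiles(r) for r in reactants]
    rxn = template.rxn()
    patterns = [rxn.GetReactantTemplate(s) for s in range(template.n_slots)]
    for order in itertools.permutations(range(template.n_slots)):
        ok = all(
            mols[i] is not None and mols[i].HasSubstructMatch(patterns[s])
            for s, i in enumerate(order)
        )
        if ok:
            return tuple(reactants[i] for i in order)
    return None


def candidate_bbs(
    predicted_bb: str,
    template_id: str,
    slot: int,
    space: ChemSpace,
    k: int = DEFAULT_K,
    representations: Sequence[str] = ("smiles", "morgan"),
) -> list[Candidate]:
    """Ranked candidates for one predicted block, constrained to the slot.

    If the predicted block canonical-equals a compatible catalog block, that
    block alone is returned with similarity 1.0. Otherwise the top-k
    compatible blocks under each requested representation are merged,
    re-ranked by Morgan similarity to the prediction (string similarity when
    the prediction does not parse), and the predicted molecule itself is
    appended as a novel candidate whenever it is valid and slot-matching.
    """
    compatible = space.compatible_blocks(template_id, slot)
    predicted_canonical: str | None
    try:
        predicted_canonical = canonicalize(predicted_bb)
    except InvalidSmiles:
        predicted_canonical = None

    if predicted_canonical is not None:
        exact = space.by_smiles.get(predicted_canonical)
        if exact is not None and any(bb.id == exact.id for bb in compatible):
            return [Candidate(exact.smiles, exact.id, 1.0, "exact")]

    def rank_score(bb: BuildingBlock) -> float:
        if predicted_canonical is not None:
            return morgan_tanimoto(predicted_canonical, bb.smiles)
        return smiles_string_similarity(predicted_bb, bb.smiles)

    merged: dict[str, Candidate] = {}
    if compatible:
        if "smiles" in representations:
            by_string = sorted(
                compatible,
                key=lambda bb: (-smiles_string_similarity(predicted_bb, bb.smiles), bb.id),
            )
            for bb in by_string[:k]:
                merged.setdefault(
                    bb.id, Candidate(bb.smiles, bb.id, rank_score(bb), "smiles")
                )
        if "morgan" in representations and predicted_canonical is not None:
            by_morgan = sorted(
                compatible,
                key=lambda bb: (-morgan_tanimoto(predicted_canonical, bb.smiles), bb.id),
            )
            for bb in by_morgan[:k]:
                merged.setdefault(
                    bb.id, Candidate(bb.smiles, bb.id, rank_score(bb), "morgan")
                )

    out = sorted(merged.values(), key=lambda c: (-c.similarity, c.bb_id))

    if predicted_canonical is not None:
        template = space.template(template_id)
        pattern = template.rxn().GetReactantTemplate(slot)
        mol = Chem.MolFromSmiles(predicted_canonical)
        if mol is not None and mol.HasSubstructMatch(pattern):
            out.append(Candidate(predicted_canonical, None, 1.0, "novel"))

    if not out:
        raise EmptyCandidateSet(
            f"no candidate for predicted block {predicted_bb!r} in "
            f"({template_id}, slot {slot})"
        )
    return out


def enumerate_products(
    template: ReactionTemplate, reactants_in_slot_order: Sequence[str]
) -> set[str]:
    """All distinct canonical products of one template application.

    Raises :class:`NoProducts` when the template does not fire.
    """
    products = enumerate_template_products(template, reactants_in_slot_order)
    if not products:
        raise NoProducts(
            f"template {template.id} produced nothing from {list(reactants_in_slot_order)}"
        )
    return products


def select_product(products: set[str], predicted_product: str) -> str:
    """Product closest to the prediction by SMILES string similarity.

    Ties break to the lexicographically smallest canonical SMILES.
    """
    if not products:
        raise NoProducts("empty product set")
    return min(
        products,
        key=lambda p: (-smiles_string_similarity(p, predicted_product), p),
    )


@dataclass(frozen=True)
class _BeamState:
    score: float
    produced: tuple[tuple[str, str], ...]  # (predicted product key, actual product)
    steps: tuple[SynthesisStep, ...]
    chosen: tuple[Candidate, ...]

    def produced_map(self) -> dict[str, str]:
        return dict(self.produced)


def reconstruct(
    response: ResponseBody | RetroResponse | str,
    target: str,
    space: ChemSpace,
    k: int = DEFAULT_K,
    beam_width: int = DEFAULT_BEAM_WIDTH,
) -> ReconstructionResult:
    """Rebuild routes for ``target`` from one predicted retrosynthesis.

    Raises :class:`ReconstructionFailed` when no reaction is usable or no
    candidate combination survives forward replay; otherwise returns a result
    whose status follows the classification rules in the module docstring.
    """
    body = _coerce_response(response)
    if body is None:
        raise ReconstructionFailed("response is not parseable")
    target_canonical = canonicalize(target)

    reactions = assign_slots(body, space.registry, strict=False)
    if not reactions:
        raise ReconstructionFailed("no memorized, assignable reaction in response")

    # The first retrosynthetic entry is the target-producing step; if it was
    # dropped (not memorized / not assignable), the target is out of reach.
    first = body.reactions[0]
    first_template = space.find_template_by_smarts(first.template)
    final_step_survived = (
        first_template is not None
        and _first_matching_assignment(first.reactants, first_template) is not None
    )

    # Predicted-product keys of surviving reactions, for intermediate linkage.
    produced_keys: set[str] = set()
    plans: list[tuple[AssignedReaction, list[list[Candidate] | str]]] = []
    for reaction in reactions:
        slot_plans: list[list[Candidate] | str] = []
        for slot, reactant in enumerate(reaction.reactants):
            key = _safe_key(reactant)
            if key in produced_keys:
                slot_plans.append(key)  # linked to an earlier step's product
            else:
                try:
                    slot_plans.append(
                        candidate_bbs(reactant, reaction.template.id, slot, space, k=k)
                    )
                except EmptyCandidateSet:
                    slot_plans.append([])
        plans.append((reaction, slot_plans))
        produced_keys.add(_safe_key(reaction.predicted_product))

    states = [_BeamState(1.0, (), (), ())]
    for reaction, slot_plans in plans:
        next_states: list[_BeamState] = []
        for state in states:
            produced = state.produced_map()
            options: list[list[tuple[str, Candidate | None]]] = []
            dead = False
            for plan in slot_plans:
                if isinstance(plan, str):
                    actual = produced.get(plan)
                    if actual is None:
                        dead = True
                        break
                    options.append([(actual, None)])
                else:
                    if not plan:
                        dead = True
                        break
                    options.append([(c.smiles, c) for c in plan])
            if dead:
                continue
            for combo in itertools.product(*options):
                reactant_smiles = tuple(smi for smi, _ in combo)
                chosen = tuple(c for _, c in combo if c is not None)
                products = enumerate_template_products(
                    reaction.template, reactant_smiles
                )
                if not products:
                    continue
                product = select_product(products, reaction.predicted_product)
                score = state.score
                for c in chosen:
                    score *= c.similarity
                next_states.append(
                    _BeamState(
                        score=score,
                        produced=state.produced
                        + ((_safe_key(reaction.predicted_product), product),),
                        steps=state.steps
                        + (
                            SynthesisStep(
                                reaction.template.id, reactant_smiles, product
                            ),
                        ),
                        chosen=state.chosen + chosen,
                    )
                )
        next_states.sort(
            key=lambda s: (
                -s.score,
                tuple(
                    (st.template_id, st.reactant_smiles, st.product_smiles)
                    for st in s.steps
                ),
            )
        )
        states = next_states[:beam_width]
        if not states:
            break

    if not states:
        raise ReconstructionFailed("no candidate combination survived replay")

    routes = [_state_to_route(s, space) for s in states]
    return _classify(target_canonical, routes, final_step_survived, space)


def _coerce_response(
    response: ResponseBody | RetroResponse | str,
) -> ResponseBody | None:
    if isinstance(response, str):
        response = parse_response(response)
    if isinstance(response, RetroResponse):
        return response.parsed
    return response


def _safe_key(smiles: str) -> str:
    try:
        return canonicalize(smiles)
    except InvalidSmiles:
        return smiles


def _state_to_route(state: _BeamState, space: ChemSpace) -> ReconstructedRoute:
    products = {s.product_smiles for s in state.steps}
    bb_ids: list[str] = []
    novel: list[str] = []
    for step in state.steps:
        for smi in step.reactant_smiles:
            if smi in products:
                continue
            bb = space.by_smiles.get(smi)
            if bb is not None:
                if bb.id not in bb_ids:
                    bb_ids.append(bb.id)
            elif smi not in novel:
                novel.append(smi)
    route = SynthesisRoute(
        steps=state.steps,
        target_smiles=state.steps[-1].product_smiles,
        bb_ids=tuple(bb_ids),
    )
    return ReconstructedRoute(
        route=route,
        uses_novel_bb=bool(novel),
        novel_bb_smiles=tuple(novel),
        score=state.score,
    )


def _classify(
    target_canonical: str,
    routes: list[ReconstructedRoute],
    final_step_survived: bool,
    space: ChemSpace,
) -> ReconstructionResult:
    # Soundness: every reported route must replay to its recorded target.
    def replays(r: ReconstructedRoute) -> bool:
        try:
            return replay_route(r.route, space.registry) == r.route.target_smiles
        except Exception:
            return False

    routes = [r for r in routes if replays(r)]
    exact_catalog = [
        r
        for r in routes
        if r.route.target_smiles == target_canonical and not r.uses_novel_bb
    ]
    exact_novel = [
        r for r in routes if r.route.target_smiles == target_canonical and r.uses_novel_bb
    ]
    catalog_routes = [r for r in routes if not r.uses_novel_bb]

    analogs = _collect_analogs(target_canonical, catalog_routes)

    if not final_step_survived:
        status = "failed"
    elif exact_catalog:
        status = "exact"
    elif exact_novel:
        status = "novel_bb"
    elif analogs:
        status = "analog"
    else:
        status = "failed"
    return ReconstructionResult(
        target_smiles=target_canonical, status=status, routes=routes, analogs=analogs
    )


def _collect_analogs(
    target_canonical: str, catalog_routes: list[ReconstructedRoute]
) -> list[Analog]:
    best_by_product: dict[str, ReconstructedRoute] = {}
    for r in catalog_routes:
        product = r.route.target_smiles
        if product == target_canonical:
            continue
        held = best_by_product.get(product)
        if held is None or r.score > held.score:
            best_by_product[product] = r
    analogs = [
        Analog(smiles=p, similarity=profile(p, target_canonical), route=r.route)
        for p, r in best_by_product.items()
    ]
    analogs.sort(key=lambda a: (-a.similarity.morgan, a.smiles))
    return analogs


def reconstruct_target(
    target: str,
    predictor: Predictor,
    space: ChemSpace,
    config: PredictorConfig | None = None,
    k: int = DEFAULT_K,
    beam_width: int = DEFAULT_BEAM_WIDTH,
) -> ReconstructionResult:
    """End-to-end: predict ``n_samples`` responses, reconstruct each, merge.

    The merged result keeps the best status (exact > novel_bb > analog >
    failed) and deduplicates analogs across samples, ranked by Morgan
    similarity to the target. Never raises on individual bad samples.
    """
    config = config if config is not None else PredictorConfig(n_samples=4)
    target_canonical = canonicalize(target)
    merged = ReconstructionResult(target_smiles=target_canonical, status="failed")
    seen_analogs: dict[str, Analog] = {}
    for text in predictor.predict(target, config):
        parsed = parse_response(text)
        if not parsed.ok:
            continue
        try:
            result = reconstruct(
                parsed.parsed, target_canonical, space, k=k, beam_width=beam_width
            )
        except ReconstructionFailed:
            continue
        if _STATUS_RANK[result.status] > _STATUS_RANK[merged.status]:
            merged.status = result.status
        merged.routes.extend(result.routes)
        for analog in result.analogs:
            held = seen_analogs.get(analog.smiles)
            if held is None:
                seen_analogs[analog.smiles] = analog
    merged.analogs = sorted(
        seen_analogs.values(), key=lambda a: (-a.similarity.morgan, a.smiles)
    )
    return merged


def hit_expand(
    target: str,
    core: str,
    n_analogs: int,
    predictor: Predictor,
    space: ChemSpace,
    config: PredictorConfig | None = None,
    k: int = DEFAULT_K,
    beam_width: int = DEFAULT_BEAM_WIDTH,
) -> list[Analog]:
    """Core-constrained analog generation around a confirmed hit.

    ``core`` is a SMARTS (or SMILES) substructure that must be present in the
    target and in every returned analog; the variable region is whatever lies
    outside it. Rediscovering the target itself is allowed and flagged.
    Returns at most ``n_analogs`` analogs, ranked by Morgan similarity.
    """
    core_query = Chem.MolFromSmarts(core)
    if core_query is None or core_query.GetNumAtoms() == 0:
        core_query = Chem.MolFromSmiles(core)
    if core_query is None:
        raise CoreNotInTarget(f"core pattern does not parse: {core!r}")
    target_mol = mol_from_smiles(target)
    if not target_mol.HasSubstructMatch(core_query):
        raise CoreNotInTarget(f"core {core!r} is not a substructure of the target")

    result = reconstruct_target(
        target, predictor, space, config=config, k=k, beam_width=beam_width
    )
    target_canonical = canonicalize(target)

    pool: dict[str, Analog] = {a.smiles: a for a in result.analogs}
    for r in result.exact_routes():
        pool.setdefault(
            target_canonical,
            Analog(
                smiles=target_canonical,
                similarity=profile(target_canonical, target_canonical),
                route=r.route,
                is_rediscovery=True,
            ),
        )

    kept: list[Analog] = []
    for analog in pool.values():
        mol = Chem.MolFromSmiles(analog.smiles)
        if mol is None or not mol.HasSubstructMatch(core_query):
            continue
        kept.append(
            Analog(
                smiles=analog.smiles,
                similarity=analog.similarity,
                route=analog.route,
                is_rediscovery=analog.smiles == target_canonical,
            )
        )
    kept.sort(key=lambda a: (-a.similarity.morgan, a.smiles))
    return kept[:n_analogs]
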