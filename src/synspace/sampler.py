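"""Forward enumeration of synthesis routes from a chemical space.

Routes are grown bottom-up: an initial template is drawn with probability
proportional to the number of realizable first reactions (the product of its
per-slot compatible building-block counts), its slots are filled with
uniformly chosen compatible building blocks, and the resulting intermediate
is then iteratively fed back into any template slot it matches -- partner
slots again filled from the catalog -- until no reaction applies, a
continuation coin-flip says stop, or the step cap (default five steps) is
reached.

Every sampled route is replayable: re-executing its templates on its recorded
reactants reproduces its recorded products. ``replay_route`` is the
validation oracle for that property and is reused as the forward engine by
the reconstruction pipeline.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import (
    ChemSpace,
    ReactionTemplate,
    applicable_reactions,
    canonicalize,
    enumerate_template_products,
)
from .errors import NoFeasibleReaction, ReplayFailure, SamplingExhausted, UnknownTemplate

__all__ = [
    "SynthesisStep",
    "SynthesisRoute",
    "initial_reaction_weights",
    "sample_initial_template",
    "sample_route",
    "replay_route",
    "sample_corpus",
]

#: Default forward-expansion continuation probability after each step.
DEFAULT_P_CONT = 0.6
#: Default cap on route length, matching the at-most-five-steps space definition.
DEFAULT_MAX_STEPS = 5
#: Dead-end retries before a single route sample gives up.
RETRY_BUDGET = 20


@dataclass(frozen=True)
class SynthesisStep:
    """One template application: reactants in slot order and the product."""

    template_id: str
    reactant_smiles: tuple[str, ...]
    product_smiles: str


@dataclass(frozen=True)
class SynthesisRoute:
    """An ordered forward synthesis from catalog blocks to ``target_smiles``.

    ``bb_ids`` are the catalog ids of consumed building blocks, i.e. of
    reactants that are not themselves a product of an earlier step.
    """

    steps: tuple[SynthesisStep, ...]
    target_smiles: str
    bb_ids: tuple[str, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def building_block_smiles(self) -> list[str]:
        """Canonical SMILES of reactants that are not any step's product (deduplicated)."""
        products = {s.product_smiles for s in self.steps}
        out: list[str] = []
        for step in self.steps:
            for r in step.reactant_smiles:
                if r not in products and r not in out:
                    out.append(r)
        return out


def initial_reaction_weights(space: ChemSpace) -> dict[str, float]:
    """Initial-template distribution: weight ∝ Π_slots |compatible blocks|.

    Templates with any empty slot get weight zero. Raises
    :class:`NoFeasibleReaction` if every template is infeasible.
    """
    raw: dict[str, float] = {}
    for template in space.registry:
        counts = [
            len(space.index.compatible(template.id, slot))
            for slot in range(template.n_slots)
        ]
        raw[template.id] = float(np.prod(counts)) if all(counts) else 0.0
    total = sum(raw.values())
    if total == 0:
        raise NoFeasibleReaction("no template has all slots covered by the catalog")
    return {tid: w / total for tid, w in raw.items()}


def sample_initial_template(space: ChemSpace, rng: random.Random) -> str:
    """Draw the first template id according to :func:`initial_reaction_weights`."""
    weights = initial_reaction_weights(space)
    ids = list(weights)
    return rng.choices(ids, weights=[weights[i] for i in ids], k=1)[0]


def _pick_product(products: set[str]) -> str:
    # Deterministic representative when a template yields several products.
    return min(products)


def sample_route(
    space: ChemSpace,
    max_steps: int = DEFAULT_MAX_STEPS,
    rng: random.Random | None = None,
    p_cont: float = DEFAULT_P_CONT,
) -> SynthesisRoute:
    """Sample one replay-valid route of 1..``max_steps`` steps.

    After each step the sampler continues with probability ``p_cont``
    provided some reaction still applies to the running intermediate.
    Dead ends (template applications that yield no valid product) are
    retried up to a fixed budget before :class:`SamplingExhausted` is raised.
    """
    rng = rng if rng is not None else random.Random()
    last_error: Exception | None = None
    for _ in range(RETRY_BUDGET):
        try:
            return _sample_route_once(space, max_steps, rng, p_cont)
        except _DeadEnd as exc:
            last_error = exc
            continue
    raise SamplingExhausted(f"no route found in {RETRY_BUDGET} attempts: {last_error}")


class _DeadEnd(Exception):
    pass


def _sample_route_once(
    space: ChemSpace, max_steps: int, rng: random.Random, p_cont: float
) -> SynthesisRoute:
    template_id = sample_initial_template(space, rng)
    template = space.template(template_id)
    reactants = tuple(
        rng.choice(space.index.compatible(template_id, slot))
        for slot in range(template.n_slots)
    )
    reactant_smiles = tuple(space.by_id[i].smiles for i in reactants)
    products = enumerate_template_products(template, reactant_smiles)
    if not products:
        raise _DeadEnd(f"initial template {template_id} fired no product")
    product = _pick_product(products)
    steps = [SynthesisStep(template_id, reactant_smiles, product)]

    intermediate = product
    while len(steps) < max_steps:
        options = applicable_reactions(space, intermediate)
        if not options or rng.random() >= p_cont:
            break
        tid, slot = options[rng.randrange(len(options))]
        template = space.template(tid)
        partner_ids: dict[int, str] = {
            other: rng.choice(space.index.compatible(tid, other))
            for other in range(template.n_slots)
            if other != slot
        }
        step_reactants = tuple(
            intermediate if i == slot else space.by_id[partner_ids[i]].smiles
            for i in range(template.n_slots)
        )
        products = enumerate_template_products(template, step_reactants)
        if not products:
            raise _DeadEnd(f"template {tid} fired no product on intermediate")
        product = _pick_product(products)
        steps.append(SynthesisStep(tid, step_reactants, product))
        intermediate = product

    # bb_ids follow the accounting rule (reactants that are not any step's
    # product) rather than the draw history, so the stored list stays correct
    # even if a drawn block coincides with an intermediate.
    products_seen = {s.product_smiles for s in steps}
    bb_ids: list[str] = []
    for step in steps:
        for smi in step.reactant_smiles:
            if smi in products_seen:
                continue
            bb = space.by_smiles[smi]
            if bb.id not in bb_ids:
                bb_ids.append(bb.id)
    return SynthesisRoute(
        steps=tuple(steps), target_smiles=intermediate, bb_ids=tuple(bb_ids)
    )


def replay_route(
    route: SynthesisRoute, registry: Sequence[ReactionTemplate]
) -> str:
    """Re-execute a route and return its final canonical product.

    Each step's template is applied to its recorded reactants; if the recorded
    product is not among the generated products the replay fails at that step.
    """
    by_id = {t.id: t for t in registry}
    last = ""
    for i, step in enumerate(route.steps):
        template = by_id.get(step.template_id)
        if template is None:
            raise UnknownTemplate(step.template_id)
        products = enumerate_template_products(template, step.reactant_smiles)
        if canonicalize(step.product_smiles) not in products:
            raise ReplayFailure(i)
        last = canonicalize(step.product_smiles)
    return last


def sample_corpus(
    space: ChemSpace,
    n: int,
    max_steps: int = DEFAULT_MAX_STEPS,
    rng: random.Random | None = None,
    p_cont: float = DEFAULT_P_CONT,
) -> list[SynthesisRoute]:
    """Sample ``n`` routes with pairwise-distinct canonical targets.

    Collisions are resampled; :class:`SamplingExhausted` is raised if the
    space cannot supply ``n`` unique targets within the retry budget.
    """
    rng = rng if rng is not None else random.Random()
    routes: list[SynthesisRoute] = []
    seen: set[str] = set()
    attempts = 0
    budget = max(100, 50 * n)
    while len(routes) < n:
        if attempts >= budget:
            raise SamplingExhausted(
                f"only {len(routes)}/{n} unique targets after {attempts} attempts"
            )
        attempts += 1
        route = sample_route(space, max_steps=max_steps, rng=rng, p_cont=p_cont)
        if route.target_smiles in seen:
            continue
        seen.add(route.target_smiles)
        routes.append(route)
    return routes
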