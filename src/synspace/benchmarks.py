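"""Instruction-following and reaction-chemistry metrics for predictor output.

Six scores summarise how usable a set of raw predictor responses is for
downstream route reconstruction. Three measure instruction following:

* **valid JSON** -- the response parses and follows the two-part schema
  (denominator: every response);
* **template memorization** -- a predicted reaction's SMARTS exactly matches
  a registry template after whitespace normalization (denominator: every
  reaction entry in parsed responses); string-level on purpose -- a
  chemically equivalent but rewritten SMARTS counts as a miss;
* **BB selection** -- the response's building-block list equals the
  reactants-minus-products set recomputed from its reactions, as canonical
  SMILES sets (denominator: every parsed response).

Three measure reaction chemistry:

* **valid SMILES** -- parsable fraction over every SMILES occurrence
  (reactants, products, and building-block list) in parsed responses;
* **matched reactants** -- some assignment of a reaction's reactants to its
  template's slots matches every slot pattern (denominator: reaction entries
  with a memorized template and all-valid reactant SMILES; slot assignment is
  an exhaustive permutation search, so reactant order never matters);
* **good products** -- the predicted product is among the products actually
  generated by applying the template to the reactants under any matching
  assignment (denominator: entries additionally having a valid product).

Responses that fail JSON or schema validation are excluded from every
downstream denominator: those metrics are undefined on unparsed text.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .chem import ReactionTemplate, enumerate_template_products
from .corpus import ReactionEntry, ResponseBody, RetroResponse, parse_response
from .predictors import Predictor, PredictorConfig

__all__ = [
    "BenchmarkReport",
    "valid_json_rate",
    "template_memorization_rate",
    "bb_selection_rate",
    "valid_smiles_rate",
    "matched_reactants_rate",
    "good_products_rate",
    "score_responses",
    "benchmark",
]

METRICS = (
    "valid_json",
    "template_memorization",
    "bb_selection",
    "valid_smiles",
    "matched_reactants",
    "good_products",
)


@dataclass(frozen=True)
class BenchmarkReport:
    """Six percentages with their numerators and denominators."""

    counts: dict[str, tuple[int, int]]  # metric -> (numerator, denominator)

    def percent(self, metric: str) -> float:
        num, den = self.counts[metric]
        return 100.0 * num / den if den else 0.0

    @property
    def valid_json(self) -> float:
        return self.percent("valid_json")

    @property
    def template_memorization(self) -> float:
        return self.percent("template_memorization")

    @property
    def bb_selection(self) -> float:
        return self.percent("bb_selection")

    @property
    def valid_smiles(self) -> float:
        return self.percent("valid_smiles")

    @property
    def matched_reactants(self) -> float:
        return self.percent("matched_reactants")

    @property
    def good_products(self) -> float:
        return self.percent("good_products")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": m,
                "percent": self.percent(m),
                "numerator": self.counts[m][0],
                "denominator": self.counts[m][1],
            }
            for m in METRICS
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _ensure_parsed(responses: Iterable[str | RetroResponse]) -> list[RetroResponse]:
    return [r if isinstance(r, RetroResponse) else parse_response(r) for r in responses]


def _safe_canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def _normalize_smarts(smarts: str) -> str:
    return "".join(smarts.split())


def recompute_building_blocks(body: ResponseBody) -> set[str]:
    """Reactants that are not any reaction's product, as canonical SMILES.

    Unparsable SMILES participate as their raw strings so the comparison
    stays total.
    """
    products = {(_safe_canonical(e.product) or e.product) for e in body.reactions}
    out: set[str] = set()
    for e in body.reactions:
        for r in e.reactants:
            key = _safe_canonical(r) or r
            if key not in products:
                out.add(key)
    return out


def _matching_assignments(
    entry: ReactionEntry, template: ReactionTemplate
) -> list[tuple[str, ...]]:
    """Slot-order arrangements of the entry's reactants where every slot matches."""
    if len(entry.reactants) != template.n_slots:
        return []
    mols = [Chem.MolFromSmiles(r) for r in entry.reactants]
    if any(m is None for m in mols):
        return []
    rxn = template.rxn()
    patterns = [rxn.GetReactantTemplate(s) for s in range(template.n_slots)]
    out = []
    for order in permutations(range(template.n_slots)):
        if all(mols[i].HasSubstructMatch(patterns[s]) for s, i in enumerate(order)):
            out.append(tuple(entry.reactants[i] for i in order))
    return out


def valid_json_rate(responses: Iterable[str | RetroResponse]) -> float:
    parsed = _ensure_parsed(responses)
    ok = sum(1 for r in parsed if r.ok)
    return 100.0 * ok / len(parsed) if parsed else 0.0


def template_memorization_rate(
    responses: Iterable[str | RetroResponse], registry: Sequence[ReactionTemplate]
) -> float:
    report = score_responses(responses, registry)
    return report.template_memorization


def bb_selection_rate(responses: Iterable[str | RetroResponse]) -> float:
    report = score_responses(responses, registry=())
    return report.bb_selection


def valid_smiles_rate(responses: Iterable[str | RetroResponse]) -> float:
    report = score_responses(responses, registry=())
    return report.valid_smiles


def matched_reactants_rate(
    responses: Iterable[str | RetroResponse], registry: Sequence[ReactionTemplate]
) -> float:
    report = score_responses(responses, registry)
    return report.matched_reactants


def good_products_rate(
    responses: Iterable[str | RetroResponse], registry: Sequence[ReactionTemplate]
) -> float:
    report = score_responses(responses, registry)
    return report.good_products


def score_responses(
    responses: Iterable[str | RetroResponse], registry: Sequence[ReactionTemplate]
) -> BenchmarkReport:
    """Compute all six metrics over a set of raw or pre-parsed responses."""
    parsed = _ensure_parsed(responses)
    by_smarts = {_normalize_smarts(t.smarts): t for t in registry}

    n_json_ok = sum(1 for r in parsed if r.ok)
    counts = {"valid_json": (n_json_ok, len(parsed))}

    bodies = [r.parsed for r in parsed if r.ok]

    tm_num = tm_den = 0
    mr_num = mr_den = 0
    gp_num = gp_den = 0
    vs_num = vs_den = 0
    bb_num = bb_den = 0

    for body in bodies:
        bb_den += 1
        predicted = {(_safe_canonical(b) or b) for b in body.building_blocks}
        if predicted == recompute_building_blocks(body):
            bb_num += 1

        for smiles in [
            s
            for e in body.reactions
            for s in (*e.reactants, e.product)
        ] + list(body.building_blocks):
            vs_den += 1
            if _safe_canonical(smiles) is not None:
                vs_num += 1

        for entry in body.reactions:
            tm_den += 1
            template = by_smarts.get(_normalize_smarts(entry.template))
            if template is None:
                continue
            tm_num += 1

            reactant_mols_valid = all(
                _safe_canonical(r) is not None for r in entry.reactants
            )
            if not reactant_mols_valid:
                continue
            mr_den += 1
            assignments = _matching_assignments(entry, template)
            if assignments:
                mr_num += 1

            product_canonical = _safe_canonical(entry.product)
            if product_canonical is None:
                continue
            gp_den += 1
            generated: set[str] = set()
            for assignment in assignments:
                generated |= enumerate_template_products(template, assignment)
            if product_canonical in generated:
                gp_num += 1

    counts["template_memorization"] = (tm_num, tm_den)
    counts["bb_selection"] = (bb_num, bb_den)
    counts["valid_smiles"] = (vs_num, vs_den)
    counts["matched_reactants"] = (mr_num, mr_den)
    counts["good_products"] = (gp_num, gp_den)
    return BenchmarkReport(counts)


def benchmark(
    predictor: Predictor,
    targets: Sequence[str],
    registry: Sequence[ReactionTemplate],
    config: PredictorConfig | None = None,
) -> BenchmarkReport:
    """Run ``predictor`` on every target and score the pooled responses."""
    if not targets:
        raise ValueError("benchmark needs at least one target")
    config = config if config is not None else PredictorConfig()
    texts: list[str] = []
    for target in targets:
        texts.extend(predictor.predict(target, config))
    return score_responses(texts, registry)
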