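"""Retrosynthetic prompt/response records and total response parsing.

A sampled forward route becomes a training record whose response lists the
route's reactions in *retrosynthetic* (reverse) order -- each entry carrying
the full template SMARTS, the reactant SMILES in slot order, and the product
-- followed by the building-block summary: every reactant that is not itself
the product of another reaction, deduplicated by canonical SMILES.

Parsing predictor output is total: any text yields a :class:`RetroResponse`
whose flags say whether it was valid JSON and whether it followed the
two-part schema; nothing in this module raises on malformed input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .chem import ReactionTemplate
from .errors import IOFailure, UnknownTemplate
from .sampler import SynthesisRoute, SynthesisStep

__all__ = [
    "route_to_dict",
    "route_from_dict",
    "write_routes_jsonl",
    "read_routes_jsonl",
    "DEFAULT_INSTRUCTION",
    "ReactionEntry",
    "ResponseBody",
    "PromptRecord",
    "RetroResponse",
    "route_to_record",
    "serialize_record",
    "serialize_response",
    "parse_response",
    "write_jsonl",
    "read_jsonl",
]

#: Task text included in every prompt record. Only a real LLM adapter cares
#: about the wording; the toolkit's logic never inspects it.
DEFAULT_INSTRUCTION = (
    "Propose a retrosynthetic route for the input molecule using the provided "
    "reaction templates, then list the building blocks required. Answer as JSON "
    'with keys "reactions" and "building_blocks".'
)


@dataclass(frozen=True)
class ReactionEntry:
    """One predicted (or ground-truth) reaction: template SMARTS + molecules."""

    template: str
    reactants: tuple[str, ...]
    product: str

    def to_dict(self) -> dict:
        return {
            "template": self.template,
            "reactants": list(self.reactants),
            "product": self.product,
        }


@dataclass(frozen=True)
class ResponseBody:
    """The two-part response: reactions (retrosynthetic order) + building blocks."""

    reactions: tuple[ReactionEntry, ...]
    building_blocks: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "reactions": [r.to_dict() for r in self.reactions],
            "building_blocks": list(self.building_blocks),
        }


@dataclass(frozen=True)
class PromptRecord:
    """Instruction + input molecule + ground-truth response."""

    instruction: str
    input_smiles: str
    response: ResponseBody

    def to_dict(self) -> dict:
        return {
            "instruction": self.instruction,
            "input": self.input_smiles,
            "response": self.response.to_dict(),
        }


@dataclass
class RetroResponse:
    """A predictor's raw text plus its parse outcome.

    ``parsed`` is present iff ``valid_json`` and ``schema_ok`` are both true.
    """

    raw_text: str
    parsed: ResponseBody | None
    valid_json: bool
    schema_ok: bool

    @property
    def ok(self) -> bool:
        return self.parsed is not None


def route_to_record(
    route: SynthesisRoute,
    registry: Sequence[ReactionTemplate],
    instruction: str = DEFAULT_INSTRUCTION,
) -> PromptRecord:
    """Convert a forward route into a retrosynthetic prompt/response record.

    Reactions are the route's steps reversed; each embeds its template's full
    SMARTS. Building blocks follow the reactants-minus-products rule.

    Raises
    ------
    UnknownTemplate
        If a step references a template id missing from ``registry``.
    """
    by_id = {t.id: t for t in registry}
    entries = []
    for step in reversed(route.steps):
        template = by_id.get(step.template_id)
        if template is None:
            raise UnknownTemplate(step.template_id)
        entries.append(
            ReactionEntry(
                template=template.smarts,
                reactants=tuple(step.reactant_smiles),
                product=step.product_smiles,
            )
        )
    return PromptRecord(
        instruction=instruction,
        input_smiles=route.target_smiles,
        response=ResponseBody(
            reactions=tuple(entries),
            building_blocks=tuple(route.building_block_smiles()),
        ),
    )


def serialize_response(body: ResponseBody) -> str:
    """Stable JSON text for a response body (fixed key order, no whitespace drift)."""
    return json.dumps(body.to_dict(), separators=(", ", ": "))


def serialize_record(record: PromptRecord) -> str:
    """Stable JSON text for a full prompt record."""
    return json.dumps(record.to_dict(), separators=(", ", ": "))


def _coerce_body(payload: object) -> ResponseBody | None:
    """Validate the two-part schema; None on any violation."""
    if not isinstance(payload, dict):
        return None
    if "reactions" not in payload or "building_blocks" not in payload:
        return None
    reactions_raw = payload["reactions"]
    bbs_raw = payload["building_blocks"]
    if not isinstance(reactions_raw, list) or not isinstance(bbs_raw, list):
        return None
    entries: list[ReactionEntry] = []
    for item in reactions_raw:
        if not isinstance(item, dict):
            return None
        template = item.get("template")
        reactants = item.get("reactants")
        product = item.get("product")
        if not isinstance(template, str) or not isinstance(product, str):
            return None
        if not isinstance(reactants, list) or not reactants:
            return None
        if not all(isinstance(r, str) for r in reactants):
            return None
        entries.append(ReactionEntry(template, tuple(reactants), product))
    if not all(isinstance(b, str) for b in bbs_raw):
        return None
    return ResponseBody(reactions=tuple(entries), building_blocks=tuple(bbs_raw))


def parse_response(text: str) -> RetroResponse:
    """Parse predictor output; never raises.

    Accepts either a bare response body or a full prompt record (in which
    case the ``response`` field is validated).
    """
    try:
        payload = json.loads(text)
    except (json.JSONDecodeError, TypeError):
        return RetroResponse(text, None, valid_json=False, schema_ok=False)
    if isinstance(payload, dict) and "response" in payload and "reactions" not in payload:
        payload = payload["response"]
    body = _coerce_body(payload)
    return RetroResponse(text, body, valid_json=True, schema_ok=body is not None)


def write_jsonl(path: str | Path, records: Iterable[PromptRecord]) -> int:
    """Write one record per line; returns the number written."""
    path = Path(path)
    n = 0
    try:
        with path.open("w", encoding="utf-8") as fh:
            for record in records:
                fh.write(serialize_record(record) + "\n")
                n += 1
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    return n


def route_to_dict(route: SynthesisRoute) -> dict:
    return {
        "steps": [
            {
                "template_id": s.template_id,
                "reactants": list(s.reactant_smiles),
                "product": s.product_smiles,
            }
            for s in route.steps
        ],
        "target": route.target_smiles,
        "bb_ids": list(route.bb_ids),
    }


def route_from_dict(payload: dict) -> SynthesisRoute:
    steps = tuple(
        SynthesisStep(s["template_id"], tuple(s["reactants"]), s["product"])
        for s in payload["steps"]
    )
    return SynthesisRoute(
        steps=steps, target_smiles=payload["target"], bb_ids=tuple(payload["bb_ids"])
    )


def write_routes_jsonl(path: str | Path, routes: Iterable[SynthesisRoute]) -> int:
    """One route JSON object per line (``steps[]``, ``target``, ``bb_ids[]``)."""
    n = 0
    try:
        with Path(path).open("w", encoding="utf-8") as fh:
            for route in routes:
                fh.write(json.dumps(route_to_dict(route), separators=(", ", ": ")) + "\n")
                n += 1
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    return n


def read_routes_jsonl(path: str | Path) -> list[SynthesisRoute]:
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    return [
        route_from_dict(json.loads(line))
        for line in text.splitlines()
        if line.strip()
    ]


@dataclass
class JsonlReadResult:
    """Parsed records plus per-line failures (line number, raw text)."""

    records: list[PromptRecord] = field(default_factory=list)
    failures: list[tuple[int, str]] = field(default_factory=list)


def read_jsonl(path: str | Path) -> JsonlReadResult:
    """Read a record-per-line corpus; corrupt lines are flagged, not fatal."""
    path = Path(path)
    result = JsonlReadResult()
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            payload = json.loads(line)
        except json.JSONDecodeError:
            result.failures.append((lineno, line))
            continue
        if not isinstance(payload, dict):
            result.failures.append((lineno, line))
            continue
        body = _coerce_body(payload.get("response"))
        instruction = payload.get("instruction")
        input_smiles = payload.get("input")
        if body is None or not isinstance(instruction, str) or not isinstance(input_smiles, str):
            result.failures.append((lineno, line))
            continue
        result.records.append(PromptRecord(instruction, input_smiles, body))
    return result
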