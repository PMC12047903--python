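"""Predictor contract plus deterministic mock oracles.

The reconstruction pipeline only ever sees a function from a target SMILES to
a list of raw response texts. A fine-tuned language model is one such
function (reachable through :class:`LLMAdapter`), but everything in this
toolkit is testable without one:

* :class:`PerfectOracle` replays the ground-truth response for targets drawn
  from a corpus -- the upper-bound predictor.
* :class:`CorruptingOracle` perturbs ground truth with three chemistry-aware
  error modes (building-block swaps, SMILES character noise, truncated JSON)
  emulating the failure modes real model output exhibits.

All predictors are deterministic: the same target, configuration, and seed
always produce identical texts.
"""

from __future__ import annotations

import json
import random
import urllib.error
import urllib.request
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Protocol, Sequence

from rdkit import Chem

from .chem import canonicalize
from .corpus import (
    PromptRecord,
    ReactionEntry,
    ResponseBody,
    serialize_response,
)
from .errors import PredictorUnavailable, UnknownTarget

__all__ = [
    "PredictorConfig",
    "Predictor",
    "PerfectOracle",
    "CorruptingOracle",
    "LLMAdapter",
    "perturb_molecule",
    "corrupt_smiles",
    "predictor_from_config",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Sampling configuration shared by all predictors.

    Defaults follow the low-temperature inference regime used for
    reproducible benchmarking (temperature 0.1, top-p 0.1).
    """

    n_samples: int = 1
    temperature: float = 0.1
    top_p: float = 0.1

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if not (0 < self.top_p <= 1):
            raise ValueError("top_p must be in (0, 1]")


class Predictor(Protocol):
    """Anything that maps a target SMILES to raw response texts."""

    def predict(self, target_smiles: str, config: PredictorConfig) -> list[str]: ...


class PerfectOracle:
    """Returns the ground-truth serialized response for known corpus targets."""

    def __init__(self, corpus: Iterable[PromptRecord]):
        self._by_target: dict[str, ResponseBody] = {}
        for record in corpus:
            self._by_target[canonicalize(record.input_smiles)] = record.response

    def response_for(self, target_smiles: str) -> ResponseBody:
        key = canonicalize(target_smiles)
        if key not in self._by_target:
            raise UnknownTarget(target_smiles)
        return self._by_target[key]

    def predict(self, target_smiles: str, config: PredictorConfig) -> list[str]:
        text = serialize_response(self.response_for(target_smiles))
        return [text] * config.n_samples


def perturb_molecule(smiles: str, rng: random.Random) -> str:
    """Structurally perturb a molecule: graft F/Cl/CH3 onto a C-H carbon.

    Returns a canonical SMILES guaranteed to differ from the input. Falls
    back to the input unchanged only if no carbon accepts a substituent
    (which does not happen for the organic molecules this toolkit handles).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return smiles
    original = Chem.MolToSmiles(mol)
    candidates = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    ]
    rng.shuffle(candidates)
    for idx in candidates:
        for symbol in rng.sample(["F", "C", "Cl"], 3):
            edit = Chem.RWMol(mol)
            new_idx = edit.AddAtom(Chem.Atom(symbol))
            edit.AddBond(idx, new_idx, Chem.BondType.SINGLE)
            try:
                out = edit.GetMol()
                Chem.SanitizeMol(out)
            except Exception:
                continue
            result = Chem.MolToSmiles(out)
            if result != original:
                return result
    return smiles


def corrupt_smiles(smiles: str, rng: random.Random) -> str:
    """Character-level corruption: insert, delete, or substitute one character."""
    if not smiles:
        return "("
    op = rng.randrange(3)
    pos = rng.randrange(len(smiles))
    if op == 0:
        return smiles[:pos] + "(" + smiles[pos:]
    if op == 1 and len(smiles) > 1:
        return smiles[:pos] + smiles[pos + 1 :]
    return smiles[:pos] + "%" + smiles[pos + 1 :]


class CorruptingOracle:
    """Ground truth with seeded, chemistry-aware corruption.

    Per response (independently for each of the ``n_samples`` draws):

    * with probability ``bb_swap_rate`` one building block is replaced by a
      structural perturbation of itself, consistently in both the
      building-block list and every reaction that consumes it;
    * with probability ``smiles_noise_rate`` one SMILES occurrence gets a
      character corruption;
    * with probability ``json_break_rate`` the serialized text is truncated.

    Deterministic: corruption randomness is derived from the oracle seed, the
    sample index, and the target, never from global state.
    """

    def __init__(
        self,
        corpus: Iterable[PromptRecord],
        seed: int = 0,
        bb_swap_rate: float = 0.0,
        smiles_noise_rate: float = 0.0,
        json_break_rate: float = 0.0,
    ):
        for name, rate in (
            ("bb_swap_rate", bb_swap_rate),
            ("smiles_noise_rate", smiles_noise_rate),
            ("json_break_rate", json_break_rate),
        ):
            if not (0 <= rate <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        self._oracle = PerfectOracle(corpus)
        self.seed = seed
        self.bb_swap_rate = bb_swap_rate
        self.smiles_noise_rate = smiles_noise_rate
        self.json_break_rate = json_break_rate

    def predict(self, target_smiles: str, config: PredictorConfig) -> list[str]:
        body = self._oracle.response_for(target_smiles)
        out = []
        for i in range(config.n_samples):
            rng = random.Random(f"{self.seed}:{i}:{canonicalize(target_smiles)}")
            out.append(self._corrupt_one(body, rng))
        return out

    def _corrupt_one(self, body: ResponseBody, rng: random.Random) -> str:
        if self.bb_swap_rate and rng.random() < self.bb_swap_rate and body.building_blocks:
            body = self._swap_building_block(body, rng)
        if self.smiles_noise_rate and rng.random() < self.smiles_noise_rate:
            body = self._noise_one_smiles(body, rng)
        text = serialize_response(body)
        if self.json_break_rate and rng.random() < self.json_break_rate:
            text = text[: max(1, len(text) // 2)]
        return text

    def _swap_building_block(self, body: ResponseBody, rng: random.Random) -> ResponseBody:
        target_bb = body.building_blocks[rng.randrange(len(body.building_blocks))]
        swapped = perturb_molecule(target_bb, rng)
        if swapped == target_bb:
            return body
        reactions = tuple(
            ReactionEntry(
                template=e.template,
                reactants=tuple(swapped if r == target_bb else r for r in e.reactants),
                product=e.product,
            )
            for e in body.reactions
        )
        bbs = tuple(swapped if b == target_bb else b for b in body.building_blocks)
        return ResponseBody(reactions=reactions, building_blocks=bbs)

    def _noise_one_smiles(self, body: ResponseBody, rng: random.Random) -> ResponseBody:
        # Occurrences: (kind, reaction index, position) over reactants,
        # products, and the building-block list.
        occurrences: list[tuple[str, int, int]] = []
        for i, e in enumerate(body.reactions):
            occurrences += [("reactant", i, j) for j in range(len(e.reactants))]
            occurrences.append(("product", i, 0))
        occurrences += [("bb", -1, j) for j in range(len(body.building_blocks))]
        if not occurrences:
            return body
        kind, i, j = occurrences[rng.randrange(len(occurrences))]
        reactions = list(body.reactions)
        bbs = list(body.building_blocks)
        if kind == "reactant":
            e = reactions[i]
            reactants = list(e.reactants)
            reactants[j] = corrupt_smiles(reactants[j], rng)
            reactions[i] = ReactionEntry(e.template, tuple(reactants), e.product)
        elif kind == "product":
            e = reactions[i]
            reactions[i] = ReactionEntry(e.template, e.reactants, corrupt_smiles(e.product, rng))
        else:
            bbs[j] = corrupt_smiles(bbs[j], rng)
        return ResponseBody(tuple(reactions), tuple(bbs))


#: Transport signature for :class:`LLMAdapter`: payload dict -> list of texts.
Transport = Callable[[dict], list[str]]


def _http_transport(endpoint: str) -> Transport:
    def send(payload: dict) -> list[str]:
        data = json.dumps(payload).encode("utf-8")
        request = urllib.request.Request(
            endpoint, data=data, headers={"Content-Type": "application/json"}
        )
        try:
            with urllib.request.urlopen(request, timeout=60) as response:
                out = json.loads(response.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, json.JSONDecodeError) as exc:
            raise PredictorUnavailable(f"endpoint {endpoint}: {exc}") from exc
        if not isinstance(out, list) or not all(isinstance(t, str) for t in out):
            raise PredictorUnavailable(f"endpoint {endpoint}: malformed reply")
        return out

    return send


class LLMAdapter:
    """Bridge to a user-supplied fine-tuned model endpoint.

    The endpoint receives ``{"instruction", "input", "n", "temperature",
    "top_p"}`` and must return a JSON list of response texts, which are passed
    through unmodified. A custom ``transport`` callable may replace HTTP for
    testing or in-process models.
    """

    def __init__(
        self,
        endpoint: str = "",
        instruction: str = "",
        transport: Transport | None = None,
    ):
        if transport is None and not endpoint:
            raise ValueError("either an endpoint or a transport is required")
        self.instruction = instruction
        self._transport = transport if transport is not None else _http_transport(endpoint)

    def predict(self, target_smiles: str, config: PredictorConfig) -> list[str]:
        payload = {
            "instruction": self.instruction,
            "input": target_smiles,
            "n": config.n_samples,
            "temperature": config.temperature,
            "top_p": config.top_p,
        }
        texts = self._transport(payload)
        if len(texts) != config.n_samples:
            raise PredictorUnavailable(
                f"endpoint returned {len(texts)} texts, expected {config.n_samples}"
            )
        return list(texts)


def predictor_from_config(
    config: dict, corpus: Sequence[PromptRecord] | None = None
) -> Predictor:
    """Build a predictor from a ``predictor.*`` configuration mapping.

    Recognised keys: ``kind`` in {perfect, corrupting, llm}; for corrupting,
    ``seed`` and the three rates; for llm, ``endpoint``.
    """
    kind = config.get("kind", "perfect")
    if kind == "perfect":
        if corpus is None:
            raise ValueError("perfect predictor needs a corpus")
        return PerfectOracle(corpus)
    if kind == "corrupting":
        if corpus is None:
            raise ValueError("corrupting predictor needs a corpus")
        return CorruptingOracle(
            corpus,
            seed=int(config.get("seed", 0)),
            bb_swap_rate=float(config.get("bb_swap_rate", 0.0)),
            smiles_noise_rate=float(config.get("smiles_noise_rate", 0.0)),
            json_break_rate=float(config.get("json_break_rate", 0.0)),
        )
    if kind == "llm":
        return LLMAdapter(endpoint=config.get("endpoint", ""))
    raise ValueError(f"unknown predictor kind {kind!r}")
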