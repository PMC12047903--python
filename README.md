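# synspace

Toolkit for coupling retrosynthesis predictors to a *synthesizable chemical
space* — a catalog of purchasable building blocks (BBs) plus a registry of
reaction SMARTS templates (RXNs). It is aimed at workflows where a generative
model (typically a fine-tuned LLM) proposes retrosynthetic routes as text,
and everything around the model has to be reliable, deterministic chemistry:

* **forward enumeration** of synthesis routes from BBs and RXNs, for building
  training corpora;
* **retrosynthetic prompt/response records** (reactions in reverse order +
  building-block summary) and total, never-raising parsing of predictor
  output;
* **six benchmark metrics** for raw responses: valid JSON, template
  memorization, BB selection, valid SMILES, matched reactants, good products;
* **reconstruction** of predicted routes — exact targets, novel-BB routes, or
  catalog-constrained *analogs* found by nearest-neighbour BB substitution —
  plus core-constrained **hit expansion**.

The predictor itself sits behind a minimal contract (`predict(smiles, config)
-> list[str]`); deterministic oracles (`PerfectOracle`, `CorruptingOracle`)
stand in for a trained model so the whole pipeline is testable offline.

## The core ideas

**Space and sampling.** A compatibility index maps every template slot to the
catalog BBs matching that slot's reactant pattern. Routes are grown forward:
the initial template *t* is drawn with probability

    P(t) ∝ ∏_slots |compatible BBs in slot|,

its slots are filled uniformly from the compatible sets, and the running
intermediate is re-fed into any slot it matches (partner slots again drawn
from the catalog) until nothing applies, a continuation coin-flip (p = 0.6)
says stop, or the five-step cap is hit. Every route *replays*: re-running its
templates on its recorded reactants reproduces its recorded products.

**Reconstruction.** A predicted retrosynthesis is replayed forward. Each
predicted BB is looked up in the catalog subset *compatible with its reaction
slot*; misses trigger a nearest-neighbour search under two representations —
canonical-SMILES edit similarity and Tanimoto over 4096-bit Morgan
fingerprints (radius 2) — whose top-k (default 2) lists are merged and
re-ranked by Morgan similarity. Valid predicted BBs absent from the catalog
are also admitted as *novel* candidates. A beam search (width 32) over
candidate combinations replays each assembly with the real reaction engine,
resolving multi-product reactions by SMILES string similarity to the
predicted product. Results are classified **exact** (target reached, catalog
BBs only), **novel_bb** (target reached only via a non-catalog BB),
**analog** (similar catalog-constrained products), or **failed**. Analogs are
scored by Morgan, Murcko-scaffold, and Gobbi-2D-pharmacophore Tanimoto
similarity to the target.

## Worked example

```python
import random
from synspace import (
    make_toy_space, sample_corpus, route_to_record, PerfectOracle,
    CorruptingOracle, PredictorConfig, reconstruct_target,
)
from synspace.benchmarks import benchmark

# 7 functional-group families x 20 members, 5 coupling templates
space = make_toy_space(n_per_family=20, seed=0)
routes = sample_corpus(space, 100, rng=random.Random(42))
records = [route_to_record(r, space.registry) for r in routes]

oracle = PerfectOracle(records)
report = benchmark(oracle, [r.target_smiles for r in routes], space.registry)
print(report.to_frame().to_string(index=False))

noisy = CorruptingOracle(records, seed=3, bb_swap_rate=1.0)
result = reconstruct_target(routes[0].target_smiles, noisy, space,
                            PredictorConfig(n_samples=4))
print(result.status, result.best_analog.smiles)
```

prints

```
               metric  percent  numerator  denominator
           valid_json    100.0        100          100
template_memorization    100.0        170          170
         bb_selection    100.0        100          100
         valid_smiles    100.0        777          777
    matched_reactants    100.0        170          170
        good_products    100.0        170          170
```

— the ground-truth oracle scores 100% on all six metrics, as it must — and
for the first target (`CCCc1ccc(CNS(=O)(=O)CCCl)cc1`, a sulfonamide) under a
predictor whose every building block is perturbed off-catalog:

```
status : exact
analog : CCc1ccc(CNS(=O)(=O)CCCl)cc1  morgan=0.76 scaffold=1.00 pharm=1.00
```

The swap was small enough that the true BB is still in the candidate top-k,
so the target is recovered *exactly*, and the closest distinct analog (propyl
→ ethyl) keeps the scaffold and pharmacophore intact.

The same flows are available from the shell:

```bash
synspace fixtures make --n 20 --seed 7 --out data/
synspace sample-routes --bbs data/building_blocks.smi --templates data/templates.tsv \
    --n 1000 --seed 1 --out routes.jsonl --records records.jsonl
synspace benchmark --templates data/templates.tsv --corpus records.jsonl \
    --predictor perfect --out report.csv
synspace reconstruct --bbs data/building_blocks.smi --templates data/templates.tsv \
    --corpus records.jsonl --target 'CCN' --out result.json
synspace expand-hit ... --core 'C(=O)N' --n 50 --out analogs.csv
```

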