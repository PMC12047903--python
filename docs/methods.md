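# Methods

## The model of synthesizable space

The toolkit treats "synthesizable" as membership in the closure of a finite
building-block catalog under a finite set of reaction SMARTS templates,
bounded at five forward steps. This is the operational definition used by
purchasable-space vendors and by synthesis-aware generative models: a
molecule is in scope exactly when some sequence of at most five template
applications over catalog reactants produces it. Two consequences shape the
design:

* every object the toolkit manipulates (route, record, reconstruction) is
  *replayable* — validity is always decided by re-executing reaction SMARTS
  with RDKit, never by trusting stored strings;
* all molecule equality is canonical-SMILES equality, and every stored
  SMILES is canonical (the loaders canonicalize, and `canon(canon(s)) ==
  canon(s)` is tested as a property). Atom-less SMILES are treated as
  invalid. Stereochemistry survives canonicalization but is not required by
  any shipped template.

**Compatibility** of a building block with a template slot is defined as a
substructure match of that slot's reactant pattern alone, not joint
applicability with specific partners. This is the unit both the sampler's
probabilistic model and the reconstruction's constrained nearest-neighbour
search consume, and it is cheap enough to verify against an exhaustive
double loop, which the tests do. Protecting-group and selectivity logic is
deliberately out of scope; a slot match is a slot match.

## Route sampling

The initial template is drawn with probability proportional to the product
of its per-slot compatible-BB counts — i.e. proportional to the number of
realizable first reactions — with infeasible templates (any empty slot) at
zero. Slots are filled uniformly at random from their compatible sets.
After each step, expansion continues with probability `p_cont` (default
0.6) provided the intermediate still matches some slot whose partner slots
are coverable; the intermediate then occupies a uniformly chosen (template,
slot) option and partners come uniformly from the catalog. The default 0.6
yields a spread of one- to five-step routes (roughly 40% single-step, with
five-step routes appearing reliably in a 400-route corpus) rather than a
fixed depth. When one application yields several products, the sampler
records the lexicographically smallest canonical SMILES — an arbitrary but
deterministic choice. Dead ends (a template that matches but fires no
sanitizable product) are retried up to 20 times per route.

Building-block accounting follows the summary rule used in the record
format: the BBs of a route are exactly its reactants that are not any
step's product, deduplicated by canonical SMILES. The stored `bb_ids` are
recomputed from the steps at construction so the invariant cannot drift.

## Records and parsing

A route is serialized as an instruction/input/response record whose
response lists the reactions in retrosynthetic (reverse) order, each with
the full template SMARTS, reactants in slot order, and product, followed by
the building-block list. The exact instruction wording is a configurable
constant: only a real LLM adapter would care. The schema is the minimal
two-part encoding `{"reactions": [{"template", "reactants", "product"}],
"building_blocks": [...]}`. Parsing is total: any text returns a response
object with `valid_json` / `schema_ok` flags, and downstream code treats
only fully-flagged responses as usable. Intermediates are not separately
labeled; they appear implicitly as one step's product and a later step's
reactant.

## Mock predictors

`PerfectOracle` replays ground truth; `CorruptingOracle` perturbs it with
three independent, per-response error modes mirroring what imperfect model
output actually does: truncated text (breaks JSON), character-level SMILES
noise (breaks SMILES validity), and building-block swaps. Swaps are
chemistry-aware — a C–H carbon gains a F/Cl/CH3 substituent, so the swapped
molecule is valid, structurally close, and usually still slot-compatible —
and are applied consistently to the BB list *and* the reactions consuming
the block, so corruption exercises the analog-generation path rather than
the schema checks. Corruption randomness derives from (seed, sample index,
target), making every predictor deterministic under fixed configuration.
Default sampling parameters are temperature 0.1 / top-p 0.1, the
low-temperature regime appropriate for reproducible benchmarking; they are
carried in the request payload of the LLM adapter but do not affect the
oracles.

## Benchmark denominators

The six metrics leave denominators implicit in their usual phrasing; the
choices here are: valid JSON per response; BB selection per parsed
response; template memorization per reaction entry; valid SMILES per SMILES
occurrence (reactants, products, and the BB list); matched reactants per
reaction entry with a memorized template and all-valid reactant SMILES;
good products per such entry with a valid product. Responses failing
JSON/schema are excluded from all downstream denominators (the metrics are
undefined on unparsed text). Template matching is string-level after
whitespace normalization — a chemically identical but rewritten SMARTS
counts as a miss, because memorization, not equivalence, is what is being
measured. Reactant-to-slot matching searches all permutations (slot counts
are ≤ 3, so this is exhaustive), and good-products membership is tested
against the full enumerated product set of every matching assignment.

## Reconstruction

Forward order is recovered by reversing the retrosynthetic list; each
reaction's reactants are assigned to template slots by exhaustive
permutation search (first matching permutation in index order — ground
truth records already in slot order are therefore reproduced verbatim).
Reactions whose template is not in the registry are dropped rather than
fuzzily matched: memorization rates in practice are near-perfect, and fuzzy
SMARTS matching has no defensible semantics. If the dropped reaction was
the target-producing (first retrosynthetic) step, the result is failed by
definition.

Candidate search for a predicted BB runs over the slot-compatible catalog
subset only. An exact catalog hit short-circuits with similarity 1.0.
Otherwise the top-k (default 2, the common choice for this workflow) under
each of two representations — canonical-SMILES edit similarity and Morgan
Tanimoto — are merged, deduplicated, and re-ranked by Morgan similarity;
the two-representation union with Morgan re-ranking is this package's
choice for combining searches that are usually described separately. A
valid, slot-matching predicted molecule is appended as a novel candidate
with similarity 1.0; novelty is tracked per route (`uses_novel_bb`) since
purchasability screening of novel blocks is outside the toolkit.

Combinations of candidates are explored by beam search (width 32, scored by
the product of per-block similarities) rather than full Cartesian product,
which explodes for multi-step routes; determinism is kept by total
tie-breaking on the route signature. Each partial assembly is replayed with
the real engine; multi-product steps resolve by SMILES string similarity to
the predicted product (ties to the lexicographically smallest). Predicted
intermediates guide only this product selection; the chain itself is
rebuilt from actual products. Every surviving route is replay-validated
before classification, and analogs (catalog-only products differing from
the target) carry Morgan/scaffold/pharmacophore profiles and are ranked by
Morgan similarity.

`reconstruct_target` merges the per-sample results of `n_samples` predictor
draws (default 4), keeping the best status (exact > novel_bb > analog >
failed) and the union of analogs. Hit expansion filters the merged analog
pool to molecules containing a user-supplied core substructure —
"modifies only the variable region" is operationalized as "retains the
given core", since which region is fixed is inherently a user decision —
and flags rediscoveries of the target itself.

## Similarity metrics

Morgan fingerprints are 4096-bit, radius 2 (the ECFP4-equivalent default).
Scaffold similarity is Morgan Tanimoto over Murcko scaffolds with the
convention empty-vs-empty = 1.0, empty-vs-nonempty = 0.0; the same
both-empty convention applies to Gobbi pharmacophore fingerprints (benzene
has no Gobbi features, and identity must score 1). String similarity is
1 − Levenshtein/max-length over canonical SMILES (raw strings when parsing
fails), with an exact-canonical short-circuit; edit distance is computed by
edlib and checked in the tests against a textbook dynamic-programming
implementation.

## The toy space

Real purchasable catalogs cannot ship with a package, so the fixture module
generates deterministic catalogs organized into the seven functional-group
families real coupling chemistry is built around (carboxylic acids,
primary/secondary amines, aryl boronic acids, aryl halides, sulfonyl
chlorides, aldehydes), decorated from seeded substituent grids over small
scaffolds. A few substituents are themselves reactive handles (aryl
bromide on an acid, carboxyl on an aryl halide), so multi-step routes —
e.g. amide coupling then Suzuki coupling — exist by construction and are
verified constructively in the tests. The default registry holds five
two-slot textbook couplings (amide, Suzuki, sulfonamide, reductive
amination, ester); the amine slots carry `!$(NC=O)`/`!$(NS=O)` guards so a
freshly formed amide/sulfonamide N–H cannot immediately re-react, which
would otherwise dominate forward expansion. The ester template's alcohol
slot is empty in the default catalog (no alcohol family): it exercises the
zero-weight/empty-slot paths.

What the toy space does *not* emulate: real catalogs' property
distributions (MW, logP), scale (10^5 blocks vs 140), protecting-group
chemistry, stereochemical templates, or 3-slot reactions (supported by the
code, absent from the fixtures). Passing tests therefore demonstrate the
correctness of the machinery — replay validity, metric definitions,
candidate search, classification — not predictive performance on real
drug-like space, which depends on the predictor being benchmarked.

## Problem sizes and numerical choices

The shipped verification runs use 400-route corpora, 200-target benchmark
and reconstruction sets, 1000 random pairs for the analog-similarity
baseline, and ≤100-item fixtures for brute-force oracle comparisons —
large enough for the binomial checks (3-standard-error bands) to be
meaningful and small enough to run in seconds. Similarity values compared
against set-arithmetic oracles use 1e-12 absolute tolerance; sets and
rankings are compared exactly. Fingerprints and parsed reactions are
cached per process (`lru_cache`); caches key on canonical SMILES, so
equality semantics are unaffected.

## Known limitations

* Compatibility ignores joint applicability: a slot-compatible pair can
  still fire no product (handled by dead-end retries and beam pruning, but
  a pathological template set could make sampling slow).
* Reconstruction explores the joint BB assignment under one beam; it does
  not independently explore sub-route substitutions, so analogs of deep
  convergent routes may be under-enumerated at small beam widths.
* Novel-BB candidates are admitted on validity + slot match alone; no
  purchasability oracle is included.
* The SMILES-representation nearest-neighbour search uses edit distance;
  n-gram or learned embeddings could be plugged in behind the same
  interface but are not provided.
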