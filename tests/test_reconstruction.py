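"""Route reconstruction: slot assignment, candidate search, replay, statuses."""

import random

import pytest
from rdkit import Chem

from synspace.chem import (
    BuildingBlock,
    ChemSpace,
    canonicalize,
    enumerate_template_products,
    make_template,
)
from synspace.corpus import ReactionEntry, ResponseBody, route_to_record, serialize_response
from synspace.errors import (
    CoreNotInTarget,
    EmptyCandidateSet,
    NoProducts,
    UnassignableReaction,
)
from synspace.predictors import CorruptingOracle, PerfectOracle, PredictorConfig, perturb_molecule
from synspace.reconstruction import (
    assign_slots,
    candidate_bbs,
    enumerate_products,
    hit_expand,
    reconstruct,
    reconstruct_target,
    select_product,
)
from synspace.sampler import replay_route
from synspace.similarity import morgan_tanimoto, smiles_string_similarity

AMIDE = "[C:1](=[O:2])[OX2H1].[NX3;H2,H1:3]>>[C:1](=[O:2])[N:3]"


class TestAssignSlots:
    def test_either_order_lands_acid_in_slot0(self, space):
        amide = space.template("T1")
        for reactants in (("CC(=O)O", "CN"), ("CN", "CC(=O)O")):
            body = ResponseBody(
                reactions=(ReactionEntry(amide.smarts, reactants, "CNC(C)=O"),),
                building_blocks=reactants,
            )
            assigned = assign_slots(body, space.registry)
            assert assigned[0].reactants == ("CC(=O)O", "CN")

    def test_forward_order_recovered(self, space, corpus_routes, records):
        route = next(r for r in corpus_routes if r.n_steps >= 2)
        record = route_to_record(route, space.registry)
        assigned = assign_slots(record.response, space.registry)
        assert [a.template.id for a in assigned] == [s.template_id for s in route.steps]
        assert [a.reactants for a in assigned] == [s.reactant_smiles for s in route.steps]

    def test_matches_exhaustive_permutation_oracle(self, space, records):
        from itertools import permutations

        for record in records[:20]:
            assigned = assign_slots(record.response, space.registry)
            for reaction in assigned:
                patterns = [
                    reaction.template.rxn().GetReactantTemplate(s)
                    for s in range(reaction.template.n_slots)
                ]
                valid_orders = [
                    order
                    for order in permutations(reaction.reactants)
                    if all(
                        Chem.MolFromSmiles(r).HasSubstructMatch(p)
                        for r, p in zip(order, patterns)
                    )
                ]
                assert tuple(reaction.reactants) in valid_orders

    def test_unassignable_raises_in_strict_mode(self, space):
        amide = space.template("T1")
        body = ResponseBody(
            reactions=(ReactionEntry(amide.smarts, ("CC", "CCC"), "CCCC"),),
            building_blocks=("CC", "CCC"),
        )
        with pytest.raises(UnassignableReaction):
            assign_slots(body, space.registry)
        assert assign_slots(body, space.registry, strict=False) == []

    def test_foreign_template_raises_in_strict_mode(self, space):
        body = ResponseBody(
            reactions=(ReactionEntry("[C:1][OH]>>[C:1]", ("CCO",), "CC"),),
            building_blocks=("CCO",),
        )
        with pytest.raises(UnassignableReaction):
            assign_slots(body, space.registry)


class TestCandidateBBs:
    def test_exact_catalog_match_is_rank_one(self, space):
        bb = space.compatible_blocks("T1", 0)[0]
        candidates = candidate_bbs(bb.smiles, "T1", 0, space)
        assert candidates[0].bb_id == bb.id
        assert candidates[0].similarity == 1.0
        assert candidates[0].representation == "exact"

    def test_offcatalog_merges_topk_plus_novel(self, space):
        bb = space.compatible_blocks("T1", 0)[0]
        perturbed = perturb_molecule(bb.smiles, random.Random(0))
        assert perturbed not in space.by_smiles
        candidates = candidate_bbs(perturbed, "T1", 0, space, k=2)
        catalog_candidates = [c for c in candidates if not c.is_novel]
        novel = [c for c in candidates if c.is_novel]
        assert 1 <= len(catalog_candidates) <= 4  # union of two top-2 lists
        if novel:  # admitted only when the perturbed block still slot-matches
            assert novel[0].smiles == perturbed
            assert novel[0].similarity == 1.0

    def test_catalog_candidates_all_slot_compatible(self, space):
        perturbed = perturb_molecule(
            space.compatible_blocks("T2", 0)[3].smiles, random.Random(1)
        )
        pattern = space.template("T2").rxn().GetReactantTemplate(0)
        for c in candidate_bbs(perturbed, "T2", 0, space):
            if not c.is_novel:
                assert Chem.MolFromSmiles(c.smiles).HasSubstructMatch(pattern)

    def test_ranking_equals_full_scan_oracle(self, space):
        """Top catalog candidates are the global Morgan argmaxes over the
        slot-compatible subset."""
        bb = space.compatible_blocks("T1", 1)[5]
        perturbed = perturb_molecule(bb.smiles, random.Random(2))
        candidates = [
            c for c in candidate_bbs(perturbed, "T1", 1, space, k=2) if not c.is_novel
        ]
        scored = sorted(
            (
                (morgan_tanimoto(perturbed, b.smiles), b.id)
                for b in space.compatible_blocks("T1", 1)
            ),
            key=lambda t: (-t[0], t[1]),
        )
        # the best Morgan hit is always in the merged candidate list, first
        assert candidates[0].bb_id == scored[0][1]
        assert candidates[0].similarity == pytest.approx(scored[0][0])
        # string-representation hits are the top-k by edit similarity
        by_string = sorted(
            (
                (smiles_string_similarity(perturbed, b.smiles), b.id)
                for b in space.compatible_blocks("T1", 1)
            ),
            key=lambda t: (-t[0], t[1]),
        )
        candidate_ids = {c.bb_id for c in candidates}
        assert by_string[0][1] in candidate_ids

    def test_empty_slot_and_invalid_prediction_raises(self, space):
        # ester alcohol slot has no compatible catalog blocks and the
        # prediction does not parse: nothing to offer
        with pytest.raises(EmptyCandidateSet):
            candidate_bbs("C((", "T5", 1, space)


class TestProductSelection:
    def test_enumerate_known_amide(self, space):
        products = enumerate_products(space.template("T1"), ["CC(=O)O", "CN"])
        assert products == {"CNC(C)=O"}

    def test_unmatched_reactants_raise(self, space):
        with pytest.raises(NoProducts):
            enumerate_products(space.template("T1"), ["CC", "CCC"])

    def test_multiple_products_all_returned(self, space):
        products = enumerate_products(space.template("T1"), ["CC(=O)O", "NCCNC"])
        assert len(products) > 1

    def test_select_prefers_predicted(self):
        products = {"CNC(C)=O", "CC(=O)NCCNC"}
        assert select_product(products, "CNC(C)=O") == "CNC(C)=O"

    def test_select_singleton(self):
        assert select_product({"CCO"}, "totally-different") == "CCO"

    def test_tie_breaks_lexicographically(self):
        # equidistant from the prediction -> smaller canonical string wins
        products = {"CCN", "CCF"}
        assert select_product(products, "CCO") == "CCF"


class TestReconstruct:
    def test_perfect_response_gives_exact_ground_truth_route(
        self, space, corpus_routes, records
    ):
        for route, record in list(zip(corpus_routes, records))[:15]:
            result = reconstruct(record.response, route.target_smiles, space)
            assert result.status == "exact"
            best = max(result.routes, key=lambda r: r.score)
            assert best.route.steps == route.steps
            assert not best.uses_novel_bb

    def test_routes_replay_and_analog_routes_are_catalog_only(
        self, space, corpus_routes, records
    ):
        corrupting = CorruptingOracle(records, seed=5, bb_swap_rate=1.0)
        checked_analogs = 0
        for route in corpus_routes[:15]:
            text = corrupting.predict(route.target_smiles, PredictorConfig())[0]
            try:
                result = reconstruct(text, route.target_smiles, space)
            except Exception:
                continue
            for r in result.routes:
                assert replay_route(r.route, space.registry) == r.route.target_smiles
            for analog in result.analogs:
                checked_analogs += 1
                for smiles in analog.route.building_block_smiles():
                    assert smiles in space.by_smiles
        assert checked_analogs > 0

    def test_single_swap_recovers_exact_when_true_block_in_topk(self):
        """Graceful degradation: a small perturbation of one block still
        reconstructs the original target through the candidate list."""
        catalog = [
            BuildingBlock("ac1", canonicalize("OC(=O)c1ccccc1")),
            BuildingBlock("ac2", canonicalize("OC(=O)CCC")),
            BuildingBlock("am1", canonicalize("NCc1ccccc1")),
        ]
        space = ChemSpace(catalog, [make_template("A", "amide", AMIDE)])
        acid, amine = catalog[0].smiles, catalog[2].smiles
        product = sorted(enumerate_template_products(space.template("A"), [acid, amine]))[0]
        perturbed_acid = perturb_molecule(acid, random.Random(4))
        body = ResponseBody(
            reactions=(ReactionEntry(AMIDE, (perturbed_acid, amine), product),),
            building_blocks=(perturbed_acid, amine),
        )
        result = reconstruct(body, product, space)
        assert result.status == "exact"

    def test_swapped_block_yields_analog_or_novel(self, space, corpus_routes, records):
        corrupting = CorruptingOracle(records, seed=7, bb_swap_rate=1.0)
        statuses = set()
        for route in corpus_routes[:20]:
            text = corrupting.predict(route.target_smiles, PredictorConfig())[0]
            try:
                result = reconstruct(text, route.target_smiles, space)
            except Exception:
                continue
            statuses.add(result.status)
            if result.status in ("analog", "novel_bb") and result.analogs:
                assert result.best_analog.similarity.morgan == max(
                    a.similarity.morgan for a in result.analogs
                )
        assert statuses & {"analog", "novel_bb", "exact"}

    def test_foreign_final_template_fails(self, space, corpus_routes, records):
        route, record = corpus_routes[0], records[0]
        entries = list(record.response.reactions)
        entries[0] = ReactionEntry(
            "[C:1][OX2H1]>>[C:1]Cl", entries[0].reactants, entries[0].product
        )
        body = ResponseBody(tuple(entries), record.response.building_blocks)
        if len(entries) == 1:
            with pytest.raises(Exception):
                reconstruct(body, route.target_smiles, space)
        else:
            result = reconstruct(body, route.target_smiles, space)
            assert result.status == "failed"

    def test_deterministic(self, space, corpus_routes, records):
        corrupting = CorruptingOracle(records, seed=9, bb_swap_rate=1.0)
        route = corpus_routes[1]
        text = corrupting.predict(route.target_smiles, PredictorConfig())[0]
        one = reconstruct(text, route.target_smiles, space)
        two = reconstruct(text, route.target_smiles, space)
        assert one.status == two.status
        assert [r.route for r in one.routes] == [r.route for r in two.routes]
        assert [a.smiles for a in one.analogs] == [a.smiles for a in two.analogs]


class TestReconstructTarget:
    def test_perfect_oracle_exact_everywhere(self, space, corpus_routes, oracle):
        for route in corpus_routes[:20]:
            result = reconstruct_target(
                route.target_smiles, oracle, space, PredictorConfig(n_samples=1)
            )
            assert result.status == "exact"

    def test_merge_keeps_best_status_and_analog_max(
        self, space, corpus_routes, records
    ):
        corrupting = CorruptingOracle(records, seed=11, bb_swap_rate=0.7)
        route = corpus_routes[2]
        config = PredictorConfig(n_samples=4)
        merged = reconstruct_target(route.target_smiles, corrupting, space, config)
        rank = {"failed": 0, "analog": 1, "novel_bb": 2, "exact": 3}
        per_sample = []
        for text in corrupting.predict(route.target_smiles, config):
            try:
                per_sample.append(reconstruct(text, route.target_smiles, space))
            except Exception:
                continue
        assert rank[merged.status] == max(
            (rank[r.status] for r in per_sample), default=0
        )
        if merged.best_analog is not None:
            for r in per_sample:
                if r.best_analog is not None:
                    assert (
                        merged.best_analog.similarity.morgan
                        >= r.best_analog.similarity.morgan
                    )


class TestHitExpand:
    def _hit_setup(self, space, corpus_routes, records):
        # a 2-step target whose final step is an amide: the amide fragment is
        # a natural fixed core
        for route, record in zip(corpus_routes, records):
            if route.n_steps >= 2 and route.steps[-1].template_id == "T1":
                return route, record
        pytest.skip("no 2-step amide-terminated route in corpus")

    def test_all_survivors_contain_core_with_valid_routes(
        self, space, corpus_routes, records
    ):
        route, record = self._hit_setup(space, corpus_routes, records)
        core = "C(=O)N"
        corrupting = CorruptingOracle(records, seed=13, bb_swap_rate=1.0)
        analogs = hit_expand(
            route.target_smiles, core, 10, corrupting, space,
            PredictorConfig(n_samples=4),
        )
        query = Chem.MolFromSmarts(core)
        for analog in analogs:
            assert Chem.MolFromSmiles(analog.smiles).HasSubstructMatch(query)
            assert replay_route(analog.route, space.registry) == analog.smiles

    def test_rediscovery_kept_and_flagged(self, space, corpus_routes, records, oracle):
        route, record = self._hit_setup(space, corpus_routes, records)
        analogs = hit_expand(
            route.target_smiles, "C(=O)N", 10, oracle, space,
            PredictorConfig(n_samples=1),
        )
        assert any(a.is_rediscovery and a.smiles == route.target_smiles for a in analogs)

    def test_core_not_in_target_raises(self, space, oracle, corpus_routes):
        with pytest.raises(CoreNotInTarget):
            hit_expand(
                "CCCCCC", "c1ccccc1", 5, oracle, space, PredictorConfig(n_samples=1)
            )
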