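import itertools

import pytest

from pyrdetour import (ConstraintSet, FixtureSpec, Metabolite, ModelError,
                       Objective, Reaction, StoichiometricModel,
                       carbon_core_reactants, classify_routes,
                       enumerate_release_sets, enumerate_routes,
                       equivalence_closure, find_producers, minimize,
                       random_network)
from pyrdetour.routes import producer_fixing

from _oracles import exhaustive_release_sets


def cofactor_toy():
    """Three-reaction chain a->b->c, each step shedding phosphate."""
    mets = [Metabolite(id=i) for i in
            ("a", "b", "c", "pi_c", "atp", "adp", "amp", "h2o_c",
             "pep", "pyr", "x", "y")]
    rxns = [
        Reaction("r_ab", {"a": -1, "b": 1, "pi_c": 1}),
        Reaction("r_bc", {"b": -1, "c": 1, "pi_c": 1}),
        Reaction("r_atp", {"atp": -1, "h2o_c": -1, "adp": 1, "pi_c": 1}),
        Reaction("r_adk", {"adp": -1, "amp": 1, "pi_c": 1}),
        Reaction("r_pyk", {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}),
        Reaction("r_xy", {"x": -2, "y": 1}),
    ]
    return StoichiometricModel(metabolites=mets, reactions=rxns)


class TestEquivalence:
    def test_adenylates_form_one_class(self):
        eq = equivalence_closure(cofactor_toy())
        assert eq.equivalent("atp", "adp")
        assert eq.equivalent("adp", "amp")
        assert eq.equivalent("atp", "amp")  # transitive

    def test_chain_closure_by_transitivity(self):
        eq = equivalence_closure(cofactor_toy())
        # a ~ b via r_ab (+pi), b ~ c via r_bc, hence a ~ c
        assert eq.equivalent("a", "b") and eq.equivalent("a", "c")

    def test_two_to_one_reactions_do_not_merge(self):
        eq = equivalence_closure(cofactor_toy())
        assert not eq.equivalent("x", "y")

    def test_isolated_metabolite_is_singleton(self):
        model = StoichiometricModel(
            metabolites=[Metabolite(id="solo"), Metabolite(id="a"),
                         Metabolite(id="b")],
            reactions=[Reaction("r", {"a": -1, "b": 1})])
        eq = equivalence_closure(model, cofactors=frozenset())
        assert {"solo"} in [set(c) for c in eq.classes()]

    def test_classes_form_a_partition(self):
        eq = equivalence_closure(cofactor_toy())
        classes = eq.classes()
        seen = [m for c in classes for m in c]
        assert len(seen) == len(set(seen))  # disjoint
        assert set(seen) == {m.id for m in cofactor_toy().metabolites}  # total
        for c in classes:  # consistent with the pairwise relation
            for a, b in itertools.combinations(sorted(c), 2):
                assert eq.equivalent(a, b)

    def test_closure_is_stable_under_recomputation(self):
        eq1 = equivalence_closure(cofactor_toy())
        eq2 = equivalence_closure(cofactor_toy())
        assert eq1.classes() == eq2.classes()


class TestCarbonCore:
    def test_cofactor_pair_is_dropped(self):
        model = cofactor_toy()
        eq = equivalence_closure(model)
        # pep + adp -> pyr + atp: atp~adp pairing removes the pair
        assert carbon_core_reactants(model.reaction("r_pyk"), "pyr", eq) == {"pep"}

    def test_plain_precursor_is_kept(self):
        model = cofactor_toy()
        eq = equivalence_closure(model)
        assert carbon_core_reactants(model.reaction("r_xy"), "y", eq) == {"x"}

    def test_equivalent_reactant_is_the_carrier(self):
        # atp + h2o -> adp + pi: ATP carries ADP's carbon core
        model = cofactor_toy()
        eq = equivalence_closure(model)
        assert carbon_core_reactants(model.reaction("r_atp"), "adp", eq) == {"atp"}

    def test_cofactor_only_reactant_side_is_empty(self):
        mets = [Metabolite(id=i) for i in ("pi_c", "h2o_c", "weird")]
        model = StoichiometricModel(
            metabolites=mets,
            reactions=[Reaction("r", {"pi_c": -1, "h2o_c": -1, "weird": 1})])
        eq = equivalence_closure(model)
        assert carbon_core_reactants(model.reaction("r"), "weird", eq) == set()

    def test_non_producing_reaction_rejected(self):
        model = cofactor_toy()
        eq = equivalence_closure(model)
        with pytest.raises(ModelError):
            carbon_core_reactants(model.reaction("r_ab"), "a", eq)


class TestProducers:
    def test_moi_has_three_varying_zero_rate_producers(self, fig5_cset):
        ps = find_producers(fig5_cset, "MOI")
        assert [p.reaction_id for p in ps] == ["J5", "J6", "J7"]
        for p in ps:
            assert p.minimal_rate == pytest.approx(0.0, abs=1e-8)
            assert p.varies

    def test_sole_producer_is_mandatory(self, fig5_cset):
        ps = find_producers(fig5_cset, "E2")
        assert [p.reaction_id for p in ps] == ["J8"]
        assert ps.producers[0].minimal_rate > 1e-6
        assert not ps.producers[0].varies

    def test_unproduced_metabolite_gives_empty_set(self):
        model = StoichiometricModel(
            metabolites=[Metabolite(id="S_e", balanced=False),
                         Metabolite(id="a"), Metabolite(id="dead")],
            reactions=[Reaction("up", {"S_e": -1, "a": 1}),
                       Reaction("mu", {"a": -1}),
                       Reaction("sink", {"dead": -1, "a": 1},
                                lower_bound=0.0, upper_bound=0.0)],
            boundary={"S_e": -1000.0}, biomass_reaction="mu")
        ps = find_producers(ConstraintSet.k_a(model, growth=0.1), "dead")
        assert ps.producers == ()


class TestReleaseSets:
    def test_figure5_singletons(self, fig5_cset):
        ps = find_producers(fig5_cset, "MOI")
        rs = enumerate_release_sets(fig5_cset, ps, k_max=2, substrate="S_e")
        assert [sorted(r.released) for r in rs] == [["J5"], ["J6"], ["J7"]]
        for r in rs:
            assert r.feasible_yield == pytest.approx(0.5, rel=1e-6)

    def test_single_producer_enumerates_nothing(self, fig5_cset):
        ps = find_producers(fig5_cset, "E2")
        assert enumerate_release_sets(fig5_cset, ps, k_max=2) == []

    def test_k_max_below_one_rejected(self, fig5_cset):
        ps = find_producers(fig5_cset, "MOI")
        with pytest.raises(ModelError):
            enumerate_release_sets(fig5_cset, ps, k_max=0)

    def test_minimality_each_member_is_needed(self, fig5_cset):
        ps = find_producers(fig5_cset, "MOI")
        fixes = producer_fixing(ps)
        for rs in enumerate_release_sets(fig5_cset, ps, k_max=2):
            for member in rs.released:
                smaller = rs.released - {member}
                kept = {r: v for r, v in fixes.items() if r not in smaller}
                res = minimize(fig5_cset.with_fixed_fluxes(kept), Objective())
                assert res.status == "infeasible"

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_subset_search(self, seed):
        model = random_network(FixtureSpec(
            seed=seed, n_extra=4, reversible_fraction=0.25))
        cset = ConstraintSet.k_a(model, growth=0.1)
        for met in ("m2_0", "m3_0"):
            ps = find_producers(cset, met)
            fixes = producer_fixing(ps)
            ours = [rs.released
                    for rs in enumerate_release_sets(cset, ps, k_max=len(fixes) or 1)]
            ref = exhaustive_release_sets(cset, fixes)
            assert sorted(ours, key=sorted) == sorted(ref, key=sorted)


class TestRoutes:
    def test_figure5_yields_exactly_six_routes(self, fig5_cset):
        routes = enumerate_routes(fig5_cset, "S_e", "MOI", k_max=2)
        assert [sorted(r.released) for r in routes] == [
            ["J3", "J5"], ["J3", "J6"], ["J3", "J7"],
            ["J4", "J5"], ["J4", "J6"], ["J4", "J7"]]

    def test_route_flux_patterns_are_feasible_and_yielding(self, fig5_cset):
        for route in enumerate_routes(fig5_cset, "S_e", "MOI", k_max=2):
            assert route.flux_pattern  # representative vector found
            assert route.feasible_yield == pytest.approx(0.5, rel=1e-6)
            for rxn_id in route.released:
                assert abs(route.flux_pattern[rxn_id]) > 1e-8  # release active

    def test_linear_chain_gives_single_release_free_route(self):
        model = StoichiometricModel(
            metabolites=[Metabolite(id="S_e", balanced=False),
                         Metabolite(id="a"), Metabolite(id="b")],
            reactions=[Reaction("up", {"S_e": -1, "a": 1}),
                       Reaction("r", {"a": -1, "b": 1}),
                       Reaction("mu", {"b": -1})],
            boundary={"S_e": -1000.0}, biomass_reaction="mu")
        routes = enumerate_routes(ConstraintSet.k_a(model, growth=0.1),
                                  "S_e", "b", k_max=2)
        assert len(routes) == 1
        assert routes[0].released == frozenset()

    def test_enumeration_is_deterministic(self, fig5_cset):
        def run():
            return [(sorted(r.released), r.released_per_level, r.feasible_yield)
                    for r in enumerate_routes(fig5_cset, "S_e", "MOI", k_max=2)]
        assert run() == run()

    @pytest.mark.parametrize("seed", range(8))
    def test_random_layered_networks_match_exhaustive_enumeration(self, seed):
        """On layered DAG fixtures the route family equals an exhaustive
        path-times-release enumeration (full subset search at every level,
        no pruning, no memoization)."""
        model = random_network(FixtureSpec(
            seed=seed, n_extra=3, reversible_fraction=0.0, cofactor_pair=False))
        cset = ConstraintSet.k_a(model, growth=0.1)
        moi = "m3_0"
        routes = enumerate_routes(cset, "S_e", moi, k_max=3)

        eqv = equivalence_closure(model, frozenset())

        def family(met, seen) -> set[frozenset]:
            if not model.metabolite(met).balanced or met in seen:
                return {frozenset()}
            ps = find_producers(cset, met)
            fam = exhaustive_release_sets(cset, producer_fixing(ps))
            if fam:
                alternatives = [(rs, rs) for rs in fam]
            else:
                mandatory = frozenset(p.reaction_id for p in ps
                                      if p.minimal_rate > 1e-6)
                alternatives = [(frozenset(), mandatory)]
            out: set[frozenset] = set()
            for released, last in alternatives:
                pre: set[str] = set()
                for rxn_id in last:
                    pre |= carbon_core_reactants(model.reaction(rxn_id), met, eqv)
                combos = {frozenset()}
                for p in sorted(pre):
                    combos = {c | f for c in combos
                              for f in family(p, seen | {met})}
                out |= {released | c for c in combos}
            return out

        assert {r.released for r in routes} == family(moi, set())


class TestClassify:
    def test_key_metabolite_tagging(self):
        mets = [Metabolite(id="S_e", balanced=False), Metabolite(id="dha"),
                Metabolite(id="pyr")]
        rxns = [Reaction("up", {"S_e": -1, "dha": 1}),
                Reaction("r", {"dha": -1, "pyr": 1}),
                Reaction("mu", {"pyr": -1})]
        model = StoichiometricModel(metabolites=mets, reactions=rxns,
                                    boundary={"S_e": -1000.0},
                                    biomass_reaction="mu")
        cset = ConstraintSet.k_a(model, growth=0.1)
        routes = classify_routes(enumerate_routes(cset, "S_e", "pyr", k_max=2))
        assert routes[0].class_tag == "dihydroxyacetone-path"

    def test_unmatched_routes_are_unclassified(self, fig5_cset):
        routes = classify_routes(enumerate_routes(fig5_cset, "S_e", "MOI"))
        assert all(r.class_tag == "unclassified" for r in routes)
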