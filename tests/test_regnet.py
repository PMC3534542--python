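import pytest
from hypothesis import given, settings, strategies as st

from pyrdetour import (ConstraintSet, ExpressionTable, Metabolite, ModelError,
                       Reaction, RuleError, enzymatic_capacity, error_variance,
                       exemption_candidates, min_substrate_uptake, parse_rules,
                       predict_uptake_triplet, steady_state, tfn_constraints,
                       toy_regnet)
from pyrdetour.model import GeneStateMap

from _oracles import truth_table_fixpoints


class TestParse:
    def test_two_rule_file(self):
        net = parse_rules("gA = env:glc and env:o2\ngB = gA or env:stress\n")
        assert net.genes == {"gA", "gB"}
        assert net.signals == {"env:glc", "env:o2", "env:stress"}

    def test_cycle_is_rejected_and_named(self):
        with pytest.raises(RuleError, match="g1"):
            parse_rules("g1 = g2\ng2 = g1\n")

    def test_malformed_formula_locates_line(self):
        with pytest.raises(RuleError, match="line 2"):
            parse_rules("g1 = env:a\ng2 = and or\n")

    def test_duplicate_target_rejected(self):
        with pytest.raises(RuleError, match="duplicate"):
            parse_rules("g1 = env:a\ng1 = env:b\n")

    def test_reads_from_file(self, tmp_path):
        path = tmp_path / "rules.txt"
        path.write_text("# comment\ngA = env:o2\n")
        assert parse_rules(path).genes == {"gA"}


class TestSteadyState:
    def test_no_rules_means_all_genes_default_on(self):
        net = parse_rules("")
        state = steady_state(net, {})
        assert state["anything"] is True

    def test_cascade_and_knockout(self):
        net = parse_rules("g1 = env:sig\ng2 = g1\n")
        on = steady_state(net, {"env:sig": True})
        assert on["g1"] and on["g2"]
        ko = steady_state(net, {"env:sig": True}, tf_knockouts={"g1"})
        assert not ko["g1"] and not ko["g2"]

    def test_not_inverts_downstream(self):
        net = parse_rules("rep = env:glc\ntarget = not rep\n")
        assert steady_state(net, {"env:glc": True})["target"] is False
        assert steady_state(net, {"env:glc": False})["target"] is True

    def test_missing_signal_defaults_false_with_warning(self):
        net = parse_rules("g = env:mystery\n")
        with pytest.warns(UserWarning, match="env:mystery"):
            state = steady_state(net, {})
        assert state["g"] is False

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_unique_truth_table_fixpoint(self, seed):
        net, env, _ = toy_regnet(seed)
        for ko in (frozenset(), {"tfA"}):
            state = steady_state(net, env, tf_knockouts=set(ko))
            fixpoints = truth_table_fixpoints(net, env, knockouts=ko)
            assert len(fixpoints) == 1  # acyclic => unique
            assert {g: state[g] for g in net.genes} == {
                g: fixpoints[0][g] for g in net.genes}


class TestTfnConstraints:
    def test_all_on_gives_empty_set(self, fig5):
        k_tf = tfn_constraints(fig5, GeneStateMap())
        assert k_tf.fixed_fluxes == ()

    def test_off_gene_blocks_single_gene_reaction(self, fig5):
        k_tf = tfn_constraints(fig5, GeneStateMap({"g6": False}))
        assert dict(k_tf.fixed_fluxes) == {"J6": 0.0}

    def test_exempt_reaction_stays_open(self, fig5):
        k_tf = tfn_constraints(fig5, GeneStateMap({"g6": False}),
                               exemptions={"J6"})
        assert k_tf.fixed_fluxes == ()

    def test_complex_needs_every_subunit(self, fig5):
        k_tf = tfn_constraints(fig5, GeneStateMap({"g5b": False}))
        assert dict(k_tf.fixed_fluxes) == {"J5": 0.0}  # "g5a and g5b"

    def test_exemption_candidates_finds_essential_blocked(self):
        # a chain whose only step is downregulated: essential AND blocked
        from pyrdetour import StoichiometricModel
        model = StoichiometricModel(
            metabolites=[Metabolite(id="S_e", compartment="e", balanced=False),
                         Metabolite(id="a"), Metabolite(id="b")],
            reactions=[Reaction("up", {"S_e": -1, "a": 1}),
                       Reaction("step", {"a": -1, "b": 1}, gpr="gx"),
                       Reaction("mu", {"b": -1})],
            boundary={"S_e": -1000.0}, biomass_reaction="mu")
        k_m = ConstraintSet.k_a(model, growth=0.1, name="K_m")
        k_tf = tfn_constraints(model, GeneStateMap({"gx": False}))
        assert exemption_candidates(model, k_m, k_tf) == {"step"}

    def test_non_essential_blocked_reaction_is_no_candidate(self, fig3):
        # either branch alone suffices for growth, so neither is essential
        k_m = ConstraintSet.k_a(fig3, growth=0.1, name="K_m")
        k_tf = tfn_constraints(fig3, GeneStateMap({"g_m1": False}))
        assert exemption_candidates(fig3, k_m, k_tf) == frozenset()


def _with_acetate(model):
    m = model.add_reaction(
        Reaction("J_ac", {"MOI": -1, "ac_e": 1}) if "MOI" in
        {x.id for x in model.metabolites} else
        Reaction("J_ac", {"M2": -1, "ac_e": 1}),
        declare=[Metabolite(id="ac_e", compartment="e", balanced=False)])
    return m.set_boundary("ac_e", 0.0)


class TestUptakeTriplet:
    def test_empty_network_gives_identical_predictions(self, fig5):
        m = _with_acetate(fig5)
        net = parse_rules("")
        trip = predict_uptake_triplet(m, 0.1, 0.0, "S_e", net, {})
        a, b, c = trip.values()
        assert a == pytest.approx(b) == pytest.approx(c)

    def test_blocking_efficient_branch_raises_uptake(self, fig3):
        # regulation forces the 2:1 branch: predicted uptake doubles
        m = _with_acetate(fig3)
        net = parse_rules("g_m2a = env:x\ng_m2b = env:x\n")
        trip = predict_uptake_triplet(m, 0.1, 0.0, "S_e", net,
                                      env={"env:x": False})
        base, reg, _ = trip.values()
        assert base == pytest.approx(0.1, abs=1e-8)
        assert reg == pytest.approx(0.2, abs=1e-8)

    def test_regulated_prediction_never_below_metabolic(self, fig3, fig5):
        for model in (fig3, fig5):
            m = _with_acetate(model)
            for seed in range(5):
                net, env, _ = toy_regnet(seed)
                trip = predict_uptake_triplet(m, 0.1, 0.0, "S_e", net, env)
                base, reg, ko = trip.values()
                if reg is not None:
                    assert reg >= base - 1e-9
                if ko is not None:
                    assert ko >= base - 1e-9

    def test_irrelevant_tf_knockout_changes_nothing(self, fig5):
        m = _with_acetate(fig5)
        net = parse_rules("lonely = env:x\n")  # regulates no GPR gene
        trip = predict_uptake_triplet(m, 0.1, 0.0, "S_e", net,
                                      {"env:x": True}, tf_knockout={"lonely"})
        a, b, c = trip.values()
        assert a == pytest.approx(b) == pytest.approx(c)

    def test_inconsistent_measurements_raise(self, fig5):
        m = _with_acetate(fig5).set_boundary("S_e", -0.01)
        net = parse_rules("")
        with pytest.raises(ModelError, match="infeasible"):
            predict_uptake_triplet(m, 0.5, 0.0, "S_e", net, {})

    def test_acetate_constraint_is_enforced(self, fig5):
        m = _with_acetate(fig5)
        net = parse_rules("")
        trip = predict_uptake_triplet(m, 0.1, 0.05, "S_e", net, {})
        # growth demand (E2 + MOI: two substrate units per growth unit)
        # plus the secreted carbon must be taken up
        assert trip.metabolic.objective_value == pytest.approx(0.25, abs=1e-8)
        assert trip.metabolic.fluxes["J_ac"] == pytest.approx(0.05, abs=1e-8)


class TestErrorVariance:
    def test_perfect_prediction_is_zero(self):
        assert error_variance([1.0, 2.0], [1.0, 2.0])[0] == 0.0

    def test_worked_arithmetic(self):
        value, excluded = error_variance([1, 2], [1.5, 1.5])
        assert value == pytest.approx(0.25)
        assert excluded == 0

    def test_infeasible_predictions_excluded_pairwise(self):
        value, excluded = error_variance([1, 2, 3], [1.0, None, 3.0])
        assert value == 0.0
        assert excluded == 1

    def test_ddof_one_matches_unbiased_denominator(self):
        v0, _ = error_variance([1, 2, 3], [0, 0, 0])
        v1, _ = error_variance([1, 2, 3], [0, 0, 0], ddof=1)
        assert v1 == pytest.approx(v0 * 3 / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ModelError):
            error_variance([1], [1, 2])

    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
                    min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_invariant_under_pair_permutation(self, pairs, rnd):
        obs = [p[0] for p in pairs]
        pred = [p[1] for p in pairs]
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        v1, _ = error_variance(obs, pred)
        v2, _ = error_variance([p[0] for p in shuffled],
                               [p[1] for p in shuffled])
        assert v1 == pytest.approx(v2, rel=1e-12, abs=1e-12)


class TestCapacity:
    @pytest.mark.parametrize("gpr,values,expected", [
        ("g1", {"g1": 7.5}, True),                  # at/above threshold
        ("g1", {"g1": 6.9}, False),
        ("g1 and g2", {"g1": 8.0, "g2": 6.0}, False),   # complex needs all
        ("g1 or g2", {"g1": 8.0, "g2": 5.0}, True),     # isozyme suffices
        ("", {}, True),                              # spontaneous
    ])
    def test_threshold_rule(self, gpr, values, expected):
        model = __import__("pyrdetour").StoichiometricModel(
            metabolites=[Metabolite(id="a"), Metabolite(id="b")],
            reactions=[Reaction("r", {"a": -1, "b": 1}, gpr=gpr)])
        table = ExpressionTable(values=values, threshold=7.0)
        assert enzymatic_capacity(model, ["r"], table)["r"] is expected

    def test_missing_gene_policy(self, fig5):
        table = ExpressionTable(values={}, threshold=7.0)
        with pytest.warns(UserWarning, match="missing"):
            off = enzymatic_capacity(fig5, ["J6"], table, missing="assume-off")
        assert off["J6"] is False
        with pytest.warns(UserWarning, match="missing"):
            on = enzymatic_capacity(fig5, ["J6"], table, missing="assume-on")
        assert on["J6"] is True

    def test_route_verdict_requires_every_active_reaction(self, fig5_cset):
        from pyrdetour import enumerate_routes
        routes = enumerate_routes(fig5_cset, "S_e", "MOI", k_max=2)
        r35 = next(r for r in routes if r.released == {"J3", "J5"})
        values = {"g3": 8.0, "g5a": 8.0, "g5b": 8.0}
        table = ExpressionTable(values=values, threshold=7.0)
        ok = enzymatic_capacity(fig5_cset.model, [r35], table)
        assert list(ok.values()) == [True]
        table_low = ExpressionTable(values={**values, "g5b": 6.0}, threshold=7.0)
        bad = enzymatic_capacity(fig5_cset.model, [r35], table_low)
        assert list(bad.values()) == [False]
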