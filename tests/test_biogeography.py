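"""DEC likelihood/marginals vs enumeration oracles, DIVA DP vs exhaustive search."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from phyloniche.biogeography import (
    DECModel,
    _dec_generator,
    build_state_space,
    cladogenetic_scenarios,
    diva_parsimony,
    plan_tree_resampling,
    summarize_over_trees,
)
from phyloniche.trees import Chronogram

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_dec_loglik(tree: Chronogram, tips, space, d, e):
    """Enumerate every assignment of states to internal nodes and every
    cladogenetic scenario, with numerically exponentiated matrices."""
    Q = _dec_generator(space, d, e)
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    P = {n: expm(Q * (n.edge.length or 0.0)) for n in nodes if n.parent_node is not None}
    idx = space.index
    total = 0.0
    for assign in itertools.product(space.states, repeat=len(internal)):
        state = dict(zip(internal, assign))
        for n in nodes:
            if n.is_leaf():
                state[n] = space.parse(tips[n.taxon.label])
        # scenario-averaged probability for this node-state assignment
        prob = 1.0
        for n in internal:
            kids = n.child_nodes()
            scen = cladogenetic_scenarios(state[n])
            acc = 0.0
            for x, y in scen:
                acc += (P[kids[0]][idx[x], idx[state[kids[0]]]]
                        * P[kids[1]][idx[y], idx[state[kids[1]]]])
            prob *= acc / len(scen)
        total += prob
    return math.log(total) if total > 0 else -math.inf


def exhaustive_diva(tree: Chronogram, tips, space):
    """Minimum event cost and all optimal per-node states by full enumeration."""
    from phyloniche.biogeography import _anagenetic_cost, _diva_splits

    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    tips_parsed = {t: space.parse(r) for t, r in tips.items()}
    best_cost = math.inf
    per_node_opt = {n: set() for n in internal}
    for assign in itertools.product(space.states, repeat=len(internal)):
        state = dict(zip(internal, assign))
        for n in nodes:
            if n.is_leaf():
                state[n] = tips_parsed[n.taxon.label]
        cost = 0.0
        feasible = True
        for n in internal:
            kids = n.child_nodes()
            # best split of state[n] into daughter starting ranges, then
            # anagenetic change to each daughter's own state
            c = min(
                (_anagenetic_cost(x, state[kids[0]]) + _anagenetic_cost(y, state[kids[1]])
                 for x, y in _diva_splits(state[n])
                 if x in space.index and y in space.index),
                default=math.inf,
            )
            if not math.isfinite(c):
                feasible = False
                break
            cost += c
        if not feasible:
            continue
        if cost < best_cost - 1e-9:
            best_cost = cost
            per_node_opt = {n: {state[n]} for n in internal}
        elif abs(cost - best_cost) <= 1e-9:
            for n in internal:
                per_node_opt[n].add(state[n])
    return best_cost, {Chronogram.bipartition(n): s for n, s in per_node_opt.items()}


# ---------------------------------------------------------------------------
# DEC


class TestDECLikelihood:
    def test_single_area_system_has_probability_one(self):
        tree = Chronogram.from_newick("((a:1,b:1):1,c:2);")
        space = build_state_space(["A"], 1)
        m = DECModel(tree, {t: "A" for t in "abc"}, space=space)
        assert m.loglik(0.4, 0.2) == 0.0

    def test_no_event_limit(self):
        tree = Chronogram.from_newick("((a:1,b:1):1,c:2);")
        space = build_state_space(list("ABCDEFG"), 2)
        same = DECModel(tree, {t: "F" for t in "abc"}, space=space)
        assert same.loglik(0.0, 0.0) == 0.0
        # (F,(F,E)) is still reachable event-free via a widespread EF root
        # splitting by vicariance; three pairwise-distinct singletons under a
        # two-area cap are not, so that configuration is impossible
        diff = DECModel(tree, {"a": "A", "b": "B", "c": "C"}, space=space)
        assert diff.loglik(0.0, 0.0) == -math.inf
        reachable = DECModel(tree, {"a": "F", "b": "F", "c": "E"}, space=space)
        assert -math.inf < reachable.loglik(0.0, 0.0) < 0.0

    @pytest.mark.parametrize("newick,tips", [
        ("(x:1.0,y:1.0);", {"x": "A", "y": "B"}),
        ("((x:1.0,y:1.0):0.5,z:1.5);", {"x": "A", "y": "AB", "z": "B"}),
        ("((x:0.7,y:0.7):0.8,z:1.5);", {"x": "B", "y": "B", "z": "A"}),
    ])
    def test_pruning_matches_enumeration_oracle(self, newick, tips):
        tree = Chronogram.from_newick(newick)
        space = build_state_space(["A", "B"], 2)
        m = DECModel(tree, tips, space=space)
        for d, e in [(0.1, 0.1), (0.05, 0.3), (1.0, 0.2)]:
            want = brute_force_dec_loglik(tree, tips, space, d, e)
            assert m.loglik(d, e) == pytest.approx(want, abs=1e-8)

    def test_loglik_invariant_to_tip_order(self):
        space = build_state_space(list("ABC"), 2)
        t1 = Chronogram.from_newick("((x:1,y:1):1,z:2);")
        t2 = Chronogram.from_newick("(z:2,(y:1,x:1):1);")
        tips = {"x": "A", "y": "BC", "z": "C"}
        a = DECModel(t1, tips, space=space).loglik(0.2, 0.1)
        b = DECModel(t2, tips, space=space).loglik(0.2, 0.1)
        assert a == pytest.approx(b, abs=1e-12)

    def test_rate_matrix_rows_sum_to_zero_and_transitions_stochastic(self):
        space = build_state_space(list("ABCDEFG"), 2)
        Q = _dec_generator(space, 0.17, 0.31)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        for t in (0.1, 1.0, 10.0, 100.0):
            P = expm(Q * t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() >= -1e-12

    def test_tip_range_beyond_cap_rejected(self):
        tree = Chronogram.from_newick("(x:1,y:1);")
        space = build_state_space(list("ABC"), 2)
        with pytest.raises(ValueError, match="cap"):
            DECModel(tree, {"x": "ABC", "y": "A"}, space=space)


class TestDECMarginals:
    def test_marginals_match_exhaustive_posterior_on_three_tips(self):
        tree = Chronogram.from_newick("((x:1.0,y:1.0):0.5,z:1.5);")
        tips = {"x": "A", "y": "B", "z": "B"}
        space = build_state_space(["A", "B"], 2)
        d, e = 0.15, 0.1
        m = DECModel(tree, tips, space=space)
        summ = m.marginal_ranges(d, e)

        # oracle: enumerate internal-state assignments; joint probability of
        # each assignment, marginalize per node
        Q = _dec_generator(space, d, e)
        nodes = list(tree.tree.postorder_node_iter())
        internal = [n for n in nodes if not n.is_leaf()]
        P = {n: expm(Q * (n.edge.length or 0.0))
             for n in nodes if n.parent_node is not None}
        idx = space.index
        marg = {n: np.zeros(len(space)) for n in internal}
        for assign in itertools.product(space.states, repeat=len(internal)):
            state = dict(zip(internal, assign))
            for n in nodes:
                if n.is_leaf():
                    state[n] = space.parse(tips[n.taxon.label])
            prob = 1.0
            for n in internal:
                kids = n.child_nodes()
                scen = cladogenetic_scenarios(state[n])
                acc = sum(P[kids[0]][idx[x], idx[state[kids[0]]]]
                          * P[kids[1]][idx[y], idx[state[kids[1]]]]
                          for x, y in scen)
                prob *= acc / len(scen)
            for n in internal:
                marg[n][idx[state[n]]] += prob
        for n in internal:
            want = marg[n] / marg[n].sum() * 100.0
            got = summ.at(Chronogram.bipartition(n))
            for i, s in enumerate(space.states):
                assert got.get(space.label(s), 0.0) == pytest.approx(want[i], abs=1e-8)

    def test_per_node_frequencies_sum_to_hundred(self):
        tree = Chronogram.from_newick("((x:1,y:1):1,(z:0.5,w:0.5):1.5);")
        tips = {"x": "A", "y": "AB", "z": "B", "w": "A"}
        summ = DECModel(tree, tips).marginal_ranges(0.2, 0.1)
        for freqs in summ.frequencies.values():
            assert sum(freqs.values()) == pytest.approx(100.0, abs=0.1)

    def test_uniform_singleton_tips_give_that_range_everywhere(self):
        tree = Chronogram.from_newick("((x:1,y:1):1,(z:0.5,w:0.5):1.5);")
        space = build_state_space(list("ABCDEFG"), 2)
        summ = DECModel(tree, {t: "F" for t in "xyzw"}, space=space).marginal_ranges(0.01, 0.01)
        for freqs in summ.frequencies.values():
            assert freqs["F"] == pytest.approx(max(freqs.values()))
            assert freqs["F"] > 90.0


class TestDECFit:
    def test_identical_singletons_drive_dispersal_to_lower_bound(self):
        tree = Chronogram.from_newick("((x:1,y:1):1,z:2);")
        space = build_state_space(["A", "B"], 2)
        with pytest.warns(UserWarning, match="identical"):
            fit = DECModel(tree, {t: "A" for t in "xyz"}, space=space).fit()
        assert fit.d == pytest.approx(1e-6, rel=10)

    def test_optimum_beats_a_grid_around_it(self):
        tree = Chronogram.from_newick("((x:2,y:2):3,(z:1,w:1):4);")
        tips = {"x": "A", "y": "AB", "z": "B", "w": "B"}
        model = DECModel(tree, tips)
        fit = model.fit()
        for fd in np.linspace(0.5, 2.0, 11):
            for fe in np.linspace(0.5, 2.0, 11):
                d = min(max(fit.d * fd, 1e-6), 10.0)
                e = min(max(fit.e * fe, 1e-6), 10.0)
                assert fit.loglik >= model.loglik(d, e) - 1e-6


# ---------------------------------------------------------------------------
# DIVA


class TestDIVA:
    def test_cherry_with_disjoint_singletons_gives_vicariant_ancestor(self):
        tree = Chronogram.from_newick("(x:1,y:1);")
        space = build_state_space(["A", "B"], 2)
        recon = diva_parsimony(tree, {"x": "A", "y": "B"}, space=space)
        assert recon[frozenset({"x", "y"})] == {frozenset("AB")}

    def test_monophyletic_area_f_clade_reconstructs_f(self):
        tree = Chronogram.from_newick(
            "(((a:1,b:1):1,(c:1.5,(d:0.5,e:0.5):1):0.5):1,f:3);")
        space = build_state_space(list("ABCDEFG"), 2)
        tips = {t: "F" for t in "abcdef"}
        recon = diva_parsimony(tree, tips, space=space)
        for opts in recon.values():
            assert opts == {frozenset("F")}

    def test_enicosanthellum_pattern_gives_unique_ef_crown(self):
        tree = Chronogram.from_newick("(p:4.8,(q:3.4,r:3.4):1.4);")
        space = build_state_space(list("ABCDEFG"), 2)
        recon = diva_parsimony(tree, {"p": "F", "q": "E", "r": "E"}, space=space)
        assert recon[frozenset({"p", "q", "r"})] == {frozenset("EF")}
        assert recon[frozenset({"q", "r"})] == {frozenset("E")}

    @pytest.mark.parametrize("newick,tips,areas", [
        ("((a:1,b:1):1,c:2);", {"a": "A", "b": "B", "c": "C"}, "ABC"),
        ("((a:1,b:1):1,(c:1,d:1):1);", {"a": "A", "b": "AB", "c": "B", "d": "C"}, "ABC"),
        ("(((a:1,b:1):1,c:2):1,(d:1.5,e:1.5):1.5);",
         {"a": "A", "b": "B", "c": "AB", "d": "C", "e": "A"}, "ABC"),
        ("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1.5,f:1.5):1.5);",
         {"a": "A", "b": "B", "c": "B", "d": "C", "e": "C", "f": "A"}, "ABC"),
    ])
    def test_dp_matches_exhaustive_search(self, newick, tips, areas):
        tree = Chronogram.from_newick(newick)
        space = build_state_space(list(areas), 2)
        recon = diva_parsimony(tree, tips, space=space)
        best, oracle = exhaustive_diva(tree, tips, space)
        assert recon == oracle


# ---------------------------------------------------------------------------
# tree-sample summaries and resampling arithmetic


class TestSummaries:
    def test_identical_reconstructions_give_hundred_percent(self):
        tree = Chronogram.from_newick("((x:1,y:1):1,z:2);")
        recon = {frozenset({"x", "y"}): {frozenset("A")},
                 frozenset({"x", "y", "z"}): {frozenset("A")}}
        summ = summarize_over_trees([tree] * 5, [recon] * 5, tree)
        assert summ.at({"x", "y"}) == {"A": 100.0}

    def test_two_cooptimal_ranges_split_fifty_fifty(self):
        tree = Chronogram.from_newick("((x:1,y:1):1,z:2);")
        recon = {frozenset({"x", "y"}): {frozenset("A"), frozenset("B")},
                 frozenset({"x", "y", "z"}): {frozenset("A")}}
        summ = summarize_over_trees([tree] * 3, [recon] * 3, tree)
        got = summ.at({"x", "y"})
        assert got["A"] == pytest.approx(50.0) and got["B"] == pytest.approx(50.0)

    def test_partial_bipartition_support_uses_matching_trees_only(self):
        ref = Chronogram.from_newick("((x:1,y:1):1,z:2);")
        with_node = {frozenset({"x", "y"}): {frozenset("A")},
                     frozenset({"x", "y", "z"}): {frozenset("A")}}
        without_node = {frozenset({"x", "z"}): {frozenset("B")},
                        frozenset({"x", "y", "z"}): {frozenset("B")}}
        summ = summarize_over_trees([ref] * 5, [with_node] * 3 + [without_node] * 2, ref)
        assert summ.support[frozenset({"x", "y"})] == 3
        assert summ.at({"x", "y"}) == {"A": 100.0}
        root = summ.at({"x", "y", "z"})
        assert root["A"] == pytest.approx(60.0) and root["B"] == pytest.approx(40.0)


class TestResamplingPlan:
    def test_study_settings_yield_thousand_trees(self):
        assert plan_tree_resampling(8, 100_000_000, 5_000, 0.25, 600_000) == 1000

    def test_no_burnin_no_thinning_keeps_everything(self):
        assert plan_tree_resampling(1, 1_000_000, 5_000, 0.0, 5_000) == 200

    def test_small_run_arithmetic(self):
        assert plan_tree_resampling(1, 1_200_000, 600_000, 0.0, 600_000) == 2

    def test_non_divisible_interval_rejected(self):
        with pytest.raises(ValueError):
            plan_tree_resampling(1, 1_000_000, 7_000, 0.25, 600_000)


class TestStateSpace:
    def test_seven_areas_cap_two_gives_28_states(self):
        assert len(build_state_space(list("ABCDEFG"), 2)) == 28

    def test_single_area(self):
        assert len(build_state_space(["A"], 1)) == 1

    def test_two_areas_cap_two_enumeration(self):
        sp = build_state_space(["A", "B"], 2)
        assert sp.states == [frozenset("A"), frozenset("B"), frozenset("AB")]
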