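"""Squared-change parsimony, tip statistics, ancestral envelopes, PP filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from phyloniche.enm import EnvelopeModel
from phyloniche.geodata import RasterLayer, RasterStack
from phyloniche.niche_evolution import (
    ancestral_envelopes,
    filter_by_support,
    project_ancestral,
    reconstruct_niche_summaries,
    squared_change_parsimony,
    tip_statistics,
)
from phyloniche.trees import Chronogram


class TestTipStatistics:
    def test_basic_summaries(self):
        env = pd.DataFrame({"species": ["s"] * 3, "lon": 0.0, "lat": 0.0,
                            "Bio1": [1.0, 2.0, 3.0]})
        stats = tip_statistics(env)
        assert stats.loc["s", ("Bio1", "mean")] == 2.0
        assert stats.loc["s", ("Bio1", "min")] == 1.0
        assert stats.loc["s", ("Bio1", "max")] == 3.0

    def test_single_point_sd_is_zero(self):
        env = pd.DataFrame({"species": ["s"], "lon": [0.0], "lat": [0.0],
                            "Bio1": [5.0]})
        assert tip_statistics(env).loc["s", ("Bio1", "sd")] == 0.0

    def test_sd_matches_direct_formula(self):
        vals = np.array([2.0, 4.0, 4.0, 4.0, 6.0])
        env = pd.DataFrame({"species": ["s"] * 5, "lon": 0.0, "lat": 0.0,
                            "Bio1": vals})
        expected = np.sqrt(((vals - vals.mean()) ** 2).sum() / (len(vals) - 1))
        assert tip_statistics(env).loc["s", ("Bio1", "sd")] == pytest.approx(expected)


class TestSquaredChangeParsimony:
    def test_constant_tips_give_constant_nodes_and_zero_score(self, balanced4_tree):
        tips = pd.DataFrame({"t": {n: 3.5 for n in "abcd"}})
        recon = squared_change_parsimony(balanced4_tree, tips)
        assert np.allclose(recon.values["t"], 3.5)
        assert recon.score["t"] == pytest.approx(0.0)

    def test_star_tree_root_is_mean(self, star3_tree):
        recon = squared_change_parsimony(star3_tree, {"a": 0.0, "b": 0.0, "c": 3.0})
        root_val = recon.at_node({"a", "b", "c"})["trait"]
        assert root_val == pytest.approx(1.0)  # mean minimizes sum of squares
        assert recon.score["trait"] == pytest.approx(6.0)  # 1 + 1 + 4

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_numeric_optimizer_on_balanced_tree(self, balanced4_tree, weighted):
        tipvals = {"a": 0.0, "b": 2.0, "c": 5.0, "d": 9.0}
        recon = squared_change_parsimony(balanced4_tree, tipvals, weighted=weighted)

        nodes = list(balanced4_tree.tree.preorder_node_iter())
        internal = [n for n in nodes if not n.is_leaf()]

        def score(x):
            vals = {}
            for n in nodes:
                if n.is_leaf():
                    vals[n] = tipvals[n.taxon.label]
            for n, v in zip(internal, x):
                vals[n] = v
            s = 0.0
            for n in nodes:
                if n.parent_node is not None:
                    w = 1.0 / n.edge.length if weighted else 1.0
                    s += w * (vals[n.parent_node] - vals[n]) ** 2
            return s

        res = minimize(score, np.zeros(len(internal)), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        got = [float(recon.values.loc[i, "trait"])
               for i, lab in recon.node_labels.items()
               if len(recon.bipartitions[i]) > 1]
        # match values (internal order follows preorder in both cases)
        assert np.allclose(sorted(got), sorted(res.x), atol=1e-6)
        assert recon.score["trait"] == pytest.approx(score(res.x), abs=1e-8)

    def test_solution_is_a_strict_minimum(self):
        rng = np.random.default_rng(0)
        tree = Chronogram.from_newick("((a:1.5,b:1.5):1,(c:0.5,d:0.5):2);")
        tips = {t: float(rng.normal()) for t in "abcd"}
        recon = squared_change_parsimony(tree, tips)

        internal_ids = [i for i in recon.values.index if len(recon.bipartitions[i]) > 1]

        def total(vals):
            nodes = list(tree.tree.preorder_node_iter())
            s = 0.0
            lookup = dict(zip(internal_ids, vals))
            row = {n: i for i, n in enumerate(nodes)}
            node_val = {}
            k = 0
            for i, n in enumerate(nodes):
                if n.is_leaf():
                    node_val[n] = tips[n.taxon.label]
                else:
                    node_val[n] = lookup[internal_ids[k]]
                    k += 1
            for n in nodes:
                if n.parent_node is not None:
                    s += (node_val[n.parent_node] - node_val[n]) ** 2
            return s

        base = [float(recon.values.loc[i, "trait"]) for i in internal_ids]
        s0 = total(base)
        for j in range(len(base)):
            for delta in (0.01, -0.01):
                pert = list(base)
                pert[j] += delta
                assert total(pert) > s0

    def test_unweighted_invariant_to_edge_rescaling_weighted_not(self):
        t1 = Chronogram.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = Chronogram.from_newick("((a:10,b:10):10,(c:10,d:10):10);")
        tips = {"a": 0.0, "b": 1.0, "c": 4.0, "d": 9.0}
        u1 = squared_change_parsimony(t1, tips).values["trait"]
        u2 = squared_change_parsimony(t2, tips).values["trait"]
        assert np.allclose(u1, u2)
        t3 = Chronogram.from_newick("((a:1,b:1):5,(c:5,d:5):1);")
        w_uniform = squared_change_parsimony(t1, tips, weighted=True).values["trait"]
        w_skew = squared_change_parsimony(t3, tips, weighted=True).values["trait"]
        assert not np.allclose(w_uniform, w_skew)

    def test_missing_tip_named_in_error(self, cherry_tree):
        with pytest.raises(ValueError, match="y"):
            squared_change_parsimony(cherry_tree, {"x": 1.0})


class TestAncestralEnvelopes:
    def _recon(self, tree, stats):
        return reconstruct_niche_summaries(tree, stats)

    def test_identical_tip_envelopes_reconstruct_identically(self, balanced4_tree):
        stats = pd.DataFrame(
            {("Bio1", "min"): {n: 10.0 for n in "abcd"},
             ("Bio1", "max"): {n: 20.0 for n in "abcd"}})
        stats.columns = pd.MultiIndex.from_tuples(stats.columns,
                                                  names=["variable", "statistic"])
        recon = self._recon(balanced4_tree, stats)
        envs = ancestral_envelopes(recon)
        for env in envs.values():
            assert env.lower["Bio1"] == 10.0 and env.upper["Bio1"] == 20.0

    def test_cherry_root_min_is_mean_of_tip_mins(self, cherry_tree):
        stats = pd.DataFrame(
            {("Bio1", "min"): {"x": 0.0, "y": 8.0},
             ("Bio1", "max"): {"x": 20.0, "y": 30.0}})
        stats.columns = pd.MultiIndex.from_tuples(stats.columns,
                                                  names=["variable", "statistic"])
        recon = self._recon(cherry_tree, stats)
        root = recon.at_node({"x", "y"})
        assert root["Bio1:min"] == pytest.approx(4.0)
        assert root["Bio1:max"] == pytest.approx(25.0)

    def test_crossed_reconstruction_is_flagged_and_swapped(self, cherry_tree):
        # adversarial input: tip "min" above tip "max" forces a crossed node
        stats = pd.DataFrame(
            {("Bio1", "min"): {"x": 50.0, "y": 60.0},
             ("Bio1", "max"): {"x": 0.0, "y": 10.0}})
        stats.columns = pd.MultiIndex.from_tuples(stats.columns,
                                                  names=["variable", "statistic"])
        recon = self._recon(cherry_tree, stats)
        with pytest.warns(UserWarning, match="swapping"):
            envs = ancestral_envelopes(recon)
        for env in envs.values():
            assert env.lower["Bio1"] <= env.upper["Bio1"]


class TestSupportFilter:
    def test_threshold_excludes_weak_nodes(self):
        tree = Chronogram.from_newick("((a:1,b:1)[&pp=0.76]:1,(c:1,d:1)[&pp=1.0]:1)[&pp=1.0];")
        kept = filter_by_support(tree, 0.95)
        bips = {Chronogram.bipartition(n) for n in kept}
        assert frozenset({"c", "d"}) in bips
        assert frozenset({"a", "b"}) not in bips

    def test_zero_threshold_keeps_all_internal_nodes(self):
        tree = Chronogram.from_newick("((a:1,b:1)[&pp=0.3]:1,(c:1,d:1)[&pp=0.5]:1)[&pp=1.0];")
        assert len(filter_by_support(tree, 0.0)) == 3


class TestProjection:
    def _stack(self):
        ext = (0.0, 4.0, 0.0, 1.0)
        vals = np.array([[1.0, 2.0, 3.0, 4.0]])
        return RasterStack([RasterLayer("Bio1", vals, ext, 1.0)])

    def test_full_range_envelope_gives_all_ones(self):
        surf = project_ancestral(EnvelopeModel({"Bio1": 0.0}, {"Bio1": 10.0}), self._stack())
        np.testing.assert_allclose(surf.values, 1.0)

    def test_empty_intersection_envelope_gives_all_zeros(self):
        surf = project_ancestral(EnvelopeModel({"Bio1": 50.0}, {"Bio1": 60.0}), self._stack())
        np.testing.assert_allclose(surf.values, 0.0)

    def test_surface_is_region_indicator(self):
        surf = project_ancestral(EnvelopeModel({"Bio1": 2.0}, {"Bio1": 3.0}), self._stack())
        np.testing.assert_allclose(surf.values, [[0.0, 1.0, 1.0, 0.0]])

    def test_missing_variable_rejected(self):
        with pytest.raises(ValueError, match="Bio9"):
            project_ancestral(EnvelopeModel({"Bio9": 0.0}, {"Bio9": 1.0}), self._stack())
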