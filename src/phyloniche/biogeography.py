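"""Ancestral range estimation: DEC likelihood and DIVA-style event parsimony.

Geographic ranges are non-empty subsets of a fixed set of areas, capped at
``max_areas`` (the study convention: 7 areas A-G, cap 2, hence 28 range
states).  Two reconstruction methods are provided.

**DEC** (dispersal-extinction-cladogenesis) is a continuous-time Markov model
on range states.  Anagenetic events along branches are area gains (rate d
per source area, all dispersal multipliers 1) and area losses (rate e per
occupied area); cladogenesis at nodes partitions a widespread range between
daughters by vicariance or subset (peripheral-isolate) sympatry, all
scenarios equally weighted; a singleton range is inherited identically by
both daughters.  Branch transition probabilities come from the matrix
exponential of the anagenetic generator; the likelihood is computed by
post-order pruning with root states equally weighted.  :class:`DECModel` follows the
model/results idiom: ``fit()`` maximizes the likelihood over (d, e) from
fixed multistarts and returns a :class:`DECResults` with rates, per-node
marginal ranges and a summary table.

**DIVA** parsimony assigns ranges minimizing event costs: each area gained
(dispersal) or lost (extinction) along a branch costs 1; vicariance and
duplication at nodes are free; at cladogenesis the ancestral range is split
into two disjoint non-empty subsets (duplication for singletons).  An exact
min-plus dynamic program over the range state space returns *all*
minimum-cost ranges per node.  The S-DIVA style summary runs the parsimony
on every tree of a posterior sample and reports per-node relative
frequencies of ranges over trees containing that node's bipartition,
weighting co-optimal solutions within a tree equally.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import Chronogram

__all__ = [
    "RangeStateSpace",
    "build_state_space",
    "DECModel",
    "DECResults",
    "dec_loglik",
    "dec_fit",
    "dec_marginal_ranges",
    "diva_parsimony",
    "summarize_over_trees",
    "plan_tree_resampling",
    "read_tip_ranges",
    "AncestralRangeSummary",
]


# ---------------------------------------------------------------------------
# Range state space


class RangeStateSpace:
    """Ordered enumeration of allowed ranges: non-empty subsets up to a cap.

    States are frozensets of single-letter area codes, ordered by size then
    lexicographically, so the order is deterministic; the empty range is not
    a state.
    """

    def __init__(self, areas: Sequence[str], max_areas: int = 2):
        areas = list(areas)
        if not 1 <= max_areas <= len(areas):
            raise ValueError("need 1 <= max_areas <= number of areas")
        self.areas = areas
        self.max_areas = max_areas
        states = []
        for k in range(1, max_areas + 1):
            for combo in itertools.combinations(sorted(areas), k):
                states.append(frozenset(combo))
        self.states: list[frozenset] = states
        self.index: dict[frozenset, int] = {s: i for i, s in enumerate(states)}

    def __len__(self) -> int:
        return len(self.states)

    def label(self, state: frozenset) -> str:
        return "".join(sorted(state))

    def parse(self, text: str) -> frozenset:
        s = frozenset(text.strip())
        unknown = s - set(self.areas)
        if unknown:
            raise ValueError(f"unknown area code(s) {sorted(unknown)} in {text!r}")
        if not s:
            raise ValueError("empty range")
        if len(s) > self.max_areas:
            raise ValueError(f"range {text!r} exceeds the {self.max_areas}-area cap")
        return s


def build_state_space(areas: Sequence[str], max_areas: int = 2) -> RangeStateSpace:
    """All non-empty area subsets of size <= ``max_areas``, in fixed order."""
    return RangeStateSpace(areas, max_areas)


# ---------------------------------------------------------------------------
# Cladogenetic scenarios (shared by DEC and the simulator)


def cladogenetic_scenarios(state: frozenset) -> list[tuple[frozenset, frozenset]]:
    """Equally weighted daughter-range pairs for an ancestral range.

    Singleton: identical inheritance.  Widespread: vicariance (singleton vs
    the rest, both assignments) and subset sympatry (full range vs each
    singleton, both assignments).
    """
    if len(state) == 1:
        return [(state, state)]
    out: list[tuple[frozenset, frozenset]] = []
    seen: set[tuple[frozenset, frozenset]] = set()
    for a in sorted(state):
        x = frozenset({a})
        rest = state - x
        for pair in ((x, rest), (rest, x), (x, state), (state, x)):
            if pair not in seen:  # a two-area range yields each vicariance once
                seen.add(pair)
                out.append(pair)
    return out


# ---------------------------------------------------------------------------
# DEC generator and likelihood


def _dec_generator(space: RangeStateSpace, d: float, e: float) -> np.ndarray:
    """Anagenetic rate matrix over the allowed (non-empty) range states.

    Conservative generator: rows sum to 0, so transition matrices are
    stochastic over any duration.  Local extinction removes one area from a
    widespread range; a singleton range cannot be lost anagenetically (the
    lineage survives to be observed), so there is no absorbing null state.
    """
    n = len(space)
    Q = np.zeros((n, n))
    for i, s in enumerate(space.states):
        # dispersal: gain area a at rate d per source area (multipliers all 1)
        if len(s) < space.max_areas:
            for a in space.areas:
                if a not in s:
                    t = s | {a}
                    Q[i, space.index[t]] += d * len(s)
        # extinction: lose one occupied area at rate e each (widespread only)
        if len(s) > 1:
            for a in s:
                Q[i, space.index[s - {a}]] += e
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q


@dataclass
class DECModel:
    """DEC model specification bound to a tree and tip ranges.

    Parameters
    ----------
    tree : Chronogram
    tip_ranges : mapping of tip label -> area-set (frozenset or "EF"-style
        string)
    space : RangeStateSpace, optional
        Defaults to the 7-area, 2-cap study state space restricted to the
        areas appearing in the tip data plus any supplied explicitly.
    d, e : float
        Dispersal and extinction rates (events per Ma) used by
        :meth:`loglik` / :meth:`marginal_ranges`; :meth:`fit` estimates them.
    """

    tree: Chronogram
    tip_ranges: Mapping[str, frozenset | str]
    space: RangeStateSpace | None = None
    d: float = 0.1
    e: float = 0.1

    def __post_init__(self):
        if self.space is None:
            areas = sorted({a for r in self.tip_ranges.values() for a in r})
            self.space = RangeStateSpace(areas, max_areas=min(2, len(areas)))
        self._tips: dict[str, frozenset] = {}
        for tip, r in self.tip_ranges.items():
            s = self.space.parse(r) if isinstance(r, str) else frozenset(r)
            if len(s) > self.space.max_areas:
                raise ValueError(f"tip {tip!r} range exceeds the {self.space.max_areas}-area cap")
            if not s:
                raise ValueError(f"tip {tip!r} has an empty range")
            self._tips[tip] = s
        missing = [t for t in self.tree.taxa if t not in self._tips]
        if missing:
            raise ValueError(f"missing tip range(s) for: {missing}")

    # -- pruning machinery -------------------------------------------------

    def _edge_transition(self, Q: np.ndarray, duration: float) -> np.ndarray:
        P = expm(Q * duration)
        P = np.clip(P, 0.0, None)
        return P

    def _node_partials(self, d: float, e: float):
        """Post-order conditional likelihoods.

        Returns (nodes, L_node, L_top, P_edge) where for each node ``L_node``
        is the likelihood at the node immediately before cladogenesis (after
        combining daughters at internal nodes) and ``L_top`` the likelihood
        at the top (rootward end) of the node's subtending edge.
        """
        space = self.space
        n = len(space)
        Q = _dec_generator(space, d, e)
        nodes = list(self.tree.tree.postorder_node_iter())
        L_node: dict = {}
        L_top: dict = {}
        scen = {s: cladogenetic_scenarios(s) for s in space.states}
        for node in nodes:
            if node.is_leaf():
                vec = np.zeros(n)
                vec[space.index[self._tips[node.taxon.label]]] = 1.0
            else:
                kids = node.child_nodes()
                if len(kids) != 2:
                    raise ValueError("DEC requires a strictly bifurcating tree")
                la, lb = L_top[kids[0]], L_top[kids[1]]
                vec = np.zeros(n)
                for i, s in enumerate(space.states):
                    pairs = scen[s]
                    acc = 0.0
                    for x, y in pairs:
                        acc += la[space.index[x]] * lb[space.index[y]]
                    vec[i] = acc / len(pairs)
            L_node[node] = vec
            if node.parent_node is not None:
                dur = node.edge.length or 0.0
                P = self._edge_transition(Q, dur)
                # top-of-edge likelihood: P[i, j] = Pr(j at node | i at top)
                L_top[node] = P @ vec
        return nodes, L_node, L_top, Q

    def loglik(self, d: float | None = None, e: float | None = None) -> float:
        """DEC log-likelihood, root states equally weighted.

        Root states carry equal weight 1, so a system with a single possible
        history (one area, or d = e = 0 with identical singleton tips) scores
        log-likelihood exactly 0.
        """
        d = self.d if d is None else d
        e = self.e if e is None else e
        nodes, L_node, _, _ = self._node_partials(d, e)
        root = nodes[-1]
        like = float(np.sum(L_node[root]))
        if like <= 0.0:
            return -math.inf
        return math.log(like)

    def marginal_ranges(self, d: float | None = None, e: float | None = None) -> "AncestralRangeSummary":
        """Per-node marginal range probabilities immediately before cladogenesis.

        Marginal(node = S) is proportional to inside(node, S) x outside(node,
        S), where inside is the pruning partial (daughters already combined
        over cladogenetic scenarios) and outside carries the root prior, the
        branch above the node and every other subtree.  Normalized to % per
        node.
        """
        d = self.d if d is None else d
        e = self.e if e is None else e
        space = self.space
        n = len(space)
        nodes, L_node, L_top, Q = self._node_partials(d, e)
        root = nodes[-1]
        scen = {s: cladogenetic_scenarios(s) for s in space.states}
        prior = np.full(n, 1.0 / n)
        outside: dict = {root: prior.copy()}
        for node in reversed(nodes):  # preorder
            if node.is_leaf():
                continue
            kids = node.child_nodes()
            O_node = outside[node]
            for child, sister in ((kids[0], kids[1]), (kids[1], kids[0])):
                ls = L_top[sister]
                # outside at the top of the child's edge, per child state x
                O_top = np.zeros(n)
                for i, s in enumerate(space.states):
                    if O_node[i] == 0.0:
                        continue
                    pairs = scen[s]
                    w = O_node[i] / len(pairs)
                    first = child is kids[0]
                    for x, y in pairs:
                        if first:
                            O_top[space.index[x]] += w * ls[space.index[y]]
                        else:
                            O_top[space.index[y]] += w * ls[space.index[x]]
                dur = child.edge.length or 0.0
                P = self._edge_transition(Q, dur)
                outside[child] = O_top @ P
        rows = {}
        for node in nodes:
            if node.is_leaf():
                continue
            post = outside[node] * L_node[node]
            total = post.sum()
            if total <= 0:
                continue
            freq = post / total * 100.0
            bip = Chronogram.bipartition(node)
            rows[bip] = {space.label(s): float(freq[i])
                         for i, s in enumerate(space.states) if freq[i] > 1e-12}
        return AncestralRangeSummary(frequencies=rows, method="DEC")

    # -- statsmodels-style fitting ----------------------------------------

    def fit(self, bounds: tuple[float, float] = (1e-6, 10.0)) -> "DECResults":
        """Maximize the likelihood over (d, e) from fixed multistarts.

        Deterministic: L-BFGS-B on log-rates from a fixed 3x3 start grid.
        Warns when the tips carry no dispersal signal (all ranges equal).
        """
        import warnings

        if len({self._tips[t] for t in self.tree.taxa}) < 2:
            warnings.warn("all tip ranges identical: d is weakly identified "
                          "and will head to its lower bound")
        lo, hi = bounds

        def nll(theta):
            dd, ee = np.exp(theta)
            ll = self.loglik(dd, ee)
            return 1e10 if not np.isfinite(ll) else -ll

        starts = [(a, b) for a in (0.01, 0.1, 1.0) for b in (0.01, 0.1, 1.0)]
        best = None
        for d0, e0 in starts:
            res = minimize(nll, np.log([d0, e0]), method="L-BFGS-B",
                           bounds=[(math.log(lo), math.log(hi))] * 2)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"DEC optimization failed: {best}")
        d_hat, e_hat = np.exp(best.x)
        return DECResults(model=self, d=float(d_hat), e=float(e_hat),
                          loglik=-float(best.fun), n_starts=len(starts))


@dataclass
class DECResults:
    """Fitted DEC rates with access to per-node marginal ranges."""

    model: DECModel
    d: float
    e: float
    loglik: float
    n_starts: int

    def marginal_ranges(self) -> "AncestralRangeSummary":
        return self.model.marginal_ranges(self.d, self.e)

    def summary(self) -> str:
        lines = [
            "DEC ancestral range model",
            f"  tips: {len(self.model.tree)}   areas: {''.join(self.model.space.areas)}"
            f"   states: {len(self.model.space)} (cap {self.model.space.max_areas})",
            f"  dispersal rate d: {self.d:.6g} events/Ma",
            f"  extinction rate e: {self.e:.6g} events/Ma",
            f"  log-likelihood: {self.loglik:.6f}",
        ]
        return "\n".join(lines)


def dec_loglik(tree: Chronogram, tips: Mapping[str, frozenset | str],
               d: float, e: float, space: RangeStateSpace | None = None) -> float:
    return DECModel(tree, tips, space=space).loglik(d, e)


def dec_fit(tree: Chronogram, tips: Mapping[str, frozenset | str],
            space: RangeStateSpace | None = None) -> DECResults:
    return DECModel(tree, tips, space=space).fit()


def dec_marginal_ranges(tree: Chronogram, tips: Mapping[str, frozenset | str],
                        d: float, e: float,
                        space: RangeStateSpace | None = None) -> "AncestralRangeSummary":
    return DECModel(tree, tips, space=space).marginal_ranges(d, e)


# ---------------------------------------------------------------------------
# DIVA-style parsimony


def _anagenetic_cost(parent: frozenset, child: frozenset) -> int:
    """Dispersal (+1 per area gained) plus extinction (+1 per area lost)."""
    return len(child - parent) + len(parent - child)


def _diva_splits(state: frozenset) -> list[tuple[frozenset, frozenset]]:
    """Zero-cost cladogenetic splits: disjoint bipartitions (duplication for
    singletons)."""
    if len(state) == 1:
        return [(state, state)]
    out = []
    items = sorted(state)
    # all ordered pairs (X, S-X) over non-empty proper subsets X
    for r in range(1, len(items)):
        for combo in itertools.combinations(items, r):
            x = frozenset(combo)
            out.append((x, state - x))
    return out


def diva_parsimony(tree: Chronogram, tips: Mapping[str, frozenset | str],
                   max_areas: int = 2,
                   space: RangeStateSpace | None = None) -> dict[frozenset, set[frozenset]]:
    """All minimum-cost ancestral ranges per internal node (exact DP).

    Returns a mapping from each internal node's descendant-tip bipartition to
    the set of range states attained in at least one globally optimal
    reconstruction.
    """
    if space is None:
        areas = sorted({a for r in tips.values() for a in r})
        space = RangeStateSpace(areas, max_areas=min(max_areas, len(areas)))
    tips_parsed = {t: (space.parse(r) if isinstance(r, str) else frozenset(r))
                   for t, r in tips.items()}
    n = len(space)
    INF = float("inf")
    nodes = list(tree.tree.postorder_node_iter())

    # inside[node][i]: min cost of the subtree when the node's range,
    # immediately before cladogenesis, is state i
    inside: dict = {}
    # down[node][j]: min cost of the node's subtree plus its subtending edge
    # when the range at the TOP of that edge (just after the parent's
    # cladogenesis assigned it) is state j
    down: dict = {}
    cost_edge = np.zeros((n, n))
    for i, s in enumerate(space.states):
        for j, t in enumerate(space.states):
            cost_edge[i, j] = _anagenetic_cost(s, t)
    splits = {s: _diva_splits(s) for s in space.states}

    for node in nodes:
        if node.is_leaf():
            vec = np.full(n, INF)
            vec[space.index[tips_parsed[node.taxon.label]]] = 0.0
        else:
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ValueError("DIVA parsimony requires a strictly bifurcating tree")
            da, db = down[kids[0]], down[kids[1]]
            vec = np.full(n, INF)
            for i, s in enumerate(space.states):
                best = INF
                for x, y in splits[s]:
                    ix, iy = space.index.get(x), space.index.get(y)
                    if ix is None or iy is None:
                        continue  # split piece exceeds the cap
                    c = da[ix] + db[iy]
                    if c < best:
                        best = c
                vec[i] = best
        inside[node] = vec
        if node.parent_node is not None:
            down[node] = np.min(cost_edge + vec[None, :], axis=1)

    root = nodes[-1]
    total = float(np.min(inside[root]))

    # outside[node][i]: min cost of everything outside the node's subtree,
    # given the node (before its own cladogenesis) is in state i
    outside: dict = {root: np.zeros(n)}
    for node in reversed(nodes):
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        O = outside[node]
        # cost to pass from node-state i through its cladogenesis giving the
        # focal child top-state x, with the sister's best completion
        for child, sister in ((kids[0], kids[1]), (kids[1], kids[0])):
            first = child is kids[0]
            O_top = np.full(n, INF)
            ds = down[sister]
            for i, s in enumerate(space.states):
                if O[i] == INF:
                    continue
                for x, y in splits[s]:
                    if first:
                        cx, cy = x, y
                    else:
                        cx, cy = y, x
                    ix, iy = space.index.get(cx), space.index.get(cy)
                    if ix is None or iy is None:
                        continue
                    c = O[i] + ds[iy]
                    if c < O_top[ix]:
                        O_top[ix] = c
            # then along the child's edge: child-state j costs edge change
            outside[child] = np.min(O_top[:, None] + cost_edge, axis=0)

    result: dict[frozenset, set[frozenset]] = {}
    for node in nodes:
        if node.is_leaf():
            continue
        tot = inside[node] + outside[node]
        best = tot.min()
        assert np.isclose(best, total), "inside/outside decomposition mismatch"
        opt = {space.states[i] for i in range(n) if np.isclose(tot[i], best)}
        result[Chronogram.bipartition(node)] = opt
    return result


# ---------------------------------------------------------------------------
# Summaries over a posterior tree sample


@dataclass
class AncestralRangeSummary:
    """Per-node relative frequencies (%) of reconstructed ranges.

    Nodes are keyed by their descendant-tip bipartition so summaries can be
    mapped onto a reference (MCC) tree regardless of node indexing.
    ``support`` records, per node, how many trees of a sample contained the
    bipartition (1 for single-tree summaries).
    """

    frequencies: dict[frozenset, dict[str, float]]
    method: str
    support: dict[frozenset, int] = field(default_factory=dict)

    def at(self, tips: Iterable[str]) -> dict[str, float]:
        key = frozenset(tips)
        if key not in self.frequencies:
            raise KeyError(f"no node with descendant tips {sorted(key)}")
        return self.frequencies[key]

    def to_frame(self, reference: Chronogram | None = None) -> pd.DataFrame:
        rows = []
        for bip, freqs in self.frequencies.items():
            label = "|".join(sorted(bip))
            if reference is not None:
                node = reference.node_by_bipartition(bip)
                if node is not None and node.label:
                    label = node.label
            for rng, pct in sorted(freqs.items(), key=lambda kv: -kv[1]):
                rows.append({"node": label, "method": self.method,
                             "range": rng, "frequency_pct": pct})
        return pd.DataFrame(rows, columns=["node", "method", "range", "frequency_pct"])


def summarize_over_trees(trees: Sequence[Chronogram],
                         reconstructions: Sequence[dict[frozenset, set[frozenset]]],
                         reference: Chronogram,
                         method: str = "S-DIVA") -> AncestralRangeSummary:
    """S-DIVA style frequency summary of per-tree reconstructions.

    For each internal node of the reference (MCC) tree, frequencies are taken
    over the trees whose topology contains that node's bipartition,
    weighting co-optimal within-tree solutions equally.  A bipartition found
    in no tree is reported with an empty frequency map.
    """
    if len(trees) != len(reconstructions):
        raise ValueError("need one reconstruction per tree")
    freqs: dict[frozenset, dict[str, float]] = {}
    support: dict[frozenset, int] = {}
    for node in reference.internal_nodes():
        bip = Chronogram.bipartition(node)
        weights: dict[str, float] = {}
        count = 0
        for recon in reconstructions:
            if bip not in recon:
                continue
            count += 1
            opts = recon[bip]
            for s in opts:
                lbl = "".join(sorted(s))
                weights[lbl] = weights.get(lbl, 0.0) + 1.0 / len(opts)
        if count:
            freqs[bip] = {k: v / count * 100.0 for k, v in weights.items()}
        else:
            freqs[bip] = {}
        support[bip] = count
    return AncestralRangeSummary(frequencies=freqs, method=method, support=support)


def plan_tree_resampling(runs: int, generations: int, sample_every: int,
                         burnin_frac: float, resample_every: int) -> int:
    """Retained tree count when thinning post-burn-in MCMC samples.

    Per run: floor((1 − burnin_frac) × generations / resample_every); total
    over runs.  ``resample_every`` must be a multiple of ``sample_every``.
    """
    if resample_every % sample_every != 0:
        raise ValueError("resample_every must be a multiple of sample_every")
    if not 0.0 <= burnin_frac < 1.0:
        raise ValueError("burnin_frac must be in [0, 1)")
    per_run = math.floor((1.0 - burnin_frac) * generations / resample_every)
    return runs * per_run


def read_tip_ranges(path) -> dict[str, str]:
    """Read a 'species,areas' CSV with areas as concatenated letters (e.g. EF)."""
    df = pd.read_csv(path)
    return {str(r.species): str(r.areas) for r in df.itertuples(index=False)}
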