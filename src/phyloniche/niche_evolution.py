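"""Ancestral niche reconstruction on a chronogram.

Per-species climate summaries (mean, sd, min, max of each selected variable
over the species' localities) are treated as continuous characters and
assigned to internal nodes by squared-change parsimony: internal values
minimize the sum over edges of squared parent-child differences (optionally
dividing each term by the edge duration).  The objective is a strictly
convex quadratic, so the minimizer is the unique solution of a linear
system — solved directly, no iteration, no seed.  Each character is
optimized independently.

Reconstructed per-variable [min, max] ranges at a node define an ancestral
BIOCLIM envelope, which can be projected onto present-day climate layers;
projection is usually restricted to nodes whose posterior support reaches a
threshold (default PP >= 0.95).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import EnvelopeModel, SuitabilitySurface
from .geodata import RasterStack
from .trees import Chronogram

__all__ = [
    "Chronogram",
    "ContinuousReconstruction",
    "tip_statistics",
    "squared_change_parsimony",
    "ancestral_envelopes",
    "filter_by_support",
    "project_ancestral",
]

STATISTICS = ("mean", "sd", "min", "max")


def tip_statistics(env: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Per-species (mean, sd, min, max) of each variable over its localities.

    The sd is the sample standard deviation (ddof=1); a single-locality
    species gets sd 0.  Returns a frame indexed by species with a
    (variable, statistic) column MultiIndex.
    """
    if variables is None:
        variables = [c for c in env.columns if c not in ("species", "lon", "lat")]
    g = env.groupby("species")[variables]
    parts = {
        "mean": g.mean(),
        "sd": g.std(ddof=1).fillna(0.0),
        "min": g.min(),
        "max": g.max(),
    }
    out = pd.concat(parts, axis=1)  # (statistic, variable) columns
    out.columns = pd.MultiIndex.from_tuples(
        [(var, stat) for stat, var in out.columns], names=["variable", "statistic"]
    )
    return out.sort_index(axis=1)


@dataclass
class ContinuousReconstruction:
    """Squared-change parsimony solution for one or more characters.

    ``values`` holds one column per character and one row per node (tips and
    internal nodes, keyed by node id); tip rows equal the observed inputs.
    ``score`` is the minimized sum of (weighted) squared changes per
    character.  ``node_labels`` maps node ids to human-readable labels and
    ``bipartitions`` to descendant tip sets.
    """

    values: pd.DataFrame
    score: pd.Series
    weighted: bool
    node_labels: dict[int, str]
    bipartitions: dict[int, frozenset]

    def at_node(self, tips: frozenset | set) -> pd.Series:
        want = frozenset(tips)
        for nid, bip in self.bipartitions.items():
            if bip == want:
                return self.values.loc[nid]
        raise KeyError(f"no node with descendant tips {sorted(want)}")

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "node", [self.node_labels[i] for i in df.index])
        return df


def squared_change_parsimony(
    tree: Chronogram, tip_values: pd.DataFrame | dict, weighted: bool = False
) -> ContinuousReconstruction:
    """Minimize the sum of squared changes along edges over internal values.

    ``tip_values``: DataFrame indexed by tip label (columns = characters) or
    a flat ``{tip: value}`` mapping for a single character.  When
    ``weighted``, each squared change is divided by the edge duration (all
    durations must then be positive).  The unweighted solution is invariant
    to rescaling edge durations; the weighted one is not.
    """
    if isinstance(tip_values, dict):
        tip_values = pd.DataFrame({"trait": tip_values})
    missing = [t for t in tree.taxa if t not in tip_values.index]
    if missing:
        raise ValueError(f"missing tip value(s) for: {missing}")

    nodes = list(tree.tree.preorder_node_iter())
    nid = {node: i for i, node in enumerate(nodes)}
    leaves = [n for n in nodes if n.is_leaf()]
    internal = [n for n in nodes if not n.is_leaf()]
    int_index = {node: k for k, node in enumerate(internal)}

    edges = []
    for node in nodes:
        if node.parent_node is not None:
            dur = node.edge.length if node.edge.length is not None else 0.0
            if weighted:
                if not dur > 0:
                    raise ValueError("weighted reconstruction needs positive edge durations")
                w = 1.0 / dur
            else:
                w = 1.0
            edges.append((node.parent_node, node, w))

    n_int = len(internal)
    A = np.zeros((n_int, n_int))
    labels = list(tip_values.columns)
    B = np.zeros((n_int, len(labels)))
    tipvals = tip_values.loc[[l.taxon.label for l in leaves]].to_numpy(float)
    leaf_row = {node: r for r, node in enumerate(leaves)}
    for parent, child, w in edges:
        pi = int_index[parent]
        A[pi, pi] += w
        if child.is_leaf():
            B[pi] += w * tipvals[leaf_row[child]]
        else:
            ci = int_index[child]
            A[ci, ci] += w
            A[pi, ci] -= w
            A[ci, pi] -= w
    x = np.linalg.solve(A, B)

    all_vals = np.zeros((len(nodes), len(labels)))
    for node in nodes:
        if node.is_leaf():
            all_vals[nid[node]] = tipvals[leaf_row[node]]
        else:
            all_vals[nid[node]] = x[int_index[node]]
    score = np.zeros(len(labels))
    for parent, child, w in edges:
        score += w * (all_vals[nid[parent]] - all_vals[nid[child]]) ** 2

    node_labels = {}
    bips = {}
    for node in nodes:
        i = nid[node]
        if node.is_leaf():
            node_labels[i] = node.taxon.label
        else:
            node_labels[i] = node.label or f"node{i}"
        bips[i] = Chronogram.bipartition(node)
    values = pd.DataFrame(all_vals, columns=tip_values.columns)
    return ContinuousReconstruction(values=values, score=pd.Series(score, index=labels),
                                    weighted=weighted, node_labels=node_labels,
                                    bipartitions=bips)


def reconstruct_niche_summaries(
    tree: Chronogram, tip_stats: pd.DataFrame, weighted: bool = False
) -> ContinuousReconstruction:
    """Squared-change parsimony over every (variable, statistic) character."""
    flat = tip_stats.copy()
    flat.columns = [f"{v}:{s}" for v, s in tip_stats.columns]
    return squared_change_parsimony(tree, flat, weighted=weighted)


def ancestral_envelopes(recon: ContinuousReconstruction, nodes=None) -> dict[int, EnvelopeModel]:
    """Binary BIOCLIM envelopes from reconstructed per-variable min/max.

    ``recon`` must come from :func:`reconstruct_niche_summaries` (columns
    named ``variable:statistic``).  A node where some reconstructed minimum
    exceeds the maximum is flagged with a warning and the two values are
    swapped.  ``nodes`` restricts output to the given node ids (default: all
    internal nodes).
    """
    cols = recon.values.columns
    variables = sorted({c.split(":")[0] for c in cols if c.endswith(":min")})
    internal_ids = [i for i, lab in recon.node_labels.items()
                    if len(recon.bipartitions[i]) > 1]
    ids = internal_ids if nodes is None else list(nodes)
    out: dict[int, EnvelopeModel] = {}
    for i in ids:
        lower, upper = {}, {}
        for v in variables:
            lo = float(recon.values.loc[i, f"{v}:min"])
            hi = float(recon.values.loc[i, f"{v}:max"])
            if lo > hi:
                warnings.warn(
                    f"node {recon.node_labels[i]!r}, variable {v!r}: reconstructed "
                    f"min {lo:.4g} > max {hi:.4g}; swapping"
                )
                lo, hi = hi, lo
            lower[v], upper[v] = lo, hi
        out[i] = EnvelopeModel(lower=lower, upper=upper, mode="binary")
    return out


def filter_by_support(tree: Chronogram, threshold: float = 0.95):
    """Internal nodes whose posterior support reaches the threshold."""
    out = []
    for node in tree.internal_nodes():
        if node.pp is not None and node.pp >= threshold:
            out.append(node)
    return out


def project_ancestral(envelope: EnvelopeModel, stack: RasterStack,
                      label: str = "") -> SuitabilitySurface:
    """Project an ancestral envelope onto present-day climate layers."""
    return envelope.project(stack, label=label)
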