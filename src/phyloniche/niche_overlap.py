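"""Niche overlap statistics and ordination of climate variables.

Schoener's D and Warren's I compare two habitat-suitability surfaces after
each is normalized to sum 1 over the shared grid:

    D = 1 − ½ Σ_i |p_i − q_i|
    I = 1 − ½ Σ_i (√p_i − √q_i)²  =  1 − H²/2   (H: Hellinger distance)

Both run from 0 (disjoint niches) to 1 (identical niches).  Surfaces must
share one grid; models trained on different continents are first projected
onto a common extent.

The ordination is detrended correspondence analysis (DCA): correspondence
analysis by singular decomposition of the chi-square standardized table,
with higher axes detrended against axis 1 by segment-wise centering
(default 26 segments).  Environmental variables are min-shifted to 0 and
range-scaled to [0, 100] first, since correspondence analysis requires
non-negative data; Hill's rescaling is not applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import SuitabilitySurface

__all__ = [
    "NicheOverlapResult",
    "schoener_d",
    "warren_i",
    "pairwise_overlap",
    "genus_mean_overlap",
    "DCAOrdination",
    "dca",
]


@dataclass
class NicheOverlapResult:
    species_a: str
    species_b: str
    D: float
    I: float
    n_cells: int


def _shared_normalized(p: SuitabilitySurface, q: SuitabilitySurface) -> tuple[np.ndarray, np.ndarray, int]:
    if p.values.shape != q.values.shape or not np.allclose(p.extent, q.extent):
        raise ValueError("surfaces must share one grid (shape and extent)")
    valid = np.isfinite(p.values) & np.isfinite(q.values)
    pv = np.where(valid, p.values, 0.0).ravel()
    qv = np.where(valid, q.values, 0.0).ravel()
    if pv.sum() <= 0 or qv.sum() <= 0:
        raise ValueError("a surface sums to zero over the shared grid")
    return pv / pv.sum(), qv / qv.sum(), int(valid.sum())


def schoener_d(p: SuitabilitySurface, q: SuitabilitySurface) -> float:
    """Schoener's D = 1 − ½Σ|p−q| on normalized suitability surfaces."""
    pv, qv, _ = _shared_normalized(p, q)
    return float(1.0 - 0.5 * np.abs(pv - qv).sum())


def warren_i(p: SuitabilitySurface, q: SuitabilitySurface) -> float:
    """Warren's I = 1 − ½Σ(√p−√q)² (one minus half squared Hellinger distance)."""
    pv, qv, _ = _shared_normalized(p, q)
    return float(1.0 - 0.5 * ((np.sqrt(pv) - np.sqrt(qv)) ** 2).sum())


def pairwise_overlap(surfaces: dict[str, SuitabilitySurface]) -> list[NicheOverlapResult]:
    """All unordered pairs among the given per-species surfaces."""
    out = []
    for a, b in itertools.combinations(surfaces, 2):
        pv, qv, n = _shared_normalized(surfaces[a], surfaces[b])
        d = float(1.0 - 0.5 * np.abs(pv - qv).sum())
        i = float(1.0 - 0.5 * ((np.sqrt(pv) - np.sqrt(qv)) ** 2).sum())
        out.append(NicheOverlapResult(a, b, d, i, n))
    return out


def genus_mean_overlap(results: list[NicheOverlapResult]) -> tuple[float, float]:
    """Unweighted arithmetic means of D and I over within-genus pairs."""
    if not results:
        raise ValueError("need at least one species pair")
    return (float(np.mean([r.D for r in results])),
            float(np.mean([r.I for r in results])))


# ---------------------------------------------------------------------------
# Detrended correspondence analysis


@dataclass
class DCAOrdination:
    """Sample scores on the DCA axes.

    ``scores`` is (n_samples x n_axes); axis 1 is the plain CA axis, higher
    axes are detrended by segments against the running lower axis.  Gradient
    lengths are the score ranges per axis.  ``meta`` records the
    preprocessing applied to the input table.
    """

    scores: np.ndarray
    gradient_lengths: np.ndarray
    segments: int
    axes: int
    meta: dict


def _detrend_by_segments(axis: np.ndarray, against: np.ndarray, segments: int) -> np.ndarray:
    """Center ``axis`` within equal-width segments of ``against``."""
    lo, hi = against.min(), against.max()
    if hi == lo:
        return axis - axis.mean()
    edges = np.linspace(lo, hi, segments + 1)
    idx = np.clip(np.searchsorted(edges, against, side="right") - 1, 0, segments - 1)
    out = axis.astype(float).copy()
    for s in range(segments):
        m = idx == s
        if m.any():
            out[m] -= out[m].mean()
    return out


def dca(table: pd.DataFrame, segments: int = 26, axes: int = 2) -> DCAOrdination:
    """Detrended correspondence analysis of an environment table.

    Rows are samples (locality points), columns the selected environmental
    variables.  Variables are min-shifted and range-scaled to [0, 100];
    correspondence analysis row scores are taken in principal coordinates;
    axes beyond the first are detrended by segment-wise centering against
    axis 1.  With one segment, axis 2 is the plain CA axis 2 minus its mean.
    Rank-deficient tables yield fewer axes (logged in ``meta``).
    """
    X = table.to_numpy(float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(X).all():
        raise ValueError("table contains non-finite values")
    if segments < 1:
        raise ValueError("segments must be >= 1")
    # scale each variable to [0, 100]
    mins = X.min(axis=0)
    rng = X.max(axis=0) - mins
    keep = rng > 0
    Xs = (X[:, keep] - mins[keep]) / rng[keep] * 100.0
    if Xs.shape[1] == 0:
        raise ValueError("all variables are constant")
    total = Xs.sum()
    P = Xs / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero-mass sample row or variable column after scaling")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    tol = max(S.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank = int((sv > max(tol, 1e-12)).sum())
    n_axes = min(axes, rank)
    # principal-coordinate row scores
    F = (U[:, :n_axes] * sv[:n_axes]) / np.sqrt(r)[:, None]
    scores = F.copy()
    for k in range(1, n_axes):
        scores[:, k] = _detrend_by_segments(scores[:, k], scores[:, 0], segments)
    glen = scores.max(axis=0) - scores.min(axis=0) if scores.size else np.array([])
    meta = {
        "preprocessing": "per-variable min-shift and range-scale to [0, 100]",
        "hill_rescaling": False,
        "rank": rank,
        "requested_axes": axes,
        "returned_axes": n_axes,
    }
    return DCAOrdination(scores=scores, gradient_lengths=glen,
                         segments=segments, axes=n_axes, meta=meta)
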