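"""Extant-species niche models: presence-background maximum-entropy and BIOCLIM.

Two model families are provided:

* :class:`MaxentLikeModel` — an exponential-family presence-background model
  ``q(x) ∝ exp(w·f(x))`` over a finite background of climate cells, with
  linear and quadratic features, an L1 penalty, and a deterministic proximal
  gradient fit.  ``fit()`` returns a :class:`MaxentLikeResults` object that
  predicts raw and logistic-scale suitability and prints a summary table.
* :class:`EnvelopeModel` — the rectilinear BIOCLIM climate envelope defined by
  per-variable bounds, in a binary (inside/outside) or percentile mode.

Model discrimination is measured with the rank-based (Mann-Whitney) AUC,
ties counted one half; 0.5 is random, 1.0 perfect separation of presences
from background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geodata import RasterLayer, RasterStack

__all__ = [
    "MaxentLikeModel",
    "MaxentLikeResults",
    "EnvelopeModel",
    "fit_bioclim",
    "auc",
    "background_sample",
    "predict_logistic",
    "SuitabilitySurface",
    "jackknife_contributions",
]


# ---------------------------------------------------------------------------
# AUC


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC of presence vs background scores (ties count 0.5)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need at least one presence and one background score")
    pooled = np.concatenate([p, b])
    if np.allclose(pooled, pooled[0]):
        warnings.warn("all predictions identical; AUC undefined, returning 0.5")
        return 0.5
    ranks = rankdata(pooled)  # average ranks handle ties as 0.5
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


# ---------------------------------------------------------------------------
# Suitability surfaces


@dataclass
class SuitabilitySurface:
    """Per-cell habitat suitability aligned to a raster stack grid."""

    values: np.ndarray  # in [0, 1], NaN where any input layer is nodata
    extent: tuple[float, float, float, float]
    cell_size: float
    label: str = ""
    scale: str = "logistic"  # raw | logistic | envelope

    def __post_init__(self):
        v = self.values[np.isfinite(self.values)]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")

    def as_layer(self, nodata: float = -9999.0) -> RasterLayer:
        vals = np.where(np.isfinite(self.values), self.values, nodata)
        return RasterLayer(self.label or "suitability", vals, self.extent,
                           self.cell_size, nodata)

    def normalized(self) -> np.ndarray:
        """Values rescaled to sum 1 over valid cells (for overlap statistics)."""
        v = np.where(np.isfinite(self.values), self.values, 0.0)
        s = v.sum()
        if s <= 0:
            raise ValueError("surface sums to zero; cannot normalize")
        return v / s


def background_sample(stack: RasterStack, variables: Sequence[str] | None = None,
                      n_max: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Background climate sample: all jointly-valid cells, thinned to ``n_max``.

    Follows the common presence-background default of at most 10,000
    background cells, sampled without replacement under a seed when the
    valid-cell count exceeds that.
    """
    tbl = stack.table(variables)
    if len(tbl) > n_max:
        rng = np.random.default_rng(seed)
        tbl = tbl.iloc[np.sort(rng.choice(len(tbl), size=n_max, replace=False))]
        tbl = tbl.reset_index(drop=True)
    return tbl


# ---------------------------------------------------------------------------
# Maximum-entropy-style presence-background model


class MaxentLikeModel:
    """Presence-background exponential model with linear+quadratic features.

    Parameters
    ----------
    presence : DataFrame
        Environment values at training presences (columns = variables).
    background : DataFrame
        Environment values at background cells (same columns, >= 100 rows).
    reg : float
        Regularization multiplier scaling the L1 penalty (default 1.0).
    max_iter : int
        Iteration cap for the proximal gradient fit (default 500).

    Features are linear and squared terms per variable, standardized to mean
    0 / sd 1 over the background.  The fit maximizes the penalized presence
    log-likelihood ``mean_presence(w·f) − log Z(w) − Σ_j β_j |w_j|`` with
    ``Z`` the normalizer over background cells and ``β_j =
    reg·λ(m)·s_j/√m`` (``s_j`` the presence standard deviation of feature
    j, ``m`` the presence count).  λ(m) is the sample-size-dependent default
    penalty scale of maximum-entropy SDM practice — heavier shrinkage for
    sparse presence sets — interpolated from 1.0 at m <= 10 through 0.5 at
    m = 30 to 0.1 at m >= 100; ``reg`` multiplies it.  Optimization is
    proximal gradient (FISTA) with deterministic backtracking on the smooth
    part's quadratic upper bound — no randomness.
    """

    def __init__(self, presence: pd.DataFrame, background: pd.DataFrame,
                 reg: float = 1.0, max_iter: int = 500):
        self.variables = list(presence.columns)
        if list(background.columns) != self.variables:
            background = background[self.variables]
        P = presence.to_numpy(float)
        B = background.to_numpy(float)
        if P.shape[0] < 5:
            raise ValueError("need at least 5 training presences")
        if B.shape[0] < 100:
            raise ValueError("need at least 100 background cells")
        if np.unique(B, axis=0).shape[0] < 2:
            raise ValueError("degenerate background: one distinct environment")
        self.reg = float(reg)
        self.max_iter = int(max_iter)
        raw_b = np.hstack([B, B ** 2])
        self._mu = raw_b.mean(axis=0)
        sd = raw_b.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._Fb = (raw_b - self._mu) / self._sd
        raw_p = np.hstack([P, P ** 2])
        self._Fp = (raw_p - self._mu) / self._sd
        self.feature_names = [f"{v}" for v in self.variables] + [f"{v}^2" for v in self.variables]
        m = self._Fp.shape[0]
        lam = float(np.interp(m, [10.0, 30.0, 100.0], [1.0, 0.5, 0.1]))
        s = self._Fp.std(axis=0)
        s = np.where(s > 0, s, np.median(s[s > 0]) if (s > 0).any() else 1.0)
        #: per-feature L1 penalty actually applied by fit()
        self.penalty_ = self.reg * lam * s / np.sqrt(m)

    def _features(self, env: pd.DataFrame) -> np.ndarray:
        X = env[self.variables].to_numpy(float)
        return (np.hstack([X, X ** 2]) - self._mu) / self._sd

    def fit(self) -> "MaxentLikeResults":
        Fb, Fp = self._Fb, self._Fp
        fbar = Fp.mean(axis=0)
        beta = self.penalty_

        def smooth(wv):
            """g(w) = log Z(w) - mean presence score (smooth part of -loglik)."""
            eta = Fb @ wv
            shift = eta.max()
            return float(shift + np.log(np.exp(eta - shift).sum()) - fbar @ wv)

        def grad_smooth(wv):
            eta = Fb @ wv
            eta -= eta.max()
            q = np.exp(eta)
            q /= q.sum()
            return Fb.T @ q - fbar

        # FISTA with deterministic backtracking on the quadratic upper bound
        w = np.zeros(Fb.shape[1])
        z = w.copy()
        t = 1.0
        step = 1.0
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            gz = smooth(z)
            grad = grad_smooth(z)
            step = min(step * 2.0, 1.0)  # let the step recover between iterations
            while True:
                w_new = z - step * grad
                w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * beta, 0.0)
                diff = w_new - z
                if smooth(w_new) <= gz + grad @ diff + diff @ diff / (2.0 * step) + 1e-12:
                    break
                step *= 0.5
                if step < 1e-14:
                    break
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            z = w_new + (t - 1.0) / t_new * (w_new - w)
            delta = np.max(np.abs(w_new - w))
            w, t = w_new, t_new
            if delta < 1e-6:
                converged = True
                break
        eta_full = Fb @ w
        shift = eta_full.max()
        Z = np.exp(eta_full - shift).sum()
        q = np.exp(eta_full - shift) / Z
        entropy = float(-(q * np.log(np.where(q > 0, q, 1.0))).sum())
        return MaxentLikeResults(model=self, weights=w, converged=converged,
                                 n_iter=n_iter, entropy=entropy,
                                 _log_norm=float(np.log(Z) + shift),
                                 background_dist=q)


@dataclass
class MaxentLikeResults:
    """Fitted presence-background model: weights, entropy, predictions."""

    model: MaxentLikeModel
    weights: np.ndarray
    converged: bool
    n_iter: int
    entropy: float  # entropy of the fitted distribution over background cells
    _log_norm: float
    background_dist: np.ndarray

    def predict_raw(self, env: pd.DataFrame) -> np.ndarray:
        """Raw suitability q(x) = exp(w·f(x)) / Z (sums to 1 over background)."""
        F = self.model._features(env)
        return np.exp(F @ self.weights - self._log_norm)

    # generic prediction used by AUC screens: any monotone scale works
    predict = predict_raw

    def predict_logistic(self, env: pd.DataFrame) -> np.ndarray:
        """Logistic-scale output e^H q / (1 + e^H q), in (0, 1).

        H is the entropy of the fitted background distribution, so a model
        indistinguishable from uniform scores 0.5 everywhere.
        """
        q = self.predict_raw(env)
        x = np.exp(self.entropy) * q
        return x / (1.0 + x)

    def summary(self) -> str:
        lines = [
            "Maximum-entropy-style niche model",
            f"  variables: {', '.join(self.model.variables)}",
            f"  regularization multiplier: {self.model.reg}",
            f"  converged: {self.converged} (iterations: {self.n_iter})",
            f"  background entropy H: {self.entropy:.4f}",
            "  feature weights:",
        ]
        for name, w in zip(self.model.feature_names, self.weights):
            lines.append(f"    {name:>12s}  {w:+.6f}")
        return "\n".join(lines)


def predict_logistic(results: MaxentLikeResults, stack: RasterStack,
                     label: str = "") -> SuitabilitySurface:
    """Project a fitted model onto a stack as a logistic-scale surface."""
    missing = [v for v in results.model.variables if v not in stack]
    if missing:
        raise ValueError(f"stack is missing model variable(s): {missing}")
    mask = np.ones(stack.shape, dtype=bool)
    for v in results.model.variables:
        mask &= stack[v].mask()
    env = pd.DataFrame({v: stack[v].values[mask] for v in results.model.variables})
    out = np.full(stack.shape, np.nan)
    out[mask] = results.predict_logistic(env)
    return SuitabilitySurface(out, stack.extent, stack.cell_size, label, "logistic")


# ---------------------------------------------------------------------------
# BIOCLIM envelope model


@dataclass
class EnvelopeModel:
    """Rectilinear climate envelope (BIOCLIM-style).

    ``binary`` mode scores 1 iff every variable lies within its [lower,
    upper] bound.  ``percentile`` mode scores each variable as
    ``2·min(F, 1−F)`` where F is the value's training percentile with
    ``F = (rank − 1)/(n − 1)`` and linear interpolation between sorted
    training values (so the training minimum and maximum score exactly 0 and
    the median exactly 1), takes the minimum across variables, and scores 0
    outside the training range.
    """

    lower: dict[str, float]
    upper: dict[str, float]
    training: dict[str, np.ndarray] | None = None  # sorted per-variable values
    mode: str = "binary"

    def __post_init__(self):
        for v in self.lower:
            if self.lower[v] > self.upper[v]:
                raise ValueError(f"envelope for {v!r}: lower {self.lower[v]} > upper {self.upper[v]}")
        if self.mode not in ("binary", "percentile"):
            raise ValueError(f"unknown envelope mode {self.mode!r}")
        if self.mode == "percentile" and self.training is None:
            raise ValueError("percentile mode needs training values")

    @property
    def variables(self) -> list[str]:
        return list(self.lower)

    def _score_var_percentile(self, v: str, x: np.ndarray) -> np.ndarray:
        xs = self.training[v]
        n = xs.size
        if n == 1 or xs[0] == xs[-1]:
            return np.where(x == xs[0], 1.0, 0.0)
        F = np.interp(x, xs, (np.arange(n)) / (n - 1))
        score = 2.0 * np.minimum(F, 1.0 - F)
        return np.where((x < xs[0]) | (x > xs[-1]), 0.0, score)

    def score(self, env: pd.DataFrame) -> np.ndarray:
        """Per-row suitability in [0, 1]."""
        out = np.ones(len(env))
        for v in self.variables:
            x = env[v].to_numpy(float)
            if self.mode == "binary":
                s = ((x >= self.lower[v]) & (x <= self.upper[v])).astype(float)
            else:
                s = self._score_var_percentile(v, x)
            out = np.minimum(out, s)
        return out

    def project(self, stack: RasterStack, label: str = "") -> SuitabilitySurface:
        missing = [v for v in self.variables if v not in stack]
        if missing:
            raise ValueError(f"stack is missing envelope variable(s): {missing}")
        mask = np.ones(stack.shape, dtype=bool)
        for v in self.variables:
            mask &= stack[v].mask()
        env = pd.DataFrame({v: stack[v].values[mask] for v in self.variables})
        out = np.full(stack.shape, np.nan)
        out[mask] = self.score(env)
        return SuitabilitySurface(out, stack.extent, stack.cell_size, label, "envelope")


def fit_bioclim(values: Mapping[str, Sequence[float]] | pd.DataFrame,
                mode: str = "binary") -> EnvelopeModel:
    """Fit a BIOCLIM envelope from per-variable training values.

    ``values`` maps each variable to its training values; binary mode also
    accepts bare (min, max) pairs.
    """
    if isinstance(values, pd.DataFrame):
        values = {c: values[c].to_numpy(float) for c in values.columns}
    lower, upper, training = {}, {}, {}
    for v, arr in values.items():
        xs = np.sort(np.asarray(arr, dtype=float))
        if xs.size == 0:
            raise ValueError(f"no training values for variable {v!r}")
        lower[v], upper[v] = float(xs[0]), float(xs[-1])
        training[v] = xs
    return EnvelopeModel(lower=lower, upper=upper, training=training, mode=mode)


# ---------------------------------------------------------------------------
# Variable contributions (jackknife-style)


def jackknife_contributions(presence: pd.DataFrame, background: pd.DataFrame,
                            reg: float = 1.0, max_iter: int = 500) -> pd.DataFrame:
    """Leave-one-variable-out drop in training gain, per variable.

    The training gain of a fitted model is the mean presence log-probability
    minus the uniform-background log-probability; a variable's contribution is
    the gain lost when it is withheld, normalized over variables to sum to 1
    when any drop is positive.
    """

    def gain(cols: list[str]) -> float:
        res = MaxentLikeModel(presence[cols], background[cols], reg, max_iter).fit()
        logp = np.log(np.maximum(res.predict_raw(presence[cols]), 1e-300))
        return float(logp.mean() + np.log(len(background)))

    variables = list(presence.columns)
    full = gain(variables)
    rows = []
    for v in variables:
        rest = [u for u in variables if u != v]
        drop = full - gain(rest) if rest else full
        rows.append({"variable": v, "gain_drop": drop})
    df = pd.DataFrame(rows)
    pos = df.gain_drop.clip(lower=0.0)
    df["contribution"] = pos / pos.sum() if pos.sum() > 0 else 0.0
    return df
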