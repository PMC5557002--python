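"""Environmental variable screening: correlation pruning with mean-AUC tie-breaks.

Candidate variables are screened in two steps.  First, pairwise Pearson
correlations are computed on the pooled environment table of every unique
locality point.  Second, each variable's predictive power is scored as the
mean, over species, of the test AUC of a single-variable niche model; among
highly correlated pairs (|r| at or above a threshold, default 0.8) the member
with the lower mean AUC is discarded.  Pairs are processed in strictly
descending |r| (ties broken by variable-name pair), and pruning iterates on
the surviving set until no correlated pair remains, so the retained set is
deterministic and contains no pair at or above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geodata import CANONICAL_LAYER_ORDER

__all__ = [
    "CorrelationMatrix",
    "SelectionReport",
    "pearson_matrix",
    "per_variable_mean_auc",
    "prune_correlated",
    "load_screen_table",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over named variables."""

    variables: list[str]
    matrix: pd.DataFrame  # variables x variables, diagonal 1, NaN where undefined

    def __post_init__(self):
        m = self.matrix.to_numpy(float)
        if not np.allclose(np.diag(m), 1.0, equal_nan=True):
            raise ValueError("correlation matrix diagonal must be 1")
        asym = np.nanmax(np.abs(m - m.T)) if m.size else 0.0
        if asym > 1e-12:
            raise ValueError(f"correlation matrix asymmetry {asym} exceeds 1e-12")

    def r(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


@dataclass
class SelectionReport:
    """Outcome of correlation pruning.

    ``pruned`` lists (kept, dropped, |r|) triples in processing order, so the
    trace documents exactly why each variable left the candidate set.
    """

    retained: list[str]
    pruned: list[tuple[str, str, float]]
    mean_auc: dict[str, float]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pruned, columns=["kept", "dropped", "abs_r"])


def pearson_matrix(env: pd.DataFrame, variables: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations of an environment table.

    Zero-variance variables get NaN correlations (undefined) rather than an
    error; pandas' pairwise-complete ``corr`` supplies the machinery.
    Requires at least 3 complete rows per pair.
    """
    if variables is None:
        variables = [c for c in env.columns if c not in ("species", "lon", "lat")]
    sub = env[variables].astype(float)
    n_complete = (~sub.isna()).astype(int).T @ (~sub.isna()).astype(int)
    if (n_complete.to_numpy() < 3).any():
        raise ValueError("fewer than 3 complete rows for some variable pair")
    corr = sub.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationMatrix(variables=list(variables), matrix=corr)


def per_variable_mean_auc(stack, occurrences, variables=None, *, seed: int = 0,
                          train_frac: float = 0.75) -> dict[str, float]:
    """Mean over species of single-variable model test AUC, per variable.

    For each variable independently, a one-variable presence-background model
    is trained on a random 75% of each species' localities and its AUC
    measured on the held-out 25% against the background sample.  Species
    failing the split precondition are skipped with a warning.
    """
    import warnings

    from . import enm
    from .geodata import extract_values
    from .occurrences import train_test_split

    if variables is None:
        variables = stack.names
    train, test = train_test_split(occurrences, train_frac=train_frac, seed=seed)
    env_train, _ = extract_values(stack, train)
    env_test, _ = extract_values(stack, test)
    background = enm.background_sample(stack, variables, seed=seed)
    out: dict[str, float] = {}
    for var in variables:
        aucs = []
        for sp in occurrences.species:
            tr = env_train.loc[env_train.species == sp, [var]].dropna()
            te = env_test.loc[env_test.species == sp, [var]].dropna()
            if len(tr) < 5 or len(te) < 1:
                warnings.warn(f"species {sp!r} skipped for variable {var!r}: too few points")
                continue
            model = enm.MaxentLikeModel(tr, background[[var]], reg=1.0).fit()
            aucs.append(enm.auc(model.predict(te), model.predict(background[[var]])))
        out[var] = float(np.mean(aucs)) if aucs else float("nan")
    return out


def _pair_order_key(names: tuple[str, str]) -> tuple[str, str]:
    return tuple(sorted(names))


def prune_correlated(
    corr: CorrelationMatrix, mean_auc: dict[str, float], threshold: float = 0.8
) -> SelectionReport:
    """Iteratively drop the lower-AUC member of the most correlated pair.

    Among currently retained variables, the pair with the largest |r| at or
    above ``threshold`` is resolved by discarding the member with the lower
    mean AUC; on an AUC tie the variable later in the canonical
    (ALT, Bio1..Bio19) order is dropped.  Repeats until no pair remains.
    """
    missing = [v for v in corr.variables if v not in mean_auc]
    if missing:
        raise ValueError(f"mean AUC missing for variables: {missing}")
    rank = {n: i for i, n in enumerate(CANONICAL_LAYER_ORDER)}
    retained = list(corr.variables)
    pruned: list[tuple[str, str, float]] = []
    while True:
        pairs = []
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = corr.r(a, b)
                if np.isfinite(r) and abs(r) >= threshold:
                    pairs.append((abs(r), _pair_order_key((a, b)), a, b))
        if not pairs:
            break
        pairs.sort(key=lambda p: (-p[0], p[1]))
        absr, _, a, b = pairs[0]
        if mean_auc[a] == mean_auc[b]:
            drop = a if rank.get(a, 1e9) > rank.get(b, 1e9) else b
        else:
            drop = a if mean_auc[a] < mean_auc[b] else b
        keep = b if drop == a else a
        pruned.append((keep, drop, float(absr)))
        retained.remove(drop)
    return SelectionReport(retained=retained, pruned=pruned,
                           mean_auc=dict(mean_auc), threshold=threshold)


def load_screen_table(path: str | Path | None = None) -> tuple[CorrelationMatrix, dict[str, float]]:
    """Load a screening table: lower-triangle correlations plus a mean-AUC column.

    With no path, loads the packaged WorldClim screening table for the 20
    candidate variables (altitude plus Bio1-Bio19), transcribed from the
    published pairwise correlations and per-variable mean AUC values for the
    18 modelled species.
    """
    if path is None:
        ref = resources.files("phyloniche.data") / "worldclim_screen.csv"
        df = pd.read_csv(ref, index_col=0)  # type: ignore[arg-type]
    else:
        df = pd.read_csv(path, index_col=0)
    mean_auc = df["mean_auc"].astype(float).to_dict()
    C = df.drop(columns="mean_auc").astype(float)
    names = list(C.index)
    M = C.to_numpy()
    for i in range(len(names)):
        for j in range(i):
            M[j, i] = M[i, j]
        M[i, i] = 1.0
    corr = CorrelationMatrix(variables=names,
                             matrix=pd.DataFrame(M, index=names, columns=names))
    return corr, mean_auc
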