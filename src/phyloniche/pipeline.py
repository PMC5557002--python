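"""Pipeline orchestration: one configuration, staged execution, run manifest.

Stages run in dependency order: occurrence preparation -> variable selection
-> extant niche models -> niche overlap / ordination -> ancestral state
reconstruction -> ancestral niche models; ancestral range estimation is
independent once the tree is loaded.  Every stage writes CSV/ASCII-grid
reports into the run directory and records input/output SHA-256 digests in
``manifest.json``, so a rerun with the same config and seeds is
byte-comparable.  All randomness derives from one master seed via
per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    biogeography,
    enm,
    geodata,
    niche_evolution,
    niche_overlap,
    occurrences as occ_mod,
    synthetic_data,
    variable_selection,
)
from .trees import Chronogram

log = logging.getLogger("phyloniche")

STAGES = ("occurrences", "selection", "enm", "overlap", "asr", "ancestral_enm", "ranges")


@dataclass
class RunConfig:
    """Validated run configuration; defaults are the study settings."""

    out_dir: str = "phyloniche_run"
    rasters: list[str] = field(default_factory=list)  # raster file paths
    occurrences: str | None = None  # CSV path; None -> synthetic
    tree: str | None = None  # newick path; None -> packaged fixture
    tip_ranges: str | None = None  # CSV path; None -> packaged fixture codings
    min_n: int = 10
    correlation_threshold: float = 0.8
    train_frac: float = 0.75
    reg: float = 1.0
    max_iter: int = 500
    pp_threshold: float = 0.95
    max_areas: int = 2
    dca_segments: int = 26
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self):
        if not 0 < self.train_frac <= 1:
            raise ValueError("train_frac must be in (0, 1]")
        if not 0 <= self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in [0, 1]")
        if not 0 <= self.pp_threshold <= 1:
            raise ValueError("pp_threshold must be in [0, 1]")
        if self.min_n < 1 or self.max_areas < 1 or self.max_iter < 1:
            raise ValueError("min_n, max_areas and max_iter must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage error aborts the run with the stage name; the manifest written
    so far is flushed as ``manifest.partial.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}}
    state: dict = {}

    def record(stage: str, outputs: list[Path]):
        manifest["stages"][stage] = {
            "seed": config.stage_seed(stage),
            "outputs": {p.name: _digest(p) for p in outputs},
        }

    try:
        _load_inputs(config, state)
        for stage in STAGES:
            if stage not in config.stages:
                continue
            deps = _STAGE_DEPS[stage]
            missing = [d for d in deps if d not in state]
            if missing:
                log.warning("stage %s skipped: needs disabled stage output %s", stage, missing)
                continue
            log.info("running stage %s", stage)
            outputs = _STAGE_FNS[stage](config, state, out)
            record(stage, outputs)
    except Exception as exc:
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline aborted in stage context: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _load_inputs(config: RunConfig, state: dict) -> None:
    seed = config.stage_seed("inputs")
    if config.rasters:
        layers = [geodata.read_raster(p) for p in config.rasters]
        state["stack"] = geodata.RasterStack(layers)
    else:
        spec = synthetic_data.SyntheticWorldSpec(
            variables=("Bio1", "Bio7", "Bio12", "Bio15"),
            correlation=np.array([
                [1.0, 0.3, -0.2, 0.0],
                [0.3, 1.0, -0.3, 0.4],
                [-0.2, -0.3, 1.0, -0.3],
                [0.0, 0.4, -0.3, 1.0],
            ]),
            means={"Bio1": 22.0, "Bio7": 12.0, "Bio12": 2200.0, "Bio15": 45.0},
            sds={"Bio1": 4.0, "Bio7": 5.0, "Bio12": 700.0, "Bio15": 18.0},
            seed=seed,
        )
        state["stack"] = synthetic_data.gen_raster_stack(spec)
    state["tree"] = (Chronogram.from_newick(config.tree) if config.tree
                     else synthetic_data.fixture_chronogram())
    if config.tip_ranges:
        state["tip_ranges"] = biogeography.read_tip_ranges(config.tip_ranges)
    else:
        state["tip_ranges"] = synthetic_data.fixture_tip_ranges()
    if config.occurrences:
        state["raw_occurrences"] = occ_mod.read_occurrences(config.occurrences)
    else:
        stack = state["stack"]
        rng = np.random.default_rng(seed)
        sets = []
        for i, sp in enumerate(["sp_wet", "sp_dry", "sp_cool"]):
            lo = {"Bio1": (18.0, 24.0), "Bio12": (2000.0, 3500.0)}
            if sp == "sp_dry":
                lo = {"Bio1": (20.0, 28.0), "Bio12": (500.0, 1900.0)}
            if sp == "sp_cool":
                lo = {"Bio1": (12.0, 19.0), "Bio12": (1200.0, 2600.0)}
            spec = synthetic_data.SyntheticSpeciesSpec(sp, lo, n_true=40,
                                                       seed=seed + i + 1)
            sets.append(synthetic_data.gen_species_occurrences(spec, stack))
        state["raw_occurrences"] = occ_mod.OccurrenceSet(
            [r for s in sets for r in s])


_STAGE_DEPS = {
    "occurrences": [],
    "selection": ["occurrence_set"],
    "enm": ["occurrence_set", "selected"],
    "overlap": ["surfaces"],
    "asr": ["env_selected"],
    "ancestral_enm": ["recon"],
    "ranges": [],
}


def _stage_occurrences(config, state, out: Path) -> list[Path]:
    dedup, removed = occ_mod.deduplicate(state["raw_occurrences"])
    aug = occ_mod.augment_pseudo(dedup, min_n=config.min_n,
                                 seed=config.stage_seed("occurrences"))
    state["occurrence_set"] = aug
    p1 = out / "occurrences.csv"
    occ_mod.write_occurrences(aug, p1)
    p2 = out / "occurrence_counts.csv"
    aug.counts().to_csv(p2, index=False)
    return [p1, p2]


def _stage_selection(config, state, out: Path) -> list[Path]:
    stack = state["stack"]
    occ = state["occurrence_set"]
    env, rejects = geodata.extract_values(stack, occ)
    state["env"] = env
    corr = variable_selection.pearson_matrix(env)
    auc_map = variable_selection.per_variable_mean_auc(
        stack, occ, seed=config.stage_seed("selection"),
        train_frac=config.train_frac)
    report = variable_selection.prune_correlated(
        corr, auc_map, threshold=config.correlation_threshold)
    state["selected"] = report.retained
    state["env_selected"] = env[["species", "lon", "lat"] + report.retained]
    p1 = out / "env_table.csv"
    env.to_csv(p1, index=False)
    p2 = out / "variable_selection.csv"
    report.to_frame().to_csv(p2, index=False)
    p3 = out / "retained_variables.csv"
    pd.DataFrame({"variable": report.retained,
                  "mean_auc": [report.mean_auc[v] for v in report.retained]}
                 ).to_csv(p3, index=False)
    return [p1, p2, p3]


def _stage_enm(config, state, out: Path) -> list[Path]:
    stack, occ = state["stack"], state["occurrence_set"]
    variables = state["selected"]
    seed = config.stage_seed("enm")
    train, test = occ_mod.train_test_split(occ, config.train_frac, seed)
    env_train, _ = geodata.extract_values(stack, train)
    env_test, _ = geodata.extract_values(stack, test)
    bg = enm.background_sample(stack, variables, seed=seed)
    surfaces = {}
    rows = []
    outputs = []
    for sp in occ.species:
        tr = env_train.loc[env_train.species == sp, variables].dropna()
        te = env_test.loc[env_test.species == sp, variables].dropna()
        res = enm.MaxentLikeModel(tr, bg, reg=config.reg,
                                  max_iter=config.max_iter).fit()
        a = enm.auc(res.predict(te), res.predict(bg)) if len(te) else float("nan")
        surf = enm.predict_logistic(res, stack, label=sp)
        surfaces[sp] = surf
        rows.append({"species": sp, "auc": a, "converged": res.converged,
                     "reliable": bool(a > 0.7) if np.isfinite(a) else False})
        p = out / f"suitability_{sp}.asc"
        geodata.write_raster(surf.as_layer(), p, format="ascii_grid")
        outputs.append(p)
    state["surfaces"] = surfaces
    p = out / "enm_summary.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    outputs.append(p)
    return outputs


def _stage_overlap(config, state, out: Path) -> list[Path]:
    results = niche_overlap.pairwise_overlap(state["surfaces"])
    df = pd.DataFrame([{"species_a": r.species_a, "species_b": r.species_b,
                        "D": r.D, "I": r.I, "n_cells": r.n_cells} for r in results])
    p1 = out / "niche_overlap.csv"
    df.to_csv(p1, index=False)
    ord_ = niche_overlap.dca(state["env_selected"].drop(columns=["species", "lon", "lat"]),
                             segments=config.dca_segments)
    sc = pd.DataFrame(ord_.scores, columns=[f"DCA{i+1}" for i in range(ord_.axes)])
    sc.insert(0, "species", state["env_selected"]["species"].to_numpy())
    p2 = out / "dca_scores.csv"
    sc.to_csv(p2, index=False)
    return [p1, p2]


def _stage_asr(config, state, out: Path) -> list[Path]:
    tree = state["tree"]
    env = state["env_selected"]
    present = [t for t in tree.taxa if t in set(env.species)]
    if len(present) < 2:
        # synthetic occurrence species are not tree tips; reconstruct on
        # simulated tip climates instead so the stage is still exercised
        sim = {
            v: synthetic_data.sim_brownian_traits(tree, 0.0, 1.0,
                                                  seed=config.stage_seed("asr") + k)
            for k, v in enumerate(c for c in env.columns if c not in ("species", "lon", "lat"))
        }
        stats = pd.concat({(v, "mean"): pd.Series(sim[v]) for v in sim}, axis=1)
        stats.columns = pd.MultiIndex.from_tuples(stats.columns,
                                                  names=["variable", "statistic"])
    else:
        stats = niche_evolution.tip_statistics(env)
        stats = stats.loc[present]
    recon = niche_evolution.reconstruct_niche_summaries(tree, stats)
    state["recon"] = recon
    p = out / "ancestral_reconstruction.csv"
    recon.to_frame().to_csv(p, index=False)
    return [p]


def _stage_ancestral_enm(config, state, out: Path) -> list[Path]:
    tree, recon = state["tree"], state["recon"]
    cols = recon.values.columns
    if not any(c.endswith(":min") for c in cols):
        log.warning("no reconstructed min/max statistics; ancestral models skipped")
        return []
    keep = {Chronogram.bipartition(n) for n in
            niche_evolution.filter_by_support(tree, config.pp_threshold)}
    ids = [i for i, b in recon.bipartitions.items() if b in keep and len(b) > 1]
    envelopes = niche_evolution.ancestral_envelopes(recon, ids)
    outputs = []
    for i, envlp in envelopes.items():
        if not all(v in state["stack"] for v in envlp.variables):
            continue
        surf = niche_evolution.project_ancestral(envlp, state["stack"],
                                                 label=recon.node_labels[i])
        p = out / f"ancestral_{recon.node_labels[i]}.asc"
        geodata.write_raster(surf.as_layer(), p, format="ascii_grid")
        outputs.append(p)
    return outputs


def _stage_ranges(config, state, out: Path) -> list[Path]:
    tree = state["tree"]
    tips = state["tip_ranges"]
    space = biogeography.build_state_space(sorted({a for r in tips.values() for a in r}),
                                           config.max_areas)
    recon = biogeography.diva_parsimony(tree, tips, space=space)
    diva = biogeography.summarize_over_trees([tree], [recon], tree, method="S-DIVA")
    model = biogeography.DECModel(tree, tips, space=space)
    fit = model.fit()
    dec = fit.marginal_ranges()
    df = pd.concat([diva.to_frame(tree), dec.to_frame(tree)], ignore_index=True)
    p1 = out / "ancestral_ranges.csv"
    df.to_csv(p1, index=False)
    p2 = out / "dec_fit.txt"
    p2.write_text(fit.summary() + "\n")
    return [p1, p2]


_STAGE_FNS = {
    "occurrences": _stage_occurrences,
    "selection": _stage_selection,
    "enm": _stage_enm,
    "overlap": _stage_overlap,
    "asr": _stage_asr,
    "ancestral_enm": _stage_ancestral_enm,
    "ranges": _stage_ranges,
}
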