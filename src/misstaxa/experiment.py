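"""Replicate orchestration and summary tables for the missing-taxa study.

One replicate = one cell draw of the factorial design (generating model x
missingness scenario x missing percentage):

1. size the tree so ``n_target`` tips remain after pruning;
2. simulate a unit-height pure-birth tree;
3. repeat {Mk regimes; trait; sampling status} until the minority regime
   covers 25-45% of the *retained* tips (capped attempts);
4. measure the Fritz-Purvis D of the sampling status on the full tree;
5. prune, transfer the regime painting, fit the candidate models, and pick
   the AICc-best one.

Summaries mirror the study's tables: model-selection error counts, median
delta AICc of the generating model when it loses, normalized bias
((mean estimate - true)/true) and normalized precision (median absolute
deviation from the median, divided by the true value).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dstat import DResult, d_statistic
from .fit import MODEL_ORDER, fit_all, select_best
from .missingness import (apply_missingness, sample_missing_clumped,
                          sample_missing_correlated, sample_missing_random)
from .simulate import (STUDY_DEFAULTS, ModelSpec, initial_tree_size,
                       regime_balance_ok, simulate_liability, simulate_mk_regimes,
                       simulate_trait, simulate_yule_tree)

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "ReplicateRecord",
    "run_replicate",
    "run_cell",
    "records_to_frame",
    "summarize_error_rates",
    "summarize_delta_aicc",
    "summarize_bias",
    "summarize_precision",
    "summarize_dstat_means",
    "run_experiment",
    "dstat_calibration",
]

SCENARIOS = ("nMT", "rMT", "cluMT", "corMT")

#: parameters reported per generating model, and their study-condition values
PARAMS_BY_MODEL = {
    "BM": ("sigma2_0",),
    "BMS": ("sigma2_0", "sigma2_1"),
    "OU": ("sigma2_0", "theta_0", "alpha"),
    "OUM": ("sigma2_0", "theta_0", "theta_1", "alpha"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the design plus its execution knobs."""

    model: str
    scenario: str
    p_missing: float = 0.0
    n_reps: int = 1
    seed: int | None = None
    n_target: int = STUDY_DEFAULTS["n_target"]
    mk_rate: float = STUDY_DEFAULTS["mk_rate"]
    n_dstat_null: int = 1000
    compute_dstat: bool = True
    max_attempts: int = 1000
    models_to_fit: tuple = MODEL_ORDER
    trait_spec: ModelSpec | None = None

    def __post_init__(self):
        if self.model not in MODEL_ORDER:
            raise ValueError(f"unknown generating model {self.model!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if (self.scenario == "nMT") != (self.p_missing == 0):
            raise ValueError("nMT requires p_missing = 0 (and vice versa)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def resolved_trait_spec(self):
        return self.trait_spec or ModelSpec.study_default(self.model)


@dataclass
class ReplicateRecord:
    replicate: int
    seed_entropy: int
    spec: ScenarioSpec
    attempts: int
    n_retained: int
    dstat: DResult | None
    fits: dict
    best_model: str
    deltas: dict

    @property
    def delta_generating(self):
        return self.deltas.get(self.spec.model)


def _sampling_status(spec, tree, painting, trait_spec, rngs):
    """Draw (status, trait-or-None) for one rejection-loop attempt."""
    labels = tree.tip_labels
    if spec.scenario == "nMT":
        return pd.Series(np.ones(len(labels), dtype=np.int8), index=labels,
                         name="status"), None
    if spec.scenario == "rMT":
        return sample_missing_random(labels, spec.p_missing, rngs["missing"]), None
    if spec.scenario == "cluMT":
        liab = simulate_liability(tree, STUDY_DEFAULTS["liability_sigma2"],
                                  rngs["missing"])
        return sample_missing_clumped(liab, spec.p_missing), None
    # corMT: the status depends on the trait, so T is drawn inside the loop
    trait = simulate_trait(tree, painting, trait_spec, rngs["trait"])
    return sample_missing_correlated(trait, spec.p_missing, rngs["missing"]), trait


def run_replicate(spec, seed=None):
    """Run the full per-replicate pipeline; see the module docstring."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        seed if seed is not None else spec.seed)
    streams = ss.spawn(5)
    rngs = {name: np.random.default_rng(s)
            for name, s in zip(("tree", "regimes", "trait", "missing", "dstat"),
                               streams)}
    trait_spec = spec.resolved_trait_spec()
    n0 = initial_tree_size(spec.p_missing, spec.n_target)
    tree = simulate_yule_tree(n0, rngs["tree"])

    for attempt in range(1, spec.max_attempts + 1):
        painting = simulate_mk_regimes(tree, spec.mk_rate, rngs["regimes"])
        status, trait = _sampling_status(spec, tree, painting, trait_spec, rngs)
        retained = [lab for lab, s in status.items() if s == 1]
        if len(retained) >= 2 and regime_balance_ok(tree, painting, retained):
            break
    else:
        warnings.warn("regime-balance rejection loop exhausted; re-seeding replicate")
        return run_replicate(spec, ss.spawn(1)[0])

    if trait is None:
        trait = simulate_trait(tree, painting, trait_spec, rngs["trait"])

    dres = None
    if spec.scenario != "nMT" and spec.compute_dstat:
        dres = d_statistic(tree, status, spec.n_dstat_null, rngs["dstat"])

    if spec.scenario == "nMT":
        ptree, ptrait, ppaint = tree, trait, painting
    else:
        ptree, ptrait, node_map = apply_missingness(tree, trait, status,
                                                    return_map=True)
        ppaint = painting.restrict(node_map) if node_map is not None else painting

    fits = fit_all(ptree, ppaint, ptrait, spec.models_to_fit)
    if len(fits) == 1:
        only = next(iter(fits.values()))
        best, deltas = only.model, {only.model: 0.0}
    else:
        best, deltas = select_best(list(fits.values()))
    seed_id = int(ss.generate_state(1, np.uint64)[0])  # stable stream fingerprint
    return ReplicateRecord(replicate=0, seed_entropy=seed_id, spec=spec,
                           attempts=attempt, n_retained=ptree.n_tips, dstat=dres,
                           fits=fits, best_model=best, deltas=deltas)


def run_cell(spec, progress=False):
    """All replicates of one design cell, each on an independent substream."""
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.n_reps)
    records = []
    iterator = enumerate(children)
    if progress:
        from tqdm import tqdm  # optional nicety; not a dependency

        iterator = tqdm(list(iterator), desc=f"{spec.model}/{spec.scenario}"
                        f"/{spec.p_missing:g}")
    for i, child in iterator:
        rec = run_replicate(spec, child)
        rec.replicate = i
        records.append(rec)
    return records


def records_to_frame(records):
    """Flatten replicate records into one row each."""
    rows = []
    for rec in records:
        spec = rec.spec
        row = {
            "model": spec.model,
            "scenario": spec.scenario,
            "p_missing": spec.p_missing,
            "replicate": rec.replicate,
            "seed_entropy": rec.seed_entropy,
            "attempts": rec.attempts,
            "n_retained": rec.n_retained,
            "D": rec.dstat.D if rec.dstat is not None else np.nan,
            "best_model": rec.best_model,
            "delta_generating": rec.delta_generating,
        }
        for m, f in rec.fits.items():
            row[f"loglik_{m}"] = f.loglik
            row[f"aicc_{m}"] = f.aicc
            row[f"delta_{m}"] = rec.deltas[m]
            row[f"converged_{m}"] = f.converged
        gen = rec.fits.get(spec.model)
        if gen is not None:
            for p in PARAMS_BY_MODEL[spec.model]:
                row[f"est_{p}"] = gen.params[p]
            row["converged_generating"] = gen.converged
        rows.append(row)
    return pd.DataFrame(rows)


_CELL = ["model", "scenario", "p_missing"]


def summarize_error_rates(frame):
    """Miss-selection count/proportion per cell, plus best-model breakdown."""
    rows = []
    for key, g in frame.groupby(_CELL, sort=False):
        model = key[0]
        n = len(g)
        miss = int((g["best_model"] != model).sum())
        row = dict(zip(_CELL, key)) | {
            "n": n, "n_misselected": miss, "prop_misselected": miss / n}
        for m in MODEL_ORDER:
            row[f"selected_{m}"] = int((g["best_model"] == m).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_delta_aicc(frame):
    """Median delta AICc of the generating model among miss-selected runs."""
    rows = []
    for key, g in frame.groupby(_CELL, sort=False):
        lost = g.loc[g["best_model"] != key[0], "delta_generating"]
        rows.append(dict(zip(_CELL, key)) | {
            "n_misselected": len(lost),
            "median_delta_aicc": lost.median() if len(lost) else np.nan})
    return pd.DataFrame(rows)


def _converged(g):
    if "converged_generating" in g:
        return g[g["converged_generating"].fillna(False)]
    return g


def summarize_bias(frame, true_params=None):
    """Normalized bias (mean estimate - true)/true of the generating model's
    parameters, over converged fits of the generating model itself."""
    rows = []
    for key, g in frame.groupby(_CELL, sort=False):
        model = key[0]
        truths = true_params or ModelSpec.study_default(model).true_params()
        gc = _converged(g)
        for p in PARAMS_BY_MODEL[model]:
            col = f"est_{p}"
            if col not in gc or gc[col].dropna().empty:
                continue
            est = gc[col].dropna()
            true = truths[p]
            rows.append(dict(zip(_CELL, key)) | {
                "parameter": p, "true": true, "n": len(est),
                "mean_estimate": est.mean(),
                "normalized_bias": (est.mean() - true) / true,
                "bias": est.mean() - true,
            })
    return pd.DataFrame(rows)


def summarize_precision(frame, true_params=None):
    """Normalized precision: median(|est - median(est)|)/true, per parameter."""
    rows = []
    for key, g in frame.groupby(_CELL, sort=False):
        model = key[0]
        truths = true_params or ModelSpec.study_default(model).true_params()
        gc = _converged(g)
        for p in PARAMS_BY_MODEL[model]:
            col = f"est_{p}"
            if col not in gc or gc[col].dropna().empty:
                continue
            est = gc[col].dropna()
            mad = (est - est.median()).abs().median()
            rows.append(dict(zip(_CELL, key)) | {
                "parameter": p, "true": truths[p], "n": len(est),
                "mad": mad, "normalized_precision": mad / truths[p],
            })
    return pd.DataFrame(rows)


def summarize_dstat_means(frame):
    """Mean D per (scenario, model), pooled over percentages; nMT excluded."""
    g = frame[frame["scenario"] != "nMT"].dropna(subset=["D"])
    if g.empty:
        return pd.DataFrame(columns=["scenario", "model", "n", "mean_D"])
    return (g.groupby(["scenario", "model"], sort=False)["D"]
            .agg(n="size", mean_D="mean").reset_index())


def run_experiment(config, out_dir):
    """Run every cell in ``config`` and write the study's output files.

    ``config`` keys: models, scenarios, percentages, n_reps, seed, and
    optionally n_target / n_dstat_null / mk_rate.  Writes replicates.csv,
    table2_error_rates.csv, table3_delta_aicc.csv, table4_bias.csv,
    table5_precision.csv, dstat_means.csv and manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = config.get("models", list(MODEL_ORDER))
    scenarios = config.get("scenarios", list(SCENARIOS))
    percentages = config.get("percentages", [0.1, 0.5, 0.9])
    n_reps = int(config.get("n_reps", 1000))
    master = np.random.SeedSequence(config.get("seed"))
    extra = {k: config[k] for k in ("n_target", "n_dstat_null", "mk_rate")
             if k in config}

    cells = []
    for model in models:
        for scenario in scenarios:
            for p in ([0.0] if scenario == "nMT" else percentages):
                cells.append((model, scenario, p))

    records = []
    manifest_cells = []
    for (model, scenario, p), child in zip(cells, master.spawn(len(cells))):
        spec = ScenarioSpec(model=model, scenario=scenario, p_missing=p,
                            n_reps=n_reps, seed=None, **extra)
        cell_records = []
        for i, rep_seed in enumerate(child.spawn(n_reps)):
            rec = run_replicate(spec, rep_seed)
            rec.replicate = i
            cell_records.append(rec)
        records.extend(cell_records)
        manifest_cells.append({
            "model": model, "scenario": scenario, "p_missing": p,
            "n_reps": n_reps, "seed_entropy": int(child.entropy),
            "rejection_attempts": [r.attempts for r in cell_records],
        })

    frame = records_to_frame(records)
    frame.to_csv(out / "replicates.csv", index=False)
    summarize_error_rates(frame).to_csv(out / "table2_error_rates.csv", index=False)
    summarize_delta_aicc(frame).to_csv(out / "table3_delta_aicc.csv", index=False)
    summarize_bias(frame).to_csv(out / "table4_bias.csv", index=False)
    summarize_precision(frame).to_csv(out / "table5_precision.csv", index=False)
    summarize_dstat_means(frame).to_csv(out / "dstat_means.csv", index=False)
    manifest = {
        "package": "misstaxa", "version": __version__,
        "master_seed_entropy": int(master.entropy), "cells": manifest_cells,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"frame": frame, "out_dir": out}


# ------------------------------------------------------- D-statistic studies


def dstat_calibration(scheme, p, n_reps, seed=None, n_target=None,
                      trait_model="BM", n_null=1000):
    """D values of the sampling status over replicate simulations.

    ``scheme`` is one of rMT / cluMT / corMT.  Trees are sized so
    ``n_target`` tips remain after pruning.  corMT simulates the trait under
    ``trait_model`` at study defaults; rMT and cluMT never touch the trait.
    The regime-balance rejection loop is skipped here: the sampling status is
    independent of the regime character in every scheme this routine covers.
    """
    if scheme not in ("rMT", "cluMT", "corMT"):
        raise ValueError(f"unknown scheme {scheme!r}")
    n_target = n_target or STUDY_DEFAULTS["n_target"]
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    n0 = initial_tree_size(p, n_target)
    trait_spec = ModelSpec.study_default(trait_model)
    out = np.empty(n_reps)
    for i, child in enumerate(master.spawn(n_reps)):
        streams = child.spawn(4)
        rngs = [np.random.default_rng(s) for s in streams]
        tree = simulate_yule_tree(n0, rngs[0])
        if scheme == "rMT":
            status = sample_missing_random(tree.tip_labels, p, rngs[1])
            if status.min() == status.max():  # all sampled by chance
                status.iloc[0] = 0
        elif scheme == "cluMT":
            liab = simulate_liability(tree, STUDY_DEFAULTS["liability_sigma2"],
                                      rngs[1])
            status = sample_missing_clumped(liab, p)
        else:
            painting = (simulate_mk_regimes(tree, STUDY_DEFAULTS["mk_rate"], rngs[2])
                        if trait_model in ("BMS", "OUM") else None)
            trait = simulate_trait(tree, painting, trait_spec, rngs[1])
            status = sample_missing_correlated(trait, p, rngs[2])
        out[i] = d_statistic(tree, status, n_null, rngs[3]).D
    return out
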