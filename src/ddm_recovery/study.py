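"""Orchestration of the factorial recovery study and the retest-ceiling
simulation: configuration, seed bookkeeping, per-cell loops, summaries.

Every cell of the grid (parameter set x trial number x contamination x
criterion x model) derives its own seed from the master seed and the cell
labels, so runs are fully reproducible and embarrassingly parallel in
principle.  Failed or filtered cells are kept in the record table with
status flags rather than dropped.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import (CELL_COLUMNS, PrecisionWeights, summarize_cell,
                       model_superiority, retest_reliability)
from .fitting import ModelSpec, fit
from .params import DiffusionParams, MAIN_PARAM_NAMES
from .simulate import (ParameterPopulation, TrialData, apply_contamination,
                       draw_parameter_sets, simulate_trials,
                       study1_population, study2_population,
                       threshold_balance_filter)

__all__ = ["StudyConfig", "run_recovery_study", "run_retest_simulation",
           "subset_first_n", "cell_seed"]

def cell_seed(master_seed: int, *labels) -> np.random.SeedSequence:
    """Derive a per-cell seed from the master seed and the cell labels."""
    hashed = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *hashed])


def _cell_int_seed(master_seed: int, *labels) -> int:
    return int(cell_seed(master_seed, *labels).generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyConfig:
    """Configuration of a recovery or retest run."""

    design: str = "one_drift"
    population: str = "study1"  # study1 | study2_ldt | study2_rmt
    n_parameter_sets: int = 100
    trial_numbers: tuple = (48, 200, 1000)
    contamination: tuple = ("none",)
    contamination_rate: float = 0.04
    criteria: tuple = ("ks", "ml")
    models: tuple = (4, 5, 7)
    init: str = "default"
    seed: int = 20160913
    output_dir: str | None = None
    precision_weights: str | dict = "default"
    min_frac: float = 0.04
    fitter_options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("trial_numbers", "contamination", "criteria", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolve_population(self) -> ParameterPopulation:
        if self.population == "study1":
            return study1_population(self.design)
        if self.population in ("study2_ldt", "study2_rmt"):
            return study2_population(self.population.split("_")[1])
        raise ValueError(f"unknown population {self.population!r}")

    def resolve_weights(self) -> PrecisionWeights:
        if self.precision_weights == "default":
            return PrecisionWeights()
        if isinstance(self.precision_weights, dict):
            return PrecisionWeights(**self.precision_weights)
        raise ValueError("precision_weights must be 'default' or a mapping")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _param_columns(prefix: str, p: DiffusionParams) -> dict:
    d = {f"{prefix}{k}": getattr(p, k) for k in
         ("a", "v", "t0", "zr", "sv", "st0", "szr")}
    d[f"{prefix}v1"] = p.v1 if p.is_two_drift else np.nan
    d[f"{prefix}v_total"] = p.v_total
    return d


def subset_first_n(data: TrialData, n: int) -> TrialData:
    """First ``n`` trials in their original order."""
    if not (1 <= n <= data.n):
        raise ValueError(f"n must be in [1, {data.n}], got {n}")
    return TrialData(data.response[:n].copy(), data.rt[:n].copy(),
                     None if data.stimulus is None else data.stimulus[:n].copy(),
                     data.flag[:n].copy())


# ---------------------------------------------------------------------------
# recovery study
# ---------------------------------------------------------------------------
def run_recovery_study(cfg: StudyConfig, progress: bool = False) -> dict:
    """Simulate -> contaminate -> filter -> fit -> evaluate over the grid.

    Returns a dict with the trial-level ``records`` frame, the per-cell
    ``summary``, the model-``superiority`` table, and the run ``manifest``;
    writes them as CSV/JSON when the config names an output directory.
    """
    pop = cfg.resolve_population()
    weights = cfg.resolve_weights()
    truths = draw_parameter_sets(pop, cfg.n_parameter_sets,
                                 seed=cell_seed(cfg.seed, "draw"))
    rows = []
    for i, p_true in enumerate(truths):
        for n_trials in cfg.trial_numbers:
            base = simulate_trials(p_true, n_trials,
                                   seed=cell_seed(cfg.seed, "sim", i, n_trials))
            for contam in cfg.contamination:
                data = apply_contamination(
                    base, contam, p_true, cfg.contamination_rate,
                    seed=cell_seed(cfg.seed, "contam", i, n_trials, contam))
                passed = threshold_balance_filter(data, cfg.min_frac)
                for criterion in cfg.criteria:
                    for m in cfg.models:
                        spec = ModelSpec(m, cfg.design)
                        res = fit(data, spec, criterion, init=cfg.init,
                                  seed=_cell_int_seed(cfg.seed, "fit", i,
                                                      n_trials, contam,
                                                      criterion, m),
                                  **cfg.fitter_options)
                        row = {"set_idx": i, "design": cfg.design,
                               "n_trials": n_trials, "contamination": contam,
                               "criterion": criterion, "model": m,
                               "filter_pass": passed,
                               "converged": res.converged,
                               "n_iter": res.n_iter,
                               "objective": res.objective}
                        row.update(_param_columns("true_", p_true))
                        row.update(_param_columns("est_", res.params))
                        rows.append(row)
        if progress:
            print(f"parameter set {i + 1}/{len(truths)} done")
    records = pd.DataFrame(rows)
    summary = summarize_records(records, weights)
    superiority = superiority_table(summary)
    manifest = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
                "master_seed": cfg.seed,
                "n_records": int(len(records)),
                "n_filtered_out": int((~records["filter_pass"]).sum()),
                "n_nonconverged": int((~records["converged"]).sum()),
                "precision_weights": weights.as_dict()}
    out = {"records": records, "summary": summary,
           "superiority": superiority, "manifest": manifest}
    if cfg.output_dir:
        _write_outputs(cfg.output_dir, out)
    return out


def summarize_records(records: pd.DataFrame,
                      weights: PrecisionWeights) -> pd.DataFrame:
    """Per-cell evaluation measures, one row per (cell x parameter) plus a
    "mean" row per cell (Fisher-Z mean correlation, mean-precision
    quantile).  Only records passing the threshold-balance filter enter,
    matching how the study tabulates its results; the full record table
    keeps everything."""
    kept = records[records["filter_pass"]]
    rows = []
    for key, grp in kept.groupby(CELL_COLUMNS):
        if len(grp) < 3:
            continue
        true_ps = [{"a": r.true_a, "v": r.true_v_total, "t0": r.true_t0,
                    "zr": r.true_zr} for r in grp.itertuples()]
        est_ps = [{"a": r.est_a, "v": r.est_v_total, "t0": r.est_t0,
                   "zr": r.est_zr} for r in grp.itertuples()]
        model = key[CELL_COLUMNS.index("model")]
        stats = summarize_cell(true_ps, est_ps, weights, n_free=int(model))
        base = dict(zip(CELL_COLUMNS, key))
        for k in MAIN_PARAM_NAMES:
            rows.append({**base, "parameter": k,
                         "corr": stats["corr"].get(k, np.nan),
                         "bias": stats["bias"][k],
                         "precision_q": stats["precision_q"][k],
                         "n_sets": stats["n_sets"]})
        rows.append({**base, "parameter": "mean",
                     "corr": stats["fisher_z_mean_corr"], "bias": np.nan,
                     "precision_q": stats["mep_q"],
                     "mep_median": stats["mep_median"],
                     "n_sets": stats["n_sets"]})
    cols = CELL_COLUMNS + ["parameter", "corr", "bias", "precision_q",
                           "mep_median", "n_sets"]
    return pd.DataFrame(rows, columns=cols if not rows else None)


def superiority_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Winning-model labels ("corr/bias/precision") per parameter cell."""
    rows = []
    if summary.empty:
        return pd.DataFrame(columns=["contamination", "criterion", "parameter",
                                     "n_trials", "winners"])
    per_param = summary[summary["parameter"] != "mean"]
    group_cols = ["contamination", "criterion", "parameter", "n_trials"]
    for key, grp in per_param.groupby(group_cols):
        label = model_superiority(grp, parameter=key[2])
        rows.append(dict(zip(group_cols, key)) | {"winners": label})
    return pd.DataFrame(rows)


def _write_outputs(output_dir, out: dict) -> None:
    path = Path(output_dir)
    path.mkdir(parents=True, exist_ok=True)
    out["records"].to_csv(path / "records.csv", index=False)
    if "summary" in out:
        out["summary"].to_csv(path / "summary.csv", index=False)
    if len(out.get("superiority", [])):
        out["superiority"].to_csv(path / "superiority.csv", index=False)
    if "reliability" in out:
        out["reliability"].to_csv(path / "reliability.csv", index=False)
    with open(path / "manifest.json", "w") as fh:
        json.dump(out["manifest"], fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# retest-ceiling simulation
# ---------------------------------------------------------------------------
def run_retest_simulation(cfg: StudyConfig, progress: bool = False) -> dict:
    """Equal-parameter two-session simulation (reliability ceiling).

    Each subject keeps one parameter set for both sessions; sessions are
    simulated and fitted independently, so the resulting between-session
    correlations estimate the maximum attainable retest reliability.
    """
    pop = cfg.resolve_population()
    if all(d[0] != "normal" for _, d in pop.spec):
        raise ValueError("retest simulation expects a multivariate-normal "
                         "(study-2 style) population")
    truths = draw_parameter_sets(pop, cfg.n_parameter_sets,
                                 seed=cell_seed(cfg.seed, "draw"))
    fit_rows = []
    rel_rows = []
    for n_trials in cfg.trial_numbers:
        estimates: dict[tuple, dict[int, list]] = {}
        for i, p_true in enumerate(truths):
            sessions = []
            for session in (1, 2):
                data = simulate_trials(
                    p_true, n_trials,
                    seed=cell_seed(cfg.seed, "retest-sim", i, n_trials, session))
                sessions.append(data)
            for criterion in cfg.criteria:
                for m in cfg.models:
                    spec = ModelSpec(m, cfg.design)
                    for session, data in zip((1, 2), sessions):
                        res = fit(data, spec, criterion, init=cfg.init,
                                  seed=_cell_int_seed(cfg.seed, "retest-fit", i,
                                                      n_trials, session,
                                                      criterion, m),
                                  **cfg.fitter_options)
                        key = (n_trials, criterion, m)
                        estimates.setdefault(key, {1: [], 2: []})
                        estimates[key][session].append(res.params)
                        row = {"set_idx": i, "session": session,
                               "n_trials": n_trials, "criterion": criterion,
                               "model": m, "converged": res.converged,
                               "objective": res.objective}
                        row.update(_param_columns("est_", res.params))
                        fit_rows.append(row)
            if progress:
                print(f"n={n_trials}: subject {i + 1}/{len(truths)} done")
        for (nt, criterion, m), sess in estimates.items():
            rel = retest_reliability(sess[1], sess[2], n_free=m)
            rel_rows.append({"n_trials": nt, "criterion": criterion,
                             "model": m, **rel})
    records = pd.DataFrame(fit_rows)
    reliability = pd.DataFrame(rel_rows)
    manifest = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
                "master_seed": cfg.seed, "n_records": int(len(records)),
                "mode": "retest"}
    out = {"records": records, "reliability": reliability,
           "manifest": manifest}
    if cfg.output_dir:
        _write_outputs(cfg.output_dir, out)
    return out
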