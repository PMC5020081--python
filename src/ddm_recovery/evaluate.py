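"""Recovery evaluation: correlation, bias, estimation precision,
model-superiority tabulation, and test-retest reliability.

Three criteria grade how well estimated parameters recover the generating
truth across a population of parameter sets:

1. *Correlation* — Pearson r between true and estimated values per
   parameter, averaged over the four main parameters (a, v, t0, zr) on the
   Fisher-Z scale.
2. *Bias* — mean signed deviation (estimated - true) per parameter.
3. *Estimation precision* — squared deviations weighted by a
   per-parameter "best possible accuracy" scale; the mean across the four
   main parameters is

       mep = (1/4) * sum_k ((est_k - true_k) / w_k)**2

   summarized by its 95% quantile across parameter sets (lower = better).

For two-drift designs the drift measure is nu_total, the difference
between the upper-stimulus and lower-stimulus drifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DiffusionParams, MAIN_PARAM_NAMES

__all__ = [
    "PrecisionWeights", "mean_estimation_precision", "fisher_z_mean",
    "fisher_z_mean_correlation", "parameter_correlations", "bias",
    "precision_quantile", "summarize_cell", "model_superiority",
    "retest_reliability",
]

CELL_COLUMNS = ["n_trials", "contamination", "criterion", "model"]


@dataclass(frozen=True)
class PrecisionWeights:
    """Per-parameter "best possible accuracy" scales for a, v, t0, zr.

    The defaults are the standard deviations of (estimated - true)
    achieved by the generating seven-parameter model fitted with ML at
    5000 trials on the one-drift uniform-range population (the package's
    calibration run; see docs/methods.md).  ``calibrate`` recomputes them
    for any population.
    """

    a: float = 0.0456
    v: float = 0.1774
    t0: float = 0.0161
    zr: float = 0.0218

    def __post_init__(self) -> None:
        if min(self.a, self.v, self.t0, self.zr) <= 0:
            raise ValueError("precision weights must all be positive")

    def as_dict(self) -> dict[str, float]:
        return {"a": self.a, "v": self.v, "t0": self.t0, "zr": self.zr}

    @classmethod
    def calibrate(cls, deviations: dict[str, np.ndarray]) -> "PrecisionWeights":
        """Build weights from arrays of (est - true) deviations."""
        return cls(**{k: float(np.std(np.asarray(deviations[k])))
                      for k in MAIN_PARAM_NAMES})


def _main_vector(p: DiffusionParams | dict) -> dict[str, float]:
    if isinstance(p, DiffusionParams):
        return p.main_values()
    missing = [k for k in MAIN_PARAM_NAMES if k not in p]
    if missing:
        raise ValueError(f"missing parameters {missing} in {p}")
    return {k: float(p[k]) for k in MAIN_PARAM_NAMES}


def mean_estimation_precision(est, true, weights: PrecisionWeights) -> float:
    """Weighted mean squared deviation over the four main parameters."""
    e, t, w = _main_vector(est), _main_vector(true), weights.as_dict()
    return float(np.mean([((e[k] - t[k]) / w[k]) ** 2 for k in MAIN_PARAM_NAMES]))


def fisher_z_mean(correlations) -> float:
    """Mean of Pearson correlations on the atanh scale, back-transformed.

    Coefficients with |r| = 1 are clamped just inside the open interval
    before the transform.
    """
    r = np.asarray(list(correlations), dtype=float)
    if r.size == 0:
        raise ValueError("need at least one correlation")
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(r))))


def _degenerate(x: np.ndarray) -> bool:
    # guards against fuzz-level variance in nominally constant estimates
    return float(np.std(x)) <= 1e-10 * max(1.0, float(np.max(np.abs(x))))


def parameter_correlations(true_params, est_params,
                           include_zr: bool = True) -> dict[str, float]:
    """Pearson r between true and estimated values per main parameter."""
    t = pd.DataFrame([_main_vector(p) for p in true_params])
    e = pd.DataFrame([_main_vector(p) for p in est_params])
    if len(t) < 3:
        raise ValueError("need at least 3 parameter sets per cell")
    names = [k for k in MAIN_PARAM_NAMES if include_zr or k != "zr"]
    out = {}
    for k in names:
        tv, ev = t[k].to_numpy(), e[k].to_numpy()
        if _degenerate(tv) or _degenerate(ev):
            out[k] = np.nan
        else:
            out[k] = float(np.corrcoef(tv, ev)[0, 1])
    return out


def fisher_z_mean_correlation(true_params, est_params,
                              include_zr: bool = True) -> float:
    """Fisher-Z mean correlation over the main parameters of one cell."""
    corrs = parameter_correlations(true_params, est_params, include_zr)
    return fisher_z_mean(corrs.values())


def bias(true_params, est_params) -> dict[str, float]:
    """Mean signed deviation (estimated - true) per main parameter."""
    t = pd.DataFrame([_main_vector(p) for p in true_params])
    e = pd.DataFrame([_main_vector(p) for p in est_params])
    return {k: float((e[k] - t[k]).mean()) for k in MAIN_PARAM_NAMES}


def precision_quantile(values, q: float = 0.95) -> float:
    """Empirical q-quantile (linear interpolation, "type 7") of precision
    values across parameter sets."""
    return float(np.quantile(np.asarray(list(values), dtype=float), q,
                             method="linear"))


def summarize_cell(true_params, est_params, weights: PrecisionWeights,
                   n_free: int = 7, q: float = 0.95) -> dict:
    """All evaluation measures for one design cell."""
    include_zr = n_free != 3
    corrs = parameter_correlations(true_params, est_params, include_zr)
    per_param_prec = {}
    w = weights.as_dict()
    t = pd.DataFrame([_main_vector(p) for p in true_params])
    e = pd.DataFrame([_main_vector(p) for p in est_params])
    for k in MAIN_PARAM_NAMES:
        dev = ((e[k] - t[k]) / w[k]) ** 2
        per_param_prec[k] = precision_quantile(dev, q)
    mep = [mean_estimation_precision(ep, tp, weights)
           for tp, ep in zip(true_params, est_params)]
    return {
        "corr": corrs,
        "fisher_z_mean_corr": fisher_z_mean(corrs.values()),
        "bias": bias(true_params, est_params),
        "precision_q": per_param_prec,
        "mep_q": precision_quantile(mep, q),
        "mep_median": float(np.median(mep)),
        "n_sets": len(t),
    }


def model_superiority(cell_stats: pd.DataFrame,
                      parameter: str | None = None) -> str:
    """Winning model labels "c/b/p" for one parameter cell.

    ``cell_stats`` must hold one row per model with columns ``model``,
    ``corr``, ``bias`` and ``precision_q``.  Winners: highest correlation,
    smallest absolute bias, smallest precision quantile.  Ties are
    reported jointly, comma-separated.  For the relative starting point
    the 3-parameter model is excluded (zr is fixed there).
    """
    df = cell_stats.copy()
    if parameter == "zr":
        df = df[df["model"] != 3]
    if df.empty:
        raise ValueError("no models to compare")

    def winners(series: pd.Series, minimize: bool) -> str:
        vals = series.to_numpy(dtype=float)
        best = np.nanmin(vals) if minimize else np.nanmax(vals)
        lab = df["model"][np.isclose(vals, best, rtol=0, atol=1e-12)]
        return ",".join(str(int(m)) for m in sorted(lab))

    return "/".join([winners(df["corr"], minimize=False),
                     winners(df["bias"].abs(), minimize=True),
                     winners(df["precision_q"], minimize=True)])


def retest_reliability(session1, session2, n_free: int = 7) -> dict:
    """Per-parameter Pearson r between two sessions and their Fisher-Z mean.

    ``session1`` / ``session2`` are paired per-subject parameter estimates
    (DiffusionParams or dicts); the drift enters as nu_total.  Parameters
    with zero variance in either session yield NaN (flagged by the caller).
    """
    if len(session1) != len(session2):
        raise ValueError("sessions must hold paired estimates")
    if len(session1) < 3:
        raise ValueError("need at least 3 subjects")
    s1 = pd.DataFrame([_main_vector(p) for p in session1])
    s2 = pd.DataFrame([_main_vector(p) for p in session2])
    names = [k for k in MAIN_PARAM_NAMES if n_free != 3 or k != "zr"]
    out: dict[str, float] = {}
    for k in names:
        a, b = s1[k].to_numpy(), s2[k].to_numpy()
        if _degenerate(a) or _degenerate(b):
            out[k] = np.nan
        else:
            out[k] = float(np.corrcoef(a, b)[0, 1])
    valid = [r for r in out.values() if np.isfinite(r)]
    out["mean_retest_reliability"] = fisher_z_mean(valid) if valid else np.nan
    return out
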