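"""Synthetic-data stage: parameter populations, trial generation,
contaminants, and the threshold-balance filter.

Two population styles are supported, mirroring how recovery studies in
this literature generate ground truth: independent uniform ranges per
parameter, and multivariate normal draws (with a configurable correlation
matrix) truncated to the parameter domain by redrawing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import wfpt
from .params import DiffusionParams, ParameterDomainError

__all__ = [
    "TrialData", "ParameterPopulation", "PopulationSpecError",
    "study1_population", "study2_population", "draw_parameter_sets",
    "simulate_trials", "inject_fast_contaminants", "inject_slow_contaminants",
    "threshold_balance_filter", "write_trials", "read_trials",
]

FLAG_NONE, FLAG_FAST, FLAG_SLOW = 0, 1, 2
_FLAG_NAMES = {FLAG_NONE: "none", FLAG_FAST: "fast", FLAG_SLOW: "slow"}


class PopulationSpecError(ValueError):
    """Raised for population specifications that cannot yield valid sets."""


# ---------------------------------------------------------------------------
# trial container and the fast-dm-style text format
# ---------------------------------------------------------------------------
@dataclass
class TrialData:
    """Per-trial records: response (0 = lower, 1 = upper), rt in seconds,
    optional stimulus type (two-drift designs) and contaminant flag."""

    response: np.ndarray
    rt: np.ndarray
    stimulus: np.ndarray | None = None
    flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=np.int8)
        self.rt = np.asarray(self.rt, dtype=float)
        if self.response.shape != self.rt.shape:
            raise ValueError("response and rt must have equal length")
        if self.stimulus is not None:
            self.stimulus = np.asarray(self.stimulus, dtype=np.int8)
        if self.flag is None:
            self.flag = np.zeros(self.rt.shape[0], dtype=np.int8)
        else:
            self.flag = np.asarray(self.flag, dtype=np.int8)

    @property
    def n(self) -> int:
        return self.rt.shape[0]

    def __len__(self) -> int:
        return self.n

    def copy(self) -> "TrialData":
        return TrialData(self.response.copy(), self.rt.copy(),
                         None if self.stimulus is None else self.stimulus.copy(),
                         self.flag.copy())

    def stim_codes(self) -> np.ndarray:
        if self.stimulus is None:
            return np.zeros(self.n, dtype=np.int8)
        return self.stimulus

    def to_frame(self) -> pd.DataFrame:
        d = {"response": self.response, "rt": self.rt,
             "flag": [_FLAG_NAMES[f] for f in self.flag]}
        if self.stimulus is not None:
            d["stimulus"] = self.stimulus
        return pd.DataFrame(d)


def write_trials(data: TrialData, path, extended: bool = False) -> None:
    """Write trials as whitespace-delimited text: ``response rt``.

    The extended dialect appends the contaminant flag (0/1/2) as a third
    column and, for two-drift data, the stimulus type as a fourth.
    """
    cols = [data.response.astype(int), np.round(data.rt, 6)]
    fmt = ["%d", "%.6f"]
    if extended:
        cols.append(data.flag.astype(int))
        fmt.append("%d")
        if data.stimulus is not None:
            cols.append(data.stimulus.astype(int))
            fmt.append("%d")
    np.savetxt(path, np.column_stack(cols), fmt=" ".join(fmt).split())


def read_trials(path) -> TrialData:
    """Read the fast-dm-style text format written by :func:`write_trials`."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 'response rt' columns")
    response = arr[:, 0].astype(np.int8)
    rt = arr[:, 1]
    flag = arr[:, 2].astype(np.int8) if arr.shape[1] >= 3 else None
    stim = arr[:, 3].astype(np.int8) if arr.shape[1] >= 4 else None
    return TrialData(response, rt, stim, flag)


# ---------------------------------------------------------------------------
# parameter populations
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ParameterPopulation:
    """Distributional spec of a ground-truth parameter population.

    ``spec`` maps parameter names (``a, v, t0, zr, sv, st0, szr`` for
    one-drift; ``v0``/``v1`` instead of ``v`` for two-drift designs) to
    either ``("uniform", lo, hi)`` or ``("normal", mean, sd)``.
    ``correlation`` (optional) applies to the normally distributed
    parameters, in the order they appear in ``spec``.
    """

    design: str  # "one_drift" | "two_drift"
    spec: tuple[tuple[str, tuple], ...]
    correlation: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.design not in ("one_drift", "two_drift"):
            raise PopulationSpecError(f"unknown design {self.design!r}")
        names = [n for n, _ in self.spec]
        want = {"one_drift": {"a", "v", "t0", "zr", "sv", "st0", "szr"},
                "two_drift": {"a", "v0", "v1", "t0", "zr", "sv", "st0", "szr"}}
        if set(names) != want[self.design]:
            raise PopulationSpecError(
                f"{self.design} population must specify {sorted(want[self.design])}, got {names}")
        self._check_uniform_feasibility()

    def _bounds(self, name: str) -> tuple[float, float]:
        d = dict(self.spec)[name]
        if d[0] == "uniform":
            return d[1], d[2]
        return -np.inf, np.inf

    def _check_uniform_feasibility(self) -> None:
        # worst-case combinations of uniform bounds must satisfy the domain
        kinds = {n: d[0] for n, d in self.spec}
        if any(k == "normal" for k in kinds.values()):
            return  # normals are redrawn, not range-checked
        zr_lo, zr_hi = self._bounds("zr")
        szr_lo, szr_hi = self._bounds("szr")
        t0_lo, _ = self._bounds("t0")
        st0_lo, st0_hi = self._bounds("st0")
        a_lo, _ = self._bounds("a")
        if a_lo <= 0:
            raise PopulationSpecError("threshold-separation range must be positive")
        if zr_lo - szr_hi / 2 <= 0 or zr_hi + szr_hi / 2 >= 1:
            raise PopulationSpecError("zr range incompatible with szr range")
        if t0_lo - st0_hi / 2 < 0:
            raise PopulationSpecError("t0 range incompatible with st0 range")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.spec]


# Ground-truth generating conditions of the two study designs: uniform
# ranges for the recovery study, multivariate normals (empirical means/SDs
# of a lexical-decision and a recognition-memory task) for the retest
# simulation.  The two-drift recovery design draws its drifts from normals
# with means -2.35 / 2.00 (difference of magnitudes 0.35) and SD 1.0.
_STUDY1_COMMON = (
    ("a", ("uniform", 0.5, 2.0)),
    ("t0", ("uniform", 0.2, 0.5)),
    ("zr", ("uniform", 0.3, 0.7)),
    ("sv", ("uniform", 0.0, 1.0)),
    ("st0", ("uniform", 0.0, 0.2)),
    ("szr", ("uniform", 0.0, 0.5)),
)

_STUDY2 = {
    "ldt": (("a", ("normal", 1.42, 0.32)), ("v0", ("normal", -4.01, 1.13)),
            ("v1", ("normal", 3.10, 1.11)), ("t0", ("normal", 0.48, 0.04)),
            ("zr", ("normal", 0.53, 0.06)), ("sv", ("normal", 1.34, 0.64)),
            ("st0", ("normal", 0.15, 0.05)), ("szr", ("normal", 0.37, 0.25))),
    "rmt": (("a", ("normal", 1.60, 0.36)), ("v0", ("normal", -3.07, 1.14)),
            ("v1", ("normal", 2.44, 1.20)), ("t0", ("normal", 0.61, 0.05)),
            ("zr", ("normal", 0.55, 0.08)), ("sv", ("normal", 1.41, 0.83)),
            ("st0", ("normal", 0.17, 0.08)), ("szr", ("normal", 0.15, 0.22))),
}


def study1_population(design: str = "one_drift") -> ParameterPopulation:
    """Uniform-range population of the recovery study (Table-1 ranges)."""
    if design == "one_drift":
        spec = (("v", ("uniform", -4.0, 4.0)),) + _STUDY1_COMMON
    else:
        spec = (("v0", ("normal", -2.35, 1.0)), ("v1", ("normal", 2.00, 1.0))) + _STUDY1_COMMON
    return ParameterPopulation(design, spec)


def study2_population(task: str = "ldt",
                      correlation: np.ndarray | None = None) -> ParameterPopulation:
    """Multivariate-normal population fitted to empirical task data.

    ``correlation`` defaults to the identity (independent parameters); the
    empirical correlation structure can be supplied as an 8x8 matrix in
    spec order.
    """
    if task not in _STUDY2:
        raise PopulationSpecError(f"unknown task {task!r}; use 'ldt' or 'rmt'")
    corr = None if correlation is None else tuple(map(tuple, np.asarray(correlation)))
    return ParameterPopulation("two_drift", _STUDY2[task], corr)


def _valid_row(row: dict[str, float], design: str) -> bool:
    try:
        if design == "two_drift":
            DiffusionParams(row["a"], row["v0"], row["t0"], row["zr"],
                            row["sv"], row["st0"], row["szr"], v1=row["v1"])
        else:
            DiffusionParams(row["a"], row["v"], row["t0"], row["zr"],
                            row["sv"], row["st0"], row["szr"])
        return True
    except ParameterDomainError:
        return False


def draw_parameter_sets(pop: ParameterPopulation, n_sets: int,
                        seed=None) -> list[DiffusionParams]:
    """Draw ``n_sets`` valid parameter sets from a population.

    Normal draws falling outside the parameter domain are redrawn;
    uniform bounds were validated as feasible up front.
    """
    rng = np.random.default_rng(seed)
    names = pop.names
    normal_idx = [i for i, (_, d) in enumerate(pop.spec) if d[0] == "normal"]
    if pop.correlation is not None:
        corr = np.asarray(pop.correlation, dtype=float)
        if corr.shape != (len(normal_idx), len(normal_idx)):
            raise PopulationSpecError(
                f"correlation matrix must be {len(normal_idx)}x{len(normal_idx)}")
        chol = np.linalg.cholesky(corr)
    else:
        chol = None

    def draw_block(m: int) -> np.ndarray:
        cols = np.empty((m, len(names)))
        z = rng.standard_normal((m, len(normal_idx))) if normal_idx else None
        if chol is not None and z is not None:
            z = z @ chol.T
        zi = 0
        for j, (_, d) in enumerate(pop.spec):
            if d[0] == "uniform":
                cols[:, j] = rng.uniform(d[1], d[2], size=m)
            else:
                cols[:, j] = d[1] + d[2] * z[:, zi]
                zi += 1
        return cols

    out: list[DiffusionParams] = []
    attempts = 0
    while len(out) < n_sets:
        attempts += 1
        if attempts > 1000:
            raise PopulationSpecError(
                "could not draw valid parameter sets; population mass lies "
                "almost entirely outside the parameter domain")
        block = draw_block(n_sets - len(out))
        for rowvals in block:
            row = dict(zip(names, rowvals))
            if not _valid_row(row, pop.design):
                continue
            if pop.design == "two_drift":
                out.append(DiffusionParams(row["a"], row["v0"], row["t0"], row["zr"],
                                           row["sv"], row["st0"], row["szr"],
                                           v1=row["v1"]))
            else:
                out.append(DiffusionParams(row["a"], row["v"], row["t0"], row["zr"],
                                           row["sv"], row["st0"], row["szr"]))
    return out


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------
def simulate_trials(p: DiffusionParams, n_trials: int, seed=None) -> TrialData:
    """Generate ``n_trials`` (response, rt) pairs by exact sampling.

    Per trial the drift, relative start and non-decision time are drawn
    from their intertrial distributions, the boundary from the exact
    absorption probability, and the decision time by inverse-CDF sampling
    of the basic first-passage distribution.  Two-drift parameter sets
    interleave the two stimulus types in (as close as possible) equal
    numbers.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)

    def block(v: float, m: int) -> tuple[np.ndarray, np.ndarray]:
        return wfpt.sample_fpt(p.a, v, p.t0, p.zr, p.sv, p.st0, p.szr,
                               rng.standard_normal(m), rng.random(m),
                               rng.random(m), rng.random(m), rng.random(m))

    if not p.is_two_drift:
        resp, rts = block(p.v, n_trials)
        return TrialData(resp, rts)

    stimulus = np.arange(n_trials, dtype=np.int8) % 2  # interleave 0,1,0,1,...
    n0 = int(np.sum(stimulus == 0))
    r0, t0_ = block(p.v, n0)
    r1, t1_ = block(p.v1, n_trials - n0)
    resp = np.empty(n_trials, dtype=np.int8)
    rts = np.empty(n_trials)
    resp[stimulus == 0], rts[stimulus == 0] = r0, t0_
    resp[stimulus == 1], rts[stimulus == 1] = r1, t1_
    return TrialData(resp, rts, stimulus)


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------
def _n_contaminants(n: int, rate: float) -> int:
    if not (0 <= rate < 1):
        raise ValueError(f"contamination rate {rate} must be in [0, 1)")
    return int(round(rate * n))


def inject_fast_contaminants(data: TrialData, p: DiffusionParams,
                             rate: float = 0.04, seed=None) -> TrialData:
    """Replace a random ``rate`` share of trials by fast guesses.

    Selected trials get a Bernoulli(0.5) response and an RT drawn
    uniformly from ``t_min - 100 ms`` to ``t_min + 100 ms`` (truncated
    below at zero), with ``t_min = t0 - st0/2`` of the generating
    parameters.
    """
    out = data.copy()
    k = _n_contaminants(data.n, rate)
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(data.n, size=k, replace=False)
    t_min = p.t_min
    lo, hi = max(0.0, t_min - 0.1), t_min + 0.1
    out.response[idx] = (rng.random(k) < 0.5).astype(np.int8)
    out.rt[idx] = rng.uniform(lo, hi, size=k)
    out.flag[idx] = FLAG_FAST
    return out


def inject_slow_contaminants(data: TrialData, rate: float = 0.04,
                             seed=None) -> TrialData:
    """Replace a random ``rate`` share of RTs by slow outliers.

    Replacement values lie uniformly between 1.5 and 5 interquartile
    ranges above the third quartile of the pre-replacement RT
    distribution; responses are left unchanged.
    """
    if data.n < 4:
        raise ValueError("slow contamination needs at least 4 trials for quartiles")
    out = data.copy()
    k = _n_contaminants(data.n, rate)
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(data.n, size=k, replace=False)
    q1, q3 = np.quantile(data.rt, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("degenerate RT distribution (IQR = 0); slow contaminants "
                      "collapse to a constant above Q3", stacklevel=2)
    out.rt[idx] = rng.uniform(q3 + 1.5 * iqr, q3 + 5.0 * iqr, size=k)
    out.flag[idx] = FLAG_SLOW
    return out


def apply_contamination(data: TrialData, kind: str, p: DiffusionParams,
                        rate: float = 0.04, seed=None) -> TrialData:
    if kind == "none":
        return data.copy()
    if kind == "fast":
        return inject_fast_contaminants(data, p, rate, seed)
    if kind == "slow":
        return inject_slow_contaminants(data, rate, seed)
    raise ValueError(f"unknown contamination kind {kind!r}")


def threshold_balance_filter(data: TrialData, min_frac: float = 0.04) -> bool:
    """True iff both response categories hold at least ``min_frac`` of trials."""
    n_upper = int(np.sum(data.response == 1))
    n_lower = data.n - n_upper
    need = min_frac * data.n
    return n_upper >= need and n_lower >= need
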