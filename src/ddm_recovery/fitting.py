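"""Diffusion-model parameter estimation.

Fitting minimizes one of the three objectives (ML / KS / CS) with
Nelder-Mead on a transformed unconstrained space (log scale for a, t0,
sv, st0; logit for zr and for szr as a fraction of its feasible width),
from a data-driven start (EZ-style moment inversion for a, v, t0) plus
perturbed restarts.

Model complexity is expressed by nested specifications: the 7-parameter
model frees everything; the 5-parameter model fixes sv = szr = 0; the
4-parameter (basic) model additionally fixes st0 = 0; the 3-parameter
model additionally fixes zr = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .objectives import DENSITY_FLOOR, Objective
from .params import DiffusionParams
from .simulate import TrialData

__all__ = ["ModelSpec", "InitStrategy", "FitResult", "DiffusionFitter", "fit"]

_FIXATIONS: dict[int, dict[str, float]] = {
    7: {},
    5: {"sv": 0.0, "szr": 0.0},
    4: {"sv": 0.0, "szr": 0.0, "st0": 0.0},
    3: {"sv": 0.0, "szr": 0.0, "st0": 0.0, "zr": 0.5},
}

# starting values for the intertrial variabilities (sv, szr, st0); the
# "default" triple matches the fast-dm defaults, the alternatives are the
# robustness series (zeros / half the generating maxima / the maxima)
_VAR_STARTS: dict[str, tuple[float, float, float]] = {
    "default": (0.5, 0.3, 0.2),
    "zeros": (1e-3, 1e-3, 1e-3),
    "half_max": (0.5, 0.25, 0.1),
    "max": (1.0, 0.5, 0.2),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free and which are fixed, plus drift design."""

    n_free: int = 7
    drift_design: str = "one_drift"

    def __post_init__(self) -> None:
        if self.n_free not in _FIXATIONS:
            raise ValueError(f"n_free must be one of {sorted(_FIXATIONS)}")
        if self.drift_design not in ("one_drift", "two_drift"):
            raise ValueError(f"unknown drift design {self.drift_design!r}")

    @property
    def fixed(self) -> dict[str, float]:
        return dict(_FIXATIONS[self.n_free])

    @property
    def free_names(self) -> list[str]:
        base = ["a", "v", "t0", "zr", "sv", "st0", "szr"]
        if self.drift_design == "two_drift":
            base.insert(1, "v1")
        return [n for n in base if n not in self.fixed]


@dataclass(frozen=True)
class InitStrategy:
    """Starting-point policy: data-driven starts for a, v, t0 (and zr at
    the midline) plus one of four series of variability starting values."""

    variability_start: str = "default"

    def __post_init__(self) -> None:
        if self.variability_start not in _VAR_STARTS:
            raise ValueError(
                f"variability_start must be one of {sorted(_VAR_STARTS)}")

    @property
    def variability_values(self) -> tuple[float, float, float]:
        return _VAR_STARTS[self.variability_start]


@dataclass
class FitResult:
    """Outcome of one model fit."""

    params: DiffusionParams
    objective: float
    criterion: str
    spec: ModelSpec
    converged: bool
    n_iter: int
    n_restarts: int
    start: DiffusionParams | None = None


# ---------------------------------------------------------------------------
# parameter transform
# ---------------------------------------------------------------------------
class _Transform:
    """Bijection between free parameters and an unconstrained vector."""

    _PERTURB = {"a": 0.3, "v": 0.5, "v1": 0.5, "t0": 0.15, "zr": 0.5,
                "sv": 0.5, "st0": 0.5, "szr": 0.5}

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.names = spec.free_names
        self.fixed = spec.fixed

    @property
    def ndim(self) -> int:
        return len(self.names)

    def perturb_scales(self) -> np.ndarray:
        return np.array([self._PERTURB[n] for n in self.names])

    def encode(self, values: dict[str, float]) -> np.ndarray:
        x = np.empty(self.ndim)
        zr = values.get("zr", self.fixed.get("zr", 0.5))
        for i, n in enumerate(self.names):
            val = values[n]
            if n in ("a", "t0", "sv", "st0"):
                x[i] = math.log(max(val, 1e-6))
            elif n == "zr":
                x[i] = logit(min(max(val, 1e-9), 1 - 1e-9))
            elif n == "szr":
                width = 2.0 * min(zr, 1.0 - zr)
                frac = min(max(val / width, 1e-9), 1 - 1e-9)
                x[i] = logit(frac)
            else:  # drifts, untransformed
                x[i] = val
        return x

    def decode(self, x: np.ndarray) -> tuple[DiffusionParams, float]:
        """Map a free vector to a valid parameter set plus a penalty for
        any clipped domain violation (t0 < st0 / 2)."""
        vals = dict(self.fixed)
        raw: dict[str, float] = {}
        for i, n in enumerate(self.names):
            xi = float(np.clip(x[i], -30.0, 30.0))
            if n in ("a", "t0", "sv", "st0"):
                raw[n] = math.exp(xi)
            elif n in ("zr", "szr"):
                raw[n] = float(np.clip(expit(xi), 1e-12, 1 - 1e-12))
            else:
                raw[n] = float(np.clip(xi, -100.0, 100.0))
        vals.update(raw)
        penalty = 0.0
        if "szr" in raw:  # stored as fraction of the feasible width
            width = 2.0 * min(vals["zr"], 1.0 - vals["zr"])
            vals["szr"] = raw["szr"] * width * (1 - 1e-9)
        if vals.get("st0", 0.0) > 2.0 * vals["t0"]:
            excess = vals["st0"] - 2.0 * vals["t0"]
            penalty = 100.0 * excess
            vals["st0"] = 2.0 * vals["t0"] * (1 - 1e-12)
        v1 = vals.pop("v1", None)
        p = DiffusionParams(vals["a"], vals["v"], vals["t0"], vals["zr"],
                            vals["sv"], vals["st0"], vals["szr"], v1=v1)
        return p, penalty


# ---------------------------------------------------------------------------
# data-driven starting values (EZ-style moment inversion)
# ---------------------------------------------------------------------------
def _ez_point(pc: float, mrt: float, vrt: float, min_rt: float):
    """Closed-form moment inversion for (a, v, t0) with unit diffusion."""
    pc = float(np.clip(pc, 0.001, 0.999))
    fallback_t0 = float(np.clip(0.9 * min_rt, 0.025, mrt))
    if abs(pc - 0.5) < 1e-3 or vrt <= 0:
        a = float(np.clip(math.sqrt(4.0 * max(mrt - fallback_t0, 0.02)), 0.4, 3.0))
        return a, 0.0, fallback_t0
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc * pc - L * pc + pc - 0.5) / vrt
    if x <= 0:
        a = float(np.clip(math.sqrt(4.0 * max(mrt - fallback_t0, 0.02)), 0.4, 3.0))
        return a, 0.0, fallback_t0
    v = math.copysign(x ** 0.25, pc - 0.5)
    a = float(np.clip(L / v, 0.3, 3.5))
    v = float(np.clip(v, -5.0, 5.0))
    y = -v * a
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    t0 = mrt - mdt
    t0 = float(np.clip(t0, 0.025, max(0.95 * min_rt, 0.03)))
    return a, v, t0


def data_driven_starts(data: TrialData, spec: ModelSpec,
                       init: InitStrategy) -> dict[str, float]:
    sv0, szr0, st00 = init.variability_values
    stim = data.stim_codes()
    if spec.drift_design == "two_drift" and np.any(stim == 1):
        parts = []
        for s in (0, 1):
            sel = stim == s
            rt = data.rt[sel]
            parts.append(_ez_point(float(np.mean(data.response[sel])),
                                   float(np.mean(rt)), float(np.var(rt)),
                                   float(np.min(rt))))
        a = 0.5 * (parts[0][0] + parts[1][0])
        t0 = 0.5 * (parts[0][2] + parts[1][2])
        starts = {"a": a, "v": parts[0][1], "v1": parts[1][1], "t0": t0}
    else:
        a, v, t0 = _ez_point(float(np.mean(data.response)),
                             float(np.mean(data.rt)), float(np.var(data.rt)),
                             float(np.min(data.rt)))
        starts = {"a": a, "v": v, "t0": t0}
        if spec.drift_design == "two_drift":
            starts["v1"] = -v
    starts.update({"zr": 0.5, "sv": sv0, "szr": min(szr0, 0.49),
                   "st0": min(st00, 1.8 * starts["t0"])})
    return starts


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------
class DiffusionFitter(BaseEstimator):
    """Scikit-learn style estimator fitting diffusion parameters to trials.

    Parameters
    ----------
    n_free : {3, 4, 5, 7}
        Model complexity (nested fixations, see module docstring).
    criterion : {"ml", "ks", "cs"}
        Optimization criterion.
    drift_design : {"one_drift", "two_drift"}
        Whether one drift or two stimulus-specific drifts are estimated.
    init : str or InitStrategy
        Variability starting-value series ("default", "zeros", "half_max",
        "max").
    n_restarts : int
        Total Nelder-Mead starts (the data-driven start plus perturbed
        restarts).
    tol : float
        Nelder-Mead xatol/fatol convergence tolerance.
    maxfev_factor, restart_maxfev_factor : int
        Function-evaluation budget per dimension for the first start and
        for each restart.
    n_gl : int
        Gauss-Legendre nodes for the intertrial uniforms.
    ml_mode : {"auto", "exact", "grid"}
        ML density evaluation path (see :class:`Objective`).
    random_state : int or None
        Seed for restart perturbations.

    Attributes
    ----------
    params_ : DiffusionParams
        Estimated parameters (fixed entries exactly at their fixation).
    result_ : FitResult
    objective_ : float
    converged_ : bool
    n_iter_ : int
        Total objective evaluations across starts.
    """

    def __init__(self, n_free: int = 7, criterion: str = "ml",
                 drift_design: str = "one_drift", init: str = "default",
                 n_restarts: int = 3, tol: float = 1e-4,
                 maxfev_factor: int = 150, restart_maxfev_factor: int = 80,
                 n_gl: int = 11, grid_size: int = 385,
                 floor: float = DENSITY_FLOOR, ml_mode: str = "auto",
                 random_state=None):
        self.n_free = n_free
        self.criterion = criterion
        self.drift_design = drift_design
        self.init = init
        self.n_restarts = n_restarts
        self.tol = tol
        self.maxfev_factor = maxfev_factor
        self.restart_maxfev_factor = restart_maxfev_factor
        self.n_gl = n_gl
        self.grid_size = grid_size
        self.floor = floor
        self.ml_mode = ml_mode
        self.random_state = random_state

    # -- data coercion ----------------------------------------------------
    @staticmethod
    def _as_trialdata(X) -> TrialData:
        if isinstance(X, TrialData):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("X must be TrialData or an (n, 2+) array of "
                             "(response, rt[, stimulus]) rows")
        stim = arr[:, 2].astype(np.int8) if arr.shape[1] >= 3 else None
        return TrialData(arr[:, 0].astype(np.int8), arr[:, 1], stim)

    def _spec(self) -> ModelSpec:
        return ModelSpec(self.n_free, self.drift_design)

    def fit(self, X, y=None, extra_starts=()):
        """Fit the model to trial data.

        ``extra_starts`` may hold additional DiffusionParams used as warm
        starts (e.g. the optimum of a nested model)."""
        data = self._as_trialdata(X)
        spec = self._spec()
        init = self.init if isinstance(self.init, InitStrategy) else InitStrategy(self.init)
        objective = Objective(data, self.criterion, n_gl=self.n_gl,
                              grid_size=self.grid_size, floor=self.floor,
                              ml_mode=self.ml_mode)
        transform = _Transform(spec)
        rng = np.random.default_rng(self.random_state)

        def penalized(x: np.ndarray) -> float:
            p, pen = transform.decode(x)
            return objective(p) + pen

        starts_dict = data_driven_starts(data, spec, init)
        x0 = transform.encode(starts_dict)
        ndim = transform.ndim
        scales = transform.perturb_scales()

        starts = [(x0, self.maxfev_factor * ndim)]
        for _ in range(max(self.n_restarts - 1, 0)):
            starts.append((x0 + rng.normal(0.0, scales),
                           self.restart_maxfev_factor * ndim))
        for p_extra in extra_starts:
            vals = {n: getattr(p_extra, n) for n in transform.names}
            starts.append((transform.encode(vals),
                           self.restart_maxfev_factor * ndim))

        best = None
        n_iter = 0
        for x_start, maxfev in starts:
            res = minimize(penalized, x_start, method="Nelder-Mead",
                           options={"xatol": self.tol, "fatol": self.tol,
                                    "maxfev": maxfev, "adaptive": ndim > 4})
            n_iter += res.nfev
            if best is None or res.fun < best.fun:
                best = res

        params, _ = transform.decode(best.x)
        start_params, _ = transform.decode(x0)
        self.result_ = FitResult(params=params, objective=float(best.fun),
                                 criterion=self.criterion, spec=spec,
                                 converged=bool(best.success), n_iter=n_iter,
                                 n_restarts=len(starts), start=start_params)
        self.params_ = params
        self.objective_ = float(best.fun)
        self.converged_ = bool(best.success)
        self.n_iter_ = n_iter
        return self

    def score(self, X, y=None) -> float:
        """Negative criterion value of the fitted parameters on ``X``."""
        if not hasattr(self, "params_"):
            raise AttributeError("fit the estimator before scoring")
        data = self._as_trialdata(X)
        objective = Objective(data, self.criterion, n_gl=self.n_gl,
                              grid_size=self.grid_size, floor=self.floor,
                              ml_mode=self.ml_mode)
        return -objective(self.params_)


def fit(data: TrialData, spec: ModelSpec | int = 7, criterion: str = "ml",
        init: InitStrategy | str = "default", seed=None,
        extra_starts=(), **kwargs) -> FitResult:
    """Thin functional wrapper around :class:`DiffusionFitter`."""
    if isinstance(spec, int):
        spec = ModelSpec(spec)
    fitter = DiffusionFitter(n_free=spec.n_free, drift_design=spec.drift_design,
                             criterion=criterion, init=init, random_state=seed,
                             **kwargs)
    fitter.fit(data, extra_starts=extra_starts)
    return fitter.result_
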