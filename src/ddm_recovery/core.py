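"""First-passage-time density, CDF and response probabilities.

Public surface of the numerical engine.  All functions take decision data
on the response-time scale (seconds); boundaries are named ``"upper"`` and
``"lower"``.

With intertrial variabilities the drift integral is handled in closed
form for the density; the starting-point and non-decision-time uniforms
use Gauss-Legendre quadrature.  The CDF uses exact series when the drift
does not vary (``sv == 0``) and otherwise cumulative integration of the
density on a cached graded grid, with the non-decision-time uniform
applied as a shifted-interpolation mixture.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import wfpt
from .params import BasicParams, DiffusionParams

__all__ = ["response_probability", "fpt_density", "fpt_cdf", "FirstPassage"]

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def gauss_hermite_prob(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for averaging over a standard normal variable."""
    if n not in _GH_CACHE:
        x, w = np.polynomial.hermite.hermgauss(n)
        _GH_CACHE[n] = (x * math.sqrt(2.0), w / math.sqrt(math.pi))
    return _GH_CACHE[n]


def _boundary_code(boundary: str) -> int:
    if boundary in ("upper", 1):
        return 1
    if boundary in ("lower", 0):
        return 0
    raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def _as_diffusion(p: BasicParams | DiffusionParams) -> DiffusionParams:
    if isinstance(p, BasicParams):
        return DiffusionParams(p.a, p.v, p.t0, p.zr)
    return p


class FirstPassage:
    """Cached evaluator of the FPT distribution for one parameter set.

    Parameters
    ----------
    params : DiffusionParams
        Model parameters; for two-drift sets pass the drift of interest via
        ``drift`` ("lower" uses ``params.v``, "upper" uses ``params.v1``).
    n_gl : int
        Gauss-Legendre nodes for the szr / st0 uniforms (default 11).
    n_gh : int
        Gauss-Hermite nodes for drift averaging where no closed form exists
        (marginal probabilities, series CDF with sv > 0; default 11).
    eps : float
        Absolute truncation error of the density series.
    grid_size : int
        Number of points of the graded CDF grid (sv > 0 path).
    """

    def __init__(self, params: DiffusionParams, *, drift_value: float | None = None,
                 n_gl: int = 11, n_gh: int = 11, eps: float = 1e-7,
                 grid_size: int = 513):
        self.p = params
        self.v = params.v if drift_value is None else drift_value
        self.n_gl = n_gl
        self.n_gh = n_gh
        self.eps = eps
        self.grid_size = grid_size
        self.glx, self.glw = gauss_legendre(n_gl)
        if params.sv > 0:
            ghx, ghw = gauss_hermite_prob(n_gh)
            self.sv_nodes = self.v + params.sv * ghx
            self.sv_w = ghw
        else:
            self.sv_nodes = np.array([self.v])
            self.sv_w = np.array([1.0])
        self._probs: tuple[float, float] | None = None
        self._grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._grid_tdmax = 0.0

    # -- marginal response probabilities --------------------------------
    def prob(self, boundary) -> float:
        if self._probs is None:
            p = self.p
            pl = wfpt.prob_lower_mix(1.0, p.a, p.zr, self.sv_nodes, self.sv_w,
                                     p.szr, self.glx, self.glw)
            self._probs = (pl, 1.0 - pl)
        return self._probs[_boundary_code(boundary)]

    # -- density ---------------------------------------------------------
    def density(self, t, boundary) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite time passed to fpt density")
        p = self.p
        responses = np.full(t.shape[0], _boundary_code(boundary), dtype=np.int8)
        stim = np.zeros(t.shape[0], dtype=np.int8)
        return wfpt.density_joint(t, responses, self.v, self.v, stim, p.a, p.t0,
                                  p.zr, p.sv, p.st0, p.szr, self.glx, self.glw,
                                  self.eps)

    def density_joint(self, rts, responses, stim=None) -> np.ndarray:
        """Defective joint density of observed (response, rt) trials."""
        p = self.p
        rts = np.asarray(rts, dtype=float)
        responses = np.asarray(responses, dtype=np.int8)
        if stim is None:
            stim = np.zeros(rts.shape[0], dtype=np.int8)
        vhi = self.p.v1 if self.p.is_two_drift else self.v
        return wfpt.density_joint(rts, responses, self.v, vhi, stim, p.a, p.t0,
                                  p.zr, p.sv, p.st0, p.szr, self.glx, self.glw,
                                  self.eps)

    # -- CDF --------------------------------------------------------------
    def cdf(self, t, boundary) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite time passed to fpt cdf")
        p = self.p
        code = _boundary_code(boundary)
        if p.sv == 0:
            return wfpt.cdf_basic_mix(t, code, self.v, p.a, p.t0, p.zr,
                                      self.sv_nodes, self.sv_w, p.st0, p.szr,
                                      self.glx, self.glw, min(self.eps, 1e-8))
        return self._cdf_from_grid(t, code)

    # grid machinery (sv > 0): densities without st0 on a graded decision-
    # time grid, cumulative-trapezoid, then st0 as a mixture of shifts.
    def _ensure_grid(self, tdmax_needed: float) -> None:
        if self._grid is not None and self._grid_tdmax >= tdmax_needed:
            return
        p = self.p
        # horizon where the residual tail is negligible even for zero drift
        td_tail = 2.0 * p.a ** 2 / math.pi ** 2 * math.log(1e8)
        tdmax = max(tdmax_needed, td_tail, 1.0)
        s = np.linspace(0.0, 1.0, self.grid_size)
        td = tdmax * s ** 2
        gl = wfpt.density_grid_boundary(td, 0, self.v, p.a, p.zr, p.sv, p.szr,
                                        self.glx, self.glw, self.eps)
        gu = wfpt.density_grid_boundary(td, 1, self.v, p.a, p.zr, p.sv, p.szr,
                                        self.glx, self.glw, self.eps)
        Fl = cumulative_trapezoid(gl, td, initial=0.0)
        Fu = cumulative_trapezoid(gu, td, initial=0.0)
        self._grid = (td, Fl, Fu)
        self._grid_tdmax = tdmax

    def _cdf_from_grid(self, t: np.ndarray, code: int) -> np.ndarray:
        p = self.p
        if p.st0 > 0:
            t0_nodes = p.t0 + 0.5 * p.st0 * self.glx
            t0_w = 0.5 * self.glw
        else:
            t0_nodes = np.array([p.t0])
            t0_w = np.array([1.0])
        tdmax_needed = max(float(np.max(t)) - float(np.min(t0_nodes)), 0.0)
        self._ensure_grid(tdmax_needed)
        td, Fl, Fu = self._grid
        F0 = Fu if code == 1 else Fl
        out = np.zeros_like(t)
        for w_j, t0_j in zip(t0_w, t0_nodes):
            out += w_j * np.interp(t - t0_j, td, F0, left=0.0, right=F0[-1])
        return out


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------
def response_probability(p: BasicParams | DiffusionParams, boundary: str = "upper",
                         **kwargs) -> float:
    """Probability that the process is absorbed at ``boundary``.

    For a basic parameter set this is the closed form
    ``P(upper) = (1 - exp(-2 v a zr)) / (1 - exp(-2 v a))``; with
    intertrial variabilities the probability is averaged over the drift
    and starting-point distributions by quadrature.
    """
    dp = _as_diffusion(p)
    if dp.sv == 0 and dp.szr == 0:
        pl = wfpt.prob_lower(dp.v * dp.a, dp.zr)
        return 1.0 - pl if _boundary_code(boundary) == 1 else pl
    return FirstPassage(dp, **kwargs).prob(boundary)


def fpt_density(t, boundary, p: DiffusionParams, **kwargs):
    """Defective first-passage-time density (per second) at time(s) ``t``."""
    out = FirstPassage(_as_diffusion(p), **kwargs).density(t, boundary)
    return out if np.ndim(t) else float(out[0])


def fpt_cdf(t, boundary, p: DiffusionParams, **kwargs):
    """Defective first-passage-time CDF at time(s) ``t``."""
    out = FirstPassage(_as_diffusion(p), **kwargs).cdf(t, boundary)
    return out if np.ndim(t) else float(out[0])
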