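"""Optimization criteria: maximum likelihood (ML), Kolmogorov-Smirnov (KS)
and chi-square (CS) objectives for diffusion-model fitting.

All three are exposed both as plain functions of (data, params) and as a
reusable :class:`Objective` that precomputes the data-dependent pieces
(sorted signed RTs, chi-square bin edges) once per dataset, which is what
the optimizer loops over.
"""

from __future__ import annotations

import numpy as np

from .core import FirstPassage, gauss_hermite_prob, gauss_legendre
from .params import DiffusionParams
from .simulate import TrialData

__all__ = ["Objective", "negative_log_likelihood", "ks_statistic",
           "chi_square_statistic"]

DENSITY_FLOOR = 1e-10  # per-trial likelihood floor; keeps ML finite for
                       # contaminant RTs outside the predicted support


def _split_by_stimulus(data: TrialData) -> list[np.ndarray]:
    stim = data.stim_codes()
    if np.all(stim == 0):
        return [np.arange(data.n)]
    return [np.flatnonzero(stim == s) for s in (0, 1)]


class Objective:
    """Criterion value as a function of parameters, for one dataset.

    Parameters
    ----------
    data : TrialData
    criterion : {"ml", "ks", "cs"}
    n_gl, n_gh, eps, grid_size : numerical-accuracy knobs passed through to
        the first-passage evaluator.
    floor : float
        ML per-trial density floor.
    ml_mode : {"auto", "exact", "grid"}
        Whether the ML density is evaluated trial-by-trial through the
        quadrature ("exact") or interpolated from a cached graded grid
        ("grid"; used automatically when the trial x quadrature-node count
        makes the exact path wasteful).
    """

    def __init__(self, data: TrialData, criterion: str = "ml", *,
                 n_gl: int = 11, n_gh: int = 11, eps: float = 1e-7,
                 grid_size: int = 385, floor: float = DENSITY_FLOOR,
                 ml_mode: str = "auto", cs_min_count: int = 12,
                 cs_quantiles=(0.1, 0.3, 0.5, 0.7, 0.9)):
        if criterion not in ("ml", "ks", "cs"):
            raise ValueError(f"unknown criterion {criterion!r}")
        if data.n < 1:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(data.rt)) or np.any(data.rt <= 0):
            raise ValueError("all response times must be finite and positive")
        self.data = data
        self.criterion = criterion
        self.n_gl, self.n_gh, self.eps = n_gl, n_gh, eps
        self.grid_size = grid_size
        self.floor = floor
        self.ml_mode = ml_mode
        self.cs_min_count = cs_min_count
        self.pooled = False  # set when a sparse response category was pooled
        self._stim_idx = _split_by_stimulus(data)

        if criterion == "ks":
            self._ks_prep()
        elif criterion == "cs":
            self._cs_prep(cs_quantiles)

    # -- shared helpers ---------------------------------------------------
    def _evaluators(self, p: DiffusionParams) -> list[FirstPassage]:
        kw = dict(n_gl=self.n_gl, n_gh=self.n_gh, eps=self.eps,
                  grid_size=self.grid_size)
        if len(self._stim_idx) == 1:
            return [FirstPassage(p, **kw)]
        if not p.is_two_drift:
            raise ValueError("two-stimulus data require a two-drift parameter set")
        return [FirstPassage(p, drift_value=p.v, **kw),
                FirstPassage(p, drift_value=p.v1, **kw)]

    # -- ML ---------------------------------------------------------------
    def _nll(self, p: DiffusionParams) -> float:
        from . import wfpt
        d = self.data
        nodes = (self.n_gl if p.szr > 0 else 1) * (self.n_gl if p.st0 > 0 else 1)
        use_grid = self.ml_mode == "grid" or (
            self.ml_mode == "auto" and nodes > 1 and d.n * nodes > 4000)
        if not use_grid:
            fp = FirstPassage(p, n_gl=self.n_gl, n_gh=self.n_gh, eps=self.eps)
            dens = fp.density_joint(d.rt, d.response, d.stim_codes())
            return float(-np.sum(np.log(np.maximum(dens, self.floor))))
        glx, glw = gauss_legendre(self.n_gl)
        drifts = [p.v, p.v1] if p.is_two_drift else [p.v]
        nll = 0.0
        for idx, v in zip(self._stim_idx, drifts):
            rts = d.rt[idx]
            tdmax, grid_l, grid_u = self._grids(p, v, float(rts.max()))
            nll += wfpt.nll_from_grids(rts, d.response[idx], tdmax, grid_l,
                                       grid_u, p.t0, p.st0, glx, glw,
                                       self.floor)
        return float(nll)

    def _grids(self, p: DiffusionParams, v: float, rt_max: float,
               cumulative: bool = False):
        """Graded decision-time grids of the density (optionally CDF) for
        both boundaries, st0 excluded (applied later as a shift mixture)."""
        from . import wfpt
        from scipy.integrate import cumulative_trapezoid
        glx, glw = gauss_legendre(self.n_gl)
        tdmax = max(rt_max - (p.t0 - p.st0 / 2), 0.05)
        td = tdmax * np.linspace(0.0, 1.0, self.grid_size) ** 2
        g_l = wfpt.density_grid_boundary(td, 0, v, p.a, p.zr, p.sv, p.szr,
                                         glx, glw, self.eps)
        g_u = wfpt.density_grid_boundary(td, 1, v, p.a, p.zr, p.sv, p.szr,
                                         glx, glw, self.eps)
        if cumulative:
            g_l = cumulative_trapezoid(g_l, td, initial=0.0)
            g_u = cumulative_trapezoid(g_u, td, initial=0.0)
        return tdmax, g_l, g_u

    # -- KS ---------------------------------------------------------------
    def _ks_prep(self) -> None:
        d = self.data
        self._ks_signed = []
        for idx in self._stim_idx:
            signed = np.where(d.response[idx] == 1, d.rt[idx], -d.rt[idx])
            self._ks_signed.append(np.sort(signed))

    def _ks(self, p: DiffusionParams) -> float:
        from . import wfpt
        glx, glw = gauss_legendre(self.n_gl)
        drifts = [p.v, p.v1] if p.is_two_drift else [p.v]
        stat = 0.0
        for signed, v in zip(self._ks_signed, drifts):
            if p.sv == 0:
                d_here = wfpt.ks_basic(signed, v, p.a, p.t0, p.zr, p.st0,
                                       p.szr, glx, glw, min(self.eps, 1e-8))
            else:
                ghx, ghw = gauss_hermite_prob(self.n_gh)
                p_low = wfpt.prob_lower_mix(1.0, p.a, p.zr, v + p.sv * ghx,
                                            ghw, p.szr, glx, glw)
                tdmax, F_l, F_u = self._grids(p, v, float(np.max(np.abs(signed))),
                                              cumulative=True)
                d_here = wfpt.ks_from_grids(signed, tdmax, F_l, F_u, p_low,
                                            p.t0, p.st0, glx, glw)
            stat = max(stat, float(d_here))
        return stat

    # -- CS ---------------------------------------------------------------
    def _cs_prep(self, quantiles) -> None:
        d = self.data
        self._cs_cells = []  # per stimulus: list of (response, edges, observed)
        for idx in self._stim_idx:
            cells = []
            for b in (0, 1):
                rts_b = d.rt[idx][d.response[idx] == b]
                if rts_b.size < self.cs_min_count:
                    self.pooled = True  # sparse category: single pooled bin
                    cells.append((b, None, np.array([rts_b.size])))
                    continue
                edges = np.quantile(rts_b, quantiles)
                counts, _ = np.histogram(rts_b, bins=np.concatenate(
                    ([0.0], edges, [np.inf])))
                cells.append((b, edges, counts))
            self._cs_cells.append((idx.shape[0], cells))

    def _cs(self, p: DiffusionParams) -> float:
        stat = 0.0
        for fp, (n_s, cells) in zip(self._evaluators(p), self._cs_cells):
            for b, edges, observed in cells:
                boundary = "upper" if b == 1 else "lower"
                p_b = fp.prob(boundary)
                if edges is None:  # pooled single bin
                    expected = np.array([n_s * p_b])
                else:
                    F = fp.cdf(edges, boundary)
                    probs = np.diff(np.concatenate(([0.0], F, [p_b])))
                    expected = n_s * np.maximum(probs, 0.0)
                stat += float(np.sum((observed - expected) ** 2
                                     / np.maximum(expected, 1e-10)))
        return stat

    # -- dispatch ---------------------------------------------------------
    def __call__(self, p: DiffusionParams) -> float:
        if self.criterion == "ml":
            return self._nll(p)
        if self.criterion == "ks":
            return self._ks(p)
        return self._cs(p)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------
def negative_log_likelihood(data: TrialData, p: DiffusionParams,
                            **kwargs) -> float:
    """-sum(log density) over trials, with a per-trial floor (default 1e-10)."""
    return Objective(data, "ml", **kwargs)(p)


def ks_statistic(data: TrialData, p: DiffusionParams, **kwargs) -> float:
    """Sup distance between empirical and model joint RT distributions.

    Lower-boundary RTs are mapped to the negative half-axis so that one
    statistic covers both response categories.
    """
    return Objective(data, "ks", **kwargs)(p)


def chi_square_statistic(data: TrialData, p: DiffusionParams, **kwargs) -> float:
    """Pearson chi-square over response x RT-quantile bins.

    Bin edges sit at the 0.1/0.3/0.5/0.7/0.9 empirical quantiles of each
    response category's RTs; categories with fewer than ``cs_min_count``
    trials are pooled into a single bin.
    """
    return Objective(data, "cs", **kwargs)(p)
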