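"""Numba kernels for Wiener first-passage-time (FPT) numerics.

Everything here is expressed for the *lower* boundary of a diffusion with
absorbing boundaries at 0 and ``a``, start ``w = zr`` (fraction of ``a``),
drift ``v`` and unit diffusion coefficient; upper-boundary quantities follow
from the reflection (v, w) -> (-v, 1 - w).

Internals use the normalised process: with ``u = t / a**2`` and
``m = v * a`` the FPT of the original process equals ``a**2`` times the FPT
of a unit-interval diffusion with drift ``m`` started at ``w``.

Density of the driftless unit-interval process (``f0``) uses the standard
small-time/large-time series with the accuracy-based switching rule of the
usual implementations (truncation for absolute error <= ``eps``).  The
drift factor, including a normal intertrial drift distribution with SD
``sv``, has the closed form

    M(t) = exp((a^2 w^2 sv^2 - 2 a w v - v^2 t) / (2 (1 + sv^2 t)))
           / sqrt(1 + sv^2 t)

so the lower-boundary density is ``f0(u, w) * M(t) / a**2``.

The basic-model CDF is computed by exact series as well: a large-time
eigenfunction tail sum, or for small ``u`` a sum of Gaussian-CDF terms
obtained by integrating each reflection term of the small-time density
(evaluated in log space to avoid overflow at large drift).
"""

import math

import numpy as np
from numba import njit

SQRT_2PI = math.sqrt(2.0 * math.pi)
PI = math.pi
PISQ = math.pi * math.pi


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------
@njit(cache=True)
def log_ndtr(x):
    """log of the standard normal CDF, stable for very negative x."""
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    x2 = x * x
    # asymptotic expansion of Mills ratio
    return -0.5 * x2 - math.log(-x) - 0.5 * math.log(2.0 * math.pi) + math.log1p(
        -1.0 / x2 + 3.0 / (x2 * x2)
    )


@njit(cache=True)
def prob_lower(m, w):
    """Absorption probability at the lower boundary (normalised drift m = v*a)."""
    if abs(m) < 1e-9:
        return 1.0 - w
    if m > 0.0:
        num = math.expm1(-2.0 * m * w) - math.expm1(-2.0 * m)
        den = -math.expm1(-2.0 * m)
        return num / den
    # multiply through by exp(2 m) for stability at negative drift
    num = math.expm1(2.0 * m * (1.0 - w))
    den = math.expm1(2.0 * m)
    return num / den


@njit(cache=True)
def f0_density(u, w, eps):
    """Driftless unit-interval FPT density at the lower boundary.

    Small-time vs large-time series chosen by the Navarro-Fuss style
    truncation bounds for absolute error <= eps.
    """
    if u <= 0.0:
        return 0.0
    # number of terms needed by each representation
    arg = 2.0 * eps * math.sqrt(2.0 * math.pi * u)
    if arg < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(arg))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    argl = math.pi * u * eps
    if argl < 1.0:
        kl = math.sqrt(-2.0 * math.log(argl) / (PISQ * u))
        kl = max(kl, 1.0 / (PI * math.sqrt(u)))
    else:
        kl = 1.0 / (PI * math.sqrt(u))
    if ks < kl:
        K = int(math.ceil(ks / 2.0)) + 1
        s = 0.0
        for k in range(-K, K + 1):
            b = w + 2.0 * k
            s += b * math.exp(-b * b / (2.0 * u))
        return s / math.sqrt(2.0 * math.pi * u * u * u)
    K = int(math.ceil(kl)) + 1
    s = 0.0
    for k in range(1, K + 1):
        s += k * math.exp(-k * k * PISQ * u / 2.0) * math.sin(k * PI * w)
    return PI * s


@njit(cache=True)
def drift_factor(t, v, sv, a, w):
    """Drift-dependent factor of the lower-boundary density.

    Includes the exact Gaussian integral over a Normal(v, sv) intertrial
    drift distribution; sv = 0 reduces to exp(-v a w - v^2 t / 2).
    """
    if sv <= 0.0:
        return math.exp(-v * a * w - v * v * t / 2.0)
    g = 1.0 + sv * sv * t
    num = a * a * w * w * sv * sv - 2.0 * a * w * v - v * v * t
    return math.exp(num / (2.0 * g)) / math.sqrt(g)


@njit(cache=True)
def density_lower(t, v, sv, a, w, eps):
    """Lower-boundary FPT density at decision time t (sv integrated exactly)."""
    if t <= 0.0:
        return 0.0
    u = t / (a * a)
    return f0_density(u, w, eps) / (a * a) * drift_factor(t, v, sv, a, w)


@njit(cache=True)
def cdf0_lower(u, m, w, eps):
    """Basic-model lower-boundary CDF in normalised time (no variabilities)."""
    if u <= 0.0:
        return 0.0
    pl = prob_lower(m, w)
    ln_eps = math.log(eps)
    # terms for the small-time representation
    ks = (math.sqrt(-2.0 * u * ln_eps) + abs(m) * u + w) / 2.0 + 1.0
    # terms for the large-time representation
    arg = -m * w - ln_eps
    if arg > 0.0:
        kl = math.sqrt(2.0 * arg / (PISQ * u)) + 1.0
    else:
        kl = 1.0
    if 3.0 * ks < kl:
        # small-time: sum of integrated reflection terms
        Ks = int(math.ceil(ks))
        sq = math.sqrt(u)
        F = 0.0
        for k in range(-Ks, Ks + 1):
            b = w + 2.0 * k
            if b > 0.0:
                F += math.exp(m * (b - w) + log_ndtr(-(b + m * u) / sq))
                F += math.exp(-m * (b + w) + log_ndtr((m * u - b) / sq))
            else:
                F -= math.exp(m * (b - w) + log_ndtr((b + m * u) / sq))
                F += -math.exp(-m * (b + w) + log_ndtr((b - m * u) / sq))
        if F < 0.0:
            F = 0.0
        if F > pl:
            F = pl
        return F
    Kl = int(math.ceil(kl))
    if Kl > 100000:
        Kl = 100000
    S = 0.0
    pref = PI * math.exp(-m * w)
    for k in range(1, Kl + 1):
        lam = 0.5 * (m * m + k * k * PISQ)
        term = k * math.sin(k * PI * w) / lam * math.exp(-lam * u)
        S += term
        if lam * u > -ln_eps + 5.0 and k > 2:
            break
    F = pl - pref * S
    if F < 0.0:
        F = 0.0
    if F > pl:
        F = pl
    return F


# ---------------------------------------------------------------------------
# array kernels used by the objectives
# ---------------------------------------------------------------------------
@njit(cache=True)
def density_joint(rts, responses, vlo, vhi, stim, a, t0, zr, sv, st0, szr,
                  glx, glw, eps):
    """Joint defective density of (response, rt) per trial.

    szr and st0 uniforms via Gauss-Legendre nodes ``glx``/``glw`` on [-1, 1];
    sv in closed form.  ``stim`` selects the drift (0 -> vlo, 1 -> vhi).
    """
    n = rts.shape[0]
    nq = glx.shape[0]
    out = np.empty(n)
    for i in range(n):
        v = vlo if stim[i] == 0 else vhi
        if responses[i] == 1:  # upper boundary via reflection
            v = -v
            zr_e = 1.0 - zr
        else:
            zr_e = zr
        acc = 0.0
        if st0 > 0.0:
            for j in range(nq):
                td = rts[i] - (t0 + 0.5 * st0 * glx[j])
                if td <= 0.0:
                    continue
                if szr > 0.0:
                    inner = 0.0
                    for l in range(nq):
                        wn = zr_e + 0.5 * szr * glx[l]
                        inner += 0.5 * glw[l] * density_lower(td, v, sv, a, wn, eps)
                    acc += 0.5 * glw[j] * inner
                else:
                    acc += 0.5 * glw[j] * density_lower(td, v, sv, a, zr_e, eps)
        else:
            td = rts[i] - t0
            if td > 0.0:
                if szr > 0.0:
                    for l in range(nq):
                        wn = zr_e + 0.5 * szr * glx[l]
                        acc += 0.5 * glw[l] * density_lower(td, v, sv, a, wn, eps)
                else:
                    acc = density_lower(td, v, sv, a, zr_e, eps)
        out[i] = acc
    return out


@njit(cache=True)
def density_grid_boundary(grid_td, upper, vlo, a, zr, sv, szr, glx, glw, eps):
    """Density (st0 excluded) on a grid of decision times for one boundary."""
    m = grid_td.shape[0]
    nq = glx.shape[0]
    out = np.empty(m)
    if upper == 1:
        v = -vlo
        zr_e = 1.0 - zr
    else:
        v = vlo
        zr_e = zr
    for i in range(m):
        td = grid_td[i]
        if td <= 0.0:
            out[i] = 0.0
            continue
        if szr > 0.0:
            acc = 0.0
            for l in range(nq):
                wn = zr_e + 0.5 * szr * glx[l]
                acc += 0.5 * glw[l] * density_lower(td, v, sv, a, wn, eps)
            out[i] = acc
        else:
            out[i] = density_lower(td, v, sv, a, zr_e, eps)
    return out


@njit(cache=True)
def cdf_basic_mix(rts, upper, vlo, a, t0, zr, sv_nodes, sv_w, st0, szr,
                  glx, glw, eps):
    """CDF at given rts for one boundary via series CDF + quadrature mixing.

    Used when the drift-variability integral is handled with Gauss-Hermite
    nodes (``sv_nodes`` are drift values, ``sv_w`` their weights summing
    to 1); szr and st0 via Gauss-Legendre.
    """
    n = rts.shape[0]
    nq = glx.shape[0]
    nv = sv_nodes.shape[0]
    out = np.empty(n)
    for i in range(n):
        acc = 0.0
        for jv in range(nv):
            v = sv_nodes[jv]
            if upper == 1:
                v_e = -v
                zr_e = 1.0 - zr
            else:
                v_e = v
                zr_e = zr
            if st0 > 0.0:
                sub = 0.0
                for j in range(nq):
                    td = rts[i] - (t0 + 0.5 * st0 * glx[j])
                    if td <= 0.0:
                        continue
                    if szr > 0.0:
                        inner = 0.0
                        for l in range(nq):
                            wn = zr_e + 0.5 * szr * glx[l]
                            inner += 0.5 * glw[l] * cdf0_lower(td / (a * a), v_e * a, wn, eps)
                        sub += 0.5 * glw[j] * inner
                    else:
                        sub += 0.5 * glw[j] * cdf0_lower(td / (a * a), v_e * a, zr_e, eps)
                acc += sv_w[jv] * sub
            else:
                td = rts[i] - t0
                if td > 0.0:
                    if szr > 0.0:
                        inner = 0.0
                        for l in range(nq):
                            wn = zr_e + 0.5 * szr * glx[l]
                            inner += 0.5 * glw[l] * cdf0_lower(td / (a * a), v_e * a, wn, eps)
                        acc += sv_w[jv] * inner
                    else:
                        acc += sv_w[jv] * cdf0_lower(td / (a * a), v_e * a, zr_e, eps)
        out[i] = acc
    return out


@njit(cache=True)
def prob_lower_mix(vlo, a, zr, sv_nodes, sv_w, szr, glx, glw):
    """Marginal lower-boundary probability averaged over sv and szr."""
    nq = glx.shape[0]
    nv = sv_nodes.shape[0]
    acc = 0.0
    for jv in range(nv):
        m = sv_nodes[jv] * a
        if szr > 0.0:
            inner = 0.0
            for l in range(nq):
                wn = zr + 0.5 * szr * glx[l]
                inner += 0.5 * glw[l] * prob_lower(m, wn)
            acc += sv_w[jv] * inner
        else:
            acc += sv_w[jv] * prob_lower(m, zr)
    return acc


# ---------------------------------------------------------------------------
# fast objective kernels operating on cached graded grids
#
# grids live on decision times td = tdmax * (i / (m-1))**2, so the lookup
# index is sqrt(td / tdmax) * (m-1) (no search needed); interpolation is
# linear in the graded coordinate.
# ---------------------------------------------------------------------------
@njit(cache=True, inline="always")
def _graded_lookup(td, tdmax, grid):
    if td <= 0.0:
        return 0.0
    m = grid.shape[0]
    pos = math.sqrt(td / tdmax) * (m - 1)
    if pos >= m - 1:
        return grid[m - 1]
    i0 = int(pos)
    frac = pos - i0
    return grid[i0] * (1.0 - frac) + grid[i0 + 1] * frac


@njit(cache=True)
def _st0_mix(rt, tdmax, grid, t0, st0, glx, glw):
    if st0 <= 0.0:
        return _graded_lookup(rt - t0, tdmax, grid)
    acc = 0.0
    for j in range(glx.shape[0]):
        acc += 0.5 * glw[j] * _graded_lookup(rt - (t0 + 0.5 * st0 * glx[j]),
                                             tdmax, grid)
    return acc


@njit(cache=True)
def nll_from_grids(rts, resp, tdmax, grid_l, grid_u, t0, st0, glx, glw, floor):
    """Negative log-likelihood with densities interpolated from grids."""
    nll = 0.0
    for i in range(rts.shape[0]):
        g = grid_u if resp[i] == 1 else grid_l
        dens = _st0_mix(rts[i], tdmax, g, t0, st0, glx, glw)
        if dens < floor:
            dens = floor
        nll -= math.log(dens)
    return nll


@njit(cache=True)
def ks_from_grids(signed_sorted, tdmax, F_l, F_u, p_low, t0, st0, glx, glw):
    """KS sup distance with the model CDF interpolated from grids.

    ``signed_sorted``: lower-boundary RTs negated, sorted ascending; model
    joint CDF on that axis is p_low - F_l(-x) for x < 0 and
    p_low + F_u(x) for x >= 0.
    """
    n = signed_sorted.shape[0]
    d = 0.0
    for i in range(n):
        x = signed_sorted[i]
        if x < 0.0:
            F = p_low - _st0_mix(-x, tdmax, F_l, t0, st0, glx, glw)
        else:
            F = p_low + _st0_mix(x, tdmax, F_u, t0, st0, glx, glw)
        hi = abs(F - (i + 1) / n)
        lo = abs(F - i / n)
        if hi > d:
            d = hi
        if lo > d:
            d = lo
    return d


@njit(cache=True)
def ks_basic(signed_sorted, v, a, t0, zr, st0, szr, glx, glw, eps):
    """KS sup distance via exact series CDFs (models without drift
    variability); szr / st0 handled by Gauss-Legendre nodes."""
    n = signed_sorted.shape[0]
    nq = glx.shape[0]
    p_low = 0.0
    if szr > 0.0:
        for l in range(nq):
            p_low += 0.5 * glw[l] * prob_lower(v * a, zr + 0.5 * szr * glx[l])
    else:
        p_low = prob_lower(v * a, zr)
    d = 0.0
    aa = a * a
    for i in range(n):
        x = signed_sorted[i]
        if x < 0.0:
            rt = -x
            v_e, zr_e = v, zr
        else:
            rt = x
            v_e, zr_e = -v, 1.0 - zr
        acc = 0.0
        if st0 > 0.0:
            for j in range(nq):
                td = rt - (t0 + 0.5 * st0 * glx[j])
                if td <= 0.0:
                    continue
                if szr > 0.0:
                    for l in range(nq):
                        wn = zr_e + 0.5 * szr * glx[l]
                        acc += 0.25 * glw[j] * glw[l] * cdf0_lower(td / aa, v_e * a, wn, eps)
                else:
                    acc += 0.5 * glw[j] * cdf0_lower(td / aa, v_e * a, zr_e, eps)
        else:
            td = rt - t0
            if td > 0.0:
                if szr > 0.0:
                    for l in range(nq):
                        wn = zr_e + 0.5 * szr * glx[l]
                        acc += 0.5 * glw[l] * cdf0_lower(td / aa, v_e * a, wn, eps)
                else:
                    acc = cdf0_lower(td / aa, v_e * a, zr_e, eps)
        if x < 0.0:
            F = p_low - acc
        else:
            F = p_low + acc
        hi = abs(F - (i + 1) / n)
        lo = abs(F - i / n)
        if hi > d:
            d = hi
        if lo > d:
            d = lo
    return d


# ---------------------------------------------------------------------------
# exact trial sampler (inverse-CDF on the trial-level basic FPT distribution)
# ---------------------------------------------------------------------------
@njit(cache=True)
def sample_fpt(a, v, t0, zr, sv, st0, szr, z_norm, u_zr, u_t0, u_choice, u_quant):
    """Sample one (response, rt) pair per row of the pre-drawn random inputs.

    Per trial the drift / starting point / non-decision time are drawn from
    their intertrial distributions, the boundary is chosen from the exact
    absorption probability, and the decision time is found by bisection on
    the exact basic-model CDF (inverse-CDF sampling).
    """
    n = z_norm.shape[0]
    rts = np.empty(n)
    resp = np.empty(n, dtype=np.int8)
    eps = 1e-9
    for i in range(n):
        vi = v + sv * z_norm[i]
        wi = zr + szr * (u_zr[i] - 0.5)
        t0i = t0 + st0 * (u_t0[i] - 0.5)
        m = vi * a
        pl = prob_lower(m, wi)
        if u_choice[i] < pl:
            resp[i] = 0
            m_e = m
            w_e = wi
            target = u_quant[i] * pl
        else:
            resp[i] = 1
            m_e = -m
            w_e = 1.0 - wi
            target = u_quant[i] * (1.0 - pl)
        # bracket the normalised decision time
        hi = 1.0
        it = 0
        while cdf0_lower(hi, m_e, w_e, eps) < target and it < 60:
            hi *= 2.0
            it += 1
        lo = 0.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if cdf0_lower(mid, m_e, w_e, eps) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-9 * (1.0 + hi):
                break
        u_dec = 0.5 * (lo + hi)
        rts[i] = t0i + u_dec * a * a
    return resp, rts
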