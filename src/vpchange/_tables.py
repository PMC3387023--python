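"""Cached lookup tables for the Monte-Carlo engine (internal).

The prediction engine evaluates the same smooth special functions on millions
of points across a parameter grid. These helpers trade exact evaluation for
dense-table interpolation (relative error ~1e-7, far below Monte-Carlo
resolution) and, crucially, make sampling a deterministic transform of base
standard-normal quantiles: a single base draw can be pushed through the
gamma and Von Mises quantile functions for every parameter value, so all
grid points share identical random numbers. Public API functions
(:mod:`vpchange.encoding`, :mod:`vpchange.observers`) always use the exact
scipy paths; only the engine uses these tables.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammaincinv, i0e, i1e, ndtr

_LOG_I0 = None
_KAPPA = None
_VM = None
_GAMMA = None

Z_MAX = 6.0  # base normal quantiles are clamped to +-6 (1e-9 tail mass)


def _lerp_uniform(x, x0, h, table):
    """Linear interpolation on a uniformly spaced 1-D table."""
    pos = np.clip((x - x0) / h, 0.0, table.size - 1.000001)
    idx = pos.astype(np.int64)
    frac = pos - idx
    return table[idx] * (1.0 - frac) + table[idx + 1] * frac


def log_i0_lookup(x):
    """log I0(x) by table interpolation; exact asymptote beyond the table."""
    global _LOG_I0
    if _LOG_I0 is None:
        c = np.linspace(0.0, np.log1p(20000.0), 16384)
        k = np.expm1(c)
        _LOG_I0 = (c[0], c[1] - c[0], np.log(i0e(k)) + k)
    x = np.asarray(x, dtype=float)
    c0, h, table = _LOG_I0
    out = _lerp_uniform(np.log1p(x), c0, h, table)
    big = x > 19999.0
    if np.any(big):
        xb = x[big]
        out[big] = xb - 0.5 * np.log(2.0 * np.pi * xb)
    return out


def kappa_lookup(j):
    """kappa(J) by table interpolation; asymptotes outside the table."""
    global _KAPPA
    if _KAPPA is None:
        lj = np.linspace(np.log(1e-6), np.log(6000.0), 16384)
        jj = np.exp(lj)
        # invert J(kappa) = kappa I1/I0 by Newton from a smooth guess
        kap = np.where(jj < 0.8, np.sqrt(2.0 * jj), jj + 0.5)
        for _ in range(25):
            r = i1e(kap) / i0e(kap)
            f = kap * r - jj
            kap = np.clip(kap - f / (kap * (1.0 - r * r)), kap * 0.5, kap * 2.0)
        _KAPPA = (lj[0], lj[1] - lj[0], np.log(kap))
    j = np.asarray(j, dtype=float)
    out = np.empty_like(j)
    small = j < 1e-6
    big = j > 5999.0
    mid = ~(small | big)
    lj0, h, table = _KAPPA
    with np.errstate(divide="ignore"):
        out[mid] = np.exp(_lerp_uniform(np.log(j[mid]), lj0, h, table))
    out[small] = np.sqrt(2.0 * j[small])
    out[big] = j[big] + 0.5
    return out


def _bilerp_uniform(x, y, x0, hx, y0, hy, table):
    px = np.clip((x - x0) / hx, 0.0, table.shape[0] - 1.000001)
    py = np.clip((y - y0) / hy, 0.0, table.shape[1] - 1.000001)
    ix = px.astype(np.int64)
    iy = py.astype(np.int64)
    fx = px - ix
    fy = py - iy
    t00 = table[ix, iy]
    t01 = table[ix, iy + 1]
    t10 = table[ix + 1, iy]
    t11 = table[ix + 1, iy + 1]
    return (t00 * (1 - fx) * (1 - fy) + t01 * (1 - fx) * fy
            + t10 * fx * (1 - fy) + t11 * fx * fy)


def _build_vm_table():
    # quantile function of VM(0, kappa) evaluated at u = Phi(z):
    # rows over c = log1p(kappa), columns over z
    c = np.linspace(0.0, np.log1p(6000.0), 512)
    z = np.linspace(-Z_MAX, Z_MAX, 1537)
    u = ndtr(z)
    kappas = np.expm1(c)
    table = np.empty((c.size, z.size))
    for i, kap in enumerate(kappas):
        if kap < 1e-12:
            table[i] = (u - 0.5) * 2.0 * np.pi
            continue
        # resolve the density on a kappa-adapted angle grid
        half = min(np.pi, 8.0 / np.sqrt(kap) + 1e-3) if kap > 6.5 else np.pi
        ang = np.linspace(-half, half, 8193)
        pdf = np.exp(kap * (np.cos(ang) - 1.0))
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5)])
        cdf /= cdf[-1]
        # strictly increasing except in negligible-mass tails; np.interp is fine
        table[i] = np.interp(u, cdf, ang)
    return (c[0], c[1] - c[0], -Z_MAX, z[1] - z[0], table)


def vm_from_normal(kappa, z):
    """Von Mises(0, kappa) sample as a deterministic transform of normal z."""
    global _VM
    if _VM is None:
        _VM = _build_vm_table()
    c0, hc, z0, hz, table = _VM
    kappa = np.asarray(kappa, dtype=float)
    return _bilerp_uniform(np.log1p(kappa), np.asarray(z, dtype=float),
                           c0, hc, z0, hz, table)


def _build_gamma_table():
    ls = np.linspace(np.log(0.005), np.log(300.0), 512)
    z = np.linspace(-Z_MAX, Z_MAX, 1537)
    u = ndtr(z)
    table = gammaincinv(np.exp(ls)[:, None], u[None, :])
    return (ls[0], ls[1] - ls[0], -Z_MAX, z[1] - z[0], np.log(np.maximum(table, 1e-300)))


def gamma_from_normal(shape, z):
    """Gamma(shape, scale=1) sample as a deterministic transform of normal z."""
    global _GAMMA
    if _GAMMA is None:
        _GAMMA = _build_gamma_table()
    shape = np.asarray(shape, dtype=float)
    if np.any(shape < 0.0051) or np.any(shape > 299.0):
        return gammaincinv(shape, ndtr(np.asarray(z, dtype=float)))
    s0, hs, z0, hz, table = _GAMMA
    return np.exp(_bilerp_uniform(np.log(shape), np.asarray(z, dtype=float),
                                  s0, hs, z0, hz, table))
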