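"""Vectorized Monte-Carlo prediction engine (internal).

The probability that a model reports "change" depends on a trial only through
its type: the change-magnitude bin (0, 3, ..., 90 degrees physical; 31 bins),
the number of high-reliability items N_H (0..4), and whether the changed item
had low or high reliability - 31*5*2 = 310 cells. Items are exchangeable
given their reliability labels, so for each (N_H, changed-reliability)
stratum the engine simulates one canonical location assignment and shares the
measurement-noise draws across the 31 magnitude bins (the change magnitude
enters only as an offset on the changed item's measurement difference). This
is distribution-identical to redrawing locations per sample and keeps the
per-parameter-point cost low.

Common random numbers: each stratum draws one set of base standard-normal
quantiles keyed by (seed, stratum); every parameter point transforms the
same base draws through gamma/Von Mises quantile tables
(:mod:`vpchange._tables`). The Monte-Carlo likelihood surface is therefore a
smooth deterministic function of the parameters for a given seed, which keeps
grid arg-maxes stable.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _tables
from . import observers as _obs
from .observers import ModelSpec

N_BINS = 31
N_NH = 5
N_TYPES = N_BINS * N_NH * 2  # 310
DELTA_BIN_DEG = 3.0 * np.arange(N_BINS)           # physical degrees
DELTA_BIN_INT = DELTA_BIN_DEG * np.pi / 90.0      # internal radians
LOG4 = np.log(4.0)

# change strata (n_high, changed item high?); item 0 is the changed item
CHANGE_GROUPS = [(h, False) for h in range(4)] + [(h, True) for h in range(1, 5)]
GROUP_KEYS = [("nc", h) for h in range(N_NH)] + [("ch", h, hi) for h, hi in CHANGE_GROUPS]


def type_index(delta_bin, n_high, changed_high):
    """Flat index into the 310-cell type space."""
    return (np.asarray(delta_bin) * N_NH + np.asarray(n_high)) * 2 + np.asarray(
        changed_high, dtype=int)


def feasible_mask():
    """Boolean mask over the 310 cells reachable by the design."""
    mask = np.zeros(N_TYPES, dtype=bool)
    for b in range(N_BINS):
        for h in range(N_NH):
            mask[type_index(b, h, False)] = (b == 0) or (h <= 3)
            mask[type_index(b, h, True)] = h >= 1
    return mask


FEASIBLE = feasible_mask()


def _rel_vector(key):
    rel = np.zeros(4, dtype=bool)
    if key[0] == "ch":
        h, hi = key[1], key[2]
        rel[0] = hi
        rel[1:1 + (h - 1 if hi else h)] = True
    else:
        rel[:key[1]] = True
    return rel


def draw_base(n_samples, seed, encoding):
    """Base normal quantiles per stratum, shared by all parameter points."""
    base = {}
    for gi, key in enumerate(GROUP_KEYS):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, gi])
        entry = {"rel": _rel_vector(key)}
        # measurement noise first so EP and VP evaluations share it
        entry["z_ex"] = rng.standard_normal((n_samples, 4))
        entry["z_ey"] = rng.standard_normal((n_samples, 4))
        if encoding == "V":
            entry["z_jx"] = rng.standard_normal((n_samples, 4))
            entry["z_jy"] = rng.standard_normal((n_samples, 4))
        base[key] = entry
    return base


def draw_noise(n_samples, seed):
    """Standard-normal decision noise, shared across the parameter grid."""
    out = {}
    for gi, key in enumerate(GROUP_KEYS):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 1000 + gi])
        out[key] = rng.normal(size=(n_samples, 4))
    return out


@dataclass
class _Group:
    rel_high: np.ndarray   # (4,) bool; item 0 is the changed item in change groups
    jx: np.ndarray         # realized precisions, (n, 4)
    jy: np.ndarray
    kx: np.ndarray         # concentrations used to generate the measurements
    ky: np.ndarray
    w: np.ndarray          # measurement difference x - y before the change offset


def percepts_from_base(base, encoding, enc_params):
    """Transform base draws into percepts for one encoding-parameter point."""
    groups = {}
    for key, b in base.items():
        rel = b["rel"]
        if encoding == "E":
            j_item = np.where(rel, enc_params["J_high"], enc_params["J_low"])
            k_item = _tables.kappa_lookup(j_item.astype(float))
            n = b["z_ex"].shape[0]
            jx = jy = np.broadcast_to(j_item, (n, 4))
            kx = ky = np.broadcast_to(k_item, (n, 4))
        else:
            tau = float(enc_params["tau"])
            shape = np.where(rel, enc_params["Jbar_high"], enc_params["Jbar_low"]) / tau
            shape = np.broadcast_to(shape, b["z_jx"].shape)
            jx = tau * _tables.gamma_from_normal(shape, b["z_jx"])
            jy = tau * _tables.gamma_from_normal(shape, b["z_jy"])
            kx = _tables.kappa_lookup(jx)
            ky = _tables.kappa_lookup(jy)
        w = _tables.vm_from_normal(kx, b["z_ex"]) - _tables.vm_from_normal(ky, b["z_ey"])
        groups[key] = _Group(rel_high=rel, jx=jx, jy=jy, kx=kx, ky=ky, w=w)
    return groups


def _assumed_kappas_group(group, spec, params, enc_params):
    """(kx, ky) concentration arrays the observer plugs into d, shape (n, 4)."""
    a = spec.assumption
    if a == "V":
        return group.kx, group.ky
    if a == "E":
        if spec.encoding == "E":
            return group.kx, group.ky  # identical by construction under EP
        j = np.where(group.rel_high, enc_params["Jbar_high"], enc_params["Jbar_low"])
        k = _tables.kappa_lookup(j.astype(float))
        k = np.broadcast_to(k, group.w.shape)
        return k, k
    if a == "A":
        kx = _tables.kappa_lookup(group.jx.mean(axis=1))[:, None]
        ky = _tables.kappa_lookup(group.jy.mean(axis=1))[:, None]
        return (np.broadcast_to(kx, group.w.shape),
                np.broadcast_to(ky, group.w.shape))
    j_assumed = float(params.get("J_assumed", _obs.J_ASSUMED_REF))
    k = np.broadcast_to(_tables.kappa_lookup(np.array([j_assumed]))[0], group.w.shape)
    return k, k


def _logd(cos_w, kx, ky, li_xy):
    kc = np.sqrt(kx * kx + ky * ky + 2.0 * kx * ky * cos_w)
    return li_xy - _tables.log_i0_lookup(kc)


def _lse(a, axis):
    m = np.max(a, axis=axis, keepdims=True)
    return np.squeeze(m, axis=axis) + np.log(np.sum(np.exp(a - m), axis=axis))


@dataclass
class Stats:
    """Per-sample decision statistics, before thresholding.

    For rule O the statistic is log(mean_i d_i); for rule M it is max_i log d_i.
    The report is "change" when statistic > threshold: log((1-p)/p) for O,
    log(k) for M (k <= 0 never binds).
    """

    nc: np.ndarray  # (5, n): no-change strata, rows N_H = 0..4
    ch: np.ndarray  # (8, 31, n): change strata in CHANGE_GROUPS order


def compute_stats(groups, spec: ModelSpec, params, enc_params,
                  sigma=None, noise_z=None) -> Stats:
    """Decision statistic for every stratum, magnitude bin and MC sample."""
    n = groups["nc", 0].w.shape[0]
    nc = np.empty((N_NH, n))
    ch = np.empty((len(CHANGE_GROUPS), N_BINS, n))
    is_max = spec.rule == "M" and spec.noise == "none"
    cos_d = np.cos(DELTA_BIN_INT)[:, None]
    sin_d = np.sin(DELTA_BIN_INT)[:, None]
    for h in range(N_NH):
        g = groups["nc", h]
        kx, ky = _assumed_kappas_group(g, spec, params, enc_params)
        li = _tables.log_i0_lookup(kx) + _tables.log_i0_lookup(ky)
        logd = _logd(np.cos(g.w), kx, ky, li)
        if sigma is not None and spec.noise == "local":
            logd = logd + sigma * noise_z["nc", h]
        nc[h] = np.max(logd, axis=1) if is_max else _lse(logd, axis=1) - LOG4
        if sigma is not None and spec.noise == "global":
            nc[h] += sigma * noise_z["nc", h][:, 0]
    for gi, (h, hi) in enumerate(CHANGE_GROUPS):
        g = groups["ch", h, hi]
        kx, ky = _assumed_kappas_group(g, spec, params, enc_params)
        li = _tables.log_i0_lookup(kx) + _tables.log_i0_lookup(ky)
        logd_unch = _logd(np.cos(g.w[:, 1:]), kx[:, 1:], ky[:, 1:], li[:, 1:])
        # cos(w0 - delta) expanded so the (31, n) pass avoids transcendentals
        w0 = g.w[:, 0]
        cos_wd = np.cos(w0)[None, :] * cos_d + np.sin(w0)[None, :] * sin_d
        logd_ch = _logd(cos_wd, kx[:, 0][None, :], ky[:, 0][None, :], li[:, 0][None, :])
        if sigma is not None and spec.noise == "local":
            z = noise_z["ch", h, hi]
            logd_unch = logd_unch + sigma * z[:, 1:]
            logd_ch = logd_ch + sigma * z[:, 0][None, :]
        if is_max:
            ch[gi] = np.maximum(np.max(logd_unch, axis=1)[None, :], logd_ch)
        else:
            s_unch = _lse(logd_unch, axis=1)                         # (n,)
            ch[gi] = np.logaddexp(s_unch[None, :], logd_ch) - LOG4
            if sigma is not None and spec.noise == "global":
                ch[gi] += sigma * noise_z["ch", h, hi][:, 0][None, :]
    return Stats(nc=nc, ch=ch)


def thresholds_for(spec: ModelSpec, values):
    """Log-scale decision thresholds for the rule parameter values."""
    values = np.asarray(values, dtype=float)
    if spec.rule == "O":
        return np.log((1.0 - values) / values)
    with np.errstate(divide="ignore"):
        return np.where(values > 0.0, np.log(np.maximum(values, 1e-300)), -np.inf)


def table_from_stats(stats: Stats, log_thresh, n_samples) -> np.ndarray:
    """Probability of reporting change per type cell, clipped away from {0,1}.

    Uses the add-half (Anscombe) estimator (count + 1/2)/(n + 1), which
    removes the leading-order bias of plugging a raw Monte-Carlo frequency
    into a log-likelihood, then clips to [eps, 1-eps], eps = 1/(2 n_samples).
    Returns array (n_thresholds, 310) with NaN at infeasible cells.
    """
    log_thresh = np.atleast_1d(np.asarray(log_thresh, dtype=float))
    eps = 1.0 / (2.0 * n_samples)
    den = float(n_samples + 1)
    out = np.full((log_thresh.size, N_TYPES), np.nan)
    p_nc = (np.sum(stats.nc[:, None, :] > log_thresh[None, :, None], axis=2)
            + 0.5) / den  # (5, T)
    for h in range(N_NH):
        out[:, type_index(0, h, False)] = p_nc[h]
    p_ch = (np.sum(stats.ch[:, :, None, :] > log_thresh[None, None, :, None], axis=3)
            + 0.5) / den
    for gi, (h, hi) in enumerate(CHANGE_GROUPS):
        b0 = 0 if hi else 1  # bin-0 low cells are the genuine no-change cells
        for b in range(b0, N_BINS):
            out[:, type_index(b, h, hi)] = p_ch[gi, b]
    fe = FEASIBLE
    out[:, fe] = np.clip(out[:, fe], eps, 1.0 - eps)
    return out


# ---------------------------------------------------------------------------
# grid evaluation

def _grid_axes(spec: ModelSpec, grid):
    names = list(spec.free_params)
    missing = [p for p in names if p not in grid]
    if missing:
        raise ValueError(f"grid missing parameters {missing} for model {spec.code}")
    axes = [np.atleast_1d(np.asarray(grid[p], dtype=float)) for p in names]
    if any(a.size == 0 for a in axes):
        raise ValueError("empty parameter grid")
    return names, axes


def grid_prediction_tables(spec: ModelSpec, grid, n_samples, seed):
    """Prediction tables over a full parameter grid.

    Parameters are split into simulation dimensions (precisions, tau), an
    optional assumed-precision dimension (reuses the same percepts), the rule
    threshold (p_change or k; a cheap sweep over precomputed statistics) and,
    for noise variants, sigma. Random numbers are common to all grid points.

    Returns (names, axes, P) where P has shape (prod sizes, 310) in
    row-major (itertools.product) order over the axes.
    """
    names, axes = _grid_axes(spec, grid)
    sizes = [a.size for a in axes]
    thresh_name = "p_change" if spec.rule == "O" else "k"
    enc_names = [n for n in names if n in
                 ("J_low", "J_high", "Jbar_low", "Jbar_high", "tau")]
    t_pos = names.index(thresh_name)
    log_t = thresholds_for(spec, axes[t_pos])
    sigma_name = next((n for n in names if n.startswith("sigma")), None)
    n_points = int(np.prod(sizes))
    P = np.full((n_points, N_TYPES), np.nan, dtype=np.float32)

    base = draw_base(n_samples, seed, spec.encoding)
    noise_z = draw_noise(n_samples, seed) if sigma_name else None
    enc_axes = [axes[names.index(n)] for n in enc_names]
    for enc_idx in itertools.product(*(range(a.size) for a in enc_axes)):
        enc_params = {n: enc_axes[i][enc_idx[i]] for i, n in enumerate(enc_names)}
        groups = percepts_from_base(base, spec.encoding, enc_params)
        ja_values = axes[names.index("J_assumed")] if "J_assumed" in names else [None]
        for jai, ja in enumerate(ja_values):
            params = dict(enc_params)
            if ja is not None:
                params["J_assumed"] = ja
            sigmas = axes[names.index(sigma_name)] if sigma_name else [None]
            for si, sigma in enumerate(sigmas):
                stats = compute_stats(groups, spec, params, enc_params,
                                      sigma=sigma, noise_z=noise_z)
                tab = table_from_stats(stats, log_t, n_samples)  # (T, 310)
                idx = {n: enc_idx[enc_names.index(n)] for n in enc_names}
                if ja is not None:
                    idx["J_assumed"] = jai
                if sigma is not None:
                    idx[sigma_name] = si
                for ti in range(log_t.size):
                    idx[thresh_name] = ti
                    flat = np.ravel_multi_index([idx[n] for n in names], sizes)
                    P[flat] = tab[ti]
    return names, axes, P


def grid_points_frame(names, axes):
    """DataFrame of grid points in the same row order as the P matrix."""
    import pandas as pd

    mesh = np.meshgrid(*axes, indexing="ij")
    return pd.DataFrame({n: m.ravel() for n, m in zip(names, mesh)})


def counts_from_cells(cell_idx, responded_change):
    """Per-cell counts of change / no-change responses over 310 cells."""
    cell_idx = np.asarray(cell_idx)
    responded_change = np.asarray(responded_change, dtype=bool)
    c1 = np.bincount(cell_idx[responded_change], minlength=N_TYPES).astype(float)
    c0 = np.bincount(cell_idx[~responded_change], minlength=N_TYPES).astype(float)
    return c1, c0


def loglik_from_tables(P, c1, c0):
    """Dataset log-likelihood for each grid row of prediction table P."""
    used = (c1 + c0) > 0
    if np.any(used & ~FEASIBLE):
        raise ValueError("trials mapped to infeasible type cells")
    Pu = P[:, used].astype(np.float64)
    return np.log(Pu) @ c1[used] + np.log1p(-Pu) @ c0[used]
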