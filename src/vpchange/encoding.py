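"""Encoding stage: precision <-> concentration mapping and the measurement process.

A measurement x of an orientation theta (internal doubled space) follows a
Von Mises distribution VM(theta, kappa). The concentration kappa corresponds
one-to-one with encoding precision J, defined as the Fisher information of
the measurement about theta:

    J(kappa) = kappa * I1(kappa) / I0(kappa),

with I0, I1 the modified Bessel functions of the first kind of orders 0 and 1.
J(0) = 0, J is strictly increasing, and J(kappa) < kappa for kappa > 0.

Under equal precision (EP) the precision of an item is fixed by its
reliability (J_low or J_high). Under variable precision (VP) the precision
itself is a random variable, drawn independently for every item, display and
trial from a gamma distribution with mean Jbar (reliability dependent) and
scale tau. The marginal measurement distribution is then a gamma mixture of
infinitely many Von Mises distributions - a circular analog of Student's t.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .angles import wrap

__all__ = [
    "log_i0",
    "bessel_ratio",
    "j_from_kappa",
    "kappa_from_j",
    "sample_von_mises",
    "PrecisionDistribution",
    "sample_measurement",
    "vm_pdf",
    "vp_error_pdf",
]


def log_i0(x):
    """log I0(x), stable for large argument (uses the exponentially scaled I0)."""
    x = np.asarray(x, dtype=float)
    return np.log(i0e(x)) + x


def bessel_ratio(kappa):
    """I1(kappa)/I0(kappa); the mean resultant length of VM(mu, kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    return i1e(kappa) / i0e(kappa)


def j_from_kappa(kappa):
    """Fisher information J as a function of the Von Mises concentration.

    J(kappa) = kappa * I1(kappa)/I0(kappa). Accepts scalars or arrays.
    """
    kappa = np.asarray(kappa, dtype=float)
    if not np.all(np.isfinite(kappa)) or np.any(kappa < 0):
        raise ValueError("kappa must be finite and >= 0")
    out = kappa * bessel_ratio(kappa)
    return float(out) if out.ndim == 0 else out


def _dj_dkappa(kappa):
    # d/dkappa [kappa * r(kappa)] = kappa * (1 - r^2), via r' = 1 - r/kappa - r^2
    r = bessel_ratio(kappa)
    return kappa * (1.0 - r * r)


_INV_TABLE = None


def _inverse_table():
    # monotone log-log lookup table for the initial Newton guess
    global _INV_TABLE
    if _INV_TABLE is None:
        kap = np.logspace(-4, np.log10(5000.0), 4096)
        jj = kap * bessel_ratio(kap)
        _INV_TABLE = (np.log(jj), np.log(kap))
    return _INV_TABLE


def kappa_from_j(j):
    """Numerical inverse of :func:`j_from_kappa`.

    Scalars are solved by bracketed root finding; arrays by a cached monotone
    interpolation polished with Newton steps. Round-trips to relative error
    below 1e-9 over the working range.
    """
    arr = np.asarray(j, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("J must be finite and >= 0")
    if arr.ndim == 0:
        jj = float(arr)
        if jj == 0.0:
            return 0.0
        # kappa* in (J, J+2): J(kappa) < kappa and J(kappa) > kappa - 1
        return brentq(lambda k: j_from_kappa(k) - jj, jj, jj + 2.0,
                      xtol=1e-14, rtol=8.9e-16)
    log_j, log_k = _inverse_table()
    kappa = np.zeros_like(arr)
    pos = arr > 0
    with np.errstate(divide="ignore"):
        kappa[pos] = np.exp(np.interp(np.log(arr[pos]), log_j, log_k))
    # outside the table the large-kappa asymptote J ~ kappa - 1/2 takes over
    big = arr > 4999.0
    kappa[big] = arr[big] + 0.5
    for _ in range(3):
        k = kappa[pos]
        f = k * bessel_ratio(k) - arr[pos]
        kappa[pos] = np.clip(k - f / _dj_dkappa(k), k * 0.5, k * 2.0 + 1e-12)
    return kappa


def sample_von_mises(mu, kappa, n=None, rng=None):
    """Draw Von Mises samples in internal space, wrapped to [-pi, pi).

    kappa = 0 yields the uniform distribution on the circle.
    """
    if rng is None:
        raise ValueError("an explicit seeded rng is required")
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0) or not np.all(np.isfinite(kappa)):
        raise ValueError("kappa must be finite and >= 0")
    size = n if n is not None else np.broadcast(np.asarray(mu), kappa).shape or None
    return wrap(rng.vonmises(mu, kappa, size=size))


@dataclass(frozen=True)
class PrecisionDistribution:
    """Gamma distribution over precision J with mean `mean_j` and scale `scale_tau`."""

    mean_j: float
    scale_tau: float

    def __post_init__(self):
        if not (self.mean_j > 0 and np.isfinite(self.mean_j)):
            raise ValueError("mean_j must be positive and finite")
        if not (self.scale_tau > 0 and np.isfinite(self.scale_tau)):
            raise ValueError("scale_tau must be positive and finite")

    @property
    def shape(self) -> float:
        return self.mean_j / self.scale_tau

    def sample(self, n, rng):
        return rng.gamma(self.shape, self.scale_tau, size=n)


def sample_measurement(theta, reliability, encoding, params, rng, n=None):
    """Draw noisy measurements of orientation `theta` (internal space).

    Parameters
    ----------
    theta : float or array
        True orientation(s) in internal space.
    reliability : {"low", "high"}
        The item's reliability label.
    encoding : {"E", "V"}
        Equal precision (J fixed by reliability) or variable precision
        (J ~ Gamma with reliability-dependent mean Jbar and scale tau).
    params : mapping
        Needs J_low/J_high (EP) or Jbar_low/Jbar_high and tau (VP).
    rng : numpy.random.Generator
    n : int, optional
        Number of draws; defaults to the shape of `theta`.

    Returns
    -------
    (x, realized_j) : measurements and the precision actually used for each
    draw. The realized precision is returned so that an omniscient observer
    (assumption "V") can condition on it.
    """
    if reliability not in ("low", "high"):
        raise ValueError("reliability must be 'low' or 'high'")
    if encoding == "E":
        j = params[f"J_{reliability}"]
        if not (j > 0 and np.isfinite(j)):
            raise ValueError("J must be positive and finite")
        size = n if n is not None else np.shape(theta) or None
        realized = np.broadcast_to(float(j), () if size is None else size).copy()
    elif encoding == "V":
        dist = PrecisionDistribution(params[f"Jbar_{reliability}"], params["tau"])
        size = n if n is not None else np.shape(theta) or None
        realized = dist.sample(size, rng)
    else:
        raise ValueError("encoding must be 'E' or 'V'")
    x = sample_von_mises(theta, kappa_from_j(np.asarray(realized)), rng=rng)
    return x, realized


def vm_pdf(x, mu, kappa):
    """Von Mises density on the internal circle [-pi, pi)."""
    x = np.asarray(x, dtype=float)
    return np.exp(np.asarray(kappa) * np.cos(x - mu) - log_i0(kappa)) / (2.0 * np.pi)


def vp_error_pdf(eps, mean_j, scale_tau, n_grid=8000):
    """Marginal density of the measurement error under variable precision.

    Quadrature evaluation of the gamma mixture of Von Mises densities:
    integral over J of Gamma(J; mean_j/scale_tau, scale_tau) VM(eps; 0, kappa(J)).
    Used as an oracle for the doubly stochastic measurement process.
    """
    from scipy.stats import gamma as gamma_dist

    dist = PrecisionDistribution(mean_j, scale_tau)
    g = gamma_dist(dist.shape, scale=scale_tau)
    # integrate on the quantile scale: int f(J) p(J) dJ = int f(J(u)) du
    u = (np.arange(n_grid) + 0.5) / n_grid
    j = g.ppf(u)
    kap = kappa_from_j(j)
    eps = np.atleast_1d(np.asarray(eps, dtype=float))
    dens = np.mean(vm_pdf(eps[:, None], 0.0, kap[None, :]), axis=1)
    return dens if dens.size > 1 else float(dens[0])
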