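"""Decision stage: the 14-model taxonomy, local decision variables and rules.

Each observer model is a point in {encoding: E|V} x {assumption about
precision: V|E|A|S} x {integration rule: O|M}:

* encoding - whether the stimuli are encoded with equal (E) or variable (V)
  precision (see :mod:`vpchange.encoding`);
* assumption - the concentrations the observer plugs into the local decision
  variable: V uses each item's realized precision (omniscient), E uses the
  reliability-determined value, A uses the average realized precision of the
  display ("gist"), S uses one value for the whole experiment;
* rule - O integrates optimally across locations, M thresholds the largest
  local decision variable at a criterion k.

Under equal-precision encoding assumptions V and E coincide (there is no
extra variability to know about), which leaves (4+3)*2 = 14 models. Two
decision-noise variants of EEO (local/global Gaussian noise on log decision
variables) serve as controls.

The local decision variable at location i is the likelihood ratio of change
versus no change given the two measurements:

    d_i = I0(kx_i) I0(ky_i) / I0(kc_i),
    kc_i = sqrt(kx_i^2 + ky_i^2 + 2 kx_i ky_i cos(x_i - y_i)),

and the optimal observer reports "change" when
(p_change / (1 - p_change)) * mean_i(d_i) > 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .angles import wrap
from .encoding import kappa_from_j, log_i0

__all__ = [
    "ModelSpec",
    "TrialPercept",
    "MODEL_CODES",
    "PARAM_RANGES",
    "J_ASSUMED_REF",
    "enumerate_models",
    "parse_model_code",
    "validate_params",
    "assumed_kappas",
    "local_decision_variable",
    "log_local_decision_variable",
    "optimal_rule",
    "max_rule",
    "apply_decision_noise",
    "decide",
]

# Fixed reference precision for the S-assumption Max-rule models (VSM/ESM).
# Thresholding max_i d_i under a single assumed precision is equivalent to
# thresholding the maximum absolute circular difference, so the assumed
# precision is not identifiable and is absorbed into the criterion k; any
# fixed value defines the same model family up to reparameterizing k. The
# value 8 (the scale of typical encoding precisions in this task) maps the
# criterion search range onto maximum-difference criteria in the band where
# these observers produce realistic (non-degenerate) false-alarm rates.
J_ASSUMED_REF = 8.0

#: Uniform prior ranges used for fitting and model comparison.
PARAM_RANGES = {
    "J_low": (1.0, 100.0),
    "J_high": (1.0, 100.0),
    "Jbar_low": (1.0, 100.0),
    "Jbar_high": (1.0, 100.0),
    "J_assumed": (1.0, 100.0),
    "tau": (1.0, 30.0),  # source range unrecoverable; see run metadata
    "k": (-2.2, 51.8),
    "p_change": (0.3, 0.7),
    "sigma_local": (0.0, 1.0),
    "sigma_global": (0.0, 1.0),
}

_ENCODINGS = ("E", "V")
_ASSUMPTIONS = ("V", "E", "A", "S")
_RULES = ("O", "M")
_NOISES = ("none", "local", "global")


@dataclass(frozen=True)
class ModelSpec:
    """One observer model: encoding x assumption x rule (+ noise variant)."""

    encoding: str
    assumption: str
    rule: str
    noise: str = "none"

    def __post_init__(self):
        if self.encoding not in _ENCODINGS:
            raise ValueError(f"encoding must be one of {_ENCODINGS}")
        if self.assumption not in _ASSUMPTIONS:
            raise ValueError(f"assumption must be one of {_ASSUMPTIONS}")
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}")
        if self.noise not in _NOISES:
            raise ValueError(f"noise must be one of {_NOISES}")
        if self.noise != "none" and (self.encoding, self.assumption, self.rule) != ("E", "E", "O"):
            raise ValueError("decision-noise variants are defined only for EEO")

    @property
    def code(self) -> str:
        base = f"{self.encoding}{self.assumption}{self.rule}"
        return base if self.noise == "none" else f"{base}+{self.noise}"

    @property
    def is_canonical(self) -> bool:
        """True for the 14 taxonomy models (EV* combinations are redundant)."""
        return self.noise == "none" and not (self.encoding == "E" and self.assumption == "V")

    @property
    def free_params(self) -> tuple:
        if self.encoding == "V":
            names = ["Jbar_low", "Jbar_high", "tau"]
        else:
            names = ["J_low", "J_high"]
        if self.assumption == "S" and self.rule == "O":
            names.append("J_assumed")  # under the Max rule it is absorbed into k
        names.append("p_change" if self.rule == "O" else "k")
        if self.noise == "local":
            names.append("sigma_local")
        elif self.noise == "global":
            names.append("sigma_global")
        return tuple(names)

    def __str__(self):
        return self.code


#: Table-order codes of the 14 canonical models.
MODEL_CODES = (
    "VVO", "VEO", "VAO", "VSO", "VVM", "VEM", "VAM", "VSM",
    "EEO", "EAO", "ESO", "EEM", "EAM", "ESM",
)


def parse_model_code(code: str) -> ModelSpec:
    """Parse a three-letter model code, optionally '+local'/'+global'."""
    base, _, noise = code.partition("+")
    noise = noise or "none"
    if len(base) != 3:
        raise ValueError(f"unknown model code {code!r}; valid codes: {', '.join(MODEL_CODES)}")
    spec = ModelSpec(base[0], base[1], base[2], noise)
    if not spec.is_canonical and noise == "none":
        raise ValueError(f"unknown model code {code!r}; valid codes: {', '.join(MODEL_CODES)}")
    return spec


def enumerate_models() -> list:
    """The 14 canonical models, in taxonomy-table order."""
    return [parse_model_code(c) for c in MODEL_CODES]


def validate_params(spec: ModelSpec, params) -> dict:
    """Check that `params` covers the free parameters of `spec` with legal values."""
    out = {}
    for name in spec.free_params:
        if name not in params:
            raise ValueError(f"model {spec.code} requires parameter {name!r}")
        v = float(params[name])
        if not np.isfinite(v):
            raise ValueError(f"parameter {name!r} must be finite")
        if name.startswith("J") and v <= 0:
            raise ValueError(f"parameter {name!r} must be > 0")
        if name == "tau" and v <= 0:
            raise ValueError("tau must be > 0")
        if name == "p_change" and not (0.0 < v < 1.0):
            raise ValueError("p_change must be in (0, 1)")
        if name.startswith("sigma") and v < 0:
            raise ValueError("noise sigma must be >= 0")
        out[name] = v
    return out


@dataclass
class TrialPercept:
    """Measurements and realized precisions of one trial (internal space)."""

    x: np.ndarray            # display-1 measurements, shape (4,)
    y: np.ndarray            # display-2 measurements, shape (4,)
    realized_jx: np.ndarray  # precision actually used per item, display 1
    realized_jy: np.ndarray
    reliabilities: np.ndarray  # bool, True = high

    def __post_init__(self):
        for name in ("x", "y", "realized_jx", "realized_jy", "reliabilities"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (4,):
                raise ValueError(f"{name} must have shape (4,)")
            setattr(self, name, arr)


def assumed_kappas(percept: TrialPercept, spec: ModelSpec, params) -> tuple:
    """Concentrations the observer plugs into the decision variable.

    Assumption V uses each item's realized precision; E the reliability-
    determined value (J_low/J_high under EP, Jbar_low/Jbar_high under VP);
    A the mean realized precision of each display (averaged over the four
    items, per display); S a single value J_assumed for everything.
    """
    a = spec.assumption
    if a == "V":
        jx, jy = percept.realized_jx, percept.realized_jy
    elif a == "E":
        low, high = (("J_low", "J_high") if spec.encoding == "E"
                     else ("Jbar_low", "Jbar_high"))
        j = np.where(percept.reliabilities, float(params[high]), float(params[low]))
        jx = jy = j
    elif a == "A":
        jx = np.full(4, np.mean(percept.realized_jx))
        jy = np.full(4, np.mean(percept.realized_jy))
    else:  # S
        j_assumed = float(params.get("J_assumed", J_ASSUMED_REF))
        jx = jy = np.full(4, j_assumed)
    return kappa_from_j(np.asarray(jx, dtype=float)), kappa_from_j(np.asarray(jy, dtype=float))


def log_local_decision_variable(xi, yi, kx, ky):
    """log d_i; stable for large concentrations."""
    xi, yi = np.asarray(xi, dtype=float), np.asarray(yi, dtype=float)
    kx, ky = np.asarray(kx, dtype=float), np.asarray(ky, dtype=float)
    if not all(np.all(np.isfinite(a)) for a in (xi, yi, kx, ky)):
        raise ValueError("inputs must be finite")
    if np.any(kx < 0) or np.any(ky < 0):
        raise ValueError("concentrations must be >= 0")
    kc = np.sqrt(kx**2 + ky**2 + 2.0 * kx * ky * np.cos(xi - yi))
    return log_i0(kx) + log_i0(ky) - log_i0(kc)


def local_decision_variable(xi, yi, kx, ky):
    """Posterior ratio of change vs no change at one location (Bessel form)."""
    out = np.exp(log_local_decision_variable(xi, yi, kx, ky))
    return float(out) if np.ndim(out) == 0 else out


def optimal_rule(d, p_change) -> bool:
    """Report change iff (p/(1-p)) * mean_i(d_i) > 1; ties -> no change."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("decision variables must be > 0")
    if not (0.0 < p_change < 1.0):
        raise ValueError("p_change must be in (0, 1)")
    return bool(p_change / (1.0 - p_change) * np.mean(d) > 1.0)


def max_rule(d, k) -> bool:
    """Report change iff max_i(d_i) > k; ties -> no change."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("decision variables must be > 0")
    return bool(np.max(d) > float(k))


def apply_decision_noise(d, variant, sigma, p_change, rng) -> bool:
    """Optimal rule with Gaussian noise on log decision variables.

    'local' perturbs each log d_i independently before integration; 'global'
    perturbs the log of the integrated quantity once. sigma = 0 reduces to
    the noiseless optimal rule.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("decision variables must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    logd = np.log(d)
    if variant == "local":
        logd = logd + rng.normal(0.0, sigma, size=logd.shape)
        lhs = np.log(p_change / (1.0 - p_change)) + _log_mean_exp(logd)
    elif variant == "global":
        lhs = (np.log(p_change / (1.0 - p_change)) + _log_mean_exp(logd)
               + rng.normal(0.0, sigma))
    else:
        raise ValueError("variant must be 'local' or 'global'")
    return bool(lhs > 0.0)


def _log_mean_exp(logd, axis=None):
    m = np.max(logd, axis=axis, keepdims=True)
    out = np.squeeze(m, axis=axis) if axis is not None else np.squeeze(m)
    return out + np.log(np.mean(np.exp(logd - m), axis=axis))


def decide(percept: TrialPercept, spec: ModelSpec, params, rng=None) -> bool:
    """Full decision for one percept under `spec`."""
    kx, ky = assumed_kappas(percept, spec, params)
    logd = log_local_decision_variable(percept.x, percept.y, kx, ky)
    if spec.noise != "none":
        sigma = params["sigma_local" if spec.noise == "local" else "sigma_global"]
        return apply_decision_noise(np.exp(logd), spec.noise, sigma,
                                    params["p_change"], rng)
    if spec.rule == "O":
        p = params["p_change"]
        return bool(np.log(p / (1.0 - p)) + _log_mean_exp(logd) > 0.0)
    k = params["k"]
    if k <= 0.0:
        return True
    return bool(np.max(logd) > np.log(k))
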