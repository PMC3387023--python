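"""Monte-Carlo model predictions and dataset likelihoods.

A model's probability of reporting "change" depends on a trial only through
its type: the magnitude-of-change bin (|delta| binned to the nearest multiple
of 3 degrees, 0..90: 31 bins), the number of high-reliability items N_H, and
the reliability of the changed item - 31*5*2 = 310 types. No-change trials
enter the bin-0 / low-reliability cell of their N_H, and that cell is
predicted by simulating genuine no-change trials. Per type, predictions are
Monte-Carlo estimates over `n_samples` simulated percepts; probabilities are
clipped to [eps, 1-eps] with eps = 1/(2 n_samples) so log-likelihoods stay
finite. All grid evaluations share random numbers across parameter points.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _engine
from ._engine import FEASIBLE, N_TYPES, type_index
from .observers import PARAM_RANGES, ModelSpec, validate_params

__all__ = [
    "TrialType",
    "N_TRIAL_TYPES",
    "all_trial_types",
    "classify_trial",
    "classify_table",
    "PredictionTable",
    "predict_table",
    "log_likelihood",
    "make_grid",
    "grid_from_config",
    "FitResult",
    "fit_mle",
]

N_TRIAL_TYPES = N_TYPES


class TrialType(NamedTuple):
    """One of the 310 trial types."""

    delta_bin: int                # 0..30; bin value is 3*delta_bin degrees
    n_high: int                   # 0..4
    changed_reliability: str      # "low" | "high"; no-change trials -> "low"

    @property
    def index(self) -> int:
        return int(type_index(self.delta_bin, self.n_high,
                              self.changed_reliability == "high"))


def all_trial_types():
    """The full 310-cell type space, in index order."""
    out = []
    for b in range(31):
        for h in range(5):
            for rel in ("low", "high"):
                out.append(TrialType(b, h, rel))
    return out


def classify_trial(trial) -> TrialType:
    """Map one trial (row of a trial table) to its type."""
    delta = abs(float(trial["delta"]))
    b = int(min(np.floor(delta / 3.0 + 0.5), 30))
    rels = [trial[f"rel_{i}"] for i in range(1, 5)]
    n_high = sum(r == "H" for r in rels)
    if int(trial["change"]):
        rel = "high" if rels[int(trial["change_location"]) - 1] == "H" else "low"
    else:
        b, rel = 0, "low"
    return TrialType(b, n_high, rel)


def classify_table(trials: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`classify_trial`; returns flat cell indices."""
    delta = np.abs(trials["delta"].to_numpy(dtype=float))
    b = np.minimum(np.floor(delta / 3.0 + 0.5), 30).astype(int)
    rel = (trials[[f"rel_{i}" for i in range(1, 5)]].to_numpy() == "H")
    n_high = rel.sum(axis=1)
    change = trials["change"].to_numpy(dtype=int).astype(bool)
    loc = trials["change_location"].to_numpy(dtype=int)
    changed_high = np.zeros(len(trials), dtype=bool)
    changed_high[change] = rel[np.flatnonzero(change), loc[change] - 1]
    b[~change] = 0
    return type_index(b, n_high, changed_high)


@dataclass
class PredictionTable:
    """Per-type probability of reporting "change" for one model/parameter point."""

    probs: np.ndarray  # (310,), NaN at design-unreachable cells
    n_samples: int
    spec: ModelSpec = None
    params: dict = None

    def prob(self, trial_type: TrialType) -> float:
        return float(self.probs[trial_type.index])

    def to_frame(self) -> pd.DataFrame:
        tt = all_trial_types()
        return pd.DataFrame({
            "delta_bin": [t.delta_bin for t in tt],
            "n_high": [t.n_high for t in tt],
            "changed_reliability": [t.changed_reliability for t in tt],
            "p_change_report": [self.probs[t.index] for t in tt],
        })


def predict_table(spec: ModelSpec, params, n_samples=1000, seed=0) -> PredictionTable:
    """Monte-Carlo probability of a "change" report for each of the 310 types."""
    params = validate_params(spec, params)
    grid = {name: np.array([params[name]]) for name in spec.free_params}
    _, _, P = _engine.grid_prediction_tables(spec, grid, n_samples, seed)
    return PredictionTable(probs=P[0].astype(float), n_samples=n_samples,
                           spec=spec, params=params)


def _counts(trials: pd.DataFrame):
    if trials["response"].isna().any():
        raise ValueError("all trials must have responses")
    cells = classify_table(trials)
    resp = trials["response"].to_numpy()
    if not np.all(np.isin(resp, ["change", "no_change"])):
        raise ValueError("responses must be 'change' or 'no_change'")
    return _engine.counts_from_cells(cells, resp == "change")


def log_likelihood(trials, spec: ModelSpec, params, n_samples=1000, seed=0) -> float:
    """Log probability of the responses in `trials` under (spec, params).

    Deterministic given (params, seed): the Monte-Carlo percepts are drawn
    from streams keyed by the seed, common to all parameter values.
    """
    c1, c0 = _counts(trials)
    table = predict_table(spec, params, n_samples=n_samples, seed=seed)
    return float(_engine.loglik_from_tables(table.probs[None, :], c1, c0)[0])


def make_grid(spec: ModelSpec, points_per_dim=15, fine_points=None, ranges=None,
              overrides=None):
    """Linearly spaced parameter grid over the default prior ranges.

    Axis resolution follows per-axis cost. The expensive axes are the ones
    that require fresh percept simulations per point: the variable-precision
    means and scale (gamma transforms per point) and the assumed precision
    (a decision-variable pass per point); they get `points_per_dim` points.
    The cheap axes - the decision thresholds p_change and k (a comparison
    sweep over precomputed statistics), the decision-noise sigmas, and the
    equal-precision J_low/J_high (deterministic percept transforms) - default
    to the nested 4x finer ladder (4*points_per_dim - 3). The criterion k in
    particular needs the finer ladder: the behaviorally distinct (liberal)
    criteria occupy a narrow slice of its search range.
    """
    ranges = dict(PARAM_RANGES, **(ranges or {}))
    if fine_points is None:
        fine_points = 4 * points_per_dim - 3
    fine_axes = {"p_change", "k", "sigma_local", "sigma_global", "J_low", "J_high"}
    grid = {}
    for name in spec.free_params:
        lo, hi = ranges[name]
        n = fine_points if name in fine_axes else points_per_dim
        grid[name] = np.linspace(lo, hi, n)
    for name, values in (overrides or {}).items():
        grid[name] = np.atleast_1d(np.asarray(values, dtype=float))
    return grid


def grid_from_config(config, spec: ModelSpec = None):
    """Build a grid from a {param: {min, max, points}} mapping (e.g. YAML)."""
    grid = {}
    for name, entry in config.items():
        grid[name] = np.linspace(float(entry["min"]), float(entry["max"]),
                                 int(entry["points"]))
    if spec is not None:
        missing = [p for p in spec.free_params if p not in grid]
        if missing:
            raise ValueError(f"grid config missing parameters {missing} for {spec.code}")
    return grid


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model on one dataset."""

    spec: ModelSpec
    params: dict
    log_likelihood: float
    grid: dict
    n_samples: int
    seed: int


def fit_mle(trials, spec: ModelSpec, grid, n_samples=1000, seed=0) -> FitResult:
    """Exhaustive maximum-likelihood search over a parameter grid.

    Common random numbers across grid points keep the Monte-Carlo likelihood
    surface smooth; ties return the first point in row-major grid order.
    """
    c1, c0 = _counts(trials)
    names, axes, P = _engine.grid_prediction_tables(spec, grid, n_samples, seed)
    ll = _engine.loglik_from_tables(P, c1, c0)
    best = int(np.argmax(ll))
    idx = np.unravel_index(best, [a.size for a in axes])
    params = {n: float(axes[i][idx[i]]) for i, n in enumerate(names)}
    if "k" in params and axes[names.index("k")].size > 1:
        kax = axes[names.index("k")]
        if params["k"] in (kax[0], kax[-1]):
            warnings.warn(
                f"criterion k fitted at the boundary of its search range "
                f"[{kax[0]}, {kax[-1]}]; consider widening the grid",
                stacklevel=2)
    return FitResult(spec=spec, params=params, log_likelihood=float(ll[best]),
                     grid={n: axes[i] for i, n in enumerate(names)},
                     n_samples=n_samples, seed=seed)
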