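"""Synthetic task generator: trial tables and simulated observer responses.

The experimental design being emulated: each trial shows two 4-item displays
of oriented ellipses. The number of high-reliability items N_H is uniform on
{0..4} and their locations are uniform given N_H; orientations are i.i.d.
uniform over the orientation circle. With probability 0.5 exactly one item
changes orientation between displays, the changed location is uniform, and
the change magnitude is uniform over all orientations. Files store physical
degrees in [-90, 90); the signed change magnitude `delta` lies in (-90, 90]
and is 0 on no-change trials.

Responses are generated by any observer model from the taxonomy. Each trial
uses its own counter-based random stream keyed by (seed, trial_id), so
responses carry no hidden state between trials: simulating a permuted trial
table with the same seed permutes the responses identically.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .angles import to_internal, wrap_physical
from .encoding import kappa_from_j
from .observers import ModelSpec, TrialPercept, decide, validate_params

__all__ = [
    "TRIAL_COLUMNS",
    "generate_trials",
    "simulate_responses",
    "write_trials",
    "read_trials",
]

TRIAL_COLUMNS = (
    ["trial_id"]
    + [f"rel_{i}" for i in range(1, 5)]
    + [f"theta_{i}" for i in range(1, 5)]
    + [f"phi_{i}" for i in range(1, 5)]
    + ["change", "change_location", "delta", "response"]
)


def generate_trials(n, rng) -> pd.DataFrame:
    """Generate `n` trials of the change-detection design (responses missing)."""
    if not (isinstance(n, (int, np.integer)) and n > 0):
        raise ValueError("n must be a positive integer")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_high = rng.integers(0, 5, size=n)
    # uniform high-reliability locations given N_H: rank i.i.d. uniforms
    order = np.argsort(rng.random((n, 4)), axis=1)
    rel = order < n_high[:, None]  # True = high
    theta = rng.uniform(-90.0, 90.0, size=(n, 4))
    change = rng.random(n) < 0.5
    loc = rng.integers(0, 4, size=n)
    delta = rng.uniform(-90.0, 90.0, size=n)
    # signed magnitude reported in (-90, 90]
    delta[delta == -90.0] = 90.0
    delta[~change] = 0.0
    phi = theta.copy()
    rows = np.flatnonzero(change)
    phi[rows, loc[rows]] = wrap_physical(theta[rows, loc[rows]] + delta[rows])
    df = pd.DataFrame({"trial_id": np.arange(n)})
    for i in range(4):
        df[f"rel_{i+1}"] = np.where(rel[:, i], "H", "L")
    for i in range(4):
        df[f"theta_{i+1}"] = theta[:, i]
    for i in range(4):
        df[f"phi_{i+1}"] = phi[:, i]
    df["change"] = change.astype(int)
    df["change_location"] = np.where(change, loc + 1, 0)
    df["delta"] = delta
    df["response"] = pd.array([pd.NA] * n, dtype="string")
    return df


def _percept_for_trial(theta, phi, rel_high, spec, params, rng):
    if spec.encoding == "E":
        j = np.where(rel_high, params["J_high"], params["J_low"])
        jx, jy = j, j.copy()
    else:
        jbar = np.where(rel_high, params["Jbar_high"], params["Jbar_low"])
        tau = params["tau"]
        jx = rng.gamma(jbar / tau, tau)
        jy = rng.gamma(jbar / tau, tau)
    x = rng.vonmises(theta, kappa_from_j(jx))
    y = rng.vonmises(phi, kappa_from_j(jy))
    return TrialPercept(x=x, y=y, realized_jx=jx, realized_jy=jy,
                        reliabilities=rel_high)


def simulate_responses(trials: pd.DataFrame, spec: ModelSpec, params, seed=0) -> pd.DataFrame:
    """Simulate a response for every trial under observer model `spec`.

    Percepts are drawn through the encoding model (one measurement per item
    per display), the observer's assumed concentrations are computed, and the
    model's integration rule (plus any decision-noise variant) is applied.
    """
    params = validate_params(spec, params)
    rel = (trials[[f"rel_{i}" for i in range(1, 5)]].to_numpy() == "H")
    theta = to_internal(trials[[f"theta_{i}" for i in range(1, 5)]].to_numpy(dtype=float))
    phi = to_internal(trials[[f"phi_{i}" for i in range(1, 5)]].to_numpy(dtype=float))
    trial_ids = trials["trial_id"].to_numpy()
    responses = np.empty(len(trials), dtype=object)
    for row in range(len(trials)):
        rng = np.random.Generator(
            np.random.Philox(key=np.array([seed, int(trial_ids[row])], dtype=np.uint64)))
        percept = _percept_for_trial(theta[row], phi[row], rel[row], spec, params, rng)
        responses[row] = "change" if decide(percept, spec, params, rng) else "no_change"
    out = trials.copy()
    out["response"] = pd.array(responses, dtype="string")
    return out


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (orientations in physical degrees)."""
    df = trials.copy()
    df["response"] = df["response"].astype("string")
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    try:
        df = pd.read_csv(
            path,
            dtype={"trial_id": int, "change": int, "change_location": int,
                   "response": "string"},
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError) as err:
        raise ValueError(f"malformed trial table {path}: {err}") from err
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "response"]
    if missing:
        raise ValueError(f"malformed trial table {path}: missing columns {missing}")
    if "response" not in df.columns:
        df["response"] = pd.array([pd.NA] * len(df), dtype="string")
    return df[list(TRIAL_COLUMNS)]
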