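"""Behavioral summary statistics and goodness of fit.

Summaries follow the standard presentation for this task: hit and
false-alarm rates as a function of the number of high-reliability items N_H,
hit rates additionally conditioned on the reliability of the changed item
(whose crossing with the unconditioned rate produces the Simpson's-paradox
Z-shape under precision-weighted observers), and psychometric curves of the
proportion of "change" reports in change trials over 8 equal-width
magnitude-of-change bins. R-squared compares observed and predicted
summaries either over the 10 rate points (false alarms + unconditioned hits)
or over the 8 x 5 psychometric cells.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import CHANGE_GROUPS, DELTA_BIN_DEG, N_BINS, type_index
from .likelihood import predict_table
from .observers import ModelSpec

__all__ = ["PSYCH_EDGES", "SummaryStats", "summarize", "model_summary",
           "r_squared", "plot_summary"]

#: Psychometric bin edges over |delta| in (0, 90] degrees (8 equal bins).
PSYCH_EDGES = np.linspace(0.0, 90.0, 9)


@dataclass
class SummaryStats:
    """Rates by N_H plus psychometric curves; NaN marks undefined cells."""

    false_alarm: np.ndarray   # (5,)
    hit: np.ndarray           # (5,)
    hit_low: np.ndarray       # (5,), NaN at N_H = 4
    hit_high: np.ndarray      # (5,), NaN at N_H = 0
    n_nochange: np.ndarray
    n_change_low: np.ndarray
    n_change_high: np.ndarray
    psychometric: np.ndarray  # (8, 5): proportion "change" in change trials
    psychometric_n: np.ndarray

    def rates_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_high": np.arange(5),
            "false_alarm_rate": self.false_alarm,
            "hit_rate": self.hit,
            "hit_rate_low_change": self.hit_low,
            "hit_rate_high_change": self.hit_high,
            "n_nochange": self.n_nochange,
            "n_change_low": self.n_change_low,
            "n_change_high": self.n_change_high,
        })

    def psychometric_frame(self) -> pd.DataFrame:
        rows = []
        for m in range(8):
            for h in range(5):
                rows.append({"bin_low_deg": PSYCH_EDGES[m], "bin_high_deg": PSYCH_EDGES[m + 1],
                             "n_high": h, "p_change_report": self.psychometric[m, h],
                             "n_trials": self.psychometric_n[m, h]})
        return pd.DataFrame(rows)


def _rate(num, den):
    out = np.full(np.shape(den), np.nan)
    nz = np.asarray(den) > 0
    out[nz] = np.asarray(num)[nz] / np.asarray(den)[nz]
    return out


def summarize(trials: pd.DataFrame) -> SummaryStats:
    """Empirical summary statistics of a trial table with responses."""
    if trials["response"].isna().any():
        raise ValueError("all trials must have responses")
    rel = (trials[[f"rel_{i}" for i in range(1, 5)]].to_numpy() == "H")
    n_high = rel.sum(axis=1)
    change = trials["change"].to_numpy(dtype=int).astype(bool)
    said_change = (trials["response"].to_numpy() == "change")
    loc = trials["change_location"].to_numpy(dtype=int)
    changed_high = np.zeros(len(trials), dtype=bool)
    changed_high[change] = rel[np.flatnonzero(change), loc[change] - 1]

    nc = ~change
    n_nc = np.bincount(n_high[nc], minlength=5).astype(float)
    fa = _rate(np.bincount(n_high[nc & said_change], minlength=5), n_nc)
    lo, hi = change & ~changed_high, change & changed_high
    n_lo = np.bincount(n_high[lo], minlength=5).astype(float)
    n_hi = np.bincount(n_high[hi], minlength=5).astype(float)
    hit_low = _rate(np.bincount(n_high[lo & said_change], minlength=5), n_lo)
    hit_high = _rate(np.bincount(n_high[hi & said_change], minlength=5), n_hi)
    hit = _rate(np.bincount(n_high[change & said_change], minlength=5), n_lo + n_hi)

    delta = np.abs(trials["delta"].to_numpy(dtype=float))
    mbin = np.clip(np.searchsorted(PSYCH_EDGES, delta[change], side="left") - 1, 0, 7)
    flat = mbin * 5 + n_high[change]
    psych_n = np.bincount(flat, minlength=40).astype(float).reshape(8, 5)
    psych_y = np.bincount(flat[said_change[change]], minlength=40).astype(float).reshape(8, 5)
    return SummaryStats(false_alarm=fa, hit=hit, hit_low=hit_low, hit_high=hit_high,
                        n_nochange=n_nc, n_change_low=n_lo, n_change_high=n_hi,
                        psychometric=_rate(psych_y, psych_n), psychometric_n=psych_n)


def _delta_bin_weights():
    # |delta| is uniform on [0, 90]; nearest-multiple-of-3 bins have width 3
    # except the half-width edge bins.
    w = np.full(N_BINS, 3.0)
    w[0] = w[-1] = 1.5
    return w / 90.0


def model_summary(spec: ModelSpec, params, n_samples=1000, seed=0) -> SummaryStats:
    """Summary statistics a model predicts under the experimental design.

    The per-type predicted probabilities are averaged with the design's trial
    type frequencies: N_H uniform on {0..4}, change probability 0.5, change
    location uniform (so P(changed item high | N_H) = N_H/4) and change
    magnitude uniform over [0, 90] degrees.
    """
    table = predict_table(spec, params, n_samples=n_samples, seed=seed)
    probs = table.probs
    wb = _delta_bin_weights()
    fa = np.array([probs[type_index(0, h, False)] for h in range(5)])
    hit_low = np.full(5, np.nan)
    hit_high = np.full(5, np.nan)
    for h in range(4):
        hit_low[h] = np.sum(wb * np.array([probs[type_index(b, h, False)]
                                           for b in range(N_BINS)]))
    for h in range(1, 5):
        hit_high[h] = np.sum(wb * np.array([probs[type_index(b, h, True)]
                                            for b in range(N_BINS)]))
    w_high = np.arange(5) / 4.0
    hit = np.where(w_high == 0, hit_low,
                   np.where(w_high == 1, hit_high,
                            w_high * hit_high + (1 - w_high) * hit_low))
    # expected counts per cell are proportional to the design frequencies
    n_nc = np.full(5, 0.5 / 5)
    n_lo = 0.5 / 5 * (1 - w_high)
    n_hi = 0.5 / 5 * w_high
    # psychometric: overlap weights of the 31 magnitude bins with the 8 bins
    overlap = np.zeros((8, N_BINS))
    for b in range(N_BINS):
        lo_edge, hi_edge = DELTA_BIN_DEG[b] - 1.5, DELTA_BIN_DEG[b] + 1.5
        for m in range(8):
            o = min(hi_edge, PSYCH_EDGES[m + 1]) - max(lo_edge, PSYCH_EDGES[m])
            if o > 0:
                overlap[m, b] = o
    overlap /= overlap.sum(axis=1, keepdims=True)
    psych = np.full((8, 5), np.nan)
    for h in range(5):
        p_low = np.array([probs[type_index(b, h, False)] for b in range(N_BINS)])
        p_high = np.array([probs[type_index(b, h, True)] for b in range(N_BINS)])
        mix = (w_high[h] * np.nan_to_num(p_high)
               + (1 - w_high[h]) * np.nan_to_num(p_low))
        psych[:, h] = overlap @ mix
    return SummaryStats(false_alarm=fa, hit=hit, hit_low=hit_low, hit_high=hit_high,
                        n_nochange=n_nc, n_change_low=n_lo, n_change_high=n_hi,
                        psychometric=psych, psychometric_n=np.full((8, 5), np.nan))


def r_squared(observed: SummaryStats, predicted: SummaryStats, which="rates") -> float:
    """1 - SS_res/SS_tot over the selected summary cells.

    "rates" uses the 10 points of false-alarm and unconditioned hit rates;
    "psychometric" uses the 8 x 5 curve cells. Cells undefined in either
    summary are excluded.
    """
    if which == "rates":
        obs = np.concatenate([observed.false_alarm, observed.hit])
        pred = np.concatenate([predicted.false_alarm, predicted.hit])
    elif which == "psychometric":
        obs = observed.psychometric.ravel()
        pred = predicted.psychometric.ravel()
    else:
        raise ValueError("which must be 'rates' or 'psychometric'")
    ok = np.isfinite(obs) & np.isfinite(pred)
    if ok.sum() < 2:
        raise ValueError("need at least two defined cells")
    obs, pred = obs[ok], pred[ok]
    ss_res = np.sum((obs - pred) ** 2)
    ss_tot = np.sum((obs - np.mean(obs)) ** 2)
    return float(1.0 - ss_res / ss_tot)


def plot_summary(stats: SummaryStats, model_stats: SummaryStats = None, path=None):
    """Rates-by-N_H and psychometric panels; optionally overlay a model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    x = np.arange(5)
    series = [("hit_rate", stats.hit, "tab:blue"),
              ("hit | low change", stats.hit_low, "tab:green"),
              ("hit | high change", stats.hit_high, "tab:olive"),
              ("false alarms", stats.false_alarm, "tab:red")]
    for label, y, color in series:
        ax1.plot(x, y, "o-", color=color, label=label)
    if model_stats is not None:
        for _, y, color in [("", model_stats.hit, "tab:blue"),
                            ("", model_stats.hit_low, "tab:green"),
                            ("", model_stats.hit_high, "tab:olive"),
                            ("", model_stats.false_alarm, "tab:red")]:
            ax1.plot(x, y, "--", color=color, alpha=0.6)
    ax1.set_xlabel("number of high-reliability items")
    ax1.set_ylabel("proportion 'change' reports")
    ax1.set_ylim(0, 1)
    ax1.legend(fontsize=7)
    centers = 0.5 * (PSYCH_EDGES[:-1] + PSYCH_EDGES[1:])
    for h in range(5):
        ax2.plot(centers, stats.psychometric[:, h], "o-", label=f"N_H={h}")
        if model_stats is not None:
            ax2.plot(centers, model_stats.psychometric[:, h], "--", alpha=0.6)
    ax2.set_xlabel("magnitude of change (deg)")
    ax2.set_ylim(0, 1)
    ax2.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
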