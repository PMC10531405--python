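"""Licking behavior: trial classification and learning variables.

Implements the behavioral quantities of the Go/No-go task: per-trial lick
latency, the slow polynomial latency trend selected by AIC among orders
0..5, the normalized lick-latency fluctuation, the early-lick count
(response-window [0, 0.5) s), session performance fractions, and the linear
learning slopes of fluctuation and early licks against trial index (negative
slope = improvement with training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Trial, classify_trial, stage_of

EARLY_WINDOW = (0.0, 0.5)
#: variance floor in the AIC for numerically perfect fits
RSS_FLOOR = 1e-12


@dataclass
class TrialBehavior:
    trial_id: int
    lick_latency: float | None
    latency_fluctuation: float | None
    early_lick_count: int


@dataclass
class PolyFit:
    order: int
    coefficients: np.ndarray          # ascending powers
    aic: dict[int, float]
    fitted: np.ndarray                # at the training trial indices
    x: np.ndarray                     # the trial indices used

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                self.coefficients)


@dataclass
class SessionSummary:
    fraction_correct: float
    fraction_correct_go: float | None
    fraction_incorrect_nogo: float | None
    stage: int
    fluctuation_slope: float | None = None
    early_lick_slope: float | None = None


def fit_latency_trend(latencies, trial_index=None, max_order: int = 5) -> PolyFit:
    """AIC-selected polynomial trend (orders 0..5) of lick latency vs trial.

    AIC uses the Gaussian profile form ``n * ln(RSS / n) + 2 * (order + 1)``;
    with fewer than 7 points the candidate order is capped at ``n - 2``.
    """
    y = np.asarray(latencies, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 latencies to fit a trend")
    x = (np.arange(n, dtype=float) if trial_index is None
         else np.asarray(trial_index, dtype=float))
    cap = min(max_order, n - 2)
    aics: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for order in range(cap + 1):
        coeffs = np.polynomial.polynomial.polyfit(x, y, order)
        resid = y - np.polynomial.polynomial.polyval(x, coeffs)
        rss = max(float(resid @ resid), RSS_FLOOR)
        aics[order] = n * np.log(rss / n) + 2 * (order + 1)
        fits[order] = coeffs
    best = min(aics, key=lambda o: (aics[o], o))
    coeffs = fits[best]
    return PolyFit(order=best, coefficients=coeffs, aic=aics,
                   fitted=np.polynomial.polynomial.polyval(x, coeffs), x=x)


def compute_lick_variables(trial: Trial, trend: PolyFit | None,
                           mean_latency: float,
                           trial_index: float | None = None) -> TrialBehavior:
    """Per-trial latency, fluctuation and early-lick count.

    Fluctuation = |latency - trend(trial index)| / per-mouse mean latency,
    defined for HIT/FA only (no response-window lick otherwise).
    """
    early = sum(1 for t in trial.lick_times
                if EARLY_WINDOW[0] <= t < EARLY_WINDOW[1])
    if trial.condition not in ("HIT", "FA") or trial.first_lick is None:
        return TrialBehavior(trial.trial_id, None, None, early)
    if mean_latency <= 0:
        raise ValueError("mean_latency must be positive")
    lat = trial.first_lick
    fluct = None
    if trend is not None:
        xi = trial_index if trial_index is not None else trial.trial_id
        fluct = abs(lat - float(trend.predict(xi))) / mean_latency
    return TrialBehavior(trial.trial_id, lat, fluct, early)


def mouse_mean_latency(trials) -> float | None:
    """Mean first-lick latency over a mouse's HIT and FA trials."""
    lats = [t.first_lick for t in trials
            if t.condition in ("HIT", "FA") and t.first_lick is not None]
    return float(np.mean(lats)) if lats else None


def _slope(x, y) -> float | None:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or np.ptp(x) == 0:
        return None
    return float(np.polynomial.polynomial.polyfit(x, y, 1)[1])


def summarize_session(trials, behaviors=None,
                      trial_index=None) -> SessionSummary:
    """Performance fractions and learning slopes for one session.

    Slopes are univariate least squares of lick-latency fluctuation (Go
    trials) and early-lick count (No-go trials) on the trial index.
    """
    trials = list(trials)
    n = len(trials)
    if n == 0:
        raise ValueError("empty session")
    n_correct = sum(t.condition in ("HIT", "CR") for t in trials)
    go = [t for t in trials if t.cue == "Go"]
    nogo = [t for t in trials if t.cue == "Nogo"]
    frac = n_correct / n
    frac_go = (sum(t.condition == "HIT" for t in go) / len(go)) if go else None
    frac_fa = (sum(t.condition == "FA" for t in nogo) / len(nogo)) if nogo else None
    fl_slope = el_slope = None
    if behaviors is not None:
        bmap = {b.trial_id: b for b in behaviors}
        xs = (np.arange(n, dtype=float) if trial_index is None
              else np.asarray(trial_index, float))
        fx, fy, ex, ey = [], [], [], []
        for xi, t in zip(xs, trials):
            b = bmap.get(t.trial_id)
            if b is None:
                continue
            if t.cue == "Go" and b.latency_fluctuation is not None:
                fx.append(xi)
                fy.append(b.latency_fluctuation)
            if t.cue == "Nogo":
                ex.append(xi)
                ey.append(b.early_lick_count)
        fl_slope = _slope(fx, fy)
        el_slope = _slope(ex, ey)
    return SessionSummary(fraction_correct=frac, fraction_correct_go=frac_go,
                          fraction_incorrect_nogo=frac_fa, stage=stage_of(frac),
                          fluctuation_slope=fl_slope, early_lick_slope=el_slope)


__all__ = ["TrialBehavior", "PolyFit", "SessionSummary", "classify_trial",
           "fit_latency_trend", "compute_lick_variables", "mouse_mean_latency",
           "summarize_session", "EARLY_WINDOW"]
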