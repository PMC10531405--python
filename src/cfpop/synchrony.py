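"""Complex-spike synchrony: instantaneous (per-trial) and CCG-based.

Two statistics:

* **Instantaneous synchrony** — within one trial, the number of synchronous
  spike pairs across a population (distinct neurons co-active in 30 ms bins)
  in a 300 ms window (ending at the first lick for HIT/FA, [0, 0.3) s after
  the cue for CR/MISS), normalized by the number of neuron pairs C(N, 2).

* **Synchrony strength** — for a neuron pair across a session's trials, the
  cross-correlogram of 10 ms-binned trains normalized by the geometric mean
  of the spike counts, summed over the three lags within +-10 ms of zero.
  A shift predictor (reference train rotated by one trial) estimates the
  part of the correlation locked to the cue rather than to interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .datamodel import TRIAL_END, TRIAL_START, Trial

SYNC_BIN = 0.030          # s, instantaneous-synchrony bin
SYNC_WINDOW = 0.300       # s
CCG_BIN = 0.010           # s
CCG_MAX_LAG = 0.100       # s
STRENGTH_HALF_WIDTH = 1   # lags within +-10 ms of zero => 3 bins


@dataclass
class InstantSynchrony:
    trial_id: int
    value: float
    n_neurons: int
    window: tuple[float, float]
    spike_count_per_neuron: float


@dataclass
class CCG:
    lags: np.ndarray              # seconds, 10 ms steps
    values: np.ndarray
    shift_predictor: np.ndarray | None
    n_bins: int
    flagged: bool = False         # either train empty


def synchrony_window(trial: Trial, width: float = SYNC_WINDOW) -> tuple[float, float]:
    """[first_lick - width, first_lick) for HIT/FA; [0, width) for CR/MISS."""
    if trial.condition in ("HIT", "FA") and trial.first_lick is not None:
        return (trial.first_lick - width, trial.first_lick)
    return (0.0, width)


def instantaneous_synchrony(trains: dict[int, np.ndarray], trial: Trial,
                            bin_s: float = SYNC_BIN,
                            width: float = SYNC_WINDOW) -> InstantSynchrony:
    """Pairwise co-activation statistic of one trial.

    ``trains`` maps neuron_id -> spike times of this trial.  Multiple spikes
    of one neuron in one bin count once; the value is
    ``sum_bins C(n_k, 2) / C(N, 2)`` with ``n_k`` the number of distinct
    co-active neurons in bin k.
    """
    N = len(trains)
    if N < 2:
        raise ValueError("instantaneous synchrony needs at least 2 neurons")
    t0, t1 = synchrony_window(trial, width)
    n_bins = int(round((t1 - t0) / bin_s))
    active_per_bin = np.zeros(n_bins, dtype=int)
    total_spikes = 0
    for times in trains.values():
        times = np.asarray(times, float)
        inw = times[(times >= t0) & (times < t1)]
        total_spikes += inw.size
        if inw.size:
            bins = np.unique(np.floor((inw - t0) / bin_s).astype(int))
            bins = bins[(bins >= 0) & (bins < n_bins)]
            active_per_bin[bins] += 1
    pairs = sum(comb(int(n), 2) for n in active_per_bin)
    value = pairs / comb(N, 2)
    return InstantSynchrony(trial_id=trial.trial_id, value=value, n_neurons=N,
                            window=(t0, t1),
                            spike_count_per_neuron=total_spikes / N)


# ---------------------------------------------------------------------------
# cross-correlograms
# ---------------------------------------------------------------------------

def _bin_train(times: np.ndarray, t0: float, t1: float,
               bin_s: float) -> np.ndarray:
    n = int(round((t1 - t0) / bin_s))
    out = np.zeros(n, dtype=np.int8)
    idx = np.floor((np.asarray(times, float) - t0) / bin_s).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    out[idx] = 1
    return out


def cross_correlogram(x_trials: list[np.ndarray], y_trials: list[np.ndarray],
                      bin_s: float = CCG_BIN, max_lag: float = CCG_MAX_LAG,
                      support: tuple[float, float] = (TRIAL_START, TRIAL_END),
                      shift: bool = False) -> CCG:
    """Session CCG of two neurons from per-trial spike-time lists.

    ``C(t) = sum_i X(i) Y(i - t) / sqrt(sum X * sum Y)`` with numerator and
    counts pooled across trials (no cross-trial products).  With
    ``shift=True`` a shift predictor is also computed with the reference
    (y) trial assignment rotated by one within the session.
    """
    if len(x_trials) != len(y_trials):
        raise ValueError("need the same number of trials for both neurons")
    n_lags = int(round(max_lag / bin_s))
    lags = np.arange(-n_lags, n_lags + 1) * bin_s
    xb = [_bin_train(t, *support, bin_s) for t in x_trials]
    yb = [_bin_train(t, *support, bin_s) for t in y_trials]
    nx = sum(int(b.sum()) for b in xb)
    ny = sum(int(b.sum()) for b in yb)
    n_bins = sum(b.size for b in xb)

    def raw_counts(ys: list[np.ndarray]) -> np.ndarray:
        num = np.zeros(2 * n_lags + 1)
        for x, y in zip(xb, ys):
            full = np.correlate(x.astype(float), y.astype(float), mode="full")
            mid = y.size - 1
            num += full[mid - n_lags: mid + n_lags + 1][::-1]
        return num

    denom = np.sqrt(nx * ny)
    if denom == 0:
        zeros = np.zeros_like(lags)
        return CCG(lags=lags, values=zeros,
                   shift_predictor=zeros.copy() if shift else None,
                   n_bins=n_bins, flagged=True)
    values = raw_counts(yb) / denom
    shift_values = None
    if shift:
        rotated = yb[1:] + yb[:1]
        shift_values = raw_counts(rotated) / denom
    return CCG(lags=lags, values=values, shift_predictor=shift_values,
               n_bins=n_bins)


def synchrony_strength(ccg: CCG, shift_corrected: bool = False) -> float:
    """Sum of C(t) over the three lags within +-10 ms of zero."""
    center = len(ccg.lags) // 2
    if center - STRENGTH_HALF_WIDTH < 0:
        raise ValueError("CCG lags must cover +-10 ms")
    sl = slice(center - STRENGTH_HALF_WIDTH, center + STRENGTH_HALF_WIDTH + 1)
    val = float(np.sum(ccg.values[sl]))
    if shift_corrected:
        if ccg.shift_predictor is None:
            raise ValueError("CCG has no shift predictor")
        val -= float(np.sum(ccg.shift_predictor[sl]))
    return val


def pairwise_strengths(trains_by_neuron: dict[int, list[np.ndarray]],
                       bin_s: float = CCG_BIN, max_lag: float = CCG_MAX_LAG,
                       shift: bool = True) -> list[tuple[int, int, float, float]]:
    """Synchrony strength for every neuron pair of one session.

    ``trains_by_neuron`` maps neuron_id -> per-trial spike-time lists (same
    trial order for all neurons).  Returns rows
    ``(neuron_i, neuron_j, strength, shift_corrected_strength)``.
    """
    ids = sorted(trains_by_neuron)
    rows = []
    for ii, i in enumerate(ids):
        for j in ids[ii + 1:]:
            ccg = cross_correlogram(trains_by_neuron[i], trains_by_neuron[j],
                                    bin_s=bin_s, max_lag=max_lag, shift=shift)
            s = synchrony_strength(ccg)
            sc = synchrony_strength(ccg, shift_corrected=True) if shift else float("nan")
            rows.append((i, j, s, sc))
    return rows
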