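"""Spike-triggered lick responses and lick-event decoding likelihoods.

The spike-triggered lick response (STL) histograms lick onsets relative to
spike times, pooled across trials and normalized by the trial count, within
one of three response windows: early lick [0, 0.5), reward lick [0.5, 2),
succeeding lick [2, 4) s after the cue.  Treated as ``p(l | s)``, the
probability of a lick at a given lag from a single spike, it supports a
decoding comparison across spike collections: licks in [0, 1) s are scored
under each model by ``p(l | S) = prod_{s in S} p(l | s)`` against a chance
model ``p = 1/dt0`` per lick sample, and total log-likelihoods compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STL_BIN = 0.100          # s
STL_MAX_LAG = 1.0        # s
SYNC_FILTER_BIN = 0.030  # s, synchronous-spike co-activation bin
DECODE_WINDOW = (0.0, 1.0)
DT0 = 10.0               # Hz, lick-event sampling rate (1 / lick bin)
PROB_FLOOR = 1e-6

WINDOW_CLASSES = {"early": (0.0, 0.5), "reward": (0.5, 2.0),
                  "succeeding": (2.0, 4.0),
                  # common response used for decoding: the whole [0, 1) s
                  # post-cue event window
                  "decode": DECODE_WINDOW}


@dataclass
class SpikeTriggeredLick:
    lags: np.ndarray          # bin left edges, s
    response: np.ndarray      # licks/s per trial... rate units
    window_class: str
    n_trials: int
    bin_s: float = STL_BIN

    def rate_at(self, lag: float) -> float:
        """Histogram rate at a (lick - spike) lag; 0 outside the support."""
        i = int(np.floor((lag - self.lags[0]) / self.bin_s))
        if i < 0 or i >= self.response.size:
            return 0.0
        return float(self.response[i])


def spike_triggered_lick(spikes_per_trial: list[np.ndarray],
                         licks_per_trial: list[np.ndarray],
                         window_class: str = "early",
                         bin_s: float = STL_BIN,
                         max_lag: float = STL_MAX_LAG) -> SpikeTriggeredLick:
    """Histogram of lick-minus-spike lags pooled across trials.

    Spikes and licks are both restricted to the window class before lags
    are formed; the histogram is divided by the number of trials and the
    bin width, giving licks/s per trial.
    """
    if window_class not in WINDOW_CLASSES:
        raise ValueError(f"unknown window class: {window_class}")
    n_trials = len(spikes_per_trial)
    if n_trials == 0 or n_trials != len(licks_per_trial):
        raise ValueError("need matching, non-empty per-trial event lists")
    w0, w1 = WINDOW_CLASSES[window_class]
    n_lags = int(round(max_lag / bin_s))
    edges = np.arange(-n_lags, n_lags + 1) * bin_s
    counts = np.zeros(2 * n_lags)
    for spk, lck in zip(spikes_per_trial, licks_per_trial):
        spk = np.asarray(spk, float)
        lck = np.asarray(lck, float)
        spk = spk[(spk >= w0) & (spk < w1)]
        lck = lck[(lck >= w0) & (lck < w1)]
        if spk.size and lck.size:
            diffs = (lck[None, :] - spk[:, None]).ravel()
            counts += np.histogram(diffs, bins=edges)[0]
    return SpikeTriggeredLick(lags=edges[:-1],
                              response=counts / (n_trials * bin_s),
                              window_class=window_class, n_trials=n_trials,
                              bin_s=bin_s)


def filter_synchronous_spikes(trains: dict[int, np.ndarray],
                              bin_s: float = SYNC_FILTER_BIN
                              ) -> dict[int, np.ndarray]:
    """Keep spikes co-active (same 30 ms bin) with >= 1 other neuron's spike.

    ``trains`` maps neuron_id -> spike times of one trial for the neurons of
    one population in one session.  With a single neuron the result is
    empty.  Idempotent; the output is a subset of the input.
    """
    ids = list(trains)
    if len(ids) < 2:
        return {i: np.empty(0) for i in ids}
    bins_by_neuron = {i: set(np.floor(np.asarray(trains[i], float) / bin_s)
                             .astype(int).tolist()) for i in ids}
    out: dict[int, np.ndarray] = {}
    for i in ids:
        other_bins: set[int] = set()
        for j in ids:
            if j != i:
                other_bins |= bins_by_neuron[j]
        t = np.asarray(trains[i], float)
        keep = np.array([int(np.floor(x / bin_s)) in other_bins for x in t],
                        dtype=bool) if t.size else np.empty(0, dtype=bool)
        out[i] = t[keep]
    return out


@dataclass
class DecodingResult:
    total_loglik: dict          # model name -> float
    n_licks: int
    per_trial_best: list        # best model name per trial
    fallback_licks: dict        # model name -> licks that fell back to chance


def decoding_loglik(model_spikes: dict[str, list[np.ndarray]],
                    licks_per_trial: list[np.ndarray],
                    stl: SpikeTriggeredLick, dt0: float = DT0,
                    window: tuple[float, float] = DECODE_WINDOW) -> DecodingResult:
    """Total log-likelihood of lick events under each spike model.

    ``model_spikes`` maps a model name to per-trial spike collections
    (aligned with ``licks_per_trial``).  For each lick ``l`` and model M,
    ``p(l|S) = prod_s p(l|s)`` with ``p(l|s)`` the STL rate at lag ``l - s``
    converted to a per-sample probability (rate / dt0, floored at 1e-6 and
    capped at 1).  A lick with no in-range spikes under a model falls back
    to the chance probability ``1/dt0``.  The chance model is always
    reported.  Only events inside ``window`` are scored.
    """
    if dt0 <= 0:
        raise ValueError("dt0 must be positive")
    n_trials = len(licks_per_trial)
    for name, spikes in model_spikes.items():
        if len(spikes) != n_trials:
            raise ValueError(f"model {name}: wrong number of trials")
    names = list(model_spikes) + ["chance"]
    totals = {m: 0.0 for m in names}
    fallback = {m: 0 for m in names}
    per_trial_best: list[str] = []
    n_licks = 0
    chance_p = 1.0 / dt0
    max_lag = float(stl.lags[-1] + stl.bin_s)
    min_lag = float(stl.lags[0])
    for ti, licks in enumerate(licks_per_trial):
        licks = np.asarray(licks, float)
        licks = licks[(licks >= window[0]) & (licks < window[1])]
        trial_ll = {m: 0.0 for m in names}
        for l in licks:
            n_licks += 1
            for m in model_spikes:
                spk = np.asarray(model_spikes[m][ti], float)
                spk = spk[(spk >= window[0]) & (spk < window[1])]
                lags = l - spk
                lags = lags[(lags >= min_lag) & (lags < max_lag)]
                if lags.size == 0:
                    p = chance_p
                    fallback[m] += 1
                else:
                    ps = np.array([min(1.0, max(PROB_FLOOR,
                                                stl.rate_at(x) / dt0))
                                   for x in lags])
                    p = float(np.prod(ps))
                    p = min(1.0, max(p, PROB_FLOOR))
                lp = np.log(p)
                totals[m] += lp
                trial_ll[m] += lp
            totals["chance"] += np.log(chance_p)
            trial_ll["chance"] += np.log(chance_p)
        if licks.size:
            per_trial_best.append(max(trial_ll, key=lambda m: trial_ll[m]))
    return DecodingResult(total_loglik=totals, n_licks=n_licks,
                          per_trial_best=per_trial_best,
                          fallback_licks=fallback)
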