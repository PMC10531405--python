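"""Hyperacuity complex-spike timing estimation from slow calcium imaging.

Frames arrive at ~7.8 Hz but spike times are wanted on a 10 ms (100 Hz)
grid, i.e. finer than one frame.  The detector exploits the asymmetry of the
calcium transient (10 ms rise, 300 ms decay): the transient's values at the
handful of frames it spans depend sensitively on the sub-frame onset time,
so onsets can be localized by matched filtering against a dictionary of
kernels sampled at the actual frame times for every candidate onset on the
fine grid, with greedy non-negative peeling of one event at a time.

Also provides the simulation-validation protocol: Poisson spikes at 1 Hz,
double-exponential transients, 10 dB peak SNR, 5 cells x 100 spikes, greedy
matching of estimated to true spikes within a 100 ms tolerance, and the
sensitivity / precision / f1 scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import CalciumKernelParams, synthesize_calcium

OUT_RATE = 100.0  # Hz, detection grid


@dataclass
class DetectionEval:
    hit: int
    miss: int
    false_positive: int

    @property
    def sensitivity(self) -> float:
        d = self.hit + self.miss
        return self.hit / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.hit + self.false_positive
        return self.hit / d if d else 0.0

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.precision
        return 2 * s * p / (s + p) if (s + p) else 0.0

    def __add__(self, other: "DetectionEval") -> "DetectionEval":
        return DetectionEval(self.hit + other.hit, self.miss + other.miss,
                             self.false_positive + other.false_positive)


# ---------------------------------------------------------------------------
# detector
# ---------------------------------------------------------------------------

def _onset_dictionary(k: CalciumKernelParams, n_frames: int, t0: float,
                      out_rate: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kernel values at frame times for every candidate onset.

    Returns ``(onsets, first_frame, K)`` where ``K[j, m]`` is the kernel of
    an event at ``onsets[j]`` evaluated at frame ``first_frame[j] + m``.
    """
    support = 5.0 * k.decay_tau
    width = int(np.ceil(support * k.fs)) + 1
    duration = n_frames / k.fs
    n_c = int(np.floor(duration * out_rate))
    onsets = t0 + np.arange(n_c) / out_rate
    first = np.ceil((onsets - t0) * k.fs - 1e-9).astype(int)
    m = np.arange(width)
    frame_t = t0 + (first[:, None] + m[None, :]) / k.fs
    K = k.kernel(frame_t - onsets[:, None])
    K[(first[:, None] + m[None, :]) >= n_frames] = 0.0
    return onsets, first, K


def _noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD via the MAD of a median-filter residual.

    Transient rises are sparse outliers of the residual; the median filter
    follows the slow decay, so the MAD tracks the additive noise floor.
    """
    from scipy.ndimage import median_filter
    resid = trace - median_filter(trace, size=5, mode="nearest")
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad) if mad > 0 else float(np.std(resid))


def detect_spikes(trace: np.ndarray, k: CalciumKernelParams,
                  t0: float = 0.0, out_rate: float = OUT_RATE,
                  threshold_sd: float = 1.25, max_events: int | None = None,
                  min_amplitude: float = 0.3) -> np.ndarray:
    """Estimate spike onset times on the 10 ms grid from a sampled trace.

    Orthogonal matching pursuit against the onset dictionary: repeatedly add
    the candidate onset with the largest residual-energy reduction among
    those whose least-squares amplitude exceeds
    ``max(threshold_sd * sigma_amp, min_amplitude)`` (``sigma_amp`` is the
    amplitude-estimator noise SD), then refit all accepted amplitudes
    jointly by non-negative least squares.  Returns strictly increasing
    times on the 10 ms grid.
    """
    from scipy.optimize import nnls

    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n == 0 or np.allclose(trace, trace[0]):
        return np.empty(0)
    onsets, first, K = _onset_dictionary(k, n, t0, out_rate)
    energy = (K ** 2).sum(axis=1)
    ok = energy > 1e-12
    sigma = _noise_sd(trace)
    sigma_amp = sigma / np.sqrt(np.maximum(energy, 1e-12))
    thresh = np.maximum(threshold_sd * sigma_amp, min_amplitude)

    width = K.shape[1]
    m_idx = np.arange(width)

    def column(j: int) -> np.ndarray:
        col = np.zeros(n)
        sl = slice(first[j], min(first[j] + width, n))
        col[sl] = K[j, : sl.stop - sl.start]
        return col

    def corr_all(resid: np.ndarray) -> np.ndarray:
        idx = first[:, None] + m_idx[None, :]
        vals = np.where(idx < n, resid[np.clip(idx, 0, n - 1)], 0.0)
        return (vals * K).sum(axis=1)

    def refit(sel: list[int]) -> tuple[np.ndarray, np.ndarray, float]:
        if not sel:
            return np.empty(0), trace.copy(), float(trace @ trace)
        D = np.column_stack([column(j) for j in sel])
        a, _ = nnls(D, trace)
        r = trace - D @ a
        return a, r, float(r @ r)

    def best_candidate(resid: np.ndarray, used: np.ndarray,
                       mask: np.ndarray | None = None) -> int | None:
        c = corr_all(resid)
        amp = np.where(ok & ~used, c / np.maximum(energy, 1e-12), 0.0)
        eligible = (ok & ~used) & (amp > thresh)
        if mask is not None:
            eligible &= mask
        score = np.where(eligible, amp * amp * energy, -np.inf)
        j = int(np.argmax(score))
        return j if np.isfinite(score[j]) else None

    used = np.zeros(onsets.size, dtype=bool)
    selected: list[int] = []
    amps = np.empty(0)
    resid = trace.copy()
    limit = max_events if max_events is not None else n * 4
    for _ in range(limit):
        j = best_candidate(resid, used)
        if j is None or len(selected) >= limit:
            break
        used[j] = True
        selected.append(j)
        amps, resid, _ = refit(selected)

    # pair refinement: a single fitted event of ~double amplitude sitting
    # between two true transients is replaced by the best local pair of
    # onsets (exhaustive two-column least squares) when that lowers the
    # squared error by more than the noise floor
    def best_local_pair(y0: np.ndarray, center_j: int) -> tuple[list[int], float]:
        local = np.where((np.abs(onsets - onsets[center_j]) <= 0.30) & ok)[0]
        local = local[:: 2]  # 20 ms pair grid keeps the search small
        cols = np.stack([column(j) for j in local])        # L x n
        P = cols @ y0
        G = cols @ cols.T
        best = ([], np.inf)
        L = local.size
        for ii in range(L):
            for jj in range(ii, L):
                g11, g22, g12 = G[ii, ii], G[jj, jj], G[ii, jj]
                det = g11 * g22 - g12 * g12
                if det > 1e-12 and ii != jj:
                    a1 = (g22 * P[ii] - g12 * P[jj]) / det
                    a2 = (g11 * P[jj] - g12 * P[ii]) / det
                else:
                    a1, a2 = P[ii] / max(g11, 1e-12), 0.0
                if a1 < 0 or a2 < 0:
                    continue
                sse = float(y0 @ y0) - (a1 * P[ii] + a2 * P[jj])
                if sse < best[1]:
                    best = ([int(local[ii]), int(local[jj])], sse)
        return best

    _, _, sse = refit(selected)
    min_gain = max(4.0 * sigma * sigma, 1e-9)
    for _ in range(2):
        improved = False
        # clusters of selected events separated by > 0.35 s
        order = np.argsort([onsets[j] for j in selected])
        clusters: list[list[int]] = []
        for oi in order:
            j = selected[oi]
            if clusters and onsets[j] - onsets[clusters[-1][-1]] <= 0.35:
                clusters[-1].append(j)
            else:
                clusters.append([j])
        amp_of = dict(zip(selected, amps))
        for cluster in clusters:
            total = sum(amp_of.get(j, 0.0) for j in cluster)
            if not 1.4 <= total < 2.6:
                continue
            others = [j for j in selected if j not in cluster]
            _, r0, _ = refit(others)
            center = int(cluster[len(cluster) // 2])
            pair, _ = best_local_pair(r0, center)
            if not pair:
                continue
            trial = others + [j for j in pair if j not in others]
            a_t, _, sse_t = refit(trial)
            if sse_t < sse - min_gain:
                selected, amps, sse = trial, a_t, sse_t
                amp_of = dict(zip(selected, amps))
                improved = True
        if not improved:
            break
    # timing refinement: re-localize each event against the residual with
    # its amplitude held fixed, using the posterior mean of the onset
    # likelihood (Gaussian noise) over a +-0.25 s window; tail errors of the
    # raw argmax shrink markedly at low SNR
    if selected:
        sig2 = max(sigma, 1e-6) ** 2
        order = np.argsort([onsets[j] for j in selected])
        selected = [selected[i] for i in order]
        amps, _, _ = refit(selected)
        for pos in range(len(selected)):
            a_j = amps[pos] if amps.size > pos else 1.0
            if a_j <= 0:
                continue
            others = selected[:pos] + selected[pos + 1:]
            _, r0, _ = refit(others)
            c = corr_all(r0)
            ll = (a_j * c - 0.5 * a_j * a_j * energy) / sig2
            jmax = int(np.argmax(np.where(ok, ll, -np.inf)))
            m = ok & (np.abs(onsets - onsets[jmax]) < 0.25)
            w = np.exp(np.clip(ll - ll[jmax], -50.0, 0.0)) * m
            tau = float(np.sum(onsets * w) / np.sum(w))
            selected[pos] = int(np.clip(round((tau - t0) * out_rate), 0,
                                        onsets.size - 1))
        # collapse duplicates created by refinement
        uniq = sorted(set(selected), key=lambda j: onsets[j])
        amps_u, _, _ = refit(uniq)
        selected, amps = uniq, amps_u

    # amplitude-aware splitting: a fitted amplitude near an integer multiple
    # of the unitary transient means several spikes landed within one frame
    # interval; emit that many events on adjacent grid steps
    times: list[float] = []
    grid = 1.0 / out_rate
    for j, a in zip(selected, amps):
        if a <= 0.5 * min_amplitude:
            continue
        count = max(1, int(round(a))) if a >= 1.5 else 1
        for m in range(count):
            times.append(onsets[j] + m * grid)
    return np.unique(np.round(np.sort(np.asarray(times)), 6))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_detection(true_times, est_times, tol: float = 0.100) -> DetectionEval:
    """Greedy one-to-one matching of estimated to true spikes within ``tol``.

    Candidate pairs are taken in ascending |time difference| (ties broken by
    the earlier true spike); each spike matches at most once.  Unmatched
    true spikes are misses, unmatched estimates false positives.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    true_times = np.asarray(true_times, dtype=float)
    est_times = np.asarray(est_times, dtype=float)
    pairs = [(abs(t - e), ti, ei)
             for ti, t in enumerate(true_times)
             for ei, e in enumerate(est_times)
             if abs(t - e) <= tol]
    pairs.sort(key=lambda p: (p[0], true_times[p[1]], p[2]))
    used_t: set[int] = set()
    used_e: set[int] = set()
    hit = 0
    for _, ti, ei in pairs:
        if ti in used_t or ei in used_e:
            continue
        used_t.add(ti)
        used_e.add(ei)
        hit += 1
    return DetectionEval(hit=hit, miss=true_times.size - hit,
                         false_positive=est_times.size - hit)


# ---------------------------------------------------------------------------
# benchmark (simulation validation)
# ---------------------------------------------------------------------------

def run_detection_benchmark(k: CalciumKernelParams | None = None,
                            n_cells: int = 5, spikes_per_cell: int = 100,
                            rate: float = 1.0, seed: int = 0,
                            tol: float = 0.100) -> DetectionEval:
    """Pooled detection scores for the simulation-validation protocol.

    For each cell, Poisson spikes at ``rate`` are drawn until
    ``spikes_per_cell`` events exist, quantized to the 10 ms grid; a noisy
    trace is synthesized at the kernel's frame rate and SNR, the detector is
    run, and hit/miss/false-positive counts are pooled across cells.
    """
    k = k or CalciumKernelParams()
    root = np.random.SeedSequence(seed)
    pooled = DetectionEval(0, 0, 0)
    for cell_seed in root.spawn(n_cells):
        rng = np.random.default_rng(cell_seed)
        if spikes_per_cell <= 0 or rate <= 0:
            true = np.empty(0)
            duration = 10.0
        else:
            gaps = rng.exponential(1.0 / rate, size=spikes_per_cell)
            true = np.round(np.cumsum(gaps) / 0.01) * 0.01
            true = np.unique(true[true > 0])
            duration = float(true[-1]) + 2.0
        noise_seed = int(rng.integers(2 ** 31))
        _, trace = synthesize_calcium(true, k, seed=noise_seed,
                                      duration=duration, t0=0.0)
        est = detect_spikes(trace, k, t0=0.0)
        pooled = pooled + evaluate_detection(true, est, tol=tol)
    return pooled
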