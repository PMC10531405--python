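"""Synthetic Go/No-go sessions with planted low-rank complex-spike structure.

The generator emulates the statistical structure of two-photon recordings of
climbing-fiber complex spikes in cerebellar Crus II during Go/No-go learning:

* ~30 Purkinje cells per session spread over the eight Aldolase-C
  compartments, with near-Poisson complex spikes at ~1.1 spikes/s baseline;
* a planted rank-4 non-negative (neuron x time x condition) component
  structure added to the baseline rate — component 1 a fast post-cue response
  in HIT trials concentrated in AldC-positive compartments, component 2 a
  very fast FA response in the lateral hemisphere, component 3 a slow
  prolonged HIT response in the medial hemisphere, component 4 a fast CR
  response in the lateral hemisphere;
* within-component synchrony via a thinned mother-process (common-input)
  construction with one tunable probability per component;
* lick sequences whose first-lick latency follows a slow polynomial trend
  with stage-decreasing jitter, and whose error rates (Go misses, No-go
  false alarms) decrease across the three learning stages, so sessions span
  all stages;
* GCaMP6f-like calcium transients: double-exponential kernel (10 ms rise,
  300 ms decay) sampled at 7.8 Hz with Gaussian noise at 10 dB peak SNR.

Everything is a pure function of ``(config, seed)``; child generators are
spawned deterministically per session / neuron / trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import (COMPARTMENTS, REWARD_OFFSETS, SPIKE_GRID, TRIAL_END,
                        TRIAL_START, Dataset, Neuron, Session, SpikeTrain,
                        Trial, classify_trial)

# PSTH grid on which temporal factors are planted: [-0.5, 2) s at 50 ms
PSTH_BIN = 0.05
PSTH_WINDOW = (-0.5, 2.0)
N_PSTH_BINS = 50
CONDITION_ORDER = ("HIT", "FA", "CR", "MISS")

LATERAL = ("7+", "6-", "6+", "5-")
MEDIAL = ("5+", "5a-", "5a+", "4b-")
ALDC_POSITIVE = ("7+", "6+", "5+", "5a+")


@dataclass
class CalciumKernelParams:
    """Double-exponential transient kernel and imaging noise model.

    ``snr_db`` is peak SNR: 20*log10(unit-transient peak / noise SD).
    """
    rise_tau: float = 0.010     # s
    decay_tau: float = 0.300    # s
    snr_db: float = 10.0        # dB against the unitary transient peak
    fs: float = 7.8             # imaging frame rate, Hz

    def __post_init__(self) -> None:
        if not (0 < self.rise_tau < self.decay_tau):
            raise ValueError("need 0 < rise_tau < decay_tau")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def peak_time(self) -> float:
        """Argmax of the unit double exponential (closed form)."""
        r, d = self.rise_tau, self.decay_tau
        return r * d / (d - r) * np.log(d / r)

    @property
    def peak_amplitude(self) -> float:
        t = self.peak_time
        return float(np.exp(-t / self.decay_tau) - np.exp(-t / self.rise_tau))

    def kernel(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tp = np.where(t >= 0, t, 0.0)
        out = np.exp(-tp / self.decay_tau) - np.exp(-tp / self.rise_tau)
        return np.where(t >= 0, out, 0.0)


@dataclass
class BehaviorTrends:
    """Stagewise licking-behavior parameters.

    Defaults follow the reported course of learning: fraction correct for Go
    rises 0.78 -> 0.98, fraction incorrect for No-go falls 0.66 -> 0.15, and
    lick-latency fluctuation (mean |latency - trend| / mean latency) falls
    0.45 -> 0.22 across stages; with a ~0.5 s mean latency this maps to a
    latency jitter SD of roughly 0.28 -> 0.14 s.
    """
    latency_poly: tuple[float, ...] = (0.5,)     # latency trend vs trial index (s)
    latency_sd_by_stage: tuple[float, float, float] = (0.28, 0.20, 0.14)
    miss_prob_by_stage: tuple[float, float, float] = (0.22, 0.10, 0.02)
    early_lick_prob_by_stage: tuple[float, float, float] = (0.66, 0.45, 0.15)
    lick_bout_rate: float = 6.5                  # Hz, within-bout licking
    hit_bout_end: float = 2.5                    # s, licking stops (HIT)
    fa_bout_end: float = 1.2                     # s, licking stops (FA timeout)


@dataclass
class GroundTruth:
    """Planted tensor structure and synchrony levels of a generated dataset.

    Factor columns are unit length; ``scales`` carries the spikes/s
    magnitude, so the planted rate of neuron n at PSTH bin t in condition k
    is ``baseline + sum_r scales[r] * neuron_factors[n,r] *
    temporal_factors[t,r] * condition_factors[k,r]``.
    """
    rank: int
    neuron_factors: np.ndarray       # neurons x R, unit columns
    temporal_factors: np.ndarray     # 50 x R, unit columns
    condition_factors: np.ndarray    # 4 x R, unit columns (HIT,FA,CR,MISS)
    scales: np.ndarray               # R, spikes/s
    sync_level: np.ndarray           # R, common-input probability in [0,1]
    baseline_rate: float
    neuron_ids: np.ndarray           # neurons, aligned with neuron_factors rows
    dominant_component: np.ndarray   # neurons, argmax planted component
    trends: BehaviorTrends

    def planted_rate(self, n_index: int, condition: str) -> np.ndarray:
        """Planted PSTH-bin rate (spikes/s, incl. baseline) for one neuron."""
        k = CONDITION_ORDER.index(condition)
        comp = (self.temporal_factors
                * self.neuron_factors[n_index][None, :]
                * self.condition_factors[k][None, :]
                * self.scales[None, :]).sum(axis=1)
        return self.baseline_rate + comp


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    Per-session scale follows the recorded sessions (~30 simultaneously
    imaged neurons, >=30 trials per session, 4-7 sessions per mouse spanning
    the three learning stages); ``n_mice`` defaults to the full 17-mouse
    cohort and is typically reduced for desk-scale runs.
    """
    n_mice: int = 17
    sessions_per_mouse: int = 6
    neurons_per_session: int = 30
    trials_per_session: int = 30
    planted_rank: int = 4
    baseline_rate: float = 1.1                    # spikes/s spontaneous CS rate
    component_amplitude: tuple[float, ...] = (6.0, 6.0, 3.5, 5.0)   # peak Hz
    sync_level: tuple[float, ...] = (0.6, 0.5, 0.4, 0.25)
    kernel: CalciumKernelParams = field(default_factory=CalciumKernelParams)
    trends: BehaviorTrends = field(default_factory=BehaviorTrends)
    go_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_mice", "sessions_per_mouse", "neurons_per_session",
                     "trials_per_session", "planted_rank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# planted factors
# ---------------------------------------------------------------------------

def _temporal_profiles() -> np.ndarray:
    """Raw (peak-1) temporal profiles of the four planted components."""
    t = PSTH_WINDOW[0] + (np.arange(N_PSTH_BINS) + 0.5) * PSTH_BIN
    def bump(peak, sd, tail=0.0):
        y = np.exp(-0.5 * ((t - peak) / sd) ** 2)
        if tail:  # skewed, prolonged decay
            y = np.where(t > peak, np.exp(-(t - peak) / tail), y)
        y[t < 0] = 0.0
        return y
    b1 = bump(0.20, 0.08)            # fast, peaks 200 ms post cue
    b2 = bump(0.10, 0.05)            # very fast, back to baseline by ~400 ms
    b3 = bump(0.30, 0.12, tail=0.35)  # slow, prolonged ~1 s
    b4 = bump(0.10, 0.06)
    return np.column_stack([b1, b2, b3, b4])


_RAW_CONDITION = np.array([
    # HIT   FA    CR   MISS
    [1.00, 0.30, 0.00, 0.0],   # TC1: Go-timing
    [0.25, 1.00, 0.00, 0.0],   # TC2: No-go error
    [1.00, 0.10, 0.00, 0.0],   # TC3: reward processing
    [0.00, 0.00, 1.00, 0.0],   # TC4: lick suppression
]).T                            # 4 conditions x 4 components

_COMP_AFFINITY = {  # compartment -> affinity for each component
    c: np.array([1.0 if c in ALDC_POSITIVE else 0.15,
                 1.0 if c in LATERAL else 0.10,
                 1.0 if c in MEDIAL else 0.10,
                 1.0 if c in LATERAL else 0.10])
    for c in COMPARTMENTS
}


def _draw_neuron_loading(compartment: str, rank: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Raw non-negative loading (dominant-1 scale) and dominant component."""
    aff = _COMP_AFFINITY[compartment][:rank].copy()
    dom = int(rng.choice(rank, p=aff / aff.sum()))
    w = rng.uniform(0.0, 0.15, size=rank) * aff
    w[dom] = rng.uniform(0.7, 1.0)
    return w, dom


# ---------------------------------------------------------------------------
# correlated spike generation (thinned mother process)
# ---------------------------------------------------------------------------

def _grid_times(t0: float, t1: float) -> np.ndarray:
    n = int(round((t1 - t0) / SPIKE_GRID))
    return t0 + np.arange(n) * SPIKE_GRID


def _correlated_binary(profiles: np.ndarray, p: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Correlated Bernoulli spike indicators on the 10 ms grid.

    ``profiles`` is (n_neurons, n_bins) in spikes/s.  A mother train at the
    bin-wise maximum rate is thinned per neuron with probability
    ``p * rate_n / rate_max``; independent spikes fill the remaining
    ``(1 - p) * rate_n``, so marginal rates match ``profiles`` in
    expectation while pairwise zero-lag coincidence scales with ``p``.
    """
    n, nb = profiles.shape
    prof = np.clip(profiles, 0.0, None)
    mother_rate = prof.max(axis=0)
    mother = rng.random(nb) < (1.0 - np.exp(-mother_rate * SPIKE_GRID))
    with np.errstate(invalid="ignore", divide="ignore"):
        keep_p = np.where(mother_rate > 0, p * prof / mother_rate, 0.0)
    shared = mother[None, :] & (rng.random((n, nb)) < keep_p)
    indep = rng.random((n, nb)) < (1.0 - np.exp(-(1.0 - p) * prof * SPIKE_GRID))
    return shared | indep


def draw_correlated_spikes(rate_profile: np.ndarray, n_neurons: int,
                           sync_level: float, seed: int,
                           t0: float = 0.0) -> list[np.ndarray]:
    """Spike-time arrays for ``n_neurons`` sharing a common-input fraction.

    ``rate_profile`` gives spikes/s per 10 ms bin starting at ``t0``; each
    neuron's marginal rate equals the profile in expectation, and the
    fraction ``sync_level`` of events comes from one shared mother train.
    """
    if not 0.0 <= sync_level <= 1.0:
        raise ValueError("sync_level must be in [0, 1]")
    rate_profile = np.asarray(rate_profile, dtype=float)
    if np.any(rate_profile < 0):
        raise ValueError("rate_profile must be non-negative")
    rng = np.random.default_rng(seed)
    prof = np.tile(rate_profile, (n_neurons, 1))
    spikes = _correlated_binary(prof, sync_level, rng)
    grid = t0 + np.arange(rate_profile.size) * SPIKE_GRID
    return [np.round(grid[row], 6) for row in spikes]


# ---------------------------------------------------------------------------
# calcium synthesis
# ---------------------------------------------------------------------------

def synthesize_calcium(spike_times: Sequence[float], k: CalciumKernelParams,
                       seed: int | None = None, duration: float | None = None,
                       t0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Sampled fluorescence trace for a spike train.

    Returns ``(sample_times, trace)`` at ``k.fs``; the trace is the sum of
    unit-amplitude double-exponential transients plus Gaussian noise with
    SD = transient peak / 10**(snr_db / 20).  ``seed=None`` disables noise.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if duration is None:
        duration = (float(spikes[-1]) + 5 * k.decay_tau) if spikes.size else 1.0
    n = max(1, int(np.ceil((duration - t0) * k.fs)))
    ts = t0 + np.arange(n) / k.fs
    trace = np.zeros(n)
    for s in spikes:
        trace += k.kernel(ts - s)
    if seed is not None and np.isfinite(k.snr_db):
        sd = k.peak_amplitude / (10.0 ** (k.snr_db / 20.0))
        trace = trace + np.random.default_rng(seed).normal(0.0, sd, size=n)
    return ts, trace


# ---------------------------------------------------------------------------
# licking behavior
# ---------------------------------------------------------------------------

def _poly_eval(coeffs: Sequence[float], x: float) -> float:
    return float(np.polynomial.polynomial.polyval(x, np.asarray(coeffs, float)))


def simulate_licks(cue: str, stage: int, trial_index: int,
                   trends: BehaviorTrends, seed: int) -> tuple[list[float], str]:
    """Lick times and resulting condition for one trial.

    Go trials: first-lick latency = polynomial trend of the cumulative trial
    index plus Gaussian jitter whose SD decreases with stage; a small
    stage-dependent lapse produces MISS trials.  No-go trials emit an early
    (response-window) lick with a stage-decreasing probability (FA), else no
    licks (CR).  Licking continues as a bout after the first lick.
    """
    rng = np.random.default_rng(seed)
    s = max(1, min(3, stage)) - 1
    if cue == "Go":
        if rng.random() < trends.miss_prob_by_stage[s]:
            return [], "MISS"
        bout_end = trends.hit_bout_end
    else:
        if rng.random() >= trends.early_lick_prob_by_stage[s]:
            return [], "CR"
        bout_end = trends.fa_bout_end
    base = _poly_eval(trends.latency_poly, trial_index)
    lat = base + rng.normal(0.0, trends.latency_sd_by_stage[s])
    lat = float(np.clip(lat, 0.05, 0.95))
    licks = [lat]
    t = lat
    while True:
        t += rng.exponential(1.0 / trends.lick_bout_rate)
        if t >= bout_end:
            break
        licks.append(float(t))
    licks = [round(x, 6) for x in licks]
    return licks, classify_trial(cue, licks)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def _upsample_profile(bin_profile: np.ndarray) -> np.ndarray:
    """50 ms PSTH-bin rates -> 10 ms-grid rates over the full trial."""
    n_pre = int(round((PSTH_WINDOW[0] - TRIAL_START) / SPIKE_GRID))
    n_post = int(round((TRIAL_END - PSTH_WINDOW[1]) / SPIKE_GRID))
    per_bin = int(round(PSTH_BIN / SPIKE_GRID))
    mid = np.repeat(bin_profile, per_bin)
    return np.concatenate([np.zeros(n_pre), mid, np.zeros(n_post)])


def generate_dataset(cfg: GeneratorConfig | None = None,
                     seed: int = 0) -> tuple[Dataset, GroundTruth]:
    """Generate a full multi-mouse dataset and its planted ground truth."""
    cfg = cfg or GeneratorConfig()
    R = cfg.planted_rank
    root = np.random.SeedSequence(seed)
    mouse_seeds = root.spawn(cfg.n_mice)

    b_raw = _temporal_profiles()[:, :R]
    a_raw = _RAW_CONDITION[:, :R]
    amp = np.asarray(cfg.component_amplitude[:R], dtype=float)
    sync = np.asarray(cfg.sync_level[:R], dtype=float)

    sessions: list[Session] = []
    w_rows: list[np.ndarray] = []
    neuron_ids: list[int] = []
    dominants: list[int] = []
    next_neuron, next_trial, next_session = 0, 0, 0

    for m, mseed in enumerate(mouse_seeds):
        sess_seeds = mseed.spawn(cfg.sessions_per_mouse)
        trial_counter = 0  # cumulative trial index per mouse (training order)
        for si, sseed in enumerate(sess_seeds):
            rng = np.random.default_rng(sseed)
            # training progresses across a mouse's sessions: thirds map to stages
            stage = 1 + min(2, (3 * si) // cfg.sessions_per_mouse)
            sess = Session(session_id=next_session, mouse_id=m)
            next_session += 1

            # neurons spread across all 8 compartments
            comp_idx = rng.permutation(
                np.resize(np.arange(len(COMPARTMENTS)), cfg.neurons_per_session))
            local_w = np.zeros((cfg.neurons_per_session, R))
            local_dom = np.zeros(cfg.neurons_per_session, dtype=int)
            for j, ci in enumerate(comp_idx):
                comp = COMPARTMENTS[ci]
                w, dom = _draw_neuron_loading(comp, R, rng)
                local_w[j] = w
                local_dom[j] = dom
                sess.neurons.append(Neuron(
                    neuron_id=next_neuron, session_id=sess.session_id,
                    compartment=comp,
                    x_um=round(ci * 150.0 + rng.uniform(0.0, 150.0), 3),
                    y_um=round(rng.uniform(0.0, 200.0), 3)))
                w_rows.append(w)
                neuron_ids.append(next_neuron)
                dominants.append(dom)
                next_neuron += 1

            # trials: cues, licks, conditions
            n_go = int(round(cfg.go_fraction * cfg.trials_per_session))
            cues = ["Go"] * n_go + ["Nogo"] * (cfg.trials_per_session - n_go)
            rng.shuffle(cues)
            n_correct = 0
            for cue in cues:
                lick_seed = int(rng.integers(2 ** 31))
                licks, condition = simulate_licks(cue, stage, trial_counter,
                                                  cfg.trends, lick_seed)
                rewards = ([licks[0] + o for o in REWARD_OFFSETS]
                           if condition == "HIT" else [])
                sess.trials.append(Trial(
                    trial_id=next_trial, session_id=sess.session_id, cue=cue,
                    condition=condition, lick_times=licks, reward_times=rewards))
                next_trial += 1
                trial_counter += 1
                n_correct += condition in ("HIT", "CR")
            sess.fraction_correct = n_correct / len(cues)

            # spikes: baseline (independent) + planted components (correlated
            # within each component's dominant group)
            n_bins = int(round((TRIAL_END - TRIAL_START) / SPIKE_GRID))
            grid = TRIAL_START + np.arange(n_bins) * SPIKE_GRID
            for tr in sess.trials:
                k = CONDITION_ORDER.index(tr.condition)
                spikes = np.zeros((cfg.neurons_per_session, n_bins), dtype=bool)
                base_p = 1.0 - np.exp(-cfg.baseline_rate * SPIKE_GRID)
                spikes |= rng.random(spikes.shape) < base_p
                for r in range(R):
                    members = np.where(local_dom == r)[0]
                    # neurons cross-loaded on r but dominant elsewhere fire
                    # their share independently
                    others = np.where((local_dom != r) & (local_w[:, r] > 0))[0]
                    prof_bin = amp[r] * a_raw[k, r] * b_raw[:, r]
                    if prof_bin.max() <= 0:
                        continue
                    full = _upsample_profile(prof_bin)
                    if members.size:
                        profs = local_w[members, r][:, None] * full[None, :]
                        spikes[members] |= _correlated_binary(profs, sync[r], rng)
                    for j in others:
                        pr = 1.0 - np.exp(-local_w[j, r] * full * SPIKE_GRID)
                        spikes[j] |= rng.random(n_bins) < pr
                for j in range(cfg.neurons_per_session):
                    times = np.round(grid[spikes[j]], 6)
                    if times.size:
                        sess.spike_trains.append(SpikeTrain(
                            neuron_id=sess.neurons[j].neuron_id,
                            trial_id=tr.trial_id, spike_times=times))
            sessions.append(sess)

    # canonicalize planted factors: unit columns, scale in lambda
    W = np.asarray(w_rows)
    lam = np.empty(R)
    Wn, Bn, An = W.copy(), b_raw.copy(), a_raw.copy()
    for r in range(R):
        nw = np.linalg.norm(Wn[:, r]) or 1.0
        nb = np.linalg.norm(Bn[:, r]) or 1.0
        na = np.linalg.norm(An[:, r]) or 1.0
        Wn[:, r] /= nw
        Bn[:, r] /= nb
        An[:, r] /= na
        lam[r] = amp[r] * nw * nb * na

    truth = GroundTruth(
        rank=R, neuron_factors=Wn, temporal_factors=Bn, condition_factors=An,
        scales=lam, sync_level=sync, baseline_rate=cfg.baseline_rate,
        neuron_ids=np.asarray(neuron_ids), dominant_component=np.asarray(dominants),
        trends=cfg.trends)
    ds = Dataset(sessions=sessions,
                 provenance=f"cfpop.synth.generate_dataset(seed={seed})", seed=seed)
    return ds, truth


def simulate_coupled_licking(n_trials: int = 200, seed: int = 0,
                             n_coupled: int = 3, p_fire: float = 0.85,
                             lag: float = 0.25, jitter: float = 0.02,
                             base_top_rate: float = 0.05,
                             n_background: int = 6,
                             background_rate: float = 0.04
                             ) -> dict[str, list[np.ndarray]]:
    """Stylized spike->lick coupled trials for decoding-model comparison.

    Each trial has one lick (~0.55 s after the cue) preceded by a
    synchronous volley of ``n_coupled`` component neurons ``lag`` seconds
    earlier (each fires with probability ``p_fire``, Gaussian ``jitter``,
    10 ms grid).  Sparse uncoupled spikes are added: ``base_top_rate`` Hz
    per coupled neuron (the unsynchronized remainder of the component
    population) and ``background_rate`` Hz for each of ``n_background``
    other neurons in the session.  Returns per-trial event lists keyed
    ``sync_topTC`` (volley only), ``all_topTC`` (+component background),
    ``all_session`` (+session background) and ``licks``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[np.ndarray]] = {k: [] for k in
                                        ("sync_topTC", "all_topTC",
                                         "all_session", "licks")}
    for _ in range(n_trials):
        lick = float(np.clip(rng.normal(0.55, 0.08), 0.2, 0.95))
        volley = [np.floor((lick - lag + rng.normal(0.0, jitter))
                           / SPIKE_GRID) * SPIKE_GRID
                  for _ in range(n_coupled) if rng.random() < p_fire]
        volley = np.sort(np.round([v for v in volley if 0.0 <= v < 1.0], 6))
        bt = rng.uniform(0.0, 1.0, size=rng.poisson(base_top_rate * n_coupled))
        bg = rng.uniform(0.0, 1.0,
                         size=rng.poisson(background_rate * n_background))
        out["licks"].append(np.array([lick]))
        out["sync_topTC"].append(volley)
        out["all_topTC"].append(np.sort(np.concatenate([volley, bt])))
        out["all_session"].append(np.sort(np.concatenate([volley, bt, bg])))
    return out


def small_config(**overrides) -> GeneratorConfig:
    """Desk-scale preset: 2 mice x 6 sessions x 24 neurons x 30 trials."""
    base = dict(n_mice=2, sessions_per_mouse=6, neurons_per_session=24,
                trials_per_session=30)
    base.update(overrides)
    return GeneratorConfig(**base)
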