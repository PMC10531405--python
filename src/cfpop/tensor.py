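"""PSTH tensors and non-negative tensor component analysis (TCA).

The central object is the trial-averaged, baseline-subtracted complex-spike
rate tensor ``x[n, t, k]`` (neurons x 50 time bins covering [-0.5, 2) s at
50 ms x 4 cue-response conditions in HIT/FA/CR/MISS order).  It is
decomposed by a rank-R non-negative canonical polyadic model

    x[n, t, k]  ~=  sum_r  lambda_r * w[n, r] * b[t, r] * a[k, r]

fit by hierarchical alternating least squares (HALS) from many random
non-negative initializations; solutions are clustered by factor congruence
and the best-objective member of the modal cluster is returned, with unit
length factor columns and components sorted by contribution ``lambda_r``.

Also provides variance accounted for (VAF) on the low-pass-filtered [0, 1) s
window, the trial/neuron permutation null, the cosine TC distance, top-N
component sampling ("topTC" populations) and argmax classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import khatri_rao
from scipy.signal import butter, filtfilt

from .datamodel import Dataset
from .synth import CONDITION_ORDER, N_PSTH_BINS, PSTH_BIN, PSTH_WINDOW

logger = logging.getLogger("cfpop")

BASELINE_WINDOW = (-2.0, -1.0)
MIN_TRIALS = 5
VAF_WINDOW = (0.0, 1.0)
VAF_CUTOFF_HZ = 2.0
CONGRUENCE_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# PSTH tensor
# ---------------------------------------------------------------------------

@dataclass
class PSTHTensor:
    values: np.ndarray               # neurons x 50 x 4, spikes/s
    neuron_ids: np.ndarray
    baseline_rates: np.ndarray       # per neuron, spikes/s over [-2,-1) s
    trial_counts: dict               # (session_id, condition) -> n trials
    stages: np.ndarray               # learning stage of each neuron's session
    bin_edges: np.ndarray = field(default_factory=lambda: np.arange(
        PSTH_WINDOW[0], PSTH_WINDOW[1] + PSTH_BIN / 2, PSTH_BIN))

    @property
    def time_centers(self) -> np.ndarray:
        return self.bin_edges[:-1] + PSTH_BIN / 2


def build_psth_tensor(ds: Dataset, bin_s: float = PSTH_BIN,
                      window: tuple[float, float] = PSTH_WINDOW) -> PSTHTensor:
    """Trial-averaged baseline-subtracted rate tensor for a dataset.

    Per neuron and condition, spike counts are histogrammed at ``bin_s``
    over ``window`` and averaged across that session's trials of the
    condition; the neuron's mean rate over the [-2, -1) s pre-cue window
    (all trials) is subtracted.  Slices of a (session, condition) with
    fewer than 5 trials are fixed to exactly 0.
    """
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = window[0] + np.arange(n_bins + 1) * bin_s
    neurons = ds.all_neurons()
    index = {n.neuron_id: i for i, n in enumerate(neurons)}
    values = np.zeros((len(neurons), n_bins, len(CONDITION_ORDER)))
    baseline = np.zeros(len(neurons))
    stages = np.zeros(len(neurons), dtype=int)
    counts: dict[tuple[int, str], int] = {}

    for sess in ds.sessions:
        if not sess.trials:
            names = ", ".join(str(n.neuron_id) for n in sess.neurons)
            raise ValueError(f"session {sess.session_id} has no trials for "
                             f"neurons: {names}")
        by_trial: dict[tuple[int, int], np.ndarray] = {
            (st.neuron_id, st.trial_id): st.spike_times
            for st in sess.spike_trains}
        cond_trials = {k: [t.trial_id for t in sess.trials if t.condition == k]
                       for k in CONDITION_ORDER}
        for k in CONDITION_ORDER:
            counts[(sess.session_id, k)] = len(cond_trials[k])
        n_trials = len(sess.trials)
        b0, b1 = BASELINE_WINDOW
        for nrn in sess.neurons:
            i = index[nrn.neuron_id]
            stages[i] = sess.stage
            nb = 0.0
            for tr in sess.trials:
                t = by_trial.get((nrn.neuron_id, tr.trial_id))
                if t is not None:
                    nb += np.count_nonzero((t >= b0) & (t < b1))
            baseline[i] = nb / (n_trials * (b1 - b0))
            for ki, k in enumerate(CONDITION_ORDER):
                tids = cond_trials[k]
                if len(tids) < MIN_TRIALS:
                    values[i, :, ki] = 0.0
                    continue
                h = np.zeros(n_bins)
                for tid in tids:
                    t = by_trial.get((nrn.neuron_id, tid))
                    if t is not None:
                        h += np.histogram(t, bins=edges)[0]
                values[i, :, ki] = h / (len(tids) * bin_s) - baseline[i]
    return PSTHTensor(values=values,
                      neuron_ids=np.array([n.neuron_id for n in neurons]),
                      baseline_rates=baseline, trial_counts=counts,
                      stages=stages, bin_edges=edges)


def response_strength(psth_row: np.ndarray,
                      window: tuple[float, float] = (0.0, 0.2),
                      bin_s: float = PSTH_BIN,
                      t_start: float = PSTH_WINDOW[0]) -> float:
    """Mean rate over the post-cue response window (default [0, 0.2) s)."""
    i0 = int(round((window[0] - t_start) / bin_s))
    i1 = int(round((window[1] - t_start) / bin_s))
    if i0 < 0 or i1 > len(psth_row):
        raise ValueError("window outside PSTH support")
    return float(np.mean(psth_row[i0:i1]))


# ---------------------------------------------------------------------------
# non-negative CP decomposition
# ---------------------------------------------------------------------------

@dataclass
class TCAModel:
    rank: int
    scales: np.ndarray               # lambda_r, descending
    neuron_factors: np.ndarray       # n x R, unit columns, >= 0
    temporal_factors: np.ndarray     # t x R
    condition_factors: np.ndarray    # 4 x R
    objective: float                 # ||x - xhat||^2 of the returned solution
    init_objectives: np.ndarray      # per-initialization objectives
    n_init: int
    degenerate: bool = False

    @property
    def factors(self) -> list[np.ndarray]:
        return [self.neuron_factors, self.temporal_factors,
                self.condition_factors]

    def reconstruct(self) -> np.ndarray:
        W, B, A = self.factors
        return np.einsum("r,nr,tr,kr->ntk", self.scales, W, B, A)


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _hals(x: np.ndarray, R: int, rng: np.random.Generator,
          max_iter: int = 500, tol: float = 1e-6) -> tuple[list[np.ndarray], float]:
    """Non-negative CP by hierarchical ALS; returns factors and ||x-xhat||^2."""
    dims = x.shape
    factors = [np.abs(rng.standard_normal((d, R))) + 0.1 for d in dims]
    unfolds = [_unfold(x, m) for m in range(3)]
    norm_x2 = float((x ** 2).sum())
    prev_obj = np.inf
    obj = norm_x2
    for _ in range(max_iter):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = khatri_rao(others[0], others[1])
            P = unfolds[mode] @ kr
            G = (others[0].T @ others[0]) * (others[1].T @ others[1])
            A = factors[mode]
            for r in range(R):
                g = G[r, r]
                if g <= 1e-14:
                    # dead component (all modes collapsed): restart it
                    A[:, r] = np.abs(rng.standard_normal(A.shape[0])) + 0.1
                    continue
                upd = A[:, r] + (P[:, r] - A @ G[:, r]) / g
                # tiny positive floor keeps columns revivable (plain 0 would
                # lock a component out permanently)
                A[:, r] = np.maximum(upd, 1e-12)
        # objective via the last-updated mode
        AtA = factors[2].T @ factors[2]
        obj = norm_x2 - 2.0 * float((P * factors[2]).sum()) \
            + float((G * AtA).sum())
        obj = max(obj, 0.0)
        if np.isfinite(prev_obj) and prev_obj - obj <= tol * max(prev_obj, 1e-30):
            break
        prev_obj = obj
    return factors, obj


def _canonicalize(factors: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    R = factors[0].shape[1]
    lam = np.ones(R)
    out = [f.copy() for f in factors]
    for r in range(R):
        for f in out:
            n = np.linalg.norm(f[:, r])
            if n > 0:
                f[:, r] /= n
            lam[r] *= n
    for f in out:
        # snap numerical dust from the epsilon-floored updates to exact 0
        f[f < 1e-9] = 0.0
    order = np.argsort(-lam, kind="stable")
    return lam[order], [f[:, order] for f in out]


def _pair_congruence(fa: list[np.ndarray], fb: list[np.ndarray]) -> np.ndarray:
    """R x R matrix of mean absolute cosine similarity across the 3 modes."""
    R = fa[0].shape[1]
    sim = np.zeros((R, R))
    for ma, mb in zip(fa, fb):
        na = ma / np.maximum(np.linalg.norm(ma, axis=0, keepdims=True), 1e-12)
        nb = mb / np.maximum(np.linalg.norm(mb, axis=0, keepdims=True), 1e-12)
        sim += np.abs(na.T @ nb)
    return sim / len(fa)


def greedy_match(sim: np.ndarray) -> list[tuple[int, int]]:
    """Greedy one-to-one component matching by descending similarity."""
    R = sim.shape[0]
    order = np.dstack(np.unravel_index(np.argsort(-sim, axis=None), sim.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for i, j in order:
        if i in used_a or j in used_b:
            continue
        pairs.append((int(i), int(j)))
        used_a.add(int(i))
        used_b.add(int(j))
        if len(pairs) == R:
            break
    return pairs


def solution_similarity(fa: list[np.ndarray], fb: list[np.ndarray]) -> float:
    """Mean matched congruence between two factor sets (0..1)."""
    sim = _pair_congruence(fa, fb)
    pairs = greedy_match(sim)
    return float(np.mean([sim[i, j] for i, j in pairs]))


def fit_tca(x: PSTHTensor | np.ndarray, R: int, n_init: int = 100,
            seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> TCAModel:
    """Multistart non-negative CP with stability (modal-cluster) selection.

    ``n_init`` HALS runs from random non-negative initializations are
    clustered by mean matched factor congruence at threshold 0.95; the
    best-objective member of the largest cluster is returned, canonicalized
    (unit factor columns, lambda sorted descending).
    """
    arr = x.values if isinstance(x, PSTHTensor) else np.asarray(x, float)
    if R < 1 or n_init < 1:
        raise ValueError("R and n_init must be >= 1")
    if R > min(arr.shape):
        raise ValueError(f"rank {R} exceeds tensor dimensions {arr.shape}")
    if not np.any(arr):
        Z = [np.zeros((d, R)) for d in arr.shape]
        return TCAModel(rank=R, scales=np.zeros(R), neuron_factors=Z[0],
                        temporal_factors=Z[1], condition_factors=Z[2],
                        objective=0.0, init_objectives=np.zeros(n_init),
                        n_init=n_init, degenerate=True)
    root = np.random.SeedSequence(seed)
    runs: list[tuple[list[np.ndarray], float]] = []
    for ss in root.spawn(n_init):
        runs.append(_hals(arr, R, np.random.default_rng(ss),
                          max_iter=max_iter, tol=tol))
    objs = np.array([r[1] for r in runs])
    # cluster by congruence against the first member of each cluster
    clusters: list[list[int]] = []
    reps: list[list[np.ndarray]] = []
    for i, (factors, _) in enumerate(runs):
        for ci, rep in enumerate(reps):
            if solution_similarity(factors, rep) >= CONGRUENCE_THRESHOLD:
                clusters[ci].append(i)
                break
        else:
            clusters.append([i])
            reps.append(factors)
    largest = max(clusters, key=len)
    best = min(largest, key=lambda i: objs[i])
    lam, factors = _canonicalize(runs[best][0])
    return TCAModel(rank=R, scales=lam, neuron_factors=factors[0],
                    temporal_factors=factors[1], condition_factors=factors[2],
                    objective=float(objs[best]), init_objectives=objs,
                    n_init=n_init, degenerate=bool(np.all(lam == 0)))


# ---------------------------------------------------------------------------
# fit quality
# ---------------------------------------------------------------------------

@dataclass
class FitQuality:
    vaf: float
    window: tuple[float, float] = VAF_WINDOW
    cutoff_hz: float = VAF_CUTOFF_HZ
    flagged: bool = False


def _lowpass(y: np.ndarray, cutoff_hz: float, fs: float, axis: int) -> np.ndarray:
    b, a = butter(4, cutoff_hz / (fs / 2.0))
    return filtfilt(b, a, y, axis=axis)


def compute_vaf(x: PSTHTensor | np.ndarray, model: TCAModel,
                window: tuple[float, float] = VAF_WINDOW,
                cutoff_hz: float = VAF_CUTOFF_HZ) -> FitQuality:
    """VAF = 1 - var(x - xhat)/var(x) on the low-passed [0, 1) s window."""
    arr = x.values if isinstance(x, PSTHTensor) else np.asarray(x, float)
    xhat = model.reconstruct()
    if xhat.shape != arr.shape:
        raise ValueError("model dimensions do not match tensor")
    i0 = int(round((window[0] - PSTH_WINDOW[0]) / PSTH_BIN))
    i1 = int(round((window[1] - PSTH_WINDOW[0]) / PSTH_BIN))
    fs = 1.0 / PSTH_BIN
    xf = _lowpass(arr[:, i0:i1, :], cutoff_hz, fs, axis=1)
    hf = _lowpass(xhat[:, i0:i1, :], cutoff_hz, fs, axis=1)
    vx = float(np.var(xf))
    if vx == 0.0:
        return FitQuality(vaf=float("nan"), window=window,
                          cutoff_hz=cutoff_hz, flagged=True)
    return FitQuality(vaf=1.0 - float(np.var(xf - hf)) / vx, window=window,
                      cutoff_hz=cutoff_hz)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def shuffle_dataset(ds: Dataset, seed: int) -> Dataset:
    """Permutation surrogate: every (neuron, trial) activity is replaced by
    that of a uniformly random other (neuron, trial); the destination
    trial's condition label is retained."""
    import copy
    rng = np.random.default_rng(seed)
    keys: list[tuple[int, int, int]] = []       # (session idx, neuron, trial)
    pool: list[np.ndarray] = []
    for si, sess in enumerate(ds.sessions):
        by = {(st.neuron_id, st.trial_id): st.spike_times
              for st in sess.spike_trains}
        for nrn in sess.neurons:
            for tr in sess.trials:
                keys.append((si, nrn.neuron_id, tr.trial_id))
                pool.append(by.get((nrn.neuron_id, tr.trial_id), np.empty(0)))
    n = len(keys)
    out = copy.deepcopy(ds)
    from .datamodel import SpikeTrain
    for sess in out.sessions:
        sess.spike_trains = []
    for i, (si, nid, tid) in enumerate(keys):
        j = int(rng.integers(n))
        while j == i and n > 1:
            j = int(rng.integers(n))
        times = pool[j]
        if times.size:
            out.sessions[si].spike_trains.append(
                SpikeTrain(neuron_id=nid, trial_id=tid,
                           spike_times=times.copy()))
    return out


def shuffle_null(ds: Dataset, n_perm: int = 100, r_values=range(1, 21),
                 seed: int = 0, n_init: int = 10,
                 max_iter: int = 500) -> np.ndarray:
    """VAF-vs-rank curves for ``n_perm`` trial/neuron permutations.

    Returns an array (n_perm, len(r_values)).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    r_values = list(r_values)
    root = np.random.SeedSequence(seed)
    curves = np.zeros((n_perm, len(r_values)))
    for p, ss in enumerate(root.spawn(n_perm)):
        child = np.random.default_rng(ss)
        sh = shuffle_dataset(ds, seed=int(child.integers(2 ** 31)))
        tens = build_psth_tensor(sh)
        for ri, R in enumerate(r_values):
            model = fit_tca(tens, R, n_init=n_init,
                            seed=int(child.integers(2 ** 31)),
                            max_iter=max_iter)
            curves[p, ri] = compute_vaf(tens, model).vaf
    return curves


# ---------------------------------------------------------------------------
# distances, sampling, classification
# ---------------------------------------------------------------------------

def tc_distance(w_i: np.ndarray, w_j: np.ndarray) -> float:
    """Cosine distance between two neurons' component-coefficient vectors."""
    w_i = np.asarray(w_i, float)
    w_j = np.asarray(w_j, float)
    ni, nj = np.linalg.norm(w_i), np.linalg.norm(w_j)
    if ni == 0 or nj == 0:
        return float("nan")
    return float(1.0 - (w_i @ w_j) / (ni * nj))


@dataclass
class PopulationAssignment:
    top_sets: dict                   # component r -> set of neuron_ids
    labels: np.ndarray               # per neuron: 0..R-1, or -1 for null
    neuron_ids: np.ndarray


def assign_populations(model: TCAModel, neuron_ids: np.ndarray,
                       stages: np.ndarray, top_n: int = 300) -> PopulationAssignment:
    """topTC sampling and argmax classification of all neurons.

    Per learning stage and component, the ``top_n`` neurons with the largest
    coefficients are sampled (ties broken by ascending neuron_id); neurons
    sampled by more than one component within a stage are excluded from all
    top sets.  Every neuron is labeled by its argmax coefficient, or null
    (-1) if all coefficients are exactly zero.
    """
    W = model.neuron_factors
    R = model.rank
    neuron_ids = np.asarray(neuron_ids)
    stages = np.asarray(stages)
    top_sets: dict[int, set[int]] = {r: set() for r in range(R)}
    for stage in sorted(set(stages.tolist())):
        idx = np.where(stages == stage)[0]
        if idx.size < top_n:
            logger.info("stage %s has %d neurons < top_n=%d; taking all",
                        stage, idx.size, top_n)
        picked: dict[int, set[int]] = {}
        for r in range(R):
            order = sorted(idx, key=lambda i: (-W[i, r], neuron_ids[i]))
            picked[r] = set(order[: top_n])
        counts: dict[int, int] = {}
        for r in range(R):
            for i in picked[r]:
                counts[i] = counts.get(i, 0) + 1
        for r in range(R):
            keep = {i for i in picked[r] if counts[i] == 1}
            top_sets[r] |= {int(neuron_ids[i]) for i in keep}
    labels = np.where(np.all(W == 0, axis=1), -1, np.argmax(W, axis=1))
    return PopulationAssignment(top_sets=top_sets, labels=labels,
                                neuron_ids=neuron_ids)


def matched_congruence(model: TCAModel, true_factors: list[np.ndarray]) -> float:
    """Mean matched factor congruence between a fit and planted factors."""
    return solution_similarity(model.factors, true_factors)
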