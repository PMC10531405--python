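"""Domain types and delimited-table I/O for Go/No-go complex-spike sessions.

The dataset is a hierarchy ``Dataset -> Session -> (Trial, Neuron,
SpikeTrain)``.  All event times are trial-relative seconds with the cue onset
at 0; trials span ``[TRIAL_START, TRIAL_END)`` so the pre-cue baseline window
[-2, -1) s always exists.  Spike times live on a 10 ms grid (100 Hz detection
resolution).  All binning throughout the package is half-open ``[t, t + dt)``.

On disk a dataset is a directory of five tab-delimited UTF-8 tables with a
single header line each: ``trials.tsv``, ``neurons.tsv``, ``spikes.tsv``,
``licks.tsv``, ``sessions.tsv``.  Times are printed with 6 decimals so that
``load_dataset(save_dataset(ds)) == ds`` field for field and repeated saves
are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

# Trial support (seconds, cue onset = 0).
TRIAL_START = -2.0
TRIAL_END = 6.0
#: response window for HIT/FA/CR/MISS classification, [0, 1) s
RESPONSE_WINDOW_END = 1.0
#: spike times are quantized to this grid (100 Hz)
SPIKE_GRID = 0.01
#: reward delivery offsets after the first lick in HIT trials
REWARD_OFFSETS = (0.41, 0.82, 1.23)

CUES = ("Go", "Nogo")
CONDITIONS = ("HIT", "FA", "CR", "MISS")
#: the eight Aldolase-C compartments of Crus II, lateral to medial
COMPARTMENTS = ("7+", "6-", "6+", "5-", "5+", "5a-", "5a+", "4b-")

#: learning-stage boundaries on session fraction correct; stage 2 is the
#: closed interval [low, high]
STAGE_BOUNDS = (0.6, 0.8)

_TIME_FMT = "%.6f"


def stage_of(fraction_correct: float) -> int:
    """Learning stage (1/2/3) from the session fraction correct.

    Stage 1: < 0.6; stage 2: [0.6, 0.8]; stage 3: > 0.8.
    """
    lo, hi = STAGE_BOUNDS
    if fraction_correct < lo:
        return 1
    if fraction_correct <= hi:
        return 2
    return 3


def on_spike_grid(t: float, tol: float = 1e-6) -> bool:
    """True if ``t`` lies on the 10 ms spike grid (within float tolerance)."""
    return abs(t / SPIKE_GRID - round(t / SPIKE_GRID)) < tol


@dataclass
class Trial:
    trial_id: int
    session_id: int
    cue: str                      # "Go" | "Nogo"
    condition: str                # "HIT" | "FA" | "CR" | "MISS"
    lick_times: list[float] = field(default_factory=list)
    reward_times: list[float] = field(default_factory=list)
    cue_onset: float = 0.0
    response_window_end: float = RESPONSE_WINDOW_END

    @property
    def first_lick(self) -> float | None:
        return self.lick_times[0] if self.lick_times else None


@dataclass
class Neuron:
    neuron_id: int
    session_id: int
    compartment: str
    x_um: float
    y_um: float


@dataclass
class SpikeTrain:
    neuron_id: int
    trial_id: int
    spike_times: np.ndarray       # seconds, 10 ms grid, strictly increasing

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)


@dataclass
class Session:
    session_id: int
    mouse_id: int
    trials: list[Trial] = field(default_factory=list)
    neurons: list[Neuron] = field(default_factory=list)
    spike_trains: list[SpikeTrain] = field(default_factory=list)
    fraction_correct: float = 0.0

    @property
    def stage(self) -> int:
        return stage_of(self.fraction_correct)

    def trials_by_condition(self, condition: str) -> list[Trial]:
        return [t for t in self.trials if t.condition == condition]


@dataclass
class Dataset:
    sessions: list[Session] = field(default_factory=list)
    provenance: str = ""
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return sum(len(s.neurons) for s in self.sessions)

    @property
    def n_trials(self) -> int:
        return sum(len(s.trials) for s in self.sessions)

    def all_neurons(self) -> list[Neuron]:
        return [n for s in self.sessions for n in s.neurons]

    def all_trials(self) -> list[Trial]:
        return [t for s in self.sessions for t in s.trials]

    def session(self, session_id: int) -> Session:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(f"no session with session_id={session_id}")

    def spikes_of(self, neuron_id: int, trial_id: int) -> np.ndarray:
        sess = self._session_of_neuron(neuron_id)
        for st in sess.spike_trains:
            if st.neuron_id == neuron_id and st.trial_id == trial_id:
                return st.spike_times
        return np.empty(0)

    def _session_of_neuron(self, neuron_id: int) -> Session:
        for s in self.sessions:
            if any(n.neuron_id == neuron_id for n in s.neurons):
                return s
        raise KeyError(f"no neuron with neuron_id={neuron_id}")


@dataclass
class Violation:
    entity: str
    rule: str
    value: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule} (value={self.value})"


ValidationReport = list


class DatasetError(ValueError):
    """Fatal dataset problem: missing table, dangling reference, bad time."""


# ---------------------------------------------------------------------------
# classification rule (shared with the behavior module)
# ---------------------------------------------------------------------------

def classify_trial(cue: str, lick_times: Sequence[float]) -> str:
    """HIT/FA/CR/MISS from the cue and licks in the response window [0, 1) s."""
    licked = any(0.0 <= t < RESPONSE_WINDOW_END for t in lick_times)
    if cue == "Go":
        return "HIT" if licked else "MISS"
    return "FA" if licked else "CR"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_dataset(ds: Dataset) -> ValidationReport:
    """Check every type invariant; violations are returned, never raised."""
    report: list[Violation] = []
    seen_sessions: set[int] = set()
    seen_trials: set[int] = set()
    seen_neurons: set[int] = set()
    for sess in ds.sessions:
        sid = sess.session_id
        if sid in seen_sessions:
            report.append(Violation(f"session {sid}", "duplicate session_id", str(sid)))
        seen_sessions.add(sid)
        if not (0.0 <= sess.fraction_correct <= 1.0):
            report.append(Violation(f"session {sid}", "fraction_correct in [0,1]",
                                    str(sess.fraction_correct)))
        for nrn in sess.neurons:
            if nrn.neuron_id in seen_neurons:
                report.append(Violation(f"neuron {nrn.neuron_id}",
                                        "duplicate neuron_id", str(nrn.neuron_id)))
            seen_neurons.add(nrn.neuron_id)
            if nrn.compartment not in COMPARTMENTS:
                report.append(Violation(f"neuron {nrn.neuron_id}",
                                        "compartment in the 8 AldC labels",
                                        nrn.compartment))
            if not (math.isfinite(nrn.x_um) and math.isfinite(nrn.y_um)):
                report.append(Violation(f"neuron {nrn.neuron_id}",
                                        "finite position", f"({nrn.x_um},{nrn.y_um})"))
        for tr in sess.trials:
            tid = tr.trial_id
            if tid in seen_trials:
                report.append(Violation(f"trial {tid}", "duplicate trial_id", str(tid)))
            seen_trials.add(tid)
            if tr.cue not in CUES:
                report.append(Violation(f"trial {tid}", "cue in {Go,Nogo}", tr.cue))
            if tr.condition not in CONDITIONS:
                report.append(Violation(f"trial {tid}", "condition in {HIT,FA,CR,MISS}",
                                        tr.condition))
            if any(b <= a for a, b in zip(tr.lick_times, tr.lick_times[1:])):
                report.append(Violation(f"trial {tid}", "lick_times strictly increasing",
                                        str(tr.lick_times)))
            expected = classify_trial(tr.cue, tr.lick_times)
            if tr.condition in CONDITIONS and tr.cue in CUES and tr.condition != expected:
                report.append(Violation(
                    f"trial {tid}",
                    "condition consistent with cue and response-window licks "
                    f"(classification rule gives {expected})", tr.condition))
            if tr.reward_times:
                fl = tr.first_lick
                want = [] if fl is None else [fl + o for o in REWARD_OFFSETS]
                if (fl is None or len(tr.reward_times) != len(want)
                        or any(abs(a - b) > 1e-6 for a, b in zip(tr.reward_times, want))):
                    report.append(Violation(
                        f"trial {tid}", "reward_times = first lick + {0.41,0.82,1.23} s",
                        str(tr.reward_times)))
        trial_ids = {t.trial_id for t in sess.trials}
        neuron_ids = {n.neuron_id for n in sess.neurons}
        for st in sess.spike_trains:
            ent = f"spike train (neuron {st.neuron_id}, trial {st.trial_id})"
            if st.neuron_id not in neuron_ids:
                report.append(Violation(ent, "neuron_id exists in session",
                                        str(st.neuron_id)))
            if st.trial_id not in trial_ids:
                report.append(Violation(ent, "trial_id exists in session",
                                        str(st.trial_id)))
            t = st.spike_times
            if np.any(np.diff(t) <= 0):
                report.append(Violation(ent, "spike times strictly increasing", str(t)))
            off = [x for x in t if not on_spike_grid(x)]
            if off:
                report.append(Violation(ent, "spike times on the 10 ms grid", str(off)))
            if t.size and (t[0] < TRIAL_START or t[-1] >= TRIAL_END):
                report.append(Violation(ent, "spike times within trial bounds",
                                        f"[{t[0]}, {t[-1]}]"))
    return report


# ---------------------------------------------------------------------------
# save / load
# ---------------------------------------------------------------------------

_TABLES = {
    "trials": ["trial_id", "session_id", "cue", "condition", "first_lick_s"],
    "neurons": ["neuron_id", "session_id", "compartment", "x_um", "y_um"],
    "spikes": ["neuron_id", "trial_id", "time_s"],
    "licks": ["trial_id", "time_s"],
    "sessions": ["session_id", "mouse_id", "fraction_correct", "stage"],
}


def _fmt(x: float) -> str:
    return _TIME_FMT % x


def save_dataset(ds: Dataset, path: str | Path) -> Path:
    """Write the five event tables under ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list[list[str]]] = {k: [] for k in _TABLES}
    for sess in ds.sessions:
        rows["sessions"].append([str(sess.session_id), str(sess.mouse_id),
                                 _fmt(sess.fraction_correct), str(sess.stage)])
        for tr in sess.trials:
            fl = tr.first_lick
            rows["trials"].append([str(tr.trial_id), str(sess.session_id), tr.cue,
                                   tr.condition, _fmt(fl) if fl is not None else ""])
            for lt in tr.lick_times:
                rows["licks"].append([str(tr.trial_id), _fmt(lt)])
        for nrn in sess.neurons:
            rows["neurons"].append([str(nrn.neuron_id), str(sess.session_id),
                                    nrn.compartment, _fmt(nrn.x_um), _fmt(nrn.y_um)])
        for st in sorted(sess.spike_trains,
                         key=lambda s: (s.neuron_id, s.trial_id)):
            for t in st.spike_times:
                rows["spikes"].append([str(st.neuron_id), str(st.trial_id), _fmt(t)])
    for name, header in _TABLES.items():
        lines = ["\t".join(header)]
        lines += ["\t".join(r) for r in rows[name]]
        (path / f"{name}.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`save_dataset`.

    Raises :class:`DatasetError` on a missing table, a dangling foreign key,
    or an off-grid spike time.
    """
    path = Path(path)
    frames: dict[str, pd.DataFrame] = {}
    for name in _TABLES:
        f = path / f"{name}.tsv"
        if not f.exists():
            raise DatasetError(f"missing table: {name}.tsv in {path}")
        frames[name] = pd.read_csv(f, sep="\t", dtype={"cue": str, "condition": str,
                                                       "compartment": str})
    sessions: dict[int, Session] = {}
    for r in frames["sessions"].itertuples():
        sessions[int(r.session_id)] = Session(
            session_id=int(r.session_id), mouse_id=int(r.mouse_id),
            fraction_correct=float(r.fraction_correct))

    licks_by_trial: dict[int, list[float]] = {}
    for r in frames["licks"].itertuples():
        licks_by_trial.setdefault(int(r.trial_id), []).append(float(r.time_s))

    trial_session: dict[int, int] = {}
    for r in frames["trials"].itertuples():
        sid = int(r.session_id)
        if sid not in sessions:
            raise DatasetError(f"trials.tsv: trial {r.trial_id} references unknown "
                               f"session_id {sid}")
        tid = int(r.trial_id)
        licks = sorted(licks_by_trial.get(tid, []))
        rewards = ([licks[0] + o for o in REWARD_OFFSETS]
                   if (r.condition == "HIT" and licks) else [])
        sessions[sid].trials.append(Trial(
            trial_id=tid, session_id=sid, cue=str(r.cue), condition=str(r.condition),
            lick_times=licks, reward_times=rewards))
        trial_session[tid] = sid

    dangling_licks = sorted(set(licks_by_trial) - set(trial_session))
    if dangling_licks:
        raise DatasetError(f"licks.tsv references unknown trial_id(s): {dangling_licks}")

    neuron_session: dict[int, int] = {}
    for r in frames["neurons"].itertuples():
        sid = int(r.session_id)
        if sid not in sessions:
            raise DatasetError(f"neurons.tsv: neuron {r.neuron_id} references unknown "
                               f"session_id {sid}")
        nid = int(r.neuron_id)
        sessions[sid].neurons.append(Neuron(
            neuron_id=nid, session_id=sid, compartment=str(r.compartment),
            x_um=float(r.x_um), y_um=float(r.y_um)))
        neuron_session[nid] = sid

    spike_rows: dict[tuple[int, int], list[float]] = {}
    bad_neuron, bad_trial = [], []
    for r in frames["spikes"].itertuples():
        nid, tid, t = int(r.neuron_id), int(r.trial_id), float(r.time_s)
        if nid not in neuron_session:
            bad_neuron.append(nid)
            continue
        if tid not in trial_session:
            bad_trial.append(tid)
            continue
        if not on_spike_grid(t):
            raise DatasetError(f"spikes.tsv: time {t} for neuron {nid} trial {tid} "
                               f"is off the 10 ms grid")
        spike_rows.setdefault((nid, tid), []).append(t)
    if bad_neuron:
        raise DatasetError(f"spikes.tsv references unknown neuron_id(s): "
                           f"{sorted(set(bad_neuron))}")
    if bad_trial:
        raise DatasetError(f"spikes.tsv references unknown trial_id(s): "
                           f"{sorted(set(bad_trial))}")
    for (nid, tid), times in sorted(spike_rows.items()):
        sessions[neuron_session[nid]].spike_trains.append(
            SpikeTrain(neuron_id=nid, trial_id=tid,
                       spike_times=np.array(sorted(times))))

    return Dataset(sessions=[sessions[k] for k in sorted(sessions)])


def datasets_equal(a: Dataset, b: Dataset, tol: float = 5e-7) -> bool:
    """Field-by-field equality of two datasets up to the 6-decimal print grid."""
    if len(a.sessions) != len(b.sessions):
        return False
    for sa, sb in zip(a.sessions, b.sessions):
        if (sa.session_id, sa.mouse_id) != (sb.session_id, sb.mouse_id):
            return False
        if abs(sa.fraction_correct - sb.fraction_correct) > tol:
            return False
        if len(sa.trials) != len(sb.trials) or len(sa.neurons) != len(sb.neurons):
            return False
        for ta, tb in zip(sorted(sa.trials, key=lambda t: t.trial_id),
                          sorted(sb.trials, key=lambda t: t.trial_id)):
            if (ta.trial_id, ta.cue, ta.condition) != (tb.trial_id, tb.cue, tb.condition):
                return False
            if len(ta.lick_times) != len(tb.lick_times):
                return False
            if any(abs(x - y) > tol for x, y in zip(ta.lick_times, tb.lick_times)):
                return False
        for na, nb in zip(sorted(sa.neurons, key=lambda n: n.neuron_id),
                          sorted(sb.neurons, key=lambda n: n.neuron_id)):
            if (na.neuron_id, na.compartment) != (nb.neuron_id, nb.compartment):
                return False
            if abs(na.x_um - nb.x_um) > tol or abs(na.y_um - nb.y_um) > tol:
                return False
        key = lambda st: (st.neuron_id, st.trial_id)
        sta = sorted((st for st in sa.spike_trains if st.spike_times.size), key=key)
        stb = sorted((st for st in sb.spike_trains if st.spike_times.size), key=key)
        if len(sta) != len(stb):
            return False
        for xa, xb in zip(sta, stb):
            if key(xa) != key(xb) or xa.spike_times.size != xb.spike_times.size:
                return False
            if np.max(np.abs(xa.spike_times - xb.spike_times), initial=0.0) > tol:
                return False
    return True
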