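"""End-to-end driver: generate -> detect -> behavior -> tensor -> synchrony
-> decode -> stats, with one JSON config + master seed.

Every stage writes tab-delimited tables into the run directory and reads
only prior-stage tables, so any stage can also run on externally supplied
tables in the same formats.  Re-running with the same config reproduces all
tables byte-identically (the log carries timings and is excluded from that
guarantee).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import decoding as dec
from . import statsdim as sd
from . import synchrony as syn
from . import tensor as tca
from .datamodel import Dataset, load_dataset, save_dataset, validate_dataset
from .detect import run_detection_benchmark
from .synth import (CONDITION_ORDER, CalciumKernelParams, GeneratorConfig,
                    generate_dataset, small_config)

logger = logging.getLogger("cfpop")

_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the analysis' standard values.

    PSTH bin 50 ms over [-0.5, 2) s with baseline [-2, -1) s and a 5-trial
    minimum; response window [0, 0.2) s; synchrony 30 ms bins in a 300 ms
    window; CCG 10 ms bins with strength over +-10 ms; lick histogram bin
    100 ms; rank range 1..20 with 100 initializations and 100 permutations;
    top-300 sampling; stage boundaries (0.6, 0.8).
    """
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=small_config)
    stages: tuple[str, ...] = ("generate", "detect", "behavior", "tensor",
                               "synchrony", "decode", "stats")
    psth_bin: float = 0.05
    psth_window: tuple[float, float] = (-0.5, 2.0)
    baseline_window: tuple[float, float] = (-2.0, -1.0)
    min_trials: int = 5
    response_window: tuple[float, float] = (0.0, 0.2)
    sync_bin: float = 0.03
    sync_window: float = 0.3
    ccg_bin: float = 0.01
    ccg_max_lag: float = 0.1
    lick_bin: float = 0.1
    rank: int = 4
    r_values: tuple[int, ...] = tuple(range(1, 21))
    n_init: int = 100
    n_perm: int = 100
    top_n: int = 300
    dt0: float = 10.0
    stage_bounds: tuple[float, float] = (0.6, 0.8)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        gen = raw.pop("generator", {})
        kern = gen.pop("kernel", {}) if isinstance(gen, dict) else {}
        trends = gen.pop("trends", {}) if isinstance(gen, dict) else {}
        from .synth import BehaviorTrends
        gcfg = GeneratorConfig(**gen,
                               kernel=CalciumKernelParams(**kern),
                               trends=BehaviorTrends(**{
                                   k: tuple(v) if isinstance(v, list) else v
                                   for k, v in trends.items()}))
        known = {f.name for f in fields(cls)}
        kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in raw.items() if k in known}
        return cls(generator=gcfg, **kwargs)

    def reduced(self) -> "RunConfig":
        """Preset with n_init/n_perm/r range scaled down for smoke runs."""
        import dataclasses
        return dataclasses.replace(self, n_init=10, n_perm=3,
                                   r_values=(1, 2, 4, 6), top_n=20)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
              lineterminator="\n")


def _require(out: Path, stage: str, *names: str) -> None:
    for n in names:
        if not (out / n).exists():
            raise StageError(stage, f"missing required input table {n} "
                             f"(did an earlier stage run?)")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_generate(cfg: RunConfig, out: Path) -> None:
    ds, truth = generate_dataset(cfg.generator, seed=cfg.seed)
    report = validate_dataset(ds)
    if report:
        raise StageError("generate", f"invalid dataset: {report[0]}")
    save_dataset(ds, out)
    rows = []
    for mode, mat in (("neuron", truth.neuron_factors),
                      ("time", truth.temporal_factors),
                      ("condition", truth.condition_factors)):
        for i, row in enumerate(mat):
            for r, v in enumerate(row):
                rows.append((mode, i, r + 1, v))
    _write(pd.DataFrame(rows, columns=["mode", "index", "component",
                                       "coefficient"]),
           out / "truth_factors.tsv")
    _write(pd.DataFrame({"component": np.arange(truth.rank) + 1,
                         "scale": truth.scales,
                         "sync_level": truth.sync_level}),
           out / "truth_scales.tsv")


def stage_detect(cfg: RunConfig, out: Path) -> None:
    ev = run_detection_benchmark(cfg.generator.kernel, seed=cfg.seed)
    _write(pd.DataFrame([{
        "hit": ev.hit, "miss": ev.miss, "false_positive": ev.false_positive,
        "sensitivity": ev.sensitivity, "precision": ev.precision,
        "f1": ev.f1}]), out / "detection_benchmark.tsv")


def _load(out: Path, stage: str) -> Dataset:
    _require(out, stage, "trials.tsv", "sessions.tsv", "neurons.tsv",
             "spikes.tsv", "licks.tsv")
    return load_dataset(out)


def stage_behavior(cfg: RunConfig, out: Path) -> None:
    ds = _load(out, "behavior")
    beh_rows, sess_rows = [], []
    by_mouse: dict[int, list] = {}
    for sess in ds.sessions:
        by_mouse.setdefault(sess.mouse_id, []).append(sess)
    for mouse, sessions in sorted(by_mouse.items()):
        sessions = sorted(sessions, key=lambda s: s.session_id)
        trials = [t for s in sessions for t in s.trials]
        idx = {t.trial_id: i for i, t in enumerate(trials)}
        mean_lat = bhv.mouse_mean_latency(trials)
        lat_pairs = [(idx[t.trial_id], t.first_lick) for t in trials
                     if t.condition in ("HIT", "FA") and t.first_lick is not None]
        trend = None
        if len(lat_pairs) >= 2 and mean_lat:
            xs, ys = zip(*lat_pairs)
            trend = bhv.fit_latency_trend(ys, trial_index=xs)
        behaviors = {}
        for t in trials:
            b = bhv.compute_lick_variables(t, trend, mean_lat or 1.0,
                                           trial_index=idx[t.trial_id])
            behaviors[t.trial_id] = b
            beh_rows.append({
                "trial_id": t.trial_id, "mouse_id": mouse,
                "session_id": t.session_id, "condition": t.condition,
                "lick_latency": b.lick_latency,
                "latency_fluctuation": b.latency_fluctuation,
                "early_lick_count": b.early_lick_count})
        for s in sessions:
            summ = bhv.summarize_session(
                s.trials, [behaviors[t.trial_id] for t in s.trials],
                trial_index=[idx[t.trial_id] for t in s.trials])
            sess_rows.append({
                "session_id": s.session_id, "mouse_id": mouse,
                "fraction_correct": summ.fraction_correct,
                "fraction_correct_go": summ.fraction_correct_go,
                "fraction_incorrect_nogo": summ.fraction_incorrect_nogo,
                "stage": summ.stage,
                "fluctuation_slope": summ.fluctuation_slope,
                "early_lick_slope": summ.early_lick_slope})
    _write(pd.DataFrame(beh_rows), out / "trial_behavior.tsv")
    _write(pd.DataFrame(sess_rows), out / "session_summary.tsv")


def stage_tensor(cfg: RunConfig, out: Path) -> None:
    ds = _load(out, "tensor")
    tens = tca.build_psth_tensor(ds, bin_s=cfg.psth_bin, window=cfg.psth_window)
    long = []
    for i, nid in enumerate(tens.neuron_ids):
        for t in range(tens.values.shape[1]):
            for k, cond in enumerate(CONDITION_ORDER):
                long.append((nid, t, cond, tens.values[i, t, k]))
    _write(pd.DataFrame(long, columns=["neuron_id", "bin", "condition",
                                       "rate_hz"]), out / "psth_tensor.tsv")
    model = tca.fit_tca(tens, cfg.rank, n_init=cfg.n_init, seed=cfg.seed)
    rows = []
    for mode, mat, ids in (("neuron", model.neuron_factors, tens.neuron_ids),
                           ("time", model.temporal_factors,
                            np.arange(model.temporal_factors.shape[0])),
                           ("condition", model.condition_factors,
                            np.array(CONDITION_ORDER))):
        for i, row in zip(ids, mat):
            for r, v in enumerate(row):
                rows.append((mode, i, r + 1, v))
    _write(pd.DataFrame(rows, columns=["mode", "entity", "component",
                                       "coefficient"]),
           out / "tca_factors.tsv")
    vrows = []
    rng = np.random.default_rng(cfg.seed + 1)
    for R in cfg.r_values:
        if R > min(tens.values.shape):
            continue
        m = tca.fit_tca(tens, R, n_init=max(2, cfg.n_init // 10),
                        seed=int(rng.integers(2 ** 31)))
        vrows.append({"R": R, "vaf": tca.compute_vaf(tens, m).vaf})
    _write(pd.DataFrame(vrows), out / "vaf_curve.tsv")
    assign = tca.assign_populations(model, tens.neuron_ids, tens.stages,
                                    top_n=cfg.top_n)
    lab_rows = []
    for i, nid in enumerate(tens.neuron_ids):
        tops = [r + 1 for r in range(model.rank)
                if int(nid) in assign.top_sets[r]]
        lab_rows.append({"neuron_id": nid,
                         "label": ("null" if assign.labels[i] < 0
                                   else f"TC{assign.labels[i] + 1}"),
                         "top_component": tops[0] if tops else 0})
    _write(pd.DataFrame(lab_rows), out / "labels.tsv")
    _write(pd.DataFrame([{"vaf": tca.compute_vaf(tens, model).vaf,
                          "rank": cfg.rank}]), out / "tca_vaf.tsv")


def _populations(out: Path, stage: str) -> pd.DataFrame:
    _require(out, stage, "labels.tsv")
    return pd.read_csv(out / "labels.tsv", sep="\t")


def stage_synchrony(cfg: RunConfig, out: Path) -> None:
    ds = _load(out, "synchrony")
    labels = _populations(out, "synchrony")
    top_of = dict(zip(labels.neuron_id, labels.top_component))
    inst_rows, pair_rows = [], []
    for sess in ds.sessions:
        by = {(st.neuron_id, st.trial_id): st.spike_times
              for st in sess.spike_trains}
        pops: dict[int, list[int]] = {}
        for n in sess.neurons:
            r = int(top_of.get(n.neuron_id, 0))
            if r > 0:
                pops.setdefault(r, []).append(n.neuron_id)
        for tr in sess.trials:
            for r, nids in sorted(pops.items()):
                if len(nids) < 2:
                    continue
                trains = {nid: by.get((nid, tr.trial_id), np.empty(0))
                          for nid in nids}
                isy = syn.instantaneous_synchrony(trains, tr,
                                                  bin_s=cfg.sync_bin,
                                                  width=cfg.sync_window)
                inst_rows.append({"trial_id": tr.trial_id,
                                  "session_id": sess.session_id,
                                  "population": f"TC{r}",
                                  "value": isy.value,
                                  "spike_count": isy.spike_count_per_neuron})
        trial_order = [t.trial_id for t in sess.trials]
        trains_by_neuron = {
            n.neuron_id: [by.get((n.neuron_id, tid), np.empty(0))
                          for tid in trial_order]
            for n in sess.neurons}
        for i, j, s, sc in syn.pairwise_strengths(trains_by_neuron,
                                                  bin_s=cfg.ccg_bin,
                                                  max_lag=cfg.ccg_max_lag):
            pair_rows.append({"neuron_i": i, "neuron_j": j,
                              "session_id": sess.session_id, "strength": s,
                              "shift_corrected_strength": sc})
    _write(pd.DataFrame(inst_rows, columns=["trial_id", "session_id",
                                            "population", "value",
                                            "spike_count"]),
           out / "instantaneous_synchrony.tsv")
    _write(pd.DataFrame(pair_rows, columns=["neuron_i", "neuron_j",
                                            "session_id", "strength",
                                            "shift_corrected_strength"]),
           out / "pairwise_strength.tsv")


def stage_decode(cfg: RunConfig, out: Path) -> None:
    ds = _load(out, "decode")
    labels = _populations(out, "decode")
    top_of = dict(zip(labels.neuron_id, labels.top_component))
    sync_spk, all_top_spk, all_spk, licks = [], [], [], []
    for sess in ds.sessions:
        by = {(st.neuron_id, st.trial_id): st.spike_times
              for st in sess.spike_trains}
        top_ids = [n.neuron_id for n in sess.neurons
                   if top_of.get(n.neuron_id, 0) in (1, 2)]
        all_ids = [n.neuron_id for n in sess.neurons]
        for tr in sess.trials:
            if tr.condition not in ("HIT", "FA"):
                continue
            trains = {nid: by.get((nid, tr.trial_id), np.empty(0))
                      for nid in top_ids}
            filt = dec.filter_synchronous_spikes(trains, bin_s=cfg.sync_bin)
            sync_spk.append(np.sort(np.concatenate(list(filt.values()))
                                    if filt else np.empty(0)))
            all_top_spk.append(np.sort(np.concatenate(
                [trains[n] for n in top_ids]) if top_ids else np.empty(0)))
            all_spk.append(np.sort(np.concatenate(
                [by.get((nid, tr.trial_id), np.empty(0)) for nid in all_ids])
                if all_ids else np.empty(0)))
            licks.append(np.asarray(tr.lick_times))
    if not licks:
        raise StageError("decode", "no HIT/FA trials available")
    stl = dec.spike_triggered_lick(all_spk, licks, window_class="decode",
                                   bin_s=cfg.lick_bin)
    _write(pd.DataFrame({"lag_s": stl.lags, "rate": stl.response}),
           out / "stl_response.tsv")
    result = dec.decoding_loglik(
        {"sync_topTC": sync_spk, "all_topTC": all_top_spk,
         "all_session": all_spk}, licks, stl, dt0=cfg.dt0)
    best = pd.Series(result.per_trial_best)
    rows = [{"model": m, "total_loglik": ll, "n_licks": result.n_licks,
             "fraction_trials_best": float((best == m).mean()) if len(best) else 0.0}
            for m, ll in result.total_loglik.items()]
    _write(pd.DataFrame(rows), out / "decoding_loglik.tsv")


def stage_stats(cfg: RunConfig, out: Path) -> None:
    _require(out, "stats", "trial_behavior.tsv", "instantaneous_synchrony.tsv",
             "session_summary.tsv", "psth_tensor.tsv")
    beh = pd.read_csv(out / "trial_behavior.tsv", sep="\t")
    inst = pd.read_csv(out / "instantaneous_synchrony.tsv", sep="\t")
    sessions = pd.read_csv(out / "session_summary.tsv", sep="\t")
    if inst.empty:
        wide = pd.DataFrame({"trial_id": []})
    else:
        wide = inst.pivot_table(index="trial_id", columns="population",
                                values="value", aggfunc="first")
        wide.columns = [f"syn_{c}" for c in wide.columns]
        wide = wide.reset_index()
    table = beh.merge(wide, on="trial_id", how="left").merge(
        sessions[["session_id", "fraction_correct"]], on="session_id")
    for c in sd.SYN_COLUMNS:
        if c not in table:
            table[c] = np.nan
    reg_rows = []
    for response, subset in (("latency_fluctuation",
                              table[table.condition.isin(["HIT"])]),
                             ("early_lick_count",
                              table[table.condition.isin(["FA", "CR"])])):
        # drop predictors that are structurally constant in this subset
        # (e.g. a component population never sampled at this scale)
        preds = [c for c in sd.SYN_COLUMNS + ("fraction_correct",)
                 if subset[c].fillna(0.0).nunique() > 1]
        if not preds:
            logger.warning("regression for %s skipped: no varying predictors",
                           response)
            continue
        try:
            fit = sd.synchrony_regression(
                subset.rename(columns={response: "y"}), "y",
                predictors=tuple(preds))
        except ValueError as e:
            logger.warning("regression for %s skipped: %s", response, e)
            continue
        for term, coef, p in zip(fit.terms, fit.coefficients, fit.p_values):
            reg_rows.append({"response": response, "term": term,
                             "coefficient": coef, "p": p})
    _write(pd.DataFrame(reg_rows), out / "regression_fit.tsv")

    psth = pd.read_csv(out / "psth_tensor.tsv", sep="\t")
    mat = (psth.pivot_table(index="neuron_id", columns=["condition", "bin"],
                            values="rate_hz").sort_index(axis=1).values)
    spec = sd.pca_dimension(mat)
    _write(pd.DataFrame({"i": np.arange(spec.lambda_hat.size) + 1,
                         "lambda_hat": spec.lambda_hat,
                         "vaf_k": spec.vaf_k}), out / "spectrum.tsv")
    (out / "dimension.txt").write_text(f"{spec.dimension:.6f}\n")


_STAGES = {"generate": stage_generate, "detect": stage_detect,
           "behavior": stage_behavior, "tensor": stage_tensor,
           "synchrony": stage_synchrony, "decode": stage_decode,
           "stats": stage_stats}


def run_pipeline(cfg: RunConfig, out: str | Path) -> Path:
    """Run the configured stages in order into ``out``; returns the path."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={cfg.seed}", f"stages={','.join(cfg.stages)}"]
    for name in cfg.stages:
        if name not in _STAGES:
            raise StageError(name, "unknown stage")
        t0 = time.perf_counter()
        try:
            _STAGES[name](cfg, out)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - annotate with stage name
            raise StageError(name, str(e)) from e
        log_lines.append(f"{name}: {time.perf_counter() - t0:.2f} s")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
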