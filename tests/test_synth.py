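import numpy as np
import pytest

from cfpop.datamodel import datasets_equal
from cfpop.synchrony import cross_correlogram
from cfpop.synth import (BehaviorTrends, CalciumKernelParams, CONDITION_ORDER,
                         GeneratorConfig, _temporal_profiles,
                         draw_correlated_spikes, generate_dataset,
                         simulate_licks, small_config, synthesize_calcium)
from cfpop.tensor import build_psth_tensor


def test_same_seed_is_deterministic():
    cfg = small_config(n_mice=1, sessions_per_mouse=2, neurons_per_session=6,
                       trials_per_session=10)
    a, _ = generate_dataset(cfg, seed=5)
    b, _ = generate_dataset(cfg, seed=5)
    assert datasets_equal(a, b)


def test_zero_scales_gives_baseline_only():
    cfg = small_config(n_mice=1, sessions_per_mouse=2, neurons_per_session=8,
                       trials_per_session=20,
                       component_amplitude=(0.0, 0.0, 0.0, 0.0))
    ds, _ = generate_dataset(cfg, seed=3)
    tens = build_psth_tensor(ds)
    # baseline-subtracted PSTH should hover around 0 within sampling error
    assert abs(float(tens.values.mean())) < 0.15
    rate = sum(st.spike_times.size for s in ds.sessions
               for st in s.spike_trains) / (ds.n_trials * 8.0 * 8)
    assert rate == pytest.approx(1.1, abs=3 * 0.3)


def test_generated_psths_match_planted_profiles(recovery_dataset):
    ds, truth = recovery_dataset
    tens = build_psth_tensor(ds)
    b = _temporal_profiles()
    engaged = {0: "HIT", 1: "FA", 2: "HIT", 3: "CR"}
    for r, cond in engaged.items():
        dom = truth.dominant_component == r
        k = CONDITION_ORDER.index(cond)
        mean_psth = tens.values[dom, :, k].mean(axis=0)
        assert np.corrcoef(mean_psth, b[:, r])[0, 1] > 0.8


def test_sessions_span_all_three_stages(recovery_dataset):
    ds, _ = recovery_dataset
    assert {s.stage for s in ds.sessions} == {1, 2, 3}


def test_nonpositive_counts_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n_mice=0)


class TestCorrelatedSpikes:
    def test_p1_identical_trains(self):
        prof = np.full(500, 3.0)
        trains = draw_correlated_spikes(prof, 4, 1.0, seed=0)
        for t in trains[1:]:
            assert np.array_equal(t, trains[0])

    def test_p0_coincidences_at_chance(self):
        prof = np.full(600, 2.0)
        co = chance = 0.0
        n_trials = 200
        for s in range(n_trials):
            a, b = draw_correlated_spikes(prof, 2, 0.0, seed=s)
            xa = np.zeros(600, bool)
            xa[np.round(a / 0.01).astype(int)] = True
            xb = np.zeros(600, bool)
            xb[np.round(b / 0.01).astype(int)] = True
            co += np.sum(xa & xb)
            chance += xa.sum() * xb.sum() / 600
        se = np.sqrt(chance)   # Poisson-scale error on the coincidence count
        assert abs(co - chance) < 3 * se

    def test_marginal_rate_conserved(self):
        prof = np.full(1000, 2.0)   # 10 s at 2 Hz
        counts = [len(t) for s in range(50)
                  for t in draw_correlated_spikes(prof, 3, 0.5, seed=s)]
        expect = 2.0 * 10.0
        se = np.sqrt(expect / len(counts))
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_sync_level_monotone_in_strength(self):
        from cfpop.synchrony import synchrony_strength
        prof = np.full(600, 2.0)

        def mean_strength(p):
            vals = []
            for s in range(100):
                a, b = draw_correlated_spikes(prof, 2, p, seed=s)
                ccg = cross_correlogram([a], [b], support=(0, 6))
                if not ccg.flagged:
                    vals.append(synchrony_strength(ccg))
            return np.mean(vals)

        assert mean_strength(0.5) > mean_strength(0.1)


class TestCalcium:
    def test_empty_train_no_noise_is_zero(self):
        k = CalciumKernelParams(snr_db=np.inf)
        _, tr = synthesize_calcium([], k, seed=1, duration=2.0)
        assert np.allclose(tr, 0.0)

    def test_kernel_peak_time_closed_form(self):
        k = CalciumKernelParams()
        r, d = k.rise_tau, k.decay_tau
        expect = r * d / (d - r) * np.log(d / r)
        assert k.peak_time == pytest.approx(expect)
        assert expect == pytest.approx(0.0352, abs=5e-4)
        # fine-grid argmax agrees
        t = np.arange(0, 0.5, 1e-4)
        assert t[np.argmax(k.kernel(t))] == pytest.approx(expect, abs=2e-4)

    def test_linearity_of_superposition(self):
        k = CalciumKernelParams()
        _, one_a = synthesize_calcium([0.50], k, seed=None, duration=3.0)
        _, one_b = synthesize_calcium([0.55], k, seed=None, duration=3.0)
        _, both = synthesize_calcium([0.50, 0.55], k, seed=None, duration=3.0)
        assert np.allclose(both, one_a + one_b)

    def test_noise_sd_follows_snr(self):
        k = CalciumKernelParams(snr_db=10.0)
        _, tr = synthesize_calcium([], k, seed=7, duration=200.0)
        expect = k.peak_amplitude / 10 ** 0.5
        assert np.std(tr) == pytest.approx(expect, rel=0.1)


class TestLicks:
    def test_zero_noise_latency_on_trend(self):
        trends = BehaviorTrends(latency_poly=(0.5,),
                                latency_sd_by_stage=(0.0, 0.0, 0.0),
                                miss_prob_by_stage=(0.0, 0.0, 0.0))
        licks, cond = simulate_licks("Go", 1, 0, trends, seed=2)
        assert cond == "HIT" and licks[0] == pytest.approx(0.5)

    def test_zero_early_lick_prob_gives_all_cr(self):
        trends = BehaviorTrends(early_lick_prob_by_stage=(0.0, 0.0, 0.0))
        for s in range(50):
            licks, cond = simulate_licks("Nogo", 1, 0, trends, seed=s)
            assert cond == "CR" and licks == []

    def test_stage3_fewer_nogo_errors_than_stage1(self):
        trends = BehaviorTrends()
        def frac_fa(stage):
            n = sum(simulate_licks("Nogo", stage, 0, trends, seed=s)[1] == "FA"
                    for s in range(500))
            return n / 500
        assert frac_fa(3) < frac_fa(1)
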