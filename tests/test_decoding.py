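import numpy as np
import pytest

from cfpop.decoding import (decoding_loglik, filter_synchronous_spikes,
                            spike_triggered_lick)
from cfpop.synth import simulate_coupled_licking


class TestSpikeTriggeredLick:
    def test_delta_coupled_single_peak(self):
        spikes = [np.array([0.2])] * 50
        licks = [np.array([0.45])] * 50
        stl = spike_triggered_lick(spikes, licks, "early")
        i = int(np.argmax(stl.response))
        assert stl.lags[i] == pytest.approx(0.2)       # [0.2, 0.3) bin
        assert stl.response[i] == pytest.approx(1 / 0.1)
        assert np.sum(stl.response > 0) == 1

    def test_no_licks_all_zero(self):
        stl = spike_triggered_lick([np.array([0.2])] * 5, [np.array([])] * 5,
                                   "early")
        assert np.all(stl.response == 0.0)

    def test_independence_null_flat(self):
        rng = np.random.default_rng(0)
        spikes, licks = [], []
        for _ in range(400):
            spikes.append(rng.uniform(0, 0.5, size=rng.poisson(1.0)))
            licks.append(rng.uniform(0, 0.5, size=rng.poisson(2.0)))
        stl = spike_triggered_lick(spikes, licks, "early")
        # pairs have triangular lag density on (-0.5, 0.5); compare each bin
        # with its analytic expectation within 3 SE
        lam = 1.0 * 2.0   # E[pairs]/trial
        for i, lo in enumerate(stl.lags):
            if lo < -0.5 or lo >= 0.5:
                continue
            hi = lo + stl.bin_s
            # triangular density f(d) = (0.5-|d|)/0.25 on (-0.5, 0.5)
            p = max(0.0, ((0.5 - abs(lo)) + (0.5 - min(abs(hi), 0.5))) / 2
                    / 0.25 * stl.bin_s)
            expect = lam * p / stl.bin_s
            se = np.sqrt(max(lam * p, 1e-9) * 400) / (400 * stl.bin_s)
            assert abs(stl.response[i] - expect) <= 3 * se + 1e-6

    def test_zero_trials_fatal(self):
        with pytest.raises(ValueError):
            spike_triggered_lick([], [], "early")

    def test_unknown_window_class_fatal(self):
        with pytest.raises(ValueError):
            spike_triggered_lick([np.array([0.2])], [np.array([0.3])], "huh")


class TestSynchronousFilter:
    def test_same_bin_both_retained(self):
        trains = {1: np.array([0.010]), 2: np.array([0.020])}
        out = filter_synchronous_spikes(trains)
        assert out[1].tolist() == [0.010]
        assert out[2].tolist() == [0.020]

    def test_interleaved_disjoint_bins_empty(self):
        trains = {1: np.array([0.00, 0.06]), 2: np.array([0.03, 0.09])}
        out = filter_synchronous_spikes(trains)
        assert out[1].size == 0 and out[2].size == 0

    def test_three_neuron_enumeration(self):
        # bin A has neurons 1,2; bin B has only neuron 3
        trains = {1: np.array([0.001]), 2: np.array([0.02]),
                  3: np.array([0.07])}
        out = filter_synchronous_spikes(trains)
        assert out[1].size == 1 and out[2].size == 1 and out[3].size == 0

    def test_single_neuron_empty(self):
        out = filter_synchronous_spikes({1: np.array([0.1, 0.2])})
        assert out[1].size == 0

    def test_subset_and_idempotent(self, rng):
        trains = {n: np.sort(rng.choice(np.arange(0, 1.0, 0.01), 12,
                                        replace=False)) for n in range(4)}
        once = filter_synchronous_spikes(trains)
        for n in trains:
            assert set(once[n]).issubset(set(trains[n]))
        twice = filter_synchronous_spikes(once)
        for n in trains:
            assert np.array_equal(once[n], twice[n])


class TestDecoding:
    def test_chance_total_closed_form(self):
        licks = [np.array([0.2, 0.4]), np.array([0.6])]
        spikes = [np.array([0.1]), np.array([0.1])]
        stl = spike_triggered_lick(spikes, licks, "decode")
        res = decoding_loglik({"m": spikes}, licks, stl, dt0=10.0)
        assert res.n_licks == 3
        assert res.total_loglik["chance"] == pytest.approx(3 * np.log(1 / 10.0))

    def test_coupled_model_ordering(self):
        data = simulate_coupled_licking(n_trials=200, seed=0)
        stl = spike_triggered_lick(data["all_session"], data["licks"],
                                   "decode")
        res = decoding_loglik(
            {"sync_topTC": data["sync_topTC"],
             "all_topTC": data["all_topTC"],
             "all_session": data["all_session"]}, data["licks"], stl)
        t = res.total_loglik
        assert t["sync_topTC"] > t["all_topTC"] > t["all_session"] > t["chance"]

    def test_flat_response_near_chance(self):
        # a model whose STL equals the chance rate everywhere scores chance
        rng = np.random.default_rng(2)
        licks = [np.array([rng.uniform(0.1, 0.9)]) for _ in range(100)]
        spikes = [np.array([rng.uniform(0.1, 0.9)]) for _ in range(100)]
        stl = spike_triggered_lick(spikes, licks, "decode")
        stl.response = np.full_like(stl.response, 1.0)   # rate == dt0/10
        res = decoding_loglik({"m": spikes}, licks, stl, dt0=10.0)
        assert res.total_loglik["m"] == pytest.approx(
            res.total_loglik["chance"], rel=1e-9)

    def test_additivity_over_disjoint_lick_sets(self):
        data = simulate_coupled_licking(n_trials=60, seed=1)
        stl = spike_triggered_lick(data["all_session"], data["licks"],
                                   "decode")
        models = {"sync_topTC": data["sync_topTC"]}
        full = decoding_loglik(models, data["licks"], stl)
        half1 = decoding_loglik({"sync_topTC": data["sync_topTC"][:30]},
                                data["licks"][:30], stl)
        half2 = decoding_loglik({"sync_topTC": data["sync_topTC"][30:]},
                                data["licks"][30:], stl)
        for m in ("sync_topTC", "chance"):
            assert full.total_loglik[m] == pytest.approx(
                half1.total_loglik[m] + half2.total_loglik[m])

    def test_no_inrange_spikes_falls_back_to_chance(self):
        licks = [np.array([0.5])]
        spikes = [np.array([])]
        ref = [np.array([0.2])]
        stl = spike_triggered_lick(ref, licks, "decode")
        res = decoding_loglik({"m": spikes}, licks, stl, dt0=10.0)
        assert res.total_loglik["m"] == pytest.approx(np.log(0.1))
        assert res.fallback_licks["m"] == 1
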