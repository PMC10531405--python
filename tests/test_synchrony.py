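import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfpop.datamodel import Trial
from cfpop.synchrony import (cross_correlogram, instantaneous_synchrony,
                             pairwise_strengths, synchrony_strength,
                             synchrony_window)


def _trial(cond="CR", licks=()):
    cue = "Go" if cond in ("HIT", "MISS") else "Nogo"
    return Trial(trial_id=0, session_id=0, cue=cue, condition=cond,
                 lick_times=list(licks))


class TestInstantaneous:
    def test_worked_example_seven_forty_fifths(self):
        """10 neurons, 20 spikes, bins with 4 and 2 co-active -> 7/45."""
        # bin 0: neurons 0-3 co-active; bin 1: neurons 4-5 co-active; the
        # remaining 14 spikes come from neuron 6 alone (two per bin over
        # bins 2-8), so no further bin holds two distinct active neurons
        trains = {n: np.array([0.005]) for n in range(4)}
        trains.update({n: np.array([0.035]) for n in (4, 5)})
        trains[6] = np.sort(np.concatenate(
            [[b * 0.03 + 0.005, b * 0.03 + 0.015] for b in range(2, 9)]))
        trains.update({n: np.array([]) for n in (7, 8, 9)})
        assert sum(len(v) for v in trains.values()) == 20
        isy = instantaneous_synchrony(trains, _trial("CR"))
        assert isy.value == pytest.approx(7 / 45)
        assert np.floor(isy.value * 100) / 100 == 0.15
        assert isy.spike_count_per_neuron == pytest.approx(2.0)

    def test_no_coactivation_zero(self):
        trains = {0: np.array([0.005]), 1: np.array([0.095])}
        assert instantaneous_synchrony(trains, _trial()).value == 0.0

    def test_all_coactive_is_one(self):
        trains = {n: np.array([0.01]) for n in range(5)}
        assert instantaneous_synchrony(trains, _trial()).value == 1.0

    def test_single_neuron_fatal(self):
        with pytest.raises(ValueError):
            instantaneous_synchrony({0: np.array([0.01])}, _trial())

    def test_window_rule_per_condition(self):
        hit = _trial("HIT", licks=[0.45])
        assert synchrony_window(hit) == (pytest.approx(0.15), 0.45)
        cr = _trial("CR")
        assert synchrony_window(cr) == (0.0, 0.3)

    def test_multiple_spikes_one_neuron_count_once(self):
        trains = {0: np.array([0.001, 0.004, 0.008]), 1: np.array([0.002]),
                  2: np.array([])}
        isy = instantaneous_synchrony(trains, _trial())
        assert isy.value == pytest.approx(1 / 3)  # one pair of C(3,2)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_relabeling_and_jitter(self, seed):
        rng = np.random.default_rng(seed)
        trains = {n: np.sort(rng.choice(np.arange(0, 0.30, 0.01), size=3,
                                        replace=False)) for n in range(4)}
        base = instantaneous_synchrony(trains, _trial()).value
        relabeled = {9 - n: t for n, t in trains.items()}
        assert instantaneous_synchrony(relabeled, _trial()).value == base
        jittered = {n: t + 0.004 * rng.random(t.size)
                    for n, t in trains.items()}
        assert instantaneous_synchrony(jittered, _trial()).value == base


class TestCCG:
    def test_identical_trains_unit_zero_lag(self):
        x = [np.array([0.0, 0.5, 1.0, 2.2])]
        ccg = cross_correlogram(x, x, support=(0, 3))
        i0 = len(ccg.lags) // 2
        assert ccg.values[i0] == pytest.approx(1.0)
        assert synchrony_strength(ccg) >= 1.0

    def test_symmetry_under_swap(self, rng):
        xs = [np.sort(rng.choice(np.arange(0, 6, 0.01), 8, replace=False))
              for _ in range(4)]
        ys = [np.sort(rng.choice(np.arange(0, 6, 0.01), 8, replace=False))
              for _ in range(4)]
        a = cross_correlogram(xs, ys, support=(0, 6))
        b = cross_correlogram(ys, xs, support=(0, 6))
        assert np.allclose(a.values, b.values[::-1])

    def test_empty_train_flagged_zero(self):
        ccg = cross_correlogram([np.array([])], [np.array([0.5])],
                                support=(0, 2))
        assert ccg.flagged and np.all(ccg.values == 0.0)
        assert synchrony_strength(ccg) == 0.0

    def test_independent_poisson_zero_lag_at_chance(self):
        rate, T, nb = 3.0, 6.0, 600
        num = 0.0
        nx_tot = ny_tot = 0
        rng = np.random.default_rng(9)
        for _ in range(200):
            x = np.arange(nb)[rng.random(nb) < rate * 0.01] * 0.01
            y = np.arange(nb)[rng.random(nb) < rate * 0.01] * 0.01
            ccg = cross_correlogram([x], [y], support=(0, T))
            i0 = len(ccg.lags) // 2
            num += ccg.values[i0] * np.sqrt(len(x) * len(y))
            nx_tot += len(x)
            ny_tot += len(y)
        # raw coincidence count vs analytic chance sum(X)sum(Y)/N per trial
        expect = 200 * (rate * 0.01 * T / 0.01) ** 2 / nb
        assert abs(num - expect) < 3 * np.sqrt(expect)

    def test_cue_locked_firing_matches_shift_predictor(self):
        # trial-independent but cue-locked: spike near 0.2 s every trial
        rng = np.random.default_rng(4)
        xs, ys = [], []
        for _ in range(150):
            xs.append(np.array([round(0.20 + 0.01 * rng.integers(0, 5), 2)]))
            ys.append(np.array([round(0.20 + 0.01 * rng.integers(0, 5), 2)]))
        ccg = cross_correlogram(xs, ys, support=(0, 1), shift=True)
        diff = ccg.values - ccg.shift_predictor
        se = np.sqrt(np.maximum(ccg.values, 1e-3) / 150)
        assert np.all(np.abs(diff) <= 3 * np.maximum(se, 0.05))

    def test_strength_is_three_center_bins(self):
        lags = np.arange(-10, 11) * 0.01
        from cfpop.synchrony import CCG
        vals = np.zeros(21)
        vals[9:12] = (0.1, 0.5, 0.2)
        ccg = CCG(lags=lags, values=vals, shift_predictor=None, n_bins=100)
        assert synchrony_strength(ccg) == pytest.approx(0.8)

    def test_strength_bounded_by_three(self, rng):
        xs = [np.sort(rng.choice(np.arange(0, 4, 0.01), 20, replace=False))
              for _ in range(3)]
        ccg = cross_correlogram(xs, xs, support=(0, 4))
        assert 0.0 <= synchrony_strength(ccg) <= 3.0

    def test_pairwise_strengths_rows(self, rng):
        trains = {1: [np.array([0.1, 0.5])], 2: [np.array([0.1])],
                  3: [np.array([0.9])]}
        rows = pairwise_strengths(trains)
        assert [(r[0], r[1]) for r in rows] == [(1, 2), (1, 3), (2, 3)]
        by_pair = {(r[0], r[1]): r[2] for r in rows}
        assert by_pair[(1, 2)] > by_pair[(2, 3)]
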