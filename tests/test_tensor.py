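import numpy as np
import pytest

from cfpop.datamodel import (Dataset, Neuron, Session, SpikeTrain, Trial)
from cfpop.tensor import (PSTHTensor, assign_populations, build_psth_tensor,
                          compute_vaf, fit_tca, matched_congruence,
                          response_strength, shuffle_dataset, shuffle_null,
                          tc_distance)


def _flat_session(rate, n_trials=12, n_neurons=2, condition="HIT", seed=0):
    """One session of homogeneous-Poisson neurons, all trials one condition."""
    rng = np.random.default_rng(seed)
    cue = "Go" if condition in ("HIT", "MISS") else "Nogo"
    licks = [0.4] if condition in ("HIT", "FA") else []
    sess = Session(session_id=0, mouse_id=0, fraction_correct=1.0)
    sess.neurons = [Neuron(i, 0, "5+", 10.0 * i, 0.0) for i in range(n_neurons)]
    grid = -2.0 + np.arange(800) * 0.01
    for t in range(n_trials):
        sess.trials.append(Trial(trial_id=t, session_id=0, cue=cue,
                                 condition=condition, lick_times=list(licks)))
        for n in range(n_neurons):
            mask = rng.random(800) < rate * 0.01
            times = grid[mask]
            if times.size:
                sess.spike_trains.append(SpikeTrain(n, t, times))
    return Dataset(sessions=[sess])


class TestPSTH:
    def test_homogeneous_poisson_near_zero_after_baseline(self):
        ds = _flat_session(rate=4.0, n_trials=40, seed=1)
        tens = build_psth_tensor(ds)
        k = 0  # HIT slice
        se = np.sqrt(4.0 / (0.05 * 40) / (tens.values.shape[1] * 2))
        assert abs(float(tens.values[:, :, k].mean())) < 3 * se
        assert tens.baseline_rates == pytest.approx([4.0, 4.0], abs=1.5)

    def test_fewer_than_five_trials_zeroes_slice(self):
        ds = _flat_session(rate=3.0, n_trials=4, condition="FA", seed=2)
        tens = build_psth_tensor(ds)
        assert np.all(tens.values[:, :, 1] == 0.0)

    def test_planted_boxcar_recovered(self):
        # 2 Hz above a 1 Hz baseline in [0, 0.5) s
        rng = np.random.default_rng(3)
        sess = Session(session_id=0, mouse_id=0, fraction_correct=1.0)
        sess.neurons = [Neuron(0, 0, "6+", 0.0, 0.0)]
        grid = -2.0 + np.arange(800) * 0.01
        rate = np.where((grid >= 0) & (grid < 0.5), 3.0, 1.0)
        for t in range(200):
            sess.trials.append(Trial(t, 0, "Go", "HIT", lick_times=[0.4]))
            times = grid[rng.random(800) < rate * 0.01]
            sess.spike_trains.append(SpikeTrain(0, t, times))
        tens = build_psth_tensor(Dataset(sessions=[sess]))
        window_mean = tens.values[0, 10:20, 0].mean()
        assert window_mean == pytest.approx(2.0, abs=0.35)
        assert response_strength(tens.values[0, :, 0]) == pytest.approx(
            2.0, abs=0.55)

    def test_response_strength_window_bins(self):
        row = np.zeros(50)
        row[10:14] = 2.0
        assert response_strength(row) == pytest.approx(2.0)
        assert response_strength(np.zeros(50)) == 0.0


class TestTCA:
    def test_rank1_exact_recovery(self, rng):
        w = np.abs(rng.standard_normal(30))
        b = np.abs(rng.standard_normal(50))
        a = np.abs(rng.standard_normal(4))
        x = np.einsum("n,t,k->ntk", w, b, a)
        m = fit_tca(x, 1, n_init=5, seed=0)
        cong = matched_congruence(m, [w[:, None], b[:, None], a[:, None]])
        assert cong > 0.999
        assert m.objective < 1e-8 * (x ** 2).sum()

    def test_all_zero_tensor_degenerate(self):
        m = fit_tca(np.zeros((6, 50, 4)), 2, n_init=2, seed=0)
        assert m.degenerate
        assert np.all(m.scales == 0.0)

    def test_rank_exceeding_dims_fatal(self):
        with pytest.raises(ValueError):
            fit_tca(np.ones((5, 6, 4)), 5, n_init=1, seed=0)

    def test_reconstruction_invariances(self, rng):
        w = np.abs(rng.standard_normal((20, 3)))
        b = np.abs(rng.standard_normal((50, 3)))
        a = np.abs(rng.standard_normal((4, 3)))
        x = np.einsum("nr,tr,kr->ntk", w, b, a)
        m = fit_tca(x, 3, n_init=8, seed=1)
        # canonical model: unit columns, descending scales
        for f in m.factors:
            assert np.allclose(np.linalg.norm(f, axis=0), 1.0, atol=1e-6)
        assert np.all(np.diff(m.scales) <= 1e-9)
        assert np.allclose(m.reconstruct(), x, atol=1e-3 * x.max())

    def test_planted_rank4_recovery(self, recovery_dataset):
        ds, truth = recovery_dataset
        tens = build_psth_tensor(ds)
        m = fit_tca(tens, 4, n_init=20, seed=0)
        cong = matched_congruence(m, [truth.neuron_factors,
                                      truth.temporal_factors,
                                      truth.condition_factors])
        assert cong > 0.9

    def test_determinism(self, rng):
        x = np.abs(rng.standard_normal((10, 20, 4)))
        a = fit_tca(x, 2, n_init=4, seed=7)
        b = fit_tca(x, 2, n_init=4, seed=7)
        assert np.array_equal(a.scales, b.scales)
        for fa, fb in zip(a.factors, b.factors):
            assert np.array_equal(fa, fb)


class TestVAF:
    def test_perfect_reconstruction_vaf_one(self, rng):
        w = np.abs(rng.standard_normal((10, 2)))
        b = np.abs(rng.standard_normal((50, 2)))
        a = np.abs(rng.standard_normal((4, 2)))
        x = np.einsum("nr,tr,kr->ntk", w, b, a)
        m = fit_tca(x, 2, n_init=6, seed=0)
        assert compute_vaf(x, m).vaf == pytest.approx(1.0, abs=1e-6)

    def test_zero_model_on_zero_mean_data_vaf_zero(self, rng):
        x = rng.standard_normal((8, 50, 4))
        x -= x.mean()
        m = fit_tca(np.zeros((8, 50, 4)) + 1e-12, 1, n_init=1, seed=0)
        m.scales = np.zeros(1)
        fq = compute_vaf(x, m)
        # x̂=0 and zero-mean x: VAF = 1 - var(x)/var(x) ~ 0 (filtering shifts
        # the pooled mean slightly)
        assert abs(fq.vaf) < 0.05

    def test_zero_variance_flagged(self):
        m = fit_tca(np.zeros((5, 50, 4)), 1, n_init=1, seed=0)
        fq = compute_vaf(np.zeros((5, 50, 4)), m)
        assert fq.flagged

    def test_vaf_monotone_in_rank(self, recovery_dataset):
        ds, _ = recovery_dataset
        tens = build_psth_tensor(ds)
        sub = PSTHTensor(values=tens.values[:80], neuron_ids=tens.neuron_ids[:80],
                         baseline_rates=tens.baseline_rates[:80],
                         trial_counts=tens.trial_counts, stages=tens.stages[:80])
        vafs = [compute_vaf(sub, fit_tca(sub, R, n_init=8, seed=3)).vaf
                for R in (1, 2, 4)]
        assert vafs[0] <= vafs[1] + 1e-6 and vafs[1] <= vafs[2] + 1e-6


class TestShuffleNull:
    def test_structured_beats_shuffled_vaf(self, tiny_dataset):
        ds, _ = tiny_dataset
        tens = build_psth_tensor(ds)
        v = compute_vaf(tens, fit_tca(tens, 4, n_init=8, seed=0)).vaf
        curves = shuffle_null(ds, n_perm=5, r_values=[4], seed=0, n_init=4)
        assert v > np.max(curves)

    def test_shuffle_deterministic(self, tiny_dataset):
        ds, _ = tiny_dataset
        a = shuffle_null(ds, n_perm=2, r_values=[2], seed=5, n_init=2)
        b = shuffle_null(ds, n_perm=2, r_values=[2], seed=5, n_init=2)
        assert np.array_equal(a, b)

    def test_shuffle_preserves_event_counts(self, tiny_dataset):
        ds, _ = tiny_dataset
        sh = shuffle_dataset(ds, seed=3)
        n_before = sum(st.spike_times.size for s in ds.sessions
                       for st in s.spike_trains)
        n_after = sum(st.spike_times.size for s in sh.sessions
                      for st in s.spike_trains)
        # a uniform resample of (neuron, trial) sources keeps the total
        # spike count at the same scale (not exactly equal)
        assert abs(n_after - n_before) < 0.2 * n_before


class TestDistanceAndPopulations:
    def test_tc_distance_cases(self):
        assert tc_distance([1, 0, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.0)
        assert tc_distance([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(1.0)
        assert tc_distance([1, 0, 0, 0], [1, 1, 0, 0]) == pytest.approx(
            1 - 1 / np.sqrt(2))
        assert np.isnan(tc_distance([0, 0], [1, 0]))

    def test_argmax_labels_and_null(self, rng):
        W = np.array([[0.9, 0.1], [0.0, 0.0], [0.2, 0.7]])
        m = fit_tca(np.abs(rng.standard_normal((3, 10, 4))), 2, n_init=2, seed=0)
        m.neuron_factors = W
        m.rank = 2
        out = assign_populations(m, np.array([10, 11, 12]),
                                 np.array([1, 1, 1]), top_n=1)
        assert list(out.labels) == [0, -1, 1]

    def test_overlap_exclusion_brute_force_fixture(self, rng):
        # 3 neurons, 2 components, top_n=2; neuron 0 top-ranked in both
        W = np.array([[0.9, 0.8], [0.5, 0.1], [0.1, 0.5]])
        m = fit_tca(np.abs(rng.standard_normal((3, 10, 4))), 2, n_init=2, seed=0)
        m.neuron_factors = W
        m.rank = 2
        out = assign_populations(m, np.array([0, 1, 2]), np.array([1, 1, 1]),
                                 top_n=2)
        # brute force of the rule: top2 of comp1 = {0,1}, comp2 = {0,2};
        # neuron 0 overlaps and is excluded from both
        assert out.top_sets[0] == {1}
        assert out.top_sets[1] == {2}
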