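"""Fold assignment, logistic/Bayesian/RBF/CSP baselines, subsampling."""

import numpy as np
import pytest

from timbre import decoders as dec
from timbre import simulate as sim


class TestAssignFolds:
    def test_balanced_trials_retain_everything(self):
        arms = np.tile([0, 1, 2], 10)
        plan = dec.assign_folds(arms, n_folds=5, seed=0)
        # 30 trials over 5 folds: worst-case training availability per arm
        sizes = np.ones(30, int)
        counts = min(
            sizes[(np.array([plan.fold_of_trial[t] for t in range(30)]) != f)
                  & (arms == a)].sum()
            for f in range(5) for a in range(3))
        assert plan.quota == counts

    def test_objective_matches_exhaustive_count(self, rng):
        arms = np.r_[np.zeros(12, int), np.ones(6, int), np.full(12, 2)]
        sizes = rng.integers(5, 50, len(arms))
        plan = dec.assign_folds(arms, sizes, n_folds=3, n_candidates=20, seed=1)
        folds = np.array([plan.fold_of_trial[t] for t in range(len(arms))])
        brute = min(sizes[(folds != f) & (arms == a)].sum()
                    for f in range(3) for a in range(3))
        assert plan.quota == brute

    def test_identical_seed_identical_plan(self):
        arms = np.tile([0, 1, 2], 8)
        p1 = dec.assign_folds(arms, seed=5)
        p2 = dec.assign_folds(arms, seed=5)
        assert p1.fold_of_trial == p2.fold_of_trial

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            dec.assign_folds(np.array([0, 0, 1, 1, 2, 2]), n_folds=5)

    def test_training_label_histogram_uniform(self, rng):
        arms = np.tile([0, 1, 2], 10)
        plan = dec.assign_folds(arms, seed=0)
        sample_trials = np.repeat(np.arange(30), 4)
        sample_arms = arms[sample_trials]
        for fold in range(5):
            mask = dec.balanced_training_mask(fold, plan, sample_trials,
                                              sample_arms, rng)
            counts = np.bincount(sample_arms[mask], minlength=3)
            assert counts.min() == counts.max() == plan.quota * 4 // 4 \
                or counts.min() == counts.max()


class TestLogisticArmDecoder:
    @staticmethod
    def _toy(rng, informative=True, n_trials=30, per_trial=10):
        arms = np.tile([0, 1, 2], n_trials // 3)
        trials = np.repeat(np.arange(n_trials), per_trial)
        labels = arms[trials]
        x = rng.standard_normal((len(labels), 6))
        if informative:
            x[np.arange(len(labels)), labels] += 10.0
        return x, labels, trials, arms

    def test_separable_features_decode_perfectly(self, rng):
        x, labels, trials, arms = self._toy(rng)
        plan = dec.assign_folds(arms, seed=0)
        table = dec.logistic_arm_decoder(x, labels, np.arange(3), trials, plan)
        assert table["accuracy"].min() == 1.0

    def test_uninformative_features_decode_at_chance(self, rng):
        x, labels, trials, arms = self._toy(rng, informative=False)
        plan = dec.assign_folds(arms, seed=0)
        table = dec.logistic_arm_decoder(x, labels, np.arange(3), trials, plan)
        assert abs(table["accuracy"].mean() - 1 / 3) < 0.15


class TestSpikeRateFeatures:
    def test_single_spike_filter_preserves_mass(self):
        feats_raw, _ = dec.spike_rate_features([np.array([10.0]),
                                                np.array([10.0, 10.5])], 20.0)
        # check on the unnormalized path: sum of low-passed counts = n spikes
        import scipy.signal as sps
        counts, _ = np.histogram(np.array([10.0]), bins=np.arange(501) / 25.0)
        sos = sps.butter(8, 3.0, btype="lowpass", fs=25.0, output="sos")
        assert sps.sosfiltfilt(sos, counts.astype(float)).sum() == \
            pytest.approx(1.0, abs=1e-6)

    def test_constant_rate_normalizes_to_unit_variance(self, rng):
        spikes = [np.sort(rng.uniform(0, 200, 2000))]
        feats, kept = dec.spike_rate_features(spikes, 200.0)
        assert kept.tolist() == [0]
        assert feats[:, 0].std() == pytest.approx(1.0, abs=1e-6)

    def test_silent_neuron_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="silent"):
            feats, kept = dec.spike_rate_features(
                [np.array([5.0, 6.0, 7.0]), np.array([])], 20.0)
        assert kept.tolist() == [0]


class TestRBF1D:
    def test_center_is_max_and_rows_sum_to_one(self, rng):
        x = rng.uniform(0, 1, 50)
        arm = rng.integers(0, 3, 50)
        out = dec.rbf_encode_1d(x, arm)
        assert np.allclose(out.sum(axis=1), 1.0)
        basis = dec.RBF1D()
        at_centers = dec.rbf_encode_1d(basis.centers, np.zeros(10, int))
        assert np.array_equal(np.argmax(at_centers, axis=1), np.arange(10))

    def test_matches_direct_formula(self):
        sigma = 1.0 / 9.0
        centers = np.linspace(0, 1, 10)
        raw = np.exp(-(0.5 - centers) ** 2 / (2 * sigma ** 2))
        expected = raw / raw.sum()
        out = dec.rbf_encode_1d(np.array([0.5]), np.array([1]))
        assert np.allclose(out[0, 10:20], expected, atol=1e-12)
        assert np.all(out[0, :10] == 0) and np.all(out[0, 20:] == 0)


class TestBayesianDecoder:
    def test_zero_counts_select_minimum_rate_position(self, rng):
        curves = rng.uniform(0.5, 2.0, (25, 10))
        est = dec.bayesian_decode(np.zeros((3, 10)), curves)
        assert np.all(est == np.argmin(curves.sum(axis=1)))

    def test_single_neuron_single_spike_maps_to_its_peak(self):
        curves = np.full((25, 1), 1e-3)
        curves[17, 0] = 2.0
        counts = np.zeros((1, 1))
        counts[0, 0] = 1
        assert dec.bayesian_decode(counts, curves)[0] == 17

    def test_matches_brute_force_likelihood(self, rng):
        curves = rng.uniform(0.1, 3.0, (25, 8))
        counts = rng.poisson(1.0, (40, 8)).astype(float)
        est = dec.bayesian_decode(counts, curves)
        from scipy.stats import poisson
        ll = np.array([[poisson.logpmf(counts[t], curves[b]).sum()
                        for b in range(25)] for t in range(40)])
        assert np.array_equal(est, np.argmax(ll, axis=1))

    def test_poisson_population_parameter_recovery(self, rng):
        """25 bins, 100 cells, rate scale 5: median error within one bin."""
        pop = sim.SimPopulation(100)
        bins = (np.arange(25) + 0.5) / 25
        rates = 5.0 * np.abs(sim.population_response(bins, np.zeros(25), pop))
        true_bins = rng.integers(0, 25, 500)
        counts = rng.poisson(rates[true_bins])
        curves = dec.fit_tuning_curves(
            rng.poisson(rates[true_bins]), true_bins, 25)
        est = dec.bayesian_decode(counts.astype(float), curves)
        assert np.median(np.abs(est - true_bins)) <= 1.0


class TestLinearRBFDecode:
    def test_realizable_targets_recovered(self, rng):
        targets = dec.rbf_encode_1d(rng.uniform(0, 1, 400),
                                    rng.integers(0, 3, 400))
        mixing = rng.standard_normal((30, 40))
        features = targets @ mixing
        est = dec.linear_rbf_decode(features, targets, features, alpha=1e-8)
        assert np.mean(est == np.argmax(targets, axis=1)) >= 0.99

    def test_zero_features_predict_most_visited_bin(self, rng):
        targets = np.zeros((200, 30))
        targets[np.arange(200), rng.integers(0, 5, 200)] = 1.0
        targets[:150, 2] = 1.0        # bin 2 dominates
        targets /= targets.sum(axis=1, keepdims=True)
        est = dec.linear_rbf_decode(np.zeros((200, 4)), targets,
                                    np.zeros((10, 4)))
        assert np.all(est == np.argmax(targets.mean(axis=0)))


class TestCSP:
    def test_variance_concentrated_filter_alignment(self, rng):
        n = 6
        z0 = rng.standard_normal((2000, n)) + 1j * rng.standard_normal((2000, n))
        z1 = z0.copy()
        z1[:, 0] *= 5.0
        z = np.vstack([z1, z0])
        labels = np.r_[np.zeros(2000, int), np.ones(2000, int)]
        filters, _, _ = dec.csp_multiclass(z, labels, n_per_class=1)
        f0 = filters[:, 0] / np.linalg.norm(filters[:, 0])
        assert abs(f0[0]) >= 0.99

    def test_identical_classes_give_unit_eigenvalues(self, rng):
        z = rng.standard_normal((4000, 5)) + 1j * rng.standard_normal((4000, 5))
        labels = rng.integers(0, 3, 4000)
        _, _, eigvals = dec.csp_multiclass(z, labels, n_per_class=1)
        assert np.all(np.abs(eigvals - 1.0) < 0.2)
        assert np.all(eigvals.imag == 0) and np.all(eigvals >= 0)

    def test_invariant_to_joint_channel_rescaling(self, rng):
        z = rng.standard_normal((1000, 4)) + 1j * rng.standard_normal((1000, 4))
        z[:500, 1] *= 3.0
        labels = np.r_[np.zeros(500, int), np.ones(500, int)]
        f1, _, e1 = dec.csp_multiclass(z, labels)
        f2, _, e2 = dec.csp_multiclass(10.0 * z, labels)
        assert np.allclose(e1, e2, atol=1e-9)
        for k in range(f1.shape[1]):
            c = abs(np.vdot(f1[:, k], f2[:, k])) / (
                np.linalg.norm(f1[:, k]) * np.linalg.norm(f2[:, k]))
            assert c == pytest.approx(1.0, abs=1e-6)


class TestSubsampleUnits:
    def test_full_set_matches_unsubsampled(self, rng):
        acc_of = lambda idx: 0.5 + 0.4 * len(idx) / 8
        table = dec.subsample_units(acc_of, 8, (2, 8), n_reps=3, seed=0)
        assert table.loc[table["n_units"] == 8, "mean_accuracy"].item() == \
            pytest.approx(0.9)

    def test_accuracy_grows_with_informative_units(self, rng):
        from scipy.stats import spearmanr
        truth = rng.integers(0, 3, 400)
        feats = np.tile(truth[:, None], (1, 16)) + rng.normal(0, 2.0, (400, 16))

        def acc_of(idx):
            est = np.clip(np.round(feats[:, idx].mean(axis=1)), 0, 2)
            return np.mean(est == truth)

        table = dec.subsample_units(acc_of, 16, (1, 2, 4, 8, 16), seed=0)
        rho = spearmanr(table["n_units"], table["mean_accuracy"]).statistic
        assert rho > 0

    def test_identical_seed_identical_table(self, rng):
        feats = rng.standard_normal((100, 8))
        acc_of = lambda idx: float(feats[:, idx].mean())
        t1 = dec.subsample_units(acc_of, 8, (2, 4), seed=3)
        t2 = dec.subsample_units(acc_of, 8, (2, 4), seed=3)
        assert t1.equals(t2)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            dec.subsample_units(lambda idx: 0.0, 4, (8,))


class TestSharedNoiseFoldedComparison:
    def test_network_beats_carrier_based_logistic_on_same_folds(self):
        """Shared phase noise, 5 shared folds: the logistic decoder on the
        pacemaker-demodulated LFP trails the carrier-free network on every
        fold (the network is invariant to the common phase factor)."""
        from timbre import network, preprocess, sessions
        from timbre.simulate import NoiseSpec
        cfg = sessions.MazeConfig(n_trials=20, n_electrodes=32, n_cells=150,
                                  noise=NoiseSpec("shared", 1.0, 8.0))
        sess = sessions.generate_session("maze", cfg, seed=2)
        beh = sess.behavior
        arms = beh["arm"].to_numpy()
        trials = beh["trial"].to_numpy()
        t = beh["t"].to_numpy()
        uniq = np.unique(trials)
        trial_arms = np.array([beh[beh.trial == u]["arm"].iloc[0]
                               for u in uniq])
        trial_sizes = np.array([(trials == u).sum() for u in uniq])
        plan = dec.assign_folds(trial_arms, trial_sizes, n_folds=5, seed=0)
        pacemaker = np.exp(2j * np.pi * 8 * t)
        xd = preprocess.split_complex(preprocess.demodulate(sess.z, pacemaker))
        cb = dec.carrier_based_decoder(xd, arms, np.arange(3), trials,
                                       plan)["accuracy"].to_numpy()
        xw = preprocess.whiten(sess.z).v
        folds = np.array([plan.fold_of_trial[u] for u in trials])
        rng = np.random.default_rng(0)
        cf = []
        for f in range(5):
            tr = dec.balanced_training_mask(f, plan, trials, arms, rng)
            idx = np.flatnonzero(tr)
            val = idx[::5]
            tr2 = np.setdiff1d(idx, val)
            m = network.ComplexSoftmaxNet(xw.shape[1], 3, n_classes=3, seed=f)
            m, _ = network.train(m, xw[tr2], arms[tr2], xw[val], arms[val],
                                 network.TrainConfig(seed=f))
            _, _, a = network.predict_arm(m, xw[folds == f], np.arange(3),
                                          arms[folds == f])
            cf.append(a)
        assert np.all(np.asarray(cf) > cb)


class TestSharedNoiseSessionComparison:
    def test_carrier_free_beats_carrier_based_on_shared_noise(self, rng):
        """On a shared-noise session the amplitude (carrier-free) readout of
        the demixed components outperforms the carrier-based readout."""
        pop = sim.SimPopulation(200)
        A = sim.make_mixing(32, 200, rng=rng)
        decod = sim.fit_template_decoder(pop, A)
        pos = rng.uniform(0, 1, 2000)
        ph = rng.uniform(0, 2 * np.pi, 2000)
        eps = np.broadcast_to(rng.normal(0, 1, (2000, 1)), (2000, 200))
        lfp = sim.mix_lfp(sim.population_response(pos, ph, pop, eps), A)
        tb = sim.position_bin(pos)
        acc_cf = np.mean(sim.decode_simulated(decod, lfp, ph, "carrier_free") == tb)
        acc_cb = np.mean(sim.decode_simulated(decod, lfp, ph, "carrier_based") == tb)
        assert acc_cf > acc_cb
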