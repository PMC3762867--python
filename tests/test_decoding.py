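"""Feature assembly determinism, train-only transforms (leak guard),
pairwise LDA behavior on constructed data, and dual-scored illusion
decoding."""
from __future__ import annotations

import numpy as np
import pytest

from mcgurk_ecog import (
    EpochArray,
    SimConfig,
    TrialRecord,
    build_features,
    decode_stimulus_identity,
    fit_predict_pairwise,
    mcgurk_dual_decoding,
    simulate_dataset,
)
from mcgurk_ecog.experiment import categorize_trials
from mcgurk_ecog.workflows import preprocess_epochs


def toy_epochs(rng, n_trials=6, n_el=3, fs=1000.0):
    trials = [TrialRecord(i, "BA", "BA", "BA") for i in range(n_trials)]
    epochs = [
        EpochArray(data=rng.standard_normal((3500, n_el)), fs=fs, t0=-2.0)
        for _ in range(n_trials)
    ]
    return trials, epochs


class TestBuildFeatures:
    def test_feature_count_matches_catalog(self, rng):
        trials, epochs = toy_epochs(rng)
        fm = build_features(epochs, trials, [0, 2])
        n_volt = 1500  # [-1.0, 0.5) at 1 kHz
        spec_rows = (fm.catalog.kind == "spectrogram").sum()
        assert fm.n_features == len(fm.catalog)
        assert (fm.catalog.kind == "voltage").sum() == 2 * n_volt
        assert fm.n_features == 2 * n_volt + spec_rows
        # spectrogram cells factor as T x F per electrode
        sub = fm.catalog[(fm.catalog.kind == "spectrogram") & (fm.catalog.electrode == 0)]
        n_t = sub.time.nunique()
        n_f = sub.frequency.nunique()
        assert len(sub) == n_t * n_f

    def test_identical_epochs_identical_rows(self, rng):
        trials, epochs = toy_epochs(rng, n_trials=2)
        epochs[1] = EpochArray(
            data=epochs[0].data.copy(), fs=epochs[0].fs, t0=epochs[0].t0
        )
        fm = build_features(epochs, trials, [0])
        np.testing.assert_array_equal(fm.X[0], fm.X[1])

    def test_trial_permutation_permutes_rows(self, rng):
        trials, epochs = toy_epochs(rng)
        fm = build_features(epochs, trials, [0, 1])
        perm = rng.permutation(len(trials))
        fm_p = build_features(
            [epochs[i] for i in perm], [trials[i] for i in perm], [0, 1]
        )
        np.testing.assert_array_equal(fm_p.X, fm.X[perm])
        np.testing.assert_array_equal(fm_p.trial_ids, fm.trial_ids[perm])

    def test_missing_epoch_reported_by_trial_id(self, rng):
        trials, epochs = toy_epochs(rng, n_trials=3)
        lookup = {t.trial_id: e for t, e in zip(trials, epochs)}
        del lookup[1]
        with pytest.raises(KeyError, match=r"\[1\]"):
            build_features(lookup, trials, [0])


def gaussian_problem(rng, n=40, d=30, sep=10.0):
    """Two spherical Gaussians whose centroids are ``sep`` noise-SDs
    apart, with the separation spread over all dimensions (so per-column
    z-scoring cannot collapse it)."""
    X = rng.standard_normal((n, d))
    y = np.array(["A", "B"] * (n // 2))
    X[y == "B"] += sep / np.sqrt(d)
    return X, y


class TestPairwiseClassifier:
    def test_separable_classes_perfect(self, rng):
        X, y = gaussian_problem(rng, sep=10.0)
        cm = fit_predict_pairwise(X, y, ("A", "B"), seed=0)
        assert cm.accuracy == 1.0
        assert cm.counts.sum() == 40

    def test_row_sums_equal_class_counts(self, rng):
        X, y = gaussian_problem(rng, sep=1.0)
        cm = fit_predict_pairwise(X, y, ("A", "B"), seed=0)
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [20, 20])

    def test_identical_distributions_near_chance(self, rng):
        accs = [
            fit_predict_pairwise(
                *gaussian_problem(rng, n=60, sep=0.0), ("A", "B"), seed=s
            ).accuracy
            for s in range(10)
        ]
        # 3-sigma binomial band around 0.5 at 600 pooled test trials
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / 600)

    def test_label_permutation_near_chance(self, rng):
        X, y = gaussian_problem(rng, n=60, sep=10.0)
        accs = []
        for s in range(20):
            yp = y[rng.permutation(y.size)]
            accs.append(fit_predict_pairwise(X, yp, ("A", "B"), seed=s).accuracy)
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / (60 * 20))

    def test_transform_is_train_only(self, rng):
        """The recorded z-scoring mean must match the training rows
        alone; using pooled statistics would be an information leak."""
        X, y = gaussian_problem(rng, n=20, sep=3.0)
        cm = fit_predict_pairwise(X, y, ("A", "B"), seed=5)
        pooled_mean = X[:, 0].mean()
        for fold in cm.folds["per_fold"]:
            train_rows = np.array(fold["train_rows"])
            train_mean = X[train_rows, 0].mean()
            assert fold["train_mean_col0"] == pytest.approx(train_mean)
            assert fold["train_mean_col0"] != pytest.approx(pooled_mean, abs=1e-12)
        # the two folds are disjoint and cover all trials
        r0 = set(cm.folds["per_fold"][0]["train_rows"])
        r1 = set(cm.folds["per_fold"][1]["train_rows"])
        assert r0.isdisjoint(r1)
        assert len(r0 | r1) == 20

    def test_zero_variance_columns_dropped_and_logged(self, rng):
        X, y = gaussian_problem(rng)
        X[:, 3] = 7.0
        cm = fit_predict_pairwise(X, y, ("A", "B"), seed=0)
        assert all(f["n_dropped_columns"] == 1 for f in cm.folds["per_fold"])

    def test_variance_kept_controls_components(self, rng):
        X, y = gaussian_problem(rng, n=30, d=40, sep=2.0)
        cm_small = fit_predict_pairwise(X, y, ("A", "B"), variance_kept=0.5, seed=0)
        cm_large = fit_predict_pairwise(X, y, ("A", "B"), variance_kept=0.99, seed=0)
        k_small = cm_small.folds["per_fold"][0]["n_components"]
        k_large = cm_large.folds["per_fold"][0]["n_components"]
        assert k_small < k_large

    def test_too_few_trials_rejected(self, rng):
        X = rng.standard_normal((3, 5))
        y = np.array(["A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_predict_pairwise(X, y, ("A", "B"))


@pytest.fixture(scope="module")
def mcgurk_session():
    cfg = SimConfig(seed=5)
    trials, epochs = simulate_dataset(cfg)
    epochs = preprocess_epochs(epochs)
    trials = categorize_trials(trials)
    fm = build_features(epochs, trials, list(cfg.coding_electrodes))
    return cfg, trials, fm


class TestStimulusDecoding:
    def test_video_code_recovered_on_mcgurk_trials(self, mcgurk_session):
        cfg, trials, fm = mcgurk_session
        res_v = decode_stimulus_identity(fm, trials, "video", category="mcgurk", seed=1)
        res_a = decode_stimulus_identity(fm, trials, "audio", category="mcgurk", seed=1)
        assert res_v.mean_accuracy > 0.8
        assert res_v.mean_accuracy > res_a.mean_accuracy
        assert res_v.n_pairs >= 5

    def test_dual_decoder_complementary_and_directional(self, mcgurk_session):
        cfg, trials, fm = mcgurk_session
        dual = mcgurk_dual_decoding(fm, trials, seed=2)
        for pair, acc_v in dual["video"].accuracies.items():
            assert dual["audio"].accuracies[pair] == pytest.approx(1.0 - acc_v)
        assert dual["video"].mean_accuracy > 0.5
        assert dual["audio"].mean_accuracy <= 0.5

    def test_category_filter_restricts_trials(self, mcgurk_session):
        _, trials, fm = mcgurk_session
        res = decode_stimulus_identity(fm, trials, "video", category="mcgurk", seed=0)
        n_mcgurk = sum(t.category == "mcgurk" for t in trials)
        some_cm = next(iter(res.confusions.values()))
        assert some_cm.n_trials <= n_mcgurk

    def test_zero_snr_decodes_at_chance(self):
        """Without a planted burst (snr=0) no stimulus attribute is
        decodable: mean pairwise accuracy sits in the chance band."""
        cfg = SimConfig(seed=17, snr=0.0, coupling_gain=0.0)
        trials, epochs = simulate_dataset(cfg)
        epochs = preprocess_epochs(epochs)
        fm = build_features(epochs, trials, list(cfg.coding_electrodes))
        res = decode_stimulus_identity(fm, trials, "video", seed=17)
        n_tests = sum(cm.n_trials for cm in res.confusions.values())
        assert abs(res.mean_accuracy - 0.5) < 3 * np.sqrt(0.25 / n_tests)

    def test_sparse_pair_skipped_with_warning(self, rng):
        trials = [TrialRecord(i, "BA", "BA", "BA", category="matched") for i in range(8)]
        trials += [TrialRecord(8, "GA", "GA", "GA", category="matched")]
        X = rng.standard_normal((9, 10))
        from mcgurk_ecog.decoding import FeatureMatrix
        import pandas as pd

        fm = FeatureMatrix(
            X=X, trial_ids=np.arange(9),
            catalog=pd.DataFrame({"electrode": 0, "kind": "voltage",
                                  "time": np.arange(10), "frequency": np.nan}),
        )
        with pytest.warns(UserWarning, match="skipped"):
            res = decode_stimulus_identity(fm, trials, "video", seed=0)
        assert res.accuracies == {}
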