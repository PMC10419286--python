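"""Aggregation, PCA-classifier models, cross-validation, metrics, voting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score, cohen_kappa_score

from ramanct import (AggregationSpec, PCAClassifier, aggregate_spectra,
                     balanced_accuracy, batchwise_cv, cohens_kappa,
                     confusion_matrix, fit_model, kfold_cv, majority_vote,
                     predict, uniform_axis, vector_normalize)
from ramanct.chemometrics import sensitivity_specificity, spectrum_hashes

from conftest import make_dataset


def _expand(cm):
    """Confusion matrix -> (y_true, y_pred) label vectors (oracle route)."""
    y_true, y_pred = [], []
    labels = ["sham", "sick"]
    for i, t in enumerate(labels):
        for j, p in enumerate(labels):
            y_true += [t] * int(np.asarray(cm)[i, j])
            y_pred += [p] * int(np.asarray(cm)[i, j])
    return y_true, y_pred


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class TestMetrics:
    @pytest.mark.parametrize("cm,expected", [
        ([[9, 1], [2, 3]], 0.75),   # (0.9 + 0.6) / 2
        ([[5, 0], [0, 7]], 1.0),
        ([[10, 0], [10, 0]], 0.5),  # everything predicted sham
    ])
    def test_balanced_accuracy_examples(self, cm, expected):
        assert balanced_accuracy(cm) == pytest.approx(expected)

    @pytest.mark.parametrize("cm,expected", [
        ([[40, 10], [10, 40]], 0.6),
        ([[5, 0], [0, 7]], 1.0),
        ([[25, 25], [25, 25]], 0.0),
    ])
    def test_cohens_kappa_examples(self, cm, expected):
        assert cohens_kappa(cm) == pytest.approx(expected)

    def test_empty_true_class_rejected(self):
        with pytest.raises(ValueError, match="true class"):
            balanced_accuracy([[0, 0], [3, 4]])

    def test_metrics_match_sklearn_on_exhaustive_grid(self):
        """Independent oracle: expand each matrix <= total 20 into label
        vectors and compare with scikit-learn's implementations."""
        for a, b, c, d in itertools.product(range(8), repeat=4):
            if a + b + c + d > 20 or a + b + c + d == 0:
                continue
            cm = [[a, b], [c, d]]
            y_true, y_pred = _expand(cm)
            if (a + b) and (c + d):
                assert balanced_accuracy(cm) == pytest.approx(
                    balanced_accuracy_score(y_true, y_pred))
            if len(set(y_true)) == 2 or len(set(y_pred)) == 2:
                assert cohens_kappa(cm) == pytest.approx(
                    cohen_kappa_score(y_true, y_pred,
                                      labels=["sham", "sick"]))

    def test_kappa_equals_2ba_minus_1_for_symmetric_matrices(self):
        for a, b in itertools.product(range(1, 11), repeat=2):
            cm = [[a, b], [b, a]]
            assert cohens_kappa(cm) == pytest.approx(
                2 * balanced_accuracy(cm) - 1)

    def test_sensitivity_specificity(self):
        cm = confusion_matrix(["sick"] * 10 + ["sham"] * 10,
                              ["sick"] * 9 + ["sham"] + ["sham"] * 8 + ["sick"] * 2)
        sens, spec = sensitivity_specificity(cm)
        assert sens == pytest.approx(0.9)
        assert spec == pytest.approx(0.8)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _flat_dataset(n, seed=0, groups=None, mice=None, batches=None):
    rng = np.random.default_rng(seed)
    axis = uniform_axis(400, 499)
    X = np.abs(rng.normal(1, 0.1, size=(n, axis.size)))
    return make_dataset(axis, X, groups=groups, mice=mice, batches=batches)


class TestAggregation:
    def test_counts_follow_floor_rule(self):
        ds = _flat_dataset(25, mice=["m1"] * 25)
        agg = aggregate_spectra(ds, AggregationSpec(group_size=10, seed=0))
        assert agg.n_spectra == 2  # floor(25/10); 5 discarded

    def test_group_size_one_is_renormalized_identity(self):
        ds = _flat_dataset(6, mice=["m1"] * 6)
        agg = aggregate_spectra(ds, AggregationSpec(group_size=1, seed=0))
        assert agg.n_spectra == 6
        got = np.sort(agg.intensities, axis=0)
        want = np.sort(vector_normalize(ds.intensities), axis=0)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_identical_spectra_aggregate_to_themselves(self):
        axis = uniform_axis(400, 499)
        y = np.abs(np.sin(axis / 20)) + 1
        ds = make_dataset(axis, np.tile(y, (10, 1)), mice=["m1"] * 10)
        agg = aggregate_spectra(ds, AggregationSpec(group_size=5, seed=1))
        for row in agg.intensities:
            np.testing.assert_allclose(row, vector_normalize(y), atol=1e-12)

    def test_same_seed_reproducible_and_mice_never_mixed(self):
        ds = _flat_dataset(40, mice=["m1"] * 20 + ["m2"] * 20,
                           groups=["sham"] * 20 + ["sick"] * 20)
        a1 = aggregate_spectra(ds, AggregationSpec(group_size=7, seed=3))
        a2 = aggregate_spectra(ds, AggregationSpec(group_size=7, seed=3))
        np.testing.assert_array_equal(a1.intensities, a2.intensities)
        assert a1.n_spectra == 4  # floor(20/7) per mouse
        assert set(a1.meta["mouse_id"]) == {"m1", "m2"}

    def test_oversized_group_rejected_and_small_stratum_dropped(self):
        ds = _flat_dataset(10, mice=["m1"] * 7 + ["m2"] * 3)
        with pytest.raises(ValueError, match="group_size"):
            aggregate_spectra(ds, AggregationSpec(group_size=11))
        with pytest.warns(UserWarning, match="dropped"):
            agg = aggregate_spectra(ds, AggregationSpec(group_size=5))
        assert set(agg.meta["mouse_id"]) == {"m1"}


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def separable_dataset(n_per_class=30, seed=0, n_batches=2):
    """Two classes displaced along one channel direction, clearly separable."""
    rng = np.random.default_rng(seed)
    axis = uniform_axis(400, 449)
    base = np.abs(np.sin(axis / 15)) + 1
    X, groups, mice, batches = [], [], [], []
    for cls, shift in (("sham", 0.0), ("sick", 1.0)):
        for i in range(n_per_class):
            y = base + shift * np.exp(-0.5 * ((axis - 425) / 3) ** 2)
            X.append(y + rng.normal(0, 0.02, axis.size))
            groups.append(cls)
            mice.append(f"{cls}_m{i % 4}")
            batches.append(f"b{i % n_batches}")
    return make_dataset(axis, np.vstack(X), groups=groups, mice=mice,
                        batches=batches)


class TestModel:
    def test_separable_lda_training_accuracy_one(self):
        ds = separable_dataset()
        model = fit_model(ds, n_pcs=3, classifier="lda")
        preds = predict(model, ds)
        cm = confusion_matrix(preds["group"], preds["predicted"])
        assert balanced_accuracy(cm) == 1.0

    @pytest.mark.parametrize("clf", ["lda", "rf", "svm"])
    def test_all_classifiers_fit_and_predict(self, clf):
        ds = separable_dataset()
        model = fit_model(ds, n_pcs=3, classifier=clf, seed=1)
        preds = predict(model, ds)
        cm = confusion_matrix(preds["group"], preds["predicted"])
        assert balanced_accuracy(cm) >= 0.95

    def test_permuted_labels_give_chance_level(self):
        ds = separable_dataset(n_per_class=100, seed=2)
        rng = np.random.default_rng(7)
        mice = ds.meta["mouse_id"].unique()
        new_groups = dict(zip(mice, rng.permutation(
            [g.split("_")[0] for g in mice])))  # permute at animal level
        ds.meta["group"] = ds.meta["mouse_id"].map(new_groups)
        res = kfold_cv(ds, k=10, n_pcs=3, seed=7)
        assert abs(res.balanced_accuracy - 0.5) <= 0.1

    def test_single_class_training_rejected(self):
        ds = separable_dataset(n_per_class=5).select({"group": "sham"})
        with pytest.raises(ValueError, match="single class"):
            fit_model(ds, n_pcs=2)

    def test_excessive_pcs_rejected(self):
        ds = separable_dataset(n_per_class=3)
        with pytest.raises(ValueError, match="n_components"):
            fit_model(ds, n_pcs=10)

    def test_sham_class_mean_predicted_sham(self):
        ds = separable_dataset()
        model = fit_model(ds, n_pcs=3)
        mean_sham = ds.select({"group": "sham"}).intensities.mean(0)
        assert model.predict(mean_sham[None, :])[0] == "sham"

    def test_axis_mismatch_and_empty_rejected(self):
        ds = separable_dataset()
        model = fit_model(ds, n_pcs=3)
        with pytest.raises(ValueError, match="axis mismatch"):
            model.predict(np.ones((1, 7)))
        with pytest.raises(ValueError, match="non-empty"):
            model.predict(np.empty((0, ds.n_channels)))

    def test_lda_scores_sick_negative(self):
        ds = separable_dataset()
        model = fit_model(ds, n_pcs=3)
        scores = model.decision_function(ds.intensities)
        assert scores[ds.meta.group == "sick"].mean() < 0
        assert scores[ds.meta.group == "sham"].mean() > 0

    def test_ld_loading_requires_lda(self):
        ds = separable_dataset()
        model = fit_model(ds, n_pcs=3, classifier="rf", seed=0)
        with pytest.raises(ValueError, match="LDA"):
            model.ld_loading()

    def test_ld_loading_near_zero_without_class_signal(self):
        ds = separable_dataset(seed=3)
        informative = fit_model(ds, n_pcs=3).ld_loading()
        rng = np.random.default_rng(3)
        ds.meta["group"] = rng.permutation(ds.meta["group"].to_numpy())
        null = fit_model(ds, n_pcs=3).ld_loading()
        i = np.argmin(np.abs(ds.axis - 425))  # the injected marker band
        assert abs(null[i]) < 0.1 * abs(informative[i])

    def test_sklearn_get_set_params_roundtrip(self):
        est = PCAClassifier(n_components=4, classifier="svm")
        est2 = PCAClassifier(**est.get_params())
        assert est2.get_params() == est.get_params()


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class TestCrossValidation:
    def test_leave_one_out_accounting(self):
        ds = separable_dataset(n_per_class=5)
        res = kfold_cv(ds, k=10, n_pcs=2, seed=0)
        assert res.confusion.to_numpy().sum() == 10
        assert len(res.fold_confusions) == 10

    def test_k_larger_than_n_rejected(self):
        ds = separable_dataset(n_per_class=3)
        with pytest.raises(ValueError, match="exceeds"):
            kfold_cv(ds, k=10, n_pcs=2)

    def test_kfold_reproducible_with_seed(self):
        ds = separable_dataset(n_per_class=20, seed=5)
        r1 = kfold_cv(ds, k=5, n_pcs=3, seed=9)
        r2 = kfold_cv(ds, k=5, n_pcs=3, seed=9)
        assert r1.balanced_accuracy == r2.balanced_accuracy
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_batchwise_one_fold_per_batch(self):
        ds = separable_dataset(n_per_class=24, n_batches=4)
        res = batchwise_cv(ds, n_pcs=3, seed=0)
        assert len(res.fold_confusions) == 4
        assert res.confusion.to_numpy().sum() == ds.n_spectra

    def test_batchwise_single_batch_rejected(self):
        ds = separable_dataset(n_per_class=10, n_batches=1)
        with pytest.raises(ValueError, match="2 batches"):
            batchwise_cv(ds, n_pcs=2)

    def test_batchwise_no_leakage_by_content_hash(self):
        ds = separable_dataset(n_per_class=24, n_batches=3)
        hashes = np.array(spectrum_hashes(ds))
        batches = ds.meta["batch_id"].to_numpy()
        for b in np.unique(batches):
            test_hashes = set(hashes[batches == b])
            train_hashes = set(hashes[batches != b])
            assert not test_hashes & train_hashes

    def test_single_class_batch_held_out_but_predicted(self):
        ds = separable_dataset(n_per_class=24, n_batches=3)
        relabeled = ds.meta["batch_id"].copy()
        relabeled[(ds.meta.batch_id == "b2") & (ds.meta.group == "sham")] = "b0"
        ds.meta["batch_id"] = relabeled  # b2 now contains only sick mice
        with pytest.warns(UserWarning, match="one class"):
            res = batchwise_cv(ds, n_pcs=3, seed=0)
        assert len(res.fold_confusions) == 2  # only b0 and b1 rotate
        assert res.holdout_predictions is not None
        assert set(res.holdout_predictions["batch_id"]) == {"b2"}

    def test_effect_size_sweep_monotone(self):
        """Stronger class effects never reduce cross-validated accuracy."""
        from ramanct import SyntheticConfig, generate_dataset, preprocess_pipeline
        bas = []
        for scale in (0.0, 0.5, 1.0):
            cfg = SyntheticConfig(n_batches=2, mice_per_group_per_batch=2,
                                  cells_per_mouse=15, effect_scale=scale,
                                  seed=21)
            ds, _ = generate_dataset(cfg)
            proc, _ = preprocess_pipeline(ds, None, do_despike=False)
            agg = aggregate_spectra(proc, AggregationSpec(group_size=5, seed=21))
            bas.append(kfold_cv(agg, k=5, n_pcs=5, seed=21).balanced_accuracy)
        assert bas[0] <= bas[1] + 0.1 and bas[1] <= bas[2] + 1e-9
        assert bas[2] > bas[0]


# ---------------------------------------------------------------------------
# majority vote
# ---------------------------------------------------------------------------

class TestMajorityVote:
    def make_preds(self, rows):
        return pd.DataFrame(rows, columns=["mouse_id", "group", "predicted"])

    def test_majority_sick_wins(self):
        preds = self.make_preds([("m1", "sick", "sick")] * 7
                                + [("m1", "sick", "sham")] * 3)
        table, cm, ba = majority_vote(preds)
        assert table.loc[0, "vote"] == "sick"
        assert ba == 1.0

    def test_exact_tie_goes_to_sick(self):
        preds = self.make_preds([("m1", "sham", "sick")] * 5
                                + [("m1", "sham", "sham")] * 5)
        table, _, _ = majority_vote(preds)
        assert table.loc[0, "vote"] == "sick"

    def test_tie_label_configurable(self):
        preds = self.make_preds([("m1", "sham", "sick")] * 5
                                + [("m1", "sham", "sham")] * 5)
        table, _, _ = majority_vote(preds, tie_label="sham")
        assert table.loc[0, "vote"] == "sham"

    def test_binomial_concentration_at_075_accuracy(self):
        """Per-spectrum accuracy 0.75 with >=100 spectra/mouse gives a
        perfect mouse-level vote, across 10 seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rows = []
            for g in ("sham", "sick"):
                other = "sick" if g == "sham" else "sham"
                for m in range(5):
                    correct = rng.random(120) < 0.75
                    rows += [(f"{g}{m}", g, g if c else other)
                             for c in correct]
            _, _, ba = majority_vote(self.make_preds(rows))
            assert ba == 1.0

    def test_conflicting_truth_rejected(self):
        preds = self.make_preds([("m1", "sham", "sham"), ("m1", "sick", "sham")])
        with pytest.raises(ValueError, match="conflicting"):
            majority_vote(preds)
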