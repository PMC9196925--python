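"""QDA, ROC, SFS, LOPO-CV, metrics and weighted-posterior ensembles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from maflim.core import BENIGN, MALIGNANT
from maflim.classification import (
    CLINICAL_CONFUSIONS,
    CVResult,
    FoldResult,
    compute_metrics,
    ensemble_lopo,
    ensemble_predict,
    fselected,
    lopo_cv,
    max_features,
    optimize_weights,
    roc_auc,
    selection_frequency,
    sfs_select,
    simplex_grid,
    sweep_n_sfs,
    train_qda,
)


def _records(X, y, patients=None):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["label"] = np.where(y, MALIGNANT, BENIGN)
    df["patient_id"] = (
        [f"P{i}" for i in range(len(df))] if patients is None else patients
    )
    df["lesion_id"] = [f"L{i}" for i in range(len(df))]
    return df


def _gaussian_fixture(seed=0, n=60, separation=4.0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2 == 0
    X = rng.normal(size=(n, 2))
    X[y] += separation
    return _records(X, y)


class TestQda:
    def test_posterior_matches_density_formula(self):
        """QDA posterior equals brute-force Bayes on the fitted Gaussians."""
        df = _gaussian_fixture(seed=1, separation=1.0)
        model = train_qda(df, ["f0", "f1"], ridge_rel=0.0)
        X = df[["f0", "f1"]].to_numpy()
        like = np.column_stack(
            [
                multivariate_normal(model.means[c], model.covs[c]).pdf(X)
                * model.priors[c]
                for c in range(2)
            ]
        )
        expected = like[:, 1] / like.sum(axis=1)
        np.testing.assert_allclose(model.posterior_malignant(X), expected, atol=1e-10)

    def test_matches_sklearn_qda(self):
        df = _gaussian_fixture(seed=2, separation=1.5)
        X = df[["f0", "f1"]].to_numpy()
        y = (df["label"] == MALIGNANT).to_numpy()
        mine = train_qda(df, ["f0", "f1"], ridge_rel=0.0)
        ref = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y)
        np.testing.assert_allclose(
            mine.posterior_malignant(X), ref.predict_proba(X)[:, 1], atol=1e-8
        )

    def test_separated_classes_classified_perfectly(self):
        df = _gaussian_fixture(seed=3, separation=8.0)
        model = train_qda(df, ["f0", "f1"])
        X = df[["f0", "f1"]].to_numpy()
        pred = model.posterior_malignant(X) >= 0.5
        assert (pred == (df["label"] == MALIGNANT).to_numpy()).all()

    def test_symmetric_point_has_half_posterior(self):
        X = np.array([[-1.0, 0], [-1, 1], [-1, -1], [1, 0], [1, 1], [1, -1]])
        y = np.array([False] * 3 + [True] * 3)
        model = train_qda(_records(X, y), ["f0", "f1"])
        assert model.posterior_malignant(np.array([[0.0, 0.0]]))[0] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError):
            train_qda(_records(X, np.ones(6, dtype=bool)), ["f0", "f1"])


class TestRocAuc:
    def test_perfect_and_reversed(self):
        labels = [BENIGN, BENIGN, MALIGNANT, MALIGNANT]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels) == 0.0

    def test_equals_pairwise_comparison_count(self):
        """AUC is the tie-adjusted fraction of correctly ordered pairs."""
        scores = np.array([0.1, 0.4, 0.4, 0.6, 0.8, 0.8])
        truth = np.array([False, False, True, False, True, True])
        wins = sum(
            1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            for sp in scores[truth]
            for sn in scores[~truth]
        )
        expected = wins / (truth.sum() * (~truth).sum())
        assert roc_auc(scores, truth) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [MALIGNANT, MALIGNANT])


class TestSfs:
    def test_perfect_feature_selected_first(self):
        rng = np.random.default_rng(4)
        y = np.arange(30) % 2 == 0
        X = rng.normal(size=(30, 4))
        X[:, 2] = np.where(y, 5.0, -5.0) + rng.normal(0, 0.1, 30)
        df = _records(X, y)
        assert sfs_select(df, ["f0", "f1", "f2", "f3"], 1) == ["f2"]

    def test_full_pool_returned_in_greedy_order(self):
        df = _gaussian_fixture(seed=5)
        out = sfs_select(df, ["f0", "f1"], 2)
        assert sorted(out) == ["f0", "f1"]

    def test_first_step_matches_exhaustive_search(self):
        rng = np.random.default_rng(6)
        y = np.arange(40) % 2 == 0
        X = rng.normal(size=(40, 5)) + np.where(y, 1, 0)[:, None] * rng.random(5)
        df = _records(X, y)
        pool = [f"f{i}" for i in range(5)]
        aucs = []
        for f in pool:
            model = train_qda(df, [f])
            aucs.append(roc_auc(model.posterior_malignant(df[[f]].to_numpy()), y))
        assert sfs_select(df, pool, 1)[0] == pool[int(np.argmax(aucs))]

    def test_each_greedy_step_matches_exhaustive_one_feature_addition(self):
        rng = np.random.default_rng(7)
        y = np.arange(40) % 2 == 0
        X = rng.normal(size=(40, 5)) + np.where(y, 1, 0)[:, None] * rng.random(5)
        df = _records(X, y)
        pool = [f"f{i}" for i in range(5)]
        selected = sfs_select(df, pool, 3)
        for step in range(1, 3):
            base = selected[:step]
            best_auc, best_feat = -np.inf, None
            for f in pool:
                if f in base:
                    continue
                model = train_qda(df, base + [f])
                auc = roc_auc(
                    model.posterior_malignant(df[base + [f]].to_numpy()), y
                )
                if auc > best_auc:
                    best_auc, best_feat = auc, f
            assert selected[step] == best_feat

    def test_oversized_request_rejected(self):
        df = _gaussian_fixture()
        with pytest.raises(ValueError):
            sfs_select(df, ["f0", "f1"], 3)


def _cohort_records(seed=0, n_patients=12, separation=5.0, noise_features=2):
    """Patient-grouped records: f0 separates the classes, the rest are noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        malignant = p % 2 == 1
        for j in range(2):
            rows.append(
                {
                    "lesion_id": f"L{p}_{j}",
                    "patient_id": f"P{p}",
                    "label": MALIGNANT if malignant else BENIGN,
                    "f0": rng.normal(separation if malignant else 0.0, 1.0),
                    **{
                        f"n{i}": rng.normal() for i in range(noise_features)
                    },
                }
            )
    return pd.DataFrame(rows)


class TestLopoCv:
    def test_fold_structure_and_no_leakage(self):
        df = _cohort_records()
        cv = lopo_cv(df, ["f0", "n0", "n1"], n_sfs=1)
        assert len(cv.folds) == df["patient_id"].nunique()
        assert sum(len(f.lesion_ids) for f in cv.folds) == len(df)
        for fold in cv.folds:
            test_lesions = set(fold.lesion_ids)
            train_lesions = set(df["lesion_id"]) - test_lesions
            test_patients = set(
                df.loc[df["lesion_id"].isin(test_lesions), "patient_id"]
            )
            train_patients = set(
                df.loc[df["lesion_id"].isin(train_lesions), "patient_id"]
            )
            assert test_patients == {fold.patient_id}
            assert fold.patient_id not in train_patients
        assert sum(cv.confusion) == len(df)

    def test_separable_cohort_classified_perfectly(self):
        cv = lopo_cv(_cohort_records(separation=8.0), ["f0", "n0", "n1"], n_sfs=1)
        assert cv.metrics["accuracy"] == 100.0

    def test_single_class_training_fold_rejected(self):
        df = _cohort_records(n_patients=2)  # leaving one out leaves one class
        with pytest.raises(ValueError, match="single class"):
            lopo_cv(df, ["f0"], n_sfs=1)


class TestSweep:
    def test_feature_cap_from_sample_size(self):
        assert max_features(60) == 7
        assert max_features(48) == 6

    def test_sweep_respects_pool_size(self):
        df = _cohort_records(separation=8.0)
        n_sel, cv, table = sweep_n_sfs(df, ["f0", "n0"], n_range=None)
        assert table["n_sfs"].max() <= 2

    def test_tied_f_scores_prefer_fewer_features(self):
        df = _cohort_records(separation=10.0)
        n_sel, cv, table = sweep_n_sfs(df, ["f0", "n0", "n1"])
        perfect = table.loc[table["f_score"] == 100.0, "n_sfs"]
        assert len(perfect) > 1  # several n reach a perfect F-score
        assert n_sel == perfect.min()


class TestSelectionFrequency:
    def _cv(self, folds):
        return CVResult(
            folds=[
                FoldResult(f"P{i}", tuple(sel), ("L",), np.array([0.5]),
                           np.array([True]))
                for i, sel in enumerate(folds)
            ],
            confusion=(1, 0, 0, len(folds) - 1),
            metrics={},
        )

    def test_percentages(self):
        cv = self._cv([["a", "b"]] * 29 + [["a", "c"]])
        table = selection_frequency(cv).set_index("feature")
        assert table.loc["a", "frequency_pct"] == pytest.approx(100.0)
        assert table.loc["b", "frequency_pct"] == pytest.approx(96.7, abs=0.05)

    def test_exactly_half_is_selected(self):
        cv = self._cv([["a", "b"]] * 15 + [["a", "c"]] * 15)
        table = selection_frequency(cv).set_index("feature")
        assert table.loc["b", "frequency_pct"] == 50.0
        assert bool(table.loc["b", "selected"])
        assert set(fselected(cv)) == {"a", "b", "c"}


class TestMetrics:
    @pytest.mark.parametrize(
        "confusion, expected",
        [
            ((33, 8, 6, 13), (76.67, 68.42, 80.49, 65.00)),
            ((29, 12, 3, 16), (75.00, 84.21, 70.73, 68.09)),
            ((37, 4, 3, 16), (88.33, 84.21, 90.24, 82.05)),
            ((13, 28, 3, 16), (48.33, 84.21, 31.71, 50.79)),
        ],
    )
    def test_clinical_worked_examples(self, confusion, expected):
        """Recompute the published per-pool metrics from their confusion matrices."""
        m = compute_metrics(*confusion)
        assert m["accuracy"] == pytest.approx(expected[0], abs=0.005)
        assert m["sensitivity"] == pytest.approx(expected[1], abs=0.005)
        assert m["specificity"] == pytest.approx(expected[2], abs=0.005)
        assert m["f_score"] == pytest.approx(expected[3], abs=0.005)

    def test_perfect_confusion(self):
        m = compute_metrics(41, 0, 0, 19)
        assert all(v == 100.0 for v in m.values())

    def test_degenerate_counts(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)
        m = compute_metrics(5, 0, 0, 0)  # no malignant lesions at all
        assert np.isnan(m["sensitivity"])


class TestEnsemble:
    def test_simplex_grid_counts(self):
        assert len(simplex_grid(2)) == 11
        assert len(simplex_grid(3)) == 66
        np.testing.assert_allclose(simplex_grid(3).sum(axis=1), 1.0)

    def test_predict_weighted_average(self):
        post = np.array([[0.6, 0.8]])
        assert ensemble_predict(post, [0.5, 0.5])[0] == pytest.approx(0.7)
        assert ensemble_predict(post, [1.0, 0.0])[0] == pytest.approx(0.6)
        post3 = np.array([[0.3, 0.6, 0.9]])
        assert ensemble_predict(post3, [1 / 3] * 3)[0] == pytest.approx(0.6)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict(np.array([[0.5, 0.5]]), [0.7, 0.7])

    def test_optimal_weight_favours_the_informative_pool(self):
        df = _cohort_records(seed=8, separation=8.0)
        pools = {"good": ["f0"], "noise": ["n0"]}
        w = optimize_weights(df, pools)
        post_good = train_qda(df, ["f0"]).posterior_malignant(df[["f0"]].to_numpy())
        post_noise = train_qda(df, ["n0"]).posterior_malignant(df[["n0"]].to_numpy())
        mixed = w[0] * post_good + w[1] * post_noise
        truth = (df["label"] == MALIGNANT).to_numpy()
        assert ((mixed >= 0.5) == truth).all()

    def test_identical_pools_tie_breaks_lexicographically(self):
        df = _cohort_records(seed=9, separation=8.0)
        pools = {"a": ["f0"], "b": ["f0"]}
        w = optimize_weights(df, pools)
        np.testing.assert_allclose(w, simplex_grid(2)[0])

    def test_fold_weights_satisfy_sum_to_one(self):
        df = _cohort_records(seed=10, separation=6.0)
        cv = ensemble_lopo(df, {"good": ["f0"], "noise": ["n0"]})
        for fold in cv.folds:
            assert abs(sum(fold.weights) - 1.0) < 1e-12

    def test_single_pool_ensemble_equals_plain_lopo(self):
        df = _cohort_records(seed=11, separation=6.0)
        ens = ensemble_lopo(df, {"good": ["f0"]})
        plain = lopo_cv(df, ["f0"], n_sfs=1)
        assert ens.confusion == plain.confusion
        for fe, fp in zip(ens.folds, plain.folds):
            np.testing.assert_allclose(fe.posteriors, fp.posteriors, atol=1e-12)

    def test_complementary_pools_combine_beneficially(self):
        """Pool A drives sensitivity, pool B specificity; the weighted ensemble
        does at least as well as the better single pool."""
        rng = np.random.default_rng(25)
        rows = []
        for p in range(24):
            malignant = p % 2 == 1
            for j in range(2):
                rows.append(
                    {
                        "lesion_id": f"L{p}_{j}",
                        "patient_id": f"P{p}",
                        "label": MALIGNANT if malignant else BENIGN,
                        # A: tight malignant cluster, diffuse benign
                        "fa": rng.normal(3.0, 0.4) if malignant else rng.normal(0, 2.5),
                        # B: tight benign cluster, diffuse malignant
                        "fb": rng.normal(0, 2.5) if malignant else rng.normal(-3.0, 0.4),
                    }
                )
        df = pd.DataFrame(rows)
        ens = ensemble_lopo(df, {"A": ["fa"], "B": ["fb"]})
        fa = lopo_cv(df, ["fa"], n_sfs=1)
        fb = lopo_cv(df, ["fb"], n_sfs=1)
        best_single = max(fa.metrics["f_score"], fb.metrics["f_score"])
        assert ens.metrics["f_score"] >= best_single
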