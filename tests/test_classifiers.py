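import numpy as np
import pytest

from gridvote.core_io import DatasetError
from gridvote.classifiers import (
    ModelConfig,
    fit,
    knn_neighbor_order,
    knn_votes,
    predict,
)
from .conftest import make_ds


def knn_cfg(k=3, n_features=1):
    return ModelConfig("T", "SAM", n_features, "KNN", k)


def nb_cfg(n_features=1):
    return ModelConfig("T", "SAM", n_features, "NB")


class TestModelConfig:
    def test_k_present_iff_knn(self):
        with pytest.raises(ValueError):
            ModelConfig("T", "SAM", 5, "KNN")        # KNN without k
        with pytest.raises(ValueError):
            ModelConfig("T", "SAM", 5, "NB", k=3)    # NB with k
        with pytest.raises(ValueError):
            ModelConfig("T", "bogus", 5, "NB")

    def test_config_ids_unique_and_stable(self):
        a = knn_cfg(k=3, n_features=5)
        b = knn_cfg(k=13, n_features=5)
        assert a.config_id != b.config_id
        assert a.config_id == knn_cfg(k=3, n_features=5).config_id


class TestKnn:
    def test_k1_returns_label_of_identical_training_sample(self):
        train = make_ds(np.array([[0.0], [5.0]]), labels=["N", "P"])
        model = fit(knn_cfg(k=1), train, ["f000"])
        query = make_ds(np.array([[5.0]]), role="validation")
        assert list(predict(model, query)) == ["P"]

    def test_k3_worked_example(self):
        # 1-D training x=(0,1,10,11) labels (N,N,P,P); query 10.4 has
        # nearest three at 10, 11, 1 voting P,P,N -> P
        train = make_ds(np.array([[0.0], [1.0], [10.0], [11.0]]),
                        labels=["N", "N", "P", "P"])
        model = fit(knn_cfg(k=3), train, ["f000"])
        query = make_ds(np.array([[10.4]]), role="validation")
        assert list(predict(model, query)) == ["P"]

    def test_lazy_fit_stores_restricted_matrix(self):
        rng = np.random.default_rng(0)
        train = make_ds(rng.normal(size=(6, 4)), labels=["P", "N"] * 3)
        model = fit(knn_cfg(k=1, n_features=2), train, ["f002", "f000"])
        np.testing.assert_array_equal(model.params["X"],
                                      train.values[:, [2, 0]])

    def test_distance_ties_resolved_by_sample_id(self):
        # duplicated rows (as after oversampling) with conflicting labels:
        # ordering is by id, so the prediction is deterministic
        train = make_ds(np.zeros((3, 1)), labels=["P", "N", "N"])
        order = knn_neighbor_order(train.values, train.sample_ids,
                                   np.zeros((1, 1)))
        np.testing.assert_array_equal(order[0], [0, 1, 2])
        assert knn_votes(order, train.y, 1)[0]  # s000 ('P') wins the tie

    def test_missing_feature_rejected(self):
        train = make_ds(np.zeros((4, 2)), labels=["P", "N", "P", "N"])
        model = fit(knn_cfg(k=1, n_features=2), train, ["f000", "f001"])
        query = make_ds(np.zeros((1, 1)), role="validation")
        with pytest.raises(DatasetError, match="lack"):
            predict(model, query)

    def test_matches_sklearn_on_tie_free_data(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(4)
        for trial in range(10):
            X = rng.normal(size=(15, 3))
            y = rng.random(15) > 0.5
            y[:2] = [True, False]
            train = make_ds(X, labels=np.where(y, "P", "N"))
            Xq = rng.normal(size=(8, 3))
            query = make_ds(Xq, role="validation")
            for k in (1, 3, 5):
                model = fit(knn_cfg(k=k, n_features=3), train,
                            train.feature_ids)
                ours = predict(model, query) == "P"
                ref = KNeighborsClassifier(n_neighbors=k).fit(X, y).predict(Xq)
                np.testing.assert_array_equal(ours, ref)


class TestNaiveBayes:
    def test_fit_recovers_class_means_and_priors(self):
        train = make_ds(np.array([[0.0], [0.0], [4.0], [4.0]]),
                        labels=["N", "N", "P", "P"])
        model = fit(nb_cfg(), train, ["f000"])
        assert model.params["mean_neg"][0] == 0.0
        assert model.params["mean_pos"][0] == 4.0

    def test_priors_from_label_frequencies(self):
        labels = ["P"] * 30 + ["N"] * 70
        train = make_ds(np.random.default_rng(5).normal(size=(100, 1)),
                        labels=labels)
        model = fit(nb_cfg(), train, ["f000"])
        assert np.exp(model.params["log_prior_pos"]) == pytest.approx(0.3)
        assert np.exp(model.params["log_prior_neg"]) == pytest.approx(0.7)

    def test_equal_prior_decision_at_closed_form_boundary(self):
        # classes N(0,1) vs N(4,1) with equal priors: boundary at 2, so
        # the query 1.0 goes to the first (negative-mean) class
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(4, 1, 200)])
        # force exact moments per class to make the boundary exact
        vals[:200] = (vals[:200] - vals[:200].mean()) / vals[:200].std()
        vals[200:] = (vals[200:] - vals[200:].mean()) / vals[200:].std() + 4
        train = make_ds(vals[:, None], labels=["N"] * 200 + ["P"] * 200)
        model = fit(nb_cfg(), train, ["f000"])
        query = make_ds(np.array([[1.0], [3.0]]), role="validation")
        assert list(predict(model, query)) == ["N", "P"]

    def test_decision_invariant_to_feature_location_shift(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        X[:15] += 0.8
        labels = ["P"] * 15 + ["N"] * 15
        q = rng.normal(size=(12, 4))
        base = predict(fit(nb_cfg(4), make_ds(X, labels=labels),
                           [f"f{j:03d}" for j in range(4)]),
                       make_ds(q, role="validation"))
        shifted = predict(fit(nb_cfg(4), make_ds(X + 100.0, labels=labels),
                              [f"f{j:03d}" for j in range(4)]),
                          make_ds(q + 100.0, role="validation"))
        np.testing.assert_array_equal(base, shifted)

    def test_zero_variance_feature_survives_via_floor(self):
        # duplicated oversampled rows can zero a within-class variance
        vals = np.array([[1.0, 0.3], [1.0, 0.1], [2.0, 0.2], [2.0, 0.4]])
        train = make_ds(vals, labels=["N", "N", "P", "P"])
        model = fit(nb_cfg(2), train, ["f000", "f001"])
        query = make_ds(np.array([[1.0, 0.2], [2.0, 0.3]]),
                        role="validation")
        assert list(predict(model, query)) == ["N", "P"]
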