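import numpy as np
import pytest

from gridvote.synthetic_data import (
    ENDPOINT_TABLE,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    EndpointSpec,
    bayes_error,
    class_counts,
    make_default_suite,
    make_reduced_suite,
    simulate_endpoint,
    simulate_endpoint_with_truth,
)


class TestSuiteStructure:
    def test_thirteen_endpoints_with_benchmark_sizes(self):
        suite = make_default_suite(n_features=100)
        assert [s.code for s in suite] == list("ABCDEFGHIJKLM")
        by_code = {s.code: s for s in suite}
        d = by_code["D"]
        assert (d.train_n, d.train_pn_ratio) == (130, 0.34)
        assert (d.validation_n, d.validation_pn_ratio) == (100, 0.18)
        assert by_code["I"].endpoint_class == NEGATIVE_CONTROL
        assert by_code["I"].n_informative == 0
        assert by_code["M"].endpoint_class == NEGATIVE_CONTROL
        assert {by_code[c].endpoint_class for c in "HL"} == {POSITIVE_CONTROL}

    def test_positive_controls_have_sub_percent_bayes_error(self):
        for s in make_default_suite(n_features=100):
            if s.endpoint_class == POSITIVE_CONTROL:
                assert bayes_error(s.effect_size, s.n_informative,
                                   s.noise_sd) < 0.01

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            make_default_suite(n_features=10)

    def test_reduced_suite_covers_all_classes_and_imbalance(self):
        suite = make_reduced_suite()
        classes = {s.endpoint_class for s in suite}
        assert classes == {"real", POSITIVE_CONTROL, NEGATIVE_CONTROL}
        assert any(s.endpoint_class == "real" and
                   max(s.train_pn_ratio, 1 / s.train_pn_ratio) > 4
                   for s in suite)


class TestClassCounts:
    @pytest.mark.parametrize("n,ratio,expected", [
        (100, 0.25, (20, 80)),
        (130, 0.34, (33, 97)),   # D training split
        (214, 1.33, (122, 92)),  # I validation split
    ])
    def test_rounding_rule(self, n, ratio, expected):
        assert class_counts(n, ratio) == expected

    def test_realized_ratio_close_to_requested(self):
        for _, _, tn, tr, vn, vr in ENDPOINT_TABLE:
            for n, r in ((tn, tr), (vn, vr)):
                npos, nneg = class_counts(n, r)
                assert npos + nneg == n
                assert npos / nneg == pytest.approx(r, abs=0.5 / nneg * (1 + r) ** 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            class_counts(0, 1.0)
        with pytest.raises(ValueError):
            class_counts(10, -1.0)


class TestSimulation:
    def test_deterministic_from_seed(self):
        spec = EndpointSpec(code="D", train_n=40, validation_n=30,
                            n_features=50, n_informative=5, seed=11)
        t1, v1 = simulate_endpoint(spec)
        t2, v2 = simulate_endpoint(spec)
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(v1.values, v2.values)
        assert list(t1.labels) == list(t2.labels)

    def test_split_shapes_and_roles(self):
        spec = EndpointSpec(code="A", train_n=70, train_pn_ratio=0.59,
                            validation_n=88, validation_pn_ratio=0.47,
                            n_features=60, n_informative=10)
        train, val = simulate_endpoint(spec)
        assert (train.n_samples, train.n_features) == (70, 60)
        assert (val.n_samples, val.n_features) == (88, 60)
        assert train.role == "training" and val.role == "validation"
        assert train.feature_ids == val.feature_ids
        # validation batches are fresh (unseen during training)
        assert not set(train.batches) & set(val.batches)

    def test_informative_features_shift_positive_class(self):
        spec = EndpointSpec(code="E", train_n=400, train_pn_ratio=1.0,
                            validation_n=30, n_features=40, n_informative=8,
                            effect_size=1.0, batch_sd=0.0, seed=3)
        train, _ = simulate_endpoint(spec)
        y = train.y
        shift = train.values[y].mean(axis=0) - train.values[~y].mean(axis=0)
        assert shift[:8].mean() == pytest.approx(1.0, abs=0.15)
        assert abs(shift[8:].mean()) < 0.1

    def test_negative_control_labels_independent_of_features(self):
        spec = EndpointSpec(code="I", endpoint_class=NEGATIVE_CONTROL,
                            train_n=340, train_pn_ratio=1.43,
                            validation_n=30, n_features=400,
                            n_informative=0, effect_size=0.0, seed=5)
        train, _ = simulate_endpoint(spec)
        y = train.y.astype(float)
        corr = np.array([
            np.corrcoef(train.values[:, j], y)[0, 1]
            for j in range(train.n_features)
        ])
        assert abs(corr.mean()) < 3 / np.sqrt(train.n_features)

    def test_batch_offset_recovery(self):
        # with zero class effect the between-batch feature-mean gap
        # estimates the injected offset difference
        spec = EndpointSpec(code="B", train_n=600, train_pn_ratio=1.0,
                            validation_n=30, n_features=80, n_informative=0,
                            effect_size=0.0, endpoint_class=NEGATIVE_CONTROL,
                            n_batches=2, batch_sd=0.5, seed=9)
        train, _, truth = simulate_endpoint_with_truth(spec)
        b = np.asarray(train.batches)
        gap = (train.values[b == "B0"].mean(axis=0)
               - train.values[b == "B1"].mean(axis=0))
        injected = truth["train_batch_offsets"][0] - truth["train_batch_offsets"][1]
        resid = gap - injected
        # Monte-Carlo error of a mean difference over ~300 samples/batch
        assert np.abs(resid).mean() < 4 * np.sqrt(2 / 300)

    def test_negative_control_spec_must_be_uninformative(self):
        with pytest.raises(ValueError):
            EndpointSpec(code="I", endpoint_class=NEGATIVE_CONTROL,
                         n_informative=5)

    def test_weak_positive_control_rejected(self):
        with pytest.raises(ValueError, match="Bayes"):
            EndpointSpec(code="H", endpoint_class=POSITIVE_CONTROL,
                         n_informative=1, effect_size=0.5)
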