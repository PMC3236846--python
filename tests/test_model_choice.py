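import numpy as np
import pytest

from gridvote.classifiers import ModelConfig
from gridvote.crossval import CVPerformance, enumerate_grid, run_grid
from gridvote.model_choice import (
    EnsembleDegenerateError,
    build_ensemble,
    mcc_group,
    predict_ensemble,
    process_training,
    select_nominated,
    select_retained,
    vote_labels,
)
from gridvote.synthetic_data import simulate_endpoint
from .conftest import make_ds, tiny_cfg, tiny_spec


def perf(mcc=0.5, n_feat=10, method="SAM", clf="KNN", k=3, acc=0.8,
         sens=0.8, spec=0.8, rate=0.5, code="D"):
    cfg = ModelConfig(code, method, n_feat, clf, k if clf == "KNN" else None)
    return CVPerformance(config=cfg, mean_mcc=mcc, mean_accuracy=acc,
                         mean_sensitivity=sens, mean_specificity=spec,
                         n_runs=50, oof_positive_rate=rate)


class TestMccGroup:
    @pytest.mark.parametrize("value,expected", [
        (0.89, 0.9), (0.91, 0.9),   # the grouping worked example
        (-0.23, -0.2),
        (0.85, 0.9),                # half rounds away from zero
        (-0.85, -0.9),
        (0.0, 0.0), (1.0, 1.0), (-1.0, -1.0),
    ])
    def test_one_decimal_grouping(self, value, expected):
        assert mcc_group(value) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mcc_group(1.2)


class TestSelectNominated:
    def test_fewer_features_wins_within_group(self):
        a = perf(mcc=0.91, n_feat=100)
        b = perf(mcc=0.89, n_feat=20)
        assert select_nominated([a, b]).n_features == 20

    def test_higher_group_beats_parsimony(self):
        a = perf(mcc=0.91, n_feat=100)
        b = perf(mcc=0.84, n_feat=5)  # 0.8 group
        assert select_nominated([a, b]).n_features == 100

    def test_nearly_same_feature_count_decided_by_accuracy(self):
        a = perf(mcc=0.9, n_feat=10, acc=0.80)
        b = perf(mcc=0.9, n_feat=15, acc=0.95)  # within one grid step
        assert select_nominated([a, b], feature_step=5).n_features == 15

    def test_sam_preferred_then_knn(self):
        fc = perf(method="FC_P", clf="KNN", k=3)
        sam_nb = perf(method="SAM", clf="NB", k=None)
        sam_knn = perf(method="SAM", clf="KNN", k=3)
        assert select_nominated([fc, sam_nb, sam_knn]).config_id == \
            sam_knn.config_id
        assert select_nominated([sam_nb, sam_knn]).classifier == "KNN"

    def test_single_candidate_returned(self):
        only = perf()
        assert select_nominated([only]) == only.config

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        perfs = [perf(mcc=m, n_feat=f, k=k, acc=a)
                 for m, f, k, a in zip(rng.uniform(0.3, 0.9, 12),
                                       rng.choice([5, 10, 15, 20], 12),
                                       rng.choice([1, 3, 5], 12),
                                       rng.uniform(0.6, 0.95, 12))]
        base = select_nominated(perfs)
        for _ in range(5):
            rng.shuffle(perfs)
            assert select_nominated(perfs) == base

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_nominated([])


class TestSelectRetained:
    def test_boundary_ties_included(self):
        perfs = [perf(mcc=m, n_feat=f)
                 for m, f in [(0.5, 5), (0.4, 10), (0.4, 15), (0.3, 20)]]
        kept = select_retained(perfs, 0.5)
        assert len(kept) == 3  # tie at the 0.4 cut-point is kept

    def test_fraction_one_keeps_everything(self):
        perfs = [perf(mcc=0.1 * i, n_feat=5 * (i + 1)) for i in range(5)]
        assert len(select_retained(perfs, 1.0)) == 5

    def test_monotone_retention(self):
        rng = np.random.default_rng(1)
        perfs = [perf(mcc=m, n_feat=5 * (i + 1))
                 for i, m in enumerate(rng.uniform(-0.2, 0.9, 20))]
        previous = set()
        for f in (0.1, 0.25, 0.5, 0.75, 1.0):
            kept = {p.config_id for p in select_retained(perfs, f)}
            assert previous <= kept
            previous = kept


class TestEnsemble:
    @pytest.mark.parametrize("v,p_bar,expected", [
        (0.4, 0.5, False),   # ratio 0.8 -> negative
        (0.5, 0.5, True),    # ratio exactly 1 -> positive
        (0.6, 0.5, True),    # 6 of 10 models, ratio 1.2
        (1.0, 0.9, True),
    ])
    def test_vote_ratio_threshold(self, v, p_bar, expected):
        assert vote_labels(np.array([v]), p_bar)[0] == expected

    def test_p_bar_half_reduces_to_majority_vote(self):
        rng = np.random.default_rng(2)
        v = rng.integers(0, 11, 50) / 10
        np.testing.assert_array_equal(vote_labels(v, 0.5), v >= 0.5)

    def test_build_and_predict_on_synthetic_endpoint(self):
        spec = tiny_spec(seed=6)
        train, val = simulate_endpoint(spec)
        cfg = tiny_cfg(seed=6)
        configs = enumerate_grid(cfg, ["D"])
        perfs = run_grid(train, configs, cfg)
        ens = build_ensemble(perfs, train, cfg)
        n_ok = sum(p.status == "ok" for p in perfs)
        assert len(ens.retained) >= int(np.ceil(0.5 * n_ok))
        assert 0 < ens.p_bar < 1
        labels = predict_ensemble(ens, val.blinded())
        assert set(labels) <= {"P", "N"}
        assert len(labels) == val.n_samples

    def test_prediction_matches_brute_force_enumeration(self):
        from gridvote.classifiers import predict as predict_one

        spec = tiny_spec(seed=7)
        train, val = simulate_endpoint(spec)
        cfg = tiny_cfg(seed=7)
        perfs = run_grid(train, enumerate_grid(cfg, ["D"])[:12], cfg)
        ens = build_ensemble(perfs, train, cfg, fraction=0.6)
        blind = val.blinded()
        expected = []
        for i in range(blind.n_samples):
            votes = sum(
                predict_one(r.model, blind)[i] == "P" for r in ens.retained
            )
            expected.append(
                "P" if votes / len(ens.retained) / ens.p_bar >= 1 else "N")
        assert list(predict_ensemble(ens, blind)) == expected

    def test_degenerate_p_bar_raises(self):
        perfs = [perf(mcc=0.9, n_feat=5, rate=0.0),
                 perf(mcc=0.8, n_feat=10, rate=0.0)]
        train, _ = simulate_endpoint(tiny_spec(seed=8))
        with pytest.raises(EnsembleDegenerateError):
            build_ensemble(perfs, train, tiny_cfg(seed=8))

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            select_retained([perf()], 0.5)


class TestProcessTraining:
    def test_rankings_cover_both_methods(self):
        train, _ = simulate_endpoint(tiny_spec(seed=9))
        proc = process_training(train, tiny_cfg(seed=9))
        assert set(proc.rankings) == {"FC_P", "SAM"}
        assert len(proc.rankings["SAM"]) == train.n_features
        # processed set still contains every original sample
        assert set(train.sample_ids) <= set(proc.dataset.sample_ids)
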