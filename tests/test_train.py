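import numpy as np
import pandas as pd
import pytest

import petresponse.train as train_mod
from petresponse.cohort import generate_feature_table
from petresponse.metrics import ap_score
from petresponse.select import SelectionStrategy
from petresponse.train import (
    CVConfig,
    FittedPipeline,
    HyperGrids,
    PipelineSpec,
    SoftVoteEnsemble,
    cross_validate,
    fit_final,
    learning_curve,
    soft_vote,
    split_cohort,
    tune_and_rank,
)

TINY_STRATEGIES = [
    SelectionStrategy(use_pca=False, filter="anova", use_lasso=False),
    SelectionStrategy(use_pca=True, filter="fisher", use_lasso=False),
]
TINY_GRIDS = HyperGrids(
    k_features=(5, None),
    lasso_lam=(1.0,),
    classifier={
        "logistic": [{"C": 1.0}],
        "naive_bayes": [{}],
    },
)


def planted_table(seed=0, n=120, effect=2.0):
    t = generate_feature_table(
        n=n, n_features=20, planted_features=5, effect_sd=effect,
        block_correlation=0.3, prevalence=0.3, seed=seed,
    )
    return t.drop(columns="label"), t["label"].to_numpy()


def simple_spec(**kw):
    defaults = dict(
        strategy=SelectionStrategy(use_pca=False, filter="anova", use_lasso=False, k_features=5),
        classifier="logistic",
        clf_params=(("C", 1.0),),
    )
    defaults.update(kw)
    return PipelineSpec(**defaults)


class TestSplit:
    def test_printed_cohort_arithmetic(self):
        y = np.array([1] * 57 + [0] * 142)
        train_idx, test_idx = split_cohort(y, test_fraction=0.3, seed=0)
        assert len(train_idx) == 139 and len(test_idx) == 60
        assert y[train_idx].sum() == 40 and y[test_idx].sum() == 17
        assert np.array_equal(np.sort(np.concatenate([train_idx, test_idx])), np.arange(199))

    def test_same_seed_same_split(self):
        y = np.array([0, 1] * 20)
        a = split_cohort(y, seed=7)
        b = split_cohort(y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_cohort(np.array([0, 0, 0, 1]))


class TestCrossValidation:
    def test_two_folds_five_repeats_gives_ten_scores(self):
        X, y = planted_table()
        mean, sd, scores = cross_validate(simple_spec(), X, y, CVConfig(seed=1))
        assert len(scores) == 10
        assert mean == pytest.approx(scores.mean())

    def test_planted_signal_beats_prevalence(self):
        X, y = planted_table(effect=2.0)
        mean, _, _ = cross_validate(simple_spec(), X, y, CVConfig(seed=1))
        assert mean > y.mean() + 0.15

    def test_null_data_near_prevalence(self):
        means = []
        for seed in range(6):
            X, y = planted_table(seed=seed, effect=0.0)
            mean, _, _ = cross_validate(simple_spec(), X, y, CVConfig(seed=seed))
            means.append(mean)
        assert abs(np.mean(means) - 0.3) < 0.1

    def test_fold_prevalence_preserved_within_one_sample(self):
        y = np.array([1] * 30 + [0] * 70)
        cv = CVConfig(seed=2)
        for tr, va in cv.splits(y):
            for idx in (tr, va):
                expected = 0.3 * len(idx)
                assert abs(y[idx].sum() - expected) <= 1.0


class TestTuneAndRank:
    def test_leaderboard_covers_grid_and_sorts_descending(self):
        X, y = planted_table()
        lb = tune_and_rank(X, y, CVConfig(seed=0), strategies=TINY_STRATEGIES,
                           classifiers=("logistic", "naive_bayes"), grids=TINY_GRIDS)
        assert len(lb.table) == 4
        aps = lb.table["mean_ap"].to_numpy()
        assert (np.diff(aps) <= 1e-12).all()
        assert len(lb.top(3)) == 3

    def test_leaderboard_bit_reproducible(self):
        X, y = planted_table(seed=3)
        kw = dict(strategies=TINY_STRATEGIES, classifiers=("logistic", "naive_bayes"),
                  grids=TINY_GRIDS)
        lb1 = tune_and_rank(X, y, CVConfig(seed=5), **kw)
        lb2 = tune_and_rank(X, y, CVConfig(seed=5), **kw)
        pd.testing.assert_frame_equal(lb1.table, lb2.table)

    def test_full_grid_enumeration_is_144(self):
        from petresponse.select import enumerate_strategies
        from petresponse.train import CLASSIFIERS

        assert len(enumerate_strategies()) * len(CLASSIFIERS) == 144


class TestFittedPipelineAndVoting:
    def test_resubstitution_ap_at_least_cv_mean(self):
        X, y = planted_table(seed=2)
        spec = simple_spec()
        cv_mean, _, _ = cross_validate(spec, X, y, CVConfig(seed=2))
        pipe = fit_final(spec, X, y)
        resub = ap_score(y, pipe.predict_proba(X))
        assert resub >= cv_mean - 0.05  # optimism direction, small slack

    def test_identical_members_equal_single_member(self):
        X, y = planted_table(seed=4)
        pipe = fit_final(simple_spec(), X, y)
        ens = SoftVoteEnsemble([pipe] * 10)
        np.testing.assert_allclose(ens.predict_proba(X), pipe.predict_proba(X))

    def test_two_member_mean(self):
        class Stub:
            def __init__(self, value):
                self.value = value

            def predict_proba(self, X):
                return np.full(len(X), self.value)

        X = pd.DataFrame({"a": [0.0, 1.0]})
        np.testing.assert_allclose(soft_vote([Stub(0.2), Stub(0.8)], X), [0.5, 0.5])

    def test_ensemble_probabilities_bounded(self):
        X, y = planted_table(seed=5)
        members = [fit_final(simple_spec(), X, y),
                   fit_final(simple_spec(classifier="naive_bayes", clf_params=()), X, y)]
        p = SoftVoteEnsemble(members).predict_proba(X)
        assert (p >= 0).all() and (p <= 1).all()

    def test_unfitted_pipeline_rejected(self):
        X, _ = planted_table()
        with pytest.raises(RuntimeError, match="not fitted"):
            FittedPipeline(simple_spec()).predict_proba(X)


class TestLeakageAudit:
    def test_no_test_row_reaches_any_fold_fit(self, monkeypatch):
        """Instrument fold-state construction: every row fitted during the
        sweep must come from the training subset."""
        X, y = planted_table(seed=6)
        train_idx, test_idx = split_cohort(y, seed=0)
        test_row_ids = set(X.index[test_idx])
        seen: list = []
        orig_init = train_mod._FoldState.__init__

        def spy(self, X_tr, y_tr, clinical_cols, conventional):
            seen.append(set(X_tr.index))
            orig_init(self, X_tr, y_tr, clinical_cols, conventional)

        monkeypatch.setattr(train_mod._FoldState, "__init__", spy)
        tune_and_rank(X.iloc[train_idx], y[train_idx], CVConfig(seed=0),
                      strategies=TINY_STRATEGIES[:1], classifiers=("naive_bayes",),
                      grids=TINY_GRIDS)
        assert seen, "audit saw no fits"
        for rows in seen:
            assert not rows & test_row_ids


class TestLearningCurve:
    def test_curve_properties_on_planted_signal(self):
        X, y = planted_table(seed=7, n=160, effect=2.0)
        spec = simple_spec()
        cv = CVConfig(n_repeats=3, seed=7)
        curve = learning_curve(spec, X, y, sizes=(20, 40, 80), cv=cv)
        assert list(curve["n"]) == [20, 40, 80]
        # resubstitution optimism at every size
        assert (curve["train_ap"] >= curve["val_ap"] - 0.05).all()
        # more data should not hurt much: last point at least first - noise
        assert curve["val_ap"].iloc[-1] >= curve["val_ap"].iloc[0] - 0.05

    def test_full_size_point_reproduces_cross_validate(self):
        X, y = planted_table(seed=8, n=80)
        spec = simple_spec()
        cv = CVConfig(seed=8)
        full = len(X) // 2  # training half of each 2-fold split
        curve = learning_curve(spec, X, y, sizes=(full,), cv=cv)
        mean, _, _ = cross_validate(spec, X, y, cv)
        assert curve["val_ap"].iloc[0] == pytest.approx(mean, abs=1e-12)

    def test_too_small_size_skipped_with_warning(self):
        X, y = planted_table(seed=9, n=60)
        with pytest.warns(UserWarning, match="too small"):
            curve = learning_curve(simple_spec(), X, y, sizes=(1,), cv=CVConfig(seed=9))
        assert curve.empty
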