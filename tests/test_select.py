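import numpy as np
import pandas as pd
import pytest

from petresponse.cohort import generate_feature_table
from petresponse.select import (
    FILTER_METHODS,
    SelectionStrategy,
    drop_conventional_redundant,
    drop_low_icc,
    encode_clinical,
    enumerate_strategies,
    fit_pca,
    lasso_select,
    load_icc_manifest,
    project,
    rank_features,
)
from petresponse.radiomics import default_registry

from oracles import pearson_brute


class TestStrategyGrid:
    def test_exactly_24_distinct_strategies(self):
        strategies = enumerate_strategies()
        assert len(strategies) == 24
        assert len(set(strategies)) == 24

    def test_144_pipelines_with_six_classifiers(self):
        from petresponse.train import CLASSIFIERS

        assert len(enumerate_strategies()) * len(CLASSIFIERS) == 144

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="unknown filter"):
            SelectionStrategy(use_pca=False, filter="chi2", use_lasso=False)


class TestICCPreselection:
    def test_packaged_manifest_drops_22_of_143(self, rng):
        reg = default_registry()
        icc = load_icc_manifest()
        table = pd.DataFrame(rng.normal(size=(10, 143)), columns=reg.names)
        kept = drop_low_icc(table, icc)
        assert table.shape[1] == 143
        assert kept.shape[1] == 121

    def test_all_high_icc_keeps_everything(self, rng):
        table = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        icc = pd.Series(1.0, index=list("abcd"))
        assert drop_low_icc(table, icc).shape[1] == 4

    def test_boundary_icc_retained(self, rng):
        table = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x", "y"])
        icc = pd.Series({"x": 0.6, "y": 0.599})
        kept = drop_low_icc(table, icc)
        assert list(kept.columns) == ["x"]

    def test_missing_manifest_entry_names_features(self, rng):
        table = pd.DataFrame(rng.normal(size=(5, 2)), columns=["x", "y"])
        icc = pd.Series({"x": 0.9})
        with pytest.raises(KeyError, match="y"):
            drop_low_icc(table, icc)


class TestRedundancyPruning:
    def test_duplicate_of_conventional_removed_noise_kept(self, rng):
        vol = rng.uniform(10, 100, size=200)
        table = pd.DataFrame(
            {"volume": vol, "dup": vol * 2.0 + 1.0, "noise": rng.normal(size=200)}
        )
        kept = drop_conventional_redundant(table, ["volume"])
        assert "volume" in kept.columns and "noise" in kept.columns
        assert "dup" not in kept.columns

    def test_matches_brute_force_pearson_scan(self, rng):
        table = generate_feature_table(
            n=150, n_features=20, block_correlation=0.9, block_size=5, seed=7
        ).drop(columns="label")
        conventional = ["f000", "f005"]
        kept = drop_conventional_redundant(table, conventional, rho=0.8)
        for col in table.columns:
            if col in conventional:
                assert col in kept.columns
                continue
            redundant = any(
                abs(pearson_brute(table[col], table[c])) > 0.8 for c in conventional
            )
            assert (col not in kept.columns) == redundant

    def test_zero_variance_feature_retained_with_warning(self, rng):
        table = pd.DataFrame({"conv": rng.normal(size=30), "flat": np.ones(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            kept = drop_conventional_redundant(table, ["conv"])
        assert "flat" in kept.columns


class TestPCA:
    def test_single_dominant_direction_keeps_one_component(self, rng):
        z = rng.normal(size=500)
        table = pd.DataFrame(
            {"a": 10 * z, "b": 10 * z + 0.1 * rng.normal(size=500), "c": 0.1 * rng.normal(size=500)}
        )
        basis = fit_pca(table)
        assert basis.n_retained == 1
        assert basis.retained_variance > 0.95

    def test_isotropic_data_keeps_most_components(self, rng):
        d = 10
        table = pd.DataFrame(rng.normal(size=(4000, d)))
        table.columns = [f"f{j}" for j in range(d)]
        basis = fit_pca(table)
        assert basis.n_retained >= int(np.ceil(0.95 * d))

    def test_projection_orthonormal_and_variance_consistent(self, rng):
        table = pd.DataFrame(rng.normal(size=(100, 6)), columns=list("abcdef"))
        basis = fit_pca(table)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(basis.n_retained), atol=1e-10)
        Z = project(basis, table).to_numpy()
        total_var = table.to_numpy().var(axis=0, ddof=1).sum()
        np.testing.assert_allclose(
            Z.var(axis=0, ddof=1) / total_var,
            basis.explained_variance_ratio[: basis.n_retained],
            rtol=1e-8,
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 training samples"):
            fit_pca(pd.DataFrame({"a": [1.0]}))


class TestFilterRankings:
    @pytest.mark.parametrize("method", FILTER_METHODS)
    def test_separating_feature_ranked_first_by_every_method(self, method, rng):
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        table = pd.DataFrame(
            {
                "signal": y * 10.0 + rng.normal(scale=0.1, size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        ranking = rank_features(table, y, method)
        assert ranking.ordered_names[0] == "signal"

    def test_fisher_score_matches_direct_formula(self, rng):
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        x = rng.normal(size=80)
        table = pd.DataFrame({"x": x})
        score = rank_features(table, y, "fisher").scores["x"]
        mu = x.mean()
        num = sum((y == c).sum() * (x[y == c].mean() - mu) ** 2 for c in (0, 1))
        den = sum((y == c).sum() * x[y == c].var() for c in (0, 1))
        assert score == pytest.approx(num / den, rel=1e-10)

    def test_t_score_matches_welch_formula(self, rng):
        y = np.array([0] * 40 + [1] * 40)
        x = rng.normal(size=80) + y * 0.5
        table = pd.DataFrame({"x": x})
        score = rank_features(table, y, "t_score").scores["x"]
        a, b = x[y == 1], x[y == 0]
        t = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert score == pytest.approx(abs(t), rel=1e-10)

    def test_gini_matches_exhaustive_threshold_scan(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        x = rng.normal(size=40)
        table = pd.DataFrame({"x": x})
        score = rank_features(table, y, "gini").scores["x"]

        def gini(labels):
            if len(labels) == 0:
                return 0.0
            p = labels.mean()
            return 2 * p * (1 - p)

        best = 0.0
        for t in np.unique(x)[:-1]:
            left, right = y[x <= t], y[x > t]
            dec = gini(y) - (len(left) / 40) * gini(left) - (len(right) / 40) * gini(right)
            best = max(best, dec)
        assert score == pytest.approx(best, rel=1e-10)

    def test_label_independent_features_score_low(self, rng):
        n = 200
        y = np.array([0] * 140 + [1] * 60)
        table = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"n{j}" for j in range(5)])
        for method in ("anova", "t_score", "fisher"):
            scores = rank_features(table, y, method).scores
            assert scores.max() < 6.0  # comfortably inside the null range

    def test_ties_broken_lexicographically(self):
        y = np.array([0, 0, 1, 1])
        table = pd.DataFrame({"b": [0.0, 0.0, 0.0, 0.0], "a": [0.0, 0.0, 0.0, 0.0]})
        ranking = rank_features(table, y, "anova")
        assert ranking.ordered_names == ["a", "b"]

    def test_single_class_rejected(self, rng):
        table = pd.DataFrame({"x": rng.normal(size=10)})
        with pytest.raises(ValueError, match="both classes"):
            rank_features(table, np.zeros(10, dtype=int), "anova")


class TestLasso:
    def _toy(self, rng, n=80):
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        table = pd.DataFrame(
            {
                "s1": y + rng.normal(scale=0.3, size=n),
                "s2": y + rng.normal(scale=0.3, size=n),
                "noise": rng.normal(size=n),
            }
        )
        return table, y

    def test_huge_penalty_empties_support(self, rng):
        table, y = self._toy(rng)
        assert lasso_select(table, y, lam=1e6) == []

    def test_tiny_penalty_keeps_informative_features(self, rng):
        table, y = self._toy(rng)
        support = lasso_select(table, y, lam=1e-4)
        assert {"s1", "s2"} <= set(support)

    def test_support_size_non_increasing_in_lambda(self, rng):
        table, y = self._toy(rng)
        sizes = [len(lasso_select(table, y, lam)) for lam in (0.01, 0.1, 1.0, 10.0, 100.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_non_positive_lambda_rejected(self, rng):
        table, y = self._toy(rng)
        with pytest.raises(ValueError, match="positive"):
            lasso_select(table, y, lam=0.0)


class TestClinicalEncoding:
    def test_histology_and_stage_codes(self):
        table = pd.DataFrame(
            {
                "histology": ["adenocarcinoma", "squamous"],
                "t_stage": [3, "4a"],
                "n_stage": [0, 2],
                "label": [0, 1],
            }
        )
        enc = encode_clinical(table)
        assert enc["histology_adeno"].tolist() == [1, 0]
        assert enc["t_stage"].tolist() == [3, 4]
        assert enc["n_stage"].tolist() == [0, 2]
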