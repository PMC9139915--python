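"""Cross-validated selection over the 144-pipeline grid and soft voting.

The cohort is split 70/30 with stratification (proportional rounding per
class).  On the training subset every combination of the 24 feature-selection
strategies and 6 classifiers (logistic regression, SVM, random forest,
Gaussian naive Bayes, a one-hidden-layer neural network, K-nearest
neighbors) is tuned and scored by mean average precision over a 2-fold
cross-validation repeated 5 times (10 validation scores per pipeline).  The
ten best pipelines feed a soft-voting ensemble that averages their
positive-class probabilities.

Everything that learns from data — normalization, redundancy pruning, PCA,
filter rankings, LASSO and the classifier — is re-estimated inside each
fold on that fold's training half.  Because those stages do not depend on
the classifier or on the filter cut ``k``, the trainer fits them once per
fold and shares them across the grid; this is mathematically identical to
refitting them per pipeline and roughly two orders of magnitude faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .metrics import ap_score
from .preprocess import SkewAdaptiveNormalizer
from .radiomics.registry import CONVENTIONAL_FEATURES
from .select import (
    CLINICAL_COLUMNS,
    FILTER_METHODS,
    FilterRanking,
    SelectionStrategy,
    drop_conventional_redundant,
    enumerate_strategies,
    fit_pca,
    lasso_select,
    project,
    rank_features,
)

__all__ = [
    "CVConfig",
    "CLASSIFIERS",
    "HyperGrids",
    "PipelineSpec",
    "FittedPipeline",
    "SoftVoteEnsemble",
    "ModelLeaderboard",
    "split_cohort",
    "make_classifier",
    "cross_validate",
    "tune_and_rank",
    "fit_final",
    "soft_vote",
    "learning_curve",
]

CLASSIFIERS: tuple[str, ...] = (
    "logistic",
    "svm",
    "random_forest",
    "naive_bayes",
    "neural_network",
    "knn",
)


@dataclass
class CVConfig:
    """2-fold cross-validation repeated 5 times, stratified."""

    n_folds: int = 2
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0

    @property
    def n_scores(self) -> int:
        return self.n_folds * self.n_repeats

    def splits(self, labels) -> list[tuple[np.ndarray, np.ndarray]]:
        y = np.asarray(labels, dtype=int)
        if not self.stratified:
            raise NotImplementedError("only stratified CV is supported")
        rskf = RepeatedStratifiedKFold(
            n_splits=self.n_folds, n_repeats=self.n_repeats, random_state=self.seed
        )
        out = list(rskf.split(np.zeros_like(y), y))
        assert len(out) == self.n_scores
        for tr, va in out:
            assert y[tr].min() != y[tr].max() and y[va].min() != y[va].max(), (
                "stratification must leave both classes in every fold"
            )
        return out


@dataclass
class HyperGrids:
    """Desk-scale default hyperparameter grids for the 144-pipeline sweep."""

    k_features: tuple = (2, 5, None)  # None = all ranked features
    lasso_lam: tuple = (0.25, 1.0)
    classifier: dict = field(
        default_factory=lambda: {
            "logistic": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
            "svm": [{"C": c, "kernel": k} for c in (0.1, 1.0, 10.0) for k in ("rbf", "linear")],
            "random_forest": [{"n_estimators": 50, "max_depth": d} for d in (3, None)],
            "naive_bayes": [{}],
            "neural_network": [{"hidden_layer_sizes": (16,)}],
            "knn": [{"n_neighbors": k} for k in (3, 5, 11)],
        }
    )


def make_classifier(name: str, params: dict, seed: int = 0):
    if name == "logistic":
        return LogisticRegression(max_iter=2000, **params)
    if name == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **{"n_estimators": 100, **params})
    if name == "naive_bayes":
        return GaussianNB(**params)
    if name == "neural_network":
        return MLPClassifier(solver="lbfgs", max_iter=300, random_state=seed, alpha=1e-3, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def split_cohort(labels, test_fraction: float = 0.3, seed: int = 0):
    """Stratified split with proportional rounding of per-class test counts.

    Returns disjoint, exhaustive (train_idx, test_idx) integer arrays; e.g.
    199 patients with 57 positives at 30% test yield 139 train (40 positive)
    and 60 test (17 positive).
    """
    y = np.asarray(labels, dtype=int)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 members; cannot stratify")
        rng.shuffle(idx)
        n_test = int(round(idx.size * test_fraction))
        n_test = min(max(n_test, 1), idx.size - 1)
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


# ---------------------------------------------------------------------------
# pipeline spec and fitted pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineSpec:
    """A fully specified pipeline: strategy + classifier + hyperparameters."""

    strategy: SelectionStrategy
    classifier: str
    clf_params: tuple = ()  # sorted (key, value) pairs
    lasso_lam: float | None = None

    @property
    def name(self) -> str:
        return f"{self.strategy.name}+{self.classifier}"

    @property
    def params_dict(self) -> dict:
        return dict(self.clf_params)


def _select_columns(Z_tr, y_tr, ranking: FilterRanking, spec: PipelineSpec):
    cols = ranking.top(spec.strategy.k_features)
    if spec.strategy.use_lasso:
        lam = spec.lasso_lam if spec.lasso_lam is not None else 1.0
        support = lasso_select(Z_tr[cols], y_tr, lam=lam)
        if not support:
            warnings.warn(
                f"{spec.name}: empty LASSO support at lam={lam}; keeping top-ranked feature",
                stacklevel=2,
            )
            support = cols[:1]
        cols = support
    return cols


class _FoldState:
    """Classifier-independent fitted state of one fold's training half."""

    def __init__(self, X_tr: pd.DataFrame, y_tr, clinical_cols, conventional):
        self.y_tr = np.asarray(y_tr, dtype=int)
        clinical = [c for c in clinical_cols if c in X_tr.columns]
        self.normalizer = SkewAdaptiveNormalizer(passthrough=clinical)
        Xn = self.normalizer.fit_transform(X_tr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xr = drop_conventional_redundant(Xn, conventional, exempt=clinical)
        self.kept_columns = list(Xr.columns)
        self._basis = None
        self.variants: dict[bool, pd.DataFrame] = {False: Xr}
        self._rankings: dict[tuple[bool, str], FilterRanking] = {}
        self._column_cache: dict[tuple, list[str]] = {}
        self._va_cache: dict[tuple[int, bool], pd.DataFrame] = {}

    @property
    def basis(self):
        if self._basis is None:
            self._basis = fit_pca(self.variants[False])
        return self._basis

    def ranking(self, use_pca: bool, method: str) -> FilterRanking:
        """Filter rankings are computed on demand and cached per fold."""
        key = (use_pca, method)
        if key not in self._rankings:
            self._rankings[key] = rank_features(self.train_matrix(use_pca), self.y_tr, method)
        return self._rankings[key]

    def select_columns(self, spec: PipelineSpec) -> list[str]:
        """Column selection depends only on (pca, filter, k, lam); cache it
        so classifier hyperparameter sweeps reuse the same LASSO fit."""
        s = spec.strategy
        key = (s.use_pca, s.filter, s.k_features, spec.lasso_lam if s.use_lasso else None)
        if key not in self._column_cache:
            ranking = self.ranking(s.use_pca, s.filter)
            self._column_cache[key] = _select_columns(
                self.train_matrix(s.use_pca), self.y_tr, ranking, spec
            )
        return self._column_cache[key]

    def transform(self, X: pd.DataFrame, use_pca: bool) -> pd.DataFrame:
        Xn = self.normalizer.transform(X)[self.kept_columns]
        return project(self.basis, Xn) if use_pca else Xn

    def transform_cached(self, X: pd.DataFrame, use_pca: bool) -> pd.DataFrame:
        """Memoized transform for the fixed validation half of a fold."""
        key = (id(X), use_pca)
        if key not in self._va_cache:
            self._va_cache[key] = self.transform(X, use_pca)
        return self._va_cache[key]

    def train_matrix(self, use_pca: bool) -> pd.DataFrame:
        if use_pca and True not in self.variants:
            self.variants[True] = project(self.basis, self.variants[False])
        return self.variants[use_pca]


class FittedPipeline:
    """One strategy x classifier pipeline fitted on a training table."""

    def __init__(self, spec: PipelineSpec, clinical_cols=CLINICAL_COLUMNS,
                 conventional=CONVENTIONAL_FEATURES, seed: int = 0):
        self.spec = spec
        self.clinical_cols = tuple(clinical_cols)
        self.conventional = tuple(conventional)
        self.seed = seed
        self.state_: _FoldState | None = None
        self.columns_: list[str] | None = None
        self.classifier_ = None
        self.n_train_: int | None = None

    def fit(self, X: pd.DataFrame, y) -> "FittedPipeline":
        self.state_ = _FoldState(X, y, self.clinical_cols, self.conventional)
        Z_tr = self.state_.train_matrix(self.spec.strategy.use_pca)
        ranking = self.state_.ranking(self.spec.strategy.use_pca, self.spec.strategy.filter)
        self.columns_ = _select_columns(Z_tr, self.state_.y_tr, ranking, self.spec)
        self.classifier_ = make_classifier(self.spec.classifier, self.spec.params_dict, self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.classifier_.fit(Z_tr[self.columns_].to_numpy(), self.state_.y_tr)
        self.n_train_ = len(X)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Positive-class probability for each row."""
        if self.state_ is None:
            raise RuntimeError("pipeline is not fitted")
        Z = self.state_.transform(X, self.spec.strategy.use_pca)[self.columns_].to_numpy()
        return _positive_probability(self.classifier_, Z)


def _positive_probability(clf, Z: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(Z)[:, 1]
    # calibrate decision scores through a logistic link (logged fallback)
    warnings.warn(
        f"{type(clf).__name__} exposes no predict_proba; "
        "calibrating decision scores with a sigmoid",
        stacklevel=2,
    )
    return 1.0 / (1.0 + np.exp(-clf.decision_function(Z)))


@dataclass
class SoftVoteEnsemble:
    """Arithmetic mean of member pipelines' positive-class probabilities."""

    members: list

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        probs = np.stack([m.predict_proba(X) for m in self.members])
        return probs.mean(axis=0)


# ---------------------------------------------------------------------------
# grid evaluation
# ---------------------------------------------------------------------------


def _fold_states(X, y, cv: CVConfig, clinical_cols, conventional):
    states = []
    for tr, va in cv.splits(y):
        st = _FoldState(X.iloc[tr], np.asarray(y)[tr], clinical_cols, conventional)
        states.append((st, X.iloc[va], np.asarray(y)[va], tr, va))
    return states


def _score_spec_on_fold(spec: PipelineSpec, st: _FoldState, X_va, y_va, seed: int) -> float:
    Z_tr = st.train_matrix(spec.strategy.use_pca)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cols = st.select_columns(spec)
        clf = make_classifier(spec.classifier, spec.params_dict, seed)
        if isinstance(clf, SVC):
            # AP is rank-based and Platt calibration is monotone, so raw
            # decision scores give the same AP without the internal CV
            clf.set_params(probability=False)
        clf.fit(Z_tr[cols].to_numpy(), st.y_tr)
        Z_va = st.transform_cached(X_va, spec.strategy.use_pca)[cols].to_numpy()
        scores = clf.decision_function(Z_va) if isinstance(clf, SVC) else clf.predict_proba(Z_va)[:, 1]
        return ap_score(y_va, scores)


def cross_validate(
    spec: PipelineSpec,
    train_table: pd.DataFrame,
    labels,
    cv: CVConfig | None = None,
    clinical_cols=CLINICAL_COLUMNS,
    conventional=CONVENTIONAL_FEATURES,
) -> tuple[float, float, np.ndarray]:
    """Mean and SD of validation AP over the n_folds x n_repeats scores."""
    cv = cv or CVConfig()
    scores = [
        _score_spec_on_fold(spec, st, X_va, y_va, cv.seed)
        for st, X_va, y_va, _, _ in _fold_states(train_table, labels, cv, clinical_cols, conventional)
    ]
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std(ddof=1)), scores


@dataclass
class ModelLeaderboard:
    """Ranked cross-validation results over the strategy x classifier grid."""

    table: pd.DataFrame  # sorted descending by mean_ap
    specs: dict[str, PipelineSpec]  # best tuned spec per grid cell

    def top(self, n: int = 10) -> list[PipelineSpec]:
        return [self.specs[key] for key in self.table.index[:n]]

    @property
    def best(self) -> PipelineSpec:
        return self.top(1)[0]


def _spec_combos(strategy: SelectionStrategy, clf: str, grids: HyperGrids, n_feat_cap: int):
    ks = []
    for k in grids.k_features:
        kk = None if k is None else min(k, n_feat_cap)
        if kk not in ks:
            ks.append(kk)
    lams = grids.lasso_lam if strategy.use_lasso else (None,)
    for k in ks:
        for lam in lams:
            for params in grids.classifier[clf]:
                yield PipelineSpec(
                    strategy=replace(strategy, k_features=k),
                    classifier=clf,
                    clf_params=tuple(sorted(params.items())),
                    lasso_lam=lam,
                )


def tune_and_rank(
    train_table: pd.DataFrame,
    labels,
    cv: CVConfig | None = None,
    strategies: list[SelectionStrategy] | None = None,
    classifiers=CLASSIFIERS,
    grids: HyperGrids | None = None,
    clinical_cols=CLINICAL_COLUMNS,
    conventional=CONVENTIONAL_FEATURES,
) -> ModelLeaderboard:
    """Tune every strategy x classifier cell by mean CV AP and rank the grid.

    One leaderboard row per cell (144 for the full grid); each row carries
    the best hyperparameters found for that cell, its mean and SD validation
    AP, sorted descending with ties broken by (strategy, classifier) name.
    """
    cv = cv or CVConfig()
    strategies = strategies if strategies is not None else enumerate_strategies()
    grids = grids or HyperGrids()
    y = np.asarray(labels, dtype=int)
    states = _fold_states(train_table, y, cv, clinical_cols, conventional)
    n_feat_cap = min(len(st.variants[False].columns) for st, *_ in states)

    rows, specs = [], {}
    for strategy in strategies:
        for clf in classifiers:
            best = None
            for spec in _spec_combos(strategy, clf, grids, n_feat_cap):
                scores = np.array(
                    [_score_spec_on_fold(spec, st, X_va, y_va, cv.seed)
                     for st, X_va, y_va, _, _ in states]
                )
                mean = scores.mean()
                if best is None or mean > best[0]:
                    best = (mean, float(scores.std(ddof=1)), spec)
            mean, sd, spec = best
            key = f"{strategy.name}+{clf}"
            specs[key] = spec
            rows.append(
                {
                    "pipeline": key,
                    "use_pca": strategy.use_pca,
                    "filter": strategy.filter,
                    "use_lasso": strategy.use_lasso,
                    "classifier": clf,
                    "k_features": spec.strategy.k_features,
                    "lasso_lam": spec.lasso_lam,
                    "clf_params": repr(spec.params_dict),
                    "mean_ap": float(mean),
                    "sd_ap": sd,
                }
            )
    table = pd.DataFrame(rows).set_index("pipeline")
    table = table.sort_values(
        by=["mean_ap", "filter", "classifier"], ascending=[False, True, True], kind="stable"
    )
    # deterministic tie-break on the full pipeline name
    table["_name"] = table.index
    table = table.sort_values(by=["mean_ap", "_name"], ascending=[False, True], kind="stable")
    table = table.drop(columns="_name")
    return ModelLeaderboard(table=table, specs=specs)


def fit_final(
    spec: PipelineSpec,
    train_table: pd.DataFrame,
    labels,
    clinical_cols=CLINICAL_COLUMNS,
    conventional=CONVENTIONAL_FEATURES,
    seed: int = 0,
) -> FittedPipeline:
    """Refit one tuned pipeline on the full training subset."""
    return FittedPipeline(spec, clinical_cols, conventional, seed).fit(train_table, labels)


def soft_vote(members, X: pd.DataFrame) -> np.ndarray:
    """Average positive-class probability over fitted member pipelines."""
    return SoftVoteEnsemble(list(members)).predict_proba(X)


# ---------------------------------------------------------------------------
# learning curve
# ---------------------------------------------------------------------------


def learning_curve(
    spec: PipelineSpec,
    train_table: pd.DataFrame,
    labels,
    sizes,
    cv: CVConfig | None = None,
    clinical_cols=CLINICAL_COLUMNS,
    conventional=CONVENTIONAL_FEATURES,
) -> pd.DataFrame:
    """Training and validation AP as a function of training-set size.

    For each size *n* and each CV split, the pipeline is refitted on a
    stratified subsample of *n* rows from the fold's training half and
    scored on that subsample (train AP) and on the validation half.  At the
    full fold size this reproduces :func:`cross_validate` exactly.  Sizes
    too small to keep both classes are skipped with a warning.
    """
    cv = cv or CVConfig()
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(cv.seed)
    splits = cv.splits(y)
    rows = []
    for n in sizes:
        tr_aps, va_aps = [], []
        for tr, va in splits:
            y_tr = y[tr]
            if n > len(tr):
                continue
            sub = _stratified_subsample(tr, y_tr, n, rng)
            if sub is None:
                continue
            X_sub, y_sub = train_table.iloc[sub], y[sub]
            if y_sub.min() == y_sub.max():
                continue
            pipe = FittedPipeline(spec, clinical_cols, conventional, cv.seed).fit(X_sub, y_sub)
            tr_aps.append(ap_score(y_sub, pipe.predict_proba(X_sub)))
            va_aps.append(ap_score(y[va], pipe.predict_proba(train_table.iloc[va])))
        if not tr_aps:
            warnings.warn(f"size {n}: too small for a stratified subsample, skipped", stacklevel=2)
            continue
        rows.append(
            {
                "n": int(n),
                "train_ap": float(np.mean(tr_aps)),
                "train_ap_sd": float(np.std(tr_aps, ddof=1)) if len(tr_aps) > 1 else 0.0,
                "val_ap": float(np.mean(va_aps)),
                "val_ap_sd": float(np.std(va_aps, ddof=1)) if len(va_aps) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _stratified_subsample(idx, y_idx, n, rng):
    """Pick n of idx preserving class proportions (>=1 per class), or None."""
    if n < 2:
        return None
    classes = np.unique(y_idx)
    take = {}
    for c in classes:
        frac = (y_idx == c).mean()
        take[c] = max(1, int(round(frac * n)))
    # adjust to total n
    while sum(take.values()) > n:
        c = max(take, key=lambda c: take[c])
        if take[c] <= 1:
            return None
        take[c] -= 1
    while sum(take.values()) < n:
        c = max(classes, key=lambda c: (y_idx == c).sum() - take[c])
        take[c] += 1
    out = []
    for c in classes:
        pool = idx[y_idx == c]
        if take[c] > len(pool):
            return None
        out.append(rng.choice(pool, size=take[c], replace=False))
    return np.sort(np.concatenate(out))
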