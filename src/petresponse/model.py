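"""Model/Results interface over the whole prediction pipeline.

:class:`NonResponseModel` is built from a feature table (radiomic columns +
clinical covariates + a binary non-response label); ``fit()`` performs the
stratified 70/30 split, ICC preselection, the cross-validated sweep over the
24 x 6 pipeline grid, refits the leaderboard's top pipelines on the full
training subset, forms the top-10 soft-voting ensemble, and evaluates both
the best single model and the ensemble on the held-out test subset.  The
returned :class:`NonResponseResults` carries the leaderboard, the fitted
pipelines, the evaluation reports and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import EvaluationReport, ap_score, evaluate_scores
from .radiomics.registry import CONVENTIONAL_FEATURES
from .select import (
    CLINICAL_COLUMNS,
    SelectionStrategy,
    drop_low_icc,
    encode_clinical,
    enumerate_strategies,
    load_icc_manifest,
)
from .train import (
    CLASSIFIERS,
    CVConfig,
    FittedPipeline,
    HyperGrids,
    ModelLeaderboard,
    PipelineSpec,
    SoftVoteEnsemble,
    fit_final,
    learning_curve,
    split_cohort,
    tune_and_rank,
)

__all__ = ["NonResponseModel", "NonResponseResults", "filter_subgroup"]

SUBGROUPS = ("all", "t3plus", "adeno")


def filter_subgroup(table: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    """Restrict a cohort before the split: all, T3-4a only, or adenocarcinoma only."""
    if subgroup not in SUBGROUPS:
        raise ValueError(f"subgroup must be one of {SUBGROUPS}, got {subgroup!r}")
    if subgroup == "t3plus":
        return table[table["t_stage"] >= 3]
    if subgroup == "adeno":
        if "histology_adeno" in table.columns:
            return table[table["histology_adeno"] == 1]
        return table[table["histology"] == "adenocarcinoma"]
    return table


class NonResponseModel:
    """Non-response prediction model over a radiomic + clinical feature table.

    Parameters
    ----------
    table
        Patients x features DataFrame containing radiomic features, the
        clinical covariates and a binary label column (1 = non-responder).
        Clinical covariates may be raw (``histology`` strings, T-stage with
        ``"4a"``) — they are encoded on construction.
    label_col
        Name of the binary label column.
    icc_manifest
        Feature -> ICC Series for the reproducibility preselection; defaults
        to the packaged synthetic manifest.  Pass ``False`` to skip the step
        (for purely tabular synthetic data without registry names).
    subgroup
        Cohort filter applied before the split: ``all``, ``t3plus``, ``adeno``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        label_col: str = "label",
        clinical_cols=CLINICAL_COLUMNS,
        conventional=CONVENTIONAL_FEATURES,
        icc_manifest=None,
        icc_cutoff: float = 0.6,
        subgroup: str = "all",
        cv: CVConfig | None = None,
        strategies: list[SelectionStrategy] | None = None,
        classifiers=CLASSIFIERS,
        grids: HyperGrids | None = None,
        test_fraction: float = 0.3,
    ):
        if label_col not in table.columns:
            raise ValueError(f"label column {label_col!r} not in table")
        table = encode_clinical(table)
        table = filter_subgroup(table, subgroup)
        self.subgroup = subgroup
        self.label_col = label_col
        self.labels = table[label_col].astype(int).to_numpy()
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")
        X = table.drop(columns=[label_col])

        self.clinical_cols = tuple(c for c in clinical_cols if c in X.columns)
        self.conventional = tuple(c for c in conventional if c in X.columns)
        radiomic = [c for c in X.columns if c not in self.clinical_cols]

        if icc_manifest is False:
            self.icc = None
        else:
            manifest = icc_manifest if icc_manifest is not None else load_icc_manifest()
            usable = set(manifest.index) >= set(radiomic)
            if icc_manifest is None and not usable:
                # tabular synthetic features carry no registry names
                self.icc = None
            else:
                self.icc = manifest
                X = drop_low_icc(X, manifest, cutoff=icc_cutoff, exempt=self.clinical_cols)
        self.table = X
        self.cv = cv or CVConfig()
        self.strategies = strategies
        self.classifiers = tuple(classifiers)
        self.grids = grids or HyperGrids()
        self.test_fraction = test_fraction

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "NonResponseModel":
        return cls(table, **kwargs)

    @property
    def n_patients(self) -> int:
        return len(self.table)

    def fit(self, seed: int = 0, top_n: int = 10) -> "NonResponseResults":
        """Split, sweep the grid, refit the top pipelines, evaluate held-out."""
        train_idx, test_idx = split_cohort(self.labels, self.test_fraction, seed=seed)
        X_train = self.table.iloc[train_idx]
        y_train = self.labels[train_idx]
        X_test = self.table.iloc[test_idx]
        y_test = self.labels[test_idx]

        cv = CVConfig(self.cv.n_folds, self.cv.n_repeats, self.cv.stratified, seed=seed)
        leaderboard = tune_and_rank(
            X_train,
            y_train,
            cv=cv,
            strategies=self.strategies,
            classifiers=self.classifiers,
            grids=self.grids,
            clinical_cols=self.clinical_cols,
            conventional=self.conventional,
        )
        top_n = min(top_n, len(leaderboard.table))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            members = [
                fit_final(spec, X_train, y_train, self.clinical_cols, self.conventional, seed)
                for spec in leaderboard.top(top_n)
            ]
        ensemble = SoftVoteEnsemble(members)

        best = members[0]
        test_report = evaluate_scores(y_test, best.predict_proba(X_test))
        ensemble_report = evaluate_scores(y_test, ensemble.predict_proba(X_test))
        train_resub_ap = ap_score(y_train, best.predict_proba(X_train))

        return NonResponseResults(
            model=self,
            seed=seed,
            train_idx=train_idx,
            test_idx=test_idx,
            leaderboard=leaderboard,
            members=members,
            ensemble=ensemble,
            test_report=test_report,
            ensemble_report=ensemble_report,
            train_resub_ap=train_resub_ap,
        )


@dataclass
class NonResponseResults:
    """Fitted pipelines, leaderboard and held-out evaluation of one run."""

    model: NonResponseModel
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    leaderboard: ModelLeaderboard
    members: list[FittedPipeline]
    ensemble: SoftVoteEnsemble
    test_report: EvaluationReport
    ensemble_report: EvaluationReport
    train_resub_ap: float

    @property
    def best(self) -> FittedPipeline:
        return self.members[0]

    @property
    def cv_ap(self) -> tuple[float, float]:
        row = self.leaderboard.table.iloc[0]
        return float(row["mean_ap"]), float(row["sd_ap"])

    def learning_curve(self, sizes) -> pd.DataFrame:
        X_train = self.model.table.iloc[self.train_idx]
        y_train = self.model.labels[self.train_idx]
        cv = CVConfig(
            self.model.cv.n_folds, self.model.cv.n_repeats, self.model.cv.stratified, self.seed
        )
        return learning_curve(
            self.leaderboard.best,
            X_train,
            y_train,
            sizes,
            cv=cv,
            clinical_cols=self.model.clinical_cols,
            conventional=self.model.conventional,
        )

    def summary(self) -> str:
        """Plain-text summary in the spirit of a statsmodels results table."""
        mean_ap, sd_ap = self.cv_ap
        n_tr, n_te = len(self.train_idx), len(self.test_idx)
        pos_tr = int(self.model.labels[self.train_idx].sum())
        pos_te = int(self.model.labels[self.test_idx].sum())
        lines = [
            "Non-response prediction results",
            "=" * 64,
            f"cohort           n={self.model.n_patients}  subgroup={self.model.subgroup}",
            f"split            train {n_tr} ({pos_tr} pos) / test {n_te} ({pos_te} pos)",
            f"grid             {len(self.leaderboard.table)} pipelines, "
            f"CV {self.model.cv.n_folds}-fold x {self.model.cv.n_repeats} repeats, seed {self.seed}",
            "-" * 64,
            f"best pipeline    {self.leaderboard.table.index[0]}",
            f"  CV AP          {mean_ap:.3f} +/- {sd_ap:.3f}",
            f"  train AP       {self.train_resub_ap:.3f} (resubstitution)",
            f"  test AP        {self.test_report.ap:.3f}   (baseline {self.test_report.baseline_ap:.3f})",
            f"  test AUC       {self.test_report.auc:.3f}",
            f"soft vote (top {len(self.members)})",
            f"  test AP        {self.ensemble_report.ap:.3f}",
            f"  test AUC       {self.ensemble_report.auc:.3f}",
            "=" * 64,
        ]
        return "\n".join(lines)
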