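"""Four-stage feature-selection cascade and the 24-strategy grid.

Stage 1 drops radiomic features with poor multi-vendor reproducibility
(ICC < 0.6, from an editable manifest).  Stage 2 drops radiomic features
whose training-set Pearson correlation with any *conventional* PET measure
(volume, SUVmax, SUVpeak, SUVmean, TLG) exceeds 0.8 in absolute value.
The remaining per-strategy choices — optional PCA keeping the components
that explain > 95% of training variance, one of six univariable filters
(logistic |Wald z|, ANOVA F, Fisher score, ReliefF, Welch |t|, Gini
impurity decrease), and optional LASSO (support of an L1-penalized logistic
fit) — factorize into 2 x 6 x 2 = 24 selection strategies.

All statistics are estimated on training rows only; every ranking breaks
ties lexicographically by feature name so results are platform-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression

__all__ = [
    "SelectionStrategy",
    "FILTER_METHODS",
    "enumerate_strategies",
    "load_icc_manifest",
    "drop_low_icc",
    "drop_conventional_redundant",
    "PCABasis",
    "fit_pca",
    "project",
    "FilterRanking",
    "rank_features",
    "lasso_select",
    "encode_clinical",
    "CLINICAL_COLUMNS",
]

FILTER_METHODS: tuple[str, ...] = ("logistic", "anova", "fisher", "relief", "t_score", "gini")
CLINICAL_COLUMNS: tuple[str, ...] = ("histology_adeno", "t_stage", "n_stage")


# ---------------------------------------------------------------------------
# strategy grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionStrategy:
    """One cell of the {PCA} x {filter} x {LASSO} grid."""

    use_pca: bool
    filter: str
    use_lasso: bool
    k_features: int | None = None  # None = keep all ranked features

    def __post_init__(self) -> None:
        if self.filter not in FILTER_METHODS:
            raise ValueError(f"unknown filter {self.filter!r}; choose from {FILTER_METHODS}")

    @property
    def name(self) -> str:
        parts = ["pca" if self.use_pca else "raw", self.filter, "lasso" if self.use_lasso else "nolasso"]
        return "+".join(parts)


def enumerate_strategies() -> list[SelectionStrategy]:
    """The full 2 x 6 x 2 = 24 grid, in deterministic order."""
    return [
        SelectionStrategy(use_pca=pca, filter=flt, use_lasso=lasso)
        for pca in (False, True)
        for flt in FILTER_METHODS
        for lasso in (False, True)
    ]


# ---------------------------------------------------------------------------
# stage 1: ICC manifest
# ---------------------------------------------------------------------------


def load_icc_manifest(path=None) -> pd.Series:
    """Load a (feature_name, icc) manifest.

    With no path, loads the packaged ``icc_manifest_synthetic.csv`` — a
    synthetic stand-in for published multi-vendor reproducibility values
    (which are not redistributable) that flags 22 of the 143 default
    registry features as poorly reproducible.
    """
    if path is None:
        ref = resources.files("petresponse").joinpath("data/icc_manifest_synthetic.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(Path(path))
    if not {"feature_name", "icc"} <= set(df.columns):
        raise ValueError("ICC manifest needs columns feature_name, icc")
    return df.set_index("feature_name")["icc"].astype(float)


def drop_low_icc(
    table: pd.DataFrame,
    icc: pd.Series,
    cutoff: float = 0.6,
    exempt=(),
) -> pd.DataFrame:
    """Remove feature columns with ICC strictly below ``cutoff``.

    ``exempt`` columns (clinical covariates, labels) bypass the manifest.
    Every non-exempt column must appear in the manifest.
    """
    exempt = set(exempt)
    feature_cols = [c for c in table.columns if c not in exempt]
    missing = [c for c in feature_cols if c not in icc.index]
    if missing:
        raise KeyError(f"ICC manifest lacks entries for: {missing}")
    dropped = [c for c in feature_cols if icc[c] < cutoff]
    return table.drop(columns=dropped)


# ---------------------------------------------------------------------------
# stage 2: redundancy with conventional features
# ---------------------------------------------------------------------------


def drop_conventional_redundant(
    table: pd.DataFrame,
    conventional_names,
    rho: float = 0.8,
    exempt=(),
) -> pd.DataFrame:
    """Drop radiomic columns with |Pearson r| > rho against any conventional one.

    Conventional features themselves are always retained; zero-variance
    columns have undefined correlation and are retained with a warning.
    """
    conventional = [c for c in conventional_names if c in table.columns]
    exempt = set(exempt) | set(conventional)
    candidates = [c for c in table.columns if c not in exempt]
    if not conventional or not candidates:
        return table
    X = table[candidates].to_numpy(dtype=np.float64)
    C = table[conventional].to_numpy(dtype=np.float64)
    sx = X.std(axis=0)
    sc = C.std(axis=0)
    flat = [c for c, s in zip(candidates, sx) if s == 0]
    if flat:
        warnings.warn(
            f"zero-variance features retained (correlation undefined): {flat}", stacklevel=2
        )
    Xc = X - X.mean(axis=0)
    Cc = C - C.mean(axis=0)
    denom = np.outer(sx, sc) * len(table)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(Xc.T @ Cc) / np.where(denom > 0, denom, np.inf)
    dropped = [c for c, row in zip(candidates, corr) if np.any(row > rho)]
    return table.drop(columns=dropped)


# ---------------------------------------------------------------------------
# stage 3a: PCA
# ---------------------------------------------------------------------------


@dataclass
class PCABasis:
    """Training-fitted principal-component basis retaining > 95% variance."""

    mean: np.ndarray
    components: np.ndarray  # (n_retained, n_features)
    explained_variance_ratio: np.ndarray
    n_retained: int
    feature_names: list[str]

    @property
    def retained_variance(self) -> float:
        return float(self.explained_variance_ratio[: self.n_retained].sum())


def fit_pca(train_table: pd.DataFrame, variance_threshold: float = 0.95) -> PCABasis:
    """Fit PCA on training rows; keep the minimal leading set with
    cumulative explained variance strictly above the threshold."""
    if len(train_table) < 2:
        raise ValueError("PCA needs at least 2 training samples")
    X = train_table.to_numpy(dtype=np.float64)
    pca = PCA(svd_solver="full", random_state=0)
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_retained = int(np.searchsorted(cum, variance_threshold, side="right")) + 1
    n_retained = min(n_retained, len(cum))
    return PCABasis(
        mean=pca.mean_,
        components=pca.components_[:n_retained],
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_retained=n_retained,
        feature_names=list(train_table.columns),
    )


def project(basis: PCABasis, table: pd.DataFrame) -> pd.DataFrame:
    """Project any table onto the training basis; columns become pc1..pcK."""
    X = table[basis.feature_names].to_numpy(dtype=np.float64)
    Z = (X - basis.mean) @ basis.components.T
    cols = [f"pc{k + 1}" for k in range(basis.n_retained)]
    return pd.DataFrame(Z, index=table.index, columns=cols)


# ---------------------------------------------------------------------------
# stage 3b: univariable filters
# ---------------------------------------------------------------------------


@dataclass
class FilterRanking:
    """Complete descending ordering of features with scores."""

    method: str
    scores: pd.Series  # index = feature names, sorted

    @property
    def ordered_names(self) -> list[str]:
        return list(self.scores.index)

    def top(self, k: int | None) -> list[str]:
        return self.ordered_names if k is None else self.ordered_names[: k]


def _logistic_scores(X, y, n_iter: int = 40):
    """Univariable |Wald z| from single-feature logistic fits.

    All features are fitted at once by vectorized Newton-Raphson on the
    2-parameter (intercept, slope) problems.  Perfect separation drives the
    Wald statistic to infinity; such features score ``inf`` and sort first.
    """
    n, d = X.shape
    sd = X.std(axis=0)
    flat = sd == 0
    Xs = (X - X.mean(axis=0)) / np.where(flat, 1.0, sd)
    sep = np.empty(d, dtype=bool)
    pos, neg = Xs[y == 1], Xs[y == 0]
    sep = (pos.min(axis=0) > neg.max(axis=0)) | (pos.max(axis=0) < neg.min(axis=0))

    b0 = np.zeros(d)
    b1 = np.zeros(d)
    yv = y.astype(np.float64)[:, None]
    for _ in range(n_iter):
        eta = b0 + Xs * b1
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        r = yv - p
        g0 = r.sum(axis=0)
        g1 = (Xs * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * Xs).sum(axis=0)
        h11 = (w * Xs**2).sum(axis=0)
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-12, np.inf, det)
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (h00 * g1 - h01 * g0) / det
        b0 += np.clip(step0, -5, 5)
        b1 += np.clip(step1, -5, 5)
    eta = b0 + Xs * b1
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = p * (1.0 - p)
    h00 = w.sum(axis=0)
    h01 = (w * Xs).sum(axis=0)
    h11 = (w * Xs**2).sum(axis=0)
    det = h00 * h11 - h01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = h00 / det
        z = np.abs(b1) / np.sqrt(var_b1)
    z = np.nan_to_num(z, nan=np.inf, posinf=np.inf)
    z[sep] = np.inf
    z[flat] = 0.0
    return z


def _fisher_scores(X, y):
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in (0, 1):
        Xi = X[y == c]
        num += len(Xi) * (Xi.mean(axis=0) - mu) ** 2
        den += len(Xi) * Xi.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return s


def _t_scores(X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, _ = stats.ttest_ind(X[y == 1], X[y == 0], equal_var=False)
    return np.nan_to_num(np.abs(t), nan=0.0, posinf=np.inf)


def _relief_scores(X, y, n_neighbors: int = 5):
    """ReliefF for binary labels with k nearest hits/misses.

    Feature differences are range-normalized; scores accumulate
    miss-distance minus hit-distance over every sample.
    """
    n, d = X.shape
    rng_span = np.ptp(X, axis=0)
    span = np.where(rng_span > 0, rng_span, 1.0)
    Xn = X / span
    scores = np.zeros(d)
    dist = np.abs(Xn[:, None, :] - Xn[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    for i in range(n):
        for cls, sign in ((y[i], -1.0), (1 - y[i], 1.0)):
            idx = np.where(y == cls)[0]
            idx = idx[idx != i]
            if idx.size == 0:
                continue
            k = min(n_neighbors, idx.size)
            nearest = idx[np.argsort(dist[i, idx], kind="stable")[:k]]
            scores += sign * np.abs(Xn[nearest] - Xn[i]).mean(axis=0)
    scores[rng_span == 0] = 0.0
    return scores / n


def _gini_scores(X, y):
    """Best single-threshold Gini-impurity decrease per feature."""
    n = len(y)
    p = y.mean()
    parent = 2 * p * (1 - p)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        x = X[:, j]
        if np.ptp(x) == 0:
            continue
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        cum_pos = np.cumsum(ys)
        nl = np.arange(1, n)  # split after position nl-1
        valid = xs[1:] != xs[:-1]
        if not valid.any():
            continue
        pos_l = cum_pos[:-1]
        nr = n - nl
        pos_r = cum_pos[-1] - pos_l
        pl = pos_l / nl
        pr = pos_r / nr
        child = (nl / n) * 2 * pl * (1 - pl) + (nr / n) * 2 * pr * (1 - pr)
        scores[j] = np.max((parent - child)[valid])
    return scores


def rank_features(
    table: pd.DataFrame,
    labels,
    method: str,
    n_neighbors: int = 5,
) -> FilterRanking:
    """Rank all columns by one of the six univariable filters.

    Scores sort descending; ties (including the all-zero scores of
    label-independent constant features) break lexicographically by name.
    """
    if method not in FILTER_METHODS:
        raise ValueError(f"unknown filter {method!r}")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to rank features")
    X = table.to_numpy(dtype=np.float64)
    if method == "logistic":
        s = _logistic_scores(X, y)
    elif method == "anova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s, _ = f_classif(X, y)
        s = np.nan_to_num(s, nan=0.0, posinf=np.inf)
    elif method == "fisher":
        s = _fisher_scores(X, y)
    elif method == "relief":
        s = _relief_scores(X, y, n_neighbors=n_neighbors)
    elif method == "t_score":
        s = _t_scores(X, y)
    else:
        s = _gini_scores(X, y)
    ser = pd.Series(s, index=table.columns, name=method)
    ser = ser.iloc[np.lexsort((ser.index.to_numpy(), -ser.to_numpy()))]
    return FilterRanking(method=method, scores=ser)


# ---------------------------------------------------------------------------
# stage 4: LASSO
# ---------------------------------------------------------------------------


def lasso_select(table: pd.DataFrame, labels, lam: float = 1.0) -> list[str]:
    """Support of an L1-penalized logistic model at penalty ``lam``.

    ``lam`` multiplies the L1 norm (so larger means sparser); the support is
    the set of features with nonzero coefficients, in column order.
    """
    if lam <= 0:
        raise ValueError(f"lasso penalty must be positive, got {lam}")
    y = np.asarray(labels, dtype=int)
    lr = LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="liblinear", max_iter=1000, random_state=0
    )
    lr.fit(table.to_numpy(dtype=np.float64), y)
    keep = np.abs(lr.coef_[0]) > 0
    return [c for c, k in zip(table.columns, keep) if k]


# ---------------------------------------------------------------------------
# clinical encoding
# ---------------------------------------------------------------------------

_T_STAGE_CODES = {1: 1, 2: 2, 3: 3, 4: 4, "1": 1, "2": 2, "3": 3, "4a": 4, "4": 4}


def encode_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Encode clinical covariates numerically.

    Histology becomes a binary adenocarcinoma indicator; clinical T-stage
    (T4a coded 4) and N-stage stay integer ordinals, preserving order.
    """
    out = table.copy()
    if "histology" in out.columns:
        out["histology_adeno"] = (out.pop("histology") == "adenocarcinoma").astype(int)
    if "t_stage" in out.columns:
        out["t_stage"] = out["t_stage"].map(_T_STAGE_CODES).astype(int)
    if "n_stage" in out.columns:
        out["n_stage"] = out["n_stage"].astype(int)
    return out
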