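"""Skewness-branched feature normalization.

Each continuous feature is normalized with constants estimated on the
training rows only:

* approximately symmetric features (moment skewness g1 in [-0.5, 0.5],
  boundary inclusive) are *robustly* scaled — subtract the training median,
  divide by the training interquartile range;
* skewed features (|g1| > 0.5) get a Yeo-Johnson power transformation with
  the maximum-likelihood lambda, then are standardized to training mean 0 /
  SD 1 so both branches land on comparable scales for PCA and penalized
  models.

The fitted :class:`NormalizationPlan` records every constant and serializes
to JSON for audit; applying a plan to new (test) rows touches no test-row
statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "sample_skewness",
    "yeo_johnson",
    "NormalizationPlan",
    "FeatureNorm",
    "fit_plan",
    "apply_plan",
    "SkewAdaptiveNormalizer",
]

SKEW_BOUNDARY = 0.5


def sample_skewness(values) -> float:
    """Fisher-Pearson moment coefficient g1 = m3 / m2^(3/2).

    Zero-variance samples are declared symmetric (skewness 0) with a warning.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ValueError(f"skewness needs at least 3 values, got {x.size}")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 <= 0:
        warnings.warn("zero-variance sample: skewness declared 0", stacklevel=2)
        return 0.0
    m3 = np.mean((x - m) ** 3)
    return float(m3 / m2**1.5)


def yeo_johnson(x, lam: float) -> np.ndarray:
    """Yeo-Johnson transform with parameter ``lam`` (two-branch formula).

    x >= 0: ((x+1)^lam - 1)/lam, or log(x+1) at lam = 0;
    x < 0:  -(((-x+1)^(2-lam) - 1)/(2-lam)), or -log(-x+1) at lam = 2.
    Strictly monotone for every lam; x = 0 maps to 0 for any lam.
    """
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lam) < 1e-12:
        out[pos] = np.log1p(x[pos])
    else:
        out[pos] = (np.power(x[pos] + 1.0, lam) - 1.0) / lam
    if abs(lam - 2.0) < 1e-12:
        out[~pos] = -np.log1p(-x[~pos])
    else:
        out[~pos] = -(np.power(-x[~pos] + 1.0, 2.0 - lam) - 1.0) / (2.0 - lam)
    return out


@dataclass
class FeatureNorm:
    """Training constants for one feature."""

    branch: str  # "robust" | "yeo_johnson" | "identity"
    skewness: float = 0.0
    median: float = 0.0
    iqr: float = 1.0
    lam: float = 1.0
    mean: float = 0.0
    sd: float = 1.0

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.branch == "robust":
            return (x - self.median) / self.iqr
        if self.branch == "yeo_johnson":
            return (yeo_johnson(x, self.lam) - self.mean) / self.sd
        return x.astype(np.float64)


@dataclass
class NormalizationPlan:
    """Per-feature normalization constants, estimated on training rows only."""

    features: dict[str, FeatureNorm] = field(default_factory=dict)
    passthrough: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.features) + list(self.passthrough)

    def to_json(self, path) -> None:
        payload = {
            "passthrough": self.passthrough,
            "features": {k: vars(v) for k, v in self.features.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "NormalizationPlan":
        raw = json.loads(Path(path).read_text())
        return cls(
            features={k: FeatureNorm(**v) for k, v in raw["features"].items()},
            passthrough=list(raw["passthrough"]),
        )


def _fit_feature(x: np.ndarray, name: str) -> FeatureNorm:
    if np.ptp(x) == 0:
        warnings.warn(f"{name}: constant on training rows, identity transform", stacklevel=3)
        return FeatureNorm(branch="identity")
    g1 = sample_skewness(x)
    if abs(g1) <= SKEW_BOUNDARY:
        med = float(np.median(x))
        q75, q25 = np.percentile(x, [75, 25])
        iqr = float(q75 - q25)
        if iqr <= 0:
            warnings.warn(f"{name}: zero IQR, centering with unit scale", stacklevel=3)
            iqr = 1.0
        return FeatureNorm(branch="robust", skewness=g1, median=med, iqr=iqr)
    lam = float(stats.yeojohnson_normmax(x))
    z = yeo_johnson(x, lam)
    sd = float(z.std())
    return FeatureNorm(
        branch="yeo_johnson",
        skewness=g1,
        lam=lam,
        mean=float(z.mean()),
        sd=sd if sd > 0 else 1.0,
    )


def fit_plan(train_table: pd.DataFrame, passthrough=()) -> NormalizationPlan:
    """Fit the skew-branched plan on the training table.

    ``passthrough`` columns (ordinal clinical codes, labels) are recorded but
    left untouched by :func:`apply_plan`.
    """
    passthrough = [c for c in passthrough if c in train_table.columns]
    feats = {}
    for col in train_table.columns:
        if col in passthrough:
            continue
        feats[col] = _fit_feature(train_table[col].to_numpy(dtype=np.float64), col)
    return NormalizationPlan(features=feats, passthrough=passthrough)


def apply_plan(plan: NormalizationPlan, table: pd.DataFrame) -> pd.DataFrame:
    """Apply training constants to any table (train or test rows)."""
    unseen = [c for c in table.columns if c not in plan.features and c not in plan.passthrough]
    if unseen:
        raise KeyError(f"columns not covered by the normalization plan: {unseen}")
    out = table.copy()
    for col, norm in plan.features.items():
        if col in out.columns:
            out[col] = norm.transform(out[col].to_numpy(dtype=np.float64))
    return out


class SkewAdaptiveNormalizer:
    """Thin fit/transform wrapper around :func:`fit_plan` / :func:`apply_plan`."""

    def __init__(self, passthrough=()):
        self.passthrough = tuple(passthrough)
        self.plan_: NormalizationPlan | None = None

    def fit(self, table: pd.DataFrame, y=None) -> "SkewAdaptiveNormalizer":
        self.plan_ = fit_plan(table, passthrough=self.passthrough)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.plan_ is None:
            raise RuntimeError("normalizer is not fitted")
        return apply_plan(self.plan_, table)

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table).transform(table)
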