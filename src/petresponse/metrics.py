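"""Precision-recall and ROC evaluation for imbalanced binary prediction.

Average precision (AP) — the step-summed area under the precision-recall
curve — is the pipeline's selection and reporting metric: for a chance
classifier its expectation equals the positive-class prevalence, so any AP
above the prevalence of non-responders carries signal.  ROC AUC is reported
alongside; ties in the scores are handled by grouping tied values into one
threshold (AP) and by the midrank convention (AUC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve as _sk_roc_curve,
)

__all__ = [
    "ap_score",
    "roc_auc",
    "baseline_ap",
    "pr_curve",
    "roc_curve",
    "EvaluationReport",
    "evaluate_scores",
    "plot_report",
    "plot_learning_curve",
]


def _check(labels, scores=None):
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty label vector")
    if scores is not None:
        s = np.asarray(scores, dtype=np.float64)
        if s.shape != y.shape:
            raise ValueError(f"labels {y.shape} and scores {s.shape} differ in shape")
        if y.min() == y.max():
            raise ValueError("both classes must be present to score a ranking")
        return y, s
    return y


def ap_score(labels, scores) -> float:
    """Average precision: sum_k (R_k - R_{k-1}) P_k over descending unique scores."""
    y, s = _check(labels, scores)
    return float(average_precision_score(y, s))


def roc_auc(labels, scores) -> float:
    """Trapezoidal area under the ROC curve (midrank tie convention)."""
    y, s = _check(labels, scores)
    return float(roc_auc_score(y, s))


def baseline_ap(labels) -> float:
    """Chance-level AP = positive fraction of the labels."""
    y = _check(labels)
    return float(y.mean())


def pr_curve(labels, scores) -> list[tuple[float, float]]:
    """(recall, precision) points ordered by increasing recall."""
    y, s = _check(labels, scores)
    precision, recall, _ = precision_recall_curve(y, s)
    pts = sorted(zip(recall.tolist(), precision.tolist()))
    return [(float(r), float(p)) for r, p in pts]


def roc_curve(labels, scores) -> list[tuple[float, float]]:
    """(false positive rate, true positive rate) points, increasing FPR."""
    y, s = _check(labels, scores)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return [(float(f), float(t)) for f, t in zip(fpr, tpr)]


@dataclass
class EvaluationReport:
    """Held-out evaluation of one model or ensemble."""

    ap: float
    auc: float
    baseline_ap: float
    n_test: int
    n_positive: int
    pr_curve: list[tuple[float, float]] = field(default_factory=list)
    roc_curve: list[tuple[float, float]] = field(default_factory=list)

    def to_json(self, path=None):
        payload = {
            "ap": self.ap,
            "auc": self.auc,
            "baseline_ap": self.baseline_ap,
            "n_test": self.n_test,
            "n_positive": self.n_positive,
            "pr_curve": [list(p) for p in self.pr_curve],
            "roc_curve": [list(p) for p in self.roc_curve],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EvaluationReport":
        raw = json.loads(Path(source).read_text() if Path(str(source)).exists() else source)
        return cls(
            ap=raw["ap"],
            auc=raw["auc"],
            baseline_ap=raw["baseline_ap"],
            n_test=raw["n_test"],
            n_positive=raw["n_positive"],
            pr_curve=[tuple(p) for p in raw["pr_curve"]],
            roc_curve=[tuple(p) for p in raw["roc_curve"]],
        )


def plot_report(report: EvaluationReport, path_prefix) -> list[Path]:
    """Write precision-recall and ROC curve figures for one report.

    The PR panel shows the chance baseline (test prevalence) as a dashed
    line; returns the paths written (``<prefix>_pr.png``, ``<prefix>_roc.png``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = Path(path_prefix)
    out = []

    fig, ax = plt.subplots(figsize=(4.5, 4))
    r, p = zip(*report.pr_curve) if report.pr_curve else ([], [])
    ax.step(r, p, where="post", label=f"AP = {report.ap:.2f}")
    ax.axhline(report.baseline_ap, ls="--", c="k",
               label=f"chance ({report.baseline_ap:.2f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    out.append(prefix.with_name(prefix.name + "_pr.png"))
    fig.savefig(out[-1], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    f, t = zip(*report.roc_curve) if report.roc_curve else ([], [])
    ax.plot(f, t, label=f"AUC = {report.auc:.2f}")
    ax.plot([0, 1], [0, 1], ls="--", c="k")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    out.append(prefix.with_name(prefix.name + "_roc.png"))
    fig.savefig(out[-1], dpi=120)
    plt.close(fig)
    return out


def plot_learning_curve(curve, path) -> Path:
    """Plot training and validation AP against training-set size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(curve["n"], curve["train_ap"], yerr=curve["train_ap_sd"],
                marker="o", label="train AP")
    ax.errorbar(curve["n"], curve["val_ap"], yerr=curve["val_ap_sd"],
                marker="s", label="validation AP")
    ax.set_xlabel("training samples")
    ax.set_ylabel("average precision")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def evaluate_scores(labels, scores) -> EvaluationReport:
    """Full report (AP, AUC, baseline, curves) for one score vector."""
    y, s = _check(labels, scores)
    return EvaluationReport(
        ap=ap_score(y, s),
        auc=roc_auc(y, s),
        baseline_ap=baseline_ap(y),
        n_test=int(y.size),
        n_positive=int(y.sum()),
        pr_curve=pr_curve(y, s),
        roc_curve=roc_curve(y, s),
    )
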