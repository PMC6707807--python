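"""Model evaluation: error metrics, ROC/AUC at a responder cutoff, and
per-cancer model comparison.

Cancer types are labelled responders when their true ORR meets a cutoff
(0.2 by default, inclusive); the AUC is the Mann–Whitney probability that
a responder's predicted score exceeds a non-responder's, with ties
counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screening import spearman

__all__ = [
    "EvaluationReport",
    "error_metrics",
    "roc_auc",
    "evaluate",
    "compare_models",
]

DEFAULT_RESPONDER_CUTOFF = 0.2


def error_metrics(true_orr: Sequence[float], predicted_orr: Sequence[float]
                  ) -> tuple[float, float, float]:
    """(MAE, RMSE, Spearman rho) of predictions against truth."""
    t = np.asarray(true_orr, float)
    p = np.asarray(predicted_orr, float)
    if t.shape != p.shape:
        raise ValueError("true and predicted vectors differ in length")
    if len(t) < 2:
        raise ValueError("need ≥2 pairs")
    diff = p - t
    mae = float(np.abs(diff).mean())
    rmse = float(np.sqrt((diff**2).mean()))
    rho, _ = spearman(t, p)
    return mae, rmse, rho


def roc_auc(
    true_orr: Sequence[float],
    scores: Sequence[float],
    cutoff: float = DEFAULT_RESPONDER_CUTOFF,
) -> tuple[float, pd.DataFrame]:
    """AUC and ROC points for responder labels derived from true ORR.

    Labels: true ORR ≥ ``cutoff`` → positive (inclusive).  AUC is computed
    by the rank (Mann–Whitney) formula — the probability that a random
    positive scores above a random negative, ties counting ½ — and the ROC
    points are swept over every distinct score threshold.
    """
    t = np.asarray(true_orr, float)
    s = np.asarray(scores, float)
    if t.shape != s.shape:
        raise ValueError("true and score vectors differ in length")
    labels = t >= cutoff
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"single-class labels at cutoff {cutoff}; AUC undefined")
    ranks = stats.rankdata(s)
    auc = float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))

    points = [(0.0, 0.0)]
    for threshold in np.unique(s)[::-1]:
        called = s >= threshold
        tpr = float((called & labels).sum() / n_pos)
        fpr = float((called & ~labels).sum() / n_neg)
        points.append((fpr, tpr))
    points.append((1.0, 1.0))
    roc = pd.DataFrame(points, columns=["fpr", "tpr"]).drop_duplicates()
    return auc, roc.reset_index(drop=True)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-model evaluation bundle over a fixed cancer set."""

    mae: float
    rmse: float
    spearman_rho: float
    auc: float
    per_cancer_diff: pd.Series  # predicted − true
    cutoff: float = DEFAULT_RESPONDER_CUTOFF
    roc_points: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "spearman_rho": self.spearman_rho,
            "auc": self.auc,
            "cutoff": self.cutoff,
            "per_cancer_diff": self.per_cancer_diff.to_dict(),
        }


def evaluate(
    true_orr: pd.Series,
    predicted_orr: pd.Series,
    cutoff: float = DEFAULT_RESPONDER_CUTOFF,
) -> EvaluationReport:
    """Full report: error metrics, AUC at the responder cutoff, per-cancer
    differences (predicted − true)."""
    if set(true_orr.index) != set(predicted_orr.index):
        raise ValueError("true and predicted ORR cover different cancer sets")
    pred = predicted_orr.loc[true_orr.index]
    mae, rmse, rho = error_metrics(true_orr.to_numpy(), pred.to_numpy())
    auc, roc = roc_auc(true_orr.to_numpy(), pred.to_numpy(), cutoff)
    diff = (pred - true_orr).rename("diff")
    return EvaluationReport(mae, rmse, rho, auc, diff, cutoff, roc)


def compare_models(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Side-by-side metric table for ≥2 models over the same cancer set.

    Adds a per-cancer ``winner`` table attribute: the model with the
    smaller |predicted − true| wins that cancer type; exact ties are
    reported as 'tie'.
    """
    if len(reports) < 2:
        raise ValueError("need ≥2 reports to compare")
    names = list(reports)
    cancer_sets = [set(r.per_cancer_diff.index) for r in reports.values()]
    if any(s != cancer_sets[0] for s in cancer_sets):
        raise ValueError("reports cover different cancer sets")

    metrics = pd.DataFrame(
        {
            name: {
                "mae": r.mae,
                "rmse": r.rmse,
                "spearman_rho": r.spearman_rho,
                "auc": r.auc,
            }
            for name, r in reports.items()
        }
    )
    diffs = pd.DataFrame({name: r.per_cancer_diff.abs() for name, r in reports.items()})
    winner = diffs.idxmin(axis=1)
    tied = diffs.min(axis=1).to_numpy()[:, None] == diffs.to_numpy()
    winner[tied.sum(axis=1) > 1] = "tie"
    metrics.attrs["winner"] = winner.rename("winner")
    metrics.attrs["winner_counts"] = winner.value_counts().to_dict()
    return metrics
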