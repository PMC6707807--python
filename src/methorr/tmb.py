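"""Tumor mutational burden (TMB) and the log-linear TMB → ORR model.

Per-patient TMB is the missense-mutation count divided by a 38 Mb exome
estimate (mutations per megabase); a cancer type is summarised by its
cohort median.  Cohort median TMB relates to the objective response rate
through a log-linear model, ORR = a·ln(X) + b; the shipped literature
constants are a = 0.0768, b = 0.1313, and the same form can be refit on
any cohort's own medians by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TmbSummary",
    "TmbOrrModel",
    "PUBLISHED_TMB_ORR_MODEL",
    "compute_tmb",
    "predict_orr_from_tmb",
    "fit_tmb_orr",
]

DEFAULT_EXOME_SIZE_MB = 38.0
DEFAULT_COUNTED_CLASSES = frozenset({"Missense_Mutation"})


@dataclass(frozen=True)
class TmbSummary:
    """Per-sample TMB (mutations/Mb) and the cohort median."""

    per_sample_tmb: pd.Series
    median_tmb: float
    exome_size_mb: float = DEFAULT_EXOME_SIZE_MB


@dataclass(frozen=True)
class TmbOrrModel:
    """ORR = slope·ln(median TMB) + intercept."""

    slope: float
    intercept: float


#: The literature log-linear TMB → ORR relation.
PUBLISHED_TMB_ORR_MODEL = TmbOrrModel(slope=0.0768, intercept=0.1313)


@dataclass(frozen=True)
class TmbOrrPrediction:
    value: float
    out_of_range: bool

    def __float__(self) -> float:
        return self.value


def compute_tmb(
    mutations: pd.DataFrame,
    exome_size_mb: float = DEFAULT_EXOME_SIZE_MB,
    classes: Iterable[str] = DEFAULT_COUNTED_CLASSES,
) -> TmbSummary:
    """Per-sample TMB from a tidy mutation table.

    Counts records whose ``variant_classification`` is in ``classes``
    (missense only by default) per ``sample_id`` and divides by the exome
    size.  Samples present in the table but without qualifying mutations
    get TMB 0; samples absent from the table are unknown, not zero.
    """
    if exome_size_mb <= 0:
        raise ValueError(f"exome_size_mb must be > 0, got {exome_size_mb}")
    if len(mutations) == 0:
        raise ValueError("mutation table is empty")
    classes = set(classes)
    census = pd.Index(mutations["sample_id"].unique(), name="sample_id")
    qualifying = mutations[mutations["variant_classification"].isin(classes)]
    counts = qualifying.groupby("sample_id").size().reindex(census, fill_value=0)
    per_sample = (counts / exome_size_mb).astype(float).rename("tmb")
    return TmbSummary(per_sample, float(per_sample.median()), float(exome_size_mb))


def predict_orr_from_tmb(model: TmbOrrModel, median_tmb: float) -> TmbOrrPrediction:
    """Evaluate ORR = slope·ln(X) + intercept at a cohort median TMB X.

    X must be strictly positive; for cohorts with median 0, add a
    pseudocount to the mutation counts (e.g. 0.5/exome_size_mb) before
    calling, rather than silently shifting here.
    """
    if median_tmb <= 0:
        raise ValueError(
            f"median_tmb must be > 0 (got {median_tmb}); ln is undefined at 0 — "
            "consider a pseudocount policy upstream"
        )
    value = model.slope * float(np.log(median_tmb)) + model.intercept
    return TmbOrrPrediction(float(value), not (0.0 <= value <= 1.0))


def fit_tmb_orr(median_tmbs: Mapping[str, float] | pd.Series, orr: pd.Series) -> TmbOrrModel:
    """Refit ORR = a·ln(median TMB) + b by ordinary least squares.

    ``median_tmbs`` maps cancer code → cohort median TMB; codes must match
    the ORR table, all medians strictly positive, at least 3 cancer types.
    """
    medians = pd.Series(median_tmbs, dtype=float)
    if set(medians.index) != set(orr.index):
        raise ValueError("cancer codes of medians and ORR table do not match")
    if len(medians) < 3:
        raise ValueError(f"need ≥3 cancer types, got {len(medians)}")
    if (medians <= 0).any():
        bad = medians.index[medians <= 0].tolist()
        raise ValueError(
            f"median TMB must be > 0 for a log fit; offending types: {bad} "
            "(configure a pseudocount upstream)"
        )
    x = np.log(medians.to_numpy())
    y = orr.loc[medians.index].to_numpy(dtype=float)
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return TmbOrrModel(float(slope), float(intercept))
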