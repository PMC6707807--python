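"""CpG-based objective-response-rate (ORR) prediction by Lasso regression.

The model is an L1-penalised linear regression of per-cancer ORR on the
cancer-type mean β values of pre-screened CpG probes:

    y = α + Σ_j β_j x_j,   with Σ_j |β_j| constrained (λ),

fit with 10-fold cross-validation to pick the λ minimising the mean squared
error.  With only ~18 regression rows the Lasso's sparsity is doing the real
work: it reduces hundreds of screened probes to a handful with nonzero
coefficients.  Predictors are standardised to unit variance internally and
the reported coefficients are back-transformed to the raw β scale, so they
are directly comparable to the shipped published equation.

Generalisation is assessed by leave-one-cancer-type-out cross-validation in
which (by default) the CpG screen itself is re-run inside every fold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV

from .screening import spearman, spearman_screen

logger = logging.getLogger(__name__)

__all__ = [
    "OrrLassoModel",
    "OrrPrediction",
    "LoocvResult",
    "fit_lasso",
    "predict_orr",
    "predict_cohort",
    "loocv",
    "save_model",
    "load_model",
]

#: Coefficients with |value| below this are treated as exactly zero.
COEF_ZERO_TOL = 1e-10


@dataclass(frozen=True)
class OrrLassoModel:
    """Sparse linear ORR model: intercept + probe-coefficient map.

    ``coefficients`` holds the model's support; fitted models store only
    nonzero entries, while the shipped published model retains one probe
    whose printed coefficient is illegible (stored as 0.0).
    """

    intercept: float
    coefficients: dict[str, float]
    lambda_: float | None = None
    cv_mse: float | None = None
    training_meta: dict = field(default_factory=dict)

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


@dataclass(frozen=True)
class OrrPrediction:
    value: float
    out_of_range: bool

    def __float__(self) -> float:
        return self.value


def _seeded_folds(n: int, cv_folds: int, seed: int | None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold index pairs derived from the seed, independent of row order
    (rows are pre-sorted by cancer code before this is called)."""
    k = min(cv_folds, n)
    if k < n and k != cv_folds:
        logger.info("reducing cv folds from %d to %d (only %d rows)", cv_folds, k, n)
    if k >= n:
        k = n  # leave-one-out
        if cv_folds > n:
            logger.info("cv_folds=%d > %d rows; using leave-one-out", cv_folds, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.arange(n) % k
    folds = []
    for fold in range(k):
        test = np.flatnonzero(assignment == fold)
        train = np.flatnonzero(assignment != fold)
        folds.append((train, test))
    return folds


def fit_lasso(
    profiles: pd.DataFrame,
    orr: pd.Series,
    cv_folds: int = 10,
    seed: int | None = 0,
    lambda_: float | None = None,
) -> OrrLassoModel:
    """Fit the Lasso ORR model on cancer-type mean-β profiles.

    Parameters
    ----------
    profiles
        Probes × cancer-types mean-β table, already restricted to the
        screened probes.
    orr
        Cancer-code → ORR; codes must match ``profiles`` columns.
    cv_folds
        Cross-validation folds for λ selection (reduced towards
        leave-one-out when there are fewer rows than folds).
    seed
        Governs fold assignment; the fit is deterministic given the seed
        and invariant to the input row/column order.
    lambda_
        When given, skip cross-validation and fit at this fixed penalty
        (``math.inf`` yields the intercept-only model).

    The λ reported is scikit-learn's ``alpha`` (the penalty weight in
    (1/2n)·RSS + λ·Σ|β_j|); ``cv_mse`` is the minimum cross-validated MSE.
    """
    codes = sorted(profiles.columns)
    if len(codes) < 3:
        raise ValueError(f"need ≥3 cancer types to fit, got {len(codes)}")
    if set(codes) != set(orr.index):
        raise ValueError("cancer codes of profiles and ORR table do not match")
    probes = sorted(profiles.index)
    X = profiles.loc[probes, codes].to_numpy(dtype=float).T  # rows = cancer types
    y = orr.loc[codes].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("profiles contain missing values; drop or impute first")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    kept_probes = [p for p, k in zip(probes, keep) if k]

    meta = {"cancer_codes": codes, "n_probes_offered": len(probes)}
    if lambda_ is not None and not math.isfinite(lambda_):
        return OrrLassoModel(float(y.mean()), {}, lambda_=lambda_, cv_mse=None,
                             training_meta=meta)
    if Xs.shape[1] == 0:
        return OrrLassoModel(float(y.mean()), {}, lambda_=lambda_, cv_mse=None,
                             training_meta=meta)

    if lambda_ is not None:
        est = Lasso(alpha=lambda_, max_iter=1_000_000, tol=1e-12).fit(Xs, y)
        alpha, cv_mse = float(lambda_), None
    else:
        folds = _seeded_folds(len(codes), cv_folds, seed)
        est = LassoCV(cv=folds, alphas=100, max_iter=100_000).fit(Xs, y)
        alpha = float(est.alpha_)
        cv_mse = float(est.mse_path_.mean(axis=1).min())

    coef_std = est.coef_
    coefficients: dict[str, float] = {}
    intercept = float(est.intercept_)
    for probe, c, m, s in zip(kept_probes, coef_std, mean[keep], sd[keep]):
        if abs(c) > COEF_ZERO_TOL:
            b = c / s
            coefficients[probe] = float(b)
            intercept -= float(b * m)
    return OrrLassoModel(intercept, coefficients, lambda_=alpha, cv_mse=cv_mse,
                         training_meta=meta)


def predict_orr(model: OrrLassoModel, beta_vector: Mapping[str, float]) -> OrrPrediction:
    """Apply the linear model to a probe → β map.

    Every probe of the model's support must be supplied; the prediction is
    returned unclipped with an out-of-range flag when outside [0, 1].
    """
    missing = [p for p in model.support if p not in beta_vector]
    if missing:
        raise KeyError(f"beta vector lacks model probes: {missing}")
    value = model.intercept + sum(
        coef * float(beta_vector[probe]) for probe, coef in model.coefficients.items()
    )
    return OrrPrediction(float(value), not (0.0 <= value <= 1.0))


def predict_cohort(model: OrrLassoModel, beta: pd.DataFrame) -> OrrPrediction:
    """Predict a cohort-level ORR from a probes × samples β matrix.

    The cohort is summarised first (per-probe mean β across samples,
    missing values skipped) and the linear model applied to that summary.
    """
    missing = [p for p in model.support if p not in beta.index]
    if missing:
        raise KeyError(f"cohort matrix lacks model probes: {missing}")
    means = beta.loc[list(model.support)].mean(axis=1, skipna=True)
    return predict_orr(model, means.to_dict())


# ---------------------------------------------------------------------------
# Leave-one-cancer-type-out cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoocvResult:
    """Held-out predictions per cancer type plus their rank agreement."""

    pairs: pd.DataFrame  # index cancer_code; columns true, predicted, fallback
    rho: float
    p_value: float


def loocv(
    profiles: pd.DataFrame,
    orr: pd.Series,
    rho_threshold: float = 0.7,
    p_threshold: float = 0.001,
    cv_folds: int = 10,
    seed: int | None = 0,
    rescreen: bool = True,
) -> LoocvResult:
    """Leave-one-cancer-type-out validation of the screen+Lasso pipeline.

    For each cancer type: screen probes on the remaining types (or reuse a
    single global screen when ``rescreen=False``), fit the Lasso on them,
    and predict the held-out type.  Folds where the screen returns no probe
    fall back to the training-mean ORR and are flagged.
    """
    codes = list(profiles.columns)
    if len(codes) < 4:
        raise ValueError(f"need ≥4 cancer types for leave-one-out, got {len(codes)}")
    if set(codes) != set(orr.index):
        raise ValueError("cancer codes of profiles and ORR table do not match")

    global_probes: pd.Index | None = None
    if not rescreen:
        screen = spearman_screen(profiles, orr, rho_threshold, p_threshold)
        global_probes = screen.index[screen["passes"]]

    records = []
    for held_out in codes:
        train_profiles = profiles.drop(columns=held_out)
        train_orr = orr.drop(held_out)
        if rescreen:
            screen = spearman_screen(train_profiles, train_orr, rho_threshold, p_threshold)
            selected = screen.index[screen["passes"]]
        else:
            selected = global_probes
        if len(selected) == 0:
            records.append((held_out, float(orr[held_out]), float(train_orr.mean()), True))
            continue
        model = fit_lasso(train_profiles.loc[selected], train_orr,
                          cv_folds=cv_folds, seed=seed)
        pred = predict_orr(model, profiles[held_out].to_dict())
        records.append((held_out, float(orr[held_out]), pred.value, False))

    pairs = pd.DataFrame(records, columns=["cancer_code", "true", "predicted", "fallback"])
    pairs = pairs.set_index("cancer_code")
    rho, p = spearman(pairs["true"].to_numpy(), pairs["predicted"].to_numpy())
    return LoocvResult(pairs, rho, p)


# ---------------------------------------------------------------------------
# JSON (de)serialisation
# ---------------------------------------------------------------------------

def save_model(model: OrrLassoModel, path: str | Path) -> None:
    payload = {
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "lambda": model.lambda_,
        "cv_mse": model.cv_mse,
        "meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> OrrLassoModel:
    raw = json.loads(Path(path).read_text())
    return OrrLassoModel(
        intercept=float(raw["intercept"]),
        coefficients={k: float(v) for k, v in raw["coefficients"].items()},
        lambda_=raw.get("lambda"),
        cv_mse=raw.get("cv_mse"),
        training_meta=raw.get("meta", {}),
    )
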