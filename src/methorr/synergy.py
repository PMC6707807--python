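"""CpG × TMB interaction: Rothman's synergy index and individual-level
CpG–TMB association.

Two binary exposures (a dichotomised CpG β value and dichotomised TMB) and
a binary outcome enter a logistic regression with an interaction term; the
synergy index

    S = (OR11 − 1) / ((OR10 − 1) + (OR01 − 1))

compares the joint excess odds to the sum of the single-exposure excess
odds.  S = 1 means the joint effect is exactly additive on that scale,
S > 1 synergy, S < 1 antagonism.

The outcome vector is a *required* input: response is observed per cancer
type, not per patient, so any per-sample label is a modelling choice that
the caller must make explicitly (a convenience helper propagates the
cancer-type ORR ≥ cutoff label to its samples).

Individual-level association is simpler: per probe, the Spearman
correlation between per-sample β and per-sample TMB, with
Benjamini–Hochberg q-values across the probe set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .screening import spearman_vector
from .tmb import TmbSummary

logger = logging.getLogger(__name__)

__all__ = [
    "SynergyResult",
    "synergy_index",
    "cpg_tmb_synergy_screen",
    "cpg_tmb_association",
    "labels_from_cancer_orr",
]

MIN_SYNERGY_N = 20


@dataclass(frozen=True)
class SynergyResult:
    """Rothman synergy index with the odds ratios that enter it.

    ``undefined`` is set when the denominator (OR10 − 1) + (OR01 − 1)
    crosses zero, where S has no meaningful sign.
    """

    probe_id: str | None
    s_index: float
    or11: float
    or10: float
    or01: float
    undefined: bool = False


def _fit_interaction_logit(a: np.ndarray, b: np.ndarray, y: np.ndarray,
                           weights: np.ndarray | None = None):
    X = np.column_stack([np.ones_like(a, dtype=float), a, b, a * b])
    model = sm.GLM(y.astype(float), X, family=sm.families.Binomial(),
                   freq_weights=weights)
    return model.fit()


def synergy_index(
    exposure_a: Sequence[int],
    exposure_b: Sequence[int],
    outcome: Sequence[int],
    probe_id: str | None = None,
) -> SynergyResult:
    """Rothman's S from a logistic model with an interaction term.

    All three vectors are binary and aligned per sample (n ≥ 20, both
    levels present in each).  The logistic fit yields the three odds
    ratios OR10 = exp(β_a), OR01 = exp(β_b), OR11 = exp(β_a + β_b + β_ab),
    from which S = (OR11 − 1)/((OR10 − 1) + (OR01 − 1)).
    """
    a = np.asarray(exposure_a, dtype=int)
    b = np.asarray(exposure_b, dtype=int)
    y = np.asarray(outcome, dtype=int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("exposure and outcome vectors must have equal length")
    if len(a) < MIN_SYNERGY_N:
        raise ValueError(f"need ≥{MIN_SYNERGY_N} samples, got {len(a)}")
    for name, v in (("exposure_a", a), ("exposure_b", b), ("outcome", y)):
        if not set(np.unique(v)) <= {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")
        if len(np.unique(v)) < 2:
            raise ValueError(f"{name} has a single level; both levels required")

    # Collapse to the 2×2×2 frequency table: identical fit, much faster.
    cells = pd.DataFrame({"a": a, "b": b, "y": y}).value_counts().reset_index(name="w")
    try:
        with np.errstate(over="ignore"):
            res = _fit_interaction_logit(
                cells["a"].to_numpy(), cells["b"].to_numpy(),
                cells["y"].to_numpy(), cells["w"].to_numpy(float),
            )
    except PerfectSeparationError as exc:
        raise ValueError(
            "perfect separation in the logistic fit; a larger sample or a "
            "penalised fit is needed"
        ) from exc
    beta_a, beta_b, beta_ab = res.params[1], res.params[2], res.params[3]
    if not np.isfinite([beta_a, beta_b, beta_ab]).all() or max(
        abs(beta_a), abs(beta_b), abs(beta_ab)
    ) > 30:
        raise ValueError(
            "logistic coefficients diverged (quasi-separation); a larger "
            "sample or a penalised fit is needed"
        )
    or10, or01 = float(np.exp(beta_a)), float(np.exp(beta_b))
    or11 = float(np.exp(beta_a + beta_b + beta_ab))
    denom = (or10 - 1.0) + (or01 - 1.0)
    if denom == 0:
        return SynergyResult(probe_id, float("nan"), or11, or10, or01, undefined=True)
    s = (or11 - 1.0) / denom
    return SynergyResult(probe_id, float(s), or11, or10, or01, undefined=(s <= 0))


def labels_from_cancer_orr(
    sample_cancer: Mapping[str, str] | pd.Series,
    orr: pd.Series,
    cutoff: float = 0.2,
) -> pd.Series:
    """Propagate a cancer-type responder label (ORR ≥ cutoff) to samples.

    Explicitly opt-in: response is only observed at the cancer-type level,
    so treating every sample of a responsive type as a 'case' is a coarse
    surrogate, not an observed per-patient response.
    """
    sample_cancer = pd.Series(sample_cancer)
    labels = sample_cancer.map(lambda c: int(orr[c] >= cutoff))
    labels.name = "label"
    return labels


def _dichotomize_at_median(values: np.ndarray) -> np.ndarray | None:
    """Median split; ties at the median go to the low group.  ``None`` when
    the split would leave one group empty (constant input)."""
    med = np.median(values)
    high = values > med
    if high.all() or (~high).all():
        return None
    return high.astype(int)


def cpg_tmb_synergy_screen(
    beta: pd.DataFrame,
    tmb: TmbSummary,
    labels: pd.Series,
    probes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Synergy index between each CpG and TMB across samples.

    β and TMB are each dichotomised at their cohort median (ties low); the
    per-probe logistic interaction model against the binary outcome gives
    S.  Probes that cannot be dichotomised (constant β) are skipped and
    logged.  Returns a DataFrame ranked by descending S (undefined last).
    """
    samples = beta.columns.intersection(tmb.per_sample_tmb.index).intersection(labels.index)
    if len(samples) < MIN_SYNERGY_N:
        raise ValueError(f"only {len(samples)} aligned samples; need ≥{MIN_SYNERGY_N}")
    tmb_binary = _dichotomize_at_median(tmb.per_sample_tmb.loc[samples].to_numpy(float))
    if tmb_binary is None:
        raise ValueError("TMB is constant across samples; cannot dichotomise")
    y = labels.loc[samples].to_numpy(int)
    probe_list = list(probes) if probes is not None else list(beta.index)

    rows = []
    for probe in probe_list:
        values = beta.loc[probe, samples].to_numpy(float)
        if np.isnan(values).any():
            logger.info("probe %s skipped: missing β among aligned samples", probe)
            continue
        a = _dichotomize_at_median(values)
        if a is None:
            logger.info("probe %s skipped: constant β, cannot dichotomise", probe)
            continue
        try:
            res = synergy_index(a, tmb_binary, y, probe_id=probe)
        except ValueError as exc:
            logger.info("probe %s skipped: %s", probe, exc)
            continue
        rows.append((probe, res.s_index, res.or11, res.or10, res.or01, res.undefined))
    out = pd.DataFrame(rows, columns=["probe_id", "s_index", "or11", "or10", "or01",
                                      "undefined"]).set_index("probe_id")
    return out.sort_values("s_index", ascending=False, na_position="last")


def cpg_tmb_association(
    beta: pd.DataFrame,
    tmb: TmbSummary,
    probes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-probe Spearman association between sample β and sample TMB.

    Returns a DataFrame (rho, p_value, fdr_q) across the probe set, with
    Benjamini–Hochberg q-values, sorted by p.
    """
    samples = beta.columns.intersection(tmb.per_sample_tmb.index)
    if len(samples) < 10:
        raise ValueError(f"only {len(samples)} aligned samples; need ≥10")
    probe_list = list(probes) if probes is not None else list(beta.index)
    X = beta.loc[probe_list, samples].to_numpy(float)
    t = tmb.per_sample_tmb.loc[samples].to_numpy(float)
    rho, p = spearman_vector(X, t)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out = pd.DataFrame({"rho": rho, "p_value": p, "fdr_q": q},
                       index=pd.Index(probe_list, name="probe_id"))
    return out.sort_values("p_value")
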