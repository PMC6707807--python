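"""Cancer-type-level CpG screening.

Each cancer type is summarised by its per-probe mean β across tumor
samples; probes whose mean methylation tracks the literature objective
response rate (ORR) across cancer types are selected by a Spearman rank
correlation screen (|rho| ≥ 0.7 and P ≤ 0.001 by default).  The screen is
deliberately uncorrected for multiple testing — with ~480k probes and only
18 cancer types a Bonferroni adjustment would be hopelessly conservative —
but a Benjamini–Hochberg q-value column is emitted for information.

Supporting analyses: a one-sided two-sample Kolmogorov–Smirnov test asking
whether probes annotated to known immuno-oncology target genes carry larger
|rho| than the rest, and a per-gene count of passing CpGs (genes collecting
many passing probes are candidate therapy markers).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "aggregate_to_cancer_profiles",
    "spearman_screen",
    "ks_target_enrichment",
    "gene_cpg_enrichment",
]

#: Largest n for which the Spearman null distribution is enumerated exactly.
EXACT_PERMUTATION_MAX_N = 9


def _rank(values: np.ndarray) -> np.ndarray:
    """Average ranks (standard Spearman tie convention)."""
    return stats.rankdata(values, axis=-1)


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Pearson correlation of rank vectors along the last axis."""
    rx = rx - rx.mean(axis=-1, keepdims=True)
    ry = ry - ry.mean(axis=-1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=-1) * (ry**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rx * ry).sum(axis=-1) / denom


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p: enumerate all orderings of y."""
    n = len(ry)
    count = 0
    total = 0
    rx_c = rx - rx.mean()
    for perm in itertools.permutations(range(n)):
        rho = _rho_from_ranks(rx_c + rx.mean(), ry[list(perm)])
        count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


def _asymptotic_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with n−2 degrees of freedom."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, np.minimum(p, 1.0))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a p-value.

    Ties receive average ranks.  For n ≤ 9 the p-value is the exact
    two-sided permutation probability (all n! orderings enumerated); for
    larger n the usual t approximation on n−2 degrees of freedom is used.
    Returns ``(nan, nan)`` when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx, ry = _rank(x), _rank(y)
    rho = float(_rho_from_ranks(rx, ry))
    if n <= EXACT_PERMUTATION_MAX_N:
        return rho, float(_exact_p(rx, ry, rho))
    return rho, float(_asymptotic_p(np.array(rho), n))


def spearman_vector(profile_matrix: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Spearman of each matrix row against ``y`` (asymptotic p).

    Rows containing NaN or constant rows yield ``nan``.
    """
    n = profile_matrix.shape[1]
    ry = _rank(y)
    rx = _rank(profile_matrix)
    rho = _rho_from_ranks(rx, ry)
    constant = np.ptp(profile_matrix, axis=1) == 0
    has_nan = np.isnan(profile_matrix).any(axis=1)
    rho = np.where(constant | has_nan, np.nan, rho)
    p = np.where(np.isnan(rho), np.nan, _asymptotic_p(rho, n))
    return rho, p


# ---------------------------------------------------------------------------
# Aggregation: samples → cancer-type mean-β profiles
# ---------------------------------------------------------------------------

def aggregate_to_cancer_profiles(matrices: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Collapse per-cancer sample matrices to a probes × cancer-types mean-β table.

    Each cancer type's probe value is the arithmetic mean of its non-missing
    sample β values.  Only probes present in every matrix are kept
    (intersection); probes missing in *all* samples of any cancer type are
    dropped from every profile (and logged).
    """
    if not matrices:
        raise ValueError("no cancer-type matrices supplied")
    common: pd.Index | None = None
    for code, beta in matrices.items():
        if beta.shape[1] == 0:
            raise ValueError(f"cancer type {code!r} has no samples")
        common = beta.index if common is None else common.intersection(beta.index)
    if common is None or len(common) == 0:
        raise ValueError("empty probe intersection across cancer types")
    profiles = pd.DataFrame(
        {code: beta.loc[common].mean(axis=1, skipna=True) for code, beta in matrices.items()}
    )
    fully_missing = profiles.isna().any(axis=1)
    if fully_missing.any():
        dropped = profiles.index[fully_missing].tolist()
        logger.info("dropping %d probes fully missing in ≥1 cancer type: %s…",
                    len(dropped), dropped[:5])
        profiles = profiles.loc[~fully_missing]
    profiles.index.name = "probe_id"
    return profiles


# ---------------------------------------------------------------------------
# The Spearman screen
# ---------------------------------------------------------------------------

def spearman_screen(
    profiles: pd.DataFrame,
    orr: pd.Series,
    rho_threshold: float = 0.7,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Screen probes for rank association between mean β and ORR.

    Parameters
    ----------
    profiles
        Probes × cancer-types mean-β table (from
        :func:`aggregate_to_cancer_profiles`).
    orr
        Cancer-code → ORR fraction; codes must match ``profiles`` columns.
    rho_threshold, p_threshold
        A probe passes iff |rho| ≥ ``rho_threshold`` and p ≤ ``p_threshold``.

    Returns a DataFrame indexed by probe with columns ``rho``, ``p_value``,
    ``q_value`` (Benjamini–Hochberg, informational only) and ``passes``,
    sorted by descending |rho| then ascending p.
    """
    codes = list(profiles.columns)
    if len(codes) < 4:
        raise ValueError(f"need ≥4 cancer types for a meaningful screen, got {len(codes)}")
    if set(codes) != set(orr.index):
        raise ValueError("cancer codes of profiles and ORR table do not match")
    y = orr.loc[codes].to_numpy(dtype=float)
    X = profiles.to_numpy(dtype=float)
    n = len(codes)
    if n <= EXACT_PERMUTATION_MAX_N:
        pairs = [spearman(row, y) for row in X]
        rho = np.array([r for r, _ in pairs])
        p = np.array([pv for _, pv in pairs])
    else:
        rho, p = spearman_vector(X, y)
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    passes = valid & (np.abs(rho) >= rho_threshold) & (p <= p_threshold)
    out = pd.DataFrame(
        {"rho": rho, "p_value": p, "q_value": q, "passes": passes},
        index=profiles.index,
    )
    return out.sort_values(
        ["rho", "p_value"], key=lambda s: -s.abs() if s.name == "rho" else s
    )


# ---------------------------------------------------------------------------
# Enrichment of gold-standard immuno-oncology targets
# ---------------------------------------------------------------------------

def ks_target_enrichment(
    results: pd.DataFrame,
    gold_genes: Iterable[str],
    annotation: pd.DataFrame,
) -> tuple[float, float]:
    """One-sided KS test: do gold-target probes carry larger |rho|?

    Splits screened probes into those annotated to any gold-standard
    immuno-oncology target gene vs the rest and compares the two |rho|
    samples with a one-sided two-sample Kolmogorov–Smirnov test in the
    direction "gold probes are stochastically larger".  Returns (D, p).
    """
    gold = set(gold_genes)
    if not gold:
        raise ValueError("gold_genes is empty")
    genes = annotation["genes"].reindex(results.index)
    is_gold = np.array(
        [bool(g) and bool(gold.intersection(g)) for g in genes.fillna("").to_numpy()]
    )
    abs_rho = results["rho"].abs().to_numpy()
    ok = ~np.isnan(abs_rho)
    gold_rho, other_rho = abs_rho[ok & is_gold], abs_rho[ok & ~is_gold]
    if len(gold_rho) == 0:
        raise ValueError("no screened probe maps to a gold-standard gene")
    if len(other_rho) == 0:
        raise ValueError("all probes map to gold-standard genes; nothing to compare")
    # alternative='less': the gold-sample CDF lies below, i.e. larger values.
    res = stats.ks_2samp(gold_rho, other_rho, alternative="less")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Per-gene CpG enrichment counting
# ---------------------------------------------------------------------------

def gene_cpg_enrichment(results: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Count passing CpGs per annotated gene.

    A probe annotated to several genes increments each of them once.
    Returns a DataFrame (gene_symbol, cpg_count) sorted by descending count;
    empty when no probe passes.
    """
    passing = results.index[results["passes"].astype(bool)]
    counts: dict[str, int] = {}
    genes = annotation["genes"]
    for probe in passing:
        for gene in genes.get(probe, ()):
            counts[gene] = counts.get(gene, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["gene_symbol", "cpg_count"])
    out = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
                       columns=["gene_symbol", "cpg_count"])
    return out
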