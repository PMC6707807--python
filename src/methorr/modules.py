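"""Entropy-based methylation scoring of functional modules.

CpG β values at many loci are bimodal, so a plain average across a gene
set discards most of the signal.  Instead each functional module — a
radius-1 ego network in a protein-protein interaction graph, a pathway
gene set, or a ligand-receptor gene pair — is scored per cancer type by a
Shannon-entropy-style statistic over its member probes' β values:

    H = − Σ_i β_i · ln(β_i),   with 0·ln 0 := 0,

where β_i is the cancer-type mean β of member probe i.  Each term is
non-negative on [0, 1] (maximal 1/e at β = 1/e, zero at β ∈ {0, 1}), so H
captures how far a module sits from fully methylated/unmethylated states.
Module scores are then rank-correlated with the per-cancer objective
response rates exactly as single probes are in the screening step.

H is deliberately not normalised by module size; pass
``normalize=True`` to compare modules of different sizes on a per-probe
basis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneSet
from .screening import spearman

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalModule",
    "build_ego_network_modules",
    "modules_from_gene_sets",
    "modules_from_lr_pairs",
    "resolve_module_probes",
    "module_entropy",
    "module_orr_association",
]

MODULE_KINDS = ("ppi_subnetwork", "gene_set", "ligand_receptor")


@dataclass(frozen=True)
class FunctionalModule:
    """A gene set with its resolved CpG probes."""

    module_id: str
    kind: str
    genes: tuple[str, ...]
    probes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in MODULE_KINDS:
            raise ValueError(f"unknown module kind {self.kind!r}")


def _gene_to_probes(annotation: pd.DataFrame) -> dict[str, list[str]]:
    mapping: dict[str, list[str]] = {}
    for probe, genes in annotation["genes"].items():
        for gene in genes:
            mapping.setdefault(gene, []).append(probe)
    return mapping


def resolve_module_probes(
    modules: Iterable[FunctionalModule], annotation: pd.DataFrame
) -> list[FunctionalModule]:
    """Attach to each module the union of probes annotated to its genes.

    Modules whose genes map to no probe are dropped (and logged) — the
    probes-non-empty invariant holds for everything returned.
    """
    lookup = _gene_to_probes(annotation)
    resolved = []
    for mod in modules:
        probes = sorted({p for g in mod.genes for p in lookup.get(g, ())})
        if not probes:
            logger.info("module %s dropped: no annotated probes", mod.module_id)
            continue
        resolved.append(FunctionalModule(mod.module_id, mod.kind, mod.genes, tuple(probes)))
    return resolved


# ---------------------------------------------------------------------------
# Module construction
# ---------------------------------------------------------------------------

def build_ego_network_modules(ppi: nx.Graph, genes: Iterable[str] | None = None
                              ) -> list[FunctionalModule]:
    """One module per seed gene: the seed plus its direct PPI neighbors.

    ``genes`` restricts the seeds (default: every network node).  Isolated
    seeds (<2 genes in the ego network) yield no module.
    """
    seeds = list(genes) if genes is not None else list(ppi.nodes)
    modules = []
    for seed in seeds:
        if seed not in ppi:
            continue
        members = (seed, *sorted(ppi.neighbors(seed)))
        if len(members) < 2:
            continue
        modules.append(FunctionalModule(f"ego:{seed}", "ppi_subnetwork", members))
    return modules


def modules_from_gene_sets(gene_sets: Mapping[str, GeneSet]) -> list[FunctionalModule]:
    return [
        FunctionalModule(f"set:{set_id}", "gene_set", tuple(gs.genes))
        for set_id, gs in gene_sets.items()
    ]


def modules_from_lr_pairs(pairs: Iterable[tuple[str, str]]) -> list[FunctionalModule]:
    """One module per ligand-receptor pair (union of both genes' probes)."""
    return [
        FunctionalModule(f"lr:{ligand}__{receptor}", "ligand_receptor", (ligand, receptor))
        for ligand, receptor in pairs
    ]


# ---------------------------------------------------------------------------
# Entropy scoring
# ---------------------------------------------------------------------------

def entropy_terms(beta_values: np.ndarray) -> np.ndarray:
    """−β·ln(β) per value with the 0·ln 0 := 0 convention."""
    beta_values = np.asarray(beta_values, dtype=float)
    if ((beta_values < 0) | (beta_values > 1)).any():
        raise ValueError("β values must lie in [0, 1]")
    out = np.zeros_like(beta_values)
    pos = beta_values > 0
    out[pos] = -beta_values[pos] * np.log(beta_values[pos])
    return out


def module_entropy(
    beta_values: Mapping[str, float] | pd.Series,
    module: FunctionalModule,
    normalize: bool = False,
) -> float:
    """H = −Σ β·ln β over the module's probes for one cancer type.

    ``beta_values`` maps probe → (cancer-type mean) β.  Probes missing from
    the map or with NaN β are skipped; if every probe is missing an error
    is raised.  ``normalize=True`` divides by the number of contributing
    probes.
    """
    values = []
    for probe in module.probes:
        v = beta_values.get(probe) if hasattr(beta_values, "get") else beta_values[probe]
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            values.append(float(v))
    if not values:
        raise ValueError(f"module {module.module_id}: all probes missing a β value")
    h = float(entropy_terms(np.array(values)).sum())
    return h / len(values) if normalize else h


def module_orr_association(
    modules: Sequence[FunctionalModule],
    profiles: pd.DataFrame,
    orr: pd.Series,
    p_threshold: float = 0.05,
    normalize: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every module per cancer type and rank-correlate with ORR.

    Entropies are computed from the probes × cancer-types mean-β table
    ``profiles`` (same aggregation as the CpG screen); modules whose
    entropy is constant across cancer types have no defined correlation
    and are flagged, never reported significant.  The association math is
    identical for all module kinds.

    Returns ``(scores, entropies)``: per-module rho/p/significance, and the
    modules × cancer-types entropy table.
    """
    codes = list(profiles.columns)
    if len(codes) < 4:
        raise ValueError(f"need ≥4 cancer types, got {len(codes)}")
    if set(codes) != set(orr.index):
        raise ValueError("cancer codes of profiles and ORR table do not match")
    y = orr.loc[codes].to_numpy(float)

    score_rows, entropy_rows, index = [], [], []
    for mod in modules:
        per_cancer = []
        for code in codes:
            try:
                per_cancer.append(module_entropy(profiles[code], mod, normalize=normalize))
            except ValueError:
                per_cancer.append(np.nan)
        h = np.array(per_cancer)
        if np.isnan(h).any():
            logger.info("module %s skipped: missing entropy in ≥1 cancer type",
                        mod.module_id)
            continue
        rho, p = spearman(h, y)
        degenerate = np.isnan(rho)
        significant = (not degenerate) and p <= p_threshold
        score_rows.append((mod.kind, len(mod.genes), len(mod.probes), rho, p,
                           significant, degenerate))
        entropy_rows.append(h)
        index.append(mod.module_id)
    scores = pd.DataFrame(
        score_rows,
        columns=["kind", "n_genes", "n_probes", "rho", "p_value", "significant",
                 "degenerate"],
        index=pd.Index(index, name="module_id"),
    )
    entropies = pd.DataFrame(entropy_rows, index=pd.Index(index, name="module_id"),
                             columns=codes)
    return scores.sort_values("p_value"), entropies
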