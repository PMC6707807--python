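"""Synthetic cohort generator with the statistical structure the pipeline
assumes.

The generator emulates, at desk scale, a pan-cancer 450K study design:

* a handful of cancer types, each with a literature ORR drawn uniformly
  from the observed pan-cancer range (0–0.4);
* per-probe sample β values drawn from a two-component Beta mixture with
  modes near 0.1 and 0.9, reproducing the bimodality of CpG signals;
* a planted subset of "informative" probes whose per-cancer-type mean β is
  a monotone (increasing or decreasing, recorded) function of ORR;
* per-sample missense-mutation counts, log-normally distributed with the
  log-mean tied to the cancer type's ORR, so that cohort TMB carries an
  ORR signal of tunable strength;
* a probe → gene annotation, plus random scored PPI edges, gene sets and
  ligand-receptor pairs with one module of each kind planted on the
  informative genes.

Everything derives from a single integer seed; the same seed reproduces
every matrix bit-for-bit.  A truth record lists the planted probes, their
signs and the planted module ids, so recovery rates can be measured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneSet, filter_ppi

__all__ = ["SyntheticConfig", "SimulatedCohorts", "SimulatedModules",
           "simulate_cohorts", "simulate_modules", "write_cohorts"]

# Beta-mixture components: modes near 0.1 / 0.9.
_LOW_A, _LOW_B = 2.0, 10.0     # mean 1/6, mode 0.1
_HIGH_A, _HIGH_B = 10.0, 2.0   # mean 5/6, mode 0.9
_MU_LOW = _LOW_A / (_LOW_A + _LOW_B)
_MU_HIGH = _HIGH_A / (_HIGH_A + _HIGH_B)

#: Mean-β change per unit ORR for a fully informative probe (effect_size=1).
_ORR_SLOPE = 1.25

#: Center of informative-probe mean β.  Sits above 1/e ≈ 0.368, where the
#: entropy term −β·ln β is monotone in β, so a sign-coherent planted module
#: carries a monotone entropy/ORR signal as well as a mean-β one.
_INFORMATIVE_CENTER = 0.63

#: Baseline missense mutations per patient (≈2 mutations/Mb at a 38 Mb exome).
_BASE_MISSENSE = 76.0
#: Log-scale spread of per-sample mutation counts (heavy right tail).
_MUTATION_SIGMA = 0.6


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the study design being emulated.

    ``effect_size`` scales the monotone mean-β/ORR link of informative
    probes (0 = null, 1 = full slope); ``bimodal_mix`` is the average
    weight of the high-methylation mixture component for background
    probes; ``tmb_link_strength`` is the log-count shift per standardised
    unit of ORR; ``orr_range`` spans the observed pan-cancer ORR range.
    """

    seed: int = 0
    n_cancer_types: int = 18
    n_samples_per_type: int = 60
    n_probes: int = 1000
    n_informative_probes: int = 30
    effect_size: float = 0.9
    bimodal_mix: float = 0.5
    noise_sd: float = 0.02
    tmb_link_strength: float = 0.8
    orr_range: tuple[float, float] = (0.0, 0.4)

    def __post_init__(self):
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.n_cancer_types <= 0 or self.n_samples_per_type <= 0:
            raise ValueError("cancer-type and sample counts must be positive")
        if not 0 <= self.n_informative_probes <= self.n_probes:
            raise ValueError("n_informative_probes must be in [0, n_probes]")
        for name in ("effect_size", "bimodal_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.orr_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"orr_range must satisfy 0 ≤ lo < hi ≤ 1, got {self.orr_range}")


@dataclass(frozen=True)
class SimulatedCohorts:
    """Everything the pipeline consumes, plus the generating truth."""

    matrices: dict[str, pd.DataFrame]      # cancer code → probes × samples β
    orr: pd.Series                         # cancer code → ORR
    mutations: pd.DataFrame                # tidy mutation table (MAF content)
    annotation: pd.DataFrame               # probe → genes/chromosome/coordinate
    truth: dict


@dataclass(frozen=True)
class SimulatedModules:
    ppi: nx.Graph
    gene_sets: dict[str, GeneSet]
    lr_pairs: list[tuple[str, str]]
    planted: dict  # module ids built from informative genes


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohorts(config: SyntheticConfig) -> SimulatedCohorts:
    """Draw per-cancer β matrices, ORRs, mutations and annotation.

    Informative probes' cancer-type mean β follows
    ``0.5 + sign · effect_size · 1.25 · (ORR − mid)`` plus Gaussian noise
    (sd ``noise_sd``), clipped into (0, 1); background probes sit at a
    probe-specific bimodal baseline.  Sample-level β comes from the
    two-component Beta mixture whose weight reproduces the target mean.
    """
    rng_orr, rng_layout, rng_beta, rng_mut = _child_rngs(config.seed, 4)
    codes = [f"C{i + 1:02d}" for i in range(config.n_cancer_types)]
    lo, hi = config.orr_range
    orr = pd.Series(rng_orr.uniform(lo, hi, size=config.n_cancer_types),
                    index=pd.Index(codes, name="cancer_code"), name="orr")

    probes = [f"cgS{i + 1:06d}" for i in range(config.n_probes)]
    informative_idx = np.sort(
        rng_layout.choice(config.n_probes, size=config.n_informative_probes, replace=False)
    )
    signs = rng_layout.choice([-1, 1], size=config.n_informative_probes)
    # Background bimodal baseline per probe: high-mode weight around bimodal_mix.
    conc = 6.0
    a = max(config.bimodal_mix * conc, 1e-3)
    b = max((1.0 - config.bimodal_mix) * conc, 1e-3)
    base_weight = rng_layout.beta(a, b, size=config.n_probes)
    base_mean = _MU_LOW + (_MU_HIGH - _MU_LOW) * base_weight

    # Annotation: one gene per probe, ~10% get a second gene, ~5% none.
    genes = np.array([f"G{i + 1:05d}" for i in range(config.n_probes)])
    second = rng_layout.random(config.n_probes) < 0.10
    none = rng_layout.random(config.n_probes) < 0.05
    gene_lists = []
    for i in range(config.n_probes):
        if none[i] and i not in informative_idx:
            gene_lists.append(())
        elif second[i]:
            gene_lists.append((genes[i], genes[(i + 1) % config.n_probes]))
        else:
            gene_lists.append((genes[i],))
    annotation = pd.DataFrame(
        {
            "genes": gene_lists,
            "chromosome": [str(1 + i % 22) for i in range(config.n_probes)],
            "coordinate": (np.arange(config.n_probes) + 1) * 1000.0,
        },
        index=pd.Index(probes, name="probe_id"),
    )

    mid = (lo + hi) / 2.0
    target_mean = np.tile(base_mean[:, None], (1, config.n_cancer_types))
    orr_vals = orr.to_numpy()
    for j, (idx, sign) in enumerate(zip(informative_idx, signs)):
        target_mean[idx, :] = (
            _INFORMATIVE_CENTER + sign * config.effect_size * _ORR_SLOPE * (orr_vals - mid)
        )
    target_mean = target_mean + rng_beta.normal(
        0.0, config.noise_sd, size=target_mean.shape
    )
    target_mean = np.clip(target_mean, 0.02, 0.98)

    matrices: dict[str, pd.DataFrame] = {}
    for c, code in enumerate(codes):
        weight = np.clip((target_mean[:, c] - _MU_LOW) / (_MU_HIGH - _MU_LOW), 0.0, 1.0)
        shape = (config.n_probes, config.n_samples_per_type)
        high = rng_beta.random(shape) < weight[:, None]
        low_draw = rng_beta.beta(_LOW_A, _LOW_B, size=shape)
        high_draw = rng_beta.beta(_HIGH_A, _HIGH_B, size=shape)
        beta = np.where(high, high_draw, low_draw)
        matrices[code] = pd.DataFrame(
            beta,
            index=pd.Index(probes, name="probe_id"),
            columns=[f"{code}_S{s + 1:03d}" for s in range(config.n_samples_per_type)],
        )

    mutations = _simulate_mutations(config, codes, orr_vals, genes, rng_mut)

    truth = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "cancer_codes": codes,
        "orr": {c: float(v) for c, v in orr.items()},
        "informative_probes": {
            probes[idx]: int(sign) for idx, sign in zip(informative_idx, signs)
        },
        # the realised generating means (post noise/clip): the β targets the
        # sample-level mixture is centred on, per cancer type
        "informative_target_means": {
            probes[idx]: target_mean[idx].tolist() for idx in informative_idx
        },
        "informative_genes": sorted(
            {g for idx in informative_idx for g in gene_lists[idx]}
        ),
    }
    # Genes of the majority-sign informative probes: a sign-coherent subset
    # whose module-level entropy moves monotonically with ORR (mixed signs
    # cancel within a module).
    if len(signs):
        majority = 1 if (signs == 1).sum() >= (signs == -1).sum() else -1
        truth["coherent_informative_genes"] = sorted(
            {
                g
                for idx, sign in zip(informative_idx, signs)
                if sign == majority
                for g in gene_lists[idx]
            }
        )
    else:
        truth["coherent_informative_genes"] = []
    return SimulatedCohorts(matrices, orr, mutations, annotation, truth)


def _simulate_mutations(config, codes, orr_vals, genes, rng) -> pd.DataFrame:
    """Log-normal per-sample missense counts, log-mean tied to ORR."""
    z = (orr_vals - orr_vals.mean()) / (orr_vals.std() or 1.0)
    records_sample, records_class, records_gene = [], [], []
    for c, code in enumerate(codes):
        log_mu = np.log(_BASE_MISSENSE) + config.tmb_link_strength * z[c]
        n_missense = np.maximum(
            np.rint(rng.lognormal(log_mu, _MUTATION_SIGMA,
                                  size=config.n_samples_per_type)).astype(int),
            0,
        )
        n_silent = rng.poisson(0.4 * n_missense + 2)
        for s in range(config.n_samples_per_type):
            sample = f"{code}_S{s + 1:03d}"
            total = n_missense[s] + n_silent[s]
            records_sample.append(np.repeat(sample, total))
            records_class.append(
                np.repeat(["Missense_Mutation", "Silent"], [n_missense[s], n_silent[s]])
            )
            records_gene.append(rng.choice(genes, size=total))
    return pd.DataFrame(
        {
            "sample_id": np.concatenate(records_sample),
            "gene_symbol": np.concatenate(records_gene),
            "variant_classification": np.concatenate(records_class),
        }
    )


def simulate_modules(
    config: SyntheticConfig,
    cohorts: SimulatedCohorts,
    n_gene_sets: int = 20,
    gene_set_size: int = 8,
    n_lr_pairs: int = 30,
    edges_per_gene: float = 3.0,
) -> SimulatedModules:
    """Random functional-module inputs over the simulated gene universe.

    A random scored graph, random gene sets and random ligand-receptor
    pairs — plus one planted module of each kind built from the
    informative probes' genes, so module-level recovery can be scored.
    """
    (rng,) = _child_rngs(config.seed + 2**20, 1)
    universe = sorted({g for gl in cohorts.annotation["genes"] for g in gl})
    if not universe:
        raise ValueError("empty gene universe: annotation maps no probe to a gene")
    informative = [
        g for g in cohorts.truth["coherent_informative_genes"] if g in universe
    ] or [g for g in cohorts.truth["informative_genes"] if g in universe]

    n_edges = int(edges_per_gene * len(universe))
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for _ in range(n_edges):
        u, v = rng.choice(len(universe), size=2, replace=False)
        graph.add_edge(universe[u], universe[v], score=int(rng.integers(150, 1000)))
    planted: dict = {}
    if len(informative) >= 2:
        seed_gene = informative[0]
        for neighbor in informative[1:]:
            graph.add_edge(seed_gene, neighbor, score=900)
        planted["ppi_seed_gene"] = seed_gene
    graph = filter_ppi(graph, 400)

    gene_sets: dict[str, GeneSet] = {}
    size = min(gene_set_size, len(universe))
    for i in range(n_gene_sets):
        members = tuple(rng.choice(universe, size=size, replace=False))
        set_id = f"RAND{i + 1:03d}"
        gene_sets[set_id] = GeneSet(set_id, "random background set", members)
    if informative:
        gene_sets["PLANTED"] = GeneSet("PLANTED", "planted informative-gene set",
                                       tuple(informative))
        planted["gene_set_id"] = "PLANTED"

    lr_pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(lr_pairs) < n_lr_pairs:
        u, v = rng.choice(len(universe), size=2, replace=False)
        pair = (universe[u], universe[v])
        if pair not in seen:
            seen.add(pair)
            lr_pairs.append(pair)
    if len(informative) >= 2:
        lr_pairs.append((informative[0], informative[1]))
        planted["lr_pair"] = (informative[0], informative[1])

    return SimulatedModules(graph, gene_sets, lr_pairs, planted)


def write_cohorts(cohorts: SimulatedCohorts, outdir: str | Path) -> None:
    """Write all cohort files in the pipeline's on-disk dialects."""
    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    betas = outdir / "betas"
    betas.mkdir(exist_ok=True)
    for code, beta in cohorts.matrices.items():
        io_formats.write_beta_matrix(beta, betas / f"{code}.tsv")
    io_formats.write_orr_table(cohorts.orr, outdir / "orr.tsv")
    io_formats.write_probe_annotation(cohorts.annotation, outdir / "annotation.tsv")
    maf = cohorts.mutations.rename(
        columns={
            "gene_symbol": "Hugo_Symbol",
            "variant_classification": "Variant_Classification",
            "sample_id": "Tumor_Sample_Barcode",
        }
    )[["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]]
    maf.to_csv(outdir / "mutations.maf", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(cohorts.truth, indent=2) + "\n")
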