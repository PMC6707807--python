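"""Readers, writers and shipped reference tables for every external format
the pipeline touches.

All tabular formats are plain text (TSV/CSV).  In-memory containers follow
the field's conventions: a methylation β matrix is a probes × samples
:class:`pandas.DataFrame` of fractions in [0, 1] (``NaN`` = missing), a
mutation table is a tidy record-per-mutation DataFrame, a protein-protein
interaction network is a :class:`networkx.Graph` with integer ``score``
edge attributes.

Shipped reference data (under ``methorr/data/``):

* the 18-cancer-type objective-response-rate (ORR) table,
* the published 8-CpG linear ORR model,
* the printed list of top ORR-associated CpG probes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "IoDialect",
    "GeneSet",
    "Fixtures",
    "read_beta_matrix",
    "write_beta_matrix",
    "validate_beta_matrix",
    "read_orr_table",
    "write_orr_table",
    "read_maf",
    "read_probe_annotation",
    "write_probe_annotation",
    "split_gene_symbols",
    "read_gene_sets",
    "read_ppi",
    "filter_ppi",
    "read_lr_pairs",
    "load_fixtures",
    "load_orr_fixture",
    "load_published_model",
    "load_top_cpgs_fixture",
    "load_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (e.g. β outside [0, 1])."""


#: Tokens treated as missing β values by default; TCGA exports vary.
DEFAULT_MISSING_TOKENS: tuple[str, ...] = ("NA", "NaN", "nan", "N/A", "")

#: STRING-style combined-score cutoff; edges scoring below it are discarded.
DEFAULT_PPI_MIN_SCORE = 400

#: Required MAF columns (a MAF file is a tab-separated table with '#' comments).
MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


@dataclass(frozen=True)
class IoDialect:
    """Tabular-dialect knobs shared by the TSV/CSV readers.

    ``sep=None`` sniffs tab vs comma from the header line.
    """

    sep: str | None = None
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.genes)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# β matrices
# ---------------------------------------------------------------------------

def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    """Enforce the β-matrix invariants; returns the (float-coerced) matrix.

    Probes index rows, samples index columns; all non-missing entries must
    lie in [0, 1] and identifiers must be unique.
    """
    if beta.index.duplicated().any():
        dupes = beta.index[beta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
    if beta.columns.duplicated().any():
        dupes = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    values = beta.to_numpy(dtype=float)
    bad = (values < 0.0) | (values > 1.0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"beta value {values[i, j]!r} out of [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )
    out = beta.astype(float)
    out.index.name = "probe_id"
    return out


def read_beta_matrix(path: str | Path, dialect: IoDialect | None = None) -> pd.DataFrame:
    """Read a probes × samples β matrix from a TSV/CSV file.

    First column holds probe ids, header holds sample ids.  Values are
    fractions in [0, 1]; the dialect's missing tokens become ``NaN``.
    """
    path = Path(path)
    dialect = dialect or IoDialect()
    sep = dialect.sep or _sniff_sep(path)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            na_values=list(dialect.missing_tokens),
            keep_default_na=False,
            dtype=str,
        )
    except Exception as exc:  # malformed layout
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    if df.index.name is None or df.shape[1] == 0:
        raise FormatError(f"{path}: expected a probe-id first column and sample-id header")
    try:
        numeric = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric beta value ({exc})") from exc
    return validate_beta_matrix(numeric)


def write_beta_matrix(beta: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    validate_beta_matrix(beta).to_csv(path, sep=sep, index_label="probe_id", na_rep="NA")


# ---------------------------------------------------------------------------
# ORR tables
# ---------------------------------------------------------------------------

def _validate_orr(orr: pd.Series) -> pd.Series:
    if orr.index.duplicated().any():
        raise ValidationError("duplicate cancer codes in ORR table")
    vals = orr.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
        raise ValidationError("ORR values must be fractions in [0, 1]")
    out = orr.astype(float)
    out.name = "orr"
    out.index.name = "cancer_code"
    return out


def read_orr_table(path: str | Path, dialect: IoDialect | None = None) -> pd.Series:
    """Read a cancer-code → ORR table (columns ``cancer_code``, ``orr``)."""
    path = Path(path)
    sep = (dialect.sep if dialect else None) or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = {"cancer_code", "orr"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: ORR table lacks columns {sorted(missing)}")
    return _validate_orr(df.set_index("cancer_code")["orr"])


def write_orr_table(orr: pd.Series, path: str | Path, sep: str = "\t") -> None:
    _validate_orr(orr).rename("orr").rename_axis("cancer_code").reset_index().to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# MAF mutation tables
# ---------------------------------------------------------------------------

def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a Mutation Annotation Format file into a tidy mutation table.

    Returns a DataFrame with one row per mutation and columns ``sample_id``,
    ``gene_symbol``, ``variant_classification``.  Leading ``#`` comment lines
    (e.g. ``#version 2.4``) are skipped.  The sample census — every barcode
    appearing in the file, qualifying mutations or not — is the set of
    distinct ``sample_id`` values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse MAF {path}: {exc}") from exc
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: MAF lacks required columns {missing}")
    out = df.rename(
        columns={
            "Hugo_Symbol": "gene_symbol",
            "Variant_Classification": "variant_classification",
            "Tumor_Sample_Barcode": "sample_id",
        }
    )[["sample_id", "gene_symbol", "variant_classification"]]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------

def split_gene_symbols(text: str | float) -> tuple[str, ...]:
    """Split a 450K-manifest gene field ('A; B') into a tuple of symbols."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ()
    parts = [p.strip() for p in str(text).split(";")]
    return tuple(p for p in parts if p)


def read_probe_annotation(path: str | Path, dialect: IoDialect | None = None) -> pd.DataFrame:
    """Read probe annotation (probe_id, gene_symbols, chromosome, coordinate).

    Gene symbols may be ';'-separated lists (a probe can map to 0, 1 or
    several genes); coordinates are 1-based manifest positions.
    """
    path = Path(path)
    sep = (dialect.sep if dialect else None) or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"probe_id", "gene_symbols"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation lacks columns {sorted(missing)}")
    out = pd.DataFrame(index=pd.Index(df["probe_id"], name="probe_id"))
    out["genes"] = [split_gene_symbols(g) for g in df["gene_symbols"]]
    out["chromosome"] = df.get("chromosome", pd.Series("", index=df.index)).to_numpy()
    coord = pd.to_numeric(df.get("coordinate", pd.Series(np.nan, index=df.index)),
                          errors="coerce")
    if (coord.dropna() < 1).any():
        raise ValidationError(f"{path}: coordinates must be ≥ 1 (1-based)")
    out["coordinate"] = coord.to_numpy()
    if out.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate probe ids in annotation")
    return out


def write_probe_annotation(annotation: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "probe_id": annotation.index,
            "gene_symbols": ["; ".join(g) for g in annotation["genes"]],
            "chromosome": annotation["chromosome"].to_numpy(),
            "coordinate": annotation["coordinate"].to_numpy(),
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Functional-module inputs: GMT gene sets, scored PPI edges, ligand-receptor pairs
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file: one gene set per line (id, description, members...)."""
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs id, description, ≥1 gene")
        set_id, description, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no members")
        if set_id in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        sets[set_id] = GeneSet(set_id, description, tuple(genes))
    return sets


def filter_ppi(graph: nx.Graph, min_score: int = DEFAULT_PPI_MIN_SCORE) -> nx.Graph:
    """Drop self-loops and edges scoring below ``min_score`` (idempotent)."""
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        if u != v and data.get("score", 0) >= min_score:
            out.add_edge(u, v, score=data["score"])
    return out


def read_ppi(path: str | Path, min_score: int = DEFAULT_PPI_MIN_SCORE) -> nx.Graph:
    """Read a scored PPI edge list (gene1, gene2, combined score, TSV).

    Edges with score < ``min_score`` and self-loops are discarded at load
    time; the threshold is inclusive (score == min_score is kept).
    """
    graph = nx.Graph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected gene1, gene2, score")
        g1, g2, score_text = fields[0], fields[1], fields[2]
        if lineno == 1 and not _is_int(score_text):
            continue  # header row
        if not _is_int(score_text):
            raise FormatError(f"{path}:{lineno}: non-integer score {score_text!r}")
        graph.add_edge(g1, g2, score=int(score_text))
    return filter_ppi(graph, min_score)


def _is_int(text: str) -> bool:
    try:
        int(text)
    except ValueError:
        return False
    return True


def read_lr_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read ligand-receptor pairs from a 2-column TSV; unique ordered pairs."""
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected ligand, receptor")
        if lineno == 1 and fields[0].lower() in {"ligand", "ligand_gene"}:
            continue
        pair = (fields[0], fields[1])
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# Shipped reference tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixtures:
    """The shipped in-text reference tables."""

    orr_table: pd.Series
    published_model: "object"  # OrrLassoModel; typed loosely to avoid a cycle
    top_cpgs: pd.DataFrame


def _data_path(name: str) -> Path:
    return Path(str(resources.files("methorr").joinpath("data", name)))


def load_orr_fixture() -> pd.Series:
    """The literature ORR table for the 18 cancer types (code → fraction)."""
    return read_orr_table(_data_path("orr_table.tsv"))


def load_published_model(cg04144714_coefficient: float = 0.0, quiet: bool = False):
    """The published 8-CpG linear ORR model.

    The printed source equation is typographically damaged at cg04144714 and
    its coefficient is not legible; it is stored as ``null`` and resolved
    here to ``cg04144714_coefficient`` (default 0.0) with a warning unless
    ``quiet``.  Pass an explicit value if you have a better transcription.
    """
    from .orr_model import OrrLassoModel

    raw = json.loads(_data_path("published_model.json").read_text())
    coefficients = dict(raw["coefficients"])
    unresolved = [p for p, c in coefficients.items() if c is None]
    for probe in unresolved:
        coefficients[probe] = float(cg04144714_coefficient)
    if unresolved and not quiet:
        warnings.warn(
            f"published-model coefficient(s) for {unresolved} are illegible in "
            f"the source; using {cg04144714_coefficient!r}",
            stacklevel=2,
        )
    return OrrLassoModel(
        intercept=float(raw["intercept"]),
        coefficients=coefficients,
        lambda_=raw["lambda"],
        cv_mse=raw["cv_mse"],
        training_meta=raw.get("meta", {}),
    )


def load_top_cpgs_fixture() -> pd.DataFrame:
    """The printed top ORR-associated CpG rows (probe, genes, rho, P)."""
    df = pd.read_csv(_data_path("top_orr_cpgs.tsv"), sep="\t", dtype={"gene_symbols": str},
                     keep_default_na=False)
    df["genes"] = [split_gene_symbols(g) for g in df["gene_symbols"]]
    df["rho"] = df["rho"].astype(float)
    df["p_value"] = df["p_value"].astype(float)
    return df.set_index("probe_id")


def load_fixtures() -> Fixtures:
    """All shipped reference tables in one call."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = load_published_model()
    return Fixtures(
        orr_table=load_orr_fixture(),
        published_model=model,
        top_cpgs=load_top_cpgs_fixture(),
    )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "dialect": {"sep": None, "missing_tokens": list(DEFAULT_MISSING_TOKENS)},
    "ppi_min_score": DEFAULT_PPI_MIN_SCORE,
    "screen": {"rho_threshold": 0.7, "p_threshold": 0.001},
    "tmb": {"exome_size_mb": 38.0, "classes": ["Missense_Mutation"]},
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config and merge it over the package defaults."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return config
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in user.items():
        if isinstance(value, Mapping) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def dialect_from_config(config: dict) -> IoDialect:
    d = config.get("dialect", {})
    return IoDialect(
        sep=d.get("sep"),
        missing_tokens=tuple(d.get("missing_tokens", DEFAULT_MISSING_TOKENS)),
    )
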