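"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices are genes x samples, first column holding the gene
symbol and the header row holding sample identifiers (the GCT-like
convention).  All readers validate hard: duplicate identifiers, missing
or non-numeric cells, and malformed headers raise ``ValueError`` rather
than propagating silently.  Matrices are written at full float precision
so that write -> read round-trips are loss-free; signature files carry
correlations at six decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "SurvivalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gmt",
    "read_clinical_table",
    "write_clinical_table",
    "read_signature",
    "write_signature",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene
    symbols and whose columns hold unique sample identifiers; every cell
    is finite.  Identifiers are case-sensitive.
    """

    def __init__(self, values: pd.DataFrame, impute_row_mean: bool = False):
        self.values = _validate_expression_frame(values, impute_row_mean=impute_row_mean)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        present = [g for g in gene_ids if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


def _validate_expression_frame(df: pd.DataFrame, impute_row_mean: bool = False) -> pd.DataFrame:
    df = df.copy()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    dup_genes = df.index[df.index.duplicated()].unique()
    if len(dup_genes):
        raise ValueError(f"duplicate gene symbol(s): {', '.join(dup_genes[:5])}")
    dup_samples = df.columns[df.columns.duplicated()].unique()
    if len(dup_samples):
        raise ValueError(f"duplicate sample identifier(s): {', '.join(dup_samples[:5])}")

    # locate non-numeric cells before a blanket cast so the error can name them
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value {df.at[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
    values = df.astype(float)

    if values.isna().any().any():
        if impute_row_mean:
            row_means = values.mean(axis=1)
            if row_means.isna().any():
                gene = row_means.index[row_means.isna()][0]
                raise ValueError(f"gene {gene!r} has no observed values to impute from")
            values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            n_missing = int(values.isna().sum().sum())
            raise ValueError(
                f"{n_missing} missing value(s); rerun with impute_row_mean=True to impute"
            )
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("non-finite value(s) in expression matrix")
    return values


@dataclass
class GeneSet:
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self):
        for name, gs in self.sets.items():
            if not gs.genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


class SurvivalTable:
    """Per-sample follow-up time (days), event indicator, optional covariates."""

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str)
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicated sample identifier {dup!r}")
        for col in ("time", "event"):
            if col not in data.columns:
                raise ValueError(f"missing required column {col!r}")
        data["time"] = pd.to_numeric(data["time"])
        data["event"] = pd.to_numeric(data["event"])
        if (data["time"] < 0).any():
            bad = data.index[data["time"] < 0][0]
            raise ValueError(f"negative time for sample {bad!r}")
        if not data["event"].isin([0, 1]).all():
            bad = data.index[~data["event"].isin([0, 1])][0]
            raise ValueError(f"event not in {{0,1}} for sample {bad!r}")
        data["event"] = data["event"].astype(int)
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# expression matrices (TSV / GCT 1.2)
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path,
    format: str = "tsv",
    transform: str = "none",
    impute_row_mean: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    ``transform='log2p1'`` applies log2(x + 1) elementwise after reading,
    for inputs stored on a linear scale (e.g. RSEM estimates).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    elif format == "gct":
        df = _read_gct(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    matrix = ExpressionMatrix(df, impute_row_mean=impute_row_mean)
    if transform == "log2p1":
        vals = matrix.values
        if (vals < 0).any().any():
            raise ValueError("log2p1 transform requires non-negative values")
        matrix = ExpressionMatrix(np.log2(vals + 1.0))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return matrix


def _read_gct(path) -> pd.DataFrame:
    with open(path, "rt", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"GCT version line {version!r}; expected '#1.2'")
        dims = fh.readline().strip().split("\t")
        if len(dims) != 2:
            raise ValueError("GCT dimension line must hold two tab-separated integers")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" not in df.columns:
        raise ValueError("GCT header must contain a Description column")
    df = df.drop(columns=["Description"])
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"GCT dimension mismatch: header says {n_genes}x{n_samples}, table is "
            f"{df.shape[0]}x{df.shape[1]}"
        )
    return df


def write_expression_matrix(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    if format == "tsv":
        out = matrix.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "gct":
        n_genes, n_samples = matrix.shape
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            out = matrix.values.copy()
            out.insert(0, "Description", "na")
            out.index.name = "NAME"
            out.to_csv(fh, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file (name, description, then member genes, tab-separated)."""
    sets: dict[str, GeneSet] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(
                    f"gene set {name!r}: {len(members) - len(deduped)} duplicate member(s) removed",
                    stacklevel=2,
                )
            sets[name] = GeneSet(description=desc, genes=deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, gs in collection:
            fh.write("\t".join([name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical survival tables
# ---------------------------------------------------------------------------

def read_clinical_table(path) -> SurvivalTable:
    """TSV with columns sample, time, event; extra columns become covariates."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample" not in df.columns:
        raise ValueError("clinical table must have a 'sample' column")
    df = df.set_index("sample")
    return SurvivalTable(df)


def write_clinical_table(table: SurvivalTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# signature TSV
# ---------------------------------------------------------------------------

def read_signature(path):
    """Read a signature TSV (columns: gene, set, r_cohortA, r_cohortB)."""
    from .signature import SignatureDefinition  # deferred: avoids import cycle

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "set", "r_cohortA", "r_cohortB"}
    if not required.issubset(df.columns):
        raise ValueError(f"signature file must have columns {sorted(required)}")
    unknown = set(df["set"]) - {"REST", "RESTless"}
    if unknown:
        raise ValueError(f"unknown set label(s): {sorted(unknown)}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"gene {dup!r} listed more than once")
    rest = list(df.loc[df["set"] == "REST", "gene"])
    restless = list(df.loc[df["set"] == "RESTless", "gene"])
    corr = df.set_index("gene")[["r_cohortA", "r_cohortB"]].astype(float)
    meta = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# ") and "=" in line:
                key, _, val = line[2:].strip().partition("=")
                meta[key.strip()] = val.strip()
    seed_gene = meta.get("seed_gene") or None
    cutoff = float(meta["cutoff"]) if "cutoff" in meta else None
    return SignatureDefinition(
        seed_gene=seed_gene, rest_type=rest, restless_type=restless,
        cutoff=cutoff, correlations=corr,
    )


def write_signature(signature, path) -> None:
    rows = []
    corr = signature.correlations
    for gene in signature.rest_type:
        ra, rb = _gene_corr(corr, gene)
        rows.append((gene, "REST", ra, rb))
    for gene in signature.restless_type:
        ra, rb = _gene_corr(corr, gene)
        rows.append((gene, "RESTless", ra, rb))
    with open(path, "wt", encoding="utf-8") as fh:
        if signature.seed_gene is not None:
            fh.write(f"# seed_gene = {signature.seed_gene}\n")
        if signature.cutoff is not None:
            fh.write(f"# cutoff = {signature.cutoff:g}\n")
        fh.write("gene\tset\tr_cohortA\tr_cohortB\n")
        for gene, label, ra, rb in rows:
            fh.write(f"{gene}\t{label}\t{ra:.6f}\t{rb:.6f}\n")


def _gene_corr(corr, gene):
    if corr is not None and gene in corr.index:
        return float(corr.at[gene, "r_cohortA"]), float(corr.at[gene, "r_cohortB"])
    return float("nan"), float("nan")
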