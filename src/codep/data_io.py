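"""Typed readers and writers for the tabular formats the pipeline consumes.

All matrices are held genes-by-samples in memory regardless of how the file
on disk is oriented.  Missing cells are NaN, never zero.  Gene identifiers
in DepMap-style headers ("SYMBOL (entrezid)") are reduced to the plain
symbol on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneEffectMatrix",
    "ExpressionMatrix",
    "ClinicalTable",
    "DrugResponseRaw",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "read_drug_response",
    "write_table",
    "read_table",
]

_MISSING_TOKENS = {"", "NA"}
_FLOAT_FMT = "%.17g"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _strip_entrez_suffix(token: str) -> str:
    # "CDK9 (1025)" -> "CDK9"; plain symbols pass through unchanged
    token = token.strip()
    if " (" in token:
        return token.split(" (")[0]
    return token


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DataError(f"duplicate {what} identifiers: {', '.join(map(str, dups))}")


@dataclass
class GeneEffectMatrix:
    """CRISPR knockout fitness-effect scores, genes x cell lines.

    More negative scores mean the gene is more required for viability.
    ``lineage`` optionally maps each cell line to its tissue of origin.
    """

    gene_ids: list
    cell_line_ids: list
    values: np.ndarray
    lineage: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_line_ids, "cell line")
        if self.values.shape != (len(self.gene_ids), len(self.cell_line_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_line_ids)} lines"
            )
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise DataError("non-finite (inf) entries in effect matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_line_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.values[i]


@dataclass
class ExpressionMatrix:
    """log2(TPM+1) expression, genes x samples; entries are >= 0."""

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    sample_group: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("expression matrix shape does not match id lists")
        obs = self.values[~np.isnan(self.values)]
        if not np.isfinite(obs).all():
            raise DataError("non-finite entries in expression matrix")
        if (obs < 0).any():
            raise DataError("negative expression values; expected log2(TPM+1) >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.values[i]


@dataclass
class ClinicalTable:
    """Per-sample outcome: time-to-event in days, event indicator, cancer type."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray
    cancer_type: list

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if not (len(self.time) == len(self.event) == len(self.cancer_type) == n):
            raise DataError("clinical table columns have unequal lengths")
        if (self.time < 0).any():
            raise DataError("negative time-to-event")
        if not np.isin(self.event, [0, 1]).all():
            raise DataError("event indicator must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "time_days": self.time,
                "event": self.event,
                "cancer_type": self.cancer_type,
            }
        )


@dataclass
class DrugResponseRaw:
    """Long-format (drug, cell line, AUC) rows; duplicates permitted."""

    table: pd.DataFrame  # columns: drug, cell_line, auc

    def __post_init__(self):
        required = ["drug", "cell_line", "auc"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataError(f"drug response table missing columns: {missing}")
        auc = self.table["auc"].to_numpy(dtype=float)
        if ((auc < 0) | (auc > 1)).any():
            raise DataError("AUC values must lie in [0, 1]")

    def __len__(self):
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT style) with one-line descriptions."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise DataError(f"gene set {name!r} contains duplicate genes")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _sep_for(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".txt") else ","


def _parse_numeric(df: pd.DataFrame, path) -> np.ndarray:
    """Convert a string-valued frame to floats, reporting the first bad cell."""
    raw = df.to_numpy(dtype=object)
    out = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell in _MISSING_TOKENS:
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(cell)
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric value {cell!r} at data row {i + 1}, "
                    f"column {j + 1}"
                ) from None
    return out


def read_matrix(path, orientation: str = "genes_by_samples", kind: str = "gene_effect"):
    """Read a delimited matrix file into a genes-by-samples object.

    Parameters
    ----------
    path : str or Path
        ``.csv`` (comma) or ``.tsv``/``.txt`` (tab) file with one header row
        and the row identifiers in the first column.
    orientation : {"genes_by_samples", "samples_by_genes"}
        How the *file* is laid out; the returned object is always
        genes-by-samples.
    kind : {"gene_effect", "expression"}
        Which domain type to construct.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if kind not in ("gene_effect", "expression"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(
        path, sep=_sep_for(path), dtype=str, keep_default_na=False, index_col=0
    )
    values = _parse_numeric(df, path)
    row_ids = [str(s).strip() for s in df.index]
    col_ids = [str(s).strip() for s in df.columns]
    if orientation == "samples_by_genes":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    genes = [_strip_entrez_suffix(g) for g in row_ids]
    _check_unique(genes, "gene")
    _check_unique(col_ids, "sample")
    if kind == "gene_effect":
        return GeneEffectMatrix(genes, col_ids, values)
    return ExpressionMatrix(genes, col_ids, values)


def write_matrix(matrix, path) -> None:
    """Write a matrix object genes-by-samples; missing entries become "NA"."""
    matrix.to_frame().to_csv(path, sep=_sep_for(path), na_rep="NA", float_format=_FLOAT_FMT)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: tab-delimited ``name, description, gene, gene, ...``.

    Duplicate genes within a set are dropped, first occurrence kept.
    """
    sets, descriptions = {}, {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise DataError(f"{path}: duplicate set name {name!r} at line {lineno}")
            seen, uniq = set(), []
            for g in genes:
                if g and g not in seen:
                    uniq.append(g)
                    seen.add(g)
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical outcome table: sample, time_days, event, cancer_type."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = ["sample", "time_days", "event", "cancer_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: clinical table missing columns {missing}")
    return ClinicalTable(
        sample_ids=[s.strip() for s in df["sample"]],
        time=pd.to_numeric(df["time_days"]).to_numpy(),
        event=pd.to_numeric(df["event"]).to_numpy(),
        cancer_type=[s.strip() for s in df["cancer_type"]],
    )


def read_drug_response(path) -> DrugResponseRaw:
    """Read a long-format drug response file with columns drug, cell_line, auc."""
    df = pd.read_csv(path, sep=_sep_for(path))
    return DrugResponseRaw(table=df[["drug", "cell_line", "auc"]].copy())


def write_table(result, path) -> None:
    """Write any tabular result (DataFrame or object with ``to_frame``)."""
    df = result if isinstance(result, pd.DataFrame) else result.to_frame()
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep=_sep_for(path), na_values=["NA"], keep_default_na=False)
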