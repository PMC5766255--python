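"""Reading, validation, matching and coverage filtering of expression layers.

Matrices are stored analytes x cells.  Three layers are recognised:
``protein`` and ``phospho`` (antibody measurements) and ``mrna`` (gene
symbols).  Phosphosite antibody ids follow the ``GENE_pSITE`` convention
(e.g. ``SRC_pY416``); the gene part is used for gene-level matching when no
explicit antibody-to-gene mapping is supplied.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Layer = Literal["protein", "phospho", "mrna"]

VALID_LAYERS = ("protein", "phospho", "mrna")

#: strings treated as missing when parsing matrix bodies
MISSING_TOKENS = {"", "na", "nan", "null", "none", "n/a"}


@dataclass
class ExpressionMatrix:
    """One regulatory layer: analytes x cell lines, missing values allowed."""

    layer: str
    values: pd.DataFrame  # index = analyte ids, columns = cell ids, float
    analyte_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate analyte ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids: {dups}")
        self.values = self.values.astype(float)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_analytes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def coverage(self) -> pd.Series:
        """Non-missing cell count per analyte."""
        return self.values.notna().sum(axis=1)

    def gene_of(self, analyte: str) -> str:
        """Gene symbol an analyte maps to (mapping file, else GENE_pSITE rule)."""
        if self.analyte_gene and analyte in self.analyte_gene:
            return self.analyte_gene[analyte]
        if self.layer == "mrna":
            return analyte
        if "_p" in analyte:
            return analyte.split("_p")[0]
        return analyte

    def subset_cells(self, cells: list[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[:, cells].copy())

    def subset_analytes(self, analytes: list[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[analytes].copy())


@dataclass
class Annotation:
    """Cell-line annotations: tissue of origin, tumor class, optional mutations."""

    table: pd.DataFrame  # index = cell_id; columns include tissue, tumor_class
    mutations: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids in annotation: {dups}")
        if "tissue" not in self.table.columns:
            raise ValueError("annotation table requires a 'tissue' column")
        if "tumor_class" not in self.table.columns:
            self.table = self.table.assign(tumor_class="NS")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def tissues_for(self, cells: list[str]) -> pd.Series:
        return self.table.loc[cells, "tissue"]

    def subset(self, cells: list[str]) -> "Annotation":
        muts = {c: m for c, m in self.mutations.items() if c in set(cells)}
        return Annotation(self.table.loc[cells].copy(), muts)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_matrix(
    path: str | Path,
    layer: str,
    orientation: Literal["analytes_in_rows", "cells_in_rows"] = "analytes_in_rows",
    analyte_gene: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV/CSV auto-detected, GCT 1.2 accepted).

    Missing encodings ("", NA, NaN, null, ...) all map to missing.  Raises
    ``ValueError`` locating the offending row/column for duplicate ids or
    non-numeric cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    skiprows = 0
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#1.2"):  # GCT 1.2: version line + dims line
        skiprows = 2
        sep = "\t"

    df = pd.read_csv(path, sep=sep, index_col=0, skiprows=skiprows, dtype=str)
    if skiprows and "Description" in df.columns:
        df = df.drop(columns="Description")

    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path.name}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ids in {path.name}: {dups}")

    def parse(cell: object, row: str, col: str) -> float:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        s = str(cell).strip()
        if s.lower() in MISSING_TOKENS:
            return np.nan
        try:
            v = float(s)
        except ValueError:
            raise ValueError(
                f"non-numeric value {s!r} at row {row!r}, column {col!r} in {path.name}"
            ) from None
        if not np.isfinite(v):
            return np.nan
        return v

    out = np.empty(df.shape, dtype=float)
    for i, row in enumerate(df.index):
        for j, col in enumerate(df.columns):
            out[i, j] = parse(df.iat[i, j], str(row), str(col))
    values = pd.DataFrame(out, index=df.index.astype(str), columns=df.columns.astype(str))

    if orientation == "cells_in_rows":
        values = values.T
    m = ExpressionMatrix(layer=layer, values=values,
                         analyte_gene=dict(analyte_gene) if analyte_gene else None)
    all_missing = m.coverage() == 0
    if all_missing.any():
        keep = m.coverage()[~all_missing].index.tolist()
        logger.warning("dropping %d all-missing analytes", int(all_missing.sum()))
        m = m.subset_analytes(keep)
    return m


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, analytes in rows, empty cell = missing."""
    m.values.to_csv(path, sep="\t", na_rep="")


def read_annotation(path: str | Path) -> Annotation:
    """Read the annotation CSV (cell_line, tissue, tumor_class[, mutations...])."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return Annotation(df)


def read_gene_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column antibody-to-gene mapping TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("mapping file needs two columns: antibody, gene")
    first = df.iloc[0]
    if first[0].lower() in {"antibody", "analyte"} or first[1].lower() in {"gene", "symbol"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def filter_analytes_by_coverage(m: ExpressionMatrix, min_cells: int) -> ExpressionMatrix:
    """Retain analytes with at least ``min_cells`` non-missing values (inclusive)."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    keep = m.coverage()
    retained = [a for a in m.analyte_ids if keep[a] >= min_cells]
    return m.subset_analytes(retained)


def match_layers(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    ann: Annotation | None = None,
    by: Literal["cell", "gene"] = "cell",
) -> tuple[ExpressionMatrix, ExpressionMatrix, Annotation | None, pd.DataFrame | None]:
    """Align two layers on shared cell lines and, optionally, map analytes by gene.

    Returns ``(a_matched, b_matched, ann_matched, pairs)``.  ``pairs`` is None
    for cell matching; for gene matching it is a table with columns
    ``analyte_a, analyte_b, gene`` listing every mapped analyte pair
    (many-to-one antibody-to-gene mappings produce multiple rows per gene).
    Antibodies without a gene match in the other layer are dropped with a
    logged count.
    """
    shared = [c for c in a.cell_ids if c in set(b.cell_ids)]
    if ann is not None:
        ann_cells = set(ann.cell_ids)
        shared = [c for c in shared if c in ann_cells]
    if not shared:
        raise ValueError("no shared cell lines between the two layers")

    a2, b2 = a.subset_cells(shared), b.subset_cells(shared)
    ann2 = ann.subset(shared) if ann is not None else None
    if by == "cell":
        return a2, b2, ann2, None

    gene_to_b: dict[str, list[str]] = {}
    for ab in b2.analyte_ids:
        gene_to_b.setdefault(b2.gene_of(ab), []).append(ab)
    rows, dropped = [], 0
    for aa in a2.analyte_ids:
        g = a2.gene_of(aa)
        partners = gene_to_b.get(g)
        if not partners:
            dropped += 1
            continue
        for ab in partners:
            rows.append((aa, ab, g))
    if dropped:
        logger.info("gene matching: %d analytes of layer %s had no partner in layer %s",
                    dropped, a2.layer, b2.layer)
    if not rows:
        raise ValueError("gene matching produced no pairs")
    pairs = pd.DataFrame(rows, columns=["analyte_a", "analyte_b", "gene"])
    a3 = a2.subset_analytes(sorted(set(pairs["analyte_a"]), key=a2.analyte_ids.index))
    b3 = b2.subset_analytes(sorted(set(pairs["analyte_b"]), key=b2.analyte_ids.index))
    return a3, b3, ann2, pairs
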