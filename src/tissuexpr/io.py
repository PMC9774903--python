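"""Readers, writers and the core in-memory containers.

The single substrate of every downstream stage is :class:`ExpressionMatrix`:
a genes × samples table of FPKM values plus a sample → tissue design map.
All file formats are plain delimited text (TSV by default, CSV via the
``delimiter`` argument) or standard GMT for gene-set collections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "read_expression_matrix",
    "read_design",
    "attach_design",
    "read_gmt",
    "write_gmt",
    "read_annotation",
]


class GeneSet(NamedTuple):
    """A named collection of gene identifiers (one GMT line)."""

    set_id: str
    description: str
    members: frozenset[str]


@dataclass
class ExpressionMatrix:
    """FPKM expression values for G genes × S samples with a tissue design.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id. All
        entries must be finite and non-negative.
    design
        Series mapping sample id → tissue label, or ``None`` when the design
        has not been attached yet. When present it must cover every sample
        column exactly.
    """

    values: pd.DataFrame
    design: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if arr.size and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if self.design is not None:
            missing = [s for s in cols if s not in self.design.index]
            if missing:
                raise ValueError(f"samples missing from design: {missing}")
            self.design = self.design.loc[cols].astype(str)

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance in the design."""
        if self.design is None:
            raise ValueError("no design attached")
        seen: dict[str, None] = {}
        for t in self.design:
            seen.setdefault(t, None)
        return list(seen)

    def samples_of(self, tissue: str) -> list[str]:
        if self.design is None:
            raise ValueError("no design attached")
        return list(self.design.index[self.design == tissue])

    def tissue_groups(self) -> dict[str, list[str]]:
        return {t: self.samples_of(t) for t in self.tissues}

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(self.values.loc[genes], self.design)

    def log2p1(self) -> pd.DataFrame:
        """log2(FPKM + 1) transform of the value matrix."""
        return np.log2(self.values + 1.0)

    # -- round trip ------------------------------------------------------
    def to_tsv(self, path: str | Path, delimiter: str = "\t",
               float_format: str = "%.6g") -> None:
        self.values.to_csv(path, sep=delimiter, index_label="gene_id",
                           float_format=float_format)

    def design_to_tsv(self, path: str | Path, delimiter: str = "\t") -> None:
        if self.design is None:
            raise ValueError("no design attached")
        frame = pd.DataFrame(
            {"sample_id": self.design.index, "tissue": self.design.to_numpy()}
        )
        frame.to_csv(path, sep=delimiter, index=False)


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited genes × samples FPKM table.

    First row is the sample header, first column the gene id. Values are
    parsed as double-precision floats with no rounding; row and column
    order are preserved. Duplicate identifiers, non-numeric cells and
    negative values are hard errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path.name}: {dup}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path.name}: {dup}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r} (column {j + 1}) in {path.name}"
            )
        values[col] = parsed
    return ExpressionMatrix(values)


def read_design(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, tissue) design table with header."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"design file {path} needs 2 columns, got {frame.shape[1]}")
    sample_col, tissue_col = frame.columns[:2]
    if frame[sample_col].duplicated().any():
        dup = frame[sample_col][frame[sample_col].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in design: {dup}")
    return pd.Series(frame[tissue_col].to_numpy(), index=frame[sample_col], name="tissue")


def attach_design(matrix: ExpressionMatrix,
                  design: pd.Series | Mapping[str, str] | str | Path,
                  delimiter: str = "\t") -> ExpressionMatrix:
    """Attach a sample → tissue design to a matrix.

    Samples present in the design but absent from the matrix are ignored
    with a warning; matrix samples missing from the design are a hard
    error listing the offenders.
    """
    if isinstance(design, (str, Path)):
        design = read_design(design, delimiter=delimiter)
    elif not isinstance(design, pd.Series):
        design = pd.Series(dict(design), name="tissue")
    missing = [s for s in matrix.sample_ids if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    extra = [s for s in design.index if s not in matrix.values.columns]
    if extra:
        warnings.warn(f"design samples absent from matrix ignored: {extra}")
    return ExpressionMatrix(matrix.values, design.loc[matrix.values.columns])


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: tab-separated set_id, description, members...

    Lines with fewer than three fields are a hard error citing the line
    number; empty lines are skipped.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields (need >= 3)"
                )
            set_id, desc, *members = fields
            members = [m for m in members if m]
            if set_id in seen:
                raise ValueError(f"duplicate gene set id {set_id!r} at line {lineno}")
            seen.add(set_id)
            sets.append(GeneSet(set_id, desc, frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def read_annotation(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a gene annotation table (gene_id, biotype, symbol) with header."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    gene_col = frame.columns[0]
    if frame[gene_col].duplicated().any():
        dup = frame[gene_col][frame[gene_col].duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dup}")
    return frame.set_index(gene_col)
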