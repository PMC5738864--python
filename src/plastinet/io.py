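"""Expression-matrix and probe-annotation input/output.

Expression data are genes x samples tables of intensities (arbitrary units),
keyed by probe ID. Probe IDs are the canonical gene identity everywhere in
the pipeline; gene symbols from the annotation table are display-only,
because symbols can collide across probes while probe IDs cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

GROUP_LABELS = ("naive", "plastic")
SCALE_TAGS = ("raw", "normalized", "log2")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with group labels and a scale tag.

    Parameters
    ----------
    values
        DataFrame with probe IDs as index and sample IDs as columns. No
        missing values are allowed.
    groups
        Per-sample label, ``"naive"`` or ``"plastic"``, indexed by sample ID.
    scale
        One of ``"raw"``, ``"normalized"``, ``"log2"``; recorded in all
        downstream provenance.
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if self.values.isna().any().any():
            gene = self.values.index[self.values.isna().any(axis=1)][0]
            raise ValueError(f"missing values in gene {gene!r}")
        missing = [s for s in cols if s not in self.groups.index]
        if missing:
            raise ValueError(f"sample without group label: {missing[0]!r}")
        bad = [s for s in cols if self.groups[s] not in GROUP_LABELS]
        if bad:
            raise ValueError(
                f"sample {bad[0]!r} has group {self.groups[bad[0]]!r}; "
                f"expected one of {GROUP_LABELS}"
            )
        if self.scale not in SCALE_TAGS:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        # keep group order aligned with columns
        self.groups = self.groups.reindex(cols)

    # -- convenience ----------------------------------------------------
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

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"gene not found: {missing[0]!r}")
        return ExpressionMatrix(self.values.loc[genes], self.groups, self.scale)


@dataclass
class GeneAnnotation:
    """Probe annotation: probe ID -> (GenBank accession, gene symbol).

    Probes without a known gene carry the symbol ``"EST"``.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["accession", "symbol"]))

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID in annotation: {dup!r}")

    def symbol(self, probe_id: str) -> str:
        if probe_id in self.table.index:
            return str(self.table.loc[probe_id, "symbol"])
        return "EST"

    def accession(self, probe_id: str) -> str:
        if probe_id in self.table.index:
            return str(self.table.loc[probe_id, "accession"])
        return ""

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)


def read_expression(path: str | Path, group_map: Mapping[str, str],
                    scale: str = "raw") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    The file has a header row of sample IDs and probe IDs in the first
    column. ``group_map`` must assign ``"naive"`` or ``"plastic"`` to every
    sample in the file; unmapped samples are rejected by name.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    unmapped = [s for s in df.columns if s not in group_map]
    if unmapped:
        raise ValueError(f"sample without group label: {unmapped[0]!r}")
    groups = pd.Series({s: group_map[s] for s in df.columns})
    return ExpressionMatrix(df.astype(float), groups, scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV (probe IDs first column, sample-ID header)."""
    expr.values.to_csv(path, sep="\t", index_label="probe_id")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample_id, group) into a group map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     dtype=str)
    return dict(zip(df["sample_id"], df["group"]))


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a 3-column TSV (probe_id, accession, symbol).

    An empty file yields an empty annotation whose lookups fall back to
    ``"EST"`` / ``""``.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["probe_id", "accession", "symbol"], dtype=str)
    except pd.errors.EmptyDataError:
        return GeneAnnotation()
    df = df.set_index("probe_id")
    df["symbol"] = df["symbol"].fillna("EST")
    df["accession"] = df["accession"].fillna("")
    return GeneAnnotation(df)


def log2_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Return log2(max(value, 1)) of the matrix, tagged ``scale="log2"``.

    Clipping at 1 keeps the transform defined on background-subtracted
    intensities that can dip to zero or below.
    """
    vals = np.log2(expr.values.clip(lower=1.0))
    return ExpressionMatrix(vals, expr.groups, "log2")
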