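"""Tabular and gene-set file formats shared by every analysis stage.

Expression values are exchanged on log2 scale throughout the package: RMA-style
normalisation of microarray data produces log2 intensities, and every threshold
(e.g. the low-expression filter at 2^6) is interpreted on that convention.
Linear-scale input must be log2-transformed by the caller. Missing values are
not supported: a NaN cell is a hard error, never silently dropped.

Supported formats: plain TSV (first column feature IDs, header row sample IDs,
``#``-prefixed comment lines ignored), GCT v1.2, GMT gene-set collections, and
two-column probe→gene maps. All writers terminate files with a newline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Biopsy condition labels: non-involved skin, baseline papule,
#: vehicle-treated (spontaneously resolved) papule, treated papule.
CONDITIONS: tuple[str, ...] = ("L_NI", "L1", "L3", "R3")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, features × samples.

    Parameters
    ----------
    values
        DataFrame with feature IDs as index and sample IDs as columns.
        All values must be finite floats.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float, copy=False)
        _check_unique(list(self.values.index), "feature ID")
        _check_unique(list(self.values.columns), "sample ID")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                "non-finite value at feature "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values.to_numpy(), other.values.to_numpy(), atol=0, rtol=0)
        )


@dataclass
class SampleTable:
    """Per-sample subject and condition annotation defining the pairing structure.

    Invariants: sample IDs unique; condition labels drawn from :data:`CONDITIONS`;
    a subject contributes at most one sample per condition.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        _check_unique(list(self.table["sample_id"]), "sample ID")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(
                f"unknown condition label(s) {sorted(bad)}; allowed: {list(CONDITIONS)}"
            )
        dup = self.table.duplicated(subset=["subject_id", "condition"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise FormatError(
                f"subject {row['subject_id']!r} has more than one sample "
                f"for condition {row['condition']!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, condition: str) -> list[str]:
        """Sample IDs belonging to one condition, in table order."""
        if condition not in CONDITIONS:
            raise FormatError(
                f"unknown condition {condition!r}; allowed: {list(CONDITIONS)}"
            )
        mask = self.table["condition"] == condition
        return list(self.table.loc[mask, "sample_id"])

    def subject_of(self) -> dict[str, str]:
        """Map sample_id → subject_id."""
        return dict(zip(self.table["sample_id"], self.table["subject_id"]))

    def condition_of(self) -> dict[str, str]:
        """Map sample_id → condition."""
        return dict(zip(self.table["sample_id"], self.table["condition"]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleTable):
            return NotImplemented
        return self.table[["sample_id", "subject_id", "condition"]].equals(
            other.table[["sample_id", "subject_id", "condition"]]
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"gene in set {self.name!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style); set names unique, each set non-empty."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene-set name")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


@dataclass
class ProbeGeneMap:
    """Probe-set → gene-symbol annotation; probes unique, genes may repeat."""

    pairs: pd.DataFrame  # columns: probe_id, gene_symbol

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol"}
        if not required <= set(self.pairs.columns):
            raise FormatError(f"probe map needs columns {sorted(required)}")
        _check_unique(list(self.pairs["probe_id"]), "probe ID")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.pairs["probe_id"], self.pairs["gene_symbol"]))


# ---------------------------------------------------------------------------
# Expression matrix I/O


def _read_tsv_lines(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if line == "":
                continue
            rows.append(line.split("\t"))
    return rows


def _parse_matrix_rows(
    rows: list[list[str]], n_skip: int, sample_ids: list[str]
) -> ExpressionMatrix:
    """Parse body rows; ``n_skip`` leading columns precede the data cells."""
    n_cols = len(sample_ids)
    feature_ids: list[str] = []
    data = np.empty((len(rows), n_cols), dtype=float)
    for i, row in enumerate(rows):
        feature_ids.append(row[0])
        cells = row[n_skip:]
        if len(cells) != n_cols:
            raise FormatError(
                f"row {row[0]!r} has {len(cells)} values, expected {n_cols}"
            )
        for j, cell in enumerate(cells):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"non-numeric cell {cell!r} at feature {row[0]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(pd.DataFrame(data, index=feature_ids, columns=sample_ids))


def read_expression_matrix(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a features × samples log2 expression matrix from TSV or GCT v1.2.

    TSV dialect: header row of sample IDs, first column feature IDs, ``#``
    comment lines ignored. GCT: v1.2 only (``#1.2`` version line, dimension
    line, NAME/Description columns). Duplicate IDs and non-numeric cells are
    hard errors naming the offender.
    """
    path = Path(path)
    if format == "tsv":
        rows = _read_tsv_lines(path)
        if not rows:
            raise FormatError(f"{path}: empty matrix file")
        header = rows[0]
        sample_ids = header[1:]
        return _parse_matrix_rows(rows[1:], 1, sample_ids)
    if format == "gct":
        with open(path, "r", encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(
                    f"{path}: unsupported GCT version line {version!r}; "
                    "only GCT v1.2 is supported"
                )
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            body = [
                line.rstrip("\n").split("\t")
                for line in fh
                if line.strip() != ""
            ]
        if not body:
            raise FormatError(f"{path}: GCT file has no header row")
        header = body[0]
        sample_ids = header[2:]
        data_rows = body[1:]
        if len(data_rows) != n_rows or len(sample_ids) != n_cols:
            raise FormatError(
                f"{path}: GCT dimension line says {n_rows}×{n_cols} but file has "
                f"{len(data_rows)} data rows × {len(sample_ids)} samples"
            )
        return _parse_matrix_rows(data_rows, 2, sample_ids)
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'gct'")


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write a matrix as TSV or GCT v1.2; the file ends with a newline."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if format == "tsv":
            fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
            for fid, row in zip(m.feature_ids, m.values.to_numpy()):
                fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        elif format == "gct":
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            fh.write("NAME\tDescription\t" + "\t".join(m.sample_ids) + "\n")
            for fid, row in zip(m.feature_ids, m.values.to_numpy()):
                fh.write(fid + "\tna\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        else:
            raise ValueError(f"unknown format {format!r}; use 'tsv' or 'gct'")


# ---------------------------------------------------------------------------
# Sample table I/O


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a TSV with columns sample_id, subject_id, condition."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.table[["sample_id", "subject_id", "condition"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT gene-set I/O


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, genes...

    Duplicate genes within a line are de-duplicated preserving first
    occurrence; a line whose gene list is empty after de-duplication is
    rejected. Duplicate set names and lines with fewer than 3 fields are hard
    errors reporting the line number.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line has {len(fields)} fields, "
                    "need at least name, description and one gene"
                )
            name, description = fields[0], fields[1]
            if name in names:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            names.add(name)
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name, description, tuple(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Probe→gene map I/O


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read a 2-column TSV (probe_id, gene_symbol); a header row is optional."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: probe map must have exactly 2 columns")
    first = df.iloc[0]
    if list(first) == ["probe_id", "gene_symbol"]:
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = ["probe_id", "gene_symbol"]
    return ProbeGeneMap(df)
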