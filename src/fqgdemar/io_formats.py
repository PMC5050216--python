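"""Readers and writers for the plain-text formats the pipeline touches.

All tables are tab-separated with '.' decimals and no quoting (the dialect of
GEO series-matrix exports). Readers validate strictly and raise
:class:`FormatError` naming the offending line instead of coercing silently;
every writer emits files its own reader accepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "StudyDesign",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "code_design",
    "read_design",
    "write_design",
    "read_genesets",
    "write_genesets",
    "read_edgelist",
    "write_edgelist",
    "EDGE_TYPES",
]

#: Recognized interaction-edge types; genetic and metabolic regulation are
#: directed, protein-protein (pp) contacts are undirected.
EDGE_TYPES = ("genetic", "pp", "metabolic")

_SEX_CODES = {"male": -1, "m": -1, "female": +1, "f": +1}


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class ExpressionMatrix:
    """Dense probe x sample table of log2 intensities.

    ``values`` is indexed by probe ID with sample IDs as columns;
    ``annotation`` maps probe IDs to gene symbols and may cover only part of
    the probes (unannotated probes keep an empty symbol).
    """

    values: pd.DataFrame
    annotation: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe ID {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = self.values.index[~np.isfinite(arr).all(axis=1)][0]
            raise FormatError(f"non-finite expression value at probe {bad!r}")
        if self.annotation is None:
            self.annotation = pd.Series("", index=self.values.index, dtype=object)
        else:
            self.annotation = (
                self.annotation.reindex(self.values.index).fillna("").astype(object)
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def gene_of(self, probes) -> pd.Series:
        """Gene symbols for ``probes`` (empty string when unannotated)."""
        return self.annotation.reindex(probes).fillna("")


@dataclass
class StudyDesign:
    """Per-sample +/-1 coding of the 2x2 age x sex design.

    ``table`` columns: sample_id, age_years, sex, age_code (i, +1 = Older),
    sex_code (j, +1 = Women).
    """

    table: pd.DataFrame
    age_cutoff: float = 64.0

    def __post_init__(self) -> None:
        required = {"sample_id", "age_years", "sex", "age_code", "sex_code"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample IDs in design")
        for col in ("age_code", "sex_code"):
            if not self.table[col].isin([-1, 1]).all():
                raise FormatError(f"{col} must be coded -1/+1")

    def samples_in_cell(self, i: int, j: int) -> list[str]:
        t = self.table
        sel = (t["age_code"] == i) & (t["sex_code"] == j)
        return t.loc[sel, "sample_id"].tolist()

    @property
    def cell_sizes(self) -> dict[tuple[int, int], int]:
        return {
            (i, j): len(self.samples_in_cell(i, j))
            for i in (-1, 1)
            for j in (-1, 1)
        }


# ---------------------------------------------------------------------------
# expression matrix


def _read_tsv_numeric(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        columns = header.split("\t")[1:]
        ncol = len(columns)
        index, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol + 1:
                raise FormatError(
                    f"{path}: line {lineno}: expected {ncol + 1} fields, got {len(parts)}"
                )
            index.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric cell") from None
    return pd.DataFrame(rows, index=index, columns=columns, dtype=float)


def read_expression(path, annotation_path=None) -> ExpressionMatrix:
    """Read a probes x samples log2 TSV (header row = sample IDs)."""
    values = _read_tsv_numeric(path)
    annotation = read_annotation(annotation_path) if annotation_path else None
    return ExpressionMatrix(values=values, annotation=annotation)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_annotation(path) -> pd.Series:
    """Read a two-column probe_id/gene_symbol TSV (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: annotation needs probe_id and gene_symbol columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, dtype=object)


def write_annotation(annotation: pd.Series, path) -> None:
    pd.DataFrame(
        {"probe_id": annotation.index, "gene_symbol": annotation.values}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design


def code_design(metadata: pd.DataFrame, age_cutoff: float = 64.0) -> StudyDesign:
    """Code sample metadata into the +/-1 factorial design.

    Age strictly above ``age_cutoff`` is Older (i = +1); age at or below the
    cutoff is Younger (i = -1). Women are j = +1, men j = -1; sex strings are
    accepted case-insensitively from {male, female, m, f}.
    """
    required = {"sample_id", "age_years", "sex"}
    missing = required - set(metadata.columns)
    if missing:
        raise FormatError(f"metadata missing columns {sorted(missing)}")
    ages = pd.to_numeric(metadata["age_years"], errors="coerce")
    if ages.isna().any():
        bad = metadata.loc[ages.isna(), "sample_id"].iloc[0]
        raise FormatError(f"missing or non-numeric age for sample {bad!r}")
    if (ages < 0).any():
        bad = metadata.loc[ages < 0, "sample_id"].iloc[0]
        raise FormatError(f"negative age for sample {bad!r}")
    sexes = metadata["sex"].astype(str).str.strip().str.lower()
    unknown = ~sexes.isin(_SEX_CODES)
    if unknown.any():
        bad = metadata.loc[unknown, "sex"].iloc[0]
        raise FormatError(f"unrecognized sex label {bad!r}")
    table = pd.DataFrame(
        {
            "sample_id": metadata["sample_id"].astype(str).values,
            "age_years": ages.values,
            "sex": sexes.map(lambda s: "female" if _SEX_CODES[s] > 0 else "male").values,
            "age_code": np.where(ages.values > age_cutoff, 1, -1),
            "sex_code": sexes.map(_SEX_CODES).astype(int).values,
        }
    )
    return StudyDesign(table=table, age_cutoff=age_cutoff)


def read_design(path, age_cutoff: float = 64.0) -> StudyDesign:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return code_design(meta, age_cutoff=age_cutoff)


def write_design(design: StudyDesign, path) -> None:
    design.table[["sample_id", "age_years", "sex"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT) and edge lists (SIF-style TSV)


def read_genesets(path) -> dict[str, set[str]]:
    """Read a GMT file: term, description, genes... per tab-separated line.

    Empty terms are dropped (a warning would be noise in batch use; the count
    is recoverable by the caller by comparing line counts).
    """
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: GMT needs term and description")
            term = parts[0]
            if term in terms:
                raise FormatError(f"{path}: line {lineno}: duplicate term {term!r}")
            genes = {g for g in parts[2:] if g}
            if genes:
                terms[term] = genes
    return terms


def write_genesets(terms: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, "na", *sorted(genes)]) + "\n")


def read_edgelist(path) -> pd.DataFrame:
    """Read a 3-column SIF-style TSV: source, edge_type, target."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields")
            src, etype, dst = parts
            if etype not in EDGE_TYPES:
                raise FormatError(
                    f"{path}: line {lineno}: unknown edge type {etype!r}"
                )
            rows.append((src, etype, dst))
    return pd.DataFrame(rows, columns=["source", "edge_type", "target"])


def write_edgelist(edges: pd.DataFrame, path) -> None:
    edges[["source", "edge_type", "target"]].to_csv(
        path, sep="\t", index=False, header=False
    )
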