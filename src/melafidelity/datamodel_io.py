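"""Domain types and TSV/GMT readers and writers.

Every table the pipeline touches flows through the types defined here:
gene-by-sample expression matrices (with an explicit unit tag), gene sets,
single-nucleotide variants with their trinucleotide context, per-sample
scalar score tables, survival records and ploidy-corrected copy-number
tables. All file formats are plain text: tab-separated values with a '.'
decimal (UTF-8) and the GMT dialect for gene sets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ParseError

__all__ = [
    "Unit",
    "SampleClass",
    "ExpressionMatrix",
    "GeneSet",
    "MutationRecord",
    "ScoreTable",
    "SurvivalRecord",
    "CopyNumberTable",
    "read_expression_table",
    "write_expression_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_mutation_table",
    "write_mutation_table",
    "read_score_table",
    "write_score_table",
    "read_survival_table",
    "write_survival_table",
    "read_copy_number_table",
    "write_copy_number_table",
]

VALID_BASES = frozenset("ACGT")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


class Unit(str, Enum):
    """Scale of an expression matrix."""

    TPM = "TPM"
    RPKM = "RPKM"
    LOG2_TPM1 = "LOG2_TPM1"  # log2(TPM/d + 1)
    NORMALIZED = "NORMALIZED"  # variance-stabilised or otherwise pre-normalised


class SampleClass(str, Enum):
    CELL_LINE = "CELL_LINE"
    TUMOUR = "TUMOUR"
    SINGLE_CELL = "SINGLE_CELL"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a unit tag and sample classes.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with sample identifiers as
        columns. Values must be finite; TPM/RPKM values must be >= 0.
    unit
        Scale of ``values``.
    sample_class
        Series mapping each sample identifier to a :class:`SampleClass`.
    """

    values: pd.DataFrame
    unit: Unit
    sample_class: pd.Series

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ConsistencyError(f"duplicate gene identifier: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ConsistencyError(f"duplicate sample identifier: {dup!r}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ConsistencyError("expression values must be finite")
        if self.unit in (Unit.TPM, Unit.RPKM) and (arr < 0).any():
            raise ConsistencyError(f"{self.unit.value} values must be non-negative")
        self.sample_class = pd.Series(self.sample_class).map(SampleClass)
        missing = self.values.columns.difference(self.sample_class.index)
        if len(missing):
            raise ConsistencyError(f"samples without a class: {list(missing)[:5]}")
        self.sample_class = self.sample_class.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.values.index)
        if len(missing):
            raise KeyError(f"genes not in matrix: {list(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.unit, self.sample_class)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        return ExpressionMatrix(
            self.values.loc[:, samples].copy(), self.unit, self.sample_class.loc[samples]
        )

    def with_values(self, values: pd.DataFrame, unit: Unit | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.unit if unit is None else unit, self.sample_class)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ConsistencyError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class MutationRecord:
    """One SNV with its 5' and 3' neighbouring bases (reference strand)."""

    sample: str
    ref: str
    alt: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        for name in ("ref", "alt", "five_prime", "three_prime"):
            base = getattr(self, name)
            if base not in VALID_BASES:
                raise ParseError(f"invalid base {base!r} in field {name}")
        if self.ref == self.alt:
            raise ConsistencyError(f"ref equals alt ({self.ref}) for sample {self.sample}")

    @property
    def context(self) -> str:
        return self.five_prime + self.ref + self.three_prime


@dataclass
class ScoreTable:
    """Per-sample scalar scores (Immune, Stromal, MITF, skin, ...)."""

    score_name: str
    values: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.values.index.has_duplicates:
            raise ConsistencyError("duplicate sample identifiers in score table")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ConsistencyError("scores must be finite")

    @property
    def samples(self) -> pd.Index:
        return self.values.index


@dataclass(frozen=True)
class SurvivalRecord:
    sample: str
    time: float  # months
    event: bool  # death observed
    group: str | None = None

    def __post_init__(self) -> None:
        if not (self.time >= 0 and math.isfinite(self.time)):
            raise ConsistencyError(f"negative or non-finite time for sample {self.sample}")


@dataclass
class CopyNumberTable:
    """Ploidy-corrected copy-number values, genes x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ConsistencyError("copy-number values must be finite")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty or malformed file: {path}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"no columns parsed from {path}")
    return df


def read_expression_table(
    path: str | Path,
    unit: Unit | str,
    sample_class_map: SampleClass | str | Mapping[str, SampleClass | str],
) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (header = sample ids, first column = gene ids).

    Duplicate gene rows are collapsed by taking the per-sample maximum, which
    keeps the most strongly detected isoform row. ``sample_class_map`` is
    either one class applied to every sample or a mapping per sample.
    """
    raw = _read_tsv(path, index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise FormatError(f"expression table {path} has no data rows")
    numeric = {}
    for col in raw.columns:
        try:
            # astype(float) goes through exact strtod parsing (bit-faithful
            # round trip), unlike pandas' fast to_numeric path
            numeric[col] = raw[col].astype(float)
        except (ValueError, TypeError):
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna()
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            ) from None
        if numeric[col].isna().any():
            gene = raw.index[numeric[col].isna().to_numpy().nonzero()[0][0]]
            raise ParseError(f"missing value at gene {gene!r}, sample {col!r}")
    df = pd.DataFrame(numeric, index=raw.index)
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).max()
    if isinstance(sample_class_map, (SampleClass, str)):
        classes = pd.Series(SampleClass(sample_class_map), index=df.columns)
    else:
        classes = pd.Series({s: SampleClass(c) for s, c in sample_class_map.items()})
    df.index.name = "gene"
    return ExpressionMatrix(df, Unit(unit), classes)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description, members, tab-separated."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"GMT line {lineno} lists no members")
            sets.append(GeneSet(name, frozenset(members)))
    if not sets:
        raise FormatError(f"no gene sets in {path}")
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sets:
            handle.write("\t".join([gs.name, "na", *sorted(gs.members)]) + "\n")


_MUTATION_COLUMNS = ("sample", "ref", "alt")


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-like TSV of SNVs with neighbouring-nucleotide information.

    Requires columns ``sample``, ``ref``, ``alt`` and either a 3-mer
    ``context`` column (middle base must equal ``ref``) or explicit
    ``five_prime``/``three_prime`` columns. Bases are upper-cased; row order
    is preserved.
    """
    df = _read_tsv(path, dtype=str)
    for col in _MUTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"mutation table missing column {col!r}")
    has_context = "context" in df.columns
    if not has_context and not {"five_prime", "three_prime"} <= set(df.columns):
        raise FormatError("mutation table needs 'context' or 'five_prime'/'three_prime'")
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        ref = str(row.ref).upper()
        alt = str(row.alt).upper()
        if has_context:
            context = str(row.context).upper()
            if len(context) != 3:
                raise ParseError(f"row {i}: context {context!r} is not a 3-mer")
            if context[1] != ref:
                raise ConsistencyError(
                    f"row {i}: context middle base {context[1]!r} != ref {ref!r}"
                )
            five, three = context[0], context[2]
        else:
            five = str(row.five_prime).upper()
            three = str(row.three_prime).upper()
        records.append(MutationRecord(str(row.sample), ref, alt, five, three))
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        {"sample": r.sample, "ref": r.ref, "alt": r.alt, "context": r.context}
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample", "ref", "alt", "context"]).to_csv(
        path, sep="\t", index=False
    )


def read_score_table(path: str | Path, score_name: str | None = None) -> ScoreTable:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError("score table needs columns: sample, <score>")
    name = score_name or df.columns[1]
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if values.isna().any():
        bad = df.iloc[values.isna().to_numpy().nonzero()[0][0], 0]
        raise ParseError(f"non-numeric score for sample {bad!r}")
    return ScoreTable(name, pd.Series(values.to_numpy(), index=df.iloc[:, 0].astype(str)))


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    out = table.values.rename(table.score_name)
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    df = _read_tsv(path)
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"survival table missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        group = getattr(row, "group", None)
        records.append(
            SurvivalRecord(
                str(row.sample),
                float(row.time),
                bool(int(row.event)),
                None if group is None or pd.isna(group) else str(group),
            )
        )
    return records


def write_survival_table(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    rows = [
        {"sample": r.sample, "time": r.time, "event": int(r.event), "group": r.group or ""}
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample", "time", "event", "group"]).to_csv(
        path, sep="\t", index=False
    )


def read_copy_number_table(path: str | Path) -> CopyNumberTable:
    df = _read_tsv(path, index_col=0)
    return CopyNumberTable(df.astype(float))


def write_copy_number_table(table: CopyNumberTable, path: str | Path) -> None:
    out = table.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
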