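"""Reading, validating and writing Cq tables and report bundles.

The input contract is positional: the first column holds sample
identifiers, the last column holds the group/condition label, and every
column in between is one gene's mean Cq values.  Column *names* play no
role in role assignment — a gene named "Group" in a middle column is a
gene.  Supported sources are Excel workbooks (``.xls``/``.xlsx``) and
delimited text (``.csv``/``.txt``) with a configurable delimiter and
decimal mark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, TableParseError, TableValidationError

__all__ = [
    "TableFormatOptions",
    "CqTable",
    "read_cq_table",
    "write_cq_table",
    "write_reports",
    "REPORT_FILENAMES",
]

#: canonical file names for the standard report bundle
REPORT_FILENAMES = (
    "outliers.tsv",
    "gene_reference_by_group.tsv",
    "descriptive_stats.tsv",
    "leave_one_out.tsv",
    "normfinder.tsv",
    "differential_expression.tsv",
)

_TEXT_EXTENSIONS = {".csv", ".txt", ".tsv"}
_EXCEL_EXTENSIONS = {".xls", ".xlsx"}

#: cell contents treated as missing Cq values
_NA_TOKENS = {"", "na", "nan", "n/a", "none", "null", "-"}


@dataclass(frozen=True)
class TableFormatOptions:
    """How to parse a delimited-text or workbook source.

    ``delimiter`` and ``decimal_mark`` apply to text formats only and must
    differ; ``sheet`` applies to workbooks only (Excel cells carry typed
    numbers, so no decimal-mark configuration is needed there).
    """

    delimiter: str = ","
    decimal_mark: str = "."
    sheet: int | str = 0
    has_header: bool = True

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ParameterError("delimiter must be a single character")
        if self.decimal_mark not in (".", ","):
            raise ParameterError("decimal_mark must be '.' or ','")
        if self.delimiter == self.decimal_mark:
            raise ParameterError(
                "delimiter and decimal_mark must differ "
                f"(both are {self.delimiter!r})"
            )


@dataclass
class CqTable:
    """Samples x genes matrix of quantification-cycle values with groups.

    ``cq`` is a float DataFrame indexed by sample id with one column per
    gene; ``group`` is a string Series aligned to the same index.  Missing
    Cq values are NaN and are excluded pairwise from downstream group
    statistics.
    """

    cq: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        self.cq = self.cq.astype(float)
        self.group = self.group.astype(str)
        self._validate()

    # -- contract checks -------------------------------------------------
    def _validate(self) -> None:
        if self.cq.shape[0] == 0:
            raise TableValidationError("table has no samples")
        if self.cq.shape[1] == 0:
            raise TableValidationError("table has no gene columns")
        if self.cq.index.duplicated().any():
            dups = self.cq.index[self.cq.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dups}")
        if self.cq.columns.duplicated().any():
            dups = self.cq.columns[self.cq.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate gene names: {dups}")
        if not self.group.index.equals(self.cq.index):
            raise TableValidationError("group labels do not align with samples")
        blank = self.group.str.strip() == ""
        if blank.any():
            raise TableValidationError(
                f"empty group label for samples: {list(self.group.index[blank])}"
            )
        with np.errstate(invalid="ignore"):
            if np.isinf(self.cq.to_numpy()).any():
                raise TableValidationError("non-finite Cq value present")

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.cq.index]

    @property
    def gene_names(self) -> list[str]:
        return [str(g) for g in self.cq.columns]

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.group))

    @property
    def n_samples(self) -> int:
        return self.cq.shape[0]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CqTable":
        missing = [s for s in sample_ids if s not in self.cq.index]
        if missing:
            raise TableValidationError(f"unknown sample ids: {missing}")
        return CqTable(self.cq.loc[list(sample_ids)], self.group.loc[list(sample_ids)])

    def to_frame(self) -> pd.DataFrame:
        """Full table in the input contract: Sample | genes... | Group."""
        out = self.cq.copy()
        out.insert(0, "Sample", self.cq.index)
        out["Group"] = self.group.values
        return out.reset_index(drop=True)


def _parse_cell(raw: object, decimal_mark: str, row: int, col: str) -> float:
    """Parse one Cq cell; raise with the cell address on failure."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    if isinstance(raw, (int, float, np.integer, np.floating)):
        return float(raw)
    text = str(raw).strip()
    if text.lower() in _NA_TOKENS:
        return math.nan
    if decimal_mark == ",":
        if "." in text:
            raise TableValidationError(
                f"non-numeric Cq cell {text!r} at row {row}, column {col!r} "
                "(contains '.' but decimal mark is ',')"
            )
        text = text.replace(",", ".")
    try:
        value = float(text)
    except ValueError:
        raise TableValidationError(
            f"non-numeric Cq cell {raw!r} at row {row}, column {col!r}"
        ) from None
    if not math.isfinite(value):
        raise TableValidationError(
            f"non-finite Cq cell {raw!r} at row {row}, column {col!r}"
        )
    return value


def _frame_to_cq_table(raw: pd.DataFrame, decimal_mark: str) -> CqTable:
    if raw.shape[1] < 3:
        raise TableValidationError(
            f"need at least 3 columns (sample, >=1 gene, group); got {raw.shape[1]}"
        )
    sample_col = raw.columns[0]
    group_col = raw.columns[-1]
    gene_cols = list(raw.columns[1:-1])

    sample_ids = raw[sample_col].astype(str).str.strip()
    if (sample_ids == "").any():
        raise TableValidationError("empty sample identifier present")
    if sample_ids.duplicated().any():
        dups = sample_ids[sample_ids.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate sample ids: {dups}")

    parsed = {}
    for col in gene_cols:
        parsed[str(col)] = [
            _parse_cell(v, decimal_mark, i + 1, str(col))
            for i, v in enumerate(raw[col])
        ]
    cq = pd.DataFrame(parsed, index=pd.Index(sample_ids, name="Sample"), dtype=float)
    group_raw = raw[group_col].where(raw[group_col].notna(), "")
    group = pd.Series(group_raw.astype(str).str.strip().values, index=cq.index,
                      name="Group")
    return CqTable(cq, group)


def read_cq_table(source: str | Path,
                  options: TableFormatOptions | None = None) -> CqTable:
    """Read and validate a Cq table from Excel or delimited text.

    Role assignment is positional: first column sample ids, last column
    group labels, middle columns gene Cq values.  Validation rejects
    duplicate sample ids, empty group labels and non-numeric Cq cells
    (naming the offending cell), mirroring an explicit confirm-table step.
    """
    options = options or TableFormatOptions()
    path = Path(source)
    if not path.exists():
        raise TableParseError(f"input file not found: {path}")
    ext = path.suffix.lower()
    try:
        if ext in _EXCEL_EXTENSIONS:
            raw = pd.read_excel(path, sheet_name=options.sheet,
                                header=0 if options.has_header else None,
                                dtype=object)
        elif ext in _TEXT_EXTENSIONS:
            raw = pd.read_csv(path, sep=options.delimiter,
                              header=0 if options.has_header else None,
                              dtype=object, encoding="utf-8-sig",
                              skipinitialspace=True)
        else:
            raise TableParseError(
                f"unsupported extension {ext!r}: expected one of "
                f"{sorted(_TEXT_EXTENSIONS | _EXCEL_EXTENSIONS)}"
            )
    except (pd.errors.ParserError, ValueError) as exc:
        raise TableParseError(f"cannot parse {path.name}: {exc}") from exc
    if not options.has_header:
        raw.columns = [f"C{i+1}" for i in range(raw.shape[1])]
    raw.columns = [str(c).strip() for c in raw.columns]
    decimal = options.decimal_mark if ext in _TEXT_EXTENSIONS else "."
    return _frame_to_cq_table(raw, decimal)


def write_cq_table(table: CqTable, dest: str | Path,
                   options: TableFormatOptions | None = None) -> Path:
    """Write a CqTable in the input contract (CSV or Excel by extension)."""
    options = options or TableFormatOptions()
    path = Path(dest)
    frame = table.to_frame()
    ext = path.suffix.lower()
    if ext in _EXCEL_EXTENSIONS:
        frame.to_excel(path, index=False, sheet_name="Cq")
    elif ext in _TEXT_EXTENSIONS:
        frame.to_csv(path, sep=options.delimiter, index=False,
                     decimal=options.decimal_mark)
    else:
        raise TableParseError(f"unsupported output extension {ext!r}")
    return path


def write_reports(bundle: Mapping[str, pd.DataFrame],
                  out_dir: str | Path) -> list[Path]:
    """Write named report tables as TSV files with deterministic layout.

    Keys are file names (``outliers.tsv`` etc.); an empty bundle writes
    nothing.  Float formatting is fixed so re-writing the same bundle is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, frame in bundle.items():
        path = out / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g",
                     lineterminator="\n")
        written.append(path)
    return written
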