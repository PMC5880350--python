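"""Matrix input and bicluster output.

The biclustering problem is posed on an m x n matrix whose *rows* are
attributes (genes, words, products, ...) and whose *columns* are samples.
Two readers are provided:

* :func:`read_arff` — dense ARFF files with numeric or ``{0,1}`` nominal
  attributes.  Orientation: each ``@data`` line becomes one matrix row
  (one attribute of the biclustering problem) and each declared ARFF
  attribute becomes one matrix column (one sample).  Pass
  ``transpose=True`` to flip this.
* :func:`read_delimited` — plain TSV/CSV tables with optional header row
  (sample names) and an auto-detected leading name column (attribute
  names).

Biclusters are written one per line, semicolon separated::

    nr;nc;<nr attribute names>;<nc sample names>

with rows in ascending row-index order and columns in ascending
column-index order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from .errors import ParseError, ValidationError

__all__ = ["RawMatrix", "read_arff", "read_delimited", "write_biclusters"]


def _check_names(names: Sequence[str], what: str) -> list[str]:
    names = [str(x) for x in names]
    seen: set[str] = set()
    dups = sorted({x for x in names if x in seen or seen.add(x)})
    if dups:
        raise ValidationError(f"duplicate {what} names: {dups}")
    return names


@dataclass
class RawMatrix:
    """A real-valued m x n matrix with attribute (row) and sample (column) names."""

    values: np.ndarray
    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("matrix must be two-dimensional")
        m, n = self.values.shape
        if m < 2 or n < 1:
            raise ValidationError(
                f"need at least 2 rows and 1 column for pair seeding, got {m}x{n}"
            )
        if not self.row_names:
            self.row_names = [f"row{i}" for i in range(m)]
        if not self.col_names:
            self.col_names = [f"col{j}" for j in range(n)]
        if len(self.row_names) != m:
            raise ValidationError(f"{len(self.row_names)} row names for {m} rows")
        if len(self.col_names) != n:
            raise ValidationError(f"{len(self.col_names)} column names for {n} columns")
        self.row_names = _check_names(self.row_names, "row")
        self.col_names = _check_names(self.col_names, "column")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at row {self.row_names[i]!r}, column {self.col_names[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transposed(self) -> "RawMatrix":
        return RawMatrix(self.values.T.copy(), list(self.col_names), list(self.row_names))


def read_arff(path: str | Path, transpose: bool = False) -> RawMatrix:
    """Read a dense ARFF file into a :class:`RawMatrix`.

    Each ``@data`` line is one matrix row; each declared ARFF attribute is
    one matrix column (sample).  Only numeric and ``{0,1}`` nominal
    attributes are accepted; sparse ARFF, strings and dates are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if not any(line.strip().lower().startswith("@data") for line in text.splitlines()):
        raise ParseError(
            f"{path}: no @data section found in {len(text.splitlines())} lines"
        )
    try:
        data, meta = scipy_arff.loadarff(io.StringIO(text))
    except Exception as exc:  # scipy raises several exception types
        raise ParseError(f"{path}: {exc}") from exc

    col_names = list(meta.names())
    columns = []
    for name in col_names:
        kind, extra = meta[name]
        if kind == "numeric":
            columns.append(np.asarray(data[name], dtype=np.float64))
        elif kind == "nominal":
            if set(extra) - {"0", "1"}:
                raise ParseError(
                    f"{path}: nominal attribute {name!r} has values {extra}, "
                    "only {0,1} nominals are supported"
                )
            raw = data[name]
            col = np.empty(len(raw), dtype=np.float64)
            for i, v in enumerate(raw):
                tok = v.decode() if isinstance(v, bytes) else str(v)
                try:
                    col[i] = float(tok)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: non-numeric token {tok!r} at data row {i}, "
                        f"attribute {name!r}"
                    ) from exc
            columns.append(col)
        else:
            raise ParseError(
                f"{path}: attribute {name!r} has unsupported type {kind!r}"
            )
    values = np.column_stack(columns)
    mat = RawMatrix(values, col_names=col_names)
    return mat.transposed() if transpose else mat


def read_delimited(
    path: str | Path,
    delimiter: str = "\t",
    has_header: bool = False,
) -> RawMatrix:
    """Read a rectangular delimited text matrix.

    If ``has_header`` the first line gives the sample (column) names.  A
    leading column of attribute (row) names is detected automatically when
    its entries are not numeric.  Missing names are synthesized as
    ``row0..`` / ``col0..``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, header=0 if has_header else None)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: file is empty") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: no data rows")

    row_names: list[str] = []
    first = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if first.isna().all() and df.shape[1] > 1:
        # leading column is non-numeric everywhere: treat as row names
        row_names = [str(x) for x in df.iloc[:, 0]]
        df = df.iloc[:, 1:]

    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at body row {i}, column {j} "
            "(ragged rows produce missing values)"
        )
    col_names = [str(c) for c in df.columns] if has_header else []
    return RawMatrix(values, row_names=row_names, col_names=col_names)


def write_biclusters(
    biclusters: Sequence,
    row_names: Sequence[str],
    col_names: Sequence[str],
    path: str | Path,
) -> int:
    """Write biclusters in the semicolon-separated BiBit output format.

    One line per bicluster: ``nr;nc;`` then the ``nr`` attribute names in
    ascending row-index order, then the ``nc`` sample names in ascending
    column-index order (the columns are the set bits of the pattern).
    Returns the number of lines written.
    """
    path = Path(path)
    lines = [format_bicluster(bc, row_names, col_names) for bc in biclusters]
    path.write_text("".join(line + "\n" for line in lines))
    return len(lines)


def format_bicluster(bicluster, row_names: Sequence[str], col_names: Sequence[str]) -> str:
    rows = list(bicluster.rows)
    cols = list(bicluster.pattern.columns())
    if rows and rows[-1] >= len(row_names):
        raise ValidationError(
            f"row index {rows[-1]} out of range for {len(row_names)} row names"
        )
    if cols and cols[-1] >= len(col_names):
        raise ValidationError(
            f"column index {cols[-1]} out of range for {len(col_names)} column names"
        )
    fields = [str(len(rows)), str(len(cols))]
    fields += [row_names[i] for i in rows]
    fields += [col_names[j] for j in cols]
    return ";".join(fields)
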