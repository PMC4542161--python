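"""Reading and writing the pipeline's tab-separated table dialects.

Everything is UTF-8 TSV: species names never contain tabs, but chain strings
contain spaces and slashes, which rules out whitespace- and comma-delimited
dialects. Windows line endings are accepted on input and normalized.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd


class TableFormatError(ValueError):
    """Malformed input table (ragged row, duplicate id, non-numeric cell...)."""


def read_tsv_rows(path: str | Path) -> tuple[list[list[str]], list[str]]:
    """Read a TSV into (rows, header), enforcing rectangular shape.

    Raises :class:`TableFormatError` naming the 1-based line number of the
    first ragged row.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    # drop trailing blank lines only; interior blanks are ragged rows
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        row = line.split("\t")
        if len(row) != len(header):
            raise TableFormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}")
        rows.append(row)
    return rows, header


def write_tsv_rows(path: str | Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix(path: str | Path, index_name: str = "name") -> pd.DataFrame:
    """Read a numeric matrix table: first column = row id, rest = sample columns."""
    rows, header = read_tsv_rows(path)
    if len(header) < 2:
        raise TableFormatError(f"{path}: need an id column plus >=1 sample column")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TableFormatError(f"{path}: duplicate row ids {dupes}")
    if len(set(header[1:])) != len(header[1:]):
        raise TableFormatError(f"{path}: duplicate sample columns")
    try:
        values = [[float(c) for c in r[1:]] for r in rows]
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric cell ({exc})") from None
    df = pd.DataFrame(values, index=pd.Index(ids, name=index_name),
                      columns=header[1:], dtype=float)
    return df


def write_matrix(path: str | Path, df: pd.DataFrame, index_name: str = "name",
                 float_format: str = "%.10g") -> None:
    header = [index_name, *map(str, df.columns)]
    rows = [[idx, *(float_format % v for v in row)]
            for idx, row in zip(df.index, df.to_numpy())]
    write_tsv_rows(path, header, rows)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet: columns sample, group, age_weeks."""
    rows, header = read_tsv_rows(path)
    required = {"sample", "group", "age_weeks"}
    if not required.issubset(header):
        raise TableFormatError(
            f"{path}: sample sheet missing columns {sorted(required - set(header))}")
    recs = [dict(zip(header, r)) for r in rows]
    ids = [r["sample"] for r in recs]
    if len(set(ids)) != len(ids):
        raise TableFormatError(f"{path}: duplicate sample ids")
    try:
        ages = [int(r["age_weeks"]) for r in recs]
    except ValueError:
        raise TableFormatError(f"{path}: non-integer age_weeks") from None
    return pd.DataFrame({
        "sample": ids,
        "group": [r["group"] for r in recs],
        "age_weeks": ages,
    }).set_index("sample")


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    rows = [[idx, rec["group"], rec["age_weeks"]] for idx, rec in sheet.iterrows()]
    write_tsv_rows(path, ["sample", "group", "age_weeks"], rows)
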