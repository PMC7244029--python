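"""On-disk formats: TSV matrix dialects and the GEO series-matrix reader.

All matrices share one dialect: tab-separated UTF-8, '.' decimal, a header
row of sample ids and a first column of probe/gene ids.  Time-series
matrices carry a two-row header (day, then replicate).  Parse errors report
the offending 1-based line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionSet

__all__ = [
    "ParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "write_truth_tsv",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_gene_list_tsv",
    "write_gene_list_tsv",
    "read_series_matrix",
    "read_expression_set",
]


class ParseError(ValueError):
    """Malformed input file; message includes the 1-based line number."""


def _split_lines(path) -> list[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    return [line.split("\t") for line in text.splitlines() if line != ""]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a probes x samples matrix (first column id, header of sample ids)."""
    rows = _split_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}:1: header must name at least one sample")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}:1: duplicate sample ids in header")
    ids: list[str] = []
    seen: set[str] = set()
    data = np.empty((len(rows) - 1, len(sample_ids)))
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}:{i}: expected {len(header)} fields, got {len(row)} (ragged row)"
            )
        pid = row[0]
        if pid in seen:
            raise ParseError(f"{path}:{i}: duplicate probe id {pid!r}")
        seen.add(pid)
        ids.append(pid)
        for j, cell in enumerate(row[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(f"{path}:{i}: non-numeric cell {cell!r}") from None
            if not np.isfinite(v):
                raise ParseError(f"{path}:{i}: non-finite value {cell!r}")
            data[i - 2, j] = v
    return pd.DataFrame(data, index=pd.Index(ids, name="probe_id"), columns=sample_ids)


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    df = values.copy()
    df.index.name = df.index.name or "probe_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read the sample table (sample, group, optional mv)."""
    meta = pd.read_csv(path, sep="\t", dtype={0: str})
    first = meta.columns[0]
    meta = meta.set_index(first)
    meta.index.name = "sample_id"
    if "group" not in meta.columns:
        raise ParseError(f"{path}: metadata needs a 'group' column")
    return meta


def write_metadata_tsv(samples: pd.DataFrame, path) -> None:
    df = samples.copy()
    df.index.name = df.index.name or "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", lineterminator="\n")


def write_timeseries_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a genes x (day, replicate) matrix with a two-row header."""
    days = [str(d) for d, _ in matrix.columns]
    reps = [str(r) for _, r in matrix.columns]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(days) + "\n")
        fh.write("rep\t" + "\t".join(reps) + "\n")
        for gid, row in zip(matrix.index, matrix.to_numpy()):
            fh.write(str(gid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_timeseries_tsv(path) -> pd.DataFrame:
    """Read the two-row-header (day, replicate) time-series dialect."""
    rows = _split_lines(path)
    if len(rows) < 3:
        raise ParseError(f"{path}: expected two header rows and data")
    days_row, reps_row = rows[0], rows[1]
    if len(days_row) != len(reps_row):
        raise ParseError(f"{path}:2: replicate header length differs from day header")
    try:
        days = [int(d) for d in days_row[1:]]
    except ValueError:
        raise ParseError(f"{path}:1: day labels must be integers") from None
    columns = pd.MultiIndex.from_arrays([days, reps_row[1:]], names=["day", "rep"])
    ids, seen = [], set()
    data = np.empty((len(rows) - 2, len(days)))
    for i, row in enumerate(rows[2:], start=3):
        if len(row) != len(days_row):
            raise ParseError(f"{path}:{i}: ragged row")
        gid = row[0]
        if gid in seen:
            raise ParseError(f"{path}:{i}: duplicate gene id {gid!r}")
        seen.add(gid)
        ids.append(gid)
        try:
            data[i - 3] = [float(c) for c in row[1:]]
        except ValueError:
            raise ParseError(f"{path}:{i}: non-numeric cell") from None
    return pd.DataFrame(data, index=pd.Index(ids, name="gene_id"), columns=columns)


def read_gene_list_tsv(path) -> pd.DataFrame:
    """Read a (gene, direction) list; direction is 'up' or 'down'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "gene" not in cols or "direction" not in cols:
        raise ParseError(f"{path}: expected columns 'gene' and 'direction'")
    df.columns = cols
    bad = df[~df["direction"].isin(["up", "down"])]
    if len(bad) > 0:
        raise ParseError(f"{path}: invalid direction {bad['direction'].iloc[0]!r}")
    return df[["gene", "direction"]]


def write_gene_list_tsv(records: pd.DataFrame, path) -> None:
    """Write the up/down calls of a DEG table as a (gene, direction) list."""
    called = records[records["call"].isin(["up", "down"])]
    out = pd.DataFrame({"gene": called.index, "direction": called["call"].to_numpy()})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _unquote(s: str) -> str:
    return s[1:-1] if len(s) >= 2 and s[0] == '"' and s[-1] == '"' else s


def read_series_matrix(path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Read the value table of a GEO series-matrix text file.

    Returns the probes x samples matrix from the block delimited by
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` plus a
    dict of the ``!`` metadata lines (key -> list of unquoted fields).
    Quoted ids and sample titles are unquoted.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    metadata: dict[str, list[str]] = {}
    begin = end = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped == "!series_matrix_table_begin":
            begin = i
        elif stripped == "!series_matrix_table_end":
            end = i
        elif stripped.startswith("!"):
            parts = stripped.split("\t")
            metadata.setdefault(parts[0].lstrip("!"), []).extend(
                _unquote(p) for p in parts[1:]
            )
    if begin is None:
        raise ParseError(f"{path}: missing !series_matrix_table_begin")
    if end is None or end <= begin:
        raise ParseError(f"{path}: missing !series_matrix_table_end")
    table = [line.split("\t") for line in lines[begin + 1 : end] if line]
    if len(table) < 2:
        raise ParseError(f"{path}: empty series-matrix table")
    header = [_unquote(c) for c in table[0]]
    ids, data = [], []
    for k, row in enumerate(table[1:], start=begin + 3):
        if len(row) != len(header):
            raise ParseError(f"{path}:{k}: ragged row in series-matrix table")
        ids.append(_unquote(row[0]))
        try:
            data.append([float(c) for c in row[1:]])
        except ValueError:
            raise ParseError(f"{path}:{k}: non-numeric cell") from None
    return (
        pd.DataFrame(np.array(data), index=pd.Index(ids, name="probe_id"), columns=header[1:]),
        metadata,
    )


def read_expression_set(expr_path, meta_path) -> ExpressionSet:
    """Convenience loader pairing an expression TSV with its metadata TSV."""
    values = read_expression_tsv(expr_path)
    samples = read_metadata_tsv(meta_path)
    return ExpressionSet(values=values, samples=samples)
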