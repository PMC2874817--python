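"""Readers and writers for the tab-delimited interchange formats.

All tables are UTF-8, tab-delimited, with '#'-prefixed header lines.
Homology hits use the 12-column BLAST tabular dialect (qseqid, sseqid,
pident, length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
bitscore); only query, subject, E-value and bit score are semantically
load-bearing here, the alignment-coordinate columns are carried through.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from osmonet.errors import ParseError

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 12-column BLAST tabular hit file.

    Returns a DataFrame with at least qseqid, sseqid, evalue, bitscore.
    Malformed rows raise :class:`ParseError` naming the offending line.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"expected 12 tab-separated fields, got {len(parts)}",
                    path=str(path), line=lineno,
                )
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric evalue/bitscore: {exc}",
                    path=str(path), line=lineno,
                ) from None
            if evalue < 0:
                raise ParseError("negative E-value", path=str(path), line=lineno)
            rows.append((parts[0], parts[1], evalue, bitscore))
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])


def write_blast_tabular(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write hits as 12-column BLAST tabular, padding alignment columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(BLAST_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fields = [
                row.qseqid, row.sseqid, "0.0", "0", "0", "0",
                "0", "0", "0", "0",
                format(row.evalue, ".3e"), format(row.bitscore, ".1f"),
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_tsv(path: str | os.PathLike, columns: list[str] | None = None) -> pd.DataFrame:
    """Read a '#'-headered TSV; the header line supplies column names."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        names = first[1:].strip().split("\t")
        df = pd.read_csv(path, sep="\t", comment=None, skiprows=1, names=names,
                         dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if columns is not None:
        missing = set(columns) - set(df.columns)
        if missing:
            raise ParseError(f"missing columns {sorted(missing)}", path=str(path))
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame as a '#'-headered, tab-delimited file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, lineterminator="\n")


def write_rows(rows: Iterable[Iterable], columns: list[str],
               path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
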