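"""Readers and writers for the pipeline's text interchange formats.

Canonical interchange is UTF-8 delimited text with a header row:

* interactions table - columns ``chemical term``, ``gene term``,
  ``action direction``, ``taxonomy``, ``PMID``, ``use1``..``use3``,
  ``use description`` (header matching is case- and whitespace-insensitive,
  column order free);
* gene-presence table - columns ``gene``, ``homo``, ``mus``, ``rattus``
  with 1/0, true/false or yes/no flags;
* gene sets - standard GMT (set name, description, then members,
  tab-separated);
* preranked list - two-column RNK (gene, centered score).

Every reader accepts an open text stream or a filesystem path.  Parsing is
deliberately strict: a malformed line is reported with its line number
rather than silently dropped, because the filtering contracts downstream
assume a fully validated table.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .records import (
    Direction,
    GenePresenceTable,
    GeneSetCollection,
    InteractionRecord,
    Taxon,
)

StreamOrPath = Union[str, Path, IO[str]]

#: Accepted spellings for the decrease direction; the deposited data prints a
#: typographic minus (U+2212) while most exports use the ASCII hyphen.
_DECREASE_ALIASES = {"-", "−"}

INTERACTION_COLUMNS = (
    "chemical term",
    "gene term",
    "action direction",
    "taxonomy",
    "PMID",
    "use1",
    "use2",
    "use3",
    "use description",
)

_MANDATORY = ("chemical term", "gene term", "action direction", "taxonomy", "pmid", "use1")


class SchemaError(ValueError):
    """The file's header does not carry a mandatory column."""


class RecordError(ValueError):
    """A data line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _open_maybe(stream: StreamOrPath, mode: str = "r"):
    """Return (file object, needs_close)."""
    if isinstance(stream, (str, Path)):
        return open(stream, mode, encoding="utf-8", newline=""), True
    return stream, False


def _norm_header(name: str) -> str:
    return " ".join(name.split()).lower()


def parse_direction(token: str) -> Direction:
    token = token.strip()
    if token == "+":
        return Direction.INCREASE
    if token in _DECREASE_ALIASES:
        return Direction.DECREASE
    if token == "1":
        return Direction.UNSPECIFIED
    raise ValueError(f"unknown action direction {token!r}")


def read_interactions(stream: StreamOrPath, dialect: str = "tab") -> list[InteractionRecord]:
    """Read an interactions table into a list of :class:`InteractionRecord`.

    Parameters
    ----------
    stream
        Open text stream or path.
    dialect
        ``"tab"`` (default) or ``"comma"``.

    Raises
    ------
    SchemaError
        If a mandatory column is missing from the header.
    RecordError
        If a data line has an unparseable PMID, an unknown taxon or an
        unknown direction code; the message carries the 1-based line number.
    """
    delim = "\t" if dialect == "tab" else ","
    fh, close = _open_maybe(stream)
    try:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: no header row") from None
        positions = {_norm_header(h): i for i, h in enumerate(header)}
        for col in _MANDATORY:
            if col not in positions:
                raise SchemaError(f"missing mandatory column {col!r}")

        def cell(row: list[str], col: str) -> str:
            i = positions.get(col)
            if i is None or i >= len(row):
                return ""
            return row[i].strip()

        records: list[InteractionRecord] = []
        for line_no, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue
            try:
                direction = parse_direction(cell(row, "action direction"))
            except ValueError as exc:
                raise RecordError(line_no, str(exc)) from None
            taxon_token = cell(row, "taxonomy")
            try:
                taxon = Taxon(taxon_token.capitalize())
            except ValueError:
                raise RecordError(line_no, f"unknown taxon {taxon_token!r}") from None
            pmid_token = cell(row, "pmid")
            try:
                pmid = int(pmid_token)
                if pmid <= 0:
                    raise ValueError
            except ValueError:
                raise RecordError(line_no, f"unparseable PMID {pmid_token!r}") from None
            uses = tuple(
                u for u in (cell(row, "use1"), cell(row, "use2"), cell(row, "use3")) if u
            )
            records.append(
                InteractionRecord(
                    chemical=cell(row, "chemical term"),
                    gene=cell(row, "gene term").upper(),
                    direction=direction,
                    taxon=taxon,
                    pmid=pmid,
                    uses=uses,
                    use_description=cell(row, "use description"),
                )
            )
        return records
    finally:
        if close:
            fh.close()


def write_interactions(
    records: Iterable[InteractionRecord], stream: StreamOrPath, dialect: str = "tab"
) -> None:
    """Write records in the canonical column order; inverse of :func:`read_interactions`."""
    delim = "\t" if dialect == "tab" else ","
    fh, close = _open_maybe(stream, "w")
    try:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(INTERACTION_COLUMNS)
        for r in records:
            uses = list(r.uses) + [""] * (3 - len(r.uses))
            writer.writerow(
                [
                    r.chemical,
                    r.gene,
                    r.direction.value,
                    r.taxon.value,
                    str(r.pmid),
                    uses[0],
                    uses[1],
                    uses[2],
                    r.use_description,
                ]
            )
    finally:
        if close:
            fh.close()


_TRUTHY = {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False}


def read_gene_presence(stream: StreamOrPath, dialect: str = "tab") -> GenePresenceTable:
    """Read a gene-presence table (columns gene, homo, mus, rattus).

    Duplicate rows are merged when consistent; conflicting duplicates raise.
    """
    delim = "\t" if dialect == "tab" else ","
    fh, close = _open_maybe(stream)
    try:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        positions = {_norm_header(h): i for i, h in enumerate(header)}
        for col in ("gene", "homo", "mus", "rattus"):
            if col not in positions:
                raise SchemaError(f"missing mandatory column {col!r}")
        table = GenePresenceTable()
        for line_no, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue
            gene = row[positions["gene"]].strip()
            flags = []
            for col in ("homo", "mus", "rattus"):
                token = row[positions[col]].strip().lower()
                if token not in _TRUTHY:
                    raise RecordError(line_no, f"unparseable flag {token!r} in column {col}")
                flags.append(_TRUTHY[token])
            try:
                table.add(gene, flags)
            except ValueError as exc:
                raise RecordError(line_no, str(exc)) from None
        return table
    finally:
        if close:
            fh.close()


def write_gene_presence(table: GenePresenceTable, stream: StreamOrPath) -> None:
    fh, close = _open_maybe(stream, "w")
    try:
        fh.write("gene\thomo\tmus\trattus\n")
        for gene in table.genes():
            h, m, r = table[gene]
            fh.write(f"{gene}\t{int(h)}\t{int(m)}\t{int(r)}\n")
    finally:
        if close:
            fh.close()


def read_gmt(stream: StreamOrPath, collection_name: str = "") -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then >= 1 member.

    Empty member cells (e.g. from trailing tabs) are ignored.  Duplicate set
    names and lines with fewer than three fields raise.
    """
    fh, close = _open_maybe(stream)
    try:
        collection = GeneSetCollection(collection_name)
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RecordError(line_no, f"GMT line has {len(fields)} fields, need >= 3")
            name, description = fields[0], fields[1]
            members = [m.strip() for m in fields[2:] if m.strip()]
            if not members:
                raise RecordError(line_no, f"gene set {name!r} has no members")
            try:
                collection.add(name, description, members)
            except ValueError as exc:
                raise RecordError(line_no, str(exc)) from None
        return collection
    finally:
        if close:
            fh.close()


def write_gmt(collection: GeneSetCollection, stream: StreamOrPath) -> None:
    """Write a collection in GMT form; members sorted for reproducible bytes."""
    fh, close = _open_maybe(stream, "w")
    try:
        for name, (description, members) in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
    finally:
        if close:
            fh.close()


def convert_workbook_to_tsv(workbook_path: StreamOrPath, out_path: StreamOrPath) -> int:
    """Convenience converter: first worksheet of an .xlsx workbook to TSV.

    Not part of the tested core; requires ``openpyxl`` at call time.  Returns
    the number of rows written (header included).
    """
    from openpyxl import load_workbook  # deferred: optional convenience path

    wb = load_workbook(workbook_path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    fh, close = _open_maybe(out_path, "w")
    n = 0
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in ws.iter_rows(values_only=True):
            writer.writerow(["" if v is None else str(v) for v in row])
            n += 1
    finally:
        if close:
            fh.close()
    return n


def iter_lines(text: str) -> Iterator[str]:
    """Helper for tests: iterate a string as a text stream would."""
    return iter(_io.StringIO(text))
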