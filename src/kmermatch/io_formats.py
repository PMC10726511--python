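"""File I/O: FASTA proteomes, peptide lists, and the tabular results schema.

FASTA headers in the UniProt dialect

    >sp|ACCESSION|ENTRY_NAME Protein name OS=Organism OX=taxid GN=gene PE=level

are parsed into full :class:`ProteinRecord` metadata; any other header falls
back to the first whitespace-delimited token as accession with metadata left
empty. Sequences are uppercased on read and trailing ``*`` terminators
stripped; any other out-of-alphabet character is a parse error naming the
line.

Results are written as CSV (default), TSV, or JSON with a fixed column
order. The writer is the 0-based/1-based boundary: ``start``/``end`` in files
are 1-based inclusive positions within the protein, as protein databases
print them, while the library keeps 0-based coordinates internally.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .errors import InvalidParameterError, ParseError
from .records import EXTENDED_AA, Match, ProteinRecord, QuerySet

_ALLOWED = frozenset(EXTENDED_AA)

#: Fixed column order of the result table. Optional metadata columns are
#: emitted empty, never omitted. mismatch_positions are 1-based, joined
#: with ';'.
RESULT_COLUMNS = [
    "query_id",
    "query_sequence",
    "matched_sequence",
    "accession",
    "protein_name",
    "gene",
    "mismatch_count",
    "mismatch_positions",
    "species",
    "taxon_id",
    "start",
    "end",
    "existence_level",
]

_UNIPROT_RE = re.compile(r"^(?:sp|tr)\|([^|\s]+)\|(\S+)(.*)$")
_TAG_RE = re.compile(r"\s(?:OS|OX|GN|PE|SV)=")


def _parse_header(header: str, seq: str) -> ProteinRecord:
    m = _UNIPROT_RE.match(header)
    if not m:
        return ProteinRecord(accession=header.split()[0], sequence=seq)
    accession, _entry, rest = m.groups()
    rest = " " + rest.strip() if rest.strip() else ""
    tag_match = _TAG_RE.search(rest)
    name = rest[: tag_match.start()].strip() if tag_match else rest.strip()

    def tag(key: str) -> str:
        mm = re.search(rf"\s{key}=(.*?)(?=\s(?:OS|OX|GN|PE|SV)=|$)", rest)
        return mm.group(1).strip() if mm else ""

    taxon = tag("OX")
    pe = tag("PE")
    return ProteinRecord(
        accession=accession,
        sequence=seq,
        name=name,
        gene=tag("GN"),
        species=tag("OS"),
        taxon_id=int(taxon) if taxon.isdigit() else None,
        existence_level=int(pe) if pe.isdigit() else None,
    )


def _clean_sequence(raw: str, line: int) -> str:
    seq = raw.upper().rstrip("*")
    if "*" in seq:
        raise ParseError("internal '*' in sequence", line)
    bad = set(seq) - _ALLOWED
    if bad:
        raise ParseError(f"illegal residue character(s) {sorted(bad)!r}", line)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA proteome, in file order."""
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = _clean_sequence("".join(chunks), header_line)
        if not seq:
            raise ParseError(f"record {header.split()[0]!r} has no sequence",
                             header_line)
        records.append(_parse_header(header, seq))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError("empty FASTA header", lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError("sequence data before any '>' header", lineno)
                chunks.append(line)
    flush()
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise ParseError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    return records


def format_uniprot_header(rec: ProteinRecord) -> str:
    """Inverse of the header parser, for records carrying UniProt metadata."""
    parts = [f"sp|{rec.accession}|{rec.accession}_SYN"]
    body = rec.name or "synthetic protein"
    tags = []
    if rec.species:
        tags.append(f"OS={rec.species}")
    if rec.taxon_id is not None:
        tags.append(f"OX={rec.taxon_id}")
    if rec.gene:
        tags.append(f"GN={rec.gene}")
    if rec.existence_level is not None:
        tags.append(f"PE={rec.existence_level}")
    return " ".join([parts[0], body] + tags)


def write_fasta(records: list[ProteinRecord], path: str | Path,
                width: int = 60, uniprot_headers: bool = False) -> None:
    """Write records as FASTA (wrapped at *width* columns)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = format_uniprot_header(rec) if uniprot_headers else rec.accession
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_peptides(path: str | Path) -> QuerySet:
    """Read query peptides from plain text (one per line, optional
    ``id<TAB>sequence``) or FASTA. Missing ids become q1..qn."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln.strip() for ln in text.splitlines()]
    first = next((ln for ln in lines if ln), "")
    peptides: list[tuple[str, str]] = []
    if first.startswith(">"):
        for rec in read_fasta(path):
            peptides.append((rec.accession, rec.sequence))
        return QuerySet(peptides)
    n = 0
    for lineno, line in enumerate(lines, start=1):
        if not line:
            continue
        n += 1
        if "\t" in line:
            qid, seq = line.split("\t", 1)
            qid, seq = qid.strip(), seq.strip()
        else:
            qid, seq = f"q{n}", line
        seq = seq.upper()
        bad = set(seq) - _ALLOWED
        if bad:
            raise ParseError(f"illegal residue character(s) {sorted(bad)!r}", lineno)
        peptides.append((qid, seq))
    return QuerySet(peptides)


# -- result table ---------------------------------------------------------


def matches_to_table(matches: list[Match]) -> pd.DataFrame:
    """Flatten Match records to the fixed-order result table (1-based
    coordinates, 'pos;pos' mismatch positions)."""
    rows = []
    for m in matches:
        rows.append({
            "query_id": m.query_id,
            "query_sequence": m.query_sequence,
            "matched_sequence": m.matched_sequence,
            "accession": m.accession,
            "protein_name": m.protein_name,
            "gene": m.gene,
            "mismatch_count": m.mismatch_count,
            "mismatch_positions": ";".join(str(p) for p in m.mismatch_positions),
            "species": m.species,
            "taxon_id": "" if m.taxon_id is None else m.taxon_id,
            "start": m.start + 1,
            "end": m.end + 1,
            "existence_level": "" if m.existence_level is None else m.existence_level,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(matches: list[Match], path: str | Path, format: str = "csv") -> None:
    """Write matches as csv / tsv / json; bytes are deterministic for
    identical inputs. Zero matches produce a header-only file (or ``[]``)."""
    table = matches_to_table(matches)
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False, lineterminator="\n")
    elif format == "tsv":
        table.to_csv(path, index=False, sep="\t", lineterminator="\n")
    elif format == "json":
        recs = table.to_dict(orient="records")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(recs, fh, indent=1)
            fh.write("\n")
    else:
        raise InvalidParameterError(f"unknown results format {format!r}")


def _row_to_match(row: dict) -> Match:
    positions = tuple(
        int(p) for p in str(row.get("mismatch_positions") or "").split(";") if p
    )

    def opt_int(key: str) -> int | None:
        v = row.get(key)
        if v is None or v == "" or (isinstance(v, float) and pd.isna(v)):
            return None
        return int(v)

    return Match(
        query_id=str(row["query_id"]),
        query_sequence=row["query_sequence"],
        matched_sequence=row["matched_sequence"],
        accession=str(row["accession"]),
        protein_name=str(row.get("protein_name") or ""),
        gene=str(row.get("gene") or ""),
        species=str(row.get("species") or ""),
        taxon_id=opt_int("taxon_id"),
        existence_level=opt_int("existence_level"),
        start=int(row["start"]) - 1,
        end=int(row["end"]) - 1,
        mismatch_count=int(row["mismatch_count"]),
        mismatch_positions=positions,
    )


def read_results(path: str | Path, format: str | None = None) -> list[Match]:
    """Parse a results file back into Match records (inverse of
    :func:`write_results`; coordinates return to 0-based)."""
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".json": "json"}.get(
            path.suffix, "csv"
        )
    if format == "json":
        rows = json.loads(path.read_text(encoding="utf-8"))
    else:
        sep = "\t" if format == "tsv" else ","
        frame = pd.read_csv(path, sep=sep, keep_default_na=False,
                            dtype={"mismatch_positions": str})
        rows = frame.to_dict(orient="records")
    return [_row_to_match(r) for r in rows]
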