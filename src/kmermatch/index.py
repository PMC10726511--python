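"""K-mer -> position index over a concatenated-coordinate proteome.

The proteome is laid out in a single 0-based global coordinate space: protein
i occupies the half-open interval [start_i, start_i + len_i) where start_i is
the cumulative length of the preceding proteins in file order. K-mers are
enumerated per protein and shifted by the protein's global start, so no
indexed k-mer ever spans a protein boundary. Every k-mer of every protein of
length >= k is stored, which is what makes downstream seed-and-verify search
complete rather than heuristic.

Two storage backends sit behind one save/load contract:

* ``pickle`` — a versioned single-file container holding the whole in-memory
  map; fastest to reload, used by mismatch and best-match search which touch
  many keys.
* ``sqlite`` — an embedded key-value store queried per k-mer without loading
  the map into memory (:class:`SqliteIndexReader`); suited to exact search
  over large proteomes where only a handful of keys per query are needed.

Both record the k value and a checksum of the concatenated sequences so a
stale index (different k, or rebuilt FASTA) is refused on load when
verification is requested.
"""

from __future__ import annotations

import hashlib
import pickle
import sqlite3
from array import array
from bisect import bisect_right
from pathlib import Path

from .errors import (
    IndexFormatError,
    InvalidInputError,
    InvalidParameterError,
    StaleIndexError,
)
from .records import ProteinRecord

_PICKLE_MAGIC = b"KMERIDX\x01"  # magic bytes + container format version
_FORMAT_VERSION = 1


def proteome_checksum(proteome: list[ProteinRecord]) -> str:
    """SHA-256 digest of the concatenated sequences in file order."""
    h = hashlib.sha256()
    for rec in proteome:
        h.update(rec.sequence.encode("ascii"))
    return h.hexdigest()


class ProteomeIndex:
    """In-memory k-mer index plus the protein offset table.

    Attributes
    ----------
    k : int
        The k-mer size the proteome was preprocessed with.
    kmer_map : dict[str, list[int]]
        Each k-mer mapped to the strictly increasing list of global start
        offsets where it occurs (never crossing a protein boundary).
    records : list[ProteinRecord]
        The proteins, in file order, with sequences retained so candidate
        windows can be verified without re-reading the FASTA.
    """

    def __init__(self, k: int, records: list[ProteinRecord],
                 kmer_map: dict[str, list[int]], checksum: str):
        self.k = k
        self.records = records
        self.kmer_map = kmer_map
        self.checksum = checksum
        starts: list[int] = []
        pos = 0
        for rec in records:
            starts.append(pos)
            pos += len(rec.sequence)
        self._starts = starts
        self.total_length = pos

    # -- queries ----------------------------------------------------------

    def lookup(self, kmer: str) -> list[int]:
        """All (and only) global offsets where *kmer* occurs within a single
        protein; empty list when absent."""
        if len(kmer) != self.k:
            raise InvalidParameterError(
                f"lookup key has length {len(kmer)}, index k is {self.k}"
            )
        return self.kmer_map.get(kmer, [])

    def to_protein_coords(self, g: int) -> tuple[str, int]:
        """Map a global offset to (accession, 0-based local offset)."""
        if not 0 <= g < self.total_length:
            raise IndexError(f"global offset {g} outside [0, {self.total_length})")
        i = bisect_right(self._starts, g) - 1
        return self.records[i].accession, g - self._starts[i]

    def protein_at(self, g: int) -> int:
        """Ordinal of the protein containing global offset *g*."""
        if not 0 <= g < self.total_length:
            raise IndexError(f"global offset {g} outside [0, {self.total_length})")
        return bisect_right(self._starts, g) - 1

    def global_window(self, g: int, length: int):
        """The window [g, g+length) if it lies entirely within one protein.

        Returns (record, local_start, subsequence) or None when the window
        is out of range or crosses a protein boundary.
        """
        if g < 0 or g + length > self.total_length:
            return None
        i = bisect_right(self._starts, g) - 1
        local = g - self._starts[i]
        rec = self.records[i]
        if local + length > len(rec.sequence):
            return None
        return rec, local, rec.sequence[local:local + length]

    def global_start_of(self, ordinal: int) -> int:
        return self._starts[ordinal]


def build_index(proteome: list[ProteinRecord], k: int) -> ProteomeIndex:
    """Preprocess a proteome into its k-mer index.

    Proteins shorter than k contribute no k-mers but stay in the record
    table so coordinate mapping and metadata remain complete. Done once per
    proteome and per k; reuse via :func:`save_index`/:func:`load_index`.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if not proteome:
        raise InvalidInputError("proteome is empty")
    seen: set[str] = set()
    for rec in proteome:
        if rec.accession in seen:
            raise InvalidInputError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    kmer_map: dict[str, list[int]] = {}
    start = 0
    for rec in proteome:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            kmer_map.setdefault(seq[i:i + k], []).append(start + i)
        start += len(seq)
    return ProteomeIndex(k, list(proteome), kmer_map, proteome_checksum(proteome))


# -- persistence ----------------------------------------------------------


def save_index(index: ProteomeIndex, path: str | Path, backend: str = "pickle") -> None:
    """Persist an index; ``backend`` is ``"pickle"`` or ``"sqlite"``."""
    path = Path(path)
    if backend == "pickle":
        payload = {
            "version": _FORMAT_VERSION,
            "k": index.k,
            "checksum": index.checksum,
            "records": index.records,
            "kmer_map": index.kmer_map,
        }
        with open(path, "wb") as fh:
            fh.write(_PICKLE_MAGIC)
            pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)
    elif backend == "sqlite":
        path.unlink(missing_ok=True)
        con = sqlite3.connect(path)
        try:
            con.executescript(
                """
                CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
                CREATE TABLE proteins (
                    ordinal INTEGER PRIMARY KEY, accession TEXT, name TEXT,
                    gene TEXT, species TEXT, taxon_id INTEGER,
                    existence_level INTEGER, sequence TEXT);
                CREATE TABLE kmers (kmer TEXT PRIMARY KEY, offsets BLOB);
                """
            )
            con.executemany(
                "INSERT INTO meta VALUES (?, ?)",
                [("format_version", str(_FORMAT_VERSION)),
                 ("k", str(index.k)),
                 ("checksum", index.checksum)],
            )
            con.executemany(
                "INSERT INTO proteins VALUES (?,?,?,?,?,?,?,?)",
                [(i, r.accession, r.name, r.gene, r.species, r.taxon_id,
                  r.existence_level, r.sequence)
                 for i, r in enumerate(index.records)],
            )
            con.executemany(
                "INSERT INTO kmers VALUES (?, ?)",
                ((kmer, array("q", offs).tobytes())
                 for kmer, offs in index.kmer_map.items()),
            )
            con.commit()
        finally:
            con.close()
    else:
        raise InvalidParameterError(f"unknown backend {backend!r}")


def _records_from_sqlite(con: sqlite3.Connection) -> list[ProteinRecord]:
    rows = con.execute(
        "SELECT accession, name, gene, species, taxon_id, existence_level,"
        " sequence FROM proteins ORDER BY ordinal"
    ).fetchall()
    return [
        ProteinRecord(accession=a, name=n, gene=g, species=s, taxon_id=t,
                      existence_level=e, sequence=q)
        for a, n, g, s, t, e, q in rows
    ]


def _sqlite_meta(con: sqlite3.Connection) -> dict[str, str]:
    try:
        return dict(con.execute("SELECT key, value FROM meta"))
    except sqlite3.DatabaseError as exc:
        raise IndexFormatError(f"not a kmermatch sqlite index: {exc}") from exc


def _check_meta(k: int, checksum: str, expected_k, expected_checksum) -> None:
    if expected_k is not None and k != expected_k:
        raise StaleIndexError(f"index was built with k={k}, requested k={expected_k}")
    if expected_checksum is not None and checksum != expected_checksum:
        raise StaleIndexError("index checksum does not match the supplied proteome")


def load_index(path: str | Path, expected_k: int | None = None,
               expected_checksum: str | None = None) -> ProteomeIndex:
    """Load a saved index (either backend) fully into memory.

    When ``expected_k``/``expected_checksum`` are given, a mismatch raises
    :class:`StaleIndexError` instead of silently serving stale data.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(len(_PICKLE_MAGIC))
        if head == _PICKLE_MAGIC:
            try:
                payload = pickle.load(fh)
            except Exception as exc:  # truncated/corrupt payload
                raise IndexFormatError(f"corrupt index file {path}: {exc}") from exc
            if payload.get("version") != _FORMAT_VERSION:
                raise IndexFormatError(
                    f"unsupported index format version {payload.get('version')!r}"
                )
            _check_meta(payload["k"], payload["checksum"], expected_k, expected_checksum)
            return ProteomeIndex(payload["k"], payload["records"],
                                 payload["kmer_map"], payload["checksum"])
    if path.read_bytes()[:16] == b"SQLite format 3\x00":
        con = sqlite3.connect(path)
        try:
            meta = _sqlite_meta(con)
            _check_meta(int(meta["k"]), meta["checksum"], expected_k, expected_checksum)
            records = _records_from_sqlite(con)
            kmer_map = {
                kmer: array("q", blob).tolist()
                for kmer, blob in con.execute("SELECT kmer, offsets FROM kmers")
            }
        finally:
            con.close()
        return ProteomeIndex(int(meta["k"]), records, kmer_map, meta["checksum"])
    raise IndexFormatError(f"{path} is not a kmermatch index file")


class SqliteIndexReader:
    """Lazy, read-only view of a sqlite-backed index.

    Implements the same lookup/coordinate interface as
    :class:`ProteomeIndex` but fetches offset lists per k-mer with SQL, so
    exact search over a large proteome never materialises the whole map.
    """

    def __init__(self, path: str | Path, expected_k: int | None = None,
                 expected_checksum: str | None = None):
        path = Path(path)
        if path.read_bytes()[:16] != b"SQLite format 3\x00":
            raise IndexFormatError(f"{path} is not a sqlite index file")
        self._con = sqlite3.connect(path)
        meta = _sqlite_meta(self._con)
        _check_meta(int(meta["k"]), meta["checksum"], expected_k, expected_checksum)
        self.k = int(meta["k"])
        self.checksum = meta["checksum"]
        self.records = _records_from_sqlite(self._con)
        self._shadow = ProteomeIndex(self.k, self.records, {}, self.checksum)
        self.total_length = self._shadow.total_length

    def lookup(self, kmer: str) -> list[int]:
        if len(kmer) != self.k:
            raise InvalidParameterError(
                f"lookup key has length {len(kmer)}, index k is {self.k}"
            )
        row = self._con.execute(
            "SELECT offsets FROM kmers WHERE kmer = ?", (kmer,)
        ).fetchone()
        return array("q", row[0]).tolist() if row else []

    def to_protein_coords(self, g: int) -> tuple[str, int]:
        return self._shadow.to_protein_coords(g)

    def global_window(self, g: int, length: int):
        return self._shadow.global_window(g, length)

    def close(self) -> None:
        self._con.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
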