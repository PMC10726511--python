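"""Brute-force reference search: the definition of correctness at desk scale.

These functions examine *every* window of every protein by direct
per-position comparison — no k-mers, no seeding, no index — so they are
complete by construction and share no logic with :mod:`kmermatch.search`.
Equivalence between the two routes is the package's central test. They also
generate the expected-output files the benchmark harness scores recall
against.

Window comparison is vectorised with numpy sliding windows (still a direct
character-by-character Hamming count, just batched); performance beyond that
is a non-goal.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidParameterError
from .records import Match, ProteinRecord, QuerySet


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _make_match(qid: str, qseq: str, rec: ProteinRecord, start: int,
                window: str) -> Match:
    positions = tuple(
        i + 1 for i, (a, b) in enumerate(zip(qseq, window)) if a != b
    )
    return Match(
        query_id=qid,
        query_sequence=qseq,
        matched_sequence=window,
        accession=rec.accession,
        protein_name=rec.name,
        gene=rec.gene,
        species=rec.species,
        taxon_id=rec.taxon_id,
        existence_level=rec.existence_level,
        start=start,
        end=start + len(qseq) - 1,
        mismatch_count=len(positions),
        mismatch_positions=positions,
    )


def _sort(matches: list[Match], queries: QuerySet) -> list[Match]:
    order = {qid: i for i, (qid, _) in enumerate(queries)}
    matches.sort(key=lambda m: (order[m.query_id], m.accession, m.start))
    return matches


def brute_exact(proteome: list[ProteinRecord], queries: QuerySet) -> list[Match]:
    """Naive substring scan (str.find) over every protein."""
    out: list[Match] = []
    for qid, seq in queries:
        for rec in proteome:
            start = rec.sequence.find(seq)
            while start != -1:
                out.append(_make_match(qid, seq, rec, start,
                                       rec.sequence[start:start + len(seq)]))
                start = rec.sequence.find(seq, start + 1)
    return _sort(out, queries)


def brute_hamming(proteome: list[ProteinRecord], queries: QuerySet,
                  m: int) -> list[Match]:
    """Every single-protein window at Hamming distance <= m from each
    query, by direct comparison of all windows."""
    if m < 0:
        raise InvalidParameterError(f"m must be >= 0, got {m}")
    encoded = [(rec, _encode(rec.sequence)) for rec in proteome]
    out: list[Match] = []
    for qid, seq in queries:
        l = len(seq)
        q = _encode(seq)
        for rec, arr in encoded:
            if arr.size < l:
                continue
            windows = sliding_window_view(arr, l)
            counts = (windows != q).sum(axis=1)
            for start in np.nonzero(counts <= m)[0]:
                start = int(start)
                out.append(_make_match(qid, seq, rec, start,
                                       rec.sequence[start:start + l]))
    return _sort(out, queries)


def brute_best(proteome: list[ProteinRecord], queries: QuerySet) -> list[Match]:
    """The globally minimum-Hamming window(s) per query, all ties included.

    Queries longer than every protein have no windows and produce no rows.
    """
    encoded = [(rec, _encode(rec.sequence)) for rec in proteome]
    out: list[Match] = []
    for qid, seq in queries:
        l = len(seq)
        q = _encode(seq)
        best_count = l + 1
        best: list[tuple[ProteinRecord, int]] = []
        for rec, arr in encoded:
            if arr.size < l:
                continue
            windows = sliding_window_view(arr, l)
            counts = (windows != q).sum(axis=1)
            local_min = int(counts.min())
            if local_min < best_count:
                best_count = local_min
                best = []
            if local_min <= best_count:
                best.extend((rec, int(s)) for s in np.nonzero(counts == best_count)[0])
        for rec, start in best:
            out.append(_make_match(qid, seq, rec, start,
                                   rec.sequence[start:start + l]))
    return _sort(out, queries)
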