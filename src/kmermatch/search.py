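"""The three search protocols: exact, fixed-mismatch, and best-match.

All three are seed-and-verify procedures over the k-mer index and are
deterministic and complete:

* **Exact**: every k-mer of the query (min-cover split) must vote for the
  same window start; a window passing all votes is the peptide verbatim.
* **Fixed-mismatch**: by the pigeonhole principle, if a window differs from
  the query in at most m positions, then among the m+1 disjoint k-mer tiles
  of the query (k = floor(l/(m+1)), Eq. below) at least one tile must match
  the window exactly. Every tile hit proposes a candidate window, and
  candidates are verified by a full-length Hamming comparison, so no match
  within the allowance can be missed.
* **Best-match**: a cascade of mismatch searches with k halving from l down
  to 2, each stage run at its maximum complete threshold m = floor(l/k - 1);
  queries retire at the first stage that finds them a hit, which is then
  guaranteed to carry the globally minimal mismatch count.

The seed-size arithmetic:

    optimal_k(l, m)     = floor(l / (m + 1))
    max_mismatches(l,k) = floor(l / k - 1)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

from .errors import InfeasibleParametersError, InvalidParameterError
from .index import ProteomeIndex, build_index
from .records import Match, ProteinRecord, QuerySet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchParams:
    """Bundle of the quantities governing one search: mode, peptide length
    l, allowance m, and seed size k. In mismatch mode completeness requires
    k <= floor(l / (m + 1))."""

    mode: str  # "exact" | "mismatch" | "best"
    l: int | None = None
    m: int = 0
    k: int | None = None


# -- k-mer splitting and arithmetic ---------------------------------------


def split_rolling(peptide: str, k: int) -> list[tuple[int, str]]:
    """All l-k+1 overlapping k-mers with their offsets, rolling by one."""
    if not 1 <= k <= len(peptide):
        raise InvalidParameterError(
            f"k={k} invalid for peptide of length {len(peptide)}"
        )
    return [(i, peptide[i:i + k]) for i in range(len(peptide) - k + 1)]


def split_min_cover(peptide: str, k: int) -> list[tuple[int, str]]:
    """The ceil(l/k) k-mers at offsets 0, k, 2k, ... covering the whole
    peptide with the least tiles; when k does not divide l the final tile is
    shifted left to end flush with the peptide (overlapping its neighbour)."""
    if not 1 <= k <= len(peptide):
        raise InvalidParameterError(
            f"k={k} invalid for peptide of length {len(peptide)}"
        )
    offs = list(range(0, len(peptide) - k + 1, k))
    if offs[-1] != len(peptide) - k:
        offs.append(len(peptide) - k)
    return [(i, peptide[i:i + k]) for i in offs]


def optimal_k(l: int, m: int) -> int:
    """Largest seed size that still guarantees one exact tile for any match
    with <= m substitutions: floor(l / (m + 1))."""
    if l < 1 or m < 0:
        raise InvalidParameterError(f"need l >= 1 and m >= 0, got l={l}, m={m}")
    k = l // (m + 1)
    if k < 1:
        raise InfeasibleParametersError(
            f"l={l} with m={m} would need more tiles than residues"
        )
    return k


def max_mismatches(l: int, k: int) -> int:
    """Largest allowance m for which seed size k stays complete on length-l
    queries: floor(l / k - 1)."""
    if not 1 <= k <= l:
        raise InvalidParameterError(f"need 1 <= k <= l, got k={k}, l={l}")
    return l // k - 1


def hamming(a: str, b: str) -> tuple[int, tuple[int, ...]]:
    """Hamming distance of equal-length strings and the 1-based positions
    where they differ."""
    if len(a) != len(b):
        raise InvalidParameterError(
            f"hamming needs equal lengths, got {len(a)} and {len(b)}"
        )
    positions = tuple(i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y)
    return len(positions), positions


# -- match assembly -------------------------------------------------------


def _make_match(qid: str, qseq: str, rec: ProteinRecord, local: int,
                window: str, count: int, positions: tuple[int, ...]) -> Match:
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
        start=local,
        end=local + len(qseq) - 1,
        mismatch_count=count,
        mismatch_positions=positions,
    )


def _sort_matches(matches: list[Match], queries: QuerySet) -> list[Match]:
    order = {qid: i for i, (qid, _) in enumerate(queries)}
    matches.sort(key=lambda m: (order[m.query_id], m.accession, m.start))
    return matches


ErrorHook = Callable[[str, str], None] | None


def _report(on_error: ErrorHook, qid: str, message: str) -> None:
    if on_error is not None:
        on_error(qid, message)
    else:
        logger.warning("query %s skipped: %s", qid, message)


# -- exact search ---------------------------------------------------------


def exact_search(index, queries: QuerySet, on_error: ErrorHook = None) -> list[Match]:
    """Every verbatim occurrence of every query within a single protein.

    Each query is min-cover split at the index's k; a window start is kept
    only when every tile's lookup votes for it (offset found minus offset in
    the query), then confirmed against the stored protein sequence. All
    occurrences are reported; a query shorter than k is reported through
    ``on_error`` (or a log warning) and the rest proceed.
    """
    out: list[Match] = []
    for qid, seq in queries:
        if len(seq) < index.k:
            _report(on_error, qid,
                    f"length {len(seq)} shorter than index k={index.k}")
            continue
        tiles = split_min_cover(seq, index.k)
        qoff0, kmer0 = tiles[0]
        candidates = {g - qoff0 for g in index.lookup(kmer0)}
        for qoff, kmer in tiles[1:]:
            if not candidates:
                break
            hits = {g - qoff for g in index.lookup(kmer)}
            candidates &= hits
        for start in sorted(candidates):
            w = index.global_window(start, len(seq))
            if w is None:
                continue  # crosses a protein boundary
            rec, local, window = w
            if window == seq:
                out.append(_make_match(qid, seq, rec, local, window, 0, ()))
    return _sort_matches(out, queries)


# -- fixed-mismatch search ------------------------------------------------


def mismatch_search(index: ProteomeIndex, queries: QuerySet, m: int,
                    on_error: ErrorHook = None) -> list[Match]:
    """Every window within a single protein at Hamming distance <= m from a
    query, each reported exactly once (exact matches included).

    Seeds are the m+1 disjoint tiles at query offsets 0, k, ..., m*k; any
    residues past (m+1)*k are handled by verification, not seeding. Requires
    index.k <= floor(l/(m+1)) for every query length l — otherwise pigeonhole
    completeness would be lost, and the search raises rather than silently
    under-reporting.
    """
    if m < 0:
        raise InvalidParameterError(f"m must be >= 0, got {m}")
    k = index.k
    out: list[Match] = []
    for qid, seq in queries:
        l = len(seq)
        if l < k:
            _report(on_error, qid, f"length {l} shorter than index k={k}")
            continue
        if k > l // (m + 1):
            raise InfeasibleParametersError(
                f"index k={k} exceeds floor({l}/{m + 1})={l // (m + 1)}; "
                f"completeness for m={m} on length-{l} queries is not guaranteed"
            )
        candidates: set[int] = set()
        for i in range(m + 1):
            qoff = i * k
            kmer = seq[qoff:qoff + k]
            for g in index.lookup(kmer):
                start = g - qoff
                if start >= 0:
                    candidates.add(start)
        for start in sorted(candidates):
            w = index.global_window(start, l)
            if w is None:
                continue
            rec, local, window = w
            count, positions = hamming(seq, window)
            if count <= m:
                out.append(_make_match(qid, seq, rec, local, window,
                                       count, positions))
    return _sort_matches(out, queries)


def grouped_mismatch_search(proteome: list[ProteinRecord], queries: QuerySet,
                            m: int, index_cache: dict | None = None,
                            on_error: ErrorHook = None) -> list[Match]:
    """Mismatch search for mixed-length query sets: queries are grouped by
    length and one index is built (or reused from ``index_cache``, keyed by
    k) per group at k = optimal_k(l, m)."""
    cache = index_cache if index_cache is not None else {}
    out: list[Match] = []
    for l, group in sorted(queries.by_length().items()):
        k = optimal_k(l, m)
        if k not in cache:
            cache[k] = build_index(proteome, k)
        out.extend(mismatch_search(cache[k], QuerySet(group), m, on_error))
    return _sort_matches(out, queries)


# -- best-match search ----------------------------------------------------


def best_match_schedule(l: int) -> list[int]:
    """The cascade of seed sizes for length-l queries: start at k = l, halve
    (floor) repeatedly, clamp anything below 2 up to 2, stop after the k = 2
    stage (k = 1 would be brute force). E.g. l=15 -> [15, 7, 3, 2]."""
    if l < 2:
        raise InvalidParameterError(f"best-match needs length >= 2, got {l}")
    ks = [l]
    while ks[-1] > 2:
        ks.append(max(ks[-1] // 2, 2))
    return ks


def best_match_search(proteome: list[ProteinRecord], queries: QuerySet,
                      index_cache: dict | None = None,
                      fallback_brute: bool = False) -> list[Match]:
    """For each query, the match(es) with the globally minimal mismatch
    count, provided that minimum is within the k=2 stage's bound
    max_mismatches(l, 2) = floor(l/2 - 1).

    The proteome is preprocessed once per seed size in the cascade; each
    stage searches only the queries still unmatched, at that stage's maximal
    complete threshold. Because stage thresholds increase as k decreases, the
    first stage that finds a query any hit has already seen every window at
    or below that hit's distance, so the minimal-count hits it returns are
    the global optimum; ties are all reported. Queries that fall through the
    whole cascade are simply absent from the result (callers can diff query
    ids), unless ``fallback_brute`` asks for an exhaustive scan of the
    remainder.
    """
    cache = index_cache if index_cache is not None else {}
    out: list[Match] = []
    for l, group in sorted(queries.by_length().items()):
        remaining = list(group)
        for k in best_match_schedule(l):
            if not remaining:
                break
            m_stage = max_mismatches(l, k)
            if k not in cache:
                cache[k] = build_index(proteome, k)
            hits = mismatch_search(cache[k], QuerySet(remaining), m_stage)
            by_query: dict[str, list[Match]] = {}
            for h in hits:
                by_query.setdefault(h.query_id, []).append(h)
            for qid, qhits in by_query.items():
                best = min(h.mismatch_count for h in qhits)
                out.extend(h for h in qhits if h.mismatch_count == best)
            remaining = [(qid, s) for qid, s in remaining if qid not in by_query]
        if remaining and fallback_brute:
            out.extend(_exhaustive_best(proteome, remaining))
    return _sort_matches(out, queries)


def _exhaustive_best(proteome: list[ProteinRecord],
                     group: list[tuple[str, str]]) -> list[Match]:
    """Direct scan fallback for queries whose best distance exceeds the k=2
    bound; only reachable via ``fallback_brute=True``."""
    out: list[Match] = []
    for qid, seq in group:
        l = len(seq)
        best: list[Match] = []
        best_count = l + 1
        for rec in proteome:
            for i in range(len(rec.sequence) - l + 1):
                window = rec.sequence[i:i + l]
                count, positions = hamming(seq, window)
                if count < best_count:
                    best_count = count
                    best = [_make_match(qid, seq, rec, i, window, count, positions)]
                elif count == best_count:
                    best.append(_make_match(qid, seq, rec, i, window,
                                            count, positions))
        out.extend(best)
    return out
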