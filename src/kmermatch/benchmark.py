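"""Pluggable benchmarking: phase timings plus recall against expected output.

A *method adapter* is any object exposing

* ``name`` — label for the report,
* optional ``preprocess_proteome(proteome, params)``,
* optional ``preprocess_query(queries, params)``,
* required ``search(proteome, queries, params) -> list[Match]``.

Each implemented phase is timed with a monotonic clock; file-format
conversion done by the harness itself is outside the timed phases. The
score is **recall**: the percentage of expected rows the method reports,
where a reported row counts for an expected row iff the tuple
(query sequence, matched sequence, protein accession, start position)
matches exactly. Spurious extra rows do not lower recall (precision is not
the metric); wall-clock numbers are reported but hardware-dependent, so
tests never assert them.

Adapters for external alignment tools (BLAST and the like, run with
permissive E-value settings to maximise true-positive capture) can be
plugged in the same way; the built-in stub simply reports a skipped run when
the binary is absent so the rest of the table still renders.
"""

from __future__ import annotations

import shutil
import time
from dataclasses import dataclass

from .records import Match, ProteinRecord, QuerySet
from .search import best_match_search, exact_search, grouped_mismatch_search
from .index import build_index
from . import oracle


@dataclass
class BenchmarkResult:
    """One row of the benchmark report. Timings in seconds; phases an
    adapter does not implement are None and excluded from the total."""

    method: str
    proteome_preprocess_s: float | None
    query_preprocess_s: float | None
    search_s: float | None
    total_s: float
    recall_pct: float
    status: str = "ok"  # ok | failed | skipped
    error: str = ""


@dataclass(frozen=True)
class BenchmarkParams:
    """Task description handed to adapters: search mode, allowance m (for
    mismatch mode), and the set of query lengths (so preprocessing can build
    whatever per-length indices the mode needs)."""

    mode: str  # "exact" | "mismatch" | "best"
    m: int = 0
    lengths: tuple[int, ...] = ()

    @classmethod
    def for_task(cls, mode: str, queries: QuerySet, m: int = 0) -> "BenchmarkParams":
        return cls(mode=mode, m=m,
                   lengths=tuple(sorted({len(s) for _, s in queries})))


MATCH_KEY_FIELDS = ("query_sequence", "matched_sequence", "accession", "start")


def _key(row) -> tuple:
    if isinstance(row, Match):
        return row.key()
    return tuple(row[f] for f in MATCH_KEY_FIELDS)


def compare_results(reported, expected) -> float:
    """Recall percentage: 100 x |expected rows with a matching reported
    key| / |expected rows|. Accepts Match objects or mapping rows; invariant
    to row order and duplicates in the reported set."""
    expected = list(expected)
    if not expected:
        return 100.0
    reported_keys = {_key(r) for r in reported}
    hit = sum(1 for e in expected if _key(e) in reported_keys)
    return 100.0 * hit / len(expected)


def run_benchmark(adapter, proteome: list[ProteinRecord], queries: QuerySet,
                  params, expected) -> BenchmarkResult:
    """Time the adapter's phases on one task and score recall.

    *params* is a :class:`~kmermatch.search.SearchParams`-like object with
    ``mode`` and ``m``. An adapter that raises is recorded as a failed run
    (recall 0) rather than aborting the whole comparison.
    """
    name = getattr(adapter, "name", type(adapter).__name__)
    if getattr(adapter, "available", lambda: True)() is False:
        return BenchmarkResult(name, None, None, None, 0.0, 0.0,
                               status="skipped", error="binary not found")
    pp = qp = sp = None
    try:
        t0 = time.perf_counter()
        if hasattr(adapter, "preprocess_proteome"):
            adapter.preprocess_proteome(proteome, params)
            pp = time.perf_counter() - t0
        t0 = time.perf_counter()
        if hasattr(adapter, "preprocess_query"):
            adapter.preprocess_query(queries, params)
            qp = time.perf_counter() - t0
        t0 = time.perf_counter()
        reported = adapter.search(proteome, queries, params)
        sp = time.perf_counter() - t0
    except Exception as exc:
        total = sum(t for t in (pp, qp, sp) if t is not None)
        return BenchmarkResult(name, pp, qp, sp, total, 0.0,
                               status="failed", error=str(exc))
    total = sum(t for t in (pp, qp, sp) if t is not None)
    recall = compare_results(reported, expected)
    return BenchmarkResult(name, pp, qp, sp, total, recall)


# -- built-in adapters ----------------------------------------------------


class KmerEngineAdapter:
    """The package's own k-mer engine, phase-split for the harness.

    Exact mode preprocesses one index at k = min query length; mismatch and
    best modes build their per-length / per-stage indices inside
    ``preprocess_proteome`` so the search phase measures lookups and
    verification only, mirroring how a preprocessed proteome would be reused
    across runs.
    """

    name = "kmer-engine"

    def __init__(self) -> None:
        self._cache: dict = {}
        self._exact_index = None

    def preprocess_proteome(self, proteome, params) -> None:
        from .search import best_match_schedule, optimal_k

        self._cache = {}
        lengths = set(getattr(params, "lengths", ()) or ())
        if params.mode == "exact":
            if lengths:
                self._exact_index = build_index(proteome, min(lengths))
        elif params.mode == "mismatch":
            for l in lengths:
                k = optimal_k(l, params.m)
                self._cache.setdefault(k, build_index(proteome, k))
        elif params.mode == "best":
            for l in lengths:
                for k in best_match_schedule(l):
                    self._cache.setdefault(k, build_index(proteome, k))

    def search(self, proteome, queries, params) -> list[Match]:
        if params.mode == "exact":
            index = self._exact_index
            if index is None or index.k > min(len(s) for _, s in queries):
                index = build_index(proteome, min(len(s) for _, s in queries))
            return exact_search(index, queries)
        if params.mode == "mismatch":
            return grouped_mismatch_search(proteome, queries, params.m,
                                           index_cache=self._cache)
        if params.mode == "best":
            return best_match_search(proteome, queries, index_cache=self._cache)
        raise ValueError(f"unknown mode {params.mode!r}")


class BruteForceAdapter:
    """The oracle as an adapter: no preprocessing, exhaustive search.
    Used for debugging (--engine=brute) and as the slow reference row."""

    name = "brute-force"

    def search(self, proteome, queries, params) -> list[Match]:
        if params.mode == "exact":
            return oracle.brute_exact(proteome, queries)
        if params.mode == "mismatch":
            return oracle.brute_hamming(proteome, queries, params.m)
        if params.mode == "best":
            return oracle.brute_best(proteome, queries)
        raise ValueError(f"unknown mode {params.mode!r}")


class ExternalToolAdapter:
    """Stub adapter for third-party binaries (blastp, diamond, mmseqs).

    Execution of external aligners is out of the core scope; this stub
    exists so a benchmark table lists them as skipped when the binary is
    missing and so users have a documented place to plug a real wrapper.
    Conventional permissive settings for short peptides: BLAST E-value 100
    (exact) / 10000 (mismatch); DIAMOND E-value 10000, max 100 alignments
    per query, ultra-sensitive; MMseqs2 E-value 10000, sensitivity 7.
    """

    def __init__(self, name: str, binary: str):
        self.name = name
        self.binary = binary

    def available(self) -> bool:
        return shutil.which(self.binary) is not None

    def search(self, proteome, queries, params) -> list[Match]:
        raise NotImplementedError(
            f"wrapper for {self.binary} not implemented; plug in your own "
            f"adapter implementing search()"
        )
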