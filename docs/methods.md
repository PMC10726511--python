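# Methods

## Problem and model

Given a set of query peptides (typically 8–17 residues: MHC class I ligands
are 8–11-mers, class II 13–17-mers) and a proteome, report every window of a
protein that equals a query (exact mode), differs from it in at most *m*
positions (mismatch mode), or has the globally minimal number of differing
positions (best-match mode). Distance is Hamming distance: substitutions
only, no insertions or deletions, no similarity scoring. Matches never span
protein boundaries.

## Index

The proteome is concatenated in file order into a single 0-based coordinate
space; an offset table records each protein's global start and length.
Every k-mer of every protein of length ≥ k is stored in a hash map from
k-mer string to the sorted list of global start offsets (k-mers are
enumerated per protein, then shifted, so a spanning k-mer cannot exist).
This is done once per proteome and per k; a SHA-256 checksum of the
concatenated sequences plus the k value are stored with the index so a
stale artifact is refused on load rather than silently served.

Two storage backends sit behind one save/load contract: a versioned pickle
container (magic bytes + format version + payload) that reloads the whole
map — the right shape for mismatch/best-match search, which touches many
keys — and an embedded SQLite key-value store that can be queried per k-mer
without materialising the map, suited to exact search over large proteomes
where each query touches only ⌈l/k⌉ keys. Both round-trip to identical
query behaviour; the lazy reader is exercised against the in-memory map in
the tests.

Non-canonical residues (X, B, Z, U, O) are indexed literally and compared by
strict character equality — X matches only X. Wildcard semantics would make
match counts depend on an arbitrary expansion policy; literal matching keeps
the engine deterministic. Lowercase input is uppercased at parse time and
trailing `*` terminators are stripped; any other character is a parse error
naming the line. Duplicate accessions in one FASTA are an error.

## Search protocols

**Exact.** The query is split into ⌈l/k⌉ covering k-mers (offsets 0, k, 2k,
…, with the last tile shifted left to end flush when k ∤ l). Each tile's
lookup votes for `global_offset − query_offset`; only window starts voted
for by every tile survive, and each surviving window is confirmed against
the stored protein sequence (this also discards starts whose window would
cross a protein boundary). Completeness is immediate: a verbatim occurrence
makes every tile vote for its start.

**Mismatch.** Seed size k = ⌊l/(m+1)⌋. Seeds are the m+1 disjoint tiles at
query offsets 0, k, …, m·k; residues past (m+1)·k are covered by
verification rather than seeding — the pigeonhole argument needs only that
the m+1 disjoint tiles cannot all carry a substitution when only m exist.
Every seed hit proposes a candidate window start (deduplicated across
seeds); candidates are verified by one full-length Hamming comparison. The
verification route is equivalent to comparing the query's neighbouring
k-mers against the proteome's neighbouring k-mers tile by tile — both
accept exactly the windows with total distance ≤ m — but a single
full-window comparison is simpler and boundary-safe; the equivalence is
asserted by the oracle tests, not assumed. An index whose k exceeds
⌊l/(m+1)⌋ cannot guarantee completeness, so the search raises an
infeasible-parameters error instead of silently under-reporting.

**Best match.** Seed sizes k₁ = l, k_{i+1} = ⌊k_i/2⌋ clamped up to 2,
stopping after the k = 2 stage (k = 1 would degenerate to brute force);
duplicate values collapse. Each stage runs the mismatch protocol at that
stage's maximal complete allowance m = ⌊l/k − 1⌋, only over the queries not
yet matched. Stage allowances increase as k decreases, so when a stage first
finds a query any hit, the stage has already enumerated every window at
distance ≤ its allowance, and the minimal-count hits it returns are the
global optimum. All co-optimal sites are reported (returning only one would
lose information; callers can take the first). A query whose true minimum
exceeds ⌊l/2 − 1⌋ falls through the cascade and is reported as unmatched;
an optional `fallback_brute=True` switches on an exhaustive scan for those
remainders rather than guessing a default.

Mixed-length query sets are grouped by length; seed sizes and cascade
schedules are computed per group and indices cached per k. Output is sorted
by (query input order, accession, start), so identical inputs give
byte-identical result files.

## Result schema and conventions

Results flatten to a fixed column order (query_id, query sequence, matched
sequence, accession, protein name, gene, mismatch count, mismatch
positions, species, taxon id, start, end, existence level) in CSV, TSV, or
JSON. Optional metadata columns are emitted empty, never omitted. Mismatch
positions are 1-based within the peptide, semicolon-joined. File
coordinates are 1-based inclusive within the protein, the convention of
protein databases; the library is 0-based internally and the writer/reader
pair is exactly the boundary. Snake_case column labels are a deliberate
normalisation of the display names a web UI would use.

## Oracle

`kmermatch.oracle` re-derives correctness with no shared logic: exact
matching by naive substring scan, mismatch and best-match by comparing
*every* window of every protein position-by-position (batched with numpy
sliding windows, which changes speed, not semantics). The oracle is itself
property-tested (window counts, distance bounds, boundary behaviour), and
test equivalence between oracle and engine — exact set equality on (query,
matched sequence, accession, start) — is the package's core guarantee.

## Synthetic data

The generator emulates the structure of the real study designs this tool
serves: a background proteome (default 200 proteins of 100–500 residues,
matching a desk-scale slice of a real proteome's length range), query
peptides planted by writing a copy mutated at exactly d distinct positions
(substitutions only, never to the same residue) into non-overlapping slots,
and shuffled decoys re-shuffled until verbatim absent. Background residues
are uniform over the 20 canonical amino acids by default — uniformity makes
the spurious-hit probability analytically estimable (a random window
matches a given position with probability 1/20) — with an empirical
amino-acid frequency option for protein-like composition. The same seed
yields byte-identical FASTA.

What the fixtures do *not* emulate: real amino-acid correlation structure,
homologous protein families (paralogs produce many co-optimal best matches
in real proteomes), low-complexity regions, and non-canonical residues.
Passing tests therefore demonstrate algorithmic completeness and
correctness of the bookkeeping, not performance or match statistics on real
proteomes; the engine's guarantees do not depend on sequence composition,
so completeness transfers, but observed match counts will not.

Drop-in benchmark datasets come in three kinds mirroring the three tasks —
planted 9-mers plus an equal number of shuffled decoys (exact); mixed
8–15-mers planted at distances 0–3, searched at m = 2 (mismatch); 15-mers
planted at distances 0–6 (best match) — each with oracle-generated expected
output. Desk-scale sizes (tiny/small/medium = 50/200/800 proteins,
25/100/400 planted peptides) keep the default suite and the equivalence
sweep (50 proteomes × the l ∈ 8..17, m ∈ 0..3 grid) around half a minute on
one CPU; the sizes are a design choice for a suite one runs on every
commit.

## Benchmark harness

An adapter exposes optional `preprocess_proteome`, optional
`preprocess_query`, and required `search`; each implemented phase is timed
with a monotonic clock and absent phases reported as N/A. Recall = 100 ×
(expected rows whose (query, matched sequence, accession, start) key is
reported) / (expected rows); extra reported rows do not reduce it
(precision is not the metric — the exact key already excludes false
positives from counting). Wall-clock numbers are hardware-dependent and are
printed but never asserted. Stubs for external aligners (BLAST, DIAMOND,
MMseqs2, with the permissive short-peptide settings documented in the code)
render as "skipped" rows when the binary is absent; executing them is out
of scope, and converting their gapped alignments to substitution-only rows
is undefined and deliberately left unsolved.

## Numerical and degenerate-input choices

* Seed arithmetic is pure integer floor division; no floating point
  anywhere in the matching path.
* Queries shorter than the index k are reported per-query (error hook or
  log warning) while the rest of the set proceeds; an empty proteome or
  k < 1 is an immediate error.
* Proteins shorter than k contribute no k-mers but remain in the record
  table, so coordinate mapping and metadata stay complete.
* Candidate windows extending beyond their protein are discarded during
  verification, never reported truncated.
* Ties (same query, several sites at equal distance) are all reported,
  ordered by accession then start.

## Limitations

* Substitutions only: no gapped matching, no BLOSUM-style ranking of
  matches (a natural extension), no nucleotide support.
* Best-match mode is bounded by the k = 2 stage (distance ⌊l/2 − 1⌋);
  beyond that a query is unmatched unless the exhaustive fallback is
  requested.
* The in-memory map scales linearly with proteome size; very large
  proteomes (hundreds of millions of residues) want the SQLite backend and
  per-query lookups, at a constant-factor speed cost.
* Full-scale reproduction against real proteomes (human reference proteome
  UP000005640, RefSeq betacoronavirus set) requires those downloads; the
  corresponding test activates only when the files are placed under
  `data/full_benchmark/` (`human_proteome.fasta`, `betacoronavirus.fasta`,
  `mhc_ligands.txt`, `sars_cov2.txt`, `neoepitopes.txt`,
  `milk_allergens.txt`).
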