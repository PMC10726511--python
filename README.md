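# kmermatch

Deterministic k-mer matching of short peptides in large protein sets.

Immunologists routinely need to locate linear T-cell epitopes — peptides of
roughly 8–17 residues — inside whole proteomes: assigning source proteins to
curated epitopes (exact matches), testing cross-reactivity between viral
peptide sets (matches within a substitution budget), or scoring how well a
neoepitope or allergen peptide is conserved in the human host (the
*best* match, i.e. the window with the fewest substitutions). General-purpose
aligners are built for long sequences and are not guaranteed to find every
short-peptide match. `kmermatch` is built for exactly this task and is
**complete by construction**: every match within the stated substitution
budget is found, deterministically.

## The algorithm

The proteome is preprocessed once per k into a hash index mapping every
k-mer to its start offsets in a single concatenated coordinate space (k-mers
never span protein boundaries). Three search protocols run on top:

* **Exact** — the query is split into the fewest k-mers covering it; each
  lookup votes for `offset_found − offset_in_query`, and a window start
  supported by every tile is an exact match. All occurrences are reported.
* **Mismatch** — for a query of length *l* and allowance *m*, the seed size
  is

  `k = ⌊ l / (m + 1) ⌋`

  By the pigeonhole principle, any window within Hamming distance *m* of the
  query must agree exactly with at least one of the *m+1* disjoint k-mer
  tiles of the query, so every tile hit proposes a candidate window, and a
  full-length Hamming comparison verifies it. The inverse relation
  `m = ⌊ l/k − 1 ⌋` gives the largest allowance a given index k can serve
  completely.
* **Best match** — a cascade of mismatch searches with k halving from *l*
  down to 2 (for *l* = 15: k ∈ {15, 7, 3, 2}, per-stage allowances
  {0, 1, 4, 6}); a query retires at the first stage that finds it a hit,
  which is then provably the global minimum-mismatch match (ties all
  reported).

The package also ships an exhaustive brute-force reference
(`kmermatch.oracle`), a seeded synthetic proteome/peptide generator with a
ground-truth manifest (`kmermatch.fixtures`), and a pluggable benchmarking
harness that times preprocessing/search phases and scores **recall** — the
percentage of expected rows found, keyed on (query, matched sequence,
protein ID, position) (`kmermatch.benchmark`).

## Worked example

Searching one MHC-class-I-sized peptide with up to two substitutions against
a two-protein FASTA:

```sh
$ printf 'epi1\tYLLDLHSYL\n' > peptides.txt
$ kmermatch search --proteome proteome.fasta --peptides peptides.txt --mismatches 2
query_id,query_sequence,matched_sequence,accession,protein_name,gene,mismatch_count,mismatch_positions,species,taxon_id,start,end,existence_level
epi1,YLLDLHSYL,YLLDLHSYL,P0EX01,Demo oncoprotein,DEMO1,0,,Homo sapiens,9606,5,13,1
epi1,YLLDLHSYL,YLLELHAYL,P0EX02,Demo kinase,DEMO2,2,4;7,Homo sapiens,9606,5,13,2
```

Read: the peptide occurs verbatim in P0EX01 at residues 5–13 (1-based,
inclusive), and P0EX02 carries a two-substitution variant whose differences
sit at peptide positions 4 and 7 (`D→E`, `S→A`). `--best` keeps only the
minimum-mismatch row(s); `--exact` keeps verbatim hits only. A benchmark run
on a generated dataset prints phase timings and recall:

```sh
$ kmermatch benchmark --generate exact --scale tiny --seed 1
method         proteome_s  query_s  search_s  total_s  recall_%  status
kmer-engine         0.005      N/A     0.000    0.005     100.0  ok
brute-force           N/A      N/A     0.001    0.001     100.0  ok
```

Other subcommands: `kmermatch preprocess` (build and store an index once per
proteome and k; pickle or sqlite backend) and `kmermatch generate-fixtures`
(write a synthetic proteome + peptides + oracle-made expected output).

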