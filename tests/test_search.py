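"""Unit and property tests for the seed arithmetic and the three search
protocols."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmermatch import (
    InfeasibleParametersError,
    InvalidParameterError,
    QuerySet,
    best_match_schedule,
    best_match_search,
    build_index,
    exact_search,
    hamming,
    max_mismatches,
    mismatch_search,
    optimal_k,
    split_min_cover,
    split_rolling,
)
from kmermatch import oracle
from kmermatch.fixtures import FixtureSpec, make_proteome

from conftest import match_keys

AA = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")
peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=25)


# -- splitting ------------------------------------------------------------


def test_rolling_split_enumerates_every_window():
    assert split_rolling("YLLDLHSYL", 5) == [
        (0, "YLLDL"), (1, "LLDLH"), (2, "LDLHS"), (3, "DLHSY"), (4, "LHSYL"),
    ]
    assert split_rolling("PEPTIDE", 7) == [(0, "PEPTIDE")]


def test_min_cover_split_uses_fewest_tiles():
    # 9-mer at k=5: two tiles, the last shifted left to end flush
    assert split_min_cover("YLLDLHSYL", 5) == [(0, "YLLDL"), (4, "LHSYL")]
    # divisible case tiles without overlap
    assert split_min_cover("ABCDEFGHIJ", 5) == [(0, "ABCDE"), (5, "FGHIJ")]


@given(peptides, st.integers(min_value=1, max_value=25))
@settings(derandomize=True, max_examples=100)
def test_min_cover_split_covers_every_position(pep, k):
    if k > len(pep):
        with pytest.raises(InvalidParameterError):
            split_min_cover(pep, k)
        return
    tiles = split_min_cover(pep, k)
    assert len(tiles) == -(-len(pep) // k)  # ceil(l/k)
    covered = set()
    for off, kmer in tiles:
        assert pep[off:off + k] == kmer
        covered.update(range(off, off + k))
    assert covered == set(range(len(pep)))
    assert len(split_rolling(pep, k)) == len(pep) - k + 1


# -- seed-size arithmetic -------------------------------------------------


@pytest.mark.parametrize("l,m,k", [(9, 2, 3), (15, 1, 7), (9, 0, 9), (8, 3, 2)])
def test_optimal_seed_size(l, m, k):
    assert optimal_k(l, m) == k


def test_optimal_seed_size_infeasible_when_more_tiles_than_residues():
    with pytest.raises(InfeasibleParametersError):
        optimal_k(5, 5)


@pytest.mark.parametrize("l,k,m", [(15, 2, 6), (15, 7, 1), (15, 15, 0), (9, 3, 2)])
def test_max_allowance_for_seed_size(l, k, m):
    assert max_mismatches(l, k) == m


@given(st.integers(min_value=2, max_value=50), st.integers(min_value=0, max_value=10))
@settings(derandomize=True, max_examples=200)
def test_seed_arithmetic_is_mutually_consistent(l, m):
    """The allowance recovered from the optimal seed size never undershoots
    the allowance it was derived for (pigeonhole consistency)."""
    if l // (m + 1) < 1:
        return
    k = optimal_k(l, m)
    assert 1 <= k <= l
    assert max_mismatches(l, k) >= m
    # pigeonhole: m+1 disjoint k-tiles fit inside the peptide
    assert (m + 1) * k <= l


# -- Hamming --------------------------------------------------------------


def test_hamming_counts_and_positions():
    assert hamming("AAA", "AAA") == (0, ())
    assert hamming("AAA", "ABA") == (1, (2,))
    with pytest.raises(InvalidParameterError):
        hamming("AA", "AAA")


@given(st.tuples(peptides, peptides).filter(lambda t: len(t[0]) == len(t[1])))
@settings(derandomize=True, max_examples=100)
def test_hamming_agrees_with_positionwise_comparison(pair):
    a, b = pair
    count, positions = hamming(a, b)
    expect = [i + 1 for i in range(len(a)) if a[i] != b[i]]
    assert count == len(expect)
    assert list(positions) == expect
    assert hamming(b, a)[0] == count  # symmetry


# -- exact search ---------------------------------------------------------


def test_exact_search_finds_planted_peptide_once(worked_example_protein):
    index = build_index([worked_example_protein], 5)
    q = QuerySet([("q1", "YLLDLHSYL")])
    (m,) = exact_search(index, q)
    assert (m.accession, m.start, m.mismatch_count) == ("EX1", 0, 0)
    m.validate()


def test_exact_search_reports_all_occurrences():
    from kmermatch.records import ProteinRecord

    rec = ProteinRecord(accession="R1", sequence="PEPTIDEXXPEPTIDE")
    rec2 = ProteinRecord(accession="R2", sequence="YYPEPTIDEYY")
    index = build_index([rec, rec2], 4)
    hits = exact_search(index, QuerySet([("q1", "PEPTIDE")]))
    assert [(h.accession, h.start) for h in hits] == [("R1", 0), ("R1", 9), ("R2", 2)]


def test_exact_search_skips_too_short_query_and_continues():
    from kmermatch.records import ProteinRecord

    rec = ProteinRecord(accession="R1", sequence="PEPTIDES")
    index = build_index([rec], 5)
    errors = []
    hits = exact_search(index, QuerySet([("tiny", "PE"), ("ok", "PEPTI")]),
                        on_error=lambda qid, msg: errors.append(qid))
    assert errors == ["tiny"]
    assert [h.query_id for h in hits] == ["ok"]


def test_exact_search_matches_brute_force_on_random_fixture(small_proteome):
    records, manifest = small_proteome
    queries = manifest.queries()
    index = build_index(records, min(len(s) for _, s in queries))
    assert match_keys(exact_search(index, queries)) == match_keys(
        oracle.brute_exact(records, queries))


# -- mismatch search ------------------------------------------------------


def test_mismatch_search_worked_example():
    """l=9, m=2, k=3: a window differing in exactly two residues of the
    last tile is accepted; three mismatches is rejected."""
    from kmermatch.records import ProteinRecord

    #            query  YLLDLHSYL  -> window with 2 subs in last tile
    window = "YLLDLHAYV"  # positions 7 and 9 differ
    rec = ProteinRecord(accession="R1", sequence="GGG" + window + "GGG")
    index = build_index([rec], optimal_k(9, 2))
    hits = mismatch_search(index, QuerySet([("q1", "YLLDLHSYL")]), 2)
    assert len(hits) == 1
    assert hits[0].mismatch_count == 2
    assert hits[0].mismatch_positions == (7, 9)
    assert hits[0].start == 3
    hits[0].validate()
    # same window is out of reach at m=1
    index1 = build_index([rec], optimal_k(9, 1))
    assert mismatch_search(index1, QuerySet([("q1", "YLLDLHSYL")]), 1) == []


def test_mismatch_zero_equals_exact(small_proteome):
    records, manifest = small_proteome
    queries = manifest.queries()
    index = build_index(records, 9)
    assert match_keys(mismatch_search(index, queries, 0)) == match_keys(
        exact_search(index, queries))


def test_mismatch_search_refuses_incomplete_seed_size(small_proteome):
    records, _ = small_proteome
    index = build_index(records, 5)  # k=5 > floor(9/3)=3 for m=2
    with pytest.raises(InfeasibleParametersError):
        mismatch_search(index, QuerySet([("q1", "A" * 9)]), 2)


def test_mismatch_matches_are_monotone_in_allowance(small_proteome):
    records, manifest = small_proteome
    queries = manifest.queries()
    previous = set()
    for m in range(4):
        index = build_index(records, optimal_k(9, m))
        current = match_keys(mismatch_search(index, queries, m))
        assert previous <= current
        previous = current


# -- best-match search ----------------------------------------------------


def test_best_match_schedule_halves_to_two():
    assert best_match_schedule(15) == [15, 7, 3, 2]
    assert [max_mismatches(15, k) for k in best_match_schedule(15)] == [0, 1, 4, 6]
    assert best_match_schedule(9) == [9, 4, 2]
    assert best_match_schedule(3) == [3, 2]
    assert best_match_schedule(2) == [2]


def test_best_match_verbatim_query_reports_zero_mismatches(small_proteome):
    records, manifest = small_proteome
    exact_planted = [p for p in manifest.planted if p.distance == 0][0]
    hits = best_match_search(records, QuerySet([("q", exact_planted.peptide)]))
    assert hits and all(h.mismatch_count == 0 for h in hits)
    assert any(h.accession == exact_planted.accession and
               h.start == exact_planted.start for h in hits)


def test_best_match_equals_exhaustive_minimum():
    spec = FixtureSpec(n_proteins=60, min_length=80, max_length=160,
                       n_planted=7, planted_lengths=(15,),
                       planted_distances=(0, 1, 2, 3, 4, 5, 6), seed=11)
    records, manifest = make_proteome(spec)
    queries = manifest.queries()
    reported = best_match_search(records, queries)
    expected = oracle.brute_best(records, queries)
    best_reported = {}
    for h in reported:
        best_reported.setdefault(h.query_id, h.mismatch_count)
    for e in expected:
        if e.mismatch_count <= max_mismatches(15, 2):
            assert best_reported[e.query_id] == e.mismatch_count
    # all co-optimal sites are reported, not just one
    assert match_keys(reported) == {
        e.key() for e in expected if e.mismatch_count <= max_mismatches(15, 2)}


def test_best_match_beyond_cascade_bound_is_unmatched_unless_fallback():
    from kmermatch.records import ProteinRecord

    # proteome of glycines: an all-W 8-mer is at distance 8 > floor(8/2-1)=3
    records = [ProteinRecord(accession="R1", sequence="G" * 40)]
    q = QuerySet([("q1", "W" * 8)])
    assert best_match_search(records, q) == []
    fallback = best_match_search(records, q, fallback_brute=True)
    assert fallback and fallback[0].mismatch_count == 8


def test_search_output_is_deterministic(small_proteome):
    records, manifest = small_proteome
    queries = manifest.queries()
    index = build_index(records, optimal_k(9, 2))
    first = mismatch_search(index, queries, 2)
    second = mismatch_search(build_index(records, optimal_k(9, 2)), queries, 2)
    assert first == second  # identical objects in identical order
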