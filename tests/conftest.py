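import pytest

from kmermatch.fixtures import FixtureSpec, make_proteome
from kmermatch.records import ProteinRecord, QuerySet


@pytest.fixture
def worked_example_protein():
    """The 9-mer used throughout the worked examples, as a one-protein
    proteome."""
    return ProteinRecord(accession="EX1", sequence="YLLDLHSYL")


@pytest.fixture
def small_proteome():
    """50 short proteins with three 9-mers planted at distances 0, 1, 2 and
    two shuffled decoys; returns (records, manifest)."""
    spec = FixtureSpec(
        n_proteins=50, min_length=60, max_length=120,
        n_planted=3, planted_lengths=(9,), planted_distances=(0, 1, 2),
        n_decoys=2, decoy_length=9, seed=7,
    )
    return make_proteome(spec)


def match_keys(matches):
    """Identity keys for set comparison: (query seq, matched seq,
    accession, 0-based start)."""
    return {m.key() for m in matches}


@pytest.fixture
def keyset():
    return match_keys
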