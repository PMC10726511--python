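"""Synthetic proteome / peptide generation with a ground-truth manifest.

Everything tests and benchmarks consume is generated here, seeded and
byte-reproducible. A fixture emulates the structure of the real study
designs in this problem area: a multi-protein background, query peptides
*planted* into proteins at a controlled Hamming distance (the planted window
differs from the query in exactly d positions, substitutions only), and
shuffled *decoy* peptides re-shuffled until verbatim absent from the
proteome. The manifest records every planted site and decoy so expected
output can be produced independently (by :mod:`kmermatch.oracle`) and
checked.

Background residues are drawn uniformly from the 20 canonical amino acids by
default, which keeps the probability of spurious near-matches analytically
estimable; an empirical amino-acid frequency option is available for a more
protein-like composition.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import InvalidInputError, InvalidParameterError
from .io_formats import write_fasta, write_results
from .oracle import brute_best, brute_exact, brute_hamming
from .records import CANONICAL_AA, ProteinRecord, QuerySet

#: Approximate amino-acid frequencies in vertebrate proteins (used when
#: ``frequencies="empirical"``).
EMPIRICAL_AA_FREQS = {
    "A": 0.074, "R": 0.042, "N": 0.044, "D": 0.059, "C": 0.033,
    "Q": 0.058, "E": 0.037, "G": 0.074, "H": 0.029, "I": 0.038,
    "L": 0.076, "K": 0.072, "M": 0.018, "F": 0.040, "P": 0.050,
    "S": 0.081, "T": 0.062, "W": 0.013, "Y": 0.033, "V": 0.068,
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults give the desk-scale study condition used throughout the test
    suite: 200 proteins of 100-500 residues (uniform), uniform canonical
    alphabet.
    """

    n_proteins: int = 200
    min_length: int = 100
    max_length: int = 500
    alphabet: str = CANONICAL_AA
    frequencies: str = "uniform"  # "uniform" | "empirical"
    n_planted: int = 0
    planted_lengths: tuple[int, ...] = (9,)
    planted_distances: tuple[int, ...] = (0,)
    n_decoys: int = 0
    decoy_length: int = 9
    seed: int = 0


@dataclass
class PlantedPeptide:
    """Manifest row: where a query's mutated copy was embedded."""

    query_id: str
    peptide: str          # the query sequence (what gets searched)
    window: str           # the embedded window, Hamming distance `distance` away
    accession: str
    start: int            # 0-based within the protein
    distance: int


@dataclass
class Manifest:
    planted: list[PlantedPeptide] = field(default_factory=list)
    decoys: list[tuple[str, str]] = field(default_factory=list)

    def queries(self) -> QuerySet:
        """All planted queries followed by all decoys, as a QuerySet."""
        rows = [(p.query_id, p.peptide) for p in self.planted]
        rows += list(self.decoys)
        return QuerySet(rows)

    def to_json(self) -> str:
        return json.dumps(
            {"planted": [asdict(p) for p in self.planted],
             "decoys": [list(d) for d in self.decoys]},
            indent=1,
        )


def _weights(spec: FixtureSpec) -> list[float] | None:
    if spec.frequencies == "uniform":
        return None
    if spec.frequencies == "empirical":
        return [EMPIRICAL_AA_FREQS[a] for a in spec.alphabet]
    raise InvalidParameterError(f"unknown frequencies {spec.frequencies!r}")


def _mutate(peptide: str, d: int, rng: random.Random, alphabet: str) -> str:
    """Substitute exactly d distinct positions, never to the same residue."""
    if d > len(peptide):
        raise InvalidParameterError(
            f"cannot place {d} substitutions in a {len(peptide)}-mer"
        )
    chars = list(peptide)
    for pos in rng.sample(range(len(peptide)), d):
        choices = [a for a in alphabet if a != chars[pos]]
        chars[pos] = rng.choice(choices)
    return "".join(chars)


def make_proteome(spec: FixtureSpec) -> tuple[list[ProteinRecord], Manifest]:
    """Generate a seeded random proteome with planted peptides and decoys.

    Planted windows are written into non-overlapping slots so the manifest
    is unambiguous; each planted query is mutated at exactly its requested
    distance before embedding. Decoys are residue-shuffles of fresh random
    peptides, re-shuffled (or re-drawn) until absent from the proteome
    verbatim. Identical specs (including seed) produce identical output,
    byte for byte.
    """
    if spec.min_length < 1 or spec.max_length < spec.min_length:
        raise InvalidParameterError("invalid protein length range")
    if spec.n_planted and max(spec.planted_lengths) > spec.max_length:
        raise InvalidInputError("planted peptide longer than the longest protein")
    rng = random.Random(spec.seed)
    weights = _weights(spec)

    lengths = [rng.randint(spec.min_length, spec.max_length)
               for _ in range(spec.n_proteins)]
    proteins = [
        rng.choices(spec.alphabet, weights=weights, k=n) for n in lengths
    ]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_proteins)}

    manifest = Manifest()
    for j in range(spec.n_planted):
        l = spec.planted_lengths[j % len(spec.planted_lengths)]
        d = spec.planted_distances[j % len(spec.planted_distances)]
        peptide = "".join(rng.choices(spec.alphabet, weights=weights, k=l))
        window = _mutate(peptide, d, rng, spec.alphabet)
        for _attempt in range(1000):
            p = rng.randrange(spec.n_proteins)
            if lengths[p] < l:
                continue
            start = rng.randrange(lengths[p] - l + 1)
            if all(start + l <= s or start >= s + w for s, w in occupied[p]):
                break
        else:
            raise InvalidInputError(
                "could not place all planted peptides without overlap; "
                "reduce n_planted or enlarge the proteome"
            )
        occupied[p].append((start, l))
        proteins[p][start:start + l] = list(window)
        manifest.planted.append(PlantedPeptide(
            query_id=f"p{j + 1}", peptide=peptide, window=window,
            accession=f"SYN{p + 1:05d}", start=start, distance=d,
        ))

    records = [
        ProteinRecord(
            accession=f"SYN{i + 1:05d}",
            sequence="".join(chars),
            name=f"Synthetic protein {i + 1}",
            gene=f"SYNG{i + 1}",
            species="Synthetica exempli",
            taxon_id=99999,
            existence_level=5,
        )
        for i, chars in enumerate(proteins)
    ]
    haystack = "\n".join(r.sequence for r in records)

    for j in range(spec.n_decoys):
        base = "".join(rng.choices(spec.alphabet, weights=weights,
                                   k=spec.decoy_length))
        decoy = None
        for _attempt in range(1000):
            shuffled = list(base)
            rng.shuffle(shuffled)
            cand = "".join(shuffled)
            if cand not in haystack:
                decoy = cand
                break
            base = "".join(rng.choices(spec.alphabet, weights=weights,
                                       k=spec.decoy_length))
        if decoy is None:  # pragma: no cover - astronomically unlikely
            raise InvalidInputError("could not construct an absent decoy")
        manifest.decoys.append((f"d{j + 1}", decoy))

    return records, manifest


# -- drop-in benchmark datasets ------------------------------------------

_SCALES = {"tiny": 0.25, "small": 1.0, "medium": 4.0}

_KINDS = {
    # planted 9-mers + an equal count of shuffled decoys, exact matching
    "exact": dict(n_planted=100, planted_lengths=(9,), planted_distances=(0,),
                  n_decoys=100, decoy_length=9, m=0),
    # mixed 8-15-mers planted at distances 0..3, searched at m=2
    "mismatch": dict(n_planted=96, planted_lengths=tuple(range(8, 16)),
                     planted_distances=(0, 1, 2, 3), n_decoys=0, m=2),
    # 15-mers planted at distances 0..6, best-match task
    "best": dict(n_planted=70, planted_lengths=(15,),
                 planted_distances=(0, 1, 2, 3, 4, 5, 6), n_decoys=0, m=None),
}


def make_benchmark_dataset(kind: str, scale: str = "small", seed: int = 0,
                           outdir: str | Path = ".") -> dict[str, Path]:
    """Write a complete drop-in benchmark instance.

    Produces ``proteome.fasta``, ``peptides.txt``, ``expected.csv`` (from
    the brute-force oracle), ``manifest.json`` and ``params.json`` under
    *outdir* and returns their paths. ``kind`` selects the task design
    (exact / mismatch / best); ``scale`` multiplies the planted/decoy counts
    and proteome size (tiny = 0.25x, small = 1x, medium = 4x).
    """
    if kind not in _KINDS:
        raise InvalidParameterError(f"unknown benchmark kind {kind!r}")
    if scale not in _SCALES:
        raise InvalidParameterError(f"unknown scale {scale!r}")
    f = _SCALES[scale]
    params = dict(_KINDS[kind])
    m = params.pop("m")
    spec = FixtureSpec(
        n_proteins=max(20, int(200 * f)),
        n_planted=max(len(params["planted_lengths"]), int(params["n_planted"] * f)),
        planted_lengths=params["planted_lengths"],
        planted_distances=params["planted_distances"],
        n_decoys=int(params["n_decoys"] * f),
        decoy_length=params.get("decoy_length", 9),
        seed=seed,
    )
    records, manifest = make_proteome(spec)
    queries = manifest.queries()
    if kind == "exact":
        expected = brute_exact(records, queries)
    elif kind == "mismatch":
        expected = brute_hamming(records, queries, m)
    else:
        expected = brute_best(records, queries)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "peptides": outdir / "peptides.txt",
        "expected": outdir / "expected.csv",
        "manifest": outdir / "manifest.json",
        "params": outdir / "params.json",
    }
    write_fasta(records, paths["proteome"], uniprot_headers=True)
    with open(paths["peptides"], "w", encoding="utf-8", newline="\n") as fh:
        for qid, seq in queries:
            fh.write(f"{qid}\t{seq}\n")
    write_results(expected, paths["expected"], format="csv")
    paths["manifest"].write_text(manifest.to_json(), encoding="utf-8")
    paths["params"].write_text(
        json.dumps({"kind": kind, "scale": scale, "seed": seed, "m": m}, indent=1),
        encoding="utf-8",
    )
    return paths
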