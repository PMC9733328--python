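"""Exhaustive point-mutation neighborhoods of codons and repeat units.

A trinucleotide repeat (CAG)n is read in three registers, giving three
homopolymer-coding frames: CAG -> polyQ, AGC -> polyS, GCA -> polyA.  The
frames differ sharply in how close their codon sits to the stop set
{TAA, TAG, TGA}: CAG is one substitution away from TAG (C->T at the first
position), while AGC and GCA are two away from any stop.  This module makes
those statements computable: it enumerates every codon reachable by a fixed
number of simultaneous point mutations, classifies each outcome as silent,
missense or nonsense, and reduces the enumeration to the quantities the
frame-survival arguments need (stop fractions, reachable amino-acid sets,
per-frame minimum distances to a stop).

All enumeration is exact and deterministic; nothing here is sampled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
STOP = "*"

#: Purine<->purine and pyrimidine<->pyrimidine substitutions.
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _standard_table() -> dict[str, str]:
    tab = unambiguous_dna_by_id[1]
    code = dict(tab.forward_table)
    for c in tab.stop_codons:
        code[c] = STOP
    return code


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon -> amino-acid table; stops encoded as ``'*'``."""

    table: dict[str, str] = field(default_factory=_standard_table)

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.table)}")

    def translate(self, codon: str) -> str:
        return self.table[codon]

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == STOP)


STANDARD_CODE = GeneticCode()


def _check_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"codon must be 3 letters over ACGT, got {codon!r}")
    return codon


@dataclass(frozen=True)
class MutantProfile:
    """All codons at exact Hamming distance ``distance`` from ``source``.

    ``outcomes`` holds ``(codon, amino_acid_or_stop, class)`` triples in
    lexicographic codon order; classes are ``nonsense`` (mutant is a stop),
    ``silent`` (same amino acid as the source) and ``missense`` (anything
    else).  ``counts`` totals each class.
    """

    source: str
    distance: int
    outcomes: tuple[tuple[str, str, str], ...]
    counts: dict[str, int]

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)


def _classify(source_aa: str, mutant_aa: str) -> str:
    if mutant_aa == STOP:
        return "nonsense"
    if mutant_aa == source_aa:
        return "silent"
    return "missense"


def enumerate_point_mutants(
    codon: str, distance: int, code: GeneticCode = STANDARD_CODE
) -> MutantProfile:
    """Enumerate every codon differing from ``codon`` at exactly ``distance`` positions.

    There are C(3, distance) * 3**distance outcomes (9 at distance 1, 27 at
    distance 2 or 3); each mutated position takes one of the three alternative
    bases, so no outcome ever equals the source.
    """
    codon = _check_codon(codon)
    if distance not in (1, 2, 3):
        raise ValueError(f"distance must be 1, 2 or 3, got {distance}")
    source_aa = code.translate(codon)
    outcomes = []
    for positions in itertools.combinations(range(3), distance):
        alt = [[b for b in BASES if b != codon[p]] for p in positions]
        for repl in itertools.product(*alt):
            mut = list(codon)
            for p, b in zip(positions, repl):
                mut[p] = b
            mutant = "".join(mut)
            aa = code.translate(mutant)
            outcomes.append((mutant, aa, _classify(source_aa, aa)))
    outcomes.sort()
    counts = {"silent": 0, "missense": 0, "nonsense": 0}
    for _, _, cls in outcomes:
        counts[cls] += 1
    expected = comb(3, distance) * 3**distance
    assert len(outcomes) == expected
    return MutantProfile(codon, distance, tuple(outcomes), counts)


@dataclass(frozen=True)
class Reachability:
    """Distinct non-silent amino acids reachable at a fixed mutation distance."""

    source: str
    distance: int
    amino_acids: frozenset[str]
    n_stop: int
    n_silent: int


def amino_reachability(
    codon: str, distance: int, code: GeneticCode = STANDARD_CODE
) -> Reachability:
    """Distinct amino acids (excluding the source's own and stops) reachable
    by exactly ``distance`` simultaneous point mutations."""
    prof = enumerate_point_mutants(codon, distance, code)
    source_aa = code.translate(prof.source)
    aas = frozenset(aa for _, aa, cls in prof.outcomes if cls == "missense" and aa != source_aa)
    return Reachability(prof.source, distance, aas, prof.counts["nonsense"], prof.counts["silent"])


def _mutation_weight(old: str, new: str, kappa: float) -> float:
    # kappa = transition/transversion ratio; kappa=1 makes all targets equiprobable
    return kappa / (kappa + 2) if (old, new) in TRANSITIONS else 1 / (kappa + 2)


def stop_fraction(
    codon: str,
    distance: int,
    kappa: float | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Probability that a random ``distance``-fold mutant of ``codon`` is a stop.

    With ``kappa`` unset all outcomes are equiprobable (the combinatorial
    reading: nonsense count over the outcome count).  With ``kappa`` set, each
    mutated position draws its target base with transition weight ``kappa``
    against unit transversion weights, positions chosen uniformly.
    """
    prof = enumerate_point_mutants(codon, distance, code)
    if kappa is None:
        return prof.counts["nonsense"] / prof.n_outcomes
    total = 0.0
    for mutant, _, cls in prof.outcomes:
        if cls != "nonsense":
            continue
        w = 1.0
        for old, new in zip(prof.source, mutant):
            if old != new:
                w *= _mutation_weight(old, new, kappa)
        total += w / comb(3, distance)
    return total


def rotations(unit: str) -> list[str]:
    """The three frame codons of a trinucleotide unit, offset 0, 1, 2."""
    unit = _check_codon(unit)
    return [unit[f:] + unit[:f] for f in range(3)]


@dataclass(frozen=True)
class FrameStopDistance:
    """Minimum simultaneous point mutations turning a frame's codon into a stop."""

    offset: int
    codon: str
    label: str
    min_mutations: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def frame_label(codon: str, offset: int, code: GeneticCode = STANDARD_CODE) -> str:
    """``polyQ``-style label for a repeat frame codon; ``frameN`` if it is a stop."""
    aa = code.translate(codon)
    return f"frame{offset}" if aa == STOP else f"poly{aa}"


def min_mutations_to_stop_per_frame(
    unit: str, code: GeneticCode = STANDARD_CODE
) -> dict[int, FrameStopDistance]:
    """Exact Hamming distance from each frame codon of ``unit`` to the nearest stop.

    For unit CAG this is {polyQ: 1, polyS: 2, polyA: 2}: only the glutamine
    frame can gain a stop from a single substitution (CAG -> TAG).
    """
    stops = code.stop_codons
    out = {}
    for offset, codon in enumerate(rotations(unit)):
        d = min(_hamming(codon, s) for s in stops)
        out[offset] = FrameStopDistance(offset, codon, frame_label(codon, offset, code), d)
    return out
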