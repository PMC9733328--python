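#!/usr/bin/env python
"""Mutation-space combinatorics of the CAG repeat's three reading frames.

Enumerates, exactly, what single and double point mutations can do to the
codons CAG (polyQ), AGC (polyS) and GCA (polyA): which amino acids become
reachable, how often a stop codon arises, and how many simultaneous hits each
frame needs before a stop is even possible.  Writes per-codon tables to
results/ and prints the headline numbers.
"""

import sys
from pathlib import Path

from polyframe.codon_space import (
    amino_reachability,
    enumerate_point_mutants,
    min_mutations_to_stop_per_frame,
    stop_fraction,
)
from polyframe.seqio import write_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for codon in ("CAG", "AGC", "GCA"):
        for distance in (1, 2):
            prof = enumerate_point_mutants(codon, distance)
            reach = amino_reachability(codon, distance)
            rows.append(
                {
                    "codon": codon,
                    "distance": distance,
                    "n_outcomes": prof.n_outcomes,
                    "n_silent": prof.counts["silent"],
                    "n_missense": prof.counts["missense"],
                    "n_nonsense": prof.counts["nonsense"],
                    "stop_fraction": stop_fraction(codon, distance),
                    "reachable_amino_acids": "".join(sorted(reach.amino_acids)),
                }
            )
    write_table(rows, RESULTS / "codon_mutation_space.tsv",
                columns=list(rows[0]))

    minima = min_mutations_to_stop_per_frame("CAG")
    write_table(
        [
            {"frame": d.label, "codon": d.codon, "min_mutations_to_stop": d.min_mutations}
            for d in minima.values()
        ],
        RESULTS / "frame_stop_distances.tsv",
        columns=["frame", "codon", "min_mutations_to_stop"],
    )

    q1 = stop_fraction("CAG", 1)
    q2 = stop_fraction("CAG", 2)
    s1 = amino_reachability("AGC", 1)
    print("CAG repeat frame mutation space")
    print(f"  polyQ codon CAG: {q1:.3f} of single mutants are stops "
          f"(the C->T first-position hit -> TAG)")
    print(f"  two simultaneous hits on CAG: stop chance {q2:.4f} = 1/27 "
          f"({100 * q2:.1f}%)")
    print(f"  polyS codon AGC single mutants: {len(s1.amino_acids)} distinct "
          f"amino acids {{{', '.join(sorted(s1.amino_acids))}}}, "
          f"{s1.n_stop} stops, {s1.n_silent} silent")
    print("  minimum hits to reach a stop, per frame:",
          {d.label: d.min_mutations for d in minima.values()})
    print(f"wrote {RESULTS / 'codon_mutation_space.tsv'}")
    print(f"wrote {RESULTS / 'frame_stop_distances.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
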