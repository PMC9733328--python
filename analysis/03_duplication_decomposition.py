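#!/usr/bin/env python
"""Internal-duplication structure of repeat-derived coding sequences.

Two experiments: (i) recovery benchmark — 100 random backgrounds each carrying
one planted exact 60-nt duplication, scored by breakpoint error; (ii) a
repeat-context example — an eroded serine-frame CDS with a planted codon-
aligned duplication, decomposed into duplication tiles with pure-repeat
seeding masked.
"""

import sys
from pathlib import Path

from polyframe.duplication_decomposition import self_alignment_blocks, tile_decomposition
from polyframe.seqio import write_table
from polyframe.synthetic_data import gen_planted_duplication, gen_repeat_cds

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    rows, recovered = [], 0
    for seed in range(100):
        p = gen_planted_duplication(400, 60, seed=seed)
        best = None
        for b in self_alignment_blocks(p.seq, min_len=24, min_identity=0.9):
            err = max(abs(b.a_start - p.a_start), abs(b.a_end - p.a_end),
                      abs(b.b_start - p.b_start), abs(b.b_end - p.b_end))
            best = err if best is None else min(best, err)
        rows.append({"seed": seed, "breakpoint_error": best})
        if best is not None and best <= 3:
            recovered += 1
    write_table(rows, RESULTS / "duplication_recovery.tsv",
                columns=["seed", "breakpoint_error"])
    print(f"planted-duplication recovery: {recovered}/100 within 3 nt "
          f"(exact 60-nt copies in 400-nt random background)")

    cds = gen_repeat_cds(60, 0.2, "polyS", [(60, 60)], seed=5)
    blocks = self_alignment_blocks(cds.cds, min_len=24, min_identity=0.9,
                                   mask_unit="CAG")
    dec = tile_decomposition(cds.cds, blocks)
    covered = sum(t.end - t.start for t in dec.tiles)
    print(f"repeat-context CDS ({len(cds.cds)} nt): {len(blocks)} blocks, "
          f"{len(dec.tiles)} tiles covering {covered} nt, "
          f"{sum(e - s for s, e in dec.unexplained)} nt unexplained")
    write_table(
        [
            {"a_start": b.a_start, "a_end": b.a_end, "b_start": b.b_start,
             "b_end": b.b_end, "identity": b.identity}
            for b in blocks
        ],
        RESULTS / "repeat_cds_blocks.tsv",
        columns=["a_start", "a_end", "b_start", "b_end", "identity"],
    )
    print(f"wrote {RESULTS / 'duplication_recovery.tsv'}")
    print(f"wrote {RESULTS / 'repeat_cds_blocks.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
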