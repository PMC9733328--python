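"""Seeded generators for every input class the pipeline consumes.

Real inputs for these analyses are genome assemblies, oocyte transcript
models and repeat-family alignments; none of that is needed to exercise the
methods.  Each generator here emits a small, fully annotated stand-in with
its ground truth attached:

* ``gen_ltr_family``   — copies of an element diverged from a consensus at a
  known per-position rate, with a known fraction of copies carrying start
  codons at two consensus windows (the tandem-AUG census scenario);
* ``gen_repeat_cds``   — a framed trinucleotide-repeat CDS with controlled
  point erosion and planted segmental duplications;
* ``gen_transcript_locus`` — a toy genome plus exon model whose spliced
  transcript and ORF are known by construction;
* ``gen_planted_duplication`` — a random background sequence carrying one
  exact internal duplication with recorded breakpoints.

Every generator is a pure function of its parameters and seed: the same call
regenerates byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_space import STANDARD_CODE, STOP
from .ltr_profile import FamilyAlignment
from .seqio import DnaSeq, ExonModel, write_alignment, write_bed, write_fasta, write_table

_BASES = np.frombuffer(b"ACGT", np.uint8)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    alts = [b for b in "ACGT" if b != base]
    return alts[rng.integers(3)]


# ---------------------------------------------------------------------------
# LTR family


@dataclass(frozen=True)
class MotifPlan:
    """Carrier-class fractions for two motif windows on the consensus.

    Classes are exclusive: ``f_a_only`` carry only the first motif,
    ``f_b_only`` only the second, ``f_both`` both; the remainder carry
    neither.  Windows default to two adjacent start codons (a tandem ATGATG).
    """

    window_a_start: int
    window_b_start: int
    motif: str = "ATG"
    f_a_only: float = 0.14
    f_b_only: float = 0.29
    f_both: float = 0.15

    def __post_init__(self) -> None:
        if self.f_a_only + self.f_b_only + self.f_both > 1.0 + 1e-12:
            raise ValueError("carrier fractions must sum to at most 1")


@dataclass
class LtrFamilyBundle:
    """Generated family alignment plus its planted truth."""

    alignment: FamilyAlignment
    rate_profile: np.ndarray
    copy_classes: pd.DataFrame  # copy_id, carrier class
    plan: MotifPlan | None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, outdir / "family.aln.fasta")
        write_table(
            [
                {"position": int(j), "rate": float(r)}
                for j, r in enumerate(self.rate_profile)
            ],
            outdir / "truth_rates.tsv",
        )
        self.copy_classes.to_csv(outdir / "truth_classes.tsv", sep="\t", index=False)


def gen_ltr_family(
    consensus_len: int,
    n_copies: int,
    rate_profile: float | np.ndarray,
    indel_rate: float = 0.0,
    motif_plan: MotifPlan | None = None,
    seed: int = 0,
    exact_fractions: bool = True,
) -> LtrFamilyBundle:
    """Diverge ``n_copies`` rows from a random consensus at known rates.

    Substitutions are drawn per position per copy with probability
    ``rate_profile[j]``; deletions (gap characters) with ``indel_rate``.  When
    a ``motif_plan`` is given, carrier classes are assigned to copies —
    deterministically in blocks under ``exact_fractions`` (first floor(f*n)
    copies per class, so a census over the family recovers the planted
    fractions exactly), multinomially otherwise — and the two motif windows
    are forced gap-free and set to carry or not carry the motif accordingly.
    Planted rates are therefore only guaranteed outside the motif windows.
    """
    rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(rate_profile, dtype=float), (consensus_len,)).copy()
    if rates.shape[0] != consensus_len:
        raise ValueError("rate_profile length must equal consensus_len")
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("rates must be probabilities")

    consensus = list(_random_dna(rng, consensus_len))
    windows: list[tuple[int, str]] = []
    if motif_plan is not None:
        m = motif_plan.motif.upper()
        for start in (motif_plan.window_a_start, motif_plan.window_b_start):
            if start < 0 or start + len(m) > consensus_len:
                raise ValueError(f"motif window at {start} outside consensus")
            consensus[start : start + len(m)] = list(m)
            windows.append((start, m))
    consensus = "".join(consensus)

    classes = _assign_classes(n_copies, motif_plan, exact_fractions, rng)
    copies = []
    for c in range(n_copies):
        row = list(consensus)
        sub = rng.random(consensus_len) < rates
        for j in np.flatnonzero(sub):
            row[j] = _mutate_base(rng, consensus[j])
        if indel_rate > 0:
            for j in np.flatnonzero(rng.random(consensus_len) < indel_rate):
                row[j] = "-"
        if motif_plan is not None:
            _apply_class(row, classes[c], windows, consensus, rng)
        copies.append("".join(row))

    ids = [f"copy{c:03d}" for c in range(n_copies)]
    aln = FamilyAlignment("consensus", consensus, tuple(ids), tuple(copies))
    truth = pd.DataFrame({"copy_id": ids, "carrier_class": classes})
    return LtrFamilyBundle(aln, rates, truth, motif_plan)


def _assign_classes(n, plan, exact, rng) -> list[str]:
    if plan is None:
        return ["unplanned"] * n
    if exact:
        # epsilon guards the floor against float artifacts (0.29 * 100 -> 28.999...)
        na = int(plan.f_a_only * n + 1e-9)
        nb = int(plan.f_b_only * n + 1e-9)
        nc = int(plan.f_both * n + 1e-9)
        classes = ["a_only"] * na + ["b_only"] * nb + ["both"] * nc
        classes += ["neither"] * (n - len(classes))
        return classes
    draws = rng.choice(
        ["a_only", "b_only", "both", "neither"],
        size=n,
        p=[plan.f_a_only, plan.f_b_only, plan.f_both,
           1 - plan.f_a_only - plan.f_b_only - plan.f_both],
    )
    return list(draws)


def _apply_class(row, cls, windows, consensus, rng) -> None:
    (a_start, motif), (b_start, _) = windows
    carries = {"a_only": (True, False), "b_only": (False, True),
               "both": (True, True), "neither": (False, False)}[cls]
    for (start, _), carry in zip(windows, carries):
        w = slice(start, start + len(motif))
        if carry:
            row[w] = list(motif)
        else:
            # gap-free non-carrier window: keep drawn bases, break motif if formed
            for j in range(start, start + len(motif)):
                if row[j] == "-":
                    row[j] = consensus[j]
            if "".join(row[w]) == motif:
                row[start] = _mutate_base(rng, motif[0])


# ---------------------------------------------------------------------------
# Repeat-expansion CDS

_FRAME_UNIT = {"polyQ": "CAG", "polyS": "AGC", "polyA": "GCA"}


@dataclass
class RepeatCdsBundle:
    """A framed repeat CDS with its erosion and duplication truth."""

    cds: str
    frame: str
    n_units: int
    erosions: tuple[tuple[int, int, str], ...]  # (codon index in body, pos, new base)
    duplications: tuple[dict, ...]  # src_start/src_end/insert_pos in final CDS coords

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([DnaSeq("repeat_cds", self.cds)], outdir / "cds.fasta")
        write_table(list(self.duplications), outdir / "truth_duplications.tsv",
                    columns=["src_start", "src_end", "insert_pos", "length"])
        write_table(
            [{"codon": c, "pos": p, "base": b} for c, p, b in self.erosions],
            outdir / "truth_erosions.tsv", columns=["codon", "pos", "base"],
        )


def gen_repeat_cds(
    n_units: int,
    erosion_rate: float,
    frame: str = "polyS",
    planted_dups: list[tuple[int, int]] | None = None,
    seed: int = 0,
    max_attempts: int = 100,
) -> RepeatCdsBundle:
    """ATG + eroded framed repeat body (+ planted duplications) + stop.

    Erosion mutates one base of a unit with probability ``erosion_rate`` per
    unit, resampling (up to ``max_attempts``) any mutation that would create a
    stop codon in the chosen frame, so the emitted CDS is guaranteed open.
    ``planted_dups`` are ``(src_start, length)`` pairs in body coordinates,
    codon-aligned so duplication preserves the frame, applied sequentially
    (later coordinates address the already-expanded body).
    """
    if frame not in _FRAME_UNIT:
        raise ValueError(f"frame must be one of {sorted(_FRAME_UNIT)}")
    if not 0 <= erosion_rate < 1:
        raise ValueError("erosion_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    unit = _FRAME_UNIT[frame]
    stops = STANDARD_CODE.stop_codons
    codons = [unit] * n_units
    erosions = []
    for i in range(n_units):
        if rng.random() >= erosion_rate:
            continue
        for attempt in range(max_attempts):
            pos = int(rng.integers(3))
            new = _mutate_base(rng, unit[pos])
            cand = unit[:pos] + new + unit[pos + 1 :]
            if cand not in stops:
                codons[i] = cand
                erosions.append((i, pos, new))
                break
        else:
            raise RuntimeError("could not erode unit without creating a stop")
    body = "".join(codons)
    dup_truth = []
    for src, length in planted_dups or []:
        if src % 3 or length % 3:
            raise ValueError("planted duplications must be codon-aligned")
        if src + length > len(body):
            raise ValueError("planted duplication outside body")
        segment = body[src : src + length]
        body = body[: src + length] + segment + body[src + length :]
        dup_truth.append(
            {"src_start": src + 3, "src_end": src + length + 3,
             "insert_pos": src + length + 3, "length": length}  # +3: leading ATG
        )
    cds = "ATG" + body + "TGA"
    from .repeat_frames import translate_cds  # local import avoids cycle at module load

    assert STOP not in translate_cds(cds)[:-1], "generator emitted an internal stop"
    return RepeatCdsBundle(cds, frame, n_units, tuple(erosions), tuple(dup_truth))


# ---------------------------------------------------------------------------
# Planted duplication in non-repeat background


@dataclass
class PlantedDuplicationBundle:
    """Random background carrying one exact internal duplication."""

    seq: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int


def gen_planted_duplication(
    background_len: int, dup_len: int, seed: int = 0
) -> PlantedDuplicationBundle:
    """Insert an exact copy of one random segment elsewhere in a random
    background; truth records both copies' final coordinates."""
    if dup_len > background_len:
        raise ValueError("duplication longer than background")
    rng = np.random.default_rng(seed)
    bg = _random_dna(rng, background_len)
    src = int(rng.integers(0, background_len - dup_len + 1))
    insert = int(rng.integers(src + dup_len, background_len + 1))
    seq = bg[:insert] + bg[src : src + dup_len] + bg[insert:]
    return PlantedDuplicationBundle(seq, src, src + dup_len, insert, insert + dup_len)


# ---------------------------------------------------------------------------
# Transcript locus


@dataclass
class TranscriptLocusBundle:
    """Toy genome + exon model with known transcript and ORF."""

    genome: DnaSeq
    exon_model: ExonModel
    transcript: str
    orf_start: int | None
    orf_end: int | None
    canonical_splice: bool

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], outdir / "genome.fasta")
        write_bed([self.exon_model], outdir / "exons.bed")
        write_fasta([DnaSeq("truth_transcript", self.transcript)],
                    outdir / "truth_transcript.fasta")


def gen_transcript_locus(
    n_exons: int,
    intron_lens: list[int] | None = None,
    canonical_splice: bool = True,
    seed: int = 0,
    exon_lens: list[int] | None = None,
    plant_tandem_start: bool = True,
    strand: str = "+",
) -> TranscriptLocusBundle:
    """A spliced toy gene whose transcript and ORF are known by construction.

    The first exon optionally opens with a tandem ATGATG (so the first-AUG
    ORF starts at transcript offset 0 and an inner start sits at offset 3).
    Introns get GT..AG termini when ``canonical_splice``, GC..AG otherwise.
    """
    if n_exons < 1:
        raise ValueError("need at least one exon")
    rng = np.random.default_rng(seed)
    intron_lens = intron_lens if intron_lens is not None else [50] * (n_exons - 1)
    if len(intron_lens) != n_exons - 1:
        raise ValueError("need n_exons - 1 intron lengths")
    if any(l < 4 for l in intron_lens):
        raise ValueError("introns must be at least 4 nt for terminal dinucleotides")
    exon_lens = exon_lens if exon_lens is not None else [
        int(rng.integers(60, 120)) for _ in range(n_exons)
    ]
    exons = [_random_dna(rng, l) for l in exon_lens]
    if plant_tandem_start:
        exons[0] = "ATGATG" + exons[0][6:]
    introns = []
    for l in intron_lens:
        mid = _random_dna(rng, l - 4)
        introns.append(("GT" if canonical_splice else "GC") + mid + "AG")
    parts, intervals, pos = [], [], 0
    for k, ex in enumerate(exons):
        parts.append(ex)
        intervals.append((pos, pos + len(ex)))
        pos += len(ex)
        if k < len(introns):
            parts.append(introns[k])
            pos += len(introns[k])
    plus_genome = "".join(parts)
    transcript = "".join(exons)
    if strand == "-":
        from .seqio import revcomp

        n = len(plus_genome)
        genome = DnaSeq("locus", revcomp(plus_genome))
        intervals = sorted((n - e, n - s) for s, e in intervals)
    else:
        genome = DnaSeq("locus", plus_genome)
    model = ExonModel("locus", tuple(intervals), strand, "toy_gene")
    orf_start = transcript.find("ATG")
    orf_end = None
    if orf_start != -1:
        p = orf_start
        while p + 3 <= len(transcript):
            p += 3
            if transcript[p - 3 : p] in STANDARD_CODE.stop_codons:
                break
        orf_end = p
    return TranscriptLocusBundle(
        genome, model, transcript,
        None if orf_start == -1 else orf_start, orf_end, canonical_splice,
    )
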