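"""Spliced transcript assembly and ORF inference from a designated start.

Given a genome sequence and an exon model, this module splices the transcript
(reverse-complementing minus-strand models so downstream analyses always see
the sense strand), checks each intron for the canonical GT..AG dinucleotides,
and infers the coding sequence from either the first AUG or a caller-chosen
offset.  ORFs that run off the end of the transcript without a stop are kept
and flagged rather than discarded — truncated assemblies (N blocks, partial
contigs) are a fact of life in the genomes this models.

The start-policy distinction matters because the locus this reconstructs
begins with a tandem AUGAUG: ``first_aug`` probes the outer start,
``at_offset(3)`` the inner one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .codon_space import GeneticCode, STANDARD_CODE, STOP
from .repeat_frames import find_repeat_tracts, repeat_frame_report, RepeatFrameReport
from .seqio import DnaSeq, ExonModel, revcomp

log = logging.getLogger(__name__)

FIRST_AUG = "first_aug"


def at_offset(k: int) -> tuple[str, int]:
    """Start policy fixing the start codon at transcript offset ``k``."""
    return ("at_offset", k)


@dataclass(frozen=True)
class Transcript:
    """A spliced sense-strand transcript with its genomic exon map.

    ``exon_map`` rows are ``(tx_start, tx_end, g_start, g_end)`` with
    transcript intervals contiguous in order; ``splice_flags`` marks each
    intron (5'->3' on the transcript) as canonical GT..AG or not.
    """

    id: str
    residues: str
    exon_map: tuple[tuple[int, int, int, int], ...]
    splice_flags: tuple[bool, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        assert len(self.residues) == sum(te - ts for ts, te, _, _ in self.exon_map)

    def __len__(self) -> int:
        return len(self.residues)


def splice_transcript(genome: DnaSeq, model: ExonModel) -> Transcript:
    """Extract and join exons; flag non-canonical introns without rejecting them."""
    for s, e in model.exons:
        if e > len(genome):
            raise ValueError(
                f"exon ({s}, {e}) outside sequence {genome.id!r} of length {len(genome)}"
            )
    g = genome.residues
    introns = [g[e1:s2] for (_, e1), (s2, _) in zip(model.exons, model.exons[1:])]
    if model.strand == "-":
        introns = [revcomp(i) for i in reversed(introns)]
        exon_order = list(reversed(model.exons))
        pieces = [revcomp(g[s:e]) for s, e in exon_order]
    else:
        exon_order = list(model.exons)
        pieces = [g[s:e] for s, e in exon_order]
    flags = []
    for k, intron in enumerate(introns):
        ok = len(intron) >= 4 and intron.startswith("GT") and intron.endswith("AG")
        if not ok:
            log.warning(
                "non-canonical intron %d (%s..%s) in model %s",
                k, intron[:2], intron[-2:], model.name or model.seq_id,
            )
        flags.append(ok)
    exon_map = []
    t = 0
    for piece, (s, e) in zip(pieces, exon_order):
        exon_map.append((t, t + len(piece), s, e))
        t += len(piece)
    return Transcript(
        model.name or genome.id, "".join(pieces), tuple(exon_map), tuple(flags), model.strand
    )


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame from a designated AUG.

    ``stop`` is the transcript offset just past the stop codon, or the end of
    the translated span when no in-frame stop exists (``terminated`` False).
    ``n_codons`` excludes the stop codon; a trailing partial codon is dropped
    and noted.
    """

    start: int
    stop: int
    n_codons: int
    protein: str
    terminated: bool
    partial_codon_dropped: int = 0

    def __post_init__(self) -> None:
        assert len(self.protein) == self.n_codons
        if self.terminated:
            assert (self.stop - self.start) % 3 == 0


def _residues(transcript: Transcript | DnaSeq | str) -> str:
    return transcript if isinstance(transcript, str) else transcript.residues


def find_orf(
    transcript: Transcript | DnaSeq | str,
    start_policy=FIRST_AUG,
    code: GeneticCode = STANDARD_CODE,
) -> OrfRecord | None:
    """Translate from a start codon to the first in-frame stop or transcript end.

    With ``first_aug`` the leftmost ATG is used; ``at_offset(k)`` requires an
    ATG at ``k``.  No ATG under ``first_aug`` returns ``None`` (an explicit
    "no ORF", not an error).
    """
    seq = _residues(transcript)
    if start_policy == FIRST_AUG:
        start = seq.find("ATG")
        if start == -1:
            return None
    else:
        tag, k = start_policy
        if tag != "at_offset":
            raise ValueError(f"unknown start policy {start_policy!r}")
        if seq[k : k + 3] != "ATG":
            raise ValueError(f"no ATG at transcript offset {k}")
        start = k
    protein = []
    pos = start
    terminated = False
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        aa = "X" if "N" in codon else code.translate(codon)
        pos += 3
        if aa == STOP:
            terminated = True
            break
        protein.append(aa)
    dropped = (len(seq) - start) % 3 if not terminated else 0
    return OrfRecord(start, pos, len(protein), "".join(protein), terminated, dropped)


@dataclass(frozen=True)
class CdsReport:
    """ORF joined with repeat-frame structure of its CDS and the repeat content
    left untranslated downstream of the stop codon."""

    orf: OrfRecord | None
    frames: RepeatFrameReport | None
    cds_n_codons: int
    downstream_repeat_units: int


def cds_report(
    transcript: Transcript | DnaSeq | str,
    start_policy=FIRST_AUG,
    unit: str = "CAG",
    code: GeneticCode = STANDARD_CODE,
) -> CdsReport:
    """Infer the CDS and report its repeat-frame anatomy.

    ``downstream_repeat_units`` counts repeat units in tracts 3' of the stop
    codon — the "CDS terminates before the repeat" signature of a locus whose
    reading frame died early while the repeat lived on.
    """
    seq = _residues(transcript)
    orf = find_orf(seq, start_policy, code)
    if orf is None:
        return CdsReport(None, None, 0, 0)
    # frames are reported over the CDS body (start codon through the last sense
    # codon); the terminal stop would otherwise count against its own register
    cds_body = seq[orf.start : orf.start + 3 * orf.n_codons]
    frames = repeat_frame_report(cds_body, unit, code=code) if cds_body else None
    downstream = seq[orf.stop :]
    tracts = find_repeat_tracts(downstream, unit, min_units=2, max_divergence=0.1)
    n_units = sum(t.n_units for t in tracts)
    # CDS codon count includes the start codon, excludes the stop
    return CdsReport(orf, frames, orf.n_codons, n_units)
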