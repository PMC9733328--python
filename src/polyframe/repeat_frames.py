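"""Eroded trinucleotide tract detection and repeat reading-frame analysis.

A coding sequence born from a (CAG)n expansion is rarely a pure repeat: point
mutations erode it while (usually) preserving the reading frame.  This module
finds such eroded tracts by greedy seed-and-extend, labels each codon of a CDS
by the repeat frame it still resembles (polyQ / polyS / polyA for a CAG unit),
segments the label track into runs and frame switches, and summarises
amino-acid composition and per-register stop-codon counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .codon_space import GeneticCode, STANDARD_CODE, STOP, frame_label, rotations

DNA = set("ACGTN")


def _check_dna(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - DNA
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


def canonical_unit(unit: str) -> str:
    """Lexicographically smallest rotation of a repeat unit (CAG -> AGC)."""
    return min(rotations(unit))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class RepeatTract:
    """A located, possibly eroded run of one trinucleotide unit.

    ``unit`` is the canonical (lexicographic-minimum) rotation; ``phase`` is
    the rotation offset of the tract's first full unit relative to it, so the
    observed repeat word is ``unit[phase:] + unit[:phase]``.  ``purity`` is
    the fraction of unit-length windows matching the phased unit exactly.
    """

    seq_id: str
    start: int
    end: int
    unit: str
    phase: int
    n_units: int
    purity: float

    def __post_init__(self) -> None:
        assert self.end - self.start == 3 * self.n_units
        assert 0.0 <= self.purity <= 1.0 and self.phase in (0, 1, 2)


def find_repeat_tracts(
    seq: str,
    unit: str = "CAG",
    min_units: int = 3,
    max_divergence: float = 0.0,
    seq_id: str = "",
) -> list[RepeatTract]:
    """Greedy seed-and-extend detection of eroded tandem repeat tracts.

    Exact two-unit occurrences of any rotation of ``unit`` seed candidate
    tracts, which are extended one unit-window at a time in both directions
    while the running per-base mismatch fraction of the whole tract stays at
    or below ``max_divergence``.  Terminal windows with two or more mismatches
    are trimmed back so tracts end on repeat-like units.  Overlapping
    candidates are resolved longest-first, then leftmost.
    """
    seq = _check_dna(seq)
    if len(unit) != 3:
        raise ValueError("unit must be 3 nt")
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    if not 0 <= max_divergence < 0.5:
        raise ValueError("max_divergence must be in [0, 0.5)")
    canon = canonical_unit(unit)
    rots = rotations(canon)

    candidates: dict[tuple[int, int], RepeatTract] = {}
    seen_spans: set[tuple[int, int, int]] = set()
    for phase, rot in enumerate(rots):
        seed = rot * 2
        p = seq.find(seed)
        while p != -1:
            tract = _extend(seq, p, rot, max_divergence)
            if tract is not None:
                start, end = tract
                key = (start, end, phase)
                if key not in seen_spans:
                    seen_spans.add(key)
                    n_units = (end - start) // 3
                    pure = sum(
                        seq[i : i + 3] == rot for i in range(start, end, 3)
                    )
                    candidates[(start, end)] = RepeatTract(
                        seq_id, start, end, canon, phase, n_units, pure / n_units
                    )
            p = seq.find(seed, p + 1)

    # longest-tract-wins, then leftmost; keep mutually non-overlapping tracts
    ordered = sorted(candidates.values(), key=lambda t: (-(t.end - t.start), t.start))
    accepted: list[RepeatTract] = []
    for t in ordered:
        if t.n_units < min_units:
            continue
        if all(t.end <= a.start or t.start >= a.end for a in accepted):
            accepted.append(t)
    accepted.sort(key=lambda t: t.start)
    return accepted


def _extend(seq: str, seed_pos: int, rot: str, max_div: float) -> tuple[int, int] | None:
    """Extend a 2-unit exact seed unit-by-unit under a cumulative mismatch budget."""
    start, end = seed_pos, seed_pos + 6
    mism = 0
    length = 6
    while end + 3 <= len(seq):
        w = _hamming(seq[end : end + 3], rot)
        if (mism + w) / (length + 3) > max_div:
            break
        mism += w
        end += 3
        length += 3
    while start - 3 >= 0:
        w = _hamming(seq[start - 3 : start], rot)
        if (mism + w) / (length + 3) > max_div:
            break
        mism += w
        start -= 3
        length += 3
    # trim terminal windows that look nothing like the unit
    while end - start > 6 and _hamming(seq[end - 3 : end], rot) >= 2:
        end -= 3
    while end - start > 6 and _hamming(seq[start : start + 3], rot) >= 2:
        start += 3
    return (start, end) if end - start >= 6 else None


@dataclass(frozen=True)
class FrameSegmentation:
    """Per-codon repeat-frame labels with run-length structure.

    ``n_switches`` counts adjacent run pairs whose labels are both repeat
    frames (polyX style) and differ — the frameshift events of a repeat-derived
    CDS; runs separated by ``other``/``undetermined`` codons do not count.
    """

    codon_labels: tuple[str, ...]
    runs: tuple[tuple[int, int, str], ...]
    n_switches: int


def classify_codon_frames(
    cds: str, unit: str = "CAG", code: GeneticCode = STANDARD_CODE
) -> FrameSegmentation:
    """Label every codon of ``cds`` by its nearest repeat frame.

    A codon takes a frame label when its Hamming distance to exactly one
    rotation of ``unit`` is at most 1 (one point mutation of erosion); ties
    and larger distances give ``other``; codons containing N give
    ``undetermined``.  A trailing partial codon is dropped with a warning.
    """
    cds = _check_dna(cds)
    if len(cds) % 3:
        warnings.warn(f"dropping trailing partial codon of {len(cds) % 3} nt")
        cds = cds[: len(cds) - len(cds) % 3]
    canon = canonical_unit(unit) if len(unit) == 3 else unit
    labels_by_rot = [frame_label(r, f, code) for f, r in enumerate(rotations(canon))]
    rots = rotations(canon)

    labels = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            labels.append("undetermined")
            continue
        dists = [_hamming(codon, r) for r in rots]
        m = min(dists)
        if m <= 1 and dists.count(m) == 1:
            labels.append(labels_by_rot[dists.index(m)])
        else:
            labels.append("other")

    runs = []
    for i, lab in enumerate(labels):
        if runs and runs[-1][2] == lab:
            runs[-1] = (runs[-1][0], i + 1, lab)
        else:
            runs.append((i, i + 1, lab))
    poly = [r for r in runs]
    n_switches = sum(
        1
        for a, b in zip(poly, poly[1:])
        if a[2].startswith("poly") and b[2].startswith("poly") and a[2] != b[2]
    )
    return FrameSegmentation(tuple(labels), tuple(tuple(r) for r in runs), n_switches)


@dataclass(frozen=True)
class AaComposition:
    """Residue fractions of a protein; stop symbols are excluded from the total."""

    fractions: dict[str, float]
    serine: float


def aa_composition(protein: str) -> AaComposition:
    """Amino-acid composition with the serine fraction (the polyS signature)
    reported alongside the full table."""
    residues = [a for a in protein.upper() if a != STOP]
    if not residues:
        raise ValueError("empty protein (or stops only)")
    counts = Counter(residues)
    n = len(residues)
    fr = {aa: c / n for aa, c in sorted(counts.items())}
    return AaComposition(fr, fr.get("S", 0.0))


def translate_cds(cds: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Codon-by-codon translation; N-containing codons become ``X``, stops ``*``.

    The trailing partial codon, if any, is dropped.
    """
    cds = _check_dna(cds)
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        out.append("X" if "N" in codon else code.translate(codon))
    return "".join(out)


def register_frame_labels(
    seq: str, unit: str = "CAG", code: GeneticCode = STANDARD_CODE
) -> dict[int, str]:
    """Name each of the three reading registers of ``seq`` by the majority
    repeat-frame label of its codons; registers with no repeat-like codons
    fall back to ``frameN``."""
    seq = _check_dna(seq)
    labels = {}
    for r in range(3):
        seg = classify_codon_frames(_pad(seq[r:]), unit, code) if len(seq) - r >= 3 else None
        poly = [l for l in (seg.codon_labels if seg else ()) if l.startswith("poly")]
        labels[r] = Counter(poly).most_common(1)[0][0] if poly else f"frame{r}"
    return labels


def _pad(s: str) -> str:
    return s[: len(s) - len(s) % 3]


@dataclass(frozen=True)
class RepeatFrameReport:
    """Joint tract / frame / composition / per-register stop report for a CDS."""

    tracts: tuple[RepeatTract, ...]
    segmentation: FrameSegmentation
    composition: AaComposition
    frame_labels: dict[int, str]
    stops_per_register: dict[int, int]
    stops_per_frame: dict[str, int] = field(default_factory=dict)


def repeat_frame_report(
    cds: str,
    unit: str = "CAG",
    min_units: int = 3,
    max_divergence: float = 0.1,
    code: GeneticCode = STANDARD_CODE,
) -> RepeatFrameReport:
    """Repeat tracts, frame segmentation, composition and stop counts of a CDS.

    Stops are counted by re-reading the same nucleotides in all three
    registers: a serine-frame CDS typically shows zero stops in its own
    register while the polyQ register of the identical sequence is riddled
    with them.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cds_t = _pad(_check_dna(cds))
    tracts = find_repeat_tracts(cds_t, unit, min_units, max_divergence)
    seg = classify_codon_frames(cds_t, unit, code)
    comp = aa_composition(translate_cds(cds_t, code)) if cds_t else AaComposition({}, 0.0)
    labels = register_frame_labels(cds_t, unit, code)
    stops_reg = {
        r: translate_cds(_pad(cds_t[r:]), code).count(STOP) if len(cds_t) - r >= 3 else 0
        for r in range(3)
    }
    by_label = (
        {labels[r]: stops_reg[r] for r in range(3)}
        if len(set(labels.values())) == 3
        else {}
    )
    return RepeatFrameReport(tuple(tracts), seg, comp, labels, stops_reg, by_label)
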