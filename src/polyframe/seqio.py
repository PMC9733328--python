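"""Strict readers/writers for the plain-text formats the pipeline touches.

FASTA reading is deliberately strict and line-aware: sequences are lifted to
uppercase, RNA ``U`` is mapped to ``T``, and any character outside {A,C,G,T,N}
aborts with a parse error naming the offending line — better than letting an
undefined letter propagate into codon arithmetic.  Exon models use the BED
dialect (0-based half-open intervals); report-facing helpers convert to
1-based closed coordinates and back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ltr_profile import FamilyAlignment

ALPHABET = set("ACGTN")
ALIGN_ALPHABET = ALPHABET | {"-"}


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class DnaSeq:
    """A named DNA sequence over {A,C,G,T,N}, always stored uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


def normalize(residues: str) -> str:
    residues = residues.upper().replace("U", "T")
    bad = set(residues) - ALPHABET
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)}; alphabet is A/C/G/T/N")
    return residues


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def _parse_fasta_rows(path: str | Path, alphabet: set[str]) -> list[tuple[str, str]]:
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                records.append((header, []))
            else:
                if not records:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                seq = line.upper().replace("U", "T")
                bad = set(seq) - alphabet
                if bad:
                    raise FastaParseError(
                        f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                    )
                records[-1][1].append(seq)
    return [(h, "".join(parts)) for h, parts in records]


def read_fasta(path: str | Path) -> list[DnaSeq]:
    """Read plain (ungapped) FASTA; order preserved, case lifted, U -> T."""
    return [DnaSeq(h, s) for h, s in _parse_fasta_rows(path, ALPHABET)]


def write_fasta(seqs: list[DnaSeq], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, consensus_id: str | None = None) -> FamilyAlignment:
    """Read a gapped multi-FASTA alignment; the first record is the consensus
    unless ``consensus_id`` names another row."""
    rows = _parse_fasta_rows(path, ALIGN_ALPHABET)
    if not rows:
        raise FastaParseError(f"{path}: alignment has no records")
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise FastaParseError(f"{path}: unequal alignment row lengths {sorted(lengths)}")
    return FamilyAlignment.from_rows([h for h, _ in rows], [s for _, s in rows], consensus_id)


def write_alignment(aln: FamilyAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, row in [(aln.consensus_id, aln.consensus), *zip(aln.copy_ids, aln.copies)]:
            fh.write(f">{name}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


@dataclass(frozen=True)
class ExonModel:
    """Ordered, non-overlapping exon intervals on a parent sequence (BED convention)."""

    seq_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.exons:
            if e <= s or s < 0:
                raise ValueError(f"invalid exon interval ({s}, {e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be sorted and non-overlapping")


def read_bed(path: str | Path) -> list[ExonModel]:
    """Read BED6-ish exon intervals, grouped into models by the name column."""
    groups: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: fewer than 3 BED columns at line {lineno}")
            name = f[3] if len(f) > 3 else "region"
            strand = f[5] if len(f) > 5 else "+"
            groups.setdefault(name, []).append((f[0], int(f[1]), int(f[2]), strand))
    models = []
    for name, rows in groups.items():
        chroms = {r[0] for r in rows}
        strands = {r[3] for r in rows}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{path}: model {name!r} mixes chromosomes or strands")
        exons = tuple(sorted((s, e) for _, s, e, _ in rows))
        models.append(ExonModel(rows[0][0], exons, rows[0][3], name))
    return models


def write_bed(models: list[ExonModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                fh.write(f"{m.seq_id}\t{s}\t{e}\t{m.name or 'region'}\t0\t{m.strand}\n")


def to_one_based_closed(interval: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open -> 1-based closed (human-readable reports)."""
    s, e = interval
    return s + 1, e


def from_one_based_closed(interval: tuple[int, int]) -> tuple[int, int]:
    s, e = interval
    return s - 1, e


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def write_table(
    records: list[dict],
    path: str | Path,
    format: str = "tsv",
    columns: list[str] | None = None,
) -> None:
    """Emit records as TSV or JSON with deterministic column order and floats
    at 6 significant digits; an empty record list yields a header-only TSV."""
    fmt = format.lower()
    if fmt not in ("tsv", "json"):
        raise ValueError(f"format must be tsv or json, got {format!r}")
    cols = columns if columns is not None else (list(records[0]) if records else [])
    rows = [{c: _round6(r.get(c)) for c in cols} for r in records]
    if fmt == "tsv":
        df = pd.DataFrame(rows, columns=cols)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
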