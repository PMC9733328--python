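"""Per-position divergence and motif census of an element-family alignment.

An LTR retrotransposon subfamily is summarised by a consensus (the inferred
ancestral sequence) plus many genomic copies aligned to it.  The per-position
"nucleotide exchange rate" — the fraction of copies whose base differs from
the consensus at that position — profiles where the family tolerates change,
and motif queries over consensus windows (e.g. the tandem start codons of an
exapted promoter-exon) census how many copies still carry a functional word.

Indels are treated as loss of information, not as mismatch: a copy with a gap
at a column drops out of that column's denominator, and a copy gapped anywhere
inside a motif window drops out of that window's census entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GAP = "-"


@dataclass(frozen=True)
class FamilyAlignment:
    """Gapped alignment of element copies against a designated consensus row."""

    consensus_id: str
    consensus: str
    copy_ids: tuple[str, ...]
    copies: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(len(c) != self.width for c in self.copies):
            raise ValueError("all alignment rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.consensus)

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    @property
    def column_index(self) -> np.ndarray:
        """Alignment column of each consensus coordinate (non-gap consensus positions)."""
        return np.flatnonzero(np.frombuffer(self.consensus.encode(), np.uint8) != ord(GAP))

    @property
    def consensus_length(self) -> int:
        return int(self.column_index.size)

    def _matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.copies).encode(), np.uint8).reshape(
            self.n_copies, self.width
        )

    @classmethod
    def from_rows(
        cls, ids: list[str], rows: list[str], consensus_id: str | None = None
    ) -> "FamilyAlignment":
        if not rows:
            raise ValueError("alignment has no rows")
        if consensus_id is None:
            ci = 0
        else:
            try:
                ci = ids.index(consensus_id)
            except ValueError:
                raise ValueError(f"consensus id {consensus_id!r} not in alignment") from None
        copy_ids = tuple(x for k, x in enumerate(ids) if k != ci)
        copies = tuple(x for k, x in enumerate(rows) if k != ci)
        return cls(ids[ci], rows[ci], copy_ids, copies)


@dataclass(frozen=True)
class ExchangeProfile:
    """Per-consensus-position mismatch rates.

    ``rate[j] = n_mismatch[j] / n_informative[j]``; positions where every copy
    is gapped are flagged undefined (``defined[j]`` False, rate NaN), never
    reported as zero.
    """

    n_informative: np.ndarray
    n_mismatch: np.ndarray
    rate: np.ndarray
    defined: np.ndarray


def column_exchange_rates(aln: FamilyAlignment) -> ExchangeProfile:
    """Mismatch fraction versus the consensus at every consensus position."""
    if aln.n_copies == 0:
        raise ValueError("alignment has no copy rows")
    cols = aln.column_index
    m = aln._matrix()[:, cols]
    cons = np.frombuffer(aln.consensus.encode(), np.uint8)[cols]
    informative = m != ord(GAP)
    mismatch = informative & (m != cons)
    n_inf = informative.sum(axis=0)
    n_mis = mismatch.sum(axis=0)
    defined = n_inf > 0
    rate = np.full(cols.size, np.nan)
    rate[defined] = n_mis[defined] / n_inf[defined]
    return ExchangeProfile(n_inf, n_mis, rate, defined)


@dataclass(frozen=True)
class MotifCensus:
    """Fraction of informative (gap-free-in-window) copies carrying a motif."""

    motif: str
    consensus_start: int
    n_informative: int
    n_carriers: int
    fraction: float
    defined: bool


def _window_cols(aln: FamilyAlignment, start: int, length: int) -> np.ndarray:
    if start < 0 or start + length > aln.consensus_length:
        raise ValueError(
            f"window [{start}, {start + length}) outside consensus of length "
            f"{aln.consensus_length}"
        )
    return aln.column_index[start : start + length]


def _carriers(aln: FamilyAlignment, motif: str, start: int) -> tuple[np.ndarray, np.ndarray]:
    """(informative mask, carrier mask) over copies for one motif window."""
    cols = _window_cols(aln, start, len(motif))
    m = aln._matrix()[:, cols]
    informative = ~(m == ord(GAP)).any(axis=1)
    target = np.frombuffer(motif.upper().encode(), np.uint8)
    carries = informative & (m == target).all(axis=1)
    return informative, carries


def motif_presence(aln: FamilyAlignment, motif: str, consensus_start: int) -> MotifCensus:
    """Fraction of copies whose residues at the consensus-mapped window equal
    ``motif``; gapped-in-window copies are excluded from both numerator and
    denominator."""
    informative, carries = _carriers(aln, motif, consensus_start)
    n_inf = int(informative.sum())
    n_car = int(carries.sum())
    if n_inf == 0:
        return MotifCensus(motif, consensus_start, 0, 0, float("nan"), False)
    return MotifCensus(motif, consensus_start, n_inf, n_car, n_car / n_inf, True)


@dataclass(frozen=True)
class CooccurrenceCensus:
    """Exclusive and marginal carrier fractions for two motif windows.

    Fractions are over the copies informative in *both* windows, so the
    additivity identity ``at_least_one = a_only + b_only + both`` holds
    exactly on every input.
    """

    a_only: float
    b_only: float
    both: float
    at_least_one: float
    marginal_a: float
    marginal_b: float
    n_informative: int


def motif_cooccurrence(
    aln: FamilyAlignment,
    window_a: tuple[str, int],
    window_b: tuple[str, int],
) -> CooccurrenceCensus:
    """Joint census of two motif windows (e.g. the two AUGs of a tandem start)."""
    inf_a, car_a = _carriers(aln, *window_a)
    inf_b, car_b = _carriers(aln, *window_b)
    informative = inf_a & inf_b
    n = int(informative.sum())
    if n == 0:
        nan = float("nan")
        return CooccurrenceCensus(nan, nan, nan, nan, nan, nan, 0)
    a = car_a[informative]
    b = car_b[informative]
    a_only = int((a & ~b).sum()) / n
    b_only = int((~a & b).sum()) / n
    both = int((a & b).sum()) / n
    return CooccurrenceCensus(
        a_only, b_only, both, a_only + b_only + both,
        a_only + both, b_only + both, n,
    )
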