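"""Internal duplication detection and block tiling for a single sequence.

Repeat-derived coding sequences grow not only by unit slippage but by copying
whole internal segments of themselves.  This module finds such direct
duplications by exact k-mer seeding off the main diagonal of the sequence's
self-comparison, ungapped extension under a running-identity budget, and then
tiles the accepted blocks into a non-overlapping decomposition (the
colored-rectangle annotation of a duplication-mosaic CDS).

Pure repeat tracts are everywhere self-similar, so seeding inside them floods
the output with trivial hits; when a ``mask_unit`` is given, perfectly pure
tracts of that unit are masked from seeding, while extension is still free to
run into them (real duplications carry eroded repeat sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

from .repeat_frames import find_repeat_tracts, _check_dna


@dataclass(frozen=True)
class DuplicationBlock:
    """Two near-identical, non-overlapping segments of one sequence.

    Canonical order ``a_start < b_start``; both intervals have the same
    ``length`` (ungapped copy) and never overlap each other.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float

    def __post_init__(self) -> None:
        assert self.a_start < self.b_start
        assert self.a_end - self.a_start == self.b_end - self.b_start
        assert self.a_end <= self.b_start, "block intervals must be disjoint"

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    @property
    def diagonal(self) -> int:
        return self.b_start - self.a_start


def self_alignment_blocks(
    seq: str,
    min_len: int = 24,
    min_identity: float = 0.9,
    mask_unit: str | None = None,
    k: int = 12,
    max_kmer_hits: int = 64,
) -> list[DuplicationBlock]:
    """Detect direct internal duplications by seed-and-extend self-alignment.

    Exact ``k``-mer matches between distinct positions seed ungapped
    extensions that grow in both directions while cumulative identity stays at
    or above ``min_identity`` and the two intervals remain disjoint; blocks
    shorter than ``min_len`` are dropped, and blocks contained in a longer
    block on the same diagonal are deduplicated.  Returned sorted by length
    (descending), then leftmost.
    """
    seq = _check_dna(seq)
    if min_len < 12:
        raise ValueError("min_len must be >= 12")
    if not 0.5 < min_identity <= 1:
        raise ValueError("min_identity must be in (0.5, 1]")
    n = len(seq)
    if n < min_len:
        return []

    masked = [False] * n
    if mask_unit is not None:
        for t in find_repeat_tracts(seq, mask_unit, min_units=4, max_divergence=0.0):
            for i in range(t.start, t.end):
                masked[i] = True

    # a seed is suppressed only when its whole k-mer sits inside pure repeat:
    # seeds anchored at eroded positions are the informative ones and survive
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        if all(masked[i : i + k]) or "N" in seq[i : i + k]:
            continue
        index.setdefault(seq[i : i + k], []).append(i)

    blocks: dict[tuple[int, int, int], DuplicationBlock] = {}
    for positions in index.values():
        if len(positions) < 2 or len(positions) > max_kmer_hits:
            continue
        for x, i in enumerate(positions):
            for j in positions[x + 1 :]:
                if j - i < k:  # overlapping seed copies can never satisfy disjointness
                    continue
                b = _extend_pair(seq, i, j, k, min_identity)
                if b is not None and b.length >= min_len:
                    blocks[(b.a_start, b.a_end, b.b_start)] = b

    # drop blocks contained within a longer block on the same diagonal
    by_diag: dict[int, list[DuplicationBlock]] = {}
    for b in blocks.values():
        by_diag.setdefault(b.diagonal, []).append(b)
    kept: list[DuplicationBlock] = []
    for group in by_diag.values():
        group.sort(key=lambda b: (-b.length, b.a_start))
        chosen: list[DuplicationBlock] = []
        for b in group:
            if not any(c.a_start <= b.a_start and b.a_end <= c.a_end for c in chosen):
                chosen.append(b)
        kept.extend(chosen)
    kept.sort(key=lambda b: (-b.length, b.a_start, b.b_start))
    return kept


def _window_matches(seq: str, a: int, b: int, w: int) -> int:
    return sum(seq[a + t] == seq[b + t] for t in range(w))


def _extend_pair(
    seq: str, i: int, j: int, k: int, min_identity: float
) -> DuplicationBlock | None:
    """Ungapped extension of a seed pair; ends trimmed back to matches."""
    n = len(seq)
    ai, bi = i, j
    ae, be = i + k, j + k
    matches = k
    while be < n and ae < bi:
        m = seq[ae] == seq[be]
        if (matches + m) / (ae - ai + 1) < min_identity:
            break
        matches += m
        ae += 1
        be += 1
    while ai > 0 and bi - 1 >= ae:
        m = seq[ai - 1] == seq[bi - 1]
        if (matches + m) / (ae - ai + 1) < min_identity:
            break
        matches += m
        ai -= 1
        bi -= 1
    # Trim back noisy ends: greedy extension can run past a true breakpoint by
    # absorbing chance matches while cumulative identity stays above threshold.
    # Shrink each end until its terminal window meets min_identity on its own,
    # then strip any remaining terminal mismatches so blocks end on matches.
    w = 8
    while ae - ai > k and _window_matches(seq, ae - w, be - w, w) / w < min_identity:
        ae -= 1
        be -= 1
    while ae - ai > k and _window_matches(seq, ai, bi, w) / w < min_identity:
        ai += 1
        bi += 1
    while ae > ai and seq[ae - 1] != seq[be - 1]:
        ae -= 1
        be -= 1
    while ai < ae and seq[ai] != seq[bi]:
        ai += 1
        bi += 1
    length = ae - ai
    if length < k:
        return None
    ident = sum(seq[ai + t] == seq[bi + t] for t in range(length)) / length
    if ident < min_identity:
        return None
    return DuplicationBlock(ai, ae, bi, be, ident)


@dataclass(frozen=True)
class Tile:
    """A labeled, non-overlapping interval of the decomposition."""

    start: int
    end: int
    block_id: int
    copy: str  # "a" or "b"


@dataclass(frozen=True)
class Decomposition:
    """Non-overlapping duplication tiles plus the unexplained remainder.

    Tiles and unexplained intervals together cover the whole sequence.
    """

    blocks: tuple[DuplicationBlock, ...]
    tiles: tuple[Tile, ...]
    unexplained: tuple[tuple[int, int], ...]
    seq_len: int


def tile_decomposition(seq: str, blocks: list[DuplicationBlock]) -> Decomposition:
    """Greedily tile blocks (length descending, then leftmost), trimming later
    blocks so tiles never overlap."""
    n = len(seq)
    ordered = sorted(blocks, key=lambda b: (-b.length, b.a_start, b.b_start))
    covered: list[tuple[int, int]] = []
    tiles: list[Tile] = []
    for bid, b in enumerate(ordered):
        for copy, (s, e) in (("a", (b.a_start, b.a_end)), ("b", (b.b_start, b.b_end))):
            for fs, fe in _subtract((s, e), covered):
                tiles.append(Tile(fs, fe, bid, copy))
                covered.append((fs, fe))
    tiles.sort(key=lambda t: t.start)
    covered.sort()
    unexplained = _subtract((0, n), covered)
    return Decomposition(tuple(ordered), tuple(tiles), tuple(unexplained), n)


def _subtract(
    interval: tuple[int, int], covered: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Fragments of ``interval`` not covered by any interval in ``covered``."""
    frags = [interval]
    for cs, ce in sorted(covered):
        nxt = []
        for s, e in frags:
            if ce <= s or cs >= e:
                nxt.append((s, e))
                continue
            if s < cs:
                nxt.append((s, cs))
            if ce < e:
                nxt.append((ce, e))
        frags = nxt
    return [f for f in frags if f[1] > f[0]]
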