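# Methods

## Scope and data model

The package analyses the birth and decay of protein-coding potential in
trinucleotide-repeat-derived sequences: the asymmetry of the three reading
frames of a (CAG)n repeat under point mutation, the anatomy of eroded repeat
CDSs (tracts, frame runs, internal duplications), divergence and motif
retention across copies of a transposable-element family, and a stochastic
model of a repeat locus evolving under mutation, slippage and duplication.
All coordinates are 0-based half-open internally (BED convention); report
helpers convert to 1-based closed. Sequences are uppercase DNA over
{A,C,G,T,N}; RNA input is mapped U→T at ingestion; any codon containing N is
classified "undetermined" and translated as X, never silently interpreted.
Minus-strand exon models are reverse-complemented at splicing time, so every
downstream analysis sees sense-strand transcripts.

## Codon mutation space

For a codon and a distance d ∈ {1,2,3}, the neighborhood is the exhaustive
set of C(3,d)·3^d codons differing at exactly d positions (9, 27, 27).
Classes: *nonsense* if the mutant is a stop, *silent* if it encodes the
source amino acid (at d=2 this means the double mutant restores the same
amino acid), *missense* otherwise; a stop-to-stop mutant counts as nonsense.
`stop_fraction` treats outcomes as equiprobable by default — the
combinatorial reading under which two simultaneous hits on CAG have
1/27 ≈ 3.7% stop chance — and accepts a transition/transversion ratio κ, in
which case each mutated position draws its target with weight κ (transition)
against 1 per transversion and the fraction becomes probability-weighted.
The genetic code is the standard nuclear table (via Biopython); alternative
tables can be injected but the frame-specific statements quoted throughout
assume the standard stop set {TAA, TAG, TGA}.

A deliberate redundancy: the test suite re-derives every neighborhood with an
independent brute-force enumerator (scan all 64 codons by Hamming distance)
and requires exact agreement for all 64 × 3 cases.

One notational subtlety is worth recording: the six amino acids reachable by
single mutation from the serine repeat frame — {Gly, Arg, Cys, Asn, Thr, Ile}
— identify the codon AGC (the +1 register of CAGCAG…). The threonine codon
ACG, with which AGC is easily transposed, also yields six distinct non-silent
amino acids and zero stops at distance 1, but a different set
({P, A, S, K, R, M}). Both are computable here; the named set belongs to AGC.

## Repeat tracts and frame labels

Tract detection is greedy seed-and-extend: exact two-unit occurrences of any
rotation of the unit seed a candidate, which grows one unit-window (3 nt) at
a time in both directions while the cumulative per-base mismatch fraction of
the whole tract stays ≤ `max_divergence`; terminal windows with ≥ 2
mismatches are trimmed so tracts end on repeat-like units. Overlaps are
resolved longest-first, then leftmost. The canonical unit is the
lexicographic minimum of the three rotations (AGC for any CAG-family tract)
with `phase` recording the register of the first full unit, and `purity` the
fraction of exact unit windows. The one-unit purity window matches the
visual grain at which erosion is usually drawn.

Codon frame labels use minimal Hamming distance to the three unit rotations:
a codon is polyQ/polyS/polyA when its distance to exactly one rotation is
≤ 1, "other" on ties or larger distances, "undetermined" with N. The ≤ 1
threshold encodes the dominant erosion mode (one point mutation per codon);
ties are deliberately conservative. `n_switches` counts adjacent run pairs
that are both repeat frames and differ — the frameshift signal — and ignores
transitions through "other" runs. These choices (threshold, tie rule) are
this package's decisions; published frame tracks rarely state theirs.

Per-register stop counts re-read the same nucleotides in all three registers
and count stop codons; registers are named by the majority frame label of
their codons. In `cds_inference.cds_report` the frames report covers the CDS
body from the start codon through the last sense codon — the terminal stop
codon is excluded so it does not count against its own register — and repeat
units downstream of the stop are totalled separately (the signature of a
reading frame that died before its repeat).

## ORF inference

`find_orf` scans 5′→3′: `first_aug` takes the leftmost ATG; `at_offset(k)`
requires an ATG at k (both are needed for tandem AUGAUG starts, where the
biologically used start may be the inner one). Translation runs to the first
in-frame stop or, failing that, to the transcript end with `terminated=False`
— unterminated ORFs are reported, not discarded, because truncated
assemblies (N blocks) produce them legitimately. A trailing partial codon is
dropped and its length recorded. Introns are checked for GT..AG on the
transcript sense strand; non-canonical introns are flagged and logged, never
rejected.

## Duplication decomposition

Direct internal duplications are found by exact 12-mer seeds between distinct
off-diagonal positions, extended without gaps in both directions while
cumulative identity stays ≥ `min_identity` and the two intervals remain
disjoint; blocks shorter than `min_len` (default 24 nt) are dropped. Greedy
cumulative-identity extension systematically overruns a true breakpoint by
absorbing chance matches, so each end is pulled back until its terminal
8-window meets the identity threshold on its own, then trimmed to end on
matches; on exact planted duplications this brings breakpoint error to a few
nucleotides. Extension is ungapped by design: the target structures are
contiguous segment copies, and gapped self-alignment adds cost without a
corresponding observable here.

When a `mask_unit` is given, seeds lying entirely inside *pure* tracts of
that unit (detected at `max_divergence=0`, ≥ 4 units) are suppressed — a pure
repeat is everywhere self-similar and would flood the seed table — while
seeds anchored at eroded positions survive and extensions may traverse pure
repeat freely. A consequence worth knowing: in strongly repeat-like
sequence, a tandem duplication's breakpoints are only identifiable up to the
repeat period, so recovery there is judged on the copy distance (diagonal)
and source overlap, not on exact endpoints. In random (non-repeat)
background, planted exact 60-nt duplications are recovered with ≤ 3 nt
breakpoint error in ≈ 99/100 seeded trials.

Tiling is greedy by block length (descending, then leftmost), later blocks
trimmed to the uncovered remainder; tiles plus unexplained intervals
partition the sequence exactly.

## Family divergence and motif census

The per-position exchange rate of a family alignment is the fraction of
copies whose base differs from the consensus at that consensus position.
Indels are loss of information, not mismatch: a copy gapped at a column
leaves that column's denominator, a position informative in no copy is
flagged undefined rather than zero, and consensus-gap columns carry no
coordinate. Motif queries over consensus windows exclude any copy gapped
inside the window from numerator and denominator alike; the two-window
census reports exclusive classes (A-only, B-only, both) over the copies
informative in *both* windows, so the additivity identity
at-least-one = A-only + B-only + both holds exactly, with marginal carrier
fractions reported alongside. With 100 copies and planted exclusive
fractions 0.14/0.29/0.15 the census returns (0.14, 0.29, 0.15, 0.58)
exactly.

## Evolutionary simulator

Each generation, in order: (1) every site is substituted independently with
probability μ (drawn as a Binomial site count plus distinct uniform
positions — distributionally identical, one RNG call), the target base drawn
with transition weight κ against unit transversions; (2) with probability σ
one slippage event inserts or deletes (equiprobably) one unit at a uniformly
chosen unit boundary of a currently detectable tract (tracts found at
`max_divergence=0.1`, ≥ 3 units — slippage is replication-mediated and
confined to repeats; insertion copies the local unit, so pure repeats stay
pure); (3) with probability δ one segment of uniform length in `dup_len` is
copied in place immediately after its source. At most one slippage and one
duplication per generation keeps the rates interpretable. Replicate r uses
seed + r; the event log replays to every snapshot byte-exactly (tested).

The observable is per-frame ORF survival of the *initial* repeat region: the
region's boundaries are carried through indels via the event log, stops are
counted in the frame-consistent reading of each register, and an indel of
non-multiple-of-3 length inside the region marks the replicate frameshifted
(reported separately, since frame retention despite indels is itself the
interesting outcome). Survival at generation t is the fraction of replicates
in which no stop has appeared in that register by t, with binomial standard
errors.

Closed form: for an initially pure (CAG)n locus with unbiased mutation the
only single-hit stop route is C→T at a codon's first position, so the
per-codon hazard is μ/3 and polyQ survival ≈ exp(−n·(μ/3)·t); polyS and
polyA have single-hit hazard exactly 0. The approximation neglects
second-order paths (e.g. CAG→CAA→TAA) and hazard loss from eroded codons;
both are O((μt)²) per codon and invisible at μt ≤ 0.1 against Monte-Carlo
noise at 1,000 replicates (observed agreement within 1.5 SE at every decade
of a 100-generation run).

No rate here is an estimate of a real per-generation mutation rate; μ, σ, δ
defaults are illustrative scales chosen so that the qualitative regime
(single-hit stop gain, rare indels) is reached within a 100-generation run.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed) — byte-identical on
regeneration — and each attaches its ground truth. The family generator
draws copies per-position independently at the planted rates and emits
deletion-only indels (gap characters), keeping alignment width equal to the
consensus length; real element families add insertions, CpG-biased
mutation, and phylogenetic correlation between copies, none of which are
modelled. Carrier classes are assigned in deterministic blocks under
`exact_fractions` (floor(f·n) copies per class, with an epsilon guard on the
float product) so census tests are exact; a sampled mode serves statistical
tests. The repeat-CDS generator erodes units with a rejection step that
forbids stops in the chosen frame, so its CDSs are open by construction —
tests against it check estimator behaviour, not biological frequency of open
frames. The transcript-locus generator plants a tandem ATGATG at the first
exon start and GT..AG (or GC..AG) intron termini. Passing on these inputs
demonstrates correctness of the computations under the stated generative
assumptions, not performance on real genome annotation, where alignment
error, nested elements and assembly gaps dominate.

## Problem sizes and numerical choices

Default study sizes: 100-copy families of 150–300 consensus positions,
(CAG)60 loci over 100 generations at 1,000 replicates, 100-seed duplication
benchmarks on 400-nt backgrounds — all chosen so each analysis is a
desk-scale computation (seconds) while keeping binomial/Monte-Carlo errors
small relative to the effects measured. Floats in emitted tables are fixed
at 6 significant digits so repeated runs are byte-identical. Degenerate
inputs have defined behaviour throughout: empty FASTA → empty list; no ATG →
explicit no-ORF result; zero informative copies → undefined (NaN) flagged
explicitly; empty protein → error.

## Known limitations

Duplication detection is direct-orientation and ungapped only (no inverted
or diverged-with-indels copies). Tract detection assumes 3-nt units (other
lengths accepted, untested). The simulator has no selection, no population
(a single lineage), and slippage limited to ±1 unit per generation. The
exchange-rate profile treats copies as independent draws from the consensus,
which overstates the information content of phylogenetically clustered
families.
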