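# polyframe

Reading-frame analysis and evolutionary simulation of trinucleotide-repeat-derived
coding sequences.

## The problem

A (CAG)n repeat can be read in three registers, encoding three homopolymers:
polyQ (CAG), polyS (AGC) and polyA (GCA). The three frames are not equivalent
under point mutation. Under the standard genetic code the glutamine codon CAG
is a single substitution away from a stop (C→T at the first position gives
TAG), while AGC and GCA are at Hamming distance 2 from every stop codon
{TAA, TAG, TGA}. A coding sequence born from a repeat expansion — for example
one whose promoter and start codon arrived with an LTR retrotransposon
insertion — therefore erodes very differently depending on which frame is
read: the polyQ frame accumulates stops at per-codon hazard μ/3 per
generation (unbiased mutation), whereas the polyS and polyA frames need two
hits in one codon before a stop is even possible, and single hits on the
serine codon AGC reach six other amino acids (G, R, C, N, T, I) but never a
stop.

`polyframe` makes this arithmetic, and the analyses around it, computable and
testable:

* **codon_space** — exact enumeration of point-mutation neighborhoods of any
  codon: outcome classes (silent / missense / nonsense), stop fractions
  (optionally transition/transversion-weighted), reachable amino-acid sets,
  and per-frame minimum distances to a stop.
* **repeat_frames** — seed-and-extend detection of eroded repeat tracts,
  per-codon frame labeling (Hamming ≤ 1 to a unit rotation), frame-run
  segmentation and switch counting, amino-acid composition, and per-register
  stop counts of a CDS.
* **cds_inference** — spliced transcript assembly from genome + exon model
  (GT..AG intron validation, minus-strand support), ORF inference from the
  first AUG or a fixed offset (tandem AUGAUG starts need both), and a joint
  CDS/frame report including repeat content left downstream of the stop.
* **duplication_decomposition** — internal direct-duplication detection by
  off-diagonal k-mer seeding and ungapped extension, with pure-repeat
  seed masking, tiled into a non-overlapping block decomposition.
* **ltr_profile** — per-position nucleotide exchange rates of an element
  family against its consensus, and motif presence/co-occurrence censuses
  over consensus windows (gap-bearing copies drop out of affected windows).
* **evo_simulator** — a generational model of a repeat locus under point
  mutation, ±1-unit slippage and segmental duplication, tracking per-frame
  ORF survival with a replayable event log, plus single-hit closed forms.
* **synthetic_data** — seeded generators (with ground truth) for every input
  class: diverged element families with planted motif-carrier fractions,
  eroded framed repeat CDSs with planted duplications, spliced toy loci.

## Worked example

```python
>>> from polyframe.codon_space import stop_fraction, amino_reachability
>>> stop_fraction("CAG", 2)            # two simultaneous hits on CAG
0.037037037037037035                   # 1/27 ≈ 3.7% chance of a stop
>>> sorted(amino_reachability("AGC", 1).amino_acids)
['C', 'G', 'I', 'N', 'R', 'T']         # six amino acids, zero stops

>>> from polyframe.evo_simulator import SimParams, evolve, frame_survival
>>> traj = evolve("CAG" * 60, SimParams(mu=0.001, generations=100,
...                                     n_replicates=1000, seed=1))
>>> round(float(frame_survival(traj, "polyQ").survival[-1]), 3)
0.152                                  # closed form exp(-60*(mu/3)*100) = 0.135
>>> round(float(frame_survival(traj, "polyS").survival[-1]), 3)
0.941                                  # the serine frame barely decays
```

The same story from the command line:

```sh
$ polyframe codon-space --codon CAG --distance 2 --unit CAG
{... "stop_fraction": 0.037037037037037035,
     "min_mutations_to_stop": {"polyQ": 1, "polyS": 2, "polyA": 2} ...}
```

## Analysis drivers

Numbered scripts under `analysis/` run the full set of studies on synthetic
data and write tables to `results/`:

| script | what it computes |
|---|---|
| `01_codon_mutation_space.py` | mutation-space tables for CAG/AGC/GCA; per-frame stop distances |
| `02_repeat_frames_and_cds.py` | frame anatomy of eroded serine-frame CDSs; spliced toy locus report |
| `03_duplication_decomposition.py` | planted-duplication recovery benchmark; repeat-context decomposition |
| `04_ltr_divergence_census.py` | exchange-rate recovery and the tandem-start (14/29/15 → 58%) census |
| `05_repeat_locus_simulation.py` | per-frame ORF survival vs. the single-hit closed form; full model |

For instance `python analysis/05_repeat_locus_simulation.py` prints:

```
(CAG)60, mu=0.001, 1000 replicates, 100 generations:
  polyQ survival 0.152 (closed form 0.135), polyS 0.941, polyA 0.884
  max |simulation - closed form| = 1.47 Monte-Carlo SE
```

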