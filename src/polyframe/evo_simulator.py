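"""Generational simulator of a repeat locus under the three forces that shape
repeat-derived coding sequences: point mutation, replication slippage, and
segmental duplication.

The model is deliberately minimal.  Each generation, every site is
substituted independently with probability ``mu`` (target base drawn with
transition/transversion ratio ``kappa``); with probability ``sigma`` one
slippage event inserts or deletes (equiprobably) a single repeat unit at a
unit boundary of a currently detectable tract; with probability ``delta`` one
segment of uniformly drawn length is copied in place immediately after its
source.  Rates are per generation and interpretable directly.

The tracked observable is per-frame ORF survival: reading the *initial*
repeat region in each of its three registers (polyQ / polyS / polyA for a CAG
locus), the generation at which a stop codon first appears.  The register is
carried through indels via the event log; an insertion of non-multiple-of-3
length inside the counted region marks the replicate frameshifted, reported
separately.  In the single-hit regime the glutamine-frame survival has the
closed form exp(-n_units * (mu/3) * t) for an unbiased mutation process —
only C->T at the first codon position creates a stop (CAG -> TAG) — while the
serine and alanine frames cannot gain a stop from one substitution at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_space import (
    GeneticCode,
    STANDARD_CODE,
    STOP,
    TRANSITIONS,
    rotations,
)
from .repeat_frames import find_repeat_tracts, register_frame_labels

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Per-generation rates and run dimensions of the repeat-locus simulator.

    mu     — per-site substitution probability
    kappa  — transition/transversion ratio (1 = unbiased)
    sigma  — probability of one +/-1-unit slippage event inside a repeat tract
    delta  — probability of one segmental duplication
    dup_len — inclusive (min, max) of the uniform duplication-length draw
    """

    mu: float
    sigma: float = 0.0
    delta: float = 0.0
    kappa: float = 1.0
    dup_len: tuple[int, int] = (12, 60)
    generations: int = 100
    n_replicates: int = 1
    seed: int = 0
    unit: str = "CAG"
    snapshot_every: int | None = None

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        lo, hi = self.dup_len
        if lo < 3 or hi < lo:
            raise ValueError(f"invalid dup_len range {self.dup_len}")
        if len(self.unit) != 3:
            raise ValueError("unit must be 3 nt")


@dataclass
class ReplicateResult:
    """One replicate's event log, snapshots and per-frame stop history."""

    final_seq: str
    events: list[tuple]  # (generation, type, ...) — see replay_events
    snapshots: dict[int, str]
    first_stop_gen: dict[int, int | None]  # register -> generation, None = never
    frameshift_gen: int | None
    region: tuple[int, int]  # final coordinates of the tracked repeat region


@dataclass
class SimTrajectory:
    """All replicates of one simulation, plus the register -> frame-name map."""

    initial_seq: str
    params: SimParams
    frame_labels: dict[int, str]
    replicates: list[ReplicateResult] = field(default_factory=list)


def _target_probs(kappa: float) -> dict[str, np.ndarray]:
    """For each base, probabilities over the three alternative bases."""
    out = {}
    for b in _BASES:
        alts = [x for x in _BASES if x != b]
        w = np.array([kappa if (b, a) in TRANSITIONS else 1.0 for a in alts])
        out[b] = w / w.sum()
    return out


def _count_stops(seq: list[str], rs: int, re_: int, register: int,
                 stops: frozenset[str]) -> bool:
    text = "".join(seq[rs:re_])
    for i in range(register, len(text) - 2, 3):
        if text[i : i + 3] in stops:
            return True
    return False


def evolve(initial_seq: str, params: SimParams,
           code: GeneticCode = STANDARD_CODE) -> SimTrajectory:
    """Run the generational model; fully reproducible from ``params.seed``
    (replicate r uses ``seed + r``)."""
    initial_seq = initial_seq.upper().replace("U", "T")
    if any(b not in _BASES for b in initial_seq):
        raise ValueError("initial sequence must be over ACGT")
    labels = register_frame_labels(initial_seq, params.unit, code)
    traj = SimTrajectory(initial_seq, params, labels)
    stops = code.stop_codons
    tprobs = _target_probs(params.kappa)
    for r in range(params.n_replicates):
        traj.replicates.append(
            _evolve_one(initial_seq, params, np.random.default_rng(params.seed + r), stops, tprobs)
        )
    return traj


def _evolve_one(initial_seq, params, rng, stops, tprobs) -> ReplicateResult:
    seq = list(initial_seq)
    rs, re_ = 0, len(seq)
    first_stop: dict[int, int | None] = {}
    for reg in range(3):
        first_stop[reg] = 0 if _count_stops(seq, rs, re_, reg, stops) else None
    frameshift_gen = None
    events: list[tuple] = []
    snapshots: dict[int, str] = {}
    for gen in range(1, params.generations + 1):
        changed = False
        # substitutions: Binomial site count, then distinct uniform positions
        n_mut = rng.binomial(len(seq), params.mu) if params.mu > 0 else 0
        if n_mut:
            positions = sorted(rng.choice(len(seq), size=n_mut, replace=False).tolist())
            for p in positions:
                old = seq[p]
                alts = [x for x in _BASES if x != old]
                new = alts[rng.choice(3, p=tprobs[old])]
                seq[p] = new
                events.append((gen, "sub", p, old, new))
            changed = True
        # one slippage event inside a detectable repeat tract
        if params.sigma > 0 and rng.random() < params.sigma:
            tracts = find_repeat_tracts(
                "".join(seq), params.unit, min_units=3, max_divergence=0.1
            )
            boundaries = [
                p for t in tracts for p in range(t.start, t.end - 2, 3)
            ]
            if boundaries:
                p = boundaries[rng.integers(len(boundaries))]
                unit_here = "".join(seq[p : p + 3])
                if rng.random() < 0.5:
                    seq[p:p] = list(unit_here)
                    events.append((gen, "ins", p, unit_here))
                    rs, re_, frameshift_gen = _shift_region(
                        rs, re_, p, 3, gen, frameshift_gen
                    )
                else:
                    del seq[p : p + 3]
                    events.append((gen, "del", p, unit_here))
                    rs, re_, frameshift_gen = _shift_region(
                        rs, re_, p, -3, gen, frameshift_gen
                    )
                changed = True
        # one segmental duplication, copy placed immediately after its source
        if params.delta > 0 and rng.random() < params.delta:
            lo, hi = params.dup_len
            L = int(rng.integers(lo, hi + 1))
            if L <= len(seq):
                src = int(rng.integers(0, len(seq) - L + 1))
                segment = "".join(seq[src : src + L])
                seq[src + L : src + L] = list(segment)
                events.append((gen, "dup", src, L))
                rs, re_, frameshift_gen = _shift_region(
                    rs, re_, src + L, L, gen, frameshift_gen
                )
                changed = True
        if changed and re_ - rs >= 3:
            for reg in range(3):
                if first_stop[reg] is None and _count_stops(seq, rs, re_, reg, stops):
                    first_stop[reg] = gen
        if params.snapshot_every and gen % params.snapshot_every == 0:
            snapshots[gen] = "".join(seq)
    final = "".join(seq)
    snapshots.setdefault(params.generations, final)
    return ReplicateResult(final, events, snapshots, first_stop, frameshift_gen, (rs, re_))


def _shift_region(rs, re_, pos, delta_len, gen, frameshift_gen):
    """Carry the tracked region through an indel of signed length delta_len at pos."""
    inside = rs <= pos < re_
    if pos < rs:
        rs += delta_len
        re_ += delta_len
    elif inside:
        re_ += delta_len
        if delta_len % 3 != 0 and frameshift_gen is None:
            frameshift_gen = gen
    return rs, max(re_, rs), frameshift_gen


def replay_events(initial_seq: str, events: list[tuple]) -> str:
    """Re-apply a logged event stream to the initial sequence (audit path)."""
    seq = list(initial_seq)
    for ev in events:
        kind = ev[1]
        if kind == "sub":
            _, _, p, old, new = ev
            assert seq[p] == old
            seq[p] = new
        elif kind == "ins":
            _, _, p, segment = ev
            seq[p:p] = list(segment)
        elif kind == "del":
            _, _, p, segment = ev
            assert "".join(seq[p : p + len(segment)]) == segment
            del seq[p : p + len(segment)]
        elif kind == "dup":
            _, _, src, L = ev
            seq[src + L : src + L] = seq[src : src + L]
        else:
            raise ValueError(f"unknown event type {kind!r}")
    return "".join(seq)


@dataclass(frozen=True)
class SurvivalCurve:
    """Fraction of replicates with a still stop-free reading of the repeat
    region in one frame, by generation, with binomial standard errors."""

    frame: str
    generations: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    n_replicates: int


def _resolve_register(traj: SimTrajectory, frame: str | int) -> int:
    if isinstance(frame, int):
        if frame in (0, 1, 2):
            return frame
        raise ValueError(f"register must be 0, 1 or 2, got {frame}")
    for reg, lab in traj.frame_labels.items():
        if lab == frame:
            return reg
    raise ValueError(
        f"unknown frame {frame!r}; this trajectory has {sorted(traj.frame_labels.values())}"
    )


def frame_survival(traj: SimTrajectory, frame: str | int) -> SurvivalCurve:
    """Per-generation fraction of replicates whose ``frame`` reading of the
    repeat region has never contained a stop codon (monotone non-increasing)."""
    reg = _resolve_register(traj, frame)
    n = len(traj.replicates)
    gens = np.arange(traj.params.generations + 1)
    firsts = np.array(
        [
            rep.first_stop_gen[reg] if rep.first_stop_gen[reg] is not None else np.inf
            for rep in traj.replicates
        ]
    )
    surv = (firsts[None, :] > gens[:, None]).mean(axis=1)
    se = np.sqrt(surv * (1 - surv) / n)
    label = traj.frame_labels[reg]
    return SurvivalCurve(label, gens, surv, se, n)


def stop_gain_hazard(
    unit: str,
    frame: str | int,
    mu: float,
    kappa: float = 1.0,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Closed-form per-codon per-generation probability that a single point
    mutation turns the frame's repeat codon into a stop.

    For (CAG, polyQ) with unbiased mutation this is mu/3 — the one stop-making
    change is C->T at the first position — and exactly 0 for polyS and polyA.
    """
    rots = rotations(unit)
    if isinstance(frame, int):
        if frame not in (0, 1, 2):
            raise ValueError(f"register must be 0, 1 or 2, got {frame}")
        codon = rots[frame]
    else:
        match = [
            c for f, c in enumerate(rots)
            if code.translate(c) != STOP and f"poly{code.translate(c)}" == frame
        ]
        if not match:
            raise ValueError(f"unknown frame {frame!r} for unit {unit}")
        codon = match[0]
    total = 0.0
    for pos in range(3):
        old = codon[pos]
        alts = [x for x in _BASES if x != old]
        weights = [kappa if (old, a) in TRANSITIONS else 1.0 for a in alts]
        z = sum(weights)
        for a, w in zip(alts, weights):
            mutant = codon[:pos] + a + codon[pos + 1 :]
            if code.translate(mutant) == STOP:
                total += mu * w / z
    return total


def polyq_survival_closed_form(n_units: int, mu: float, t: np.ndarray | int) -> np.ndarray:
    """Single-hit approximation exp(-n_units * (mu/3) * t) for an unbiased
    process on an initially pure CAG repeat read in the glutamine frame."""
    return np.exp(-n_units * (mu / 3.0) * np.asarray(t, dtype=float))
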