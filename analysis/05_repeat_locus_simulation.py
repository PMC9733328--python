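#!/usr/bin/env python
"""Stochastic evolution of a pure (CAG)60 locus and per-frame ORF survival.

Runs the generational simulator (point mutation only, then the full
mutation + slippage + duplication model), compares simulated glutamine-frame
ORF survival with the single-hit closed form exp(-n * (mu/3) * t), and writes
the survival curves.  The glutamine frame decays fast; the serine and alanine
frames — two hits away from any stop — survive essentially untouched on the
same timescale.
"""

import sys
from pathlib import Path

import numpy as np

from polyframe.evo_simulator import (
    SimParams,
    evolve,
    frame_survival,
    polyq_survival_closed_form,
    stop_gain_hazard,
)
from polyframe.seqio import write_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    n_units, mu = 60, 0.001
    print(f"closed-form per-codon stop-gain hazards at mu={mu}: "
          f"polyQ {stop_gain_hazard('CAG', 'polyQ', mu):.2e}, "
          f"polyS {stop_gain_hazard('CAG', 'polyS', mu):.0e}, "
          f"polyA {stop_gain_hazard('CAG', 'polyA', mu):.0e}")

    params = SimParams(mu=mu, generations=100, n_replicates=1000, seed=SEED)
    traj = evolve("CAG" * n_units, params)
    curves = {f: frame_survival(traj, f) for f in ("polyQ", "polyS", "polyA")}
    rows = []
    for t in range(0, 101, 10):
        cf = float(polyq_survival_closed_form(n_units, mu, t))
        rows.append(
            {"generation": t,
             "polyQ": float(curves["polyQ"].survival[t]),
             "polyQ_se": float(curves["polyQ"].se[t]),
             "polyQ_closed_form": cf,
             "polyS": float(curves["polyS"].survival[t]),
             "polyA": float(curves["polyA"].survival[t])}
        )
    write_table(rows, RESULTS / "frame_survival.tsv", columns=list(rows[0]))
    last = rows[-1]
    print(f"(CAG){n_units}, mu={mu}, 1000 replicates, 100 generations:")
    print(f"  polyQ survival {last['polyQ']:.3f} "
          f"(closed form {last['polyQ_closed_form']:.3f}), "
          f"polyS {last['polyS']:.3f}, polyA {last['polyA']:.3f}")
    dev = max(abs(r["polyQ"] - r["polyQ_closed_form"]) /
              max(r["polyQ_se"], 1e-9) for r in rows[1:])
    print(f"  max |simulation - closed form| = {dev:.2f} Monte-Carlo SE")

    full = SimParams(mu=mu, sigma=0.02, delta=0.005, generations=100,
                     n_replicates=200, seed=SEED + 1)
    ftraj = evolve("CAG" * n_units, full)
    lens = np.array([len(r.final_seq) for r in ftraj.replicates])
    shifted = sum(r.frameshift_gen is not None for r in ftraj.replicates)
    print(f"full model (slippage 0.02, duplication 0.005): mean final length "
          f"{lens.mean():.0f} nt (initial {3 * n_units}), "
          f"{shifted}/200 replicates frameshifted in the tracked region")
    print(f"wrote {RESULTS / 'frame_survival.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
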