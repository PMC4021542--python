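"""Decode the three oculomotor behaviors from memory-epoch spike counts.

Loads the simulated session from 01, counts spikes in the 250 ms window
ending 1400 ms after target onset (inside every trial's memory epoch), and
runs leave-one-out MAP decoding over the 72-combo joint posterior.  The
presaccade position and direction are read from the joint posterior's
marginals; the postsaccade posterior sums the mass of all (position,
direction) pairs with the same vector sum.  An untuned control population is
decoded the same way to confirm chance levels (1/9, 1/8, 1/25).

Writes results/epoch_npc.csv.
"""

import numpy as np
import pandas as pd

import npcdecode as npc
from npcdecode.io import write_table
from npcdecode.task import combo_labels
from npcdecode.timecourse import count_tensor

SEED = 1
OUT = "results"
WINDOW_END = 1400.0  # ms after target onset


def decode(trials, space, tag, rows):
    counts, _ = count_tensor(trials, len(trials[0].spikes), "target_on",
                             np.array([WINDOW_END]), 250.0)
    res = npc.loo_decode(counts[0], combo_labels(trials), space, seed=SEED + 4)
    n_b = {"presaccade": 9, "direction": 8, "postsaccade": 25}
    for b in ("presaccade", "direction", "postsaccade"):
        r = npc.npc_accuracy(res.estimates[b], res.truths[b], n_b[b],
                             n_boot=1000, seed=SEED + 5)
        rows.append({"population": tag, "behavior": b, "npc": r.npc,
                     "sem": r.sem, "chance": 1 / n_b[b]})
        print(f"  {tag:8s} {b:12s} NPC = {r.npc:.3f} +- {r.sem:.3f} "
              f"(chance {1 / n_b[b]:.3f})")


def main():
    space = npc.enumerate_behaviors(3, 8.0)
    trials = npc.read_trial_table(f"{OUT}/trials.csv", space)
    trials = npc.read_spike_table(f"{OUT}/spikes.csv", trials, 20)
    print(f"memory-window decoding ({len(trials)} trials, window ending "
          f"{WINDOW_END:.0f} ms after target onset):")
    rows = []
    decode(trials, space, "tuned", rows)

    untuned = npc.make_population(20, "untuned", seed=SEED + 3)
    bare = [npc.task.with_spikes(t, None) for t in trials]
    control = npc.simulate_spikes(untuned, bare, space, seed=SEED + 3)
    decode(control, space, "untuned", rows)

    write_table(pd.DataFrame(rows), f"{OUT}/epoch_npc.csv")
    print(f"wrote {OUT}/epoch_npc.csv")


if __name__ == "__main__":
    main()
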