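"""Time course of the NPC for saccade direction, with epoch RMS and marks.

Runs the sliding-window decoder (250 ms causal boxcar, 10 ms steps) on the
simulated session from 01, aligned to target onset, then summarizes epochs
by the RMS of the time course and locates the accuracy onset by the
derivative-difference rule.  Direction information should be absent before
target onset (chance 1/8), rise with the visual transient and stay elevated
through the memory delay.

Writes results/timecourse_direction.csv and results/timecourse_marks.csv.
"""

import pandas as pd

import npcdecode as npc
from npcdecode.io import write_table
from npcdecode.timecourse import epoch_bounds, epoch_rms

SEED = 1
OUT = "results"


def main():
    space = npc.enumerate_behaviors(3, 8.0)
    trials = npc.read_trial_table(f"{OUT}/trials.csv", space)
    trials = npc.read_spike_table(f"{OUT}/spikes.csv", trials, 20)

    tc = npc.npc_timecourse(trials, space, "direction", "target_on",
                            -700.0, 1400.0, step_ms=20.0, n_boot=200,
                            seed=SEED + 6)
    write_table(tc.to_frame(), f"{OUT}/timecourse_direction.csv")

    for name, (e0, e1) in {"fixation": ("fixation_acquired", "target_on"),
                           "visual": ("target_on", "target_off"),
                           "memory": ("target_off", "go_cue")}.items():
        lo, hi = epoch_bounds(trials, "target_on", e0, e1)
        lo = max(lo, tc.times[0])
        rms, sem = epoch_rms(tc, (lo, hi))
        print(f"  {name:8s} epoch RMS accuracy = {rms:.3f} +- {sem:.3f}")

    marks = npc.detect_onset_peak(tc, seed=SEED + 7)
    print(f"  onset = {marks.onset_ms} ms, peak = {marks.peak_ms} ms "
          f"(relative to target onset)")
    write_table(pd.DataFrame([{"behavior": "direction", "align": "target_on",
                               "onset_ms": marks.onset_ms,
                               "peak_ms": marks.peak_ms}]),
                f"{OUT}/timecourse_marks.csv")
    print(f"wrote {OUT}/timecourse_direction.csv, {OUT}/timecourse_marks.csv")


if __name__ == "__main__":
    main()
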