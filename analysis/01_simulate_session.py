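"""Simulate one delayed-memory-saccade session with a tuned model population.

Enumerates the grid behavior space (9 presaccade positions x 8 directions =
72 combos, 25 postsaccade positions), generates 11 randomized blocks (792
correct trials) and draws Poisson spike trains for 20 direction-tuned
neurons with planar eye-position gain fields.

Writes results/trials.csv, results/population.yaml, results/spikes.csv.
"""

import npcdecode as npc

SEED = 1
OUT = "results"


def main():
    space = npc.enumerate_behaviors(3, 8.0)
    print(f"behavior space: {space.n_presaccade} presaccade positions, "
          f"{space.n_directions} directions, {space.n_combos} combos, "
          f"{space.n_postsaccade} postsaccade positions")

    trials = npc.generate_session(space, n_blocks=11, seed=SEED)
    print(f"session: {len(trials)} trials (11 blocks x 72 combos)")

    pop = npc.make_population(20, "tuned", seed=SEED + 1)
    trials = npc.simulate_spikes(pop, trials, space, seed=SEED + 2)
    n_spk = sum(len(s) for t in trials for s in t.spikes.values())
    dur = trials[0].event_times["trial_end"] / 1000.0
    print(f"spikes: {n_spk} total from {pop.n} neurons "
          f"(~{n_spk / len(trials) / pop.n / dur:.1f} spk/s/neuron)")

    npc.write_trial_table(trials, space, f"{OUT}/trials.csv", meta={"seed": SEED})
    npc.population_to_yaml(pop, f"{OUT}/population.yaml", meta={"seed": SEED + 1})
    npc.write_spike_table(trials, f"{OUT}/spikes.csv", meta={"seed": SEED + 2})
    print(f"wrote {OUT}/trials.csv, {OUT}/population.yaml, {OUT}/spikes.csv")


if __name__ == "__main__":
    main()
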