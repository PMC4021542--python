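import numpy as np
import pytest

import npcdecode as npc
from npcdecode.timecourse import count_tensor

#: window end (ms after target onset) fully inside every trial's memory epoch
MEMORY_WINDOW_END = 1400.0


@pytest.fixture(scope="session")
def space():
    return npc.enumerate_behaviors(3, 8.0)


@pytest.fixture(scope="session")
def session3(space):
    """Three balanced blocks (216 trials), no spikes."""
    return npc.generate_session(space, 3, seed=11)


@pytest.fixture(scope="session")
def tuned_pop():
    return npc.make_population(20, "tuned", seed=7)


@pytest.fixture(scope="session")
def tuned_trials(space, session3, tuned_pop):
    return npc.simulate_spikes(tuned_pop, session3, space, seed=13)


@pytest.fixture(scope="session")
def untuned_trials(space, session3):
    pop = npc.make_population(20, "untuned", seed=7)
    return npc.simulate_spikes(pop, session3, space, seed=13)


def memory_counts(trials, n_neurons, window_ms=250.0):
    """Spike counts in the 250 ms window ending at 1400 ms after target onset."""
    counts, _ = count_tensor(trials, n_neurons, "target_on",
                             np.array([MEMORY_WINDOW_END]), window_ms)
    return counts[0]
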