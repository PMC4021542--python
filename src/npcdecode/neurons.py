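"""Synthetic populations of tuned Poisson neurons for the grid saccade task.

Each model neuron fires as a piecewise-constant-rate Poisson process.  Its
rate is the product of a direction-tuning term (circular bell / von-Mises
shape, active once the target is known), a planar eye-position gain field
(multiplicative, floored at zero), and an epoch-dependent gain emulating the
visual transient, sustained memory activity, the perisaccadic burst (which
leads the saccade) and a decaying postsaccadic component.  Before the saccade
the gain field reads the presaccade eye position, after it the postsaccade
position.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import read_table, read_yaml, write_table, write_yaml
from .task import TrialRecord, with_spikes

EPOCHS = ("fixation", "visual", "memory", "perisaccadic",
          "postsaccadic1", "postsaccadic2")

#: Multiplicative epoch gains shaping the canonical response profile.
DEFAULT_EPOCH_GAINS: dict[str, float] = {
    "fixation": 1.0,
    "visual": 2.5,
    "memory": 1.6,
    "perisaccadic": 2.0,
    "postsaccadic1": 1.8,
    "postsaccadic2": 1.2,
}

ARCHETYPES = ("tuned", "untuned", "duplicate-pair", "custom")


@dataclass
class NeuronModel:
    """Rate model of one neuron: baseline x direction tuning x gain field x epoch gain."""

    baseline_rate: float                      # spikes/s
    preferred_direction_deg: float
    concentration: float                      # von-Mises-shaped bell, unitless
    modulation_depth: float                   # spikes/s at the preferred direction
    gain_x: float                             # gain-field slope per deg
    gain_y: float
    gain_offset: float
    epoch_gains: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EPOCH_GAINS))
    perisaccadic_lead_ms: float = 80.0        # burst begins this long before saccade onset
    perisaccadic_tail_ms: float = 80.0

    def direction_factor(self, direction_deg: float) -> float:
        delta = np.deg2rad(direction_deg - self.preferred_direction_deg)
        return float(np.exp(self.concentration * (np.cos(delta) - 1.0)))

    def position_gain(self, xy) -> float:
        return max(0.0, self.gain_offset + self.gain_x * xy[0] + self.gain_y * xy[1])

    def rate(self, epoch: str, pre_xy, post_xy, direction_deg: float) -> float:
        """Firing rate (spikes/s) in one epoch of one trial; always >= 0."""
        if epoch == "fixation":
            drive = self.baseline_rate
            pos = pre_xy
        else:
            drive = self.baseline_rate + self.modulation_depth * self.direction_factor(direction_deg)
            pos = pre_xy if epoch in ("visual", "memory", "perisaccadic") else post_xy
        return max(0.0, self.epoch_gains[epoch] * drive * self.position_gain(pos))


@dataclass
class PopulationModel:
    neurons: list[NeuronModel]

    @property
    def n(self) -> int:
        return len(self.neurons)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population must contain at least one neuron")


#: Hyperparameter defaults for `make_population(archetype="tuned")`.
DEFAULT_HYPERPARAMS: dict = {
    "baseline_range": (5.0, 15.0),
    "depth_range": (20.0, 40.0),
    "concentration": 2.0,
    "gain_slope_range": (-0.02, 0.02),
    "gain_offset": 1.0,
    "epoch_gains": DEFAULT_EPOCH_GAINS,
    "perisaccadic_lead_ms": 80.0,
    "perisaccadic_tail_ms": 80.0,
    "untuned_rate": 10.0,
}


def make_population(n: int, archetype: str = "tuned",
                    hyperparams: dict | None = None, seed: int = 0) -> PopulationModel:
    """Build a model population of a given archetype.

    ``tuned`` spreads preferred directions over [0, 360) with seeded-random
    baselines, depths and gain-field slopes; ``untuned`` gives every neuron a
    constant rate across all behaviors and epochs; ``duplicate-pair`` copies
    neuron 0's rate function into neuron 1; ``custom`` takes explicit neuron
    parameter dicts under ``hyperparams["neurons"]``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; options: {ARCHETYPES}")
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    rng = np.random.default_rng(seed)

    if archetype == "custom":
        specs = (hyperparams or {}).get("neurons")
        if not specs:
            raise ValueError("custom archetype requires hyperparams['neurons']")
        return PopulationModel([NeuronModel(**spec) for spec in specs])

    if archetype == "untuned":
        rate = float(hp["untuned_rate"])
        gains = {e: 1.0 for e in EPOCHS}
        neurons = [
            NeuronModel(
                baseline_rate=rate,
                preferred_direction_deg=0.0,
                concentration=0.0,
                modulation_depth=0.0,
                gain_x=0.0, gain_y=0.0, gain_offset=1.0,
                epoch_gains=dict(gains),
            )
            for _ in range(n)
        ]
        return PopulationModel(neurons)

    # tuned (and duplicate-pair, which is tuned with neuron 1 := neuron 0)
    neurons = []
    for i in range(n):
        pref = (360.0 * i / n + rng.uniform(0.0, 360.0 / n)) % 360.0
        neurons.append(NeuronModel(
            baseline_rate=float(rng.uniform(*hp["baseline_range"])),
            preferred_direction_deg=pref,
            concentration=float(hp["concentration"]),
            modulation_depth=float(rng.uniform(*hp["depth_range"])),
            gain_x=float(rng.uniform(*hp["gain_slope_range"])),
            gain_y=float(rng.uniform(*hp["gain_slope_range"])),
            gain_offset=float(hp["gain_offset"]),
            epoch_gains=dict(hp["epoch_gains"]),
            perisaccadic_lead_ms=float(hp["perisaccadic_lead_ms"]),
            perisaccadic_tail_ms=float(hp["perisaccadic_tail_ms"]),
        ))
    if archetype == "duplicate-pair":
        if n < 2:
            raise ValueError("duplicate-pair requires n >= 2")
        neurons[1] = dataclasses.replace(neurons[0], epoch_gains=dict(neurons[0].epoch_gains))
    return PopulationModel(neurons)


def _trial_segments(neuron: NeuronModel, ev: dict[str, float]) -> list[tuple[float, float, str]]:
    peri0 = ev["saccade_onset"] - neuron.perisaccadic_lead_ms
    peri1 = ev["saccade_onset"] + neuron.perisaccadic_tail_ms
    bounds = [
        (0.0, ev["target_on"], "fixation"),
        (ev["target_on"], ev["target_off"], "visual"),
        (ev["target_off"], peri0, "memory"),
        (peri0, peri1, "perisaccadic"),
        (peri1, ev["fixation2_acquired"], "postsaccadic1"),
        (ev["fixation2_acquired"], ev["trial_end"], "postsaccadic2"),
    ]
    segs, t = [], 0.0
    for t0, t1, epoch in bounds:
        t0 = max(t0, t)
        t1 = min(t1, ev["trial_end"])
        if t1 > t0:
            segs.append((t0, t1, epoch))
            t = t1
    return segs


def simulate_spikes(pop: PopulationModel, trials: list[TrialRecord],
                    space, seed: int = 0) -> list[TrialRecord]:
    """Draw spike trains for every (neuron, trial) from the piecewise-constant model.

    Each (neuron, trial) pair uses its own RNG stream derived from the master
    seed, so growing the population leaves existing spike trains unchanged.
    """
    missing = [e for e in ("target_on", "target_off", "saccade_onset",
                           "fixation2_acquired", "trial_end")
               for t in trials[:1] if e not in t.event_times]
    if missing:
        raise ValueError(f"trials are missing event times: {missing}")

    out = []
    for trial in trials:
        pre_xy = space.presaccade_positions[trial.pre_idx]
        post_xy = space.postsaccade_positions[trial.post_idx]
        dir_deg = float(space.directions_deg[trial.dir_idx])
        spikes: dict[int, np.ndarray] = {}
        for nid, neuron in enumerate(pop.neurons):
            rng = np.random.default_rng([seed, trial.trial_id, nid])
            times = []
            for t0, t1, epoch in _trial_segments(neuron, trial.event_times):
                rate = neuron.rate(epoch, pre_xy, post_xy, dir_deg)
                k = rng.poisson(rate * (t1 - t0) / 1000.0)
                if k:
                    times.append(rng.uniform(t0, t1, size=k))
            spikes[nid] = (np.sort(np.concatenate(times))
                           if times else np.empty(0, dtype=float))
        out.append(with_spikes(trial, spikes))
    return out


# ---------------------------------------------------------------------------
# I/O: spike tables (trial_id, neuron_id, time_ms) and population configs

def write_spike_table(trials: list[TrialRecord], path, meta: dict | None = None) -> None:
    rows = []
    for trial in trials:
        if trial.spikes is None:
            raise ValueError(f"trial {trial.trial_id} has no spikes")
        for nid in sorted(trial.spikes):
            for t in trial.spikes[nid]:
                rows.append((trial.trial_id, nid, t))
    df = pd.DataFrame(rows, columns=["trial_id", "neuron_id", "time_ms"])
    write_table(df, path, meta=meta, float_format="%.3f")


def read_spike_table(path, trials: list[TrialRecord], n_neurons: int) -> list[TrialRecord]:
    """Attach spikes from a spike table to trial records (all neurons present per trial)."""
    df = read_table(path)
    for col in ("trial_id", "neuron_id", "time_ms"):
        if col not in df.columns:
            raise ValueError(f"spike table is missing column: {col}")
    grouped: dict[int, dict[int, list[float]]] = {}
    for tid, nid, t in df.itertuples(index=False):
        grouped.setdefault(int(tid), {}).setdefault(int(nid), []).append(float(t))
    out = []
    for trial in trials:
        per = grouped.get(trial.trial_id, {})
        spikes = {nid: np.sort(np.array(per.get(nid, []), dtype=float))
                  for nid in range(n_neurons)}
        out.append(with_spikes(trial, spikes))
    return out


def population_to_yaml(pop: PopulationModel, path, meta: dict | None = None) -> None:
    write_yaml({"n": pop.n, "neurons": [dataclasses.asdict(nm) for nm in pop.neurons]},
               path, meta=meta)


def population_from_yaml(path) -> PopulationModel:
    doc = read_yaml(path)
    return PopulationModel([NeuronModel(**spec) for spec in doc["neurons"]])
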