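"""Oculomotor behavior space and delayed-memory-saccade session generation.

The task is a delayed memory saccade on a Cartesian grid: the subject fixates
one node of a 3x3 grid (8-deg spacing), a target flashes at one of the eight
neighboring nodes, the location is remembered through a jittered delay, and on
the go cue a saccade is made to the remembered node in darkness, landing on a
5x5 grid of possible postsaccade positions.  Presaccade position and saccade
direction are independent by design; the postsaccade position is their vector
sum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import read_table, write_table

#: Grid steps of the eight saccade directions, direction k at angle 45*k deg.
DIRECTION_STEPS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1),
)

#: Trial events in their required temporal order.
EVENT_ORDER: tuple[str, ...] = (
    "fixation_on",
    "fixation_acquired",
    "target_on",
    "target_off",
    "go_cue",
    "saccade_onset",
    "fixation1_acquired",
    "fixation2_acquired",
    "trial_end",
)

BEHAVIOR_NAMES = ("presaccade", "direction", "postsaccade")


@dataclass(frozen=True, eq=False)
class BehaviorSpace:
    """Enumeration of the discrete oculomotor behaviors of the grid task.

    Positions are stored both as integer lattice indices (exact arithmetic)
    and as coordinates in degrees, origin at the central node, x rightward,
    y upward.  Combos are ordered as ``pos_idx * n_directions + dir_idx``.
    """

    extent: int
    spacing: float
    presaccade_positions: np.ndarray  # (P, 2) deg
    directions_deg: np.ndarray        # (8,) angles
    displacements: np.ndarray         # (8, 2) deg
    postsaccade_positions: np.ndarray  # (Q, 2) deg
    combos: np.ndarray                # (P*8, 2) [pos_idx, dir_idx]
    compose_table: np.ndarray         # (P, 8) -> postsaccade index

    @property
    def n_presaccade(self) -> int:
        return len(self.presaccade_positions)

    @property
    def n_directions(self) -> int:
        return len(self.directions_deg)

    @property
    def n_postsaccade(self) -> int:
        return len(self.postsaccade_positions)

    @property
    def n_combos(self) -> int:
        return len(self.combos)

    def compose(self, pre_idx: int, dir_idx: int) -> int:
        """Postsaccade position index of the vector sum ``pre + displacement``."""
        return int(self.compose_table[pre_idx, dir_idx])

    def combo_index(self, pre_idx: int, dir_idx: int) -> int:
        return pre_idx * self.n_directions + dir_idx

    def combo_to_postsaccade(self) -> np.ndarray:
        """Postsaccade index of every combo, in combo order (length P*8)."""
        return self.compose_table[self.combos[:, 0], self.combos[:, 1]]

    def postsaccade_multiplicity(self) -> np.ndarray:
        """Number of (position, direction) combos composing to each postsaccade node."""
        return np.bincount(self.combo_to_postsaccade(), minlength=self.n_postsaccade)

    def chance_level(self, behavior: str) -> float:
        n = {
            "presaccade": self.n_presaccade,
            "direction": self.n_directions,
            "postsaccade": self.n_postsaccade,
        }[behavior]
        return 1.0 / n


def enumerate_behaviors(grid_extent: int = 3, spacing: float = 8.0) -> BehaviorSpace:
    """Enumerate positions, directions and their compositions for a grid task.

    Parameters
    ----------
    grid_extent
        Side length of the presaccade fixation grid (the task uses 3).
    spacing
        Grid spacing in degrees (the task uses 8).

    The postsaccade set is the set of positions actually reachable as a vector
    sum; for ``grid_extent >= 2`` this is the full (extent+2)^2 grid, while a
    single fixation node reaches only its 8 neighbors.
    """
    if grid_extent < 1:
        raise ValueError(f"grid_extent must be >= 1, got {grid_extent}")
    if not spacing > 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")

    e = int(grid_extent)
    offset = (e - 1) / 2.0
    # lattice indices (ix, iy); row-major over y then x
    pre_lattice = [(ix, iy) for iy in range(e) for ix in range(e)]
    pre_xy = np.array([[spacing * (ix - offset), spacing * (iy - offset)]
                       for ix, iy in pre_lattice])

    steps = np.array(DIRECTION_STEPS, dtype=int)
    directions_deg = np.arange(8) * 45.0
    displacements = steps * spacing

    # reachable postsaccade lattice points, in exact integer arithmetic
    reached = sorted({(ix + dx, iy + dy)
                      for ix, iy in pre_lattice for dx, dy in DIRECTION_STEPS},
                     key=lambda p: (p[1], p[0]))
    post_index = {p: i for i, p in enumerate(reached)}
    post_xy = np.array([[spacing * (ix - offset), spacing * (iy - offset)]
                        for ix, iy in reached])

    compose_table = np.empty((len(pre_lattice), 8), dtype=int)
    for p, (ix, iy) in enumerate(pre_lattice):
        for d, (dx, dy) in enumerate(DIRECTION_STEPS):
            compose_table[p, d] = post_index[(ix + dx, iy + dy)]

    combos = np.array([(p, d) for p in range(len(pre_lattice)) for d in range(8)],
                      dtype=int)
    return BehaviorSpace(
        extent=e,
        spacing=float(spacing),
        presaccade_positions=pre_xy,
        directions_deg=directions_deg,
        displacements=displacements,
        postsaccade_positions=post_xy,
        combos=combos,
        compose_table=compose_table,
    )


def compose_postsaccade(space: BehaviorSpace, pre_idx: int, dir_idx: int) -> np.ndarray:
    """Coordinates (deg) of the vector sum of a presaccade position and a direction."""
    return space.postsaccade_positions[space.compose(pre_idx, dir_idx)]


@dataclass
class TimingConfig:
    """Epoch durations of the task, in ms.

    Defaults follow the task schedule: 1000 ms fixation, 300 ms target flash,
    1300 +- 200 ms memory delay (uniform jitter), 500 ms fixation I in darkness
    and 500 ms fixation II with the fixation light on.  Reaction time is drawn
    from a truncated normal (the task prescribes none; ground-truth saccade
    onsets are stored with each trial).
    """

    fixation_ms: float = 1000.0
    target_ms: float = 300.0
    memory_ms: float = 1300.0
    memory_jitter_ms: float = 200.0
    fixation1_ms: float = 500.0
    fixation2_ms: float = 500.0
    acquire_ms: float = 200.0       # fixation_on -> fixation_acquired
    saccade_dur_ms: float = 40.0    # saccade_onset -> fixation1_acquired
    rt_mean_ms: float = 200.0
    rt_sd_ms: float = 30.0
    rt_min_ms: float = 80.0

    def __post_init__(self) -> None:
        for name in ("fixation_ms", "target_ms", "memory_ms", "fixation1_ms",
                     "fixation2_ms", "acquire_ms", "saccade_dur_ms",
                     "rt_mean_ms", "rt_sd_ms", "rt_min_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.memory_jitter_ms < 0 or self.memory_jitter_ms >= self.memory_ms:
            raise ValueError("memory_jitter_ms must lie in [0, memory_ms)")

    @property
    def memory_min_ms(self) -> float:
        return self.memory_ms - self.memory_jitter_ms

    @property
    def memory_max_ms(self) -> float:
        return self.memory_ms + self.memory_jitter_ms


@dataclass
class TrialRecord:
    """One correct trial: behavior labels, event times, and spike times.

    Event times are in ms on the trial clock (``fixation_on`` at 0) and must
    strictly increase in :data:`EVENT_ORDER`.  ``spikes`` maps neuron id to a
    sorted array of spike times; ``None`` until spikes are simulated/loaded.
    """

    trial_id: int
    pre_idx: int
    dir_idx: int
    post_idx: int
    event_times: dict[str, float]
    spikes: dict[int, np.ndarray] | None = None

    @property
    def combo_idx(self) -> int:
        return self.pre_idx * 8 + self.dir_idx

    def validate(self, space: BehaviorSpace | None = None) -> None:
        times = [self.event_times[e] for e in EVENT_ORDER]
        if not all(a < b for a, b in zip(times, times[1:])):
            raise ValueError(f"trial {self.trial_id}: event times not strictly increasing")
        if space is not None and self.post_idx != space.compose(self.pre_idx, self.dir_idx):
            raise ValueError(f"trial {self.trial_id}: postsaccade label is not the vector sum")
        if self.spikes is not None:
            end = self.event_times["trial_end"]
            for nid, ts in self.spikes.items():
                if len(ts) and (ts[0] < 0 or ts[-1] > end):
                    raise ValueError(
                        f"trial {self.trial_id}, neuron {nid}: spike outside [0, trial_end]")


def generate_session(
    space: BehaviorSpace,
    n_blocks: int,
    timing: TimingConfig | None = None,
    seed: int = 0,
) -> list[TrialRecord]:
    """Generate a randomized session of ``n_blocks`` blocks of correct trials.

    Within each block every (position, direction) combo occurs exactly once,
    in an independent seeded-random order per block; 11 blocks of the 3x3 grid
    give the session's 11 * 72 = 792 saccades.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    timing = timing or TimingConfig()
    rng = np.random.default_rng(seed)

    order = np.concatenate([rng.permutation(space.n_combos) for _ in range(n_blocks)])
    n = len(order)
    memory = rng.uniform(timing.memory_min_ms, timing.memory_max_ms, size=n)
    a = (timing.rt_min_ms - timing.rt_mean_ms) / timing.rt_sd_ms
    rts = truncnorm.rvs(a, np.inf, loc=timing.rt_mean_ms, scale=timing.rt_sd_ms,
                        size=n, random_state=rng)

    trials = []
    for t, combo in enumerate(order):
        pre_idx, dir_idx = space.combos[combo]
        ev: dict[str, float] = {}
        ev["fixation_on"] = 0.0
        ev["fixation_acquired"] = timing.acquire_ms
        ev["target_on"] = ev["fixation_acquired"] + timing.fixation_ms
        ev["target_off"] = ev["target_on"] + timing.target_ms
        ev["go_cue"] = ev["target_off"] + memory[t]
        ev["saccade_onset"] = ev["go_cue"] + rts[t]
        ev["fixation1_acquired"] = ev["saccade_onset"] + timing.saccade_dur_ms
        ev["fixation2_acquired"] = ev["fixation1_acquired"] + timing.fixation1_ms
        ev["trial_end"] = ev["fixation2_acquired"] + timing.fixation2_ms
        trial = TrialRecord(
            trial_id=t,
            pre_idx=int(pre_idx),
            dir_idx=int(dir_idx),
            post_idx=space.compose(int(pre_idx), int(dir_idx)),
            event_times=ev,
        )
        trials.append(trial)
    return trials


def combo_labels(trials: list[TrialRecord]) -> np.ndarray:
    """Joint (position, direction) behavior label of each trial, combo-indexed."""
    return np.array([t.combo_idx for t in trials], dtype=int)


# ---------------------------------------------------------------------------
# trial-table I/O (delimited text, one row per trial)

def trials_to_frame(trials: list[TrialRecord], space: BehaviorSpace) -> pd.DataFrame:
    rows = []
    for t in trials:
        pre = space.presaccade_positions[t.pre_idx]
        post = space.postsaccade_positions[t.post_idx]
        row = {
            "trial_id": t.trial_id,
            "pre_x": pre[0], "pre_y": pre[1],
            "dir_idx": t.dir_idx,
            "post_x": post[0], "post_y": post[1],
        }
        row.update({e: t.event_times[e] for e in EVENT_ORDER})
        rows.append(row)
    return pd.DataFrame(rows)


def write_trial_table(trials: list[TrialRecord], space: BehaviorSpace, path,
                      meta: dict | None = None) -> None:
    """Write a trial table: labels as grid coordinates plus one column per event (ms)."""
    write_table(trials_to_frame(trials, space), path, meta=meta, float_format="%.3f")


def read_trial_table(path, space: BehaviorSpace) -> list[TrialRecord]:
    """Read a trial table back into :class:`TrialRecord` objects (without spikes)."""
    df = read_table(path)
    required = ["trial_id", "pre_x", "pre_y", "dir_idx", "post_x", "post_y", *EVENT_ORDER]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")

    def lookup(xy_arr):
        return {(round(x, 3), round(y, 3)): i for i, (x, y) in enumerate(xy_arr)}

    pre_lut = lookup(space.presaccade_positions)
    trials = []
    for _, row in df.iterrows():
        key = (round(float(row.pre_x), 3), round(float(row.pre_y), 3))
        if key not in pre_lut:
            raise ValueError(f"trial {int(row.trial_id)}: pre ({key}) not on the grid")
        pre_idx = pre_lut[key]
        dir_idx = int(row.dir_idx)
        if not 0 <= dir_idx < space.n_directions:
            raise ValueError(f"trial {int(row.trial_id)}: dir_idx {dir_idx} out of range")
        trial = TrialRecord(
            trial_id=int(row.trial_id),
            pre_idx=pre_idx,
            dir_idx=dir_idx,
            post_idx=space.compose(pre_idx, dir_idx),
            event_times={e: float(row[e]) for e in EVENT_ORDER},
        )
        trial.validate(space)
        trials.append(trial)
    return trials


def with_spikes(trial: TrialRecord, spikes: dict[int, np.ndarray]) -> TrialRecord:
    return dataclasses.replace(trial, spikes=spikes)
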