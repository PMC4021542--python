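# Methods

## Task and behavior space

The simulated task is a delayed memory saccade on a Cartesian grid with
8-deg node spacing.  A trial fixates one of the 3×3 = 9 grid nodes for
1000 ms, flashes a target for 300 ms at one of the 8 neighboring nodes,
imposes a memory delay of 1300 ± 200 ms (uniform jitter), and upon the go
cue the saccade is executed in darkness, followed by 500 ms of fixation
without visual input (fixation I) and 500 ms with the fixation light on
(fixation II).  Only correct trials exist in the generator.  A session is
`n_blocks` independent random permutations of the 72 (position, direction)
combos (11 blocks → 792 trials), so the design is exactly balanced and the
task-defined prior over combos is uniform.

Coordinates are in degrees, origin at the central node, x rightward, y
upward; direction k (k = 0..7) points at 45·k deg, with displacement 8 deg
for cardinal and 8·√2 deg for diagonal saccades — the behavior label is the
8-way direction index only, not the amplitude.  Composition (postsaccade =
presaccade + displacement) is computed on an integer lattice, so the
vector-sum map is exact; the 5×5 postsaccade grid's corners are reachable
from exactly one combo and its center from 8.  For a hypothetical 1×1
presaccade grid the "postsaccade grid" is defined as the set of *reachable*
sums (the 8 neighbors), which equals the full (extent+2)² grid whenever the
presaccade grid has extent ≥ 2.

Event times the task does not constrain are generator choices: 200 ms to
acquire fixation, 40 ms saccade duration, and a reaction time drawn from a
truncated normal (mean 200 ms, SD 30 ms, floor 80 ms) — values in the range
typical of trained macaques.  Ground-truth saccade onsets are stored with
every trial, so no velocity-based detection enters the analysis (a simple
configurable speed-threshold detector, default 50 deg/s, is provided for
completeness only).

## Synthetic neurons

Each model neuron is an independent piecewise-constant-rate Poisson process

    rate = epoch_gain(e) · [baseline + depth · f(θ − θ_pref)] · g(x, y)

with `f` a von-Mises-shaped bell `exp(κ(cos Δ − 1))` (κ default 2; the
tuning family is a modeling choice — only "bell-shaped" is required of it),
and `g` a planar gain field `max(0, c₀ + cₓx + c_y y)`, the standard LIP
gain-field form.  Direction tuning is inactive before target onset (the
direction is unknown to the subject until the flash), and the gain field
reads the presaccade eye position up to the saccade and the postsaccade
position after it.  Default epoch gains — fixation 1.0, visual 2.5, memory
1.6, perisaccadic 2.0 (starting 80 ms before saccade onset), postsaccadic
1.8 then 1.2 — qualitatively reproduce a visual transient, sustained delay
activity, a presaccadic burst and a postsaccadic decay.  Rates are floored
at zero everywhere.

Each (neuron, trial) pair draws from its own RNG stream derived from the
master seed, so enlarging a population never perturbs existing spike
trains.  The generator deliberately omits noise correlations, refractory
periods, non-Poisson variability and continuous rate ramps: the decoder
under test assumes independent Poisson neurons, so passing tests show the
inference machinery is correct under its own assumptions, not that real
LIP data meet them.

Archetypes: `tuned` (preferred directions tiling [0, 360), seeded-random
baselines 5–15 spk/s, depths 20–40 spk/s, gain slopes ±0.02 /deg),
`untuned` (constant rate 10 spk/s across all behaviors and epochs — the
chance-level control), `duplicate-pair` (neuron 1 is an exact copy of
neuron 0's rate function, with independent spikes — the redundancy control),
and `custom`.

## Likelihoods and tuning fits

The population response is the vector of spike counts in a counting window.
Single-neuron models:

- Poisson: `p(r|b) = μ(b)^r e^{−μ(b)} / r!`, with μ(b) the sample-mean
  count over training trials of behavior b (one parameter per cell);
- truncated Gaussian: a Gaussian in r with sample mean and unbiased sample
  variance, renormalized by its continuous integral over [0, ∞) — in
  closed form, division by Φ(μ/σ) — evaluated at the integer counts.

Population log-likelihood is the sum over neurons (independence).  All
likelihood math is in log space (hundreds of neurons would underflow
otherwise).  Before evaluation, means are floored at 0.05 and variances at
0.25 (both configurable) so behaviors whose training counts are all zero
cannot produce log p = −∞; the raw fitted parameters are stored unfloored.

## Decoding

The posterior over the 72 combos is `p(b|r) ∝ p(r|b) p(b)`, normalized by
log-sum-exp.  Generalization is protected by leave-one-out
cross-validation: each trial is scored with tuning parameters fit on all
other trials (only the trial's own behavior column changes relative to the
full fit, which the implementation exploits; an (N, T, B) per-neuron
log-likelihood cube makes subset rescoring in RNE a single subtraction).

The prior is the task prior computed from occurrence counts over all trials
(`prior_mode="full"`, the default).  A per-fold variant that recomputes the
prior on the N−1 training trials is provided (`prior_mode="loo"`), but it
is not the default because down-weighting the held-out trial's own label
(n−1 vs n occurrences) systematically biases MAP decoding of uninformative
data *below* chance — the classic leave-one-out anti-bias — whereas the
task prior is exactly uniform by design.

Presaccade position and direction are read from the marginals of the joint
72-way posterior (`mode="joint"`, default); the postsaccade posterior sums
the joint mass over all (position, direction) pairs whose vector sum is the
same node, conserving probability exactly.  A `marginal` mode fits and
decodes the 9-way position and 8-way direction models separately; its
postsaccade posterior is formed from the outer product of the two marginals
(position and direction are independent by task design).

MAP estimates break exact posterior ties (relative tolerance 1e−12)
uniformly at random from a dedicated seeded stream.  The NPC for one
behavior variable is the unweighted mean over behaviors of the per-behavior
fraction of veridical estimates; its SEM is the SD over bootstrap resamples
of trials (uniform with replacement by default, stratified-by-behavior
optional; behaviors absent from a resample are dropped from that
resample's mean).

## Time courses, epoch RMS, onsets and peaks

Spike times are aligned to target onset or saccade onset and counted in
causal boxcar windows of 250 ms sliding in 10 ms steps, each count
timestamped at the window end (`[t−250, t)`, half-open), so the count at t
never includes spikes at or after t.  Windows extending beyond a trial's
bounds are counted from the spikes that exist and flagged, never padded.
The full decode pipeline runs independently at every step with one shared
set of bootstrap resamples across steps, so epoch statistics can be formed
per replicate.

Epoch accuracy is the RMS of the time course between the events bounding
the epoch (bounds intersected across trials when events jitter), i.e. the
area under the squared time course normalized by epoch length — comparable
across epochs of different durations.

Onsets and peaks: the trace is smoothed with a Gaussian kernel truncated to
a 250 ms window (SD 50 ms — the window length constrains the kernel support;
the SD within it is a package choice), renormalized at the edges.  At each
step the mean derivative over the following 100 ms minus the preceding
100 ms (central differences) is computed; the onset maximizes this
difference, the peak maximizes its negative.  A mark is reported only if
its score exceeds the (1 − α) quantile (α = 0.01) of the same statistic on
smoothed white-noise traces whose SD is estimated from the smoothing
residual via the MAD, corrected for the variance the linear smoother
removes and inflated by two sampling SDs of the MAD estimator — without
that guard, the sharp max-statistic turns the ~7% sampling noise of the
scale estimate into a several-fold inflation of false positives.  Flat
traces return absent marks with a reason code.  Smoothing SD, derivative
span, α and the null size are all configurable and recorded in outputs.

## Recursive Neuronal Elimination

The RNE objective is the mean over the three behaviors of the RMS of
per-window NPCs over the epoch that best mediates each behavior: memory for
direction, fixation for presaccade position, fixation II for postsaccade
position.  By default each epoch is sampled at 3 windows of 250 ms evenly
spaced within the trial-intersected epoch bounds (a fast mode standing in
for the full 10 ms-step time course, which is the pipeline's cost hotspot;
the window count is configurable).  At each iteration, every candidate
single-neuron removal is scored (cube subtraction, see above) and the
neuron whose removal leaves the maximum objective is eliminated; objective
ties go to the lower neuron id, making rankings deterministic given data
and seed.  One neuron is removed per iteration by default; `batch=k`
removes the k jointly-least-important by single-removal score (greedy, not
exhaustive — exhaustive subset search is combinatorial and out of scope).
The ranking orders neurons least→most important and records the objective
at every population size, giving the accuracy-vs-size curve; a
`min_trials` validator (default threshold 9 when used) enforces the
trials-per-behavior filter applied before pooling neurons.

Bias correction scales an empirical population's time course by
(optimized epoch accuracy / empirical epoch accuracy), clipping to
[chance, 1], and reports the factor.

## Problem sizes and numerical choices

Simulated study conditions follow the task: 11 blocks (792 trials) and
8-deg 3×3 grids everywhere the session itself is the object of study; the
demonstration population has 20 tuned neurons, the near-certain direction
prediction uses ~300 sharply tuned neurons (κ = 3, depth 40–80 spk/s over
baseline 3–8 spk/s, flat gain fields), and elimination examples use tens of
neurons with a minority informative, which suffices for the ordering and
saturation phenomena of interest.  Some property tests run shorter sessions
(2–6 blocks) or coarser step sizes, chosen so each check still has the
statistical power it needs.  Posterior normalization holds to 1e−9,
marginalization mass conservation to 1e−12, and on toy problems the
log-space pipeline agrees with directly evaluated Bayes' rule to 1e−10.

## Known limitations

- The synthetic generator's tuning families and epoch gains are fixture
  choices, not fitted to recordings; absolute NPC magnitudes on synthetic
  data are therefore not comparable to empirical values, only the
  structural behaviors (chance recovery, certainty at large N, ordering,
  timing) are.
- Independence is assumed both in generation and decoding; correlated
  variability is out of scope.
- `marginal`-mode postsaccade decoding relies on the independence of the
  two marginal posteriors and is not identical to joint-posterior
  marginalization.
- Onset estimates on smoothed traces can precede the true event by up to
  the kernel half-width when the underlying rise is step-like.
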