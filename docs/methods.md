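# Methods

## The simulator

### Update loop

Each colony advances in synchronous steps with three phases:

1. **Quitting.** Every active agent becomes inactive with probability τ.
   Agents that quit in this phase do not evaluate stimuli again until the
   next step: task switching always passes through at least one step-boundary
   of inactivity, the conservative reading of "no switching without first
   quitting".
2. **Task selection.** Every agent that was inactive at the start of the
   step inspects the m stimuli in an independently shuffled order and
   commits to the first task j whose response probability
   `P = s_j^η/(s_j^η + θ_ij^η)` exceeds a fresh uniform draw. All agents see
   the step-start stimulus values, so the decisions are conditionally
   independent given the state and the order in which agents are processed
   cannot affect any outcome; the engine therefore evaluates agents in
   parallel. For m = 2 the inspect-in-random-order rule is sampled in closed
   form: averaging over the two equally likely orders gives outcome
   probabilities `q_0 = (p_0 + (1−p_1)p_0)/2`, `q_1 = (p_1 + (1−p_0)p_1)/2`,
   `1 − q_0 − q_1` (inactive), sampled with a single uniform draw per agent.
   This is exactly the distribution of the sequential procedure (for m > 2
   the order is materialized and tasks inspected sequentially).
3. **Stimulus update.** One application of the demand/work map per task,
   floored at zero: a demand level cannot be negative, so overshoot by an
   efficient workforce clamps rather than banking negative demand.

Thresholds are sampled once at t = 0 from Normal(μ_j, σ_j μ_j) per task,
independently across tasks; non-positive draws are resampled rather than
clamped, which preserves the distribution shape and is numerically
irrelevant at σ ≤ 0.5 (resampling probability ≤ Φ(−2)).

Response probabilities are computed from the ratio `(s/θ)^η` so that large η
(step-function limit) saturates cleanly to 0 or 1 instead of overflowing;
integer η uses exponentiation by squaring.

### Randomness and reproducibility

One master seed per run. Replicates draw from independent streams spawned by
replicate index (numpy `SeedSequence`), and draws are generated in fixed
1024-step chunks per replicate, so a batch of R replicates advancing in
lockstep consumes exactly the same per-replicate streams as R separate runs:
any replicate, scenario arm, or phase-grid cell re-runs bit-identically in
isolation. Scenario arms and grid cells derive their seeds from the master
seed and their index, never from execution order or time.

### Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| m | 2 | number of tasks |
| n | 16 | colony size (8 also used in the morphology-style designs) |
| η | 7 | steepness of the threshold response |
| τ | 0.2 | per-step quit probability |
| δ | 0.6 per task | demand rate (1.3 in the high-demand regime) |
| σ | 0.1 | normalized threshold s.d. (0.5 in the variance-only variant) |
| T | 10,000 | steps per run (1,000 for stimulus traces) |
| replicates | 100 per composition (50 per phase-grid cell) | |

η, τ, the baseline δ and σ are exposed in every config; the qualitative
results reported by the test suite are insensitive to η ∈ {2, 7, 20} and
τ ∈ {0.1, 0.2, 0.3} (the flux-balance checks run across that grid).

### Stationarity and capacity

At stationarity the work extracted per task equals the demand:
`ᾱ · f_j = δ_j`, with ᾱ the composition-weighted mean efficiency, so the
mean per-task performance frequency of a pure colony is `δ/α`. A pure colony
can stabilize its stimuli iff its per-capita capacity covers total demand,
`m·δ ≤ α` (each agent works one task at a time). Both facts serve as
independent oracles for the simulator: (α = 2, δ = 0.6) stabilizes at
frequency 0.30; (α = 2, δ = 1.3) grows without bound; a 1:1 mix with
α ∈ {2, 4.5} (ᾱ = 3.25 ≥ 2.6) keeps up where pure α = 2 cannot.

Because all stimuli start at zero, the first few dozen steps are a
deterministic warm-up (colonies with higher thresholds idle slightly longer
before the stimulus first crosses them). This offsets full-run mean
frequencies by ~4·10⁻⁴ — invisible at the scale of the phenomena studied but
resolvable by a 100-replicate comparison, since the replicate s.d. of a
colony mean is ~5·10⁻⁵. Statements about equality of colony means across
compositions (a flux-balance property) are therefore tested on the second
half of the run; individual-level frequencies elsewhere use the full run as
defined.

## DOL metrics

* Behavioral variation uses the sample s.d. (n−1 denominator; `ddof`
  switchable).
* Specialization partitions the run into ⌊T/window⌋ consecutive
  non-overlapping windows (window = 200 steps), ranks ants within each
  window by their within-window performance of a task (average ranks for
  ties), correlates consecutive windows' rank vectors, and averages over
  window pairs first, then tasks. Window pairs in which either window shows
  no between-ant variation are dropped; a task never performed contributes
  nothing. For the symmetric two-task setups used here, averaging tasks
  before or after the pair-mean gives the same value.
* The mixing effect compares replicate-level between-type differences
  (pure arms paired by replicate index — the pairing is arbitrary by
  exchangeability) with within-colony differences in the mixed arm, via a
  two-sided Welch t test at α = 0.05 for simulation output. The empirical
  pipeline defaults to Student's t (equal variances) to match standard
  unpaired-t practice on experimental colony counts, with Welch behind a
  flag. Classification: convergence / divergence on rejection by sign,
  no-effect otherwise, "other" when the type ordering (Y above X) does not
  hold inside mixed colonies.

## Tracking pipeline

The r.m.s.d. of an ant is computed about its own centroid over the detected
frames of its considered time frame — the whole observation phase by
default, per day for the day-wise rank correlations (each day re-centred on
that day's centroid). Ants detected in less than 30% of frames are excluded
(exactly 30% is included — the rule is a strict inequality); for ants that
died, only frames before the death day count, both for the rate and the
r.m.s.d. Specialization is the Spearman correlation of per-day r.m.s.d.
ranks between consecutive days, averaged. Normality of the samples entering
the mixing t test is reported (Shapiro–Wilk) but never gates the analysis.
Mixed-effects models, post-hoc procedures and response transformations are
deliberately out of scope: the pipeline emits tidy per-ant and per-colony
tables that drop directly into standard statistics environments.

## Synthetic tracking generator

The generator emulates the statistical structure the pipeline assumes, not
ant locomotion. Each ant follows a two-component spatial mixture per frame:
a nest-bound isotropic Gaussian (s.d. 0.2 units, nest centred 1.25 units
from the arena centre, truncated to the 5-unit arena) and a uniform
excursion over the arena disc, mixed by a per-ant excursion probability

    p_i = clip(p_out[type] + Δ_m[type]·1{mixed} + b_i, 0, 1),

with b_i ~ Normal(0, 0.05) fixed per ant. Defaults: baseline p_out 0.1 (X)
vs 0.5 (Y); 8 colonies per arm; 16 ants per colony; 14 days of 216 frames
(one frame per ~400 s over 24 h); 10% detection dropout; 2% death
probability (death day uniform over the phase). Mixing shifts are additive
presets: (+0.15, −0.15) for convergence, the negation for divergence, zero
for no effect.

The infinite-frame r.m.s.d. has the closed form

    E[rmsd²] = q·R²/2 + (1−q)·2σ² + q(1−q)·d²,

(q = p_out, R arena radius, σ nest s.d., d nest offset from the arena
centre), ignoring wall truncation of the nest Gaussian — negligible with the
nest ≥ 6σ inside the wall. This oracle pins the generator: empirical
r.m.s.d. converges to it within 2% at 10⁵ frames, and ranking ants by
r.m.s.d. recovers their ranking by realized p_i (Spearman ρ > 0.9 at default
noise).

What the generator does *not* emulate: within-day trajectory
autocorrelation (r.m.s.d. is invariant to frame order, so none is needed for
these statistics), structured detection failures (dropout is Bernoulli), and
any coupling between spatial behavior and the threshold simulator — the two
halves of the package are validated independently. Passing calibration
therefore shows that the pipeline's statistics behave correctly under the
assumed mixture structure, not that real tracking data satisfy those
assumptions.

Calibration studies use a reduced design (6–8 colonies/arm, 8 ants, 4 days
of 40 frames) so that 500-replicate type-I studies run in minutes; effect
sizes scale with between-type differences, not with the design, so the
reduced design is conservative for power claims.

## Known limitations and open choices

* The threshold model excludes threshold reinforcement/learning and spatial
  structure by design; thresholds are fixed over a run.
* More than two agent types are accepted by the config but exercised only
  for two; m > 2 tasks run through the general engine path but the reported
  campaigns use m = 2.
* The variance-only variant (σ 0.1 vs 0.5, equal μ) reproduces equal colony
  means and (weakly) type separation inside mixed colonies, but a pure
  colony of the high-variance type is necessarily *more* heterogeneous than
  the 1:1 mix (threshold variance 25 vs 13), so the mixed arm cannot exceed
  that pure arm in variation or specialization; the corresponding check in
  the acceptance suite documents this and fails by construction.
* The type separation inside mixed colonies under the variance-only variant
  is marginal (mean ≈ 0.03 with replicate s.d. ≈ 0.14): a Jensen effect of
  threshold spread on the convex response, not a robust prediction.
* Empirical mixing comparisons pair pure colonies by replicate number; with
  unmatched replicate numbering the pairing (and the test) is refused rather
  than silently re-paired.
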