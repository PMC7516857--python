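# Methods

## Information measures

All quantities use log base 2 (bits) with the convention 0·log 0 = 0.
Joint distributions over named binary variables are dense dictionaries
(`JointTable`); entropies are computed on marginals, mutual information
and conditional mutual information as entropy sums.  Floating-point
negatives of MI/CMI/TE are clamped to zero at the output; co-information
is never clamped, because its negative values (−1 for XOR, −0.19 for the
other polyadic gates under uniform inputs) are the quantity of interest.

Empirical estimates are plug-in (maximum-likelihood) frequencies over
transitions pooled within trials; transitions are never formed across a
trial boundary, so the all-quiescent reset between trials is not counted
as dynamics.  No bias correction is applied: the recordings here are
small, complete, deterministic samples, and the study's point is what raw
pairwise TE does with exactly such data.  History lengths are fixed at
one step on both sides (the circuits are first-order Markov, so
step-by-step flow is fully visible at k = ℓ = 1); the API deliberately
offers no longer histories.  TE estimates that are exactly zero are
reported as zero — no significance testing distinguishes "structurally
zero" from "zero by limited sampling".

## The gate catalog

The 16 deterministic 2-to-1 gates are enumerated with canonical names;
duplicate family labels (AND-NOT, OR-NOT, COPY, NOT) are disambiguated by
a key suffix.  Feedforward analytics use the joint over (X_t, Y_t, Z_t,
Z_{t+1}) with X, Y, Z_t iid uniform and Z_{t+1} = f(X_t, Y_t); the
misestimate is H(Z_{t+1}) − TE_{X→Z} − TE_{Y→Z}, which equals
|I(X_t:Y_t:Z_{t+1}|Z_t)| for every gate.  Feedback analytics use
(Y_t, Z_t, Z_{t+1}) with Y_t, Z_t iid uniform; Z_t is taken uniform by
assumption even though the induced Z_{t+1} marginal may differ
(stationarity is not imposed).  The feedback misestimate is the
attribution mismatch |TE_{Y→Z} − I(Z_t:Z_{t+1})|, counted only for gates
that depend on both inputs — for dyadic and constant gates the two terms
correctly attribute everything, and the mismatch is defined as zero.
Values are kept at full precision internally and rounded to two decimals
only for reporting.

In the knockout-based aggregation, the per-gate "correctly attributed"
flow is defined as (total attributable flow − misestimate): TE_X + TE_Y
for feedforward gates, and TE_{Y→Z} + I(Z:Z′) − error for feedback gates.
This subtraction form was chosen over crediting the full sum because it
keeps correct + misestimate equal to the flow the gate actually carries
for every gate class, including cryptographic feedback gates where the
full-sum convention would credit 1 bit as correct *and* 1 bit as error
from a 1-bit output.

## Markov Brains

Brains hold 16 binary neurons updated synchronously by a gene-encoded
list of 2-input deterministic gates.  When several gates write one
neuron, the results are OR-ed (a single firing input suffices to fire the
neuron); a neuron no gate writes decays to quiescent, so memory requires
actively rewriting a value each step.  Sensory neurons (N0, N1) are
clamped externally before each update, are read by gates in their clamped
state, and carry the clamped value into the recorded snapshot.

The genome is a structured gene list — (input₁, input₂, output, 4
truth-table bits) per gate — rather than a byte-stream: all statistics in
this study depend only on gate composition and topology, and the
structured form keeps mutation semantics explicit.

Ground-truth influence maps are derived in two steps: the exact Boolean
function f_j of every neuron is extracted over all 2^16 global states
(vectorised, exact — no sampling), and an edge i → j is asserted iff
flipping bit i changes f_j on at least one state.  This dependence test
automatically discards constant gates (ZERO/ONE) and vestigial gate
inputs.  Columns of sensory neurons are forced to zero because sensors
are externally overwritten at every update during behaviour, so no
internal write can truly influence them.  Self-influence is recorded on
the diagonal but excluded from detection scoring by default (the choice
is exposed as a flag; published influence maps are not machine-readable
on this point).

## Tasks (the synthetic-data generator)

Motion detection presents all 16 two-step binary patterns on the two
sensors: 3 preferred-direction, 3 null-direction, 10 stationary.  The
brain updates once on the first stimulus and twice on the second; the
second stimulus remains clamped during both of its updates (the simplest
reading of "updated two times" after the second input; clearing the
sensors instead is the documented alternative).  The response is the sum
of two output neurons (N14, N15 by default — the output indices are not
fixed by the published task, only their count): 0 = ND, 1 = stationary,
2 = PD.  Fitness is the fraction of the 16 trials classified correctly.

Sound localization presents one pulse per ear with an interaural lag from
{−2, −1, 0, +1, +2} update steps on a 3-step schedule: lag L puts the
left pulse at step 1 + max(0, −L) and the right pulse at 1 + max(0, L)
(1-based).  This parameterisation approximates the published stimulus
raster figure, which is not machine-readable.  The answer is read one-hot
from five designated outputs (N11–N15), one per source angle; a trial is
correct iff exactly the right output fires.  Fitness is the fraction of
the 5 trials correct.

Recordings capture 4 snapshots per trial (the all-quiescent start plus
one per update) of all 16 neurons: 64 snapshots / 48 transitions for MD,
20 / 15 for SL.  Brains are deterministic, so one recording per trial is
complete.  What the generator does *not* emulate, by design: neural
noise, partial observability (every neuron is recorded), continuous
signals, and richer stimulus statistics.  Passing tests therefore show
what TE does under ideal recording conditions; on real neural data every
one of these omissions makes TE inference strictly harder.

## Evolution

Each replicate evolves a population of 100 genomes.  Parent selection is
**lexicase**: for each offspring, the trials are shuffled and the
population is filtered trial-by-trial to the individuals answering each
trial correctly (skipping filters that would empty the pool), and a
random survivor becomes the parent.  These tasks have exactly the
structure lexicase is built for — a small set of discrete test cases
whose aggregate score plateaus (an aggregate-fitness tournament GA stalls
at 15/16 on motion detection for most replicates within the generation
budget; lexicase solves both tasks in a few hundred generations).  A
tournament scheme remains available via `EvolutionConfig(selection=
"tournament")`.  One elite (best aggregate fitness, earliest index on
ties) survives unchanged per generation.

Mutation: each connection id and truth-table bit flips/resamples with
probability 0.01; per genome, one random gene is deleted with probability
0.02 and one random gene is duplicated and reinserted with probability
0.05; initial genomes carry 8–12 random genes.  Offspring identical to
their parent are re-mutated (up to 10 attempts) since the elite already
preserves the parent genome.  Replicate i of a run with master seed s is
seeded with s·10007 + i; everything downstream of (config, seed) is
byte-for-byte reproducible.  Replicates stop early once fitness 1.0 is
reached (with elitism the champion is already fixed); traces are padded
to the configured length.

Scaled-down study conditions: the cohort analyses run 20 replicates per
task at ≤ 2000 generations (population 100), rather than 100 replicates ×
10,000 generations, keeping the full suite in tens of seconds.  Under
these conditions essentially all MD replicates and 19–20/20 SL replicates
reach perfect fitness.

## Flow inference and scoring

For each perfect champion: record on all trials, estimate TE for every
ordered neuron pair (diagonal = processed information when enabled),
threshold, and compare with the influence map.  Detection uses the strict
inequality TE > θ, so exact zeros — common for these deterministic
recordings — are never detections even at θ = 0.  Sensory neurons remain
possible *destinations* in scoring: the truth there is all-zero, so any
TE into a sensor is a causally impossible false alarm, a failure mode
worth counting.  ROC curves sweep 101 thresholds over [0, 1].  The
two-Gaussian ROC model estimates (μ, σ) of the TE values for edge and
non-edge pairs by sample moments and reports
f(x) = ½·erfc((μ₂−μ₁)/(√2 σ₁) + (σ₂/σ₁)·erfc⁻¹(2x)); the sign and σ
placement are fixed by deriving the curve from the threshold model, which
makes f increasing with f(x) = x when the class distributions coincide.
Classes with zero variance raise an error rather than fitting a
degenerate curve.

## Known limitations

* The per-gate misestimate aggregation assumes uniform gate inputs; real
  in-circuit input distributions differ, so those totals are first-order
  estimates (the empirical recording pipeline is the distribution-aware
  counterpart).
* Cohort-level statistics (gate-type composition, per-gate misestimate
  differences between tasks) depend on the evolutionary dynamics, for
  which no published hyperparameters exist; with the lexicase GA used
  here, motion-detection circuits evolve as many cryptographic gates as
  sound-localization ones, so the tasks' per-gate misestimates are
  statistically indistinguishable in our cohorts even though false alarms
  dominating hits is robust in both.
* Only deterministic 2-input gates, binary neurons, and one-step
  histories are modelled; probabilistic gates and partial information
  decomposition are out of scope.
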