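# Methods

This note documents the models, parameter choices and numerical decisions
behind the pipeline, and what the synthetic-session tests do and do not
establish about real recordings.

## Data model and conventions

All times are absolute seconds from session start; delay-relative time is
`t − delay_start`, where `delay_start` is the moment the animal reaches the
delay barrier (the alignment point for all delay analyses, distinct from
the earlier entry into the delay zone). Every interval in the package is
half-open `[start, end)`, so adjacent bins and zone bouts tile without
double counting, and a spike exactly at an interval's end belongs to the
next one. A full session has four treadmill/delay conditions (on/10 s,
off/10 s, on/30 s, off/30 s) with 20 trials each, collected as 8 blocks of
10 trials (a shuffled order of the four conditions, repeated once).
Principal cells are units with whole-session mean rate in [0.1, 5] Hz; all
population analyses run on principal cells only.

## LFP analysis

Both detectors use zero-phase 3rd-order Butterworth filters (forward–
backward), chosen so filtering does not shift event times; the band edges
are 6–12 Hz (theta) and 150–250 Hz (ripples). The envelope is the
magnitude of the analytic signal. Threshold statistics (mean, SD) are
computed over the *entire* trace, sleep epochs included, so task-period
detections are referenced to the session-wide baseline; a consequence,
verified by test, is that detections are invariant to rescaling the trace.

Theta bouts: envelope > mean + 0.5 SD, then gaps ≤ 0.5 s joined, then runs
< 0.5 s discarded — the join deliberately precedes the duration filter, so
two short segments bridged by a brief gap survive as one bout. The
per-trial initial bout length is the time from delay onset to the end of
the bout containing the onset, and 0 when no bout spans the onset.

SWR "power" is implemented as the squared envelope by default; a smoothed
RMS variant is available (`power_mode="rms"`) since the choice is a
dialect, not a principle. Events need ≥ 50 ms above mean + 3 SD.

## Time-cell statistics

Rate maps use complete 150 ms bins only: a 10 s delay gives
floor(10/0.15) = 66 bins and the trailing 0.05 s is dropped. Smoothing is
a Gaussian (σ = 300 ms) truncated at ±3σ whose kernel is renormalized
per source bin at the edges, which makes smoothing exactly
mass-conserving (checked to 1e-9 against raw counts).

Stability is the median pairwise Pearson correlation over trials with at
least one delay spike; pairs where either smoothed vector has zero
variance are excluded rather than erroring. Eligibility requires strictly
more than 10 such trials per condition; conditions are analyzed
independently. The shuffle null circularly shifts **every** trial's delay
spike train by an independent uniform offset in [0.5 s, delay − 0.5 s]
each iteration — an equivalent exchangeable null to re-shifting one member
of each pair, with far simpler bookkeeping (the per-pair variant exists
behind `mode` for comparison). The significance rule is the add-one rank
p-value with ties counted against significance, so the test is exact and
conservative; its empirical type-I rate on homogeneous Poisson cells is
~5% (the acceptance calibration).

The persistence split operates on the trial-averaged profile (the
per-trial variant would confound rate sparseness with persistence): a time
cell is time-limited when any bin after the peak falls below 20% of peak,
persistent otherwise, with onset at the first bin reaching that level.
Boundary decisions throughout are strict: delay-active needs > 0.5 Hz,
high-theta trials need coverage > 0.8, a bin at exactly 20% of peak counts
as above-threshold for fields and onsets (≥) but a drop must be strictly
below.

## Phase precession

The circular–linear fit maximizes the mean resultant length of
`phase − 2π·a·x` over a slope grid of ±2 cycles per field at 0.01-cycle
resolution — wider slopes than ±2 cycles per traversal are not
physiologically interpretable and destabilize the fit. The correlation
coefficient is the circular–circular correlation between observed phases
and the fitted linear phase; significance is a position-permutation test
(vectorized, seeded), and precession requires p ≤ 0.05 *and* a negative
slope, which halves the false-positive rate relative to the two-sided
test alone. Cells need ≥ 10 in-field spikes pooled across a condition's
trials. Degenerate inputs (all phases equal) return ρ = 0, never
precessing.

## Assemblies

The detection pipeline is PCA→ICA: eigenvalues of the neuron correlation
matrix are compared with the Marčenko–Pastur upper edge (1 + √(n/T))²
(valid only when bins outnumber neurons — enforced), the z-matrix is
projected onto the K supra-bound components, and FastICA (deterministic
seed, up to 5 re-seeded retries on non-convergence) unmixes them. Weight
columns are normalized to unit length and sign-oriented so the
largest-magnitude entry is positive; assemblies are ordered by the
variance of their projected activations so output order is stable.
Membership uses weight > 1/√n, the equal-contribution benchmark on a
unit-norm vector; the threshold is a parameter because the literature
offers several variants.

Strength uses the quadratic form with the projector diagonal zeroed, so a
single neuron bursting alone contributes nothing; the literal un-zeroed
form (a squared projection, always ≥ 0) is available via
`zero_diagonal=False`. Both were verified bin-by-bin against a brute-force
double loop. Activation events are bins with R strictly above mean + 1 SD
of the analyzed condition.

## Population events, selectivity, errors

Population events slide a 200 ms window in 25 ms steps (the assembly bin
grid) and merge overlapping supra-threshold positions, which makes the
result invariant to the step size; a non-overlapping tiled mode exists
because the windowing dialect is a genuine open choice. Participation
requires ≥ 1 spike in-window and ≤ 1 spike in the preceding 100 ms;
"all neurons" is read as all principal cells of the session (denominator
n/5, strict >). Sessions need ≥ 20 principal cells, and ≥ 20 events in an
area for that area's event analyses.

Turn selectivity tests |S| (S = (L−R)/(L+R) on trial-averaged values)
against label permutations that preserve the left/right trial counts. The
absolute value restores left/right symmetry that a literally signed
top-5% rule would lose; the signed statistic is available via
`statistic="signed"`. Entities are excluded before testing: cells below
0.5 Hz in the region, assemblies active in fewer than 4 of 20 trials,
entities with both trial-averaged values zero (S undefined), or fewer
than 4 trials per turn direction. Stem-bin selectivity uses 10 cm bins of
the linearized stem position and skips bins with mean per-trial occupancy
below 0.5 s.

Error consistency averages R_diff over all m×n error–correct pairs per
cell (both-zero pairs excluded as undefined 0/0; cells with no valid pair
dropped) and compares, by paired t-test across delay-active cells, with
the average over m×n correct–correct pairs sampled without replacement
when the pool allows (with replacement otherwise, logged). Restricting to
delay-active cells keeps the statistic on cells whose delay rates are
measurable at all.

## Synthetic sessions

The generator emulates one recording day: two 120 s sleep epochs flanking
8 blocks × 10 trials, with per-trial zone occupancy (entry → delay →
stem → T → reward → return) on a fixed timeline (1.5 s entry run, 4 s stem
traversal — slow enough that every 10 cm stem bin clears the 0.5 s
occupancy rule — 1 s T zone, 5 s reward, 4 s return). Turns follow the
alternation rule with errors (default rate 0.1) producing repeats. The
sleep epochs are far shorter than a real recording's rest blocks; they
exist to carry ripples and to weight the whole-session envelope
statistics, and their length is a scale choice, not a claim about sleep.

Cell types: delay-inactive (baseline 0.25 Hz everywhere), time-limited
(Gaussian delay fields, centers uniform on (0.5, 5] s), persistently
active (sigmoid onset, default 4.7 s), untuned delay-active (1.5 Hz
through the delay), and the remainder maze-active. Field width defaults
to the growth rule σ = 0.3 + 0.2·center — late fields are wider — together
with trial-to-trial center jitter (SD 0.08 s per second of center time),
because without timing jitter wide smooth fields correlate across trials
just as well as early narrow ones and stability would not decline with
peak time as it should. Both features are qualitative-trend machinery:
quantitative peak/onset recovery tests disable them (fixed σ = 0.5 s,
no jitter), since a planted center that is itself fuzzy by construction
is not a recovery target. The persistent cell's sigmoid is positioned so
that its 20%-of-total-peak crossing (the downstream onset definition,
baseline included) lands exactly at the planted onset.

The LFP is 1/f-shaped noise (15 µV SD) plus an 8 Hz cosine gated by
planted theta bouts (60 µV, 50 ms cosine ramps) plus 180 Hz ripple bursts
(90 µV, 120 ms Hann-windowed) at sleep ripple times and at the coupled
fraction (default 0.6) of planted population bursts. Theta bouts come
from an alternating renewal process with 0.7 s-shifted exponential bout
and gap durations scaled to the per-condition coverage target (0.85
treadmill-on, 0.30 off) — the shift keeps single bouts above the
detector's minimum duration and gaps beyond its join threshold, so
detected coverage tracks the target within a few percentage points. The
off-condition gap statistics are generator choices, not fitted values.

Spikes are drawn by thinning an inhomogeneous Poisson rate per unit
(verified against Poisson count statistics), with planted phase
precession implemented as a multiplicative phase preference
(1 + 0.8·cos(θ − ψ(x))) whose preferred phase advances −0.8 cycles across
the field during treadmill-on theta. Assembly members additionally fire
two near-synchronous spikes (≤ 10 ms jitter) at planted pulse times in
rest periods; population bursts recruit a random 30% of units within a
150 ms window. Determinism: one master `SeedSequence` spawns named child
streams (trials, LFP, events, per-unit spiking), so enlarging the
population does not perturb the trial or LFP draws and a given seed
reproduces the session byte-for-byte.

What passing recovery tests show — and what they do not: the pipeline
recovers exactly the structures the generator plants (Poisson rate fields,
synchronous pulses, gated oscillations). Real recordings add spike-sorting
contamination, nonstationary rates, theta frequency drift, behavioral
covariates and overlapping assemblies, none of which are modeled; the
synthetic tests validate the statistics' calibration and the code paths,
not the biology.

## Known limitations

* The delay-area population-event detector also fires on genuine
  early-delay time-cell coactivation in synthetic sessions; planted
  burst/SWR coupling is therefore verified in the reward area, where no
  competing structure is planted.
* The ±1-bin peak-recovery guarantee is information-limited for wide
  fields: even an ideal estimator localizes a σ = 1.3 s field's peak to
  ±150 ms only ~half the time at these rates, which is why quantitative
  recovery uses the fixed 0.5 s width.
* Group-level statistics across sessions/animals (ANOVAs, KS tests on
  pooled distributions) are out of scope; the pipeline reports per-session
  results.
* No NWB adapter yet; the on-disk layout is plain CSV + raw float32 LFP.
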