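# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic-data experiments
do and do not establish about real recordings.

## Task model

The task is fixed: 2 preconditioning sessions of 12 sequential-pair
trials (A→B ×6, C→D ×6, blocked, no gap between the two 10-s cues, block
order alternating across days); 6 conditioning sessions of 6 rewarded B
and 6 unrewarded D trials in alternating 3-trial blocks, with reward
deliveries 1, 4 and 7 s into B; and one probe session of 3 rewarded B
reminders interleaved with 3 D trials, followed by 6 unrewarded A and 6
unrewarded C presentations, interleaved. Within-trial times are seconds
from trial start; every trial carries a 2-s pre-cue window and a 3-s
post-cue tail. Inter-trial intervals (3–6 min, compressible by
`iti_scale`) never enter the statistics — their only analytical role,
providing a quiet pre-cue baseline, is played by the pre-cue window, so
the schedule omits them rather than simulating minutes of empty time.
`check_structure` asserts the two structural facts the design rests on:
no reward ever occurs in a trial containing cue A, and A precedes B only
during preconditioning.

## Synthetic populations

Each neuron carries one of three archetype rate templates (all rates in
Hz, rectified at zero after summing components):

* **phasic** — baseline 6; transients with 50-ms latency and 200-ms
  exponential decay at cue onset and at each reward delivery, peak gain
  45. Across conditioning a linear trajectory moves transient mass from
  reward to onset: the onset weight rises from 0.2 to 1 while the reward
  weight falls from 1 to 0.2 (`trajectory_slope=0` freezes both at their
  midpoint — the ablation used for null calibration). Onset amplitudes
  are scaled by `generalization + coding`, where `generalization = 0.5`
  gives every cue a common response and the per-neuron coding strengths
  (`b_minus_d` for B, `a_minus_c` for A) add cue-specific value signal.
  During probe presentations of A only, a small sustained component
  (1 Hz per unit coding) models elevated firing throughout a cue whose
  predicted reward lies beyond its own offset.
* **sustained_excited** — baseline 15, +8 throughout any cue.
* **sustained_inhibited** — baseline 12, −7 throughout any cue.

Coding strengths are bivariate normal with mean (0.5, 0.5), SD
(0.8, 0.8) and correlation `rho` (default 0.6; 0 for null tests). No
population firing-rate magnitudes were available to copy, so these are
the package's own choices: a few-Hz dopaminergic baseline, burst peaks a
few tens of Hz above it, and across-neuron heterogeneity wide enough
that some neurons carry negative contrasts — the regime in which the
first-second contrasts at n ≈ 50 land near t ≈ 4–5, comparable to real
probe-test populations. Because single-trial spike counts add Poisson
noise to the latent coding strengths, the *observed* across-neuron
correlation between the B−D and A−C contrasts is attenuated below the
generative `rho` (≈0.45 observed for `rho = 0.6` under the defaults);
the recovery test therefore checks that the mean recovered r falls
within the sampling interval of the generative value rather than
expecting equality.

Spike trains are inhomogeneous Poisson, sampled by thinning against each
neuron-trial's rate bound; one generator stream in a fixed loop order
makes output byte-identical under a fixed seed. Waveform features give a
configurable fraction (8%) of phasic neurons wide waveforms (negative
half-width ≈ 560 ± 30 µs with a positive deflection) against a narrow
(≈260 µs) majority.

Behavior is per-trial food-cup occupancy (percent of cue time),
Beta-distributed with concentration 8 around phase-dependent means: 5%
base for all cues, B ramping linearly to 65% across conditioning, and A
reaching 30% at probe in proportion to a transfer parameter.

What the generator does **not** emulate: spike-sorting noise, electrode
drift, non-Poisson history dependence (refractoriness, bursts), session-
to-session unit turnover, or any aversive variant. Passing recovery
tests therefore shows the analysis chain is correct and well calibrated
under its own assumptions, not that real VTA data satisfy them.

## auROC normalization

For each 100-ms post-onset bin, test counts (that latency's bin on every
trial of the cue) are compared with baseline counts (all ten 100-ms bins
of the 1-s pre-onset window, pooled over the same trials). Both
multisets are jointly min–max normalized; a discrimination threshold
sweeps the grid i/100, i = 0…100; the hit and false-alarm rates are the
fractions of test and baseline bins *strictly above* each threshold
(ties at a grid value count as not-above); the curve is closed with
(0,0) and (1,1) and integrated trapezoidally. Conventions the procedure
description leaves open, fixed here: the baseline window is the 1 s
immediately before cue onset, pooled per cue; the quantity swept against
the hit rate is the false-alarm rate (an ROC cannot be built from a
false-*negative* rate, which we read as a slip of terminology); and when
the two count multisets induce identical curves — in particular when
they are equal, or when all pooled counts are equal — the area is the
diagonal's, returned as exactly 0.5. Bins are half-open, so a spike on a
boundary belongs to the later bin.

## Classification

The conditioning-phase classification matrix is the auROC trace over the
full 10-s cue-B window (100 bins), which contains both the cue and all
three reward deliveries. PCA mean-centers time bins but does not rescale
them (auROC values already share a scale); component signs are fixed by
making each component's largest-magnitude loading positive. Clustering
is agglomerative complete linkage on Euclidean distances over the first
3 component scores, cut at exactly k = 3 (no attempt is made to recover
a distance criterion; only the cluster count is specified). Archetype
labels come from cluster-mean traces: lowest full-window mean →
sustained-inhibited; of the rest, larger onset-minus-sustained transient
index → phasic. Exact ties on a deciding statistic raise an error rather
than resolving arbitrarily.

The waveform screen passes units with negative half-width > 450 µs *and*
a positive/negative deflection ratio above 0. Taken over magnitudes that
ratio would always be positive, so the package stores the trough as a
signed negative value and requires a genuinely positive maximal
deflection; zero or positive troughs are rejected as ill-formed. The
thresholds are configurable.

## Signals

The peak-migration measure is the per-neuron-session difference between
the mean auROC over the first 500 ms after B onset and over the first
500 ms after the *first* reward delivery (the earliest unambiguous
reward event), correlated with conditioning-session index across
neuron-sessions (each neuron-session is one unit of analysis, matching
how populations recorded across days are counted). Probe contrasts use
baseline-subtracted trial firing rates (Hz) in the first 1 s (phasic)
or the final 9 s (sustained) of the cue; an auROC-based variant is
available behind `measure="auroc"`. Paired t tests are two-sided with
df = n−1; correlations are Pearson with df = n−2; no multiple-testing
correction is applied (alpha 0.05 throughout). A contrast whose
per-neuron differences are all exactly zero returns t = 0, p = 1; zero
variance with a non-zero mean is an error. Behavior ANOVAs are ordinary
linear-model F tests: one-way across the four cues in preconditioning,
cue × session in conditioning, and cue × presentation-order at probe
(additive when a single subject leaves the interaction no residual df);
all-constant occupancy is flagged degenerate rather than tested.

## Agents

Time is discretized at 1 s with a complete-serial-compound
representation (state `X{i}` is second i of cue X); reward magnitude is
1 per delivery, arriving on the transition into the state whose second
contains it. The background/ITI state has its value pinned at zero and
is never learned, which encodes the assumption that cue onsets are
unpredictable after minutes-long, variable ITIs; the onset prediction
error is then `gamma * V(first cue state)`. The model-free agent is
tabular TD(0). The model-based agent was left open by design; the
implementation here learns incremental one-step transition estimates
(exponential moving average, the same alpha) during all phases — it
learns pure structure in preconditioning, where there is no reward —
plus per-state reward estimates, and evaluates cues by value iteration
(sweep tolerance 1e-12, fixed state order for bit reproducibility). It
is one illustrative member of the model-based class, not a mechanistic
claim. Both agents are fully deterministic; the dissociation
(model-free A−C ≡ 0, model-based A−C > 0, both B−D > 0) holds across
the tested alpha × gamma grid, and the TD trace stores pre-update
values so the Bellman identity is checked exactly.

## Problem sizes and numerical conventions

The recovery experiments run at the scales the analyses are designed
for: 300 neurons (100 per archetype) for archetype recovery; 52 phasic
neurons × 200 replicate populations for coding-correlation recovery and
its rho = 0 null; 50 neurons × 6 sessions (300 neuron-sessions) for the
migration signature with a 100-replicate frozen-trajectory null. Null
rejection rates are accepted within three binomial standard errors of
the nominal 0.05. Threshold grids are generated as exact integer ratios
(i/100) so independent implementations agree to 1e-12; auROC/clustering
equivalence is verified against brute-force re-implementations kept in
the test suite, never against the library code under test.

## Known limitations

* The generator's magnitudes are free parameters; conclusions about
  statistical power at other signal-to-noise regimes require re-running
  the recovery experiments at those settings.
* Attenuation means the recovered inferred-vs-cached correlation is a
  lower bound on the generative coupling; the package does not attempt
  disattenuation.
* Complete-linkage clustering is exactly reproduced only up to ties in
  merge distances; ties have measure zero for continuous scores but can
  occur on degenerate (e.g. duplicated) inputs.
* The behavior ANOVAs treat trials (and, when present, subjects) as
  exchangeable replicates; no mixed-effects structure is modeled.
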