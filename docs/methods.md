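# Methods

`eventseg` implements an end-to-end analysis of event segmentation under
temporal community structure: stimulus-sequence design on a 15-node
community graph, a generative simulator of scalp EEG and behavior with
known planted effects, and the ERP, decoding, predictive-classification and
pattern-similarity analyses that operate on such data. Because all inputs
are simulated, every analysis is validated by parameter recovery: the
simulator's ground truth is the reference against which the pipeline is
tested.

## The paradigm and its design mathematics

The stimulus graph has three 5-node communities arranged in a ring. Inner
nodes connect to all four community members; each community's two boundary
nodes carry the single edge to an adjacent community, and the two boundary
nodes of a community are not connected. The graph is degree-4 regular, so
local transition statistics cannot reveal community membership; only the
temporal clustering of a random walk can.

*Exposure* sequences are plain random walks (default 1,400 trials, one
stimulus per 1.25 s, 25% of trials rotated for the orientation cover task).
*Parsing* sequences (default 1,200 trials) alternate 15-trial pseudorandom
walks with 15-trial Hamiltonian paths. The pseudorandom walk forces a
community exit at the next boundary-node visit once nine consecutive
same-community stimuli have occurred; the counter starts fresh with each
walk block and resets on every community change. Hamiltonian paths are
drawn from a pool generated by randomized depth-first search, rooted at a
graph neighbor of the preceding walk's final node, so every junction is an
ordinary edge and every block contributes 15 fresh trials (a
`ham_origin="shared"` variant treats the walk's final node as the path's
origin instead; it yields shorter sequences and is off by default because
only the neighbor rule reproduces the 1,200-trial / 40+40-block layout).
Exhaustive enumeration shows Hamiltonian paths on this graph have *at
least* two between-community transitions (11,664 paths with exactly 2,
5,184 with 3 — a path that starts at a boundary node, or threads both
external edges of a community, re-enters it).

Per 200-trial block, one of the three community transitions is manipulated:
each of its boundary nodes swaps stimuli with a randomly chosen inner node
of its own community (bidirectional swap, partners fixed within the block),
and the three transitions cycle so each is manipulated twice over six
blocks. Transitions are labeled into the destination trial: within-community
steps are `nonboundary`; between-community steps are `novel_boundary` when
they cross the currently manipulated transition and `learned_boundary`
otherwise. Under this construction about 5.0% of all stimulus transitions
are novel (one third of all community transitions), close to the design
value of 4.59%; the residual reflects Hamiltonian paths averaging 2.31
rather than exactly 2 crossings.

The posttest presents each of the 15 stimuli as a cue four times, once with
each same-community member as target and a random other-community lure
(60 trials).

## The generative simulator

A session renders a labeled trial table into a continuous 64-channel scalp
(Biosemi-named extended 10-20 montage) + 4 EOG recording, in microvolts:

* **Background**: 1/f^β noise (β = 1, 10 µV RMS broadband), common-phase
  line noise (60 Hz, 1 µV).
* **Evoked component**: a Gaussian voltage bump (peak 350 ms, SD 50 ms)
  with a parietal spatial profile centered on Pz (Gaussian falloff,
  σ = 6 cm), scaled per condition (defaults: learned 5, novel 3,
  nonboundary 2 µV). The 250–450 ms analysis window covers the bump; its
  window-mean equals amplitude × 0.598 (the bump's window average).
* **Community templates**: each community has a fixed, posterior-weighted
  channel-gain pattern; each trial adds amplitude-modulated narrowband
  noise (5–7 Hz) through the gain pattern of the *displayed* stimulus's
  community (4 µV at unit gain). Narrowband noise rather than a sinusoid
  keeps wavelet tests non-degenerate.
* **Predictive mixing**: boundary-node trials additionally receive the
  *adjacent* community's template, scaled by α(run) = α₀ + α₁·run
  (clipped to [0, 1]; defaults α₀ = 0, α₁ = 0.25), applied from 250 ms
  after onset. `run` counts consecutive same-community trials before the
  boundary visit, so long dwells produce stronger predictive evidence.
* **Artifacts**: Poisson blinks (0.05 Hz, 120 µV on vertical EOG, coupled
  into frontal channels with a y-weighted profile) and rare per-trial
  spikes (p = 0.02, 350 µV, placed inside the analyzed 0–1 s span so the
  generator's log is recoverable by the epoch-level detector).

Behavior is simulated from the group means of the paradigm: parse
probabilities 18.3 / 19.0 / 14.0% and parse RTs 690 / 648 / 631 ms
(truncated normal, SD 150 ms, bounds 150–1,250 ms) for
novel/learned/nonboundary; rotation hit/false-alarm rates 0.85/0.15
(d′ ≈ 2.07) with boundary/nonboundary RTs 676/665 ms; posttest accuracy
65.6%. Both response modes are supported (respond-every-trial and
parse-only). Neural effect sizes have no published anchors; they were set
once, at design time, to be recoverable at the small simulated samples the
test-suite uses, and are ground-truth knobs rather than estimates of real
effect sizes. Passing recovery tests therefore demonstrates correctness of
the analysis code under the simulator's assumptions (linear superposition,
stationary 1/f noise, community-level spectral codes), not fidelity to
human EEG: real data have non-stationary artifacts, correlated noise,
individual montage geometry and far weaker, item-heterogeneous effects.

## Preprocessing

Band-pass 0.5–200 Hz (FIR; the high cutoff clips below Nyquist with a
warning at low sampling rates) plus a 60 Hz notch and harmonics. Ocular
cleaning decomposes the scalp channels with FastICA, correlates every
component with every EOG channel, z-scores the correlation distribution per
EOG channel and zeroes components with |z| > 3 before reconstruction (note
that with k components the largest attainable |z| of one outlier is
(k−1)/√k, so the rule needs ≳11 components to be able to fire). Manual
artifact-interval marking is replaced by the automatic detector below.

Epochs span −100 to 1,000 ms around onsets (inclusive endpoints on the time
axis); all analysis windows, including the baseline, are closed on the left
and open on the right in samples (baseline [−100, 0) ms). Epochs are
rejected when any channel's peak-to-peak range within a sliding 200 ms
window (50 ms steps; a final partial window counts if at least half the
window remains) exceeds ±250 µV.

Spectral power uses Morlet wavelets with 4 cycles at 30 log-spaced
frequencies from 4 to 100 Hz; each epoch is mirror-reflected before and
after itself, transformed, and the buffers discarded; power is log₁₀
transformed. Features are z-scored per channel × frequency across retained
epochs, using the epoch-level (time-averaged) mean and SD; time-resolved
features reuse those epoch-level statistics for every sample so that
within-epoch evoked dynamics survive standardization. Rejected epochs are
excluded before the statistics are computed.

## Statistical analyses

**ERP.** The parietal measure is the mean preprocessed voltage at Pz over
[250, 450) ms (an identical code path serves the [50, 250) ms early
window). Group statistics: repeated-measures ANOVA over the three
conditions plus pairwise paired t tests; Pearson correlation between
participant-level Δamplitude and Δparse-probability difference scores; and
a seeded permutation test for r(novel) − r(learned) in which each
permutation independently swaps, per participant, which condition's
(Δamplitude, Δparse) pair is labeled novel — the scheme is this package's
construction, documented rather than asserted to match any particular
published variant.

**PCA feature selection.** Missing feature cells are imputed from a
Gaussian with the feature's observed mean and SD; PCA retains components
with eigenvalue strictly greater than 1 (Kaiser, on standardized features).
Loading topographies combine retained components *weighted by explained
variance* (a design choice: the unweighted signed mean over ~150 retained
components is dominated by sign-indeterminate minor components and washes
out real structure at small samples; the dominant components carry both the
structure and a deterministic sign convention). Unweighted and
absolute-value variants are flags. Electrode and frequency profiles are
tested against zero with one-sample t tests under Benjamini–Hochberg FDR
(q < 0.05); electrodes aggregate into hemisphere × anterior/posterior ROIs
by montage coordinates (x sign → hemisphere, y sign → anterior/posterior,
midline excluded) for a 2×2 repeated-measures ANOVA.

**Decoding.** L2-penalized logistic regression over eight log-spaced
regularization strengths λ ∈ [10⁻⁴, 10⁴] (C = 1/λ); reported AUC is the
mean over penalties; cross-validation is leave-one-trial-out. Classifiers
use balanced class weights: without them the fold-dependent class prior
biases the intercept against the held-out trial's class and drags null AUC
below chance at small n. By default imputation + PCA are refit inside each
training fold (`pooled_pca=True` reproduces the simpler fit-once pipeline;
the default passes a leakage guard in which duplicating trials must not
lift null AUC). Feature importance uses the activation-pattern transform
A = Σₓw/σ_y² (feature covariance × weights / variance of the linear
outputs, with matching degrees of freedom), projected to channel ×
frequency space through the PC loadings and aggregated into bands
(theta 5–7, alpha 9–10, beta 17–21, gamma 45–80 Hz) × ROIs.

**Predictive decoding.** For each of the three community rotations,
classifiers are trained on unmanipulated inner-node trials of two
communities and tested on the held-out community's boundary-node trials
(excluding visits where the same boundary node occurred within the previous
two trials), labeled by the adjacent trained community. Training and
testing happen independently within each 100 ms window (50 ms steps) on
window-averaged time-resolved features; a whole-epoch decoder uses features
averaged over the full 0–1 s presentation span (the mean of the window AUC
timecourse is also reported, since "averaged across the presentation
interval" admits both readings). Controls: testing on pre-boundary
inner-node trials of the held-out community, and training on permuted
labels. The early/late contrast median-splits boundary test trials by
preceding run length (ties to early) and computes per-group AUC from the
pooled cross-rotation scores. Window significance is a one-sided
across-participant t test vs 0.5 per window with BH-FDR.

**Pattern similarity.** Pairs of inner-node epochs within a Hamiltonian
block at lag 3, with no parse response anywhere in the closed span
(`parse_rule="endpoints"` implements the looser reading), classified as
novel/learned/nonboundary by the intervening transition labels. Similarity
is the Pearson correlation over retained PC scores, Fisher r-to-z
transformed (|r| = 1 clipped to 1 − 10⁻¹⁰ and logged), averaged within
condition, compared across participants by RM-ANOVA and paired t tests.
The boundary-item analysis compares epochs of the two true boundary nodes
of a transition (learned–learned) with epochs of a true boundary node vs
the swapped-in inner stimulus at the other boundary position
(learned–novel), using the mean pairwise Fisher-z across epoch pairs.

**Behavior.** d′ uses the log-linear correction (add 0.5 to every cell)
unconditionally, so perfect performance is finite and the estimator is
continuous; d′ is antisymmetric under swapping hits and false alarms.
Posttest percent correct is tested against 50% with a Wilcoxon signed-rank
test. Experiment-style response modes are pooled, with the mode retained as
a column.

## Problem sizes and runtime choices

The default pipeline configuration runs 4 simulated participants × 450
parsing trials at 250 Hz with 30 frequencies — a few minutes on one CPU.
The test suite uses smaller sizes chosen for determinism and runtime, not
for fidelity: sequence ensembles of 100 × 1,200 trials; P300 recovery at
4 participants × 300 trials/condition (tolerance ±0.5 µV); template
topography at 4 participants × 150 trials with the full 30-frequency axis;
predictive-onset localization at 8 participants × 240 trials, 125 Hz,
10 frequencies to 30 Hz (tolerance ±100 ms around the planted 250 ms
onset — wavelet temporal smoothing at theta, σ ≈ 106 ms, genuinely blurs
the onset); decoder null calibration at 20 × 300 trials; null FDR
calibration and the early/late power check at 8 simulated participants
(at 4 participants the across-participant t machinery is miscalibrated —
the discreteness of small-sample AUC occasionally yields near-identical
values and enormous t statistics — and paired power is far below its
target; 8 is still well under the paradigm's N = 34); the similarity power
check at 4 participants, where the many pairs per participant already give
precise condition means. Power
checks for the early/late and similarity contrasts run on score- and
feature-level simulations drawn from the same planted-effect model rather
than full EEG synthesis, which keeps 200-replicate power estimation
tractable; the full signal path from voltage to statistics is exercised by
the parameter-recovery tests.

## Numerical conventions and degenerate inputs

All randomness flows from explicit seeds through NumPy `SeedSequence`
spawning; two runs with the same configuration produce identical tables.
Trial indexing is 0-based internally. Zero-variance features raise with the
offending channel and frequency named; imputation of an all-missing feature
raises; AUC groups with fewer than 3 trials or one class return NaN and are
logged; rotations without usable test trials are skipped and logged;
|r| = 1 is clipped before the Fisher transform. The Kaiser rule falls back
to the single dominant component if no eigenvalue exceeds 1 (degenerate
inputs only). Continuous recordings are saved as `.npz` arrays with a JSON
sidecar describing channels, units, sampling rate and the generative ground
truth; events are tab-separated text.

## Known limitations

No forward head model (channel gains are geometric, not biophysical); no
eye-movement kinematics beyond blink templates; community templates are
stationary within session; the simulator's novel/learned multivariate
contrast arises only through the evoked-amplitude difference and the
swapped display identity, so out of the box the novel-vs-learned decoder is
only weakly above chance at small trial counts, mirroring the modest effect
the analysis is designed to detect; real-data ingestion (EGI name map) is
provided but untested against actual recordings.
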