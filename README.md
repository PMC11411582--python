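# eventseg

Analysis pipeline for event segmentation under **temporal community
structure**: how people come to parse a continuous stimulus stream into
events after statistically learning which items cluster together, and how
scalp EEG distinguishes *learned* event boundaries (transitions consistent
with the learned graph) from *novel* ones (transitions created by swapping
boundary and inner stimuli).

The package is aimed at cognitive/EEG researchers who want a tested,
fully simulatable implementation of this paradigm's sequence design and
analysis chain. It provides:

- **`graph_sequences`** — the 15-node, 3-community ring graph (degree-4
  regular; inner vs boundary node roles), exposure random walks,
  parsing-phase pseudorandom walks (forced community exit after nine
  within-community stimuli) alternating with Hamiltonian paths, the
  boundary-swap manipulation schedule, transition labeling
  (novel/learned/nonboundary), and the 60-trial forced-choice posttest.
- **`synthetic`** — a generative simulator producing 64-channel EEG + EOG
  with planted effects (condition-dependent P300-like deflection at Pz,
  posterior-theta community templates, run-length-scaled predictive mixing
  of the adjacent community at boundary nodes, 1/f noise, line noise,
  blinks, spikes) and behavioral responses, with full ground-truth logging.
- **`preprocessing`** — filtering, ICA-based ocular removal (|z| > 3 EOG
  correlation rule), epoching with baseline correction, sliding-window
  ±250 µV artifact rejection, Morlet wavelet log-power (4 cycles, 30
  log-spaced frequencies 4–100 Hz, mirrored buffers), per-feature z-scoring.
- **`erp`**, **`multivariate`**, **`pattern_similarity`**, **`behavior`** —
  window amplitudes and condition contrasts; Kaiser-criterion PCA feature
  selection and loading topographies; penalty-swept L2 logistic decoding
  with leave-one-trial-out AUC and activation-pattern (covariance-based)
  feature importance A = Σₓw/σ²_y; sliding-window cross-community
  predictive decoding with early/late, pre-boundary and permuted-label
  controls; lag-matched Fisher-z pattern similarity; d′, parsing and
  posttest statistics.
- **`pipeline`** / `eventseg` CLI — config-driven simulate → preprocess →
  analyze → report orchestration with a run manifest and deterministic
  outputs.

## Worked example

```python
import numpy as np
from eventseg import graph_sequences as gs, synthetic as syn
from eventseg import preprocessing as pp, erp, multivariate as mv

graph = gs.build_graph(seed=3)
trials = gs.build_parsing_sequence(graph, seed=11)   # 1,200 parsing trials
print(trials["transition_label"].value_counts(normalize=True).round(3))

spec = syn.GenerativeSpec()                     # planted-effect ground truth
sess = syn.simulate_session(trials, spec, seed=7, graph=graph)

epochs = pp.epoch_and_baseline(sess.data, sess.sfreq, sess.onsets,
                               sess.ch_names, metadata=sess.trials)
scalp = [epochs.ch_names.index(c) for c in sess.ch_names[:64]]
epochs.data, epochs.ch_names = epochs.data[:, scalp, :], sess.ch_names[:64]
pp.reject_artifacts(epochs)
retained = epochs.retained()
print(erp.condition_means(retained).round(2))

power = pp.spectral_power(retained, decim=4)
z = pp.zscore_features(power)
pred = mv.predictive_decode(z, graph)
print(f"predictive AUC {pred.whole_epoch_auc:.3f}")
el = mv.early_late_split(pred.trial_table)
print({k: round(v, 3) for k, v in el.items()})
```

Output (seed-exact; a few minutes on one CPU):

```
transition_label
nonboundary         0.839
learned_boundary    0.104
novel_boundary      0.056
                    0.001
Name: proportion, dtype: float64
transition_label
learned_boundary    3.52
nonboundary         1.46
novel_boundary      1.63
Name: amplitude, dtype: float64
predictive AUC 0.915
{'median': 5.0, 'early': 0.913, 'late': 0.927}
```

Reading the numbers: about 5.6% of transitions are manipulated (novel)
boundaries and 10.4% are learned boundaries (the unlabeled 0.1% is the
first trial, which has no incoming transition); the Pz 250–450 ms window
mean is largest for learned boundaries, as planted (values are attenuated
from the planted peak amplitudes by the window average of the evoked bump
plus residual noise); classifiers trained on inner nodes of two communities
recognize the adjacent community's signature in held-out boundary-node
epochs (AUC 0.92 vs 0.5 chance), slightly more so for boundaries reached
after long same-community runs (late 0.93 vs early 0.91 — at this
session's strong default mixing most boundary trials are near the
saturation of the run-length weighting, so the split is compressed).

The full pipeline, with behavioral simulation, PCA topographies,
novel-vs-learned decoding and pattern similarity, runs from a config:

```bash
eventseg --seed 7 --outdir results/demo all
```

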