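# ecogwaves

Analysis pipeline for sensorimotor rhythms in multichannel cortical-surface
(ECoG) recordings, together with a synthetic-data generator that provides
ground truth for every stage. The package covers:

- **Spectral decomposition** (`ecogwaves.spectral`) — irregular-resampling
  auto-spectral analysis (IRASA) separating each electrode's power spectrum
  into a fractal (1/f, arrhythmic) and an oscillatory component;
  sum-of-Gaussians parameterization of individual alpha/beta bands; the
  30–50 Hz log-log fractal slope as an excitation/inhibition index; and
  broadband 60–120 Hz power taken from the fractal component.
- **Electrode localization** (`ecogwaves.selection`) — restriction to
  stimulation-positive electrodes, 99%-confidence-bound local maxima per
  spectral feature, chi-squared category tests, and overlap/separation
  statistics.
- **Band dynamics** (`ecogwaves.dynamics`) — sliding-window (1 s Hann,
  50 ms step) time-frequency transforms, session-offset correction,
  bootstrapped percent-change baseline normalization, duration
  equalization, and 1-D cluster-based sign-flip permutation tests.
- **Traveling waves** (`ecogwaves.waves`) — zero-phase Butterworth band
  filtering, analytic-signal phase, principal-axes planar projection,
  circular phase gradients on a regular grid, phase-gradient directionality
  (PGD), propagation direction/speed, time- and electrode-shuffle nulls,
  directional consistency, Rayleigh tests, direction-distribution KL
  divergence, and relative phase maps.
- **Feature similarity** (`ecogwaves.similarity`) — per-trial temporal /
  spatial / spatiotemporal correlations between features, trial-by-trial
  representational similarity matrices with second-order Spearman
  correlation, and one-sample group inference with JZS Bayes factors.
- **Behavior** (`ecogwaves.behavior`) — sine-law psychometric fits of
  grasp-choice data, 50% switch points, and high/low demand labeling.
- **Synthetic ECoG** (`ecogwaves.synthetic`) — 1/f^χ backgrounds,
  narrowband traveling oscillations with exact planar phase-lag fields,
  condition-dependent amplitude modulation, broadband 60–120 Hz
  co-modulation, trial/session structure, and sine-law behavioral
  responses; all parameters recorded in a round-trippable ground-truth
  JSON.

Datasets are exchanged as plain EDF (a minimal reader/writer ships in
`ecogwaves.edf`), tab-separated electrode/event/behavior tables, and JSON.

## CLI

```bash
ecogwaves run-all --seed 1 --output-dir results/run1     # simulate + analyze
ecogwaves simulate --seed 1 --output-dir results/sim     # dataset only
ecogwaves decompose|select|dynamics|waves|similarity|behavior ...
ecogwaves run-all --config my_config.yaml                # YAML overrides
```

Each subcommand runs the stages it needs (simulating a dataset when no
input paths are configured). Output tables carry the config hash and seed
as a comment header; re-running with the same config and seed reproduces
them bit-for-bit.

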