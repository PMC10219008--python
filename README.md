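# modsense

Simulated psychophysics and neurophysiology of amplitude-modulation (AM)
sensitivity in layered sound-recognition networks.

## The scientific problem

Human hearing detects sinusoidal amplitude modulation with a sensitivity that
depends jointly on the AM rate, the carrier bandwidth and the stimulus
duration: the temporal modulation transfer function (TMTF) is low-pass for
broadband carriers and high-pass for narrowband ones. Why did this pattern
emerge, and which stations of the auditory pathway carry the representation
it relies on? One way to study this is to optimize a model for a task the
auditory system plausibly evolved for — recognizing natural sounds — and then
run the *same experiments on the model* that psychophysicists run on people
and neurophysiologists run on animals.

`modsense` implements this paradigm end to end at desk scale:

1. **Recognizer** — a fully convolutional network over raw waveforms; each
   layer is a dilated 1-D convolution plus an ELU, with receptive field
   `1 + Σ (kᵢ − 1)·dᵢ` constrained to a 0.2 s input window. Training uses
   Adam on softmax cross-entropy at a single output time step, with early
   stopping; architecture search samples filter sizes and dilations under
   the receptive-field constraint.
2. **Psychophysics** — x-interval forced-choice AM detection on the frozen
   layers: per trial, x noise carriers with exactly one modulated by
   `(1 + 10^{m/20} sin(2πf t + φ))·C(t)`. A logistic regression over
   time-averaged unit activities (4-fold outer CV, inner CV for the L2
   strength) or a template dot-product names the modulated interval. The
   proportion correct per depth (128 trials, constant-stimulus method) is
   fitted with an asymmetric sigmoid `ψ(m) = γ + (1−γ)(1+e^{−(m−α)/β})^{−λ}`;
   the threshold is the depth at `ψ = 0.707`, clipped to the tested range
   when the curve never crosses it.
3. **Comparison** — model vs. human TMTFs pooled over six stimulus
   conditions × eight log-spaced rates: pattern similarity (Pearson r),
   discrepancy (RMS deviation, dB) and net difference (signed mean, dB),
   with `discrepancy² = net² + var` as an exact identity.
4. **Neurophysiology** — AM tuning per unit from fully modulated noise
   probes: rate coding (time-averaged activity) and synchrony coding
   (vector strength), summarized by best and upper-cutoff rates; layers map
   onto auditory brain regions (AN → … → AC) by `1 − KS distance` between
   characteristic-rate distributions.
5. **Synthetic corpora** — labeled sound sets whose categories differ in
   their modulation spectra and carrier tilts, plus Env/TFS "chimera"
   degradations (envelope preserved with noise fine structure, or fine
   structure preserved with flattened envelope, full-band or per ERB band)
   for asking which natural sound statistics matter.

Everything runs from synthetic data; adapters for real everyday-sound and
phone-labelled speech corpora are provided but optional.

## Worked example

```python
from modsense.pipeline import RunConfig, run_experiment

out = run_experiment(RunConfig(out_dir="runs/demo", seed=7, n_trials=16))
print((out / "recognition.json").read_text())
```

prints (seed 7):

```
{"validation_accuracy": 0.9722222222222222, "chance_level": 0.3333333333333333, "early_stop_accuracy": 1.0}
```

— the 3-layer, 32-unit recognizer classifies the 3-category synthetic AM
corpus at 97% against a 33% chance level. The run directory also contains
`tmtf.csv` (per-layer detection thresholds), `similarity.json` (pooled
pattern-similarity / discrepancy / net-difference per layer against the
bundled synthetic human-like reference), `tuning.csv` and
`region_similarity.csv` (simulated neurophysiology and the layer × region
map). The same stages are available individually from the `modsense` CLI
(`synth-corpus`, `degrade`, `stimgen`, `train`, `eval`, `tmtf`, `compare`,
`neurophys`, `run`).

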