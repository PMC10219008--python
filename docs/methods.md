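# Methods

This note documents the models, procedures and parameter choices behind
`modsense`, what the synthetic data do and do not emulate, and the numerical
decisions a user extending the package should know about.

## The recognizer

The model is a feedforward stack of 1-D dilated convolutions along time,
each followed by an exponential linear unit (ELU, α = 1), applied directly
to the raw waveform (no fixed cochlear front end). A classification layer —
a convolution with filter size one — sits on top and is excluded from every
psychophysical and neurophysiological analysis. All convolutions are
"valid" (no padding, stride 1), so a layer's output loses
`(filter_size − 1) × dilation` samples relative to its input and the
network's receptive field is `RF = 1 + Σᵢ (kᵢ − 1)·dᵢ`.

**Architecture space.** Layer counts 7/9/11/13; 32–512 units per layer
(uniform across layers); filter sizes 2–8 and dilations sampled per layer
under the constraint `RF ≤ 0.2 s × sample rate`. The sampler draws each
dilation uniformly up to the largest value that leaves every remaining layer
at least dilation one, so the constraint holds by construction rather than
by rejection. Four published 13-layer reference architectures for the
44.1 kHz everyday-sound recognizer ship as fixtures; all satisfy
`RF ≤ 8820` samples.

**Training.** Weights start fan-in-scaled uniform
(`±√(6/(C·k))`, variance-preserving so deep stacks neither decay nor blow
up), biases at zero; this initial state is the "nonoptimized model". The
loss is softmax cross-entropy at a single output time step: each training
example is a randomly positioned window exactly one receptive field long,
so the topmost convolution emits one frame. Adam (default learning rate
1e−4; the toy presets use 3e−3, appropriate for their much smaller scale)
updates weights and biases; each clip's amplitude is jittered by a uniform
±6 dB gain during training only. One epoch is a pass over the update split
(`windows_per_clip` windows per clip); after each epoch, whole-clip accuracy
on the early-stopping split is measured, and training stops when it has not
improved for `patience_epochs` epochs, restoring the best epoch's
parameters. Evaluation classifies a clip (or a labeled segment span) by the
argmax of the time-averaged classification output. The two-step
architecture search trains all candidates with a small patience, ranks
layer counts by the mean accuracy of each count's four best models, then
retrains the winning count's candidates with a larger patience and keeps
the four best.

After training, models are frozen: the simulated experiments only read
activations, and the tests verify a parameter checksum is unchanged.

**Implementation.** The network, backpropagation and Adam are written in
numpy (einsum contractions over strided views). At the scales this package
targets — a few layers, tens of units, sub-second clips — this trains in
about two CPU-minutes, and gradients are verified against finite differences
in the development history.

## Stimuli

AM is applied as `y(t) = (1 + a·sin(2πft + φ))·C(t)` with
`a = 10^{m/20} ∈ (0, 1]`; `m = 0 dB` is full modulation and `m = −∞`
an unmodulated carrier. Six conditions are built in, differing in carrier
bandwidth (2, 3, 31, 314 Hz around a configurable center, or broadband),
duration (0.5–2 s), AM starting phase (fixed zero vs. uniform random per
stimulus), and processing order: the 314 Hz condition bandpasses *after*
modulation (sidebands outside the carrier band are removed), the other
narrowband conditions before; the short broadband condition equalizes RMS
*before* modulation, so its power grows with depth by the analytic factor
`1 + a²/2`, while all others are rescaled to the target RMS after
modulation. Every stimulus gets 10 ms raised-cosine ramps; in
equalize-after conditions the final RMS equals the target exactly (scaling
happens after ramping). Carriers are fresh Gaussian noise per stimulus.

The per-condition AM rate ranges (eight rates, evenly log-spaced) and the
5 kHz default narrowband center frequency are editable defaults chosen to
span the ranges used in the classical human experiments; nothing downstream
depends on their exact values. Depths run −60…0 dB in the 2 Hz-bandwidth
condition and −40…0 dB elsewhere, in 4 dB steps.

## AM-detection simulation

Trials are x-interval forced choice (2 or 3 intervals by condition), exactly
one interval modulated, independent carriers per interval; chance is `1/x`.

*Logistic detector:* features are each unit's time-averaged activity over
the stimulus. 128 trials per (rate, depth) are split into 4 outer folds
(trials, not stimuli, are the CV unit, so a trial's intervals never
straddle folds). Per fold, features are standardized by training-fold
statistics and an L2-regularized logistic regression is fitted, with the
regularization strength selected by an inner 4-fold CV over 13 values
log-spaced 10⁻³…10³ (ties resolve to the stronger regularization). Class
weights are not rebalanced across the (x−1):1 interval label imbalance.
The response is the interval with the maximum modulated-probability; exact
ties break uniformly at random (seeded).

*Template detector:* the template is the mean unit × time activity over 128
fully modulated stimuli minus the mean over 128 unmodulated ones; the
decision variable is the non-normalized correlation (dot product) between a
stimulus's activity and the template.

*Psychometric fit:* the proportion correct per depth is fitted by least
squares with the asymmetric (Richards-type) sigmoid
`ψ(m) = γ + (1−γ)(1 + e^{−(m−α)/β})^{−λ}`, γ pinned at `1/x`, β, λ > 0,
multi-start over α/β/λ grids. The exponent is clipped at ±500 to avoid
overflow far from the transition. The threshold is the depth where ψ
crosses 0.707 (bisection); if ψ sits entirely above (below) the criterion
over the tested range, the threshold is clipped to the range minimum
(maximum) and flagged, which keeps uninformative conditions in the pooled
comparison instead of silently inflating similarity. A detector is trained
independently per (layer, condition, rate, depth); nothing is shared across
depths.

## TMTF comparison

Human references are tables (condition, subject, rate, threshold).
Subject averaging interpolates linearly in log₂(rate); target rates outside
a subject's span are clamped to the endpoint value and flagged rather than
extrapolated. Model TMTFs average the same way across models. The three
pooled indices over all conditions × rates are Pearson correlation
(pattern similarity), RMS deviation in dB (discrepancy) and signed mean
deviation in dB (net difference; positive = model less sensitive). Pooling
is unweighted, and `discrepancy² = net² + var(differences)` holds to 1e−9.
Per-layer correlations between recognition accuracy and each index use
Pearson r with Bonferroni correction over layers; degenerate variance is
reported as missing rather than zero.

Because no table of human thresholds is available as text, the bundled
reference (`data/synthetic_human_tmtf.csv`) is **synthetic**: three
pseudo-subjects per condition with low-pass-shaped broadband TMTFs and
high-pass-shaped narrowband ones plus seeded inter-subject scatter, one
subject deliberately sampled at off-grid rates to exercise interpolation.
It is a format fixture and demo reference, not human data; real references
can be supplied in the same CSV schema.

## Simulated neurophysiology

Probes are fully modulated (0 dB) broadband noise, independent carriers per
repeat (default 10; the toy pipeline uses fewer). Rate tuning is the
time-averaged activity per AM rate; synchrony tuning is the vector strength
`VS(f) = |Σ a(t)e^{−i2πft}| / Σ a(t)` of the activity after subtracting its
minimum (ELU activities can be negative; the shift is the minimal
nonnegativity fix — vector strength is the field's standard synchrony
measure, chosen here as a convention). Best rate is the argmax (ties to
the lowest rate). The upper cutoff is the highest rate at which the
baseline-shifted curve stays within −3 dB (0.707×) of its peak,
interpolated linearly in log₂(rate); −3 dB is the conventional criterion
for "starts to decrease". Curves whose peak-to-floor contrast is below
1.2 (relative range below 0.2 of the peak magnitude) are marked untuned and
excluded from distributions.

Layer–region similarity is `1 − KS distance` between the layer's and the
region's distribution of a characteristic rate (best/cutoff × rate/sync
coding), averaged over the characteristics available on both sides. The KS
statistic is rank-based, hence identical on log or linear rate axes. The
bundled region table (`data/synthetic_region_tuning.csv`) is likewise
**synthetic**: 25 log-normal samples per region × characteristic with the
canonical periphery-to-center trend (synchrony tuned to high rates in AN/CN,
low rates in MGB/AC; rate tuning sharpening centrally). Literature samples
can be substituted in the same schema.

## Synthetic corpora

Each category is a modulation-spectrum bump (Gaussian on the log₂-rate
axis: center, width in octaves, depth) plus a carrier spectral tilt
(dB/octave re 1 kHz). A clip draws a fresh tilted-noise carrier and a fresh
modulator from the bump, forms `carrier × max(1 + depth·mod, 0)`, adds a
small noise floor, high-passes at 20 Hz, ramps and scales to unit RMS.
Clips are generated at unit RMS so the ELU nonlinearities operate in their
curved region; psychophysical stimuli for models trained on these corpora
use the same target RMS (matching the convention of scaling stimuli to the
training-set RMS). Per-clip generators are spawned from the corpus seed, so
corpora are byte-reproducible and clips regenerable in isolation. Splits
are per-category 0.6/0.2/0.2 into update/early-stop/validation.

The default corpus is 10 categories × 40 × 1 s at 16 kHz. The toy preset
used by the end-to-end demo is 3 categories × 60 × 0.5 s at 8 kHz with
modulation centers 8/32/128 Hz and tilts −10/0/+10 dB per octave — chosen
so the categories are separable by both AM statistics and spectrum, the way
natural sound categories are, while a 3-layer model trains in minutes.

What the generator emulates: category-discriminative modulation spectra and
carrier spectra with within-category stochastic variability. What it does
not: harmonic structure, transients and onsets, semantic or phonetic
content, multi-source mixtures, reverberation. Passing tests therefore
demonstrate that the machinery — optimization, detectors, fitting, tuning,
mapping — behaves correctly and that AM statistics in training data shape
AM sensitivity directionally; they do not certify quantitative agreement
with human TMTFs, which requires real corpora and full-scale training.

## Env/TFS degradations

Envelope and temporal fine structure are the magnitude and phase of the
Hilbert analytic signal, computed on the whole clip (no framing; edge
effects are excluded from measurement windows in tests). The four chimeras
follow the standard constructions: `env1` keeps the full-band envelope on a
white-noise fine structure of matched RMS; `tfs1` keeps the fine structure
under a flattened envelope `RMS(Env)`; `envN`/`tfsN` apply the same per
band of an ERB-spaced filterbank and sum. One property worth knowing: the
chimera product `Env·e^{iTFS'}` is not an analytic signal, so the Hilbert
envelope *re-measured* from a chimera deviates from the imposed envelope
(e.g. flattened-envelope signals re-acquire a coefficient of variation of
roughly 0.35 on broadband material, versus about 0.94 intact). The
constructions themselves are exact and tested as such; corpus-level tests
assert strong attenuation or preservation rather than perfection.

The filterbank places center frequencies every one ERB (Glasberg–Moore,
`ERB(f) = 24.7(4.37f/1000 + 1)`) from 20 Hz up to the Nyquist frequency —
42 bands at 22.05 kHz Nyquist, 33 at 8 kHz — with brick-wall FFT band edges
at ERB-scale midpoints between centers. Brick-wall partitioning is a design
choice (the degradation equations require the bands to sum exactly back to
the signal, which this guarantees to machine precision); gammatone or FIR
realizations are out of scope. Each rFFT bin belongs to exactly one band
(half-open intervals, the top band taking the Nyquist bin).

## Pipeline and reproducibility

`run_experiment` chains corpus → training → per-layer TMTFs → reference
comparison → tuning → region mapping, failing fast on configuration errors
(e.g. a missing reference CSV) before any compute. The global seed fans out
to per-stage seeds via seed sequences, recorded in `stage_seeds.json`; the
same configuration reproduces every artifact byte for byte. Every stochastic
operation in the package takes an explicit seed or generator; corpus- and
trial-level seeds derive deterministically from their parents.

Problem sizes in the shipped presets (3-layer/32-unit model, 16 trials per
depth in the demo TMTF, 2 probe repeats) are the package's desk-scale
defaults; all of them are plain config fields, and the full-scale values
(13 layers, 128 trials, 10 repeats) are the documented defaults of the
corresponding functions.

## Known limitations

- Paper-scale results (real-corpus recognition accuracies, the layerwise
  similarity profile peaking near the 10th layer) require external datasets
  and long training runs and are out of scope by design.
- The logistic detector's inner CV selects among only 13 regularization
  values; detection near threshold can be sensitive to this grid at small
  trial counts.
- The asymmetric-sigmoid parameterization and the synchrony/cutoff
  conventions are standard choices, not uniquely determined by the
  procedure being simulated; both are isolated behind small functions
  (`fit_psychometric`, `vector_strength`, `best_and_cutoff`) for easy
  substitution.
- Unmodulated catch stimuli reuse the modulated pipeline with the modulator
  disabled; there is no internal-noise model, so a deterministic observer's
  psychometric slope reflects only carrier and phase variability.
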