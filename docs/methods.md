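# Methods

This note documents the models and procedures implemented in `eegmotion`,
the defaults that matter, and the design choices made where the design was
genuinely open.

## Signal model and preprocessing

A recording is a `channels × samples` matrix of scalp amplitudes in
microvolts with a sampling rate `fs` and an optional emotion-class label.
Preprocessing is a per-channel running median of odd width `w` (default 3,
`preprocessing.window`), with replicate edge padding by default.  Width 3
is the smallest impulse-rejecting window and distorts oscillatory EEG the
least; the filter is deliberately 1-D — channels are never mixed, since
median filtering across electrodes has no physiological justification.
Band-pass filtering, re-referencing and ICA artifact removal are out of
scope.

## Feature extraction

All spectral descriptors share one convention: one-sided DFT of the
rectangular-windowed segment, power = magnitude², DC bin excluded from
flatness, decrease and roll-off (DC carries no oscillatory information and
would otherwise dominate ratio statistics).  Natural logarithms are used
throughout.

The layout (`FeatureLayout`) fixes every block length.  Defaults: each of
the C channels is cut into 2 equal frames for the framed descriptors
(flatness, decrease, roll-off → 2C values each, channel-major then frame);
log band power uses one 0.5–45 Hz band per channel (C values); the Haar
block is the multi-level orthonormal approximation of the channel-averaged
signal at the smallest level L ≥ 1 whose approximation is ≤ 64
coefficients, truncated/zero-padded to exactly 64; the fluctuation index
(mean |successive difference|, per channel then averaged) and the relative
alpha-band (8–13 Hz) energy of the channel-averaged signal contribute one
scalar each.  With C = 40 the blocks are 64/80/40/1/80/80/1 = 346
features.  The roll-off fraction defaults to 0.85, the conventional choice
for this descriptor.

Useful invariants (all tested): flatness and relative energy lie in [0,1];
roll-off lies in [0, fs/2]; scaling the signal by c > 0 leaves flatness,
decrease, roll-off and relative energy unchanged, shifts each log band
power by exactly 2·ln c, and scales the fluctuation index by c.

## Augmentation

Augmentation operates on signals, not on feature vectors: each trial gets
`copies` (default 1) noisy replicas with iid Gaussian noise of per-channel
standard deviation RMS/10^(SNR/20) (default SNR 20 dB), and features are
re-extracted, so a replica's descriptors move coherently the way a
genuinely noisier trial's would.  Replicas inherit the label and carry a
group id pointing at their source trial; every evaluation split is
group-aware, so augmentation can never leak near-duplicates across the
train/test boundary.

## Classifier

The deep maxout network computes, per layer and unit,
`max_p (x·W[:,j,p] + b[j,p])`; the final layer's raw scores are compared
to one-hot targets (no softmax — the training fitness is squared error,
and prediction is the argmax with ties to the lower class index).
Parameters live in an exact bijection with a flat vector (layer-major,
weights before biases, piece-major), which is the space the optimizer
searches.

Two estimator-level choices matter in practice and are our own design:

* **Input scaling.**  The optimizer initializes weights uniformly on
  (−1, 1).  With d standardized features a random first layer then
  produces activations of scale √(d/3), which puts the initial population
  at squared errors in the thousands and wastes the whole search budget on
  shrinking norms.  The estimator therefore divides inputs by √d
  (`input_scaling="sqrt_dim"`), making random-init activations O(1); this
  is the metaheuristic analogue of fan-in-scaled initialization.
* **Restart committee.**  The search is stochastic and, on small corpora,
  its solutions vary run to run.  `n_restarts` independently seeded runs
  can be trained and their class scores averaged at prediction time —
  plain variance reduction; each member is a complete network trained by
  the same procedure.  The library default is 1 (a single network); the
  end-to-end experiment profile uses 3.

The architecture default at the estimator level is two hidden maxout
layers (32, 16) with 2 pieces.  The end-to-end experiment profile instead
uses a single maxout layer (no hidden layers): with 346 input features the
deep default would put ~23,000 parameters into the search space, an order
of magnitude beyond what a population of 20 with a few thousand fitness
evaluations can shape, whereas the single layer's ~2,800 parameters are in
the regime the optimizer handles well.  Depth remains available through
configuration.

## FASSO optimizer

The population holds Z flat vectors ("branches", default Z = 20) with
cached fitness (mean squared error over all sample × class entries).  Each
generation: sort by fitness; deal members round-robin by rank into
`n_communities` communities (default 4), so each community spans the whole
fitness range; for each member pick a strictly better community member
("horse", uniform among eligible, self if none) and a strictly worse one
("sheep"); form a candidate with the hybrid closed-form update

    Y_new = [r0·Y_best·(1 − r·S) − (δ·r∘Y_c + β·r∘Y_d)·(1 − r0)] / (r0 − r·S),

with S = δ + β, one scalar draw r0 and one random vector r shared by the δ
and β terms; replace the member only on strict fitness improvement.  The
three coefficients sum to 1, so the move is a per-coordinate affine
recombination of best, horse and sheep — contraction toward the incumbent
best with occasional overshoot, which is what gives the method both
convergence and exploration.  β decays linearly β0·(1 − φ/ϖ) (default
β0 = 0.5) and δ grows linearly δ0 + (δmax − δ0)·φ/ϖ (defaults 0.5 → 1.0)
over the fixed budget of ϖ generations (library default 200; the
experiment profile uses 1,000).

Numerical care: coordinates where |r0 − r·S| < `guard_eps` (default 1e−8)
get r redrawn (up to 10 times), then fall back to the self-evolution
operator `(1 − r)·Y_i + r·Y_best` at those coordinates, so the output is
always finite.  Degenerate identities hold exactly: δ = β = 0 returns
Y_best, and Y_c = Y_d = Y_best returns Y_best for any draws.  Termination
is the fixed generation budget; best-so-far fitness is non-increasing by
construction, and a run is a pure function of its seed.

## Evaluation

Metrics derive from the K×K confusion matrix via one-vs-rest counts per
class: accuracy (Tp+Tn)/(Tp+Tn+Fp+Fn), sensitivity Tp/(Tp+Fn),
specificity Tn/(Tn+Fp).  Headline values are unweighted (macro) class
means — classes whose ratio has a zero denominator are excluded — with the
plain micro accuracy (trace/total) always reported alongside, because for
balanced K-class data macro one-vs-rest accuracy has a chance level of
1 − (K−1)/K·(K−1)/K·… ≈ 0.625 at K = 4 while micro accuracy's chance level
is 1/K; readers should compare each against its own baseline.  Protocols:
stratified train-percentage split (default 70%) and stratified K-fold
(default 5), both seeded, both operating on source-trial groups.

## Synthetic corpus

The generator emulates the *shape* of benchmark affective-EEG corpora
(40-channel trials at 128 Hz, a few seconds, one label per trial) and
encodes class identity purely in band power: each class has a normalized
power profile over delta/theta/alpha/beta/gamma (defaults dominate a
different rhythm per class with weight 0.8), each channel is a sum of 3
random-frequency, random-phase sinusoids per band realizing that profile,
plus 1/f background noise at 10% relative RMS and optional isolated
±100 µV single-sample impulses (Poisson, default rate 0) for exercising
the median filter.  Defaults: 4 classes × 40 trials.  Because every
implemented feature is spectral or energetic, band-power coding guarantees
the pipeline's features — not a waveform shortcut — carry the class
signal; two classes with disjoint dominant bands separate by more than 3
pooled standard deviations in their band-energy features.

What passing on this corpus does **not** show: robustness to real EEG
nonstationarity, inter-subject variability, volume-conduction correlation
structure, eye/muscle artifacts beyond isolated impulses, or class
structure encoded in anything other than band power.  Results on synthetic
data are evidence that the implementation is correct and that the method
works when its assumptions hold, not evidence about any real corpus.

## Problem sizes

Defaults are chosen for single-CPU desk scale: the default end-to-end
experiment (160 trials → 320 augmented rows, single-layer maxout, 3
restarts × 1,000 generations × 20 branches) completes in about a minute;
the augmentation-doubling demonstration (1,280 one-second trials → 2,560
rows) in one to two minutes; the sphere convergence benchmark (10 seeds ×
200 generations) in seconds.

## Known limitations

* The printed-dimension layout (64/80/40/1/80/80/1) sums to 346; reports
  of a 347-column matrix for this feature set are off by one and no filler
  column is invented.
* MSE fitness on raw scores is not a calibrated probability model; scores
  are comparable only through the argmax.
* The metaheuristic's sample efficiency degrades sharply beyond a few
  thousand parameters; gradient training is deliberately out of scope.
* 16-class generation is available but the default five-rhythm profile
  cycling then reuses dominant bands, so classes are no longer pairwise
  separable by band power alone.
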