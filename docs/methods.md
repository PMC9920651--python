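# Methods

This note records the modelling assumptions, numerical choices and
deliberate reconstructions behind `ecgtcn`, in the order a reader would
meet them: architecture, parameter accounting, augmentation, data
handling, the synthetic generator, training, and evaluation.

## Architecture

The classifier is a temporal convolutional network: residual blocks of
dilated causal 1D convolutions over a fixed-length (140-sample),
single-channel beat.  Design points that were genuinely open and how
they were resolved:

- **Convolution taps.** The convolution uses `k` taps indexed
  `j = 0..k-1`.  This is the reading consistent with the unpadded
  output length `n - k + 1` and with the weight count
  `K_T · F_Tp · F_T`; a `j = 0..k` sum would imply `k + 1` taps and
  break both.
- **Causal padding.** Each convolution left-pads with `(k-1)·d` zeros,
  generalizing the undilated `k-1` so that length is preserved at every
  dilation — required for the residual addition to be well-typed.
- **Layer normalization axis.** Statistics are computed across
  *channels only*, per sample and per time step, with learnable
  per-channel scale and offset (`2·F_T` parameters, matching the
  accounting formula) and epsilon 1e-5.  Normalizing over channels and
  time jointly would also be defensible; channel-only was chosen and is
  asserted by the parameter tests.
- **Block order and ReLU placement.** Within a block:
  conv → norm → spatial dropout → conv → norm → ReLU → spatial
  dropout, then the skip addition, with no activation after the
  addition.  The single ReLU after the second normalization follows the
  block description; whether it precedes or follows the residual
  addition is not externally fixed — placing it before keeps the skip
  path free of nonlinearities, which is the stated purpose of the skip
  connection.  The order is a documented package choice, not a claim
  about the original authors' code.
- **Spatial dropout** removes whole feature channels with probability
  0.3 during training only; surviving channels are rescaled by
  `1/(1-p)`.
- **Classification head.** The dense head reads the feature vector at
  the *final time step* (the only choice consistent with the recovered
  head parameter count `F_T·5 + 5`, and sufficient because the
  four-block receptive field of the headline configuration, 167
  samples, covers the whole 140-sample input).  Global average pooling
  is available (`head="avg"`) but is not the default.
- **Receptive field formulas.** `receptive_field_paper` implements the
  printed stack formula `R = 2^l (k-1)` verbatim, and
  `receptive_field_layer` the per-layer `R = d(k-1)`.  The printed
  stack formula omits the `+1` of standard receptive-field arithmetic
  and the two-convolutions-per-block structure, so
  `measure_receptive_field` — a perturbation sweep over input
  positions — is the ground truth for any instantiated model and also
  doubles as an exact causality check.
- **Initialization.** Convolutions use zero-mean normal weights with
  variance `2/fan_in`; the head uses a uniform Glorot range.  All
  randomness flows from one user-supplied seed.

The engine (`ecgtcn.nn`) is a small hand-written numpy implementation
with explicit forward/backward passes per layer and an Adam optimizer;
gradients are verified against central finite differences in the
development workflow and the convolution against a brute-force double
loop in the test suite.

## Parameter accounting

`total_param_count` sums, per block, two convolutions
(`K_T·F_Tp·F_T + F_T`; the first convolution of the first block has
`F_Tp` = input channels) and two normalizations (`2·F_T`), plus the
dense head (`F_T·C + C`).  Two conventions are exposed:

- `include_skip=False, include_head=True` (default): excludes the 1×1
  skip projection.  This is the unique convention that reproduces all
  ten distinct published per-architecture totals exactly, and is
  therefore inferred — not stated anywhere in the source material — to
  be the convention behind them.  It is flagged as a reconstruction.
- `include_skip=True`: counts the deployed network honestly; the test
  suite asserts this equals the instantiated model's parameter count,
  and that the difference is exactly the first block's `F_T + F_T`
  projection weights and biases.

Display rounding divides by 1000, rounds half-up to one decimal and
strips a trailing `.0` (so 6037 prints as "6 K").

Two architecture rows cannot be taken verbatim: the five-block row
lists kernel sizes {2,4,6} but its printed 15.4 K total is only
consistent with {2,4,6,8,10} (the natural continuation of the even
sequence), and the three-block rows list four kernel sizes, of which
the first three reproduce the printed 8.6 K and 12.2 K.  The presets
use these reconstructions and they are commented at the definition
site.

## Augmentation

The three operators are exact and deterministic; grids are expanded
with integer-indexed arithmetic (`min + i·step`, rounded to 10
decimals) before identity filtering, so 0 and 1.0 are excluded robustly
despite floating-point steps.  Expansion order is fixed: amplitude
shifts, then time shifts, then amplification factors, each ascending.

- Time-shift boundary: edge replication by default (keeps the baseline
  continuous on z-normalized beats); zero-fill and circular wrap are
  available.  The boundary treatment is not externally specified.
- Amplification multiplies about zero (not about the beat mean); on
  z-normalized beats the two differ only by an amplitude shift, which
  the amplitude grid already spans.
- The SP class grids as printed expand to 16 transforms while the
  accompanying text counts 12 (2 + 6 + 4) and the printed
  post-augmentation count (2287) is consistent with neither.  The
  default SP preset follows the stated fold counts by truncating the
  time-shift grid to [-3, 3]; the verbatim grid is available
  (`SP_GRID_VERBATIM`).  The 6-fold SP variant of experiment row 12 has
  no published grid at all and is reconstructed as 2 + 2 + 2.
- The UB row of the published distribution table is an internal
  erratum (2 training beats before augmentation, 550 = 22×25 after); it
  is reproduced verbatim in `ecgtcn.ecg5000` and documented there, not
  silently corrected.

Augmentation applies to training splits only; passing a testing split
raises.

## Data handling

Readers cover the UCR delimited dialect (label-first rows, comma or
whitespace) and a minimal univariate `.ts` dialect (`@` directives,
`series:label` rows); both validate row lengths and label alphabets and
report parse errors by line number.  The official archive distribution
ships a 500-train/4500-test split — the reverse of the studied
4500/500 — so the intended workflow is to merge both files and re-split
90:10 with a seed.  `make_split` gives the test side
`floor(n·(1−f))` records (5000 → 4500/500) and shuffles the training
side once; stratification is available but off by default, since the
studied protocol does not mention it.

## Synthetic generator

Each class is a `BeatArchetype`: a sum of Gaussian bumps (one per wave)
plus a shared timing jitter (SD 1.5 samples) and additive Gaussian
noise (SD 0.05 in pre-normalization units), z-normalized per beat.
Defaults: N is a textbook P-QRS-T; R-on-T adds a premature wide R over
the T region; PVC has no P, a wide large QRS and inverted T; SP is an
early compressed complex; UB is a low-amplitude irregular shape.  The
noise and jitter levels were chosen once so that a 1-nearest-neighbour
baseline on 100 beats exceeds 90% accuracy — i.e. the fixture carries
clean, learnable class signal.

What the generator emulates: beat length, five-class structure, the
archive's class imbalance (largest-remainder apportionment of the
published totals), and z-normalized amplitude scale.  What it does not:
real morphological within-class variability, label noise, inter-patient
variation, or any physiological realism beyond the wave caricature.
Passing training tests on this fixture therefore demonstrates that the
pipeline can learn separable five-class structure under the archive's
imbalance — not that it attains any particular accuracy on real ECG.

## Training

Adam (learning rate 0.0025, betas 0.9/0.999, eps 1e-8 — only the
learning rate is externally specified), batches of 20 with the partial
final batch dropped (`floor(9204/20) = 460` iterations per epoch over
the published post-augmentation counts), 250 epochs, categorical
cross-entropy (the standard pairing for a softmax head; the loss is
not externally named).  The training set is shuffled once before
training, not per epoch, and no cross-validation is used.

Checkpoint selection takes the epoch of minimum monitored loss.  The
studied protocol monitors the *test* set each epoch and selects on it,
which leaks the test set into model choice; this default is kept for
fidelity and flagged, and `selection="train_loss"` (or passing a
separate validation set as `eval_set`) gives a clean variant.

The epoch sizes printed for the 24-fold-SP and 6-fold-SP variants (566
and 407) are not exactly derivable from the published per-class counts
under any integer fold arithmetic; runs log their computed epoch size
rather than forcing the printed one.

`TCNClassifier` is a scikit-learn-style estimator (get_params/clone
compatible, trailing-underscore fitted attributes) so it composes with
sklearn model selection; `train()` is a thin functional wrapper.

## Evaluation

One-vs-rest TP/FP/TN/FN from the confusion matrix; precision and
sensitivity per class; macro averages are unweighted means.  Two F1
conventions are emitted, because published headline figures rarely say
which they use: `f1_of_macros` (the F-score formula applied to the
macro-averaged precision and sensitivity — the reading most consistent
with "averaged, then combined" and used as the headline here) and
`macro_of_f1s` (mean of per-class F1).  Zero-denominator classes
contribute 0 with a warning — this matters for rare classes such as UB.
Argmax ties break toward the lowest class index.  ROC curves are
one-vs-rest threshold sweeps with trapezoid AUC (scikit-learn's
implementation behind the module surface, cross-checked in tests
against an exhaustive pairwise-comparison oracle); a class absent from
the truth vector has undefined AUC and is skipped with a warning.

## Problem sizes in the test suite

The suite exercises training at fixture scale as the package's own
test-design choice: the convolution oracle runs 1000 random cases up
to n=64; learning smoke tests use a 200-beat two-class toy at 5 epochs
and a 1000-beat five-class fixture at 10 epochs over 3 seeds (median
test accuracy asserted > 0.85); end-to-end CLI runs use 150–300 beats
at 2 epochs.  Full-scale runs (5000 beats, 250 epochs) go through the
same code path via `ecgtcn reproduce`.

## Known limitations

- The numpy engine is single-threaded and desk-scale; a full 250-epoch
  run on the augmented archive takes hours, not minutes.
- Only univariate, equal-length series are supported end-to-end.
- The published headline accuracies on the real archive are not
  asserted anywhere: they require the download and are stochastic; the
  package reproduces the protocol, not the specific draw.
- Checkpoints are `.npz` archives with the architecture spec embedded
  as JSON; they are not portable to other frameworks.
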