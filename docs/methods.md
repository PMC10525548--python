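# Methods

`medcap` implements a compact image-to-text pipeline for three-slot
descriptions of radiology-style images: every caption is the ordered word
triple *(exam type, body part, identified problem)*. This note documents
the model, the defaults and their rationale, what the synthetic data does
and does not emulate, and the numerical conventions.

## Corpus curation

A source corpus is a set of images, each with a free-text caption and a
keyword list. Curation proceeds in five steps:

1. **Keyword frequency index.** Each keyword is lowercased and stripped of
   punctuation, then counted once per record. The index is ordered by
   descending count; ties break lexicographically (the ordering is
   otherwise arbitrary, and determinism matters for reproducibility).
2. **Keywords of interest.** Keywords with frequency *strictly greater*
   than a threshold (default 500) are kept if they appear in a category
   template assigning them to one of the three slots; anything
   unclassifiable is discarded. Tokens are treated as opaque — no stemming
   — because reference keyword lists in this domain are often already
   stem-like (`pelvi`, `absces`).
3. **Triple enumeration.** All |exam| x |body| x |problem| combinations, in
   category-major order.
4. **Triple assignment and subclass selection.** A record is assigned a
   triple iff its keywords contain *exactly one* keyword per category;
   records matching zero or several keywords in any category are excluded.
   The strict rule guarantees an unambiguous three-slot target; a lenient
   rule (pick the most frequent match) would silently create label noise.
   A triple's subclass is kept when its image count lies in the inclusive
   range [min_size, max_size] (default [10, 80]).
5. **Split.** A seeded random permutation partitions the kept records
   60/20/20 into train/validation/test. Validation and test sizes are the
   half-up-rounded fractions of n and the training set takes the
   remainder, so n = 1419 gives 851/284/284 — which is why the bundled
   reference confusion matrices each sum to 284 (one fifth of 1419).

## Feature extraction

A backbone maps a preprocessed image (resized, 3-channel, intensities in
[0, 1]) to a **sequence** of feature tokens: the final spatial grid of the
network, flattened to n_tokens = Hf x Wf positions of feature_dim channels.
The attention encoder consumes a sequence, so spatial positions are kept as
tokens rather than pooled to a single vector; pooling would discard the
spatial structure that cross-attention can exploit.

`tiny_cnn` — three blocks of 3x3 same-convolution + ReLU + 2x2 average
pooling (8, 16, 32 channels; 32x32 input; about 6k parameters) — is the
executable backbone; it yields 16 tokens of 32 channels. The classical
transfer-learning backbones (vgg19, densenet201, ...) are registered by
name with their canonical input sizes, but instantiating them requires a
locally provisioned weight archive; nothing is downloaded at run time.
Frozen backbones are initialized from a fixed seed so that a saved caption
checkpoint can later be re-paired with an identical feature extractor.

Augmentation (the IA switch) is a seeded draw per image: rotation uniform
in +/-15 degrees, zoom uniform in [0.9, 1.1] (centre crop/pad back), mirror
with probability 1/2. The magnitudes are mild, conventional choices for
photographic-style augmentation and are configuration-exposed; the draw is
a pure function of (spec seed, image index).

## Caption transcoder

All tensor computation runs on a small reverse-mode autodiff engine
written for this package (`medcap._tensor`); every operation's gradient is
validated against central finite differences in the test suite.

**Encoder block** (one block): layer-normalise the feature tokens, project
each through a dense layer with ReLU to the model width d, apply multi-head
self-attention, add the attention output back to its input, and
layer-normalise. The encoder carries **no positional encoding** — image
tokens are a set, and the block is permutation-equivariant (a tested
property).

**Decoder block** (one block): token embedding plus **learned positional
embedding**, causally masked self-attention, cross-attention over the
encoder output, and a two-layer ReLU feed-forward net, each sub-layer with
residual connection and layer norm, followed by a linear map to vocabulary
logits (softmax for probabilities). Causality — position t depending only
on tokens <= t — is enforced by an additive -1e9 mask and tested directly.

Depth is configurable but defaults to a single block of each kind; the
reference architecture this follows shows single blocks, and the synthetic
tasks do not need more. Default hyperparameters (embed_dim, heads, ff_dim =
64/2/128 in the pipeline helpers, 128/2/256 as library defaults) are the
package's own choices: no authoritative values exist for this
architecture, and these are the smallest settings that train reliably.

**Targets and decoding.** The training target is the token sequence
`START e b p END`, padded to max_len (default 8). Generation is greedy:
argmax at each step, ties to the lowest index, stop at END or after
max_len - 1 tokens. Greedy decoding keeps evaluation deterministic; beam
search and sampling are out of scope.

**Vocabulary.** Reserved indices PAD=0, UNK=1, START=2, END=3, then corpus
words by descending frequency (ties lexicographic). Unseen words at
inference map to UNK.

## Training

Loss is sparse categorical cross-entropy over the vocabulary, computed
from logits with the usual log-sum-exp stabilisation; **padding positions
are excluded** from both the loss mean and token accuracy, otherwise the
scores would be inflated by trivially predictable padding. Teacher-forced
training uses mini-batches in a seeded shuffled order; one (config, seed)
pair reproduces the loss history bit-for-bit in single-threaded runs.

Optimizers: Adam (lr 1e-3), AdamW (lr 1e-3, decoupled weight decay 1e-2),
Adadelta (rho 0.95, lr 1.0), and Adafactor (factored second moments,
relative step size, update clipping) — each at its published defaults,
with the learning rate configuration-exposed. Early stopping monitors
validation loss with patience 3 and a 20-epoch cap, and restores the best
validation weights; the epoch cap and varying observed epoch counts in the
reference experiment grids imply exactly this kind of rule.

The experiment grid sweeps backbone x optimizer x {TL, TR, IA}. TL
(transfer learning) requires provisioned pretrained weights; TR
(fine-tuning) wraps the backbone and transcoder into one end-to-end model
whose joint parameter set is optimized, fed with raw pixels; IA applies
augmentation to training images. Failing cells are recorded with their
error message rather than aborting the sweep. Wall-clock training and test
times are recorded but never asserted (hardware-dependent).

**Family summaries** reduce a family's accuracies to mean, **population
standard deviation** (divisor n, not n-1 — the convention that reproduces
the bundled reference summary table, verified to 4 decimals), min, max and
mu +/- sigma. Outputs are rounded to 4 decimals from full precision. The
reference table's own derived mu +/- sigma cells are not bit-reproducible
for two of nine rows because they mix rounding conventions; the package
reports full-precision-then-round values.

## Evaluation

Token accuracy is position-wise: correct generated words over all
non-padding reference positions, with short predictions padded (as misses)
to the reference length. BLEU-1 is implemented literally as corpus-level
clipped unigram precision — total clipped matches over total predicted
unigrams, **no brevity penalty, unigrams only** — because that is the
definition this pipeline targets; captions here are three distinct words,
so count clipping never changes the score in practice. The pipeline-level
scorer pads empty or short captions to three slots with an
out-of-vocabulary filler so that a degenerate model scores near zero
instead of shrinking the denominator.

Slot confusion matrices put true classes on rows, predicted on columns;
class order is descending true-class frequency, ties lexicographic. The
one-vs-rest reduction per class yields P, N, TP, FP, TN, FN and the rates
TPR, TNR, PPV, NPV, ACC, F1. Conventions, chosen to agree with the bundled
reference metric tables cell-for-cell:

* rates are rounded **half-up to 2 decimals** for table output (internal
  values keep full precision);
* PPV is UNDEFINED (printed `-`) iff the class is never predicted
  (TP+FP=0); with predictions but no hits it is printed `0.00`;
* NPV is UNDEFINED iff TN+FN=0;
* F1 is UNDEFINED whenever TP=0 (the harmonic mean's denominator is zero
  or one operand is undefined).

One of the three bundled reference metric tables (the body-part table)
contains four cells in its 'lung' row that are inconsistent with its own
confusion matrix (printed TN=187 where the matrix and the row's own
N=FP+TN identity give 231, plus the three rates recomputed from it);
deriving that table from the confusion matrix therefore reproduces 191 of
195 cells. The other two tables reproduce exactly.

Synonym pairs discussed qualitatively in the source material
(xray/radiograph, tomography/ct, cyst/cystic) are kept as distinct classes,
exactly as the reference tables do.

## Synthetic data

The generator emulates the *layout and learnability* of a curated
radiology corpus, not its appearance. Each image renders its triple
through three independent visual factors — exam type selects a background
texture, body part a centred foreground shape, problem a small marker
glyph — plus additive Gaussian pixel noise. Factorised encoding makes each
slot separately recoverable, so partially trained models produce
non-trivial slot confusion structure.

Default conditions, fixed once: 3 fully distinct triples x 60 images,
64x64 grayscale, noise sd 8 on the 0-255 intensity scale (clearly visible
but far from masking the factors — a moderate difficulty). Generation is
byte-deterministic given the spec.

What passing tests on this data do show: the curation rules, the feature
pathway, the transcoder's optimisation and decoding, and the scoring all
compose correctly, and the model family can fit a visually separable
three-factor task to >= 95% held-out token accuracy within seconds on one
CPU. What they do not show: performance on real radiology images, where
slot factors are entangled, class-imbalanced and noisy at a completely
different scale; absolute accuracies on such corpora are not comparable.

## Problem sizes

The test suite and the acceptance script train on the default synthetic
conditions (180 images, 16x32 feature tokens, ~71k-parameter transcoder,
<= 20 epochs), grid-runner tests on a 3 x 10 corpus with 3 epochs; these
sizes were chosen so the full pipeline exercises every stage while the
whole suite runs in well under a minute on one CPU.

## Known limitations

* The classical backbones are registry entries only; without a locally
  provisioned weight archive they raise a configuration error, and no
  loader for external archive formats is bundled.
* CLI checkpoints store the transcoder (config, vocabulary, weights) but
  not a fine-tuned backbone; `medcap generate` re-pairs checkpoints with
  the fixed-seed frozen backbone, so it is not applicable to TR-trained
  models.
* Greedy decoding only; no beam search, sampling or temperature.
* BLEU-1 here is the literal clipped-unigram-precision definition; scores
  are not comparable to smoothed multi-n-gram BLEU implementations.
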