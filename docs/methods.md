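# Methods

## Problem setting and assumptions

The package targets binary image classification where the only labels are a
handful of ordinal expert scores per image (1..8; 1 confidently negative, 8
confidently positive, 4/5 equivocal) from a small reviewer panel, images are
grouped by patient, and no gold standard exists. The modelling assumptions
are: (i) the mean-aggregated binary label is reliable when reviewers are
confident and concordant, and unreliable otherwise; (ii) the review set
itself carries information about label quality that is available at training
time but never at deployment; (iii) patients, not images, are the independent
sampling units, so all data splits must be patient-wise.

## Uncertainty measure

`D = mean_i g(S_i) + sigma(S_1..S_k)` combines per-score ambiguity
(`g(s) = -|s - 4.5| + 3.5`, zero at the confident extremes, 3 at the
equivocal middle) with reviewer disagreement (the standard deviation of the
scores). Two conventions were genuinely open:

- **sigma is the population standard deviation** (divisor k). With the
  sample divisor, a two-reviewer {1, 8} panel yields D ≈ 4.95, which
  escapes the [0, 4] range that the gating and stratification thresholds
  presuppose; the population form keeps the exhaustive maximum over all
  2–4-reviewer configurations at exactly 4.0. The sample convention remains
  available (`uncertainty(..., ddof=1)`).
- **The gate boundary is exclusive**: privileged information is supplied
  strictly when `D > tau`; a record sitting exactly at the threshold gets
  the all-zero substitute. The evaluation strata mirror this: clean is
  `[0, 2)`, equivocal is `[2, max]` with a closed top so no record is
  dropped.

Single-review sets (k = 1) are accepted with sigma = 0 even though typical
panels have k ≥ 2.

Mean scores are rounded to ordinal targets with a half-up tie-break (mean
4.5 → rank 5), consistent with labelling the 4.5 boundary positive; a
half-even switch exists on `ordinal_target`.

## Network and losses

The encoder is a pluggable contract. Two implementations ship: a 3-block
strided-convolution CNN (default embedding width 64) sized for 32×32
desk-scale images, and a full ResNet-50 backbone (2048-dim embedding,
single-channel 512×512 input with resize + affine rescale to [-1024, 1024])
onto which pretrained weights can be loaded via `load_state_dict`. All
layers, the autodiff engine and Adam are implemented on numpy in
`uncertram.nn`; every primitive's gradient is checked against central finite
differences in the test suite, which anchors the training dynamics without
any external framework.

The privileged branch embeds the encoded annotation vector through a
linear-64 / batch-norm / ReLU block, concatenates with the image embedding,
and predicts through two 128-unit layers. Its head is either the CORN
rank-consistent ordinal head (K−1 = 7 conditional binary logits) or a plain
2-logit head for the non-ordinal ablation. The combined loss is
`L = CE(xi(sg(z)), y) + beta * L2` with beta = 0.5; the stop-gradient
guarantees the encoder receives gradients only from L2, which is asserted
by parameter-diff tests rather than runtime checks.

CORN normalization divides the summed negative log-likelihood by the total
number of contributing (task, example) terms — the conditional-subset
construction itself fixes which terms contribute, but the divisor is a free
choice and this one keeps the loss scale comparable across batches with
different target compositions. The base predictor xi receives no gradient
from L2: the privileged predictor consumes the embedding directly, not
through xi.

Batch-normalization statistics are undefined on singleton batches, so the
training loop drops a trailing batch of size 1; evaluation always runs in
running-statistics mode, making inference deterministic and bitwise
independent of the privileged branch.

## Training protocol

Patient-wise folds are formed by shuffling the sorted patient list with the
given seed and dealing round-robin, giving fold sizes within one patient of
each other. Validation sets are filtered to D ≤ tau_val (default 2);
training portions are never filtered. Early stopping compares against the
best validation loss seen so far (not the previous epoch) with patience 10
over at most 40 epochs — the standard semantics consistent with retaining
the lowest-validation-loss checkpoint. The validation loss for every
variant, regardless of its training loss, is the base branch's cross-entropy
against mean-aggregated labels, evaluated after each epoch.

Grid search spans lr_encoder ∈ {1e-4, 4e-4, 1e-5, 5e-5, 1e-6} and
lr_rest ∈ {1e-3, 5e-3, 1e-4, 5e-4, 1e-5} (the full 25-point grid is
configurable but desk-scale runs use reduced grids), selecting the pair with
the lowest mean across-fold best validation loss; ties break
lexicographically on (lr_encoder, lr_rest). Two seeds separate
hyperparameter search from the final run; the final models from each fold
are evaluated on a patient-disjoint holdout that is structurally unreachable
before training completes (the experiment driver only receives it after the
fold loop, and a pixel-access-tracking test enforces this). Adam runs with
default moment parameters in two parameter groups; classes are unweighted.
The gate threshold tau = 2 is treated as a fixed protocol constant here (it
is the natural median of D under the intended panel behaviour) and as an
ordinary hyperparameter on other data.

## Baselines

Linear probing trains only the 2-class head on a frozen encoder; fine tuning
unfreezes the encoder; both use cross-entropy against mean-aggregated
labels. Confusion estimation adds one trainable 2×2 confusion matrix per
panel member, parameterized by column-wise softmax so column-stochasticity
survives every optimization step; each observing annotator's binarized score
is modelled as `P^(t) @ p` with `p` the predicted true-label distribution,
plus a trace regularizer (weight 0.01, identity-biased initialization at
diagonal 0.9) that makes the decomposition identifiable. The encoder is
frozen by default (matching the linear-probing architecture) with a
trainable-encoder switch. The plain TRAM ablation predicts the binary label
in the privileged branch with no gate; `tram_thresh` adds the gate;
`tram_ord` the ordinal head; `proposed` both.

## Synthetic generator

Each patient draws a severity centre uniformly in [0, 10]; images jitter
around it (sd 0.75, clipped). Images are background Gaussian noise
(sd 0.08) plus Gaussian blobs in two lateral "lung field" regions whose
intensity and spatial extent grow with severity; below the class threshold
u0 = 5 blobs are mostly unilateral, above it bilateral — a visual correlate
the encoder can learn, echoing the bilateral-opacity hallmark of the
motivating finding without claiming radiological realism. Reviewer t scores
`clip(round(a*u + 4.5 - a*u0 + b_t + eps), 1, 8)` with slope a = 7/10
spanning the scale, one per-panel bias `b_t ~ N(0, 0.3)` and per-review
noise `eps ~ N(0, 0.5)`; 2–4 reviewers are sampled per image from a panel
of 14. These defaults were chosen so that the resulting uncertainty
distribution resembles a realistic clinical panel (median D ≈ 2, range
0–3.9, disagreement and label noise concentrated near the class boundary);
they are the fixed study conditions of the benchmark, not tuning knobs.

What the generator does *not* emulate: realistic anatomy, medical devices,
reviewer-specific systematic styles beyond an additive bias,
non-monotone severity-score relationships, and missing-data structure in
which reviewers see non-random image subsets. Passing benchmarks therefore
demonstrates that the machinery behaves as designed under the assumed noise
model, not clinical-grade performance.

## Benchmark problem sizes

The desk-scale benchmark runs ~600 training and ~300 holdout 32×32 images
(100/50 patients), all seven variants, 3 seeds, 3 folds, up to 10 epochs at
learning rates 1e-3/1e-3 — sizes chosen so the full suite completes in
minutes on a single CPU while preserving the protocol's structure. At this
scale the clean stratum saturates near perfect accuracy for most variants;
the informative signals are the clean-versus-equivocal gap (consistently
present) and the proposed-versus-plain-TRAM ordering on clean cases.

## Numerical choices and degenerate inputs

- All computation in float64; losses guarded against divergence
  (non-finite training or validation loss aborts with an error).
- Cross-entropy and CORN use max-shifted / softplus forms; no exp overflow.
- Cohen's kappa between reviewers with no shared images is NaN (written as
  empty CSV cells); a pair in perfect agreement — including the degenerate
  all-one-class case — is kappa 1. The diagonal is 1 for presentational
  completeness and must be excluded from mean-kappa summaries.
- Metrics with zero denominators (MCC, precision on zero predicted
  positives) and rank metrics on single-class samples are NaN, never 0.
- AUROC uses the rank statistic with mid-rank ties; AUPRC is step-summed
  average precision.
- Duplicate reviews by one reviewer on one image are rejected, not averaged
  (the encodings presuppose distinct reviewers).

## Known limitations

- The numpy substrate is single-device and unoptimized for large images;
  the ResNet-50 path is functional (a 512×512 forward runs in seconds) but
  not intended for full-scale training.
- No pretrained weights ship with the package; the pretrained-encoder path
  is an interface.
- The uncertainty measure is a heuristic, not an unbiased noise-rate
  estimator; its usefulness is through the gate and stratification, not as
  a calibrated probability.
- Confusion-matrix recovery assumes conditionally independent annotators
  given the true label.
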