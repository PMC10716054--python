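# Methods

`promoforge` implements a promoter-design stack for *Escherichia coli*
sigma70 promoters: supervised sequence models that recognise promoters and
predict their strength, a denoising-diffusion generator of novel 50-bp
promoters, a constraint-based random generator, and the screening and
motif-scanning analyses built on top of them.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Sequence representation and features

Promoters are fixed-length 50-bp strings over the strict {A, C, G, T}
alphabet; ambiguity codes are rejected at ingest because both encodings
are defined only on the four-letter alphabet.  Longer extracts (e.g.
81-mers) are reduced to 50 bp by a 1-based window whose default start (11)
takes the 50 nt ending just upstream of a transcription start placed at
position 61; the offset is a convention and is exposed as a flag.

*One-hot*: position-wise indicators in A, C, G, T column order, flattened
row-major; decoding is per-position argmax with alphabetical tie-break.

*Pseudo-dinucleotide composition* (pseDNC): the 16 dinucleotide
frequencies f_u augmented with λ autocorrelation tiers,

    d_u     = f_u / (1 + w Σθ),            u = 1..16
    d_{16+j} = w θ_j / (1 + w Σθ),          j = 1..λ

where θ_j averages, over all dinucleotide pairs j steps apart, the mean
squared difference of their standardized physical property values.  The
packaged property table holds the six standard local structural
parameters of B-DNA dinucleotide steps (twist, tilt, roll, shift, slide,
rise), standardized per column; it is user-replaceable via a CSV with the
same layout.  Defaults λ = 3, w = 0.05 are the conventional choices; both
are configuration parameters.  The output always sums to one, which the
test suite checks against an independently coded brute-force oracle.

## Supervised networks

Four models share one code path:

| model    | task                  | architecture |
|----------|-----------------------|--------------|
| PromoS   | strong vs weak        | ResNet + self-attention |
| PromoR   | real vs fake          | ResNet + self-attention |
| PromoA   | activity regression   | ResNet + self-attention |
| PromoNet | activity regression   | single-conv CNN |

The ResNet+attention stack is: convolution+ReLU stem → residual blocks →
single-head scaled dot-product self-attention over positions → max pool
(stride 2) → dropout → dense head (sigmoid for binary tasks).  A residual
block is conv → ReLU → conv added to an identity skip (a 1×1 convolution
reconciles channel counts when they differ).  The second convolution of
each block, the attention value projection and the head are
zero-initialised so every block starts as the identity; this lets deep
stacks (the faithful default is 20 blocks) train without normalization
layers.  The activation of the residual branch is applied before the
second convolution rather than after it — placing a ReLU directly on a
zero-initialised convolution would pin its output at zero with a dead
gradient.

All tasks minimise mean squared error with minibatch Adam (decoupled
weight decay available); binary targets are 0/1 against the sigmoid
output with a 0.5 decision threshold.  Regression targets are
standardised internally and mapped back at prediction time; activity
targets are log1p-transformed by default (raw scale optional) because
measured promoter activities are heavy-tailed.  Training is deterministic
given the config seed.

PromoNet is deliberately minimal: one convolution+ReLU layer read out by
a dense head on the *full-resolution* feature map.  Promoter activity
depends on base identities at specific offsets, so no pooling is applied;
dropout (0.3) and weight decay (0.1) carry the regularization at the
few-hundred-sample scale this model targets.  The practical classifier
configuration used in the examples and benchmarks runs two residual
blocks at eight channels; the 20-block architecture is available through
`NetConfig` and is what `NetConfig()` builds by default.

Evaluation: sensitivity, specificity, accuracy and the Matthews
correlation coefficient are computed from the confusion table (undefined
metrics are reported as `None`, never coerced to 0); AUROC uses the rank
(Mann–Whitney) identity with average ranks for ties; regression reports
Pearson correlation and MSE.  Cross-validation is stratified for binary
tasks and plain shuffled for regression, with a fresh network per fold.
Hyperparameter search is an exhaustive grid over learning rate
([1e-4, 1]) and batch size ([4, 64]), scored by mean accuracy or mean
PCC; ties prefer the smaller learning rate, then the smaller batch.
Elastic-net and gradient-boosted-tree baselines (scikit-learn, small
internal grids) provide the classical reference.

## Diffusion generator (PromoDiff)

One-hot 50×4 matrices are rescaled to [−1, 1] and treated as continuous.
The forward process is the standard Gaussian diffusion with a linear
variance schedule (defaults T = 1000, β from 1e-4 to 0.02), with the
closed-form marginal q(x_t|x_0) = N(√ᾱ_t·x_0, (1−ᾱ_t)I).  A UNet is
trained to predict the injected noise (ε-prediction, squared error) on
uniformly drawn (sample, t) pairs; sampling is ancestral reverse
diffusion from pure noise through all T steps with the posterior variance
β̃_t, followed by argmax decoding.  These are the standard DDPM choices;
none are fixed by the problem, so all are configuration parameters.

The UNet encoder is a residual block, a stride-2 downsampling convolution
(50 → 25 positions), a second residual block and a self-attention block at
the bottleneck; the decoder recovers length 50 by nearest-neighbour
upsampling into a residual block over the concatenated skip features.
Two conditioning signals are added at the stem: a learned positional
embedding — promoter elements live at fixed offsets, and a purely
convolutional (translation-equivariant) denoiser could not express
position-specific motif structure — and a sinusoidal embedding of the
diffusion step mapped onto the channels.  Default width is 16 channels.

Checkpoints are stored per epoch (thinning configurable).  Model
selection follows the real-promoter-portion (RPP) criterion: sample a
fixed-size batch (default 100) from each checkpoint, score it with a
real/fake classifier at threshold 0.5, and keep the epoch with the
highest fraction called real.  `novelty_report` counts exact duplicates
within a generated batch and against the training set.

## Constraint-based design and screening

`generate_constrained` builds 50-mers as

    upstream pad | TTGACA | spacer (16–18 nt) | TATAAT | 6-nt downstream pad

with the spacer drawn uniformly from the configured set, free positions
i.i.d. uniform over ACGT, and the upstream pad absorbing the remaining
length (the −10 box is therefore right-anchored — a fixed 6-nt
discriminator-like pad sits between it and the sequence end; the exact
placement within the 50-mer is a convention, configurable via
`downstream_length`).  `drsa_screen` is the screening cascade: keep
candidates with p_real > 0.5, then p_strong > 0.9, rank by predicted
activity descending (ties broken lexicographically) and keep the top 50.
The 6-mer scan holds one hexamer box fixed, substitutes each of the 4096
6-mers into the other box across `n_contexts` random constrained
sequences (default 100, spacer 17), and records the fraction predicted
real and strong at threshold 0.5.  Comparisons against an external
RNAP/sigma70 binding ranking accept any user-supplied motif→strength
table; the package ships none.

## Sequence logos

Per-position information content is R = 2 − H bits (H the Shannon entropy
of base frequencies), with the Schneider small-sample correction
e_n = 3/(2·ln2·n) available but off by default; per-base bits are
frequency × R, floored at zero.  Consensus is per-position argmax with
alphabetical tie-break.  Rendering is an optional stacked-bar plot; the
numeric matrix is the tested artifact.

## Synthetic ground truth

The synthetic module generates corpora with the statistical structure of
curated promoter sets — 50-bp length, −35/−10 hexamer architecture with a
16–18 bp spacer, heavy-tailed activities, real-vs-fake contrast — so the
whole stack is testable without downloads.  The activity model is linear
in motif quality:

    activity = β0 + β35·s35 + β10·s10 + γ_spacer + ε,   ε ~ N(0, σ²),

truncated at zero, where s35 and s10 are PWM log-likelihood-ratio scores
of the sampled hexamers against the background.  Coefficient defaults are
β0 = β35 = β10 = 1 with spacer penalties (0, 0, −0.5) for 16/17/18 bp —
the 18-bp spacer disfavours strong promoters — and σ = 1.

Default PWMs emulate a constraint-designed corpus: the −35 box is held at
the TTGACA consensus (as constraint-based generation fixes it) and the
−10 box varies around TATAAT at 0.7 consensus probability.  This choice
is load-bearing for the recovery benchmarks: the −10 box is right-anchored
at a fixed offset, while the −35 box shifts with the spacer.  If both
boxes varied, the spacer jitter would leave the −35 signal unlearnable at
n = 200 by any reference method we tried (ridge, lasso, CNNs all plateau
far below the ceiling), making the generator's stated purpose — ground
truth that trained models can recover — unattainable at that scale.  With
the fixed −35, a sparse linear reference reaches the analytic ceiling and
PromoNet lands within ~0.15–0.18 of it.

Because score variances are analytic, the theoretical ceiling of any
activity predictor is available in closed form:

    PCC* = sqrt(Var(signal) / (Var(signal) + σ²)),

ignoring the zero-truncation (mild at the default operating point; the
variance-decomposition test widens its tolerance accordingly).

Fake sequences are either per-sequence position shuffles of the reals
(composition-matched) or pure background draws.  The heavy-tailed corpus
draws log-normal activities calibrated so the 97.7% quantile sits at
1e4.  What these corpora do **not** emulate: real genomic base
composition, correlated positions outside the planted motifs,
non-sigma70 promoter classes, or measurement batch effects — so passing
recovery tests demonstrates correct mechanics and learnability under the
stated model, not performance on natural promoter data.

## Problem sizes used in validation

The packaged benchmarks run at deliberately modest scale so the whole
suite executes on a single CPU: diffusion motif recovery trains T = 200,
200 epochs on 2,000 sequences and samples 200 (≥50% of samples must carry
TATAAT within ±2 of the planted offset, versus <5% for an untrained
model); parameter recovery uses n = 200 with 5-fold cross-validation
(within 0.2 of PCC*) and n = 400 for real/fake classification (accuracy
≥ 0.95); the constraint generator is checked on 12,000 sequences
(uniformity by chi-square at p > 0.01); the 6-mer scan in the acceptance
script uses 10 contexts per k-mer.  Degenerate inputs (empty batches,
single-class labels, constant vectors, zero-count metric denominators,
odd class sizes) raise or warn explicitly rather than returning silent
defaults.

## Known limitations

* The networks run on a compact numpy autodiff engine written for this
  package; it is single-threaded CPU code, so the faithful 20-block
  configuration trains slowly and the practical configurations used in
  examples are small.  Gradient correctness is verified against finite
  differences.
* Continuous Gaussian diffusion on one-hot matrices is a modelling
  convenience; no discrete (multinomial) diffusion variant is provided.
* The diffusion defaults (schedule, depth, width) are conventions, and
  checkpoint selection by RPP depends on the quality of the real/fake
  classifier used to score samples.
* `binding_table_comparison` requires a user-supplied binding table;
  results inherit whatever biases that table carries.
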