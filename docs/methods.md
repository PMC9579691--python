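# Methods

## The problem and the two-stage design

N6-methyladenosine (m6A) is the most abundant internal mRNA modification.
Antibody-based sequencing locates m6A only to peak regions ("low-resolution"
sites); exact-adenosine ("base-resolution") calls are usually obtained from
those regions by post-calibration. `m6a2stage` mirrors that experimental
funnel computationally:

* **Stage 1** — a multi-task network reads a 601-nt RNA window centered on a
  candidate adenosine (central triplet GAC or AAC, the core of the RRACH
  consensus) and produces (a) the probability that the window contains a
  low-resolution m6A site and (b) a regression estimate of the site's
  experimental support count ("SupportNum", the number of independent
  experiments backing the site), min-max normalized to [0,1]. The regression
  output doubles as a confidence score for positive calls.
* **Stage 2** — a classifier with the same backbone separates
  base-resolution sites from low-resolution-only sites. It is initialized by
  transfer: every layer except the output heads copies the stage-1 weights,
  and all weights are then fine-tuned without freezing.

## Dataset construction

Windows are extracted with `k` nucleotides of genomic context on each side
(default k = 300, i.e. 601 nt, selected as optimal at the original database
scale); off-chromosome positions are padded with the pseudo-nucleotide `N`.
Minus-strand sites are reverse-complemented so the emitted window reads
5'→3' on the transcript strand, and the central motif is classified on that
strand; T becomes U at emission. Sites whose central base is not adenosine
on their strand are rejected.

Within each class, redundancy is removed by greedy incremental clustering at
sequence identity 0.7: sequences are visited in input order and join the
first representative with identity ≥ 0.7, else found a new cluster. Identity
is the exact-match fraction of the equal-length ungapped windows — an
intentional simplification of alignment-based clustering tools that is exact
for genome-anchored fixed-length windows. The larger class is then
under-sampled uniformly to the size of the smaller, and the balanced set is
split 4:1 into train/test, stratified by label, with train taking
floor(0.8·n) per class. (At the original scale this yields 8,749/2,188 per
class from 10,937; the published stage-2 counts follow the complementary
flooring and differ by one window from our rule.)

The SupportNum normalizer is fitted on training positives only and applied
with clipping to any other split, avoiding test-set leakage. Negative
windows receive a regression target of 0 — they have no experimental
support; this choice is exposed as a parameter.

## Model

The input is a 4×L one-hot matrix (rows A, U, C, G; `N` encodes as the zero
column). Three shared backbones are available:

* `cnn`: 1-D convolution (16 filters, tunable kernel) → group normalization
  (4 groups) → ELU;
* `cnn_bilstm` (default): the CNN stack followed by a bidirectional LSTM
  with 8 hidden units per direction returning the full output sequence
  (16 channels), so the subsequent pooling remains positional;
* `cnn_transformer`: the CNN stack plus a learned additive position
  embedding and a single transformer encoder block (2 attention heads,
  position-wise feed-forward of width 64, residuals + layer norm).

All variants continue with 1-D max pooling (tunable size), flatten, a dense
layer of 64 units (optionally one per task), dropout, and two heads: a
2-unit softmax classifier and a 1-unit ELU regressor. All hidden activations
are ELU. Layer order is Conv → GroupNorm → activation. The ELU regression
head can emit values slightly below 0 (its range is (−1, ∞)); raw values are
reported as-is and additionally clipped to [0,1] for the user-facing
confidence column.

### Loss

The multi-task objective is `w_class·CE + w_reg·LC` with default weights
1:1. CE is the two-class cross-entropy in the per-sample both-class form
−[y·log p + (1−y)·log(1−p)] summed over the two softmax outputs, which for a
2-class softmax equals exactly twice the standard categorical cross-entropy;
a `ce_form="categorical"` switch selects the standard form (the two differ
only by an effective learning-rate factor on the classification gradient).
LC is the log-cosh loss of the regression residual, computed with the stable
identity log cosh x = |x| + log1p(e^(−2|x|)) − log 2. Both terms are
averaged over the batch so the loss scale is independent of batch size.
Probabilities are clipped at 1e−7 before logarithms. A weight preset
0.06:1.85 (a ratio obtained elsewhere by uncertainty weighting) is available
as a configuration value; it is not re-derived here.

### Training

Optimization is SGD with momentum 0.9 (default learning rate 0.01, batch
128). No early stopping: the epoch count is a hyperparameter (stage-1
default 60). Stage-1 hyperparameters (kernel size, pool size, dropout,
learning rate, batch size, epochs) can be selected by exhaustive grid search
with stratified 5-fold cross-validation; the selection metric is mean CV
AUROC, with ties broken by smaller parameter count, then grid order. For
stage 2 only the epoch count is re-optimized (grid default {16, 32, 64, 128,
256}); the from-scratch control is additionally scored over a shifted grid
{76, 92, 124, 188, 316} to compensate for the head start that transfer
provides. Every random choice (weight init, shuffling, dropout, sampling)
derives from explicit integer seeds; two runs with identical seeds, data and
configuration produce identical training curves.

The numerical core is a compact numpy layer library with hand-written
backpropagation (`m6a2stage.nn`); the LSTM recurrence, the only inherently
sequential hot loop, is JIT-compiled with numba when available, with a
bit-identical pure-numpy fallback. Gradient correctness for every layer is
enforced by central-finite-difference tests.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, and
MCC = (TP·TN − FN·FP)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)). Hard calls use
threshold 0.5 on the positive-class probability, ties counted positive; a
zero factor in the MCC denominator defines MCC = 0, and an empty class makes
Sn or Sp NaN with a warning. AUROC is the trapezoid area under the ROC sweep
(equal to the normalized Mann–Whitney U with ties counted ½); AUPRC uses
step-wise interpolation, which avoids the optimistic bias trapezoids show in
PR space. The regression task is scored by the Pearson correlation
coefficient, which is undefined (an error, not 0) at zero variance. In
multitask mode the report also carries the Pearson r of the classification
probability against the regression targets — the "use the classifier as
confidence" baseline the dedicated regression head is meant to beat.

## The synthetic-data generator

The generator emulates the study's data conditions at desk scale, not yeast
biology. A background genome is drawn i.i.d. at GC 0.38 (budding-yeast-like)
and emitted as DNA FASTA. Sites are planted at non-overlapping loci on
random strands. Positive flanks are drawn from an RRACH-compatible PWM
(width 15; the central triplet fixed to the motif, position −2 favoring A/G
and +2 favoring A/C/U, nearby flanks mildly enriched) geometrically
interpolated with the background: column probabilities ∝ bg·(pwm/bg)^s,
where s = `signal_strength` is a single continuous dial (s = 0 reduces
positives to motif-matched background; s = 1 is the PWM itself; s > 1
sharpens it). Negatives are motif triplets planted on pure background.

SupportNum for a positive is 1 + a negative-binomial draw with mean
λ·exp(β·z), where z is the site's standardized planted flank log-odds score
(λ = 3, β = 0.8, dispersion shape 4 by default). This yields the strongly
right-skewed support distribution seen in real site databases, couples
sequence signal to experimental support when β > 0 (design correlation
corr(z, support) ≈ 0.65 at the defaults), and makes them independent at
β = 0.

A fraction of positives (default one half) is flagged base-resolution; their
flanks come from a PWM whose flank columns are blended toward a rolled
(preference-swapped) alternative by `stage2_shift` ∈ [0,1]. Shift 0 makes
the stage-2 task (base- vs low-resolution positives) chance level; larger
shifts increase its separability. The default shift (0.3) is chosen so
stage-2 separability sits clearly below stage-1's (CV AUROC ≈ 0.7 vs ≈ 0.95
at the default sizes), matching the qualitative observation that
positive/negative discrepancy is larger in stage 1.

What the generator does **not** model: real genome composition and gene
structure, spliced transcripts, the empirical SupportNum distribution beyond
its skew, chromosome-level site clustering, and experimental noise
correlated across nearby sites. Passing tests on this generator demonstrate
that the pipeline learns planted sequence signal and that multitask and
transfer mechanics behave as designed — not that the model reaches any
particular accuracy on real epitranscriptomic data.

## Desk-scale experiment sizes

The benchmark experiments (`m6a2stage.experiments`, also used by
`scripts/acceptance.py`) run the stage-1 protocol on 1,000 sites per class
with 301-nt windows (half-width 150) for 60 epochs, and the transfer
comparison on 600 positives (half base-resolution) with 101-nt windows, a
stage-1 source trained 30 epochs, and 3-fold CV at 24 stage-2 epochs over
five paired seeds. These sizes are the package's chosen desk-scale stand-in
for the original database-scale datasets (tens of thousands of 601-nt
windows, 5-fold CV, wide epoch grids).

## Numerical and degenerate-input conventions

* Probability clipping 1e−7; MCC zero-denominator → 0; Pearson zero-variance
  → error; all-N windows encode to the zero matrix and are valid inputs.
* Non-ACGTU genome characters map to `N` in windows.
* Max pooling drops the remainder of the sequence (valid pooling); pool size
  larger than the post-convolution length is an error.
* Greedy clustering accepts a seed for API symmetry but is deterministic in
  input order: first-match assignment leaves no ties to break.
* Checkpoints (weights `.npz` + config JSON) reload bit-exactly; transfer
  initialization is verified tensor-by-tensor before training.

## Known limitations

* The greedy exact-identity clustering is not an alignment-based tool; on
  real data with indel-displaced near-duplicates it retains more sequences.
* The from-scratch numerical core is CPU-only and single-threaded; it is
  sized for hundreds-to-thousands of windows, not database-scale training.
* Stage-2 transfer assumes identical window length and architecture between
  stages; transferring across window lengths is rejected, not adapted.
* The transformer variant implements a single encoder block with learned
  position embeddings; deeper stacks are out of scope.
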