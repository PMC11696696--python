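# Methods

## Model

An aligned sgRNA–DNA duplex is a pair of 23-character strings over
{A,C,G,T}: positions 1–20 the spacer, 21–23 the PAM, in the same-strand
convention (a matched position shows the identical letter in guide and
target). The classifier estimates P(cleaved | duplex) from sequence
alone; chromatin state, cell type and read depth are outside the model.

**Stack encoding.** A width-k window (k ∈ {1,2,3}, default 2) slides
over the duplex with a one-base step; window i yields the token
`guide[i..i+k-1] + target[i..i+k-1]`, indexed by its base-4 value with
A=0, C=1, G=2, T=3 (equivalently its lexicographic rank among the
4^(2k) tokens). A 23-bp pair gives 23−k+1 tokens: 22 doublets at the
default. No start/end tokens are added; the model consumes exactly the
content tokens. An alternative convention would complement the guide
before pairing; both conventions are relabelings of the same token
space, and the literal-letter one is fixed here so that token names such
as "GG to TC" read directly off the stored sequences.

**Architecture.** Token embeddings (dimension d, default 64) plus, in
the *contextual* variant, learned positional embeddings of length
23−k+1, pass through L post-norm transformer-encoder blocks (default
L=6) with H-head self-attention (default H=8, d divisible by H) and a
position-wise feed-forward of width 4d with ReLU. The *static* variant
uses the token embeddings directly. Either way a bidirectional LSTM
(default 32 units per direction) reads the sequence; its concatenated
final hidden states — rather than the per-timestep output sequence,
a deliberate choice where either reading is defensible — feed two dense
ReLU layers (defaults 128, 64) and a single sigmoid unit.

**Training.** Binary cross-entropy (computed stably from logits),
Adam (lr default 1e-4, betas 0.9/0.999), batch 64, dropout 0.1 after the
embedding stage and the first dense layer, all weights trained from
scratch — there is no masked-token pretraining objective. The epoch with
the best validation PR-AUC is kept, PR-AUC being the metric of record
under imbalance. No class reweighting by default; `pos_weight` is
exposed. A single integer seed drives initialisation, batch order and
dropout masks; identical seeds give bit-identical training logs on the
same platform. Training aborts with a diagnostic on non-finite loss and
refuses single-class training sets.

The network stack — reverse-mode autodiff over numpy arrays, attention,
LSTM, Adam — lives in `guidestack.nn`, in float64 throughout. Every
layer's gradients are checked against central differences in the test
suite (relative tolerance 1e-3 at eps 1e-6, limited by ReLU kinks).

## Data cleaning

Raw pair tables are filtered in three ordered stages: rows with
ambiguity codes (N etc.) are dropped and counted; rows containing `-` or
with sequences ≠ 23 nt are indel alignments, which this substitution-only
model excludes; the remainder is deduplicated on (guide_seq, target_seq)
regardless of genomic position. Duplicates with conflicting labels keep
label 1 — positive evidence from any replicate wins — and are logged.
Filtering is idempotent.

## Evaluation protocol

ROC-AUC and PR-AUC are delegated to scikit-learn behind this package's
function surface. PR-AUC is average precision (step interpolation), not
trapezoidal, avoiding the optimistic linear interpolation on imbalanced
data; tied scores move through thresholds as one block, making both
metrics permutation-invariant within ties. Single-class inputs raise an
explicit undefined-metric error rather than returning a conventional
value. Splits are stratified (at sub-percent positive rates an
unstratified 10% split can lose every positive); k for k-fold defaults
to 5.

Leave-one-sgRNA-out: guides are sorted ascending by positive-pair count
(ties by id) and greedily accumulated into groups until each holds
≥ `min_pos` positives (default 30); a trailing shortfall merges into the
previous group, and a dataset below the threshold altogether forms one
group flagged degenerate. Each group is held out once, scored by a model
trained on all other groups, and the result reports per-group AUCs,
their means (groups whose held-out pairs are single-class are excluded
from the means but kept in the pool), and the global AUCs over the
pooled predictions. Global and average metrics genuinely differ under
imbalance; both are always reported.

## Doublet-frequency analysis

`positional_frequency` tallies each token's occurrences per window
position; with no restriction every column sums to the number of pairs.
For mismatch characterisation the matched tokens (guide half = target
half) are zeroed first — they would otherwise dominate every ranking —
and the analysis defaults to positive pairs only, since the question is
which mismatch doublets cleaved sites tolerate. Both restrictions are
flags. Ranking is by total count with lexicographic tie-break, so top-k
lists are reproducible; heatmap export writes the numeric table beside
the image.

## Synthetic data

The generator emulates the structure of genome-wide off-target screens
without any genomic input: `n_guides` random 20-nt spacers with a fixed
PAM (default AGG; held fixed so PAM-position doublets form a controlled
background), each paired with `pairs_per_guide` targets carrying m
substitutions, m drawn from a distribution over 0..6 weighted towards
3–5 (near-miss loci outnumber true sites), positions drawn without
replacement with probability proportional to a weight vector (default: a
5'-heavy ramp over the spacer, 2.0→1.0, a variable first PAM base at
1.5, near-conserved GG at 0.2 — mismatches concentrate PAM-distal, as
tolerated mismatches do in screens).

Labels are stochastic functions of the mismatch configuration only.
*Threshold*: positive iff m ≤ m\* (default 2), flipped with probability
ε (default 0.05) — gives a deterministic oracle and a computable
information ceiling. *Logistic*: Bernoulli(σ(β₀ − Σ penalties over
mismatched positions)), default β₀=1, penalty 0.8/position — gives a
calibrated-probability regime. The standard benchmark (20 guides × 300
pairs, threshold model, fixed seed, stratified 10% validation split)
has ≈ 23% positives.

What passing on this generator shows — and what it does not: the model
can recover a mismatch-count/position signal through the doublet
vocabulary at desk scale, and the evaluation machinery is correct. It
does not show real-data performance: real off-target labels also depend
on chromatin context, sequence motifs beyond substitution count, and
assay noise, and real imbalance is far heavier (down to ~0.4%
positives). Because benchmark labels carry 5% independent flips, the
Bayes-optimal validation ROC-AUC is ≈ 0.91 on the standard split and
fluctuates by a few hundredths with the generator seed (600-point
validation set); trained models land within about 0.01 of that ceiling,
so reported AUCs track the draw, not model quality, once the ceiling is
reached. The variant ordering on real data (contextual vs static) is not
a desk-scale property and is not asserted anywhere; both variants train
to well above chance on signal-bearing data.

## Problem sizes and numerical choices

Acceptance-scale runs use the reduced architecture L=2, H=2, d=16,
8 LSTM units, dense (32, 16), lr 3e-3, 10 epochs on the 6 000-pair
benchmark — about half a minute on one CPU — chosen as a comfortable
desk-scale configuration for a ~14k-parameter model; the full default
architecture (L=6, H=8, d=64) is exercised for shape contracts and is
intended for real-scale datasets. Permuted-label null fits carve their
checkpoint-selection split from the permuted labels themselves; selecting
on true validation labels would bias the null AUC upward. Float64
everywhere; sigmoid inputs clipped at ±500; LayerNorm eps 1e-5; Adam eps
1e-8; forget-gate bias initialised to 1.

## Known limitations

- Substitution mismatches only; indel alignments are filtered out by
  design, not modelled.
- No epigenomic features, no on-target efficiency, no genome scanning
  for candidate loci — inputs are already-aligned pair tables.
- The numpy network stack is single-threaded per batch and meant for
  datasets up to ~10⁵ pairs at reduced size; it is not a GPU framework.
- Checkpoints store the exact float64 weights; portability of
  bit-identical logs across BLAS builds is not guaranteed, only
  within-platform determinism.
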