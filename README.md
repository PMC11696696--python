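# guidestack

Sequence-only prediction of CRISPR-Cas9 off-target activity from aligned
sgRNA–DNA duplexes: doublet stack encoding, contextual transformer-encoder
embedding, bidirectional LSTM classification, and the evaluation protocol
that goes with it (single split, k-fold, leave-one-sgRNA-out).

## The problem

Cas9 cuts where its single-guide RNA (sgRNA) base-pairs with genomic DNA,
but tolerates mismatches: loci that differ from the intended target by up
to six substitutions can still be cleaved. Screening every candidate locus
experimentally is expensive, so guide designers want a classifier that
scores an aligned 23-nt sgRNA/target pair (20-nt spacer + 3-nt PAM) as
cleaved or not, using sequence alone. Positive sites are rare — real
screens run from ~0.4% to ~20% positives — so ranking quality under class
imbalance (PR-AUC) matters more than raw accuracy.

## The method

**Doublet stack encoding.** A two-base window slides 5'→3' over the
aligned duplex with a one-base step. Each window stacks the guide
dinucleotide on the target dinucleotide, giving one token out of
4⁴ = 256 possibilities ("GG to TC" means guide `GG` aligned over target
`TC`); a 23-bp pair becomes a sequence of 22 tokens. The doublet mimics
the local base-stacking energy configuration of the R-loop; singlet
(k=1, 16 tokens) and triplet (k=3, 4096 tokens) encodings are available
for comparison. Token index = base-4 value of the concatenated string
with A=0, C=1, G=2, T=3.

**Contextual embedding.** The token sequence, plus learned positional
embeddings, passes through a stack of transformer-encoder blocks
(defaults: 6 layers, 8 attention heads, embedding dimension d = 64),
trained from scratch — no pretraining — so each doublet's representation
depends on its neighbours and its position. The *static* variant skips
the encoder stack and uses plain word embeddings.

**BiLSTM classifier.** A bidirectional LSTM reads the embedded sequence;
its concatenated final hidden states (h⃗_T ; h⃖_T) feed two ReLU dense
layers and a sigmoid output giving P(cleaved). Training minimises binary
cross-entropy with Adam; the checkpoint with the best validation PR-AUC
is kept.

The network stack (attention, LSTM, autodiff, Adam) is implemented in
numpy inside `guidestack.nn` and is gradient-checked against numerical
differentiation in the test suite.

**Evaluation.** ROC-AUC and PR-AUC (average precision), stratified
single-split and k-fold validation, and leave-one-sgRNA-out (LOSO):
guides are sorted by positive-pair count and merged, ascending, until
every held-out group carries ≥ 30 positives; each group is scored by a
model trained on all the others, and both the pooled (global) metrics and
the per-group averages are reported.

## Worked example

Everything runs on synthetic data with a known label model, so no
downloads are needed. The standard benchmark draws 20 guides × 300
aligned targets with 0–6 positionally biased mismatches; a pair is
positive iff it has ≤ 2 mismatches, with 5% label flips (≈ 23%
positives).

```python
import guidestack as gs
from guidestack.encoding import tokenize_pairs

train, val = gs.recoverable_benchmark()          # 20 guides x 300 pairs, fixed seed
X_tr, y_tr, _ = tokenize_pairs(train)           # (5400, 22) doublet tokens
X_val, y_val, _ = tokenize_pairs(val)

clf = gs.CrisprDuplexClassifier(
    variant="contextual", n_layers=2, n_heads=2, embed_dim=16,
    lstm_units=8, dense_units=(32, 16), learning_rate=3e-3,
    epochs=10, random_state=0,
)
clf.fit(X_tr, y_tr, validation_data=(X_val, y_val))

scores = clf.predict_proba(X_val)[:, 1]
print(f"parameters:   {clf.n_parameters_}")
print(f"best epoch:   {clf.best_epoch_}")
print(f"val ROC-AUC:  {gs.roc_auc(y_val, scores):.3f}")
print(f"val PR-AUC:   {gs.pr_auc(y_val, scores):.3f}")
```

prints

```
parameters:   13697
best epoch:   9
val ROC-AUC:  0.909
val PR-AUC:   0.862
```

A held-out ROC-AUC of 0.909 means a randomly chosen cleaved pair outranks
a randomly chosen negative 91% of the time — at the information ceiling
of this benchmark, since labels depend only on the mismatch count and the
Bayes-optimal score (the count itself) achieves 0.908 on the same split.
PR-AUC 0.862 at 23% prevalence means high precision is held deep into the
recall range.

The same estimator composes with scikit-learn tooling
(`clone`, `get_params`, pipelines), and the command line mirrors the
library:

```
guidestack simulate --n-guides 20 --pairs-per-guide 300 --seed 0 --out data/
guidestack train data/train.csv data/val.csv --n-layers 2 --n-heads 2 \
    --embed-dim 16 --lstm-units 8 --learning-rate 3e-3 --epochs 10 --out run/
guidestack evaluate run/checkpoint data/val.csv --out run/eval
guidestack loso data/train.csv --min-pos 30 --out run/loso
guidestack analyze data/train.csv --top-k 50 --out run/doublets
```

`analyze` writes the positional doublet-frequency heatmap (rows =
"XY to ZW" tokens, columns = window positions 1–22) that characterises
which mismatch doublets occur where.

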