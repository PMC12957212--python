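# paircraft

Sequence-based prediction of pairwise ncRNA–ncRNA interactions.

Non-coding RNAs (lncRNA, circRNA, miRNA, snRNA, snoRNA, scaRNA, scRNA, ...)
regulate each other through physical pairing, but experimentally mapped
interactions cover only a sliver of the possible pairs. `paircraft`
implements a supervised pipeline that learns to score candidate pairs from
primary sequence alone: it builds a labeled dataset from a FASTA file, a
sequence→type map and a curated positive edge list; generates presumed
negatives by **type-constrained corruption**; expands training pairs by a
**factor-4 order/orientation symmetry augmentation**; featurizes each pair
with a pluggable token embedder plus pooling; and trains a feed-forward
classifier with imbalance-aware mini-batches and an MCC-tuned decision
threshold. It is aimed at computational biologists who have (or can export)
an interaction edge list and want a reproducible, fully testable training
and evaluation harness around it.

## The model

Let S = {s_i} be the sequences and φ(s) ∈ T the ncRNA class of s. An
interaction is an *unordered* pair of distinct molecules, (s_i, s_j) =
(s_j, s_i), and its type is the unordered class pair (φ(s_i), φ(s_j)).

**Negative sampling.** Only positives P are observed. For each positive
(s_i, s_j) the sampler keeps s_i fixed and draws up to n = 20 candidates
s′ with

&nbsp;&nbsp;&nbsp;&nbsp;s′ ≠ s_i,&nbsp;&nbsp; φ(s′) = φ(s_j),&nbsp;&nbsp; (s_i, s′) ∉ P,

deduplicated globally, so the negative set preserves the positives'
type-pair distribution in expectation and never fabricates pairs between
classes that are not known to interact.

**Symmetry augmentation.** After splitting (never before — that would leak),
each instance (s_i, s_j) expands into the four presentations
(s_i, s_j), (s_j, s_i), (s_i^F, s_j^F), (s_j^F, s_i^F), where ^F reverses
the nucleotide order. N instances become exactly 4N.

**Featurization.** A token embedder maps a sequence to X ∈ R^{L×H}; pooling
collapses it to e_avg = mean_i x_i, e_max = cmax_i x_i, or [e_avg; e_max].
A pair is represented by the concatenation [e(left); e(right)], order
significant. Any external RNA language model can be plugged in through the
`TokenEmbedder` contract; the bundled `KmerToyEmbedder` (deterministic
k-mer lookup) makes the whole pipeline runnable and testable offline.

**Classifier.** input → [1024-unit ReLU + dropout 0.2] × 4 → sigmoid,
trained with binary cross-entropy and Adam (η = 5·10⁻⁴, linear warmup 4
epochs then cosine decay, ≤ 50 epochs, early stopping with patience 10,
best-validation-loss model restored). Mini-batches of m = 512 carry a fixed
negative fraction r (positives drawn with replacement, negatives without,
per epoch). The decision threshold t is chosen on validation data by
maximizing the Matthews correlation coefficient; calls are ŷ = [p̂ ≥ t].

**Evaluation.** Confusion-based metrics (accuracy, balanced accuracy,
precision, recall, specificity, F1, MCC) plus AUROC and AUPRC
(average-precision convention), overall and stratified per interaction type
pair. The chance baselines are AUROC = 0.5 and AUPRC = π = N₊/(N₊+N₋)
(≈ 0.0476 at the 1:20 design imbalance).

## Worked example

The synthetic generator plants a recoverable signal: each interacting type
pair gets a motif M and its reverse-paired partner M′ (A↔U, C↔G on the
reversed motif); a pair truly interacts iff one member contains M and the
other M′. Labels carry 5% noise.

```python
import paircraft as pc

data = pc.generate(seed=1)                      # 600 sequences, 1,480 positives
dataset = pc.InteractionDataset(sequences=data.sequences,
                                positives=data.positives)
embedder = pc.KmerToyEmbedder(k=3, stride=1, H=64, seed=7)
model = pc.InteractionModel(
    dataset, embedder, pooling="avg",
    classifier_config=pc.ClassifierConfig(input_dim=128, hidden_layers=2,
                                          hidden_width=64),
    train_config=pc.TrainConfig(max_epochs=50, patience=10),
)
results = model.fit(seed=1)
print(results.summary())
```

```
Interaction classifier results
==============================================================
pooling:        avg    embedder: kmer-toy:k=3:stride=1:H=64:seed=7
augment train:  True    augment eval: True
classifier: 2 x 64 hidden, dropout 0.2, 12,481 parameters
seed: 1
--------------------------------------------------------------
train/val/test pairs: 20962/5241/2911
best epoch: 26    stopped: 36    best val loss: 0.1372
decision threshold (MCC-tuned): 0.6431 (validation MCC 0.6325)
--------------------------------------------------------------
test  AUROC: 0.9408    AUPRC: 0.5828 (prevalence 0.0508)
test  MCC: 0.6440    F1: 0.6567    balanced acc: 0.8727
test  confusion: TP=460 FP=349 FN=132 TN=10703
==============================================================
```

Reading it: the fit sampled ~18.7 type-matched negatives per positive
(pool exhaustion for hub molecules is logged), split 72/18/10 with
type-pair stratification, augmented every split ×4, and stopped when the
validation loss had not improved for 10 epochs. Test AUROC 0.94 and AUPRC
0.58 — against a prevalence baseline of 0.051 — show the classifier
recovering the planted motif co-occurrence signal; the MCC-tuned threshold
0.64 trades 349 false positives for 460 of the 592 true pairs. Training
without augmentation but evaluating on the same augmented test set drops
AUROC to ≈ 0.66: the network does not learn presentation invariance unless
augmentation enforces it.

The same pipeline is scriptable from the shell:

```bash
paircraft simulate --seed 7 --out data/
paircraft build-dataset --fasta data/sequences.fasta --types data/types.tsv \
    --edges data/positive_edges.tsv --out work/
paircraft sample-negatives --dataset work/ --n 20 --seed 7 --out work/
paircraft split --dataset work/ --negatives work/negatives.tsv --seed 7 --out work/
paircraft augment --splits work/splits.tsv --out work/instances.tsv
paircraft train --dataset work/ --instances work/instances.tsv \
    --dim 64 --hidden-width 64 --hidden-layers 2 --seed 7 --out model/
paircraft predict --dataset work/ --model model/ \
    --instances work/instances.tsv --out predictions.tsv
paircraft evaluate --predictions predictions.tsv --out eval/
```

Every stage writes a JSON manifest (parameters, seeds, content digests);
rerunning with the same config and seeds reproduces the TSV outputs
byte-identically.

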