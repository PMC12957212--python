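# Methods

This note records the modelling choices behind `paircraft`: the procedure
and its assumptions, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical conventions the
implementation commits to.

## Problem setting and assumptions

The task is binary: given two ncRNA sequences and their class labels
(lncRNA, circRNA, miRNA, snRNA, snoRNA, scaRNA, scRNA, ncRNA, pseudo),
score the probability that they physically interact. Three assumptions
shape the pipeline:

1. **Interactions are unordered.** (s_i, s_j) and (s_j, s_i) are the same
   edge; identity is realized by canonical (lexicographic) id ordering, and
   the classifier is *taught* the symmetry through augmentation rather than
   having it built into the architecture.
2. **Unobserved pairs are presumed negative.** Curated resources record
   positives only. Any same-type-pair combination not listed as positive is
   treated as a negative — an approximation that necessarily mislabels
   undiscovered true interactions.
3. **Type pairs carry distinct signal.** Interactions are stratified by the
   unordered class pair throughout: rare-type filtering, negative
   corruption, splitting and per-type reporting all operate on that unit.

## Dataset construction

Sequences arrive as FASTA plus a two-column id→type map; positive edges as
a two-column id list. Loading normalizes to the uppercase RNA alphabet
(T→U, case folded), hard-errors on duplicate ids, unmapped ids and
non-ACGU/T characters, drops self-loops (logged), and collapses duplicate
edges in either order.

Two filters apply, in this order:

* **Length filter** — keep sequences ≤ `max_nt` (default 4,096 nt,
  boundary inclusive). The cutoff is a nucleotide-count proxy for the
  context window of long-context RNA language models whose BPE tokenizers
  compress roughly 4 nt/token; filtering by nucleotides keeps the rule
  deterministic and tokenizer-independent.
* **Rare-type-pair filter** — remove entire interaction type pairs with
  fewer than `min_count` (default 100) positives; classes with negligible
  support contribute noise rather than learnable signal. Sequences no
  longer referenced by any retained pair leave the working set.

## Negative sampling

For each positive (s_i, s_j), the first (canonical) member is held fixed
and candidates s′ are drawn uniformly with rejection until `n` (default
20) negatives are found, subject to: s′ ≠ s_i; φ(s′) = φ(s_j); (s_i, s′)
not positive; and the canonical pair not already sampled anywhere in the
run (global deduplication). Rejection is capped at 100·n draws per
positive, after which the eligible pool is enumerated exhaustively —
guaranteeing termination when pools are nearly exhausted. An exhausted pool
yields fewer than n (possibly zero) negatives with a logged warning, never
an error; with 600-sequence default pools the realized ratio is ≈ 18.7:1
rather than the designed 20:1, which is inherent to per-anchor pool sizes
under global deduplication.

Negatives are sampled **once** from the full positive set, before
splitting, and the labeled pool is then split jointly. This fixes the
global test-time imbalance and guarantees positive/negative disjointness;
the alternative (resampling per split) would leave the test imbalance
dependent on stratum composition.

## Splitting, augmentation, batching

* **Split** — stratified by (type pair, label): 10% test, then 20% of the
  remainder for validation (72/18/10 overall). Per-stratum counts use
  largest-remainder rounding; single-member strata go to train (logged) so
  no class silently disappears. Deterministic under seed.
* **Augmentation** — strictly after splitting, each original instance
  yields exactly 4 oriented instances: original, order-reversed, flipped
  (both sequences character-reversed — *not* reverse complement: the flip
  changes reading orientation, not strand), and both. Duplicates from
  palindromic sequences are kept so the 4× count is exact. Both training
  and evaluation splits are augmented by default; each oriented test
  instance is scored and counted independently. A `positives_only` switch
  restricts expansion to positives for ablation. Negatives are augmented
  too by default: the presentation symmetries are label-independent.
* **Batching** — each batch of m = 512 holds m_n = round(r·m) negatives
  (r default 0.7, i.e. 70% negatives) and m_p = m − m_n positives.
  Positives are drawn with replacement (they are scarce); negatives without
  replacement within an epoch, reshuffled across epochs, so the abundant
  class is covered broadly. The epoch ends when fewer than m_n negatives
  remain. Rounding of r·m is half-away-from-zero; r·m rounding to 0 or m
  is rejected as a degenerate mix.

## Featurization

The token embedder is a contract: deterministic per instance, L
non-decreasing in sequence length, hard error beyond the context limit,
with a fingerprint that changes whenever the embedding function changes.
Adapters for external language models must strip special/delimiter tokens
before handoff (pooling semantics stay uniform) and are assumed to expose
final-layer hidden states, recording the layer in the fingerprint. Flipped
sequences are re-embedded, not flipped at the embedding level — the only
reading under which the embedding of an orientation reflects its token
sequence.

The bundled `KmerToyEmbedder` tokenizes into k-mers at a fixed stride
(final partial k-mer kept) and maps each distinct k-mer to a fixed
H-dimensional standard-normal vector keyed by (seed, CRC32(k-mer)) — fully
deterministic across processes, and orientation-sensitive since reversal
changes the token multiset.

Pooling: `avg` (column mean), `max` (column maximum), `concat`
([avg; max]). A pair feature is [e(left); e(right)] — dimension 2·d_mol,
so 2H for avg/max and 4H for concat. The classifier input dimension is
always 2·d_mol: the pair must see both molecules. (A config override can
reproduce single-molecule input widths for comparison with other
conventions.)

## Classifier and optimization

Architecture: input → `hidden_layers` × [linear → ReLU → inverted dropout]
→ single sigmoid unit. Defaults: 4 hidden layers of width 1,024, dropout
0.2. Weights use fan-in-scaled (He) normal initialization under a recorded
seed; biases start at zero.

Optimization: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — conventional
defaults, recorded in the manifest), binary cross-entropy, peak learning
rate η = 5·10⁻⁴. The schedule is stepped per epoch: linear ramp from 0 at
epoch 0 to η at epoch 4, then cosine decay to 0 at `max_epochs` (50).
Early stopping monitors unweighted BCE on the (augmented) validation split
at its natural class composition — batch balancing applies to training
batches only, never to the loss. Any strict decrease counts as improvement
(no minimum delta); after `patience` (10) epochs without improvement,
training stops and the best-epoch parameters are restored. Non-finite
losses abort with diagnostics.

The decision threshold maximizes MCC on validation scores over the
midpoints of consecutive distinct sorted scores plus {0, 1} — a candidate
set provably containing a global maximizer, since MCC at a threshold
depends only on the induced confusion counts, which change only when the
threshold crosses an observed score. Ties break toward the smaller
threshold. Calls use p̂ ≥ t, so a score exactly at threshold is positive.

## Metrics

Confusion-based metrics follow the standard identities; zero-denominator
cases (e.g. precision with no positive calls) return 0 with a flag rather
than raising, keeping per-stratum aggregation total. MCC with any empty
margin is 0 by convention. AUROC and AUPRC are computed by
scikit-learn behind the module surface: AUROC is the Mann–Whitney
rank statistic (ties ½), AUPRC the average-precision convention — the
recall-weighted sum of precision at positive-triggering thresholds, no
interpolation — which is the standard unbiased step-curve estimator under
strong imbalance; the convention is recorded in every report. Per-type
strata with a single class flag AUROC/AUPRC as undefined instead of
erroring. The chance AUPRC baseline is the prevalence π = N₊/(N₊+N₋).

## The synthetic generator

The generator emulates the *statistical shape* of curated ncRNA interaction
resources so every stage is testable offline:

* six classes with class-typical length scales (miRNA 18–25 nt through
  lncRNA 200–4,000 nt), 600 sequences total;
* 1,480 positives over 8 interacting type pairs with a 10:1 skew between
  the most and least common pair type;
* a planted, oracle-checkable signal: each interacting type pair draws a
  6-nt motif M and its reverse-paired partner M′ (A↔U, C↔G on the reversed
  motif). A sequence *carries* a motif iff it contains it as a substring; a
  pair truly interacts iff one member carries M and the other M′ for their
  type pair. Positive edges sample implanted carrier pairs; with
  probability ε (default 0.05) an edge is swapped for an oracle-negative
  same-type pair, so emitted labels disagree with the oracle at rate ε.

Three design choices matter for signal integrity:

* **Implant density.** Carriers receive ~1 motif copy per 100 nt, so the
  motif's share of an avg-pooled embedding does not vanish for long
  molecules (it stays ≈ k/100 of the token mass at any length).
* **Near-exhaustive positive coverage.** `carrier_oversampling` ≈ 1.25
  keeps the constructible carrier-pair pool only slightly larger than the
  requested positive count, so nearly all true interactor pairs are
  observed as positives and presumed negatives are rarely false. (Large
  pools of unsampled true pairs would poison the negative set — the same
  false-negative hazard real resources face.)
* **Hub-structured carriers.** The side the sampler holds fixed gets many
  carriers, the corrupted side few — mirroring the hubbiness of curated
  interactomes and making ~20 distinct same-type negatives per positive
  combinatorially available. Residual negative "pollution" (oracle-positive
  pairs labeled negative, mostly chance 6-mer carriers among long
  sequences) is ≈ 3%.

What the generator does **not** emulate: RNA secondary structure,
thermodynamics, accessibility, conservation, species structure, or
realistic nucleotide composition (background is uniform). Passing the
end-to-end tests therefore demonstrates that the pipeline's machinery —
filtering, sampling, augmentation, featurization, training, thresholding,
evaluation — recovers a genuine sequence-level co-occurrence signal under
realistic imbalance and length heterogeneity; it says nothing about
predictive accuracy on real interactomes, which depends on the external
embedder and data quality.

## Problem sizes and presets

The package default classifier (4×1,024 hidden, ≈ 5.2M parameters for a
2,048-dimensional input) matches the production configuration for language
-model embeddings (H = 1,024). The synthetic end-to-end preset is scaled
down — toy k-mer embedder (k = 3, stride 1, H = 64), avg pooling, 2×64
hidden, m = 512, r = 0.7, ≤ 50 epochs — sized so a full
split→augment→train→evaluate run on the default 600-sequence dataset
completes in well under a minute per seed on one CPU while leaving the
planted signal comfortably learnable (test AUROC ≈ 0.92–0.95 across
seeds; ≈ 0.66 without training augmentation under the same augmented-test
protocol). Documented grid values from exploratory tuning of the production
configuration — hidden layers {2, 4, 6}, dropout {0.1, 0.2}, batch size
{16, 512, 1024} — ship as config presets only; no automated search is
included.

## Known limitations

* The presumed-negative assumption mislabels undiscovered interactions;
  metrics on real data are accordingly conservative.
* The nucleotide length filter only approximates a tokenizer's context
  budget; borderline sequences may differ from a BPE-exact rule.
* The toy embedder encodes composition, not context; it exists to validate
  the pipeline, not to predict biology.
* Negative-pool exhaustion for hub molecules lowers the realized
  negative:positive ratio below the design value; the shortfall is logged
  and the prevalence reported with every evaluation.
* MCC-based threshold tuning optimizes a single operating point; ranking
  metrics (AUROC/AUPRC) are reported alongside precisely because that
  point is data-dependent.
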