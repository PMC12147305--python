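# Methods

This note documents the model, its parameters, the synthetic benchmark, the
numerical choices made where the design was genuinely open, and the known
limitations. Package layout follows the pipeline: `io_formats`,
`sequence_embedding`, `graph_embedding`, `deep_features`,
`attention_fusion`, `classifier`, `evaluation`, `synthetic_data`, `cli`.

## Input model and conventions

Sequences are normalized to the RNA alphabet (uppercase, T→U); records with
ambiguous bases are dropped with a warning by default, or repaired with
seeded random canonical bases (`ambiguous="randomize"`). The association
matrix is binary: `A(i,j) = 1` means a known interaction, 0 means
*unobserved* — absence of evidence, not evidence of absence. All negatives
used in training and evaluation are uniformly sampled unobserved cells; this
is the field-standard protocol and its main caveat (some "negatives" are
undiscovered positives) is inherited.

## Sequence embedding

Overlapping k-mers (stride 1) are the tokens; one embedding space is trained
over the union of the circRNA and miRNA corpora, so both molecule classes
share token geometry.

| parameter | default | meaning |
|---|---|---|
| k | 3 | k-mer length (64-token vocabulary; configurable 1–8) |
| D | 64 | embedding dimension |
| c | 5 | context window radius (tokens) |
| k_neg | 5 | negative samples per positive pair |
| noise exponent | 0.75 | unigram smoothing of the noise distribution |
| epochs | 5 | passes over all (center, context) pairs |
| lr | 0.025 | SGD rate, linearly decayed |
| P | 64 | pooling cap: tokens per sequence actually pooled |

Training is minibatch SGD on the skip-gram negative-sampling objective.
Implementation note: within a batch, all pairs sharing the same (center,
context) token identity contribute identical gradient terms, so for small
vocabularies (≤ 512) the batch collapses to dense V×V matrix updates —
the same mathematics, two orders of magnitude faster than per-pair scatter
updates. Accumulated row gradients are normalized by the number of
contributions to the row, keeping the update magnitude at per-pair SGD scale
independent of batch composition (un-normalized summed updates diverge at
the standard learning rate). The scatter path remains for large
vocabularies and for the optional FastText-style character n-gram buckets
(off by default: short k-mers are already subword units).

Token→sequence pooling is the mean of the input vectors of the first
min(T, P) tokens (`sum` pooling available). The pooling rule is a package
choice — flagged prominently because nothing in the method pins it down —
and P = 64 means only a prefix of long circRNAs informs the sequence view.

## Structural embedding (GraRep)

The bipartite graph is embedded per random-walk order k = 1..K with the
shifted positive log (PPMI-style) matrix and truncated SVD
(`H_k = U_k Σ_k^{1/2}`), concatenated across orders. The context
normalization Γ_k(j) is a **column** sum: a row sum of a row-stochastic
matrix is identically one and would collapse the PPMI structure entirely,
so the original GraRep normalization is used. Defaults K = 4, d_k = 16
(H = 64), λ = 1. Isolated nodes get zero transition rows and zero
embeddings — never NaN. SVD signs are fixed deterministically (the
largest-magnitude component of each left singular vector is made positive)
so repeated runs are bitwise identical.

## Stacked autoencoder

Two SAEs (one per molecule class) compress the pooled sequence embeddings.
Funnel 256/128/64, sigmoid activations, tied decoder weights (`Mᵀ`; untied
variant behind a flag), Glorot-uniform init, Adam lr 1e-3, batch 128, up to
20 epochs per layer with early stopping (patience 3, best weights restored)
on a 10 % held-out slice. Inputs are min-max scaled to [0,1] per feature —
a sigmoid decoder cannot reconstruct unbounded values. Greedy layer-wise
training guarantees each layer reconstructs its *own* input codes;
full-stack reconstruction compounds the per-layer errors. At the default
20-epoch budget the funnel is deliberately cheap; trained to convergence
(~150 epochs) it reconstructs rank-32 data in 64 dimensions to under 7 % of
the input variance, which is what the capacity test in the acceptance suite
measures.

Both SAEs and the skip-gram space are fitted once per dataset, not per CV
fold: they never see a label, so refitting per fold would add cost without
changing leakage properties. Only the graph embedding is fold-dependent.

The pipeline feeds only the 64-d bottleneck to fusion. Lower-order codes
(256-d, 128-d) are exposed via `sae_encode(..., depth=1|2)` for inspection;
how low- and high-order codes would be combined is an open design point and
the default deliberately keeps the simplest reading.

## Attention fusion and classifier

Four attention heads (circ/mi × stage 1/2) compute per-sample softmax
weights over feature positions and re-scale features by Hadamard product;
stage 2 acts on [attended sequence code, structural vector] per branch and
the fused vector is the concatenation of both branches, dimension 2(64+H).
Per-pair structural features are the circRNA's node vector in the circ
branch and the miRNA's node vector in the mi branch. Stage-2 parameters
are *not* shared between branches.

Attention parameters train jointly with the MLP by backpropagation through
the fusion graph (there is no separate attention objective). Three
numerical choices matter here, all adopted after the naive variant
measurably stalled:

- **Zero-initialized heads.** `W = 0, b = 0` makes the initial softmax
  exactly uniform (1/d per position), so training refines an identity-like
  re-scaling instead of a random one.
- **Two-time-scale training.** Attention updates are scaled 0.01× relative
  to the MLP (`attn_lr_scale`). A per-sample multiplicative re-weighting
  trained at parity Adam speed changes the representation faster than the
  classifier can track; slowing it restores the fixed-weights optimum and
  lets attention drift toward informative blocks on top of it.
- **Post-fusion standardization.** Softmax weights average 1/d, shrinking
  fused features by one to two orders of magnitude. Fused features are
  z-scored before the MLP with statistics fitted once, on the training
  pairs, at initialization, and held fixed — the transform stays affine
  while attention trains. Raw input blocks are standardized with
  train-fold statistics as well.

A static-ratio fusion mode (blocks scaled by fixed ratios such as 2:2:1
instead of learned attention) exists as the ablation baseline.
`mean_attention_by_block` summarizes where stage-2 mass sits (circ-seq /
mi-seq / structure, summing to one).

The classifier is one hidden layer of 100 ReLU units with sigmoid output,
BCE + 1e-4 L2 on weights, Adam (lr 1e-3, β₁ = 0.9, β₂ = 0.999). The
5000-iteration budget is read as optimizer *steps*; training is minibatch
(batch 128) because full-batch steps at the same count are ~20× slower with
no measured accuracy benefit (full batch via `batch_size: null`). Early
stopping (10 % validation slice, patience 200 steps) is available but off
by default — the production budget is fixed-length. Prediction thresholds
at 0.5 for the confusion metrics.

## Evaluation protocol

Stratified five-fold CV: each fold tests on 20 % of pairs; when early
stopping is on, the classifier holds out 1/8 of the remaining 80 % (10 %
overall), giving a 70/10/20 split. A nominal 80/10/10 split cannot coexist
with exact five-fold testing (five disjoint test folds of 10 % cover only
half the data), so canonical five-fold is implemented and this deviation is
documented rather than hidden.

Leakage control: by default (`leakage_safe: true`) each fold's graph
embedding is rebuilt with that fold's test positives removed from A, so
structural features cannot encode the held-out answers. The alternative
(`leakage_safe: false`) embeds once on the full matrix — the protocol
typically used for published CMI benchmark numbers. The difference is not
cosmetic: on the synthetic benchmark (below) embed-once reaches AUC ≈ 0.90
while leakage-safe sits at chance, because the planted cells are uniform
and the only fold-transferable signal would be sequence complementarity,
which mean-pooled 3-mer composition carries only weakly (a 7-nt motif in a
300–1500-nt molecule shifts composition by well under one standard
deviation). Published full-matrix-embedding results should be read with
this in mind; both protocols are first-class here.

Metrics: Acc, Sen, Spe, Pre, F1, MCC from exact confusion counts —
undefined ratios (zero denominators) are reported as NaN with a warning,
never silently zero — plus ROC AUC (Mann–Whitney, ties averaged) and AUPR
(step-interpolated, scikit-learn's average precision). The imbalance
experiment resamples negatives at ratios 1:1..1:5 and reruns CV per ratio.

## Synthetic benchmark

The generator emulates a sponge-mechanism interaction screen. Standard
conditions: 300 circRNAs (300–1500 nt) × 100 miRNAs (20–24 nt), positive
density 0.05 (1500 pairs), seed region = miRNA positions 2–8 (the canonical
seed), planting probability 1, label noise ε = 0.05. For each designated
positive pair the reverse complement of the miRNA seed is inserted at a
random position of the circRNA; insertion positions are rejection-sampled
so a later plant never overwrites an earlier partner's motif (otherwise the
ε = 0 invariant "positive iff motif present" breaks for ~2 % of positives).
Label noise is swap noise: an ε-fraction of planted positives is relabeled
0 and replaced by an equal number of random unplanted cells labeled 1 —
the positive count stays at the target density and both false positives and
false negatives exist. Chance 7-mer collisions in the random background are
left in deliberately (measurable via `motif_oracle`, which is rule-based,
not label-based, and bounds achievable performance from above).

What the generator does **not** emulate: thermodynamic binding,
secondary structure, degree heterogeneity, community structure, biased base
composition (a GC-bias knob exists for robustness tests), or any
correlation between a molecule's sequence and its interaction degree.
Passing the planted benchmark therefore shows the machinery recovers a
recoverable signal end-to-end; it does not certify real-data accuracy.

Benchmark results (fixed conditions above, embed-once protocol, seeds 1/2/7):
five-fold mean AUC 0.87–0.90, AUPR 0.85–0.88; permuted-label null AUC
0.49–0.50; leakage-safe AUC ≈ 0.51 for the reason given earlier. The
acceptance script recomputes all of these at its given seed; the imbalance
harness there runs at a reduced 400-step classifier budget (its assertions
concern counts, shape and finiteness, not accuracy), which keeps the full
script around seven minutes on one CPU.

## Degenerate inputs and determinism

Sequences shorter than k yield empty token lists (warning, zero vector);
all-out-of-vocabulary sequences likewise. All-zero shifted-log matrices
factorize to zero embeddings. Constant feature columns pass through
standardization unscaled with a warning. Every stochastic stage takes an
explicit seed and uses its own `numpy` generator; identical config + seed
reproduces outputs bitwise in single-threaded mode (the determinism check
in the acceptance suite asserts this).

## Limitations

- Transductive only: molecules absent from the training graph have no
  structural embedding; `predict` warns and skips unknown ids.
- The sequence channel sees only the first P = 64 tokens of each molecule;
  long circRNAs are represented by a prefix plus global k-mer statistics of
  that prefix.
- Negative sampling treats all unobserved cells as exchangeable; no
  expression, tissue or similarity filtering.
- MLP lr and the attention learning-rate scale are package choices
  (1e-3, 0.01×); neither is pinned by the method definition.
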