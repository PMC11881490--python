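# Methods

## Scope and model overview

`cardioforge` couples three components around one task — proposing
analogues of an input molecule with a desired predicted cardiac
ion-channel profile:

1. a **conditional autoregressive SMILES decoder** (generation),
2. **tri-modal channel activity predictors** (filtering), and
3. **descriptor-space cosine ranking** (candidate selection).

The transformer stacks, graph attention network and feed-forward branches
are implemented on the package's own NumPy reverse-mode autodiff engine
(`cardioforge.nn`). The engine supports exactly the primitives these
models need (batched matmul, softmax/log-softmax, layer statistics,
gather/segment-sum over edge lists) in float64 on CPU, and its analytic
gradients are tested against finite differences. This keeps the full
training and inference path dependency-light and auditable at desk scale.

## SMILES corpus processing

Tokenization is regex-based: bracket atoms (`[nH]`, `[N+]`, `[C@@H]`),
two-letter halogens (`Cl`, `Br`) and `%nn` ring-closure labels are single
tokens; all other characters stand alone. Joining tokens always
reproduces the input string (fuzz-tested on 1 000 randomized SMILES
writings). Vocabularies reserve ids 0–3 for `<pad>`, `[CLS]`, `[EOS]`,
`<MASK>`; remaining tokens are ordered by decreasing corpus frequency with
a configurable `min_count` cutoff (full-scale corpora use 1 000;
desk-scale fixtures use 1) and molecules containing dropped tokens are
removed with a logged count.

A processed sequence occupies a constant block `[CLS] content [EOS]
pads`: the 133-token limit applies to content, so the default block is 135
total. Masked-token corruption selects each content token independently
with probability 0.15 and applies mask / random / keep with probabilities
0.8 / 0.1 / 0.1; specials and pads are never selected, and the random
replacement pool is the non-special vocabulary, uniform. Train/validation
splitting is a seeded permutation split (default 95/5).

## Transformer architecture

Both models share one stack: summed learnable token and position
embeddings (plus, for the decoder, a scaffold-token embedding table
indexed by the scaffold's own token sequence padded to the block length,
and a learned linear map of the ten z-scored physicochemical properties
broadcast over positions — the only reading consistent with all
embeddings being summed), 10% embedding dropout, then pre-norm blocks:
LayerNorm → multi-head scaled-dot-product attention → residual; LayerNorm
→ 4× GeLU MLP with 10% dropout → residual; final LayerNorm and a linear
projection onto the vocabulary. Full-scale defaults are 8 blocks, 8
heads, embedding dimension 256; all dimensions scale down through
`TransformerConfig` (tests and the acceptance script use 2 blocks, 4
heads, 64 dimensions, block length 62).

The molecular **feature vector** is the `[CLS]`-position state taken
after the final LayerNorm and immediately before the vocabulary
projection ("penultimate layer" read literally), from the bidirectional
model run without dropout; it is therefore deterministic per canonical
SMILES.

Property normalization uses per-property mean/sd computed on the training
corpus and stored in the checkpoint; constant properties get sd 1 so the
normalized value is 0 rather than undefined. Checkpoints are single
`.npz` archives embedding weights, configuration, vocabulary,
normalization statistics and training metadata — loading needs no other
file.

Training: cross entropy (next-token with pad targets excluded, or
masked-token on selected positions only), AdamW. The full-scale recipe
is 100 epochs, batch 512, lr 3e-4, weight decay 0.1; the published
full-scale training used a second-order-style optimizer, but optimizer
identity is not load-bearing for the method and AdamW meets every
loss-decrease and memorization contract, so it is the default everywhere.
Weight init is N(0, 0.02) for transformer weights (He-scaled for the
predictor branches); every entry point takes an explicit seed, and runs
are bitwise reproducible on one device.

Sampling is multinomial at temperature 1.0 (optional top-k; temperature 0
is argmax) from `[CLS]` until `[EOS]` or the block limit, with an RDKit
parse as the validity filter; the validity rate is logged and callers loop
until enough valid molecules accumulate.

## Molecular featurization

The ten conditioning properties, in the fixed order that defines the
conditioning layout: molecular weight, rings, rotatable bonds, HBD, HBA,
TPSA, heteroatoms, LogP, stereocenters, formal charge (RDKit
implementations throughout; stereocenter counting includes unassigned
centers). The fingerprint is Morgan radius 2 folded to 1024 bits.

Graph nodes carry 14 features in a documented order: C/N/O/P/S
indicators, hydrophobicity, aromaticity, HBA, HBD, ring membership,
bonds-to-heavy-atoms, bonds-to-heteroatoms, Gasteiger partial charge, and
atomic mass. Design choices where the field offers several conventions:
the **hydrophobicity indicator** marks a carbon with no bonded heteroatom
(the simplest defensible atomic hydrophobicity proxy); **HBA/HBD**
membership uses the Lipinski SMARTS definitions; **partial charges** are
Gasteiger (fast, 2D), with a non-finite charge raising an error naming
the molecule. Edges store bond orders; the attention layers do not
consume them by default (the architecture aggregates node features only),
but they remain in the data model.

The wide descriptor vector evaluates a 209-name 2D descriptor list pinned
in `data/descriptors_2d.json`; the count is asserted against that file,
not against the running toolkit, because descriptor availability drifts
across toolkit versions. Non-finite descriptor values become 0 with a
warning.

**Mutual-information pruning**: descriptors are discretized into
equal-frequency bins — requested 32, capped at √n for n molecules, since
at small n one-sample bins make every pair look maximally informative —
and columns are scanned in index order, dropping any column whose
normalized mutual information with an already-kept column exceeds the
threshold (default 0.9). Constant columns are dropped first with a
warning. The later-indexed member of an offending pair is always the one
removed, making the mask deterministic and row-order invariant.

Before pruning and cosine ranking, the descriptor matrix over {input ∪
candidates} is z-scored per column: cosine similarity on raw mixed-unit
descriptors would be dominated by large-magnitude columns such as
molecular weight.

## Activity predictors

Each channel model fuses up to three branches: the 256-d transformer
feature and the fingerprint each pass through two (linear → batch-norm →
ReLU → 50% dropout) layers; the graph passes through two GAT convolutions
(self-loops added, LeakyReLU(0.2) attention logits, softmax over each
target's incoming edges, ReLU between layers; first layer concatenates
heads, second averages them) followed by global add pooling. Branch
outputs are concatenated into a head (linear → batch-norm → ReLU → 50%
dropout → linear → 1 output). Batched graphs are processed
block-diagonally, which the permutation-invariance tests cover.

Hidden sizes were tuned in the original work but not reported; the
defaults here are branch hidden 128, GAT hidden 64 with 8 heads, fused
hidden 256, all configurable (tests use half-size settings).

Training: BCE-with-logits or MSE plus an L1 penalty (1e-4) over all
parameters; AdamW (lr 3e-4, weight decay 1e-4); gradient clipping at
global norm 5.0; learning-rate halving after 10 epochs without validation
improvement; 200 epochs for classification, 100 for regression at full
scale. The returned model is the epoch snapshot with the best validation
accuracy (classification) or Pearson r (regression). Inference always
uses batch-norm running statistics, so single-molecule prediction is
well-defined. Minibatches of size 1 are skipped during training because
batch statistics are undefined there.

Labels: a compound is a blocker iff pIC50 ≥ 5.0 (the boundary value
counts as a blocker — the dataset-definition convention governs).
Replicate pIC50 values are aggregated by a one-sided upper trim at the
replicate set's 95th percentile followed by the mean; the trim is
one-sided because high outliers dominate replicate IC50 measurements.

## Re-engineering pipeline

The loop computes the input's scaffold and properties, samples the
generator in batches, canonicalizes and deduplicates (the input itself is
excluded), predicts every constrained channel, and accepts candidates
satisfying the conjunction of constraints until the target count or an
attempt cap (default 1 000 × n, guaranteeing termination) is reached.
Upper pIC50 bounds are strict (`< 6.0` excludes 6.0; displayed values are
rounded to two decimals); "improve by one log unit" constraints are
ranges relative to the input's predicted value. Accepted candidates are
ranked by cosine similarity of the processed descriptor vectors;
similarity ties break by canonical SMILES order. The chemical-space view
standardizes the ten properties over all groups (constant columns dropped
with a warning) and projects onto the top two principal components,
reporting explained-variance fractions.

## Synthetic data

The fixture corpus is assembled from a fragment grammar — 12 ring cores,
11 linkers, and substituent pools that include halogens, amides,
sulfonamides, a trifluoromethyl, a quaternary (charged) nitrogen and a
stereocenter — with ring-closure digits renumbered at join points, then
validated and canonicalized with RDKit and deduplicated. All ten
conditioning properties vary across the corpus and molecular weight spans
roughly 90–600 g/mol, so property conditioning is learnable for every
property. A 600-molecule corpus yields 350+ distinct Murcko scaffolds.

Planted activity labels emulate the correlation structure reported for
real hERG data — activity rising with lipophilicity, falling with
polarity, boosted by a basic (aromatic or charged) nitrogen:

    pIC50 = 4.4 + 0.45·LogP − 0.9·TPSA/100 + 0.8·1[basic N] + N(0, 0.4)

Coefficients were set once so labels straddle the 5.0 blocker threshold
at roughly balanced class rates (~55% blockers on the default corpus),
maximizing the statistical power of the recovery tests. What the
fixtures do **not** emulate: realistic SAR cliffs, assay noise structure,
scaffold-family confounding, or the ~78/22 class imbalance of real hERG
training sets (an imbalanced spec is available by changing the
intercept). Passing recovery tests therefore demonstrates that the
architecture and training loop can extract a planted monotone signal at
desk scale — not benchmark-level predictive performance on real
chemistry.

## Problem sizes and numerical choices

Tests and the acceptance script train on a 600-molecule corpus (60
content-token blocks) with 2-block/4-head/64-d transformers: the
generator for 60 epochs (~3 minutes on one CPU, final token loss ≈ 0.45,
~30% sampling validity), the featurizer for 8 epochs, predictors for 25
epochs; the recovery suite uses a 2 000-molecule corpus. These sizes
were chosen as the smallest at which every statistical contract (AUC >
0.8, Pearson > 0.6, rank-test conditioning shifts at α = 0.01) holds with
comfortable margins.

Other numerical decisions: float64 throughout; attention masking adds
−1e9 to disallowed scores before softmax; softmax/log-softmax subtract
the row max; BCE uses the softplus identity for stability; LayerNorm eps
1e-5; Adam eps 1e-8; the plateau scheduler treats "no improvement" with a
1e-12 tolerance. Degenerate inputs raise explicit errors: empty corpora,
single-class classification training sets, zero vectors in cosine
similarity, masking training with zero selection probability, empty
graphs.

## Known limitations

* Desk-scale checkpoints memorize a small grammar corpus; generated
  chemistry is only as diverse as that corpus, and sampling validity
  (~30%) is far below what full-scale pretraining achieves.
* The predictors' transformer branch inherits whatever the toy featurizer
  learned in a few epochs; on the fixtures most signal flows through the
  fingerprint and graph branches.
* Bond orders are featurized but unused by the default GAT, matching the
  described node-only attention.
* The NumPy engine is single-threaded and keeps whole computation graphs
  in memory; it is sized for desk-scale models, not for the ~5.5M-molecule
  pretraining regime.
* No synthesizability or on-target activity model is included; the
  filtering stage is designed so such predictors can be added alongside
  the channel constraints.
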