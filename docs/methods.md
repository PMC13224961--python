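# Methods

## Problem setting

Many mRNA properties of practical interest — expression level of a coding
variant, stability of a vaccine construct, efficacy of a regulatory element
— depend on *codon-level* features: synonymous codon usage, rare-codon
hotspots, and short codon motifs that modulate translation kinetics.
Pretrained DNA language models produce per-nucleotide embeddings
h : X → R^{L×D} that carry rich sequence information but no explicit codon
structure. This package implements a family of small trainable adapters
that sit on top of such a *frozen* backbone and turn its nucleotide-level
embeddings into codon-aware predictors of a scalar property, trained by
regression on (sequence, value) pairs.

## Architecture

Given an embedding matrix E ∈ R^{L×D} and a reading-frame offset
f ∈ {0,1,2}, the M = ⌊(L−f)/3⌋ complete codons are formed by concatenating
each triplet of consecutive rows into a 3D-wide codon vector (concatenation,
not averaging, so intra-codon position is preserved). The mixture-of-experts
layer computes, per codon c,

    mixed(c) = Σ_{k=1..K} g_k(c) · E_k(c),

where g(c) = softmax(W_g c + b_g) is a learned per-codon gate (soft, dense
routing: all K experts are evaluated, no top-k dispatch) and each expert
E_k is a two-layer perceptron 3D → h → 3D with a GELU between the layers.
The mixed codons are reshaped back to nucleotide resolution and added
residually to the covered rows of E (rows outside the frame pass through),
after which layer normalization (over the D axis, ε = 1e−5, learned
scale/shift), GELU and dropout are applied row-wise, producing the enriched
representation H ∈ R^{L×D}.

Two heads consume H:

* **base** — flatten the 3M covered rows and apply one linear map
  (3M·D → 1). Fixed-length by construction: all sequences in a dataset must
  share one length, enforced at ingest.
* **pro** — parallel banks of full-width sliding-window filters with
  window heights {3,4,5}, 100 channels each, ReLU, then max-over-time
  pooling per channel; the three pooled vectors are concatenated (300 dims
  at the defaults), passed through dropout and a final linear map. Pooling
  makes the head position-invariant for a dominant motif, which is verified
  by construction in the test suite.

Two reference baselines complete the design progression: **mean** replaces
the MoE layer by the per-codon arithmetic mean of the three nucleotide rows
(keeping the LayerNorm → GELU → dropout stack and the linear flatten head;
no residual, since the transform already carries the embedding content),
and **dense** replaces the whole codon machinery by a plain two-hidden-layer
perceptron on the flattened embeddings whose hidden width is chosen by
deterministic integer search to match a reference parameter budget within
1% (ties to the smaller width). The mean transform destroys intra-codon
order (AAT/ATA/TAA become indistinguishable up to the positional term),
which is precisely why it serves as the averaging control.

Open design points resolved here: the gate conditions on the codon's own
3D vector (per-codon routing); the residual addition happens in nucleotide
space after ungrouping; the post-residual order is LayerNorm → GELU →
dropout; expert hidden width defaults to 2·(3D); the base head flattens
exactly the covered rows.

## Frozen backbone and the synthetic stand-in

A backbone is anything that deterministically maps a sequence to an L×D
matrix; its parameters are never touched by training, and every training
run snapshots the backbone before and after and verifies bit-identity.
The built-in synthetic backbone is an additive lookup,
row_t = E_nuc[base_t] + P[t], with both tables drawn once from a seeded
standard normal stream (max length 4096). It is not a trained model and
carries no biology; it is chosen because it is exactly reproducible across
processes and because codon identity is linearly decodable from any three
consecutive rows — the property a single-nucleotide-resolution language
model provides and the adapters rely on. Wrappers around real pretrained
backbones satisfy the same contract but are deliberately outside the tested
core.

## Numerical core

No deep-learning framework is used: forward and backward passes of all four
adapters are written directly in NumPy (float64), with hand-derived
gradients for the softmax gate, the expert perceptrons, layer
normalization, the convolutional head (gradient routed through each
channel's argmax; ReLU subgradient 0 at 0; argmax ties take the first
position) and the heads. Gradients are validated against central finite
differences in the test suite. GELU uses the tanh parameterization
0.5x(1+tanh(√(2/π)(x+0.044715x³))), whose derivative is exact and cheap.
Optimization is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) on mean-squared
error over shuffled mini-batches. Targets are standardized by train-split
mean/σ (a monotone rescaling, so rank metrics are unchanged); predictions
are mapped back. Model selection is on validation Spearman — the reported
metric — with early stopping (patience in epochs) and restoration of the
best parameters. Evaluation-mode passes are deterministic and bit-exact
across reruns.

Training defaults: 200 epochs, batch 32, learning rate 1e−3, patience 20,
dropout 0.1 after enrichment and 0.5 on the pro head's concatenated
features. All run stochasticity (initialization, shuffling, dropout)
derives from one seed through named substreams.

## Synthetic task regimes

The generator produces codon-structured datasets whose signals map one-toone
onto the architectural claims:

* **usage** — y = Σ_j w(c_j) + ε: additive codon-usage score. The 64-entry
  weight table is drawn N(0,1) from the task seed and standardized so the
  sum has unit variance at the given M; realizable by any additive model.
* **hotspot** — adds γ·1[any codon ∈ hotspot set] (presence indicator, not
  count — the nonlinearity averaging cannot express). Defaults: 2 hotspot
  codons drawn from the seed, γ = 2 (about two signal standard deviations,
  a strong rare-codon effect; with M = 10 the presence rate is ≈ 27%).
* **motif** — y = exact sliding count of an ordered adjacent codon pair.
  A specific pair arises spontaneously with probability 1/64² per position,
  so uniform sequences of ten codons would leave the target almost surely
  zero; each sequence therefore has 0–3 planted copies (uniform count,
  random non-overlapping positions), and the target is recomputed from the
  final sequence so it remains an exact count.

Codons are otherwise i.i.d. uniform over the 64 codons; noise is additive
Gaussian, σ = 0.1 by default against unit-variance signals. A separate
harness task draws a random bounded function of the first two codons
(y = f₁(c₁) + f₂(c₂), two seeded 64-entry Uniform(−1,1) tables) with no
additive-over-all-codons or motif structure, used to exercise approximation
capacity.

What the generator does *not* emulate: real codon-usage distributions,
secondary structure, degradation chemistry, UTRs, length variation, or any
property of the published mRNA datasets. Passing tests therefore establish
that the implementation is correct and that each architectural component
captures the signal class it was designed for — not that any particular
real-data accuracy would be attained.

## Experiment sizes and observed behavior

The standard desk-scale conditions are n = 1000 sequences of M = 10 codons
(L = 30), backbone D = 16, 70/15/15 splits, five run seeds with shared
per-seed splits, medians across seeds (robust to an occasional bad
initialization). The approximation demo uses n = 2000. Under these
conditions the test suite verifies: the base adapter essentially ranks the
noiseless usage training set perfectly (median train ρ ≥ 0.95); on the
motif task the medians order pro > base ≥ mean; on the hotspot task base >
mean by a wide margin (averaging both loses intra-codon order and cannot
express the indicator); and the pro adapter reaches train ρ ≥ 0.9 on the
two-codon lookup function. A substitution probe (each codon substituted
into probed positions of reference sequences, prediction deltas averaged)
recovers the ranking of the true usage weights at ρ ≥ 0.9.

## Known limitations

* The base/pro heads are fixed-length; variable-length datasets must be
  padded or cropped upstream (rejected at ingest, not silently handled).
* Per-codon gating sees a single codon, not its neighborhood; cross-codon
  structure is only captured by the pro head's convolutions.
* The max-over-time head represents motif *counts* only indirectly (through
  position-specific channels), which narrows its margin over the base
  adapter on count-valued targets.
* Symbols outside {A,C,G,T,U} (including N) are rejected rather than
  imputed, since imputation would silently change codon identity.
* The dense-baseline width search assumes the two-hidden-layer shape; other
  shapes meeting the same budget are not explored.
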