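# codonmoe

Codon-aware mixture-of-experts adapters over frozen nucleotide-embedding
backbones, for predicting scalar mRNA properties (expression, stability,
regulatory efficacy) directly from sequence.

DNA language models emit per-nucleotide embeddings h : X → R^{L×D} that
lack the codon-usage information mRNA tasks hinge on. This package keeps
the backbone frozen and trains a small adapter on top of it. Codons are
formed by concatenating triplets of embedding rows; a learned softmax gate
routes every codon through K experts (two-layer GELU perceptrons):

    mixed(c) = Σ_{k=1..K} g_k(c) · E_k(c),   g(c) = softmax(W_g c + b_g)

The mixed codons are added residually back at nucleotide resolution,
followed by LayerNorm → GELU → dropout, giving a codon-enriched L×D
representation. Prediction heads:

| adapter | head | captures |
|---|---|---|
| `mean`  | per-codon averaging + linear flatten | global codon-usage bias |
| `base`  | MoE enrichment + linear flatten (3M·D → 1) | rare-codon ("hotspot") effects |
| `pro`   | MoE enrichment + multi-scale conv (heights {3,4,5}, 100 channels each, max-over-time pooling, 300-dim concat) | local codon-pair/triplet motifs |
| `dense` | parameter-matched plain MLP on raw embeddings | capacity control |

Everything — including forward/backward passes and the Adam training loop —
is implemented in NumPy; no deep-learning framework is required. A
deterministic synthetic backbone (seeded nucleotide + position lookup
tables) makes the whole pipeline runnable and testable without any
pretrained weights; real backbones plug in through the same one-method
contract (`embed(seq) -> (L, D) array`).

## Worked example

```python
from codonmoe import CodonAdapter, SyntheticTaskSpec, TrainConfig, make_dataset

# additive codon-usage task: y = sum of per-codon weights, no noise
data = make_dataset(SyntheticTaskSpec(n=1000, M=10, task_kind="usage",
                                      noise_sigma=0.0, seed=1))
res = CodonAdapter(data, adapter="base").fit(TrainConfig(seed=0))
print(res.summary())
```

```
Codon adapter regression results
============================================
Adapter:              base
Backbone dim D:       16
Sequence length L:    30
Trainable params:     38149
Epochs run:           200
Seed:                 0
--------------------------------------------
split        n    Spearman rho
train      700          0.9973
val        150          0.9881
test       150          0.9882
============================================
```

The usage signal is additive per codon and therefore realizable by the
adapter: the fitted model ranks the 700 training sequences almost perfectly
(ρ = 0.997) and generalizes to the held-out splits (ρ ≈ 0.988). `res`
also carries `res.spearman`, `res.history` (per-epoch loss and validation
ρ), `res.predict(...)` and `res.save(path)`.

The same workflows are scriptable from the shell:

```bash
codonmoe simulate --out-prefix demo --task-kind hotspot --n 1000 --m 10 --seed 1
codonmoe train demo.csv --adapter base --out-prefix run --seed 0
codonmoe predict demo.csv run.ckpt.npz --out preds.tsv
codonmoe evaluate preds.tsv
```

See `docs/methods.md` for the model, the synthetic task regimes and all
numerical choices.

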