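"""The adaptive mixture-of-codon-experts layer and the base prediction head.

Each complete codon is a 3·D vector (three concatenated nucleotide
embeddings). A learned gate — a softmax over an affine map of the codon's
own vector — produces K nonnegative mixing weights summing to one, and K
expert networks (two-layer perceptrons with GELU) each transform the codon;
the layer output is the gate-weighted convex combination

    mixed_j = Σ_k  g_k(c_j) · E_k(c_j).

Routing is *soft and dense*: every expert is evaluated for every codon and
the gate decides which perspective dominates, so rare but functionally
critical codons can receive dedicated capacity without any sparse-dispatch
machinery.

`enrich` recombines the mixed codons with the original sequence: the mixed
matrix is ungrouped back to nucleotide resolution and added residually to
the covered rows of the backbone embedding (uncovered rows pass through),
after which layer normalization, GELU and dropout are applied row-wise. The
result keeps the backbone's L×D shape, so any head can consume it.

The functions here are the single-sequence reference implementation of the
architecture; `adapters` holds the batched training engine, which must agree
with these exactly in evaluation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnops
from .errors import ContractError, ValidationError
from .nnops import ParamDict
from .restructure import CodonTensor, group_codons, ungroup_codons

__all__ = [
    "MoEConfig",
    "EnrichedRepresentation",
    "init_moe_params",
    "init_base_head",
    "gate",
    "expert_forward",
    "moe_mix",
    "enrich",
    "base_head",
]


@dataclass
class MoEConfig:
    """Mixture-of-codon-experts hyperparameters.

    K=4 experts by default: enough capacity for the major codon-usage
    regimes (high-frequency vs rare, GC-rich vs AT-rich) at small cost.
    Expert hidden width defaults to twice the codon width 3·D.
    """

    D: int
    K: int = 4
    expert_hidden: int | None = None
    dropout_p: float = 0.1

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if self.expert_hidden is None:
            self.expert_hidden = 2 * self.codon_dim
        if self.expert_hidden < 1:
            raise ValidationError("expert_hidden must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValidationError(f"dropout_p must be in [0,1), got {self.dropout_p}")

    @property
    def codon_dim(self) -> int:
        return 3 * self.D


@dataclass
class EnrichedRepresentation:
    """Codon-enriched sequence representation (same L×D shape as the input)."""

    values: np.ndarray  # (L, D)
    mode: str  # "training" | "evaluation"
    frame_offset: int = 0
    n_codons: int = 0

    @property
    def covered(self) -> slice:
        return slice(self.frame_offset, self.frame_offset + 3 * self.n_codons)


def init_moe_params(config: MoEConfig, rng: np.random.Generator) -> ParamDict:
    """Gate, expert and layer-norm parameters (head initialized separately)."""
    cd, K, H = config.codon_dim, config.K, config.expert_hidden
    gate_W, gate_b = nnops.affine_init(rng, cd, K)
    W1 = rng.standard_normal((K, cd, H)) / np.sqrt(cd)
    W2 = rng.standard_normal((K, H, cd)) / np.sqrt(H)
    return {
        "gate_W": gate_W,
        "gate_b": gate_b,
        "W1": W1,
        "b1": np.zeros((K, H)),
        "W2": W2,
        "b2": np.zeros((K, cd)),
        "ln_gamma": np.ones(config.D),
        "ln_beta": np.zeros(config.D),
    }


def init_base_head(n_inputs: int, rng: np.random.Generator) -> ParamDict:
    w, b = nnops.affine_init(rng, n_inputs, 1)
    return {"head_w": w[:, 0], "head_b": b}


def gate(c: np.ndarray, gate_W: np.ndarray, gate_b: np.ndarray) -> np.ndarray:
    """Per-codon mixing weights: softmax of an affine map of the codon vector."""
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ContractError("gate input contains non-finite values")
    return nnops.softmax(c @ gate_W + gate_b)


def expert_forward(c: np.ndarray, k: int, params: ParamDict) -> np.ndarray:
    """Expert k applied to one codon vector: Linear → GELU → Linear."""
    h = nnops.gelu(c @ params["W1"][k] + params["b1"][k])
    return h @ params["W2"][k] + params["b2"][k]


def moe_mix(C: CodonTensor | np.ndarray, config: MoEConfig, params: ParamDict) -> np.ndarray:
    """Gate-weighted sum of expert outputs, row per codon (M × 3·D)."""
    X = C.values if isinstance(C, CodonTensor) else np.asarray(C, dtype=float)
    G = gate(X, params["gate_W"], params["gate_b"])  # (M, K)
    out = np.zeros_like(X)
    for k in range(config.K):
        out += G[:, k : k + 1] * expert_forward(X, k, params)
    return out


def enrich(
    E: np.ndarray,
    mixed: np.ndarray,
    config: MoEConfig,
    params: ParamDict,
    mode: str = "evaluation",
    frame_offset: int = 0,
    rng: np.random.Generator | None = None,
) -> EnrichedRepresentation:
    """Residual recombination followed by LayerNorm → GELU → dropout.

    ``mixed`` must come from :func:`moe_mix` on ``group_codons(E, offset)``;
    it is ungrouped to nucleotide resolution and added to the covered rows of
    E. Dropout is the identity in evaluation mode.
    """
    E = np.asarray(E, dtype=float)
    L, D = E.shape
    M = mixed.shape[0]
    if mixed.shape != (M, 3 * D) or frame_offset + 3 * M > L:
        raise ContractError(
            f"mixed shape {mixed.shape} incompatible with embedding {E.shape} "
            f"at frame offset {frame_offset}"
        )
    ct = CodonTensor(mixed, frame_offset, 0, D)
    Y = E.copy()
    cov = slice(frame_offset, frame_offset + 3 * M)
    Y[cov] += ungroup_codons(ct)
    Z, _ = nnops.layer_norm(Y, params["ln_gamma"], params["ln_beta"])
    A = nnops.gelu(Z)
    if mode == "training" and config.dropout_p > 0.0:
        if rng is None:
            raise ContractError("training-mode enrich requires an rng for dropout")
        A = A * nnops.dropout_mask(A.shape, config.dropout_p, rng)
    elif mode not in ("training", "evaluation"):
        raise ContractError(f"unknown mode {mode!r}")
    return EnrichedRepresentation(A, mode, frame_offset, M)


def base_head(H: EnrichedRepresentation, params: ParamDict) -> float:
    """Scalar prediction: linear map of the flattened covered rows.

    Fixed-length head — the flattened dimension 3·M·D must match the weight
    vector, so all sequences in a dataset must share one length.
    """
    flat = H.values[H.covered].ravel()
    w = params["head_w"]
    if flat.shape != w.shape:
        raise ContractError(
            f"base head expects {w.shape[0]} inputs, got {flat.shape[0]}"
        )
    return float(flat @ w + params["head_b"][0])
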