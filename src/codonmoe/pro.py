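"""Hierarchical multi-scale convolutional head ("pro" variant).

The enriched L×D representation is scanned by parallel banks of
full-width sliding-window filters with window heights {3, 4, 5} (trigram,
4-gram and 5-gram nucleotide motifs), each bank with 100 output channels
and a ReLU. Max-over-time pooling keeps, per channel, the strongest
response anywhere in the sequence — position-invariant motif detection —
and the pooled vectors are concatenated (300 dims at the defaults),
passed through dropout, and projected to a scalar by a final linear map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnops
from .errors import ContractError, SequenceLengthError, ValidationError
from .moe import EnrichedRepresentation
from .nnops import ParamDict

__all__ = [
    "ProHeadConfig",
    "FeatureMap",
    "init_pro_head",
    "conv_branch",
    "max_over_time",
    "pro_predict",
    "motif_invariance_check",
]


@dataclass
class ProHeadConfig:
    """Multi-scale convolution head hyperparameters."""

    D: int
    kernel_sizes: tuple[int, ...] = (3, 4, 5)
    c_out: int = 100
    dropout_p: float = 0.5

    def __post_init__(self):
        self.kernel_sizes = tuple(sorted(self.kernel_sizes))
        if not self.kernel_sizes or any(k < 1 for k in self.kernel_sizes):
            raise ValidationError("kernel sizes must be positive")
        if self.c_out < 1:
            raise ValidationError("c_out must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValidationError("dropout_p must be in [0,1)")

    @property
    def concat_dim(self) -> int:
        return len(self.kernel_sizes) * self.c_out


@dataclass
class FeatureMap:
    """Post-ReLU response map of one kernel size: (L−k+1) × c_out, entries ≥ 0."""

    values: np.ndarray
    kernel_size: int


def init_pro_head(config: ProHeadConfig, rng: np.random.Generator) -> ParamDict:
    """Filter banks (one per kernel size, ascending), biases, final affine."""
    params: ParamDict = {}
    for k in config.kernel_sizes:
        W, b = nnops.affine_init(rng, k * config.D, config.c_out)
        params[f"conv_W{k}"] = W.reshape(k, config.D, config.c_out)
        params[f"conv_b{k}"] = b
    w, b = nnops.affine_init(rng, config.concat_dim, 1)
    params["final_w"] = w[:, 0]
    params["final_b"] = b
    return params


def conv_branch(H: np.ndarray, k: int, filters: np.ndarray, biases: np.ndarray) -> FeatureMap:
    """Full-width sliding-window convolution with ReLU.

    ``filters`` has shape (c_out, k, D) or (k, D, c_out); entry (i, f) of the
    result is ReLU(Σ_{a,b} H[i+a, b]·filter_f[a, b] + bias_f).
    """
    H = np.asarray(H, dtype=float)
    L, D = H.shape
    if L < k:
        raise SequenceLengthError(f"sequence of {L} rows shorter than kernel height {k}")
    filters = np.asarray(filters, dtype=float)
    if filters.shape[:2] != (k, D):
        if filters.shape[1:] == (k, D):  # (c_out, k, D) layout
            filters = np.moveaxis(filters, 0, -1)
        else:
            raise ContractError(f"filter shape {filters.shape} incompatible with k={k}, D={D}")
    windows = np.lib.stride_tricks.sliding_window_view(H, (k, D)).reshape(L - k + 1, k * D)
    out = windows @ filters.reshape(k * D, -1) + biases
    return FeatureMap(np.maximum(out, 0.0), k)


def max_over_time(C: FeatureMap) -> np.ndarray:
    """Componentwise maximum over the position axis → c_out vector."""
    if C.values.shape[0] < 1:
        raise ContractError("empty feature map")
    return C.values.max(axis=0)


def pro_predict(
    H: EnrichedRepresentation | np.ndarray,
    config: ProHeadConfig,
    params: ParamDict,
    mode: str = "evaluation",
    rng: np.random.Generator | None = None,
) -> float:
    """Scalar prediction from the multi-scale convolutional head.

    The head consumes the full enriched matrix (pass-through rows included).
    Pooled vectors are concatenated in ascending kernel-size order; dropout
    on the concatenated features is the identity in evaluation mode.
    """
    Hm = H.values if isinstance(H, EnrichedRepresentation) else np.asarray(H, dtype=float)
    pooled = [
        max_over_time(conv_branch(Hm, k, params[f"conv_W{k}"], params[f"conv_b{k}"]))
        for k in config.kernel_sizes
    ]
    c = np.concatenate(pooled)
    if c.shape != params["final_w"].shape:
        raise ContractError(
            f"concatenated features ({c.shape[0]}) do not match final weights "
            f"({params['final_w'].shape[0]})"
        )
    if mode == "training" and config.dropout_p > 0.0:
        if rng is None:
            raise ContractError("training-mode pro_predict requires an rng for dropout")
        c = c * nnops.dropout_mask(c.shape, config.dropout_p, rng)
    elif mode not in ("training", "evaluation"):
        raise ContractError(f"unknown mode {mode!r}")
    return float(c @ params["final_w"] + params["final_b"][0])


def motif_invariance_check(
    config: ProHeadConfig,
    params: ParamDict,
    motif_block: np.ndarray,
    background_row: np.ndarray,
    positions: list[int],
    L: int,
) -> bool:
    """Verify position-invariance of the head for a dominant motif.

    Builds, for each start position, an L×D matrix equal to a constant
    background with ``motif_block`` (k rows) pasted in, and checks that
    evaluation-mode predictions agree across all placements within 1e-6.
    With max-over-time pooling the prediction depends only on the strongest
    response per channel, so a motif whose response dominates the background
    yields identical outputs wherever it sits (and however many copies
    exist); when the background dominates instead, placements are equally
    indistinguishable.
    """
    kb = motif_block.shape[0]
    preds = []
    for p in positions:
        if p < 0 or p + kb > L:
            raise ContractError(f"motif placement {p} outside sequence of length {L}")
        Hm = np.tile(background_row, (L, 1)).astype(float)
        Hm[p : p + kb] = motif_block
        preds.append(pro_predict(Hm, config, params, mode="evaluation"))
    preds = np.asarray(preds)
    return bool(np.all(np.abs(preds - preds[0]) <= 1e-6))
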