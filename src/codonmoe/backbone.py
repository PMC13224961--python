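"""Frozen-backbone contract and a deterministic synthetic backbone.

A backbone is any deterministic map from a normalized nucleotide sequence of
length L to an L×D real embedding matrix. Pretrained genomic language models
with single-nucleotide resolution satisfy this contract; the adapters in
this package never update backbone parameters.

:class:`SyntheticBackbone` is a self-contained backbone used throughout the
test and simulation harness: row t of the embedding of a sequence is
``E_nuc[base_t] + P[t]`` where ``E_nuc`` (4×D) and ``P`` (max_len×D) are
standard-normal lookup tables drawn once from a seed. It is cheap, exactly
reproducible across processes, and codon identity is linearly decodable from
any three consecutive rows — the property single-nucleotide-resolution
backbones provide and the adapters rely on.
"""

from __future__ import annotations

from typing import Mapping, Protocol, runtime_checkable

import numpy as np

from .errors import SequenceLengthError, ValidationError

__all__ = ["BackboneContract", "SyntheticBackbone", "freeze_check", "embed_dataset"]

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@runtime_checkable
class BackboneContract(Protocol):
    """Structural type every backbone must satisfy."""

    embed_dim: int

    def embed(self, seq: str) -> np.ndarray:  # (L, D)
        ...

    def snapshot(self) -> dict[str, np.ndarray]:
        """Copies of all parameters, for freeze verification."""
        ...


class SyntheticBackbone:
    """Additive nucleotide+position lookup backbone.

    Parameters
    ----------
    embed_dim : int
        Embedding width D (≥ 1).
    seed : int
        Seed for the two lookup tables; identical ``(embed_dim, seed)`` gives
        bit-identical embeddings on any machine.
    max_len : int
        Longest supported sequence (default 4096).
    """

    def __init__(self, embed_dim: int, seed: int, max_len: int = 4096):
        if embed_dim < 1:
            raise ValidationError(f"embed_dim must be >= 1, got {embed_dim}")
        self.embed_dim = int(embed_dim)
        self.seed = int(seed)
        self.max_len = int(max_len)
        rng = np.random.default_rng(seed)
        self._nuc_table = rng.standard_normal((4, embed_dim))
        self._pos_table = rng.standard_normal((max_len, embed_dim))

    def embed(self, seq: str) -> np.ndarray:
        L = len(seq)
        if L > self.max_len:
            raise SequenceLengthError(
                f"sequence length {L} exceeds backbone max_len {self.max_len}"
            )
        try:
            idx = np.fromiter((_NUC_INDEX[c] for c in seq), dtype=np.intp, count=L)
        except KeyError as exc:
            raise ValidationError(f"non-ACGT symbol {exc.args[0]!r} in sequence") from None
        return self._nuc_table[idx] + self._pos_table[:L]

    def snapshot(self) -> dict[str, np.ndarray]:
        return {"nuc_table": self._nuc_table.copy(), "pos_table": self._pos_table.copy()}


def freeze_check(before: Mapping[str, np.ndarray], after: Mapping[str, np.ndarray]) -> bool:
    """True iff two parameter snapshots are bit-identical.

    Used after every training run to assert the backbone was never updated.
    """
    if set(before) != set(after):
        return False
    return all(
        before[k].shape == after[k].shape
        and np.array_equal(before[k], after[k])
        for k in before
    )


def embed_dataset(backbone: BackboneContract, sequences: list[str]) -> np.ndarray:
    """Stack per-sequence embeddings into an (N, L, D) array.

    All sequences must share one length; the backbone is evaluated once per
    sequence (it is deterministic, so caching the result is safe).
    """
    if not sequences:
        return np.zeros((0, 0, backbone.embed_dim))
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValidationError(f"sequences have variable lengths {sorted(lengths)}")
    return np.stack([backbone.embed(s) for s in sequences])
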