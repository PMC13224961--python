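"""Codon grouping: nucleotide-level ↔ codon-level representations.

A length-L embedding matrix is partitioned, from a reading-frame offset in
{0, 1, 2}, into M = floor((L − offset)/3) complete codons. Each codon is
represented by the *concatenation* of its three nucleotide rows (width 3·D),
which preserves intra-codon position — AAT, ATA and TAA stay distinct.
Leading (pre-offset) and trailing (remainder) nucleotides are excluded from
codon processing but are never dropped: downstream recombination passes them
through so output length matches input length.

`codon_mean_transform` is the averaging baseline: within each complete codon
the three rows are each replaced by their arithmetic mean, which keeps only
the unordered multiset of the codon's nucleotide contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, SequenceLengthError

__all__ = ["CodonTensor", "group_codons", "ungroup_codons", "codon_mean_transform"]


@dataclass
class CodonTensor:
    """M×(3·D) codon representations plus frame bookkeeping."""

    values: np.ndarray  # (M, 3*D)
    frame_offset: int
    remainder: int
    embed_dim: int

    @property
    def n_codons(self) -> int:
        return self.values.shape[0]

    @property
    def covered(self) -> slice:
        """Row slice of the original matrix covered by complete codons."""
        return slice(self.frame_offset, self.frame_offset + 3 * self.n_codons)


def _check_frame(L: int, frame_offset: int) -> int:
    if frame_offset not in (0, 1, 2):
        raise ContractError(f"frame_offset must be in {{0,1,2}}, got {frame_offset}")
    M = (L - frame_offset) // 3
    if M < 1:
        raise SequenceLengthError(
            f"length {L} with frame offset {frame_offset} leaves no complete codon"
        )
    return M


def group_codons(E: np.ndarray, frame_offset: int = 0) -> CodonTensor:
    """Reshape an L×D embedding matrix into an M×(3·D) codon matrix.

    Row j is the concatenation of embedding rows ``offset+3j``,
    ``offset+3j+1``, ``offset+3j+2``.
    """
    E = np.asarray(E, dtype=float)
    L, D = E.shape
    M = _check_frame(L, frame_offset)
    block = E[frame_offset : frame_offset + 3 * M]
    values = block.reshape(M, 3 * D)
    return CodonTensor(values, frame_offset, L - frame_offset - 3 * M, D)


def ungroup_codons(C: CodonTensor) -> np.ndarray:
    """Exact inverse of :func:`group_codons` over the covered region: (3·M)×D."""
    M = C.n_codons
    return C.values.reshape(3 * M, C.embed_dim)


def codon_mean_transform(E: np.ndarray, frame_offset: int = 0) -> np.ndarray:
    """Replace each row of every complete codon by the codon's mean row.

    Pre-offset and remainder rows pass through unchanged. Idempotent, and
    commutes with whole-codon permutations.
    """
    E = np.asarray(E, dtype=float)
    L, D = E.shape
    M = _check_frame(L, frame_offset)
    out = E.copy()
    block = E[frame_offset : frame_offset + 3 * M].reshape(M, 3, D)
    means = block.mean(axis=1, keepdims=True)
    out[frame_offset : frame_offset + 3 * M] = np.broadcast_to(means, (M, 3, D)).reshape(3 * M, D)
    return out
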