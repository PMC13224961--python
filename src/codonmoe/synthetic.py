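"""Synthetic codon-structured regression tasks.

Three generative recipes, each planting a different kind of statistical
structure that the adapter family is designed to exploit:

``usage``
    Additive codon-usage score: y = Σ_j w(c_j) + ε. The per-codon weight
    table w is drawn once from the task seed and standardized so the sum
    has unit variance at the given number of codons M. This signal is
    exactly realizable by any additive per-codon model — averaging included.
``hotspot``
    Usage score plus a rare-codon effect: y = Σ_j w(c_j) + γ·1[any codon in
    the hotspot set] + ε. The *indicator* (presence, not count) is the
    nonlinearity uniform averaging cannot express, so expert routing is
    required to capture it fully.
``motif``
    Count of an ordered adjacent codon pair: y = #{j : (c_j, c_{j+1}) =
    motif_pair} + ε. Depends only on adjacent-codon joint identities —
    the local-context signal the convolutional head targets. Because a
    specific ordered pair occurs spontaneously with probability 1/64² per
    position, unconstrained uniform sequences would leave the target almost
    surely zero at desk scale; motif occurrences are therefore planted
    (0–3 copies per sequence, uniform, at random non-overlapping positions)
    and the target is the exact sliding-window count of the final sequence.

Codons in sequences are i.i.d. uniform over the 64 codons apart from the
planting step. Noise is additive Gaussian with σ defaulting to 0.1 of the
unit-variance signal scale. Every draw flows from the task seed through
named substreams, so a task spec reproduces its dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import SequenceLengthError, ValidationError
from .sequence_io import Dataset, SequenceRecord

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "SyntheticTaskSpec",
    "gen_sequences",
    "target_usage",
    "target_hotspot",
    "target_motif",
    "make_dataset",
    "make_lookup_dataset",
]

#: The 64 codons in lexicographic (A<C<G<T) order.
CODONS: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}


def seq_to_codon_indices(seq: str) -> np.ndarray:
    if len(seq) % 3 != 0:
        raise SequenceLengthError(f"sequence length {len(seq)} not divisible by 3")
    return np.array([CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)])


def draw_codon_weights(rng: np.random.Generator, M: int) -> np.ndarray:
    """64 weights ~ N(0,1), standardized so Σ_{j≤M} w(c_j) has unit variance
    under uniform codon draws (population mean 0, variance 1/M)."""
    w = rng.standard_normal(64)
    w = (w - w.mean()) / w.std()
    return w / np.sqrt(M)


@dataclass
class SyntheticTaskSpec:
    """Generative recipe for one synthetic dataset."""

    n: int
    M: int
    task_kind: str  # usage | hotspot | motif
    seed: int = 0
    noise_sigma: float = 0.1
    w: np.ndarray | None = None              # 64 per-codon weights
    hotspot_set: tuple[str, ...] | None = None
    gamma: float = 2.0
    motif_pair: tuple[str, str] | None = None
    name: str | None = None

    def __post_init__(self):
        if self.task_kind not in ("usage", "hotspot", "motif"):
            raise ValidationError(f"unknown task_kind {self.task_kind!r}")
        if self.n < 1 or self.M < 2:
            raise ValidationError("need n >= 1 and M >= 2")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.w is None and self.task_kind in ("usage", "hotspot"):
            self.w = draw_codon_weights(self.stream("weights"), self.M)
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float)
            if self.w.shape != (64,):
                raise ValidationError("w must hold one weight per codon (64)")
        if self.task_kind == "hotspot" and self.hotspot_set is None:
            picks = self.stream("structure").choice(64, size=2, replace=False)
            self.hotspot_set = tuple(CODONS[i] for i in picks)
        if self.task_kind == "hotspot" and not self.hotspot_set:
            raise ValidationError("hotspot task requires a nonempty hotspot_set")
        if self.task_kind == "motif" and self.motif_pair is None:
            picks = self.stream("structure").choice(64, size=2, replace=True)
            self.motif_pair = (CODONS[picks[0]], CODONS[picks[1]])
        if self.name is None:
            self.name = f"{self.task_kind}_n{self.n}_M{self.M}_seed{self.seed}"

    _STREAM_IDS = {"weights": 0, "structure": 1, "sequences": 2, "noise": 3}

    def stream(self, which: str) -> np.random.Generator:
        """Fresh, named random substream derived from the spec seed.

        Re-deriving (rather than storing) the generators makes every
        generation call a pure function of the spec.
        """
        children = np.random.SeedSequence(self.seed).spawn(len(self._STREAM_IDS))
        return np.random.default_rng(children[self._STREAM_IDS[which]])


def gen_sequences(spec: SyntheticTaskSpec) -> list[str]:
    """n sequences of length 3·M, codons i.i.d. uniform over the 64 codons
    (plus planted motif copies for the motif task); deterministic per seed."""
    rng = spec.stream("sequences")
    draws = rng.integers(0, 64, size=(spec.n, spec.M))
    if spec.task_kind == "motif":
        a, b = (CODON_INDEX[c] for c in spec.motif_pair)
        max_copies = min(3, spec.M // 2)
        for row in draws:
            copies = int(rng.integers(0, max_copies + 1))
            starts: list[int] = []
            for start in rng.permutation(spec.M - 1):
                if len(starts) == copies:
                    break
                if all(abs(start - s) >= 2 for s in starts):
                    starts.append(int(start))
            for s in starts:
                row[s], row[s + 1] = a, b
    return ["".join(CODONS[i] for i in row) for row in draws]


def _noise(sigma: float, rng: np.random.Generator | None) -> float:
    if sigma == 0.0:
        return 0.0
    if rng is None:
        raise ValidationError("sigma > 0 requires a noise stream")
    return sigma * rng.standard_normal()


def target_usage(seq: str, w: np.ndarray, sigma: float = 0.0,
                 rng: np.random.Generator | None = None) -> float:
    """y = Σ_j w(c_j) + Normal(0, σ²)."""
    return float(w[seq_to_codon_indices(seq)].sum() + _noise(sigma, rng))


def target_hotspot(seq: str, w: np.ndarray, hotspot_set, gamma: float,
                   sigma: float = 0.0, rng: np.random.Generator | None = None) -> float:
    """y = Σ_j w(c_j) + γ·1[some codon lies in hotspot_set] + Normal(0, σ²)."""
    idx = seq_to_codon_indices(seq)
    hot = {CODON_INDEX[c] for c in hotspot_set}
    present = bool(np.isin(idx, list(hot)).any())
    return float(w[idx].sum() + gamma * present + _noise(sigma, rng))


def target_motif(seq: str, motif_pair: tuple[str, str], sigma: float = 0.0,
                 rng: np.random.Generator | None = None) -> float:
    """y = number of adjacent ordered codon pairs equal to motif_pair + noise."""
    idx = seq_to_codon_indices(seq)
    a, b = (CODON_INDEX[c] for c in motif_pair)
    count = int(np.sum((idx[:-1] == a) & (idx[1:] == b)))
    return float(count + _noise(sigma, rng))


def make_dataset(spec: SyntheticTaskSpec) -> Dataset:
    """Generate the full dataset (sequences + targets) for a task spec."""
    seqs = gen_sequences(spec)
    noise_rng = spec.stream("noise")
    records = []
    for i, seq in enumerate(seqs, start=1):
        if spec.task_kind == "usage":
            y = target_usage(seq, spec.w, spec.noise_sigma, noise_rng)
        elif spec.task_kind == "hotspot":
            y = target_hotspot(seq, spec.w, spec.hotspot_set, spec.gamma,
                               spec.noise_sigma, noise_rng)
        else:
            y = target_motif(seq, spec.motif_pair, spec.noise_sigma, noise_rng)
        records.append(SequenceRecord(f"synth_{i:06d}", seq, y))
    return Dataset(records, name=spec.name)


def make_lookup_dataset(n: int, M: int, seed: int, sigma: float = 0.0) -> tuple[Dataset, np.ndarray]:
    """Random bounded function of the first two codons: y = f1(c_1) + f2(c_2).

    f1 and f2 are seeded 64-entry tables drawn Uniform(−1, 1) — a 128-entry
    lookup with no additive-over-all-codons or local-motif structure, used to
    exercise the architecture's approximation capacity. Returns the dataset
    and the (2, 64) table.
    """
    ss = np.random.SeedSequence([seed, 0x10_0C_00])
    f_rng, seq_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    tables = f_rng.uniform(-1.0, 1.0, size=(2, 64))
    draws = seq_rng.integers(0, 64, size=(n, M))
    records = []
    for i, row in enumerate(draws, start=1):
        seq = "".join(CODONS[j] for j in row)
        y = float(tables[0, row[0]] + tables[1, row[1]] + _noise(sigma, noise_rng))
        records.append(SequenceRecord(f"lookup_{i:06d}", seq, y))
    return Dataset(records, name=f"lookup2_n{n}_seed{seed}"), tables
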