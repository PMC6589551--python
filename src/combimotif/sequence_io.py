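"""Sequence I/O, base composition and background-sequence generators.

Peak sequences are held as plain uppercase strings over {A,C,G,T,N}. A
sequence's identity throughout the pipeline is its 0-based record order;
FASTA headers are carried as metadata only. N bases are retained in the
sequences but excluded from the base composition (and, downstream, any
k-mer window containing an N is skipped).

Two background generators are provided:

* :func:`generate_background` — i.i.d. bases drawn from the foreground
  composition, one background sequence per foreground sequence with the
  same length. This is the default control set when the user supplies no
  background file.
* :func:`train_markov` / :func:`sample_markov` — an order-``r`` Markov
  chain fitted with add-one smoothing, used by the synthetic benchmark
  (order 3 by default there) to emulate genomic peak background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
ALPHABET = frozenset("ACGTN")
_BASE_INDEX = {b: i for i, b in enumerate(DNA)}
_LUT = np.frombuffer(DNA.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class BaseComposition:
    """Mono-nucleotide counts and frequencies over A,C,G,T (N excluded)."""

    counts: dict[str, int]
    freq: dict[str, float]

    @classmethod
    def from_sequences(cls, sequences: list[str]) -> "BaseComposition":
        counts = {b: 0 for b in DNA}
        for s in sequences:
            for b in DNA:
                counts[b] += s.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no A/C/G/T bases: composition undefined")
        freq = {b: counts[b] / total for b in DNA}
        return cls(counts=counts, freq=freq)

    def freq_array(self) -> np.ndarray:
        return np.array([self.freq[b] for b in DNA], dtype=float)

    def smoothed_freq_array(self) -> np.ndarray:
        """Strictly positive frequencies: (count+1)/(total+4) per base.

        Used wherever a zero background frequency would be degenerate
        (log-odds columns of PWMs).
        """
        c = np.array([self.counts[b] for b in DNA], dtype=float)
        return (c + 1.0) / (c.sum() + 4.0)


@dataclass
class SequenceSet:
    """A foreground, background or synthetic set of DNA sequences."""

    sequences: list[str]
    label: str = "foreground"
    names: list[str] | None = None
    composition: BaseComposition = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("no sequences")
        for i, s in enumerate(self.sequences):
            if not s:
                raise ValueError(f"sequence {i} is empty")
            bad = set(s) - ALPHABET
            if bad:
                off = min(s.index(b) for b in bad)
                raise ValueError(
                    f"sequence {i}: invalid character {s[off]!r} at offset {off}"
                )
        if self.names is not None and len(self.names) != len(self.sequences):
            raise ValueError("names/sequences length mismatch")
        self.composition = BaseComposition.from_sequences(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.sequences]

    def name_of(self, i: int) -> str:
        return self.names[i] if self.names is not None else f"seq{i}"


def read_fasta(path, label: str = "foreground") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` (record order preserved).

    Sequences are uppercased. Raises ``ValueError`` for an empty file or for
    a record containing a non-ACGTN character (named with its offset).
    """
    sequences: list[str] = []
    names: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        bad = set(s) - ALPHABET
        if bad:
            off = min(s.index(b) for b in bad)
            raise ValueError(
                f"record {rec.id!r}: invalid character {s[off]!r} at offset {off}"
            )
        sequences.append(s)
        names.append(rec.id)
    if not sequences:
        raise ValueError("no sequences")
    return SequenceSet(sequences=sequences, label=label, names=names)


def write_fasta(seqs: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(s), id=seqs.name_of(i), description="")
        for i, s in enumerate(seqs.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def generate_background(fg: SequenceSet, seed: int) -> SequenceSet:
    """I.i.d. background matched per-sequence in number and length to ``fg``.

    Bases are drawn independently from the foreground base composition;
    bit-reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    p = fg.composition.freq_array()
    out = []
    for length in fg.lengths:
        idx = rng.choice(4, size=length, p=p)
        out.append(_LUT[idx].tobytes().decode("ascii"))
    return SequenceSet(sequences=out, label="background")


@dataclass
class MarkovModel:
    """Order-``r`` Markov chain over A,C,G,T with add-one smoothing.

    ``transition_matrix`` has one row per context (contexts enumerated in
    lexicographic/base-4 order, 4**order of them) and one column per base;
    ``initial`` is the smoothed empirical distribution of contexts.
    """

    order: int
    transition_matrix: np.ndarray  # (4**order, 4), rows sum to 1
    initial: np.ndarray  # (4**order,), sums to 1

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        n_ctx = 4**self.order
        if self.transition_matrix.shape != (n_ctx, 4):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not math.isclose(float(self.initial.sum()), 1.0, abs_tol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    @property
    def transition(self) -> dict[str, np.ndarray]:
        """Context-string view of the transition matrix."""
        return {
            self._ctx_string(i): self.transition_matrix[i]
            for i in range(4**self.order)
        }

    def _ctx_string(self, code: int) -> str:
        s = []
        for _ in range(self.order):
            s.append(DNA[code % 4])
            code //= 4
        return "".join(reversed(s))


def _encode(s: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(s.encode(), dtype=np.uint8)]


def train_markov(seqs: SequenceSet, order: int) -> MarkovModel:
    """Fit an order-``r`` chain by context-conditional counts + add-one smoothing.

    Windows containing N are skipped.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n_ctx = 4**order
    counts = np.zeros((n_ctx, 4), dtype=np.int64)
    ctx_counts = np.zeros(n_ctx, dtype=np.int64)
    for s in seqs.sequences:
        enc = _encode(s).astype(np.int64)
        L = enc.size
        if L < order + 1:
            continue
        n = L - order
        bad = (enc > 3).astype(np.int64)
        cbad = np.concatenate(([0], np.cumsum(bad)))
        valid = (cbad[order + 1 :] - cbad[: -(order + 1)]) == 0
        ctx = np.zeros(n, dtype=np.int64)
        e = np.where(enc > 3, 0, enc)
        for i in range(order):
            ctx = ctx * 4 + e[i : i + n]
        nxt = e[order : order + n]
        np.add.at(counts, (ctx[valid], nxt[valid]), 1)
        np.add.at(ctx_counts, ctx[valid], 1)
    trans = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 4.0)
    initial = (ctx_counts + 1.0) / (ctx_counts.sum() + n_ctx)
    return MarkovModel(order=order, transition_matrix=trans, initial=initial)


def sample_markov(model: MarkovModel, n: int, length: int, seed: int) -> SequenceSet:
    """Draw ``n`` sequences of exactly ``length`` bp; bit-reproducible from seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length <= model.order:
        raise ValueError("length must exceed the model order")
    rng = np.random.default_rng(seed)
    order = model.order
    n_ctx = 4**order
    out = np.empty((n, length), dtype=np.uint8)
    state = rng.choice(n_ctx, size=n, p=model.initial)
    # emit the initial context's bases, most significant digit first
    for j in range(order):
        shift = order - 1 - j
        out[:, j] = (state >> (2 * shift)) & 3
    cum = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random((n, length - order))
    mask = n_ctx - 1 if order > 0 else 0
    for pos in range(order, length):
        c = cum[state]
        b = (u[:, pos - order, None] > c).sum(axis=1).astype(np.int64)
        np.clip(b, 0, 3, out=b)
        out[:, pos] = b
        state = ((state << 2) | b) & mask if order > 0 else state
    seqs = [_LUT[row].tobytes().decode("ascii") for row in out]
    return SequenceSet(sequences=seqs, label="synthetic")
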