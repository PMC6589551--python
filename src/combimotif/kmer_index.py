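"""Canonical k-mer indexing of foreground and background sequence sets.

For every window width k in ``[k_min, k_max]`` both sets are scanned and a
map is built from each canonical k-mer (the lexicographically smaller of a
k-mer and its reverse complement, so both strands share one key) to the
sorted array of distinct sequence indices containing the k-mer on either
strand. Only sequence-level presence is indexed — the enrichment model is
per-sequence — and within-sequence positions are recovered on demand by a
second linear rescan when site lists must be written.

Internally each per-k map is stored compactly as a sorted array of integer
k-mer codes plus one concatenated index array (grouped by code); the
dict-of-arrays view required by callers is materialised lazily.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import DNA, SequenceSet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _ENC[ord(_b)] = _i
_LUT = np.frombuffer(DNA.encode(), dtype=np.uint8)

_EMPTY_I32 = np.empty(0, dtype=np.int32)


def reverse_complement(s: str) -> str:
    """Watson–Crick complement, reversed. Accepts A/C/G/T only."""
    bad = set(s) - set(DNA)
    if bad:
        raise ValueError(f"non-ACGT character in k-mer: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def canonical(s: str) -> tuple[str, bool]:
    """Canonical strand representative: min(s, rc(s)); flipped if rc was taken."""
    rc = reverse_complement(s)
    if rc < s:
        return rc, True
    return s, False


def kmer_to_code(s: str) -> int:
    code = 0
    for ch in s:
        code = code * 4 + DNA.index(ch)
    return code


def codes_to_kmers(codes: np.ndarray, k: int) -> list[str]:
    """Vectorised integer-code → k-mer string conversion."""
    if codes.size == 0:
        return []
    shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
    digits = (codes[:, None] >> shifts) & 3
    raw = _LUT[digits]
    return [b.decode("ascii") for b in raw.view(f"S{k}").ravel().tolist()]


@dataclass
class _KTable:
    """Grouped (code -> sequence indices) storage for one window width."""

    codes: np.ndarray  # sorted unique int64 canonical codes
    offsets: np.ndarray  # int64, len(codes)+1
    indices: np.ndarray  # int32 sequence indices, grouped by code, sorted

    @classmethod
    def empty(cls) -> "_KTable":
        return cls(
            codes=np.empty(0, dtype=np.int64),
            offsets=np.zeros(1, dtype=np.int64),
            indices=_EMPTY_I32,
        )

    def counts(self) -> np.ndarray:
        return np.diff(self.offsets)

    def support(self, code: int) -> np.ndarray:
        i = np.searchsorted(self.codes, code)
        if i == self.codes.size or self.codes[i] != code:
            return _EMPTY_I32
        return self.indices[self.offsets[i] : self.offsets[i + 1]]


@dataclass
class KmerIndex:
    """Per-length canonical k-mer → sequence-index maps for both sets."""

    k_min: int
    k_max: int
    n_fg: int
    n_bg: int
    _fg: dict[int, _KTable]
    _bg: dict[int, _KTable]
    _fg_map_cache: dict | None = field(default=None, repr=False)
    _bg_map_cache: dict | None = field(default=None, repr=False)

    def fg_support(self, kmer: str) -> np.ndarray:
        key, _ = canonical(kmer)
        return self._fg[len(key)].support(kmer_to_code(key))

    def bg_support(self, kmer: str) -> np.ndarray:
        key, _ = canonical(kmer)
        return self._bg[len(key)].support(kmer_to_code(key))

    @property
    def fg_map(self) -> dict[int, dict[str, np.ndarray]]:
        if self._fg_map_cache is None:
            self._fg_map_cache = {k: _materialise(t, k) for k, t in self._fg.items()}
        return self._fg_map_cache

    @property
    def bg_map(self) -> dict[int, dict[str, np.ndarray]]:
        if self._bg_map_cache is None:
            self._bg_map_cache = {k: _materialise(t, k) for k, t in self._bg.items()}
        return self._bg_map_cache


def _materialise(table: _KTable, k: int) -> dict[str, np.ndarray]:
    kmers = codes_to_kmers(table.codes, k)
    return {
        km: table.indices[table.offsets[i] : table.offsets[i + 1]]
        for i, km in enumerate(kmers)
    }


def _concat_encode(seqs: SequenceSet) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate sequences with a sentinel (invalid) byte between them."""
    parts = []
    starts = np.empty(len(seqs), dtype=np.int64)
    pos = 0
    for i, s in enumerate(seqs.sequences):
        starts[i] = pos
        enc = _ENC[np.frombuffer(s.encode(), dtype=np.uint8)]
        parts.append(enc)
        parts.append(np.array([255], dtype=np.uint8))
        pos += len(s) + 1
    return np.concatenate(parts), starts


def _scan(enc: np.ndarray, starts: np.ndarray, n_seqs: int, k: int) -> _KTable:
    L = enc.size
    nwin = L - k + 1
    if nwin <= 0:
        return _KTable.empty()
    bad = (enc > 3).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    if not valid.any():
        return _KTable.empty()
    e = np.where(enc > 3, 0, enc).astype(np.int64)
    fwd = np.zeros(nwin, dtype=np.int64)
    for i in range(k):
        fwd = fwd * 4 + e[i : i + nwin]
    rc = np.zeros(nwin, dtype=np.int64)
    for i in range(k - 1, -1, -1):
        rc = rc * 4 + (3 - e[i : i + nwin])
    canon = np.minimum(fwd, rc)
    wstart = np.nonzero(valid)[0]
    sid = np.searchsorted(starts, wstart, side="right") - 1
    # one (code, seq) pair per distinct per-sequence occurrence
    # (sort + adjacent-diff dedup: much faster than hash-based np.unique here)
    pair = canon[wstart] * np.int64(n_seqs) + sid
    pair.sort(kind="quicksort")
    keep = np.empty(pair.size, dtype=bool)
    keep[0] = True
    np.not_equal(pair[1:], pair[:-1], out=keep[1:])
    upair = pair[keep]
    codes_all = upair // n_seqs
    sids = (upair % n_seqs).astype(np.int32)
    ucodes, cnt = np.unique(codes_all, return_counts=True)
    offsets = np.concatenate(([0], np.cumsum(cnt)))
    return _KTable(codes=ucodes, offsets=offsets, indices=sids)


def build_index(
    fg: SequenceSet,
    bg: SequenceSet,
    k_min: int,
    k_max: int,
    workers: int = 1,
) -> KmerIndex:
    """Scan both sets for all k in [k_min, k_max].

    The work decomposes into 2*(k_max-k_min+1) independent units (per set ×
    per k); the result is identical for any ``workers`` value.
    """
    if not (3 <= k_min <= k_max <= 16):
        raise ValueError("require 3 <= k_min <= k_max <= 16")
    enc_fg, st_fg = _concat_encode(fg)
    enc_bg, st_bg = _concat_encode(bg)
    units = [("fg", k) for k in range(k_min, k_max + 1)] + [
        ("bg", k) for k in range(k_min, k_max + 1)
    ]

    def run(unit):
        which, k = unit
        if which == "fg":
            return _scan(enc_fg, st_fg, len(fg), k)
        return _scan(enc_bg, st_bg, len(bg), k)

    if workers and workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as ex:
            tables = list(ex.map(run, units))
    else:
        tables = [run(u) for u in units]
    nk = k_max - k_min + 1
    fg_tables = {k_min + i: tables[i] for i in range(nk)}
    bg_tables = {k_min + i: tables[nk + i] for i in range(nk)}
    return KmerIndex(
        k_min=k_min,
        k_max=k_max,
        n_fg=len(fg),
        n_bg=len(bg),
        _fg=fg_tables,
        _bg=bg_tables,
    )
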