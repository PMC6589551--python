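"""Seed selection, greedy primitive-motif growth and motif profiles.

A *primitive motif* is a set of near-identical significant k-mers grown
greedily from a seed: candidates are taken in ascending-p order from the
significant-k-mer array, admitted when (a) they sit at Hamming distance 1
from an existing member (in either orientation), (b) the motif stays
conserved at all but at most floor(alpha*k) positions, and (c) the motif's
Fisher exact p over the unioned per-sequence supports stays below beta.
Growth stops at the first (a)+(b) candidate whose admission would violate
(c), or when the array is exhausted.

Profiles are per-sequence-weighted: each member k-mer contributes its
foreground support size (number of sequences, not occurrences) to the
position counts, consistent with the per-sequence statistical model.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .enrichment_stats import LogPValue, _ln_upper_tail
from .kmer_index import KmerIndex, canonical, reverse_complement
from .sequence_io import DNA, BaseComposition

_BASE_IDX = {b: i for i, b in enumerate(DNA)}


class NoSignificantKmers(Exception):
    """Raised when no k-mer survives the significance filter."""


@dataclass
class PipelineConfig:
    """Tunable knobs of the discovery pipeline (defaults are the calibrated ones).

    alpha bounds the fraction of non-conserved positions a primitive motif
    may accumulate; beta is the motif-level p acceptance during growth;
    a_threshold / b_threshold are the similarity cutoffs for merging equal-
    length motifs and for redundancy deletion.
    """

    k_min: int = 5
    k_max: int = 10
    m: int = 100  # number of motif seeds
    alpha: float = 0.30
    beta: float = 0.05
    kmer_p_cutoff: float = 0.05
    a_threshold: float = 0.7
    b_threshold: float = 0.6
    n_output: int = 10
    combo_order: int = 2
    pseudocount: float = 1.0
    seed: int = 0
    workers: int | None = None  # default resolves to k_max - k_min + 1
    # take the top m seeds per k-mer length (True) or a single mixed top-m
    # list (False). Per-length is the default: in a mixed list one strongly
    # enriched length monopolises every seed and motifs of the other lengths
    # can never be discovered.
    seeds_per_length: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must be in (0, 1]")
        if not (0 < self.kmer_p_cutoff <= 1):
            raise ValueError("kmer_p_cutoff must be in (0, 1]")
        for t in (self.a_threshold, self.b_threshold):
            if not (0 <= t <= 1):
                raise ValueError("similarity thresholds must be in [0, 1]")
        if not (3 <= self.k_min <= self.k_max <= 16):
            raise ValueError("require 3 <= k_min <= k_max <= 16")
        if self.m < 1 or self.n_output < 1 or self.combo_order < 2:
            raise ValueError("m, n_output >= 1 and combo_order >= 2 required")

    @property
    def effective_workers(self) -> int:
        return self.workers if self.workers else self.k_max - self.k_min + 1


@dataclass
class MotifProfile:
    """PFM / PWM / per-position information content of a motif."""

    pfm: np.ndarray  # (k, 4), rows (positions) sum to 1
    pwm: np.ndarray  # (k, 4) log2 odds vs (smoothed) background composition
    pic: np.ndarray  # (k,) position information contents, in [0, 2]

    def __post_init__(self) -> None:
        if not np.allclose(self.pfm.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("pfm positions must sum to 1")
        if np.any(self.pic < -1e-9) or np.any(self.pic > 2 + 1e-9):
            raise ValueError("pic out of [0, 2]")

    def __len__(self) -> int:
        return self.pfm.shape[0]

    def reverse_complement(self) -> "MotifProfile":
        """Reverse positions and complement bases (ACGT <-> TGCA = full flip)."""
        return MotifProfile(
            pfm=self.pfm[::-1, ::-1].copy(),
            pwm=self.pwm[::-1, ::-1].copy(),
            pic=self.pic[::-1].copy(),
        )


@dataclass
class Motif:
    """A set of same-length member k-mers with supports, p-value and profile."""

    k: int
    members: list[tuple[str, str]]  # (oriented k-mer, canonical key)
    member_weights: list[int]  # per-member foreground support size
    fg_support: np.ndarray  # sorted distinct sequence indices (union)
    bg_support: np.ndarray
    ln_p: LogPValue
    profile: MotifProfile | None = None
    consensus: str | None = None
    name: str | None = None

    @property
    def u(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("motif needs at least one member")
        if any(len(o) != self.k for o, _ in self.members):
            raise ValueError("member length mismatch")
        if len({o for o, _ in self.members}) != len(self.members):
            raise ValueError("duplicate oriented members")


def seed_array(
    pvals: dict[str, LogPValue], cfg: PipelineConfig
) -> tuple[list[str], list[str]]:
    """Sort k-mers ascending by p, drop p > cutoff, return (array A, seeds).

    Ties are broken lexicographically by canonical k-mer so the ordering is
    total and reproducible. Seeds are the top m entries of A — per k-mer
    length when cfg.seeds_per_length is set (the default), else from the
    single mixed list.
    """
    if not pvals:
        raise NoSignificantKmers("no k-mers to rank")
    ln_cut = math.log(cfg.kmer_p_cutoff)
    entries = [(lp.ln_p, km) for km, lp in pvals.items() if lp.ln_p <= ln_cut]
    if not entries:
        raise NoSignificantKmers(
            f"no k-mer with p <= {cfg.kmer_p_cutoff}: nothing to seed from"
        )
    entries.sort()
    A = [km for _, km in entries]
    if not cfg.seeds_per_length:
        return A, A[: cfg.m]
    taken: dict[int, int] = {}
    seeds: list[str] = []
    for km in A:  # A is p-ordered, so per-length prefixes are too
        k = len(km)
        if taken.get(k, 0) < cfg.m:
            seeds.append(km)
            taken[k] = taken.get(k, 0) + 1
    return A, seeds


def motif_pvalue(M: Motif, index: KmerIndex) -> LogPValue:
    """Fisher exact p on the member-union supports (recomputed from the index)."""
    fg: np.ndarray | None = None
    bg: np.ndarray | None = None
    for _, key in M.members:
        f, b = index.fg_support(key), index.bg_support(key)
        fg = f if fg is None else np.union1d(fg, f)
        bg = b if bg is None else np.union1d(bg, b)
    return LogPValue(_ln_upper_tail(len(fg), index.n_fg, len(bg), index.n_bg))


def _hamming1_neighbours(o: str):
    for j, ch in enumerate(o):
        for b in DNA:
            if b != ch:
                yield o[:j] + b + o[j + 1 :]


def _is_hamming1(s: str, t: str) -> bool:
    d = 0
    for a, b in zip(s, t):
        if a != b:
            d += 1
            if d > 1:
                return False
    return d == 1


def grow_primitive_motif(
    seed: str,
    A: list[str],
    index: KmerIndex,
    cfg: PipelineConfig,
    positions: dict[str, int] | None = None,
) -> Motif:
    """Grow one primitive motif from ``seed`` down the significant-k-mer array A.

    ``positions`` (k-mer -> index in A) may be shared across seeds to avoid
    rebuilding it; growth itself is stateless across seeds.
    """
    if positions is None:
        positions = {km: i for i, km in enumerate(A)}
    if seed not in positions:
        raise ValueError("seed is not in the seed array")
    k = len(seed)
    n_fg, n_bg = index.n_fg, index.n_bg
    max_nc = math.floor(cfg.alpha * k)
    ln_beta = math.log(cfg.beta)

    members: list[tuple[str, str]] = [(seed, seed)]
    weights: list[int] = []
    fg = index.fg_support(seed)
    bg = index.bg_support(seed)
    weights.append(len(fg))
    ln_p = _ln_upper_tail(len(fg), n_fg, len(bg), n_bg)
    base_sets = [{ch} for ch in seed]
    member_keys = {seed}
    oriented = [seed]

    heap: list[int] = []
    pushed = {positions[seed]}

    def push_neighbours(o: str) -> None:
        for v in _hamming1_neighbours(o):
            key, _ = canonical(v)
            if len(key) != k or key in member_keys:
                continue
            i = positions.get(key)
            if i is not None and i not in pushed:
                heapq.heappush(heap, i)
                pushed.add(i)

    push_neighbours(seed)
    last = positions[seed]

    while heap:
        i = heapq.heappop(heap)
        if i <= last:
            continue  # the scan only moves forward in A
        key = A[i]
        if key in member_keys:
            continue
        # condition (a): Hamming distance 1 in some orientation; forward preferred
        if any(_is_hamming1(key, o) for o in oriented):
            cand = key
        else:
            rc = reverse_complement(key)
            if any(_is_hamming1(rc, o) for o in oriented):
                cand = rc
            else:
                continue
        # condition (b): conservation budget of the grown motif
        nc = sum(
            1
            for j, s in enumerate(base_sets)
            if len(s) > 1 or cand[j] not in s
        )
        if nc > max_nc:
            continue
        # condition (c): motif p over unioned supports must stay below beta
        tfg = index.fg_support(key)
        tbg = index.bg_support(key)
        fg_u = np.union1d(fg, tfg)
        bg_u = np.union1d(bg, tbg)
        lp = _ln_upper_tail(len(fg_u), n_fg, len(bg_u), n_bg)
        if lp >= ln_beta:
            break  # first qualifying candidate failing (c) ends the growth
        members.append((cand, key))
        weights.append(len(tfg))
        member_keys.add(key)
        oriented.append(cand)
        for j, ch in enumerate(cand):
            base_sets[j].add(ch)
        fg, bg, ln_p = fg_u, bg_u, lp
        last = i
        push_neighbours(cand)

    return Motif(
        k=k,
        members=members,
        member_weights=weights,
        fg_support=fg,
        bg_support=bg,
        ln_p=LogPValue(ln_p),
    )


def build_profile(
    M: Motif, comp: BaseComposition, cfg: PipelineConfig
) -> MotifProfile:
    """PFM/PWM/PIC from support-weighted member counts.

    Position counts are sum over members of (foreground support size) x
    (base indicator); a Laplace pseudocount is added per base before
    normalisation, and the background composition is smoothed to strict
    positivity before taking log-odds.
    """
    counts = np.zeros((M.k, 4), dtype=float)
    for (o, _), w in zip(M.members, M.member_weights):
        for j, ch in enumerate(o):
            counts[j, _BASE_IDX[ch]] += w
    counts += cfg.pseudocount
    pfm = counts / counts.sum(axis=1, keepdims=True)
    bg = comp.smoothed_freq_array()
    if np.any(bg <= 0):
        raise ValueError("background composition must be strictly positive")
    pwm = np.log2(pfm / bg)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    pic = np.clip(2.0 + plogp.sum(axis=1), 0.0, 2.0)
    return MotifProfile(pfm=pfm, pwm=pwm, pic=pic)


def render_consensus(profile: MotifProfile) -> str:
    """Textual consensus: conserved positions uppercase, alternatives as "(x/y)".

    Per position: the dominant base (frequency >= 0.7) uppercase; otherwise
    all bases with frequency >= 0.2, descending, lowercase in parentheses;
    "N" if none reach 0.2. Rendering convention only — no statistic uses it.
    """
    out = []
    for row in profile.pfm:
        order = np.argsort(-row, kind="stable")
        if row[order[0]] >= 0.7:
            out.append(DNA[order[0]])
            continue
        alts = [DNA[i].lower() for i in order if row[i] >= 0.2]
        out.append("(" + "/".join(alts) + ")" if alts else "N")
    return "".join(out)


def finalize_motif(M: Motif, comp: BaseComposition, cfg: PipelineConfig) -> Motif:
    """Attach profile and consensus in place; returns the motif for chaining."""
    M.profile = build_profile(M, comp, cfg)
    M.consensus = render_consensus(M.profile)
    return M
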