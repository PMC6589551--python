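"""Profile-vs-profile similarity (SPIC-style), motif merging and dedup.

The column score cross-scores each motif's frequencies against the other's
*centred* log-odds (each PWM column shifted to zero mean over the four
bases), weighted by the two information contents:

    s_i = IC_x[i] * (f_x[i] . w~_y[i]) + IC_y[i] * (f_y[i] . w~_x[i])

Centring is what makes the score of two unrelated informative profiles
average to zero: a raw log-odds column has a negative mean (rare bases
carry large negative weights), which would drag every mismatched pair far
below zero instead. Summed over columns and normalised cosine-style by the
geometric mean of the self-scores, the metric gives 1 for a profile against
itself, ~0 for unrelated informative profiles, and supports the calibrated
0.7 (merge) / 0.6 (dedup) thresholds. The *A-score* compares equal-length profiles at
offset 0; the *B-score* maximises the windowed score over all ungapped
offsets and both orientations. The exact formula is isolated behind
column_score/a_score/b_score so an alternative metric can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .enrichment_stats import LogPValue, _ln_upper_tail
from .kmer_index import KmerIndex, reverse_complement
from .motif_core import (
    Motif,
    MotifProfile,
    PipelineConfig,
    finalize_motif,
)
from .sequence_io import BaseComposition

_EPS = 1e-9


@dataclass(frozen=True)
class SimilarityScore:
    value: float  # in [-1, 1]
    offset: int  # start of Y relative to X (0 for unaligned scores)
    orientation: str  # "same" | "rc"


def column_score(fx, wx, icx, fy, wy, icy) -> float:
    """Information-content-weighted cross score of two profile columns.

    The log-odds vectors are centred to zero mean before scoring so that a
    random, unrelated partner column scores ~0 in expectation.
    """
    fx, wx, fy, wy = (np.asarray(v, dtype=float) for v in (fx, wx, fy, wy))
    wx = wx - wx.mean()
    wy = wy - wy.mean()
    return float(icx * (fx @ wy) + icy * (fy @ wx))


def _raw_window(X: MotifProfile, Y: MotifProfile, xs: slice, ys: slice) -> float:
    fx, wx, icx = X.pfm[xs], X.pwm[xs], X.pic[xs]
    fy, wy, icy = Y.pfm[ys], Y.pwm[ys], Y.pic[ys]
    wx = wx - wx.mean(axis=1, keepdims=True)
    wy = wy - wy.mean(axis=1, keepdims=True)
    return float(
        np.sum(icx * np.sum(fx * wy, axis=1)) + np.sum(icy * np.sum(fy * wx, axis=1))
    )


def _normalised(X: MotifProfile, Y: MotifProfile, xs: slice, ys: slice) -> float:
    sxy = _raw_window(X, Y, xs, ys)
    sxx = _raw_window(X, X, xs, xs)
    syy = _raw_window(Y, Y, ys, ys)
    if sxx <= _EPS or syy <= _EPS:
        return 0.0
    v = sxy / math.sqrt(sxx * syy)
    return max(-1.0, min(1.0, v))


def a_score(X: MotifProfile, Y: MotifProfile) -> SimilarityScore:
    """Unaligned similarity of equal-length profiles; max over Y's orientations."""
    if len(X) != len(Y):
        raise ValueError("a_score requires equal-length profiles")
    full_x, full_y = slice(0, len(X)), slice(0, len(Y))
    same = _normalised(X, Y, full_x, full_y)
    flip = _normalised(X, Y.reverse_complement(), full_x, full_y)
    if flip > same:
        return SimilarityScore(value=flip, offset=0, orientation="rc")
    return SimilarityScore(value=same, offset=0, orientation="same")


def _prep(P: MotifProfile):
    """Cached per-profile arrays for the windowed score hot path.

    icf = IC-weighted frequencies, wt = centred log-odds, and a cumulative
    sum of per-column self scores so any window's self-score is O(1).
    """
    cache = getattr(P, "_sim_cache", None)
    if cache is None:
        wt = np.ascontiguousarray(P.pwm - P.pwm.mean(axis=1, keepdims=True))
        icf = np.ascontiguousarray(P.pic[:, None] * P.pfm)
        self_col = 2.0 * np.einsum("ij,ij->i", icf, wt)
        csum = np.concatenate(([0.0], np.cumsum(self_col)))
        cache = (icf, wt, csum)
        P._sim_cache = cache
    return cache


def _rc_cached(P: MotifProfile) -> MotifProfile:
    rc = getattr(P, "_rc_cache", None)
    if rc is None:
        rc = P.reverse_complement()
        P._rc_cache = rc
    return rc


def b_score(X: MotifProfile, Y: MotifProfile) -> SimilarityScore:
    """Ungapped-alignment similarity: max windowed score over offsets/orientations.

    The overlap must cover at least max(4, ceil(min_len/2)) columns; the
    normalisation self-scores are restricted to the same windows. Each
    window's normalised score is weighted by its relative coverage of the
    shorter profile (overlap / min_len), so a full containment still scores
    1 while a chance agreement over a minimal window cannot dominate.
    """
    lx, ly = len(X), len(Y)
    min_len = min(lx, ly)
    min_ov = max(4, math.ceil(min_len / 2))
    if min_ov > min_len:
        raise ValueError("profiles too short for the minimum ungapped overlap")
    best = SimilarityScore(value=-math.inf, offset=0, orientation="same")
    icf_x, wt_x, csum_x = _prep(X)
    for orientation, Yo in (("same", Y), ("rc", _rc_cached(Y))):
        icf_y, wt_y, csum_y = _prep(Yo)
        for d in range(-(ly - min_ov), lx - min_ov + 1):
            x0, x1 = max(0, d), min(lx, d + ly)
            if x1 - x0 < min_ov:
                continue
            y0, y1 = x0 - d, x1 - d
            sxx = csum_x[x1] - csum_x[x0]
            syy = csum_y[y1] - csum_y[y0]
            if sxx <= _EPS or syy <= _EPS:
                v = 0.0
            else:
                sxy = float(
                    icf_x[x0:x1].ravel() @ wt_y[y0:y1].ravel()
                    + icf_y[y0:y1].ravel() @ wt_x[x0:x1].ravel()
                )
                v = max(-1.0, min(1.0, sxy / math.sqrt(sxx * syy)))
            v *= (x1 - x0) / min_len
            if v > best.value:
                best = SimilarityScore(value=v, offset=d, orientation=orientation)
    return best


def _flip_motif(m: Motif) -> Motif:
    """Reverse-complement every oriented member (canonical keys unchanged)."""
    return Motif(
        k=m.k,
        members=[(reverse_complement(o), key) for o, key in m.members],
        member_weights=list(m.member_weights),
        fg_support=m.fg_support,
        bg_support=m.bg_support,
        ln_p=m.ln_p,
    )


def merge_motifs(
    motifs: list[Motif],
    index: KmerIndex,
    comp: BaseComposition,
    cfg: PipelineConfig,
) -> list[Motif]:
    """Complete-linkage merging of equal-length motifs at A-score >= threshold.

    Within each length class, motifs are processed in ascending-p order;
    each joins the earliest group against ALL of whose members its A-score
    reaches the threshold, else starts a new group. Merged members are
    re-oriented to best match the group's lowest-p motif; supports, p and
    profile are recomputed. Output sorted ascending by p.
    """
    by_k: dict[int, list[Motif]] = {}
    for m in motifs:
        by_k.setdefault(m.k, []).append(m)
    out: list[Motif] = []
    for k in sorted(by_k):
        ms = sorted(by_k[k], key=lambda m: (m.ln_p.ln_p, m.members[0][0]))
        groups: list[list[Motif]] = []
        for m in ms:
            for g in groups:
                if all(
                    a_score(m.profile, x.profile).value >= cfg.a_threshold for x in g
                ):
                    g.append(m)
                    break
            else:
                groups.append([m])
        for g in groups:
            if len(g) == 1:
                out.append(g[0])
                continue
            head = g[0]
            members: list[tuple[str, str]] = []
            weights: list[int] = []
            seen: set[str] = set()
            for m in g:
                mm = m
                if m is not head and a_score(head.profile, m.profile).orientation == "rc":
                    mm = _flip_motif(m)
                for (o, key), w in zip(mm.members, mm.member_weights):
                    if o not in seen:
                        seen.add(o)
                        members.append((o, key))
                        weights.append(w)
            fg = head.fg_support
            bg = head.bg_support
            for m in g[1:]:
                fg = np.union1d(fg, m.fg_support)
                bg = np.union1d(bg, m.bg_support)
            lnp = LogPValue(_ln_upper_tail(len(fg), index.n_fg, len(bg), index.n_bg))
            merged = Motif(
                k=k,
                members=members,
                member_weights=weights,
                fg_support=fg,
                bg_support=bg,
                ln_p=lnp,
            )
            out.append(finalize_motif(merged, comp, cfg))
    out.sort(key=lambda m: (m.ln_p.ln_p, m.members[0][0]))
    return out


def deduplicate(motifs: list[Motif], cfg: PipelineConfig) -> list[Motif]:
    """Iteratively drop the higher-p motif of the most similar pair (B-score).

    Repeats until every surviving pair has B-score <= threshold. Ties on p
    remove the later-ranked motif. Terminates in at most len(motifs)-1
    rounds since every round removes one motif.
    """
    n = len(motifs)
    if n < 2:
        return list(motifs)
    score = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            score[i, j] = b_score(motifs[i].profile, motifs[j].profile).value
    alive = [True] * n
    while True:
        best, bi, bj = -math.inf, -1, -1
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if alive[j] and score[i, j] > best:
                    best, bi, bj = score[i, j], i, j
        if best <= cfg.b_threshold:
            break
        # remove the member with the higher p; on a tie the later-ranked one
        if motifs[bi].ln_p.ln_p > motifs[bj].ln_p.ln_p:
            alive[bi] = False
        else:
            alive[bj] = False
    return [m for i, m in enumerate(motifs) if alive[i]]
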