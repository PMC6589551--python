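"""Log-space probability machinery for enrichment testing.

Three tests, all kept in natural-log space end to end so p-values far below
the double-precision underflow threshold survive intact:

* one-sided Fisher's exact enrichment test on a 2x2 sequence-count table
  (the upper hypergeometric tail, summed by log-sum-exp in a fixed order);
* Fisher's combined probability test (-2*sum(ln p) ~ chi-square with 2u df,
  upper tail via the even-df closed form, again by log-sum-exp);
* the one-sided hypergeometric overlap test for co-occurring motif supports.

ln(n!) is served from an exact table for small n and extended by cumulative
log summation (numerically equivalent to log-gamma at the accuracies needed
here); display strings are rendered from log10 so extreme values never pass
through a denormal float.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

_LN10 = math.log(10.0)

# exact ln(n!) seed table from big-integer factorials
_LF: list[float] = [math.log(math.factorial(n)) if n else 0.0 for n in range(171)]


def log_factorial(n: int) -> float:
    """ln(n!); exact-table small n, cumulative-log extension above."""
    if n < 0:
        raise ValueError("n must be non-negative")
    while len(_LF) <= n:
        _LF.append(_LF[-1] + math.log(len(_LF)))
    return _LF[n]


class LogPValue:
    """A p-value held as its natural log (always <= 0)."""

    __slots__ = ("ln_p",)

    def __init__(self, ln_p: float):
        self.ln_p = min(float(ln_p), 0.0)

    @property
    def p(self) -> float:
        """Float p (may underflow to 0.0 for extreme values; ln_p never does)."""
        return math.exp(self.ln_p)

    @property
    def log10(self) -> float:
        return self.ln_p / _LN10

    @property
    def display(self) -> str:
        if self.ln_p == 0.0:
            return "1"
        l10 = self.log10
        if l10 < -320.0:
            return "<1e-320"
        e = math.floor(l10)
        m = 10.0 ** (l10 - e)
        if round(m, 2) >= 10.0:
            m /= 10.0
            e += 1
        return f"{m:.2f}e{e:d}"

    def __repr__(self) -> str:
        return f"LogPValue(ln_p={self.ln_p!r}, p~{self.display})"

    def __eq__(self, other) -> bool:
        return isinstance(other, LogPValue) and self.ln_p == other.ln_p

    def __lt__(self, other: "LogPValue") -> bool:
        return self.ln_p < other.ln_p

    def __hash__(self) -> int:
        return hash(self.ln_p)


@dataclass(frozen=True)
class ContingencyTable:
    """Sequence counts: a of n_fg foreground and c of n_bg background contain the item."""

    a: int
    n_fg: int
    c: int
    n_bg: int

    def __post_init__(self) -> None:
        for v in (self.a, self.n_fg, self.c, self.n_bg):
            if not isinstance(v, (int, np.integer)):
                raise ValueError("table entries must be integers")
        if not (0 <= self.a <= self.n_fg):
            raise ValueError("require 0 <= a <= n_fg")
        if not (0 <= self.c <= self.n_bg):
            raise ValueError("require 0 <= c <= n_bg")


@lru_cache(maxsize=None)
def _ln_upper_tail(a: int, n_fg: int, c: int, n_bg: int) -> float:
    """ln P(X >= a), X ~ Hypergeom(N=n_fg+n_bg, K=a+c, draws=n_fg)."""
    if a == 0:
        return 0.0
    N = n_fg + n_bg
    K = a + c
    hi = min(K, n_fg)
    lf = log_factorial
    ln_denom = lf(N) - lf(n_fg) - lf(n_bg)
    M = N - K
    terms = [
        lf(K) - lf(x) - lf(K - x) + lf(M) - lf(n_fg - x) - lf(M - n_fg + x)
        for x in range(a, hi + 1)
    ]
    m = max(terms)
    s = 0.0
    for t in terms:  # fixed ascending-x order: bit-reproducible
        s += math.exp(t - m)
    return min(m + math.log(s) - ln_denom, 0.0)


def fisher_exact_enrichment(t: ContingencyTable) -> LogPValue:
    """One-sided (enrichment) Fisher exact p for a 2x2 sequence-count table."""
    return LogPValue(_ln_upper_tail(t.a, t.n_fg, t.c, t.n_bg))


def kmer_pvalues(index, workers: int = 1) -> dict[str, LogPValue]:
    """Enrichment p for every foreground canonical k-mer in the index.

    a = foreground support size, c = background support size (0 when the key
    is absent from the background). Entries are inserted in (k, code)
    order so the map itself is deterministic; the per-k units are
    independent, so the result never depends on ``workers``.
    """
    from concurrent.futures import ThreadPoolExecutor

    from .kmer_index import codes_to_kmers

    n_fg, n_bg = index.n_fg, index.n_bg
    log_factorial(n_fg + n_bg)  # pre-extend the shared table before any thread use

    def one_k(k: int):
        ft = index._fg[k]
        if ft.codes.size == 0:
            return [], np.empty(0)
        a = ft.counts().astype(np.int64)
        bt = index._bg.get(k)
        if bt is None or bt.codes.size == 0:
            c = np.zeros_like(a)
        else:
            pos = np.searchsorted(bt.codes, ft.codes)
            pos_c = np.clip(pos, 0, bt.codes.size - 1)
            hit = bt.codes[pos_c] == ft.codes
            c = np.where(hit, bt.counts()[pos_c], 0).astype(np.int64)
        pair = a * np.int64(n_bg + 1) + c
        uniq, inv = np.unique(pair, return_inverse=True)
        vals = np.array(
            [
                _ln_upper_tail(int(u // (n_bg + 1)), n_fg, int(u % (n_bg + 1)), n_bg)
                for u in uniq
            ]
        )
        return codes_to_kmers(ft.codes, k), vals[inv]

    ks = sorted(index._fg.keys())
    if workers and workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as ex:
            per_k = list(ex.map(one_k, ks))
    else:
        per_k = [one_k(k) for k in ks]
    out: dict[str, LogPValue] = {}
    for kmers, lnp in per_k:
        out.update(zip(kmers, (LogPValue(v) for v in np.asarray(lnp).tolist())))
    return out


def fisher_combined(ln_ps) -> LogPValue:
    """Fisher's combined probability test for u independent p-values.

    chi2 = -2*sum(ln p_i) with 2u degrees of freedom; for even df the upper
    tail is ln P = -x/2 + ln sum_{j<u} (x/2)^j / j!, evaluated by
    log-sum-exp so inputs near ln(1e-300) are handled without underflow.
    Accepts floats (natural-log p) or LogPValue instances.
    """
    vals = [v.ln_p if isinstance(v, LogPValue) else float(v) for v in ln_ps]
    if not vals:
        raise ValueError("need at least one p-value")
    if any(v > 0 for v in vals):
        raise ValueError("ln p must be <= 0")
    u = len(vals)
    x = -2.0 * math.fsum(vals)
    if x == 0.0:
        return LogPValue(0.0)
    h = x / 2.0
    ln_h = math.log(h)
    terms = [j * ln_h - log_factorial(j) for j in range(u)]
    m = max(terms)
    s = 0.0
    for t in terms:  # fixed order
        s += math.exp(t - m)
    return LogPValue(-h + m + math.log(s))


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> LogPValue:
    """One-sided P(X >= k) for an overlap of k between sets of size K and n in a universe N."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require K, n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    if K - k > N - n:
        raise ValueError("inconsistent sizes: K - k exceeds N - n")
    return LogPValue(_ln_upper_tail(k, n, K - k, N - n))
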