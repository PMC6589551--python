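"""Combinatorial (co-factor) motif scoring and the final ranked report.

Combinations of 2..n final motifs are scored by Fisher's combined
probability test over the members' single-motif enrichment p-values — the
combination statistic is about joint significance, not joint occurrence.
Co-occurrence evidence is reported separately: a one-sided hypergeometric
test on the overlap of the two motifs' foreground supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from itertools import combinations

import numpy as np
import pandas as pd

from .enrichment_stats import LogPValue, fisher_combined, hypergeom_overlap
from .kmer_index import KmerIndex
from .motif_core import Motif, PipelineConfig


@dataclass
class MotifCombination:
    motifs: list[Motif]
    chi2: float  # -2 * sum(ln p_i)
    df: int  # 2 * len(motifs)
    ln_p_combined: LogPValue
    joint_fg_support: int  # fg sequences containing a site of EVERY member
    joint_bg_support: int

    @property
    def consensus(self) -> str:
        return " + ".join(m.consensus or "?" for m in self.motifs)


def score_combinations(
    motifs: list[Motif], index: KmerIndex, cfg: PipelineConfig, workers: int = 1
) -> list[MotifCombination]:
    """Score all subsets of sizes 2..cfg.combo_order of the given motifs.

    Enumeration order (subset size, then index order) is fixed, and each
    combination is independent, so the result never depends on workers.
    """
    if len(motifs) < 2:
        return []
    out: list[MotifCombination] = []
    for size in range(2, cfg.combo_order + 1):
        for combo in combinations(range(len(motifs)), size):
            ms = [motifs[i] for i in combo]
            lnps = [m.ln_p.ln_p for m in ms]
            chi2 = -2.0 * sum(lnps)
            combined = fisher_combined(lnps)
            jf = reduce(np.intersect1d, (m.fg_support for m in ms))
            jb = reduce(np.intersect1d, (m.bg_support for m in ms))
            out.append(
                MotifCombination(
                    motifs=ms,
                    chi2=chi2,
                    df=2 * size,
                    ln_p_combined=combined,
                    joint_fg_support=len(jf),
                    joint_bg_support=len(jb),
                )
            )
    return out


def cooccurrence_test(combo: MotifCombination, n_fg: int) -> LogPValue:
    """One-sided hypergeometric overlap test for a pair combination."""
    if len(combo.motifs) != 2:
        raise ValueError("co-occurrence test is defined for pairs")
    a, b = combo.motifs
    return hypergeom_overlap(
        N=n_fg,
        K=len(a.fg_support),
        n=len(b.fg_support),
        k=combo.joint_fg_support,
    )


@dataclass
class RankedEntry:
    rank: int
    kind: str  # "motif" | "combination"
    ln_p: LogPValue
    item: object  # Motif or MotifCombination


@dataclass
class RankedReport:
    entries: list[RankedEntry]
    primary: list[Motif]  # top n_output single motifs

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        # member ranks refer to the ranking among single motifs (1 = best single)
        single_rank = {
            id(e.item): i + 1
            for i, e in enumerate(e for e in self.entries if e.kind == "motif")
        }
        for e in self.entries:
            if e.kind == "motif":
                m: Motif = e.item
                rows.append(
                    {
                        "rank": e.rank,
                        "kind": "motif",
                        "consensus": m.consensus,
                        "width": m.k,
                        "n_members": m.u,
                        "fg_support": len(m.fg_support),
                        "bg_support": len(m.bg_support),
                        "member_ranks": str(single_rank[id(m)]),
                        "log10_p": round(e.ln_p.log10, 4),
                        "p": e.ln_p.display,
                    }
                )
            else:
                c: MotifCombination = e.item
                rows.append(
                    {
                        "rank": e.rank,
                        "kind": "combination",
                        "consensus": c.consensus,
                        "width": max(m.k for m in c.motifs),
                        "n_members": len(c.motifs),
                        "fg_support": c.joint_fg_support,
                        "bg_support": c.joint_bg_support,
                        "member_ranks": "+".join(
                            str(single_rank.get(id(m), -1)) for m in c.motifs
                        ),
                        "log10_p": round(e.ln_p.log10, 4),
                        "p": e.ln_p.display,
                    }
                )
        return pd.DataFrame(rows)


def rank_results(
    singles: list[Motif],
    combos: list[MotifCombination],
    cfg: PipelineConfig,
) -> RankedReport:
    """One merged ranking of single and combined motifs, ascending by p.

    Ties break toward fewer members, then lexicographic consensus. The top
    cfg.n_output singles are flagged as the primary output set.
    """
    items: list[tuple[float, int, str, str, object]] = []
    for m in singles:
        items.append((m.ln_p.ln_p, 1, m.consensus or "", "motif", m))
    for c in combos:
        items.append(
            (c.ln_p_combined.ln_p, len(c.motifs), c.consensus, "combination", c)
        )
    items.sort(key=lambda t: (t[0], t[1], t[2]))
    entries = [
        RankedEntry(
            rank=i + 1,
            kind=kind,
            ln_p=LogPValue(lnp),
            item=obj,
        )
        for i, (lnp, _, _, kind, obj) in enumerate(items)
    ]
    ordered_singles = sorted(singles, key=lambda m: (m.ln_p.ln_p, m.consensus or ""))
    return RankedReport(entries=entries, primary=ordered_singles[: cfg.n_output])
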