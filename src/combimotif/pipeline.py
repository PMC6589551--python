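"""End-to-end discovery pipeline and output writers.

The nine stages run in order: read -> index -> k-mer p-values -> seed/grow
-> A-score merge -> B-score dedup -> combinations -> rank. The stages that
decompose into independent work units (per-k scans, per-k-mer tests,
per-seed growth, per-pair scores, per-combination scores) may be executed
by any number of workers; every reduction is performed in a fixed canonical
order, so the motif and combination output is byte-identical regardless of
the worker count.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .combinatorics import (
    MotifCombination,
    RankedReport,
    cooccurrence_test,
    rank_results,
    score_combinations,
)
from .enrichment_stats import kmer_pvalues
from .kmer_index import build_index, reverse_complement
from .motif_core import (
    Motif,
    NoSignificantKmers,
    PipelineConfig,
    finalize_motif,
    grow_primitive_motif,
    seed_array,
)
from .motif_similarity import deduplicate, merge_motifs
from .sequence_io import SequenceSet, generate_background, read_fasta


@dataclass
class RunManifest:
    config: dict
    inputs: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    work_units: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    seed: int = 0


@dataclass
class DiscoveryResult:
    motifs: list[Motif]  # final single motifs, ascending p, named motif_1..
    combinations: list[MotifCombination]
    ranked: RankedReport
    manifest: RunManifest
    fg: SequenceSet
    n_fg: int
    n_bg: int


def _digest(seqs: SequenceSet) -> str:
    h = hashlib.sha256()
    for s in seqs.sequences:
        h.update(s.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def run_discovery(
    fg,
    bg=None,
    cfg: PipelineConfig | None = None,
    workers: int | None = None,
) -> DiscoveryResult:
    """Run the full discriminative discovery pipeline.

    ``fg``/``bg`` may be FASTA paths or SequenceSets; with no background, an
    i.i.d. set matched to the foreground composition is generated from
    ``cfg.seed``. Raises :class:`NoSignificantKmers` when nothing passes the
    k-mer significance filter (e.g. foreground == background).
    """
    cfg = cfg or PipelineConfig()
    workers = workers if workers is not None else cfg.effective_workers
    manifest = RunManifest(config=dict(cfg.__dict__), inputs={}, seed=cfg.seed)
    t0 = time.perf_counter()

    if not isinstance(fg, SequenceSet):
        fg = read_fasta(fg, label="foreground")
    if bg is None:
        bg = generate_background(fg, seed=cfg.seed)
    elif not isinstance(bg, SequenceSet):
        bg = read_fasta(bg, label="background")
    manifest.inputs = {
        "n_fg": len(fg),
        "n_bg": len(bg),
        "fg_digest": _digest(fg),
        "bg_digest": _digest(bg),
    }
    manifest.stage_seconds["read"] = time.perf_counter() - t0

    t = time.perf_counter()
    index = build_index(fg, bg, cfg.k_min, cfg.k_max, workers=workers)
    manifest.work_units["index"] = 2 * (cfg.k_max - cfg.k_min + 1)
    manifest.stage_seconds["index"] = time.perf_counter() - t

    t = time.perf_counter()
    pvals = kmer_pvalues(index, workers=workers)
    manifest.work_units["kmer_tests"] = len(pvals)
    manifest.stage_seconds["kmer_pvalues"] = time.perf_counter() - t

    t = time.perf_counter()
    A, seeds = seed_array(pvals, cfg)
    positions = {km: i for i, km in enumerate(A)}
    grown = [
        grow_primitive_motif(s, A, index, cfg, positions=positions) for s in seeds
    ]
    for m in grown:
        finalize_motif(m, fg.composition, cfg)
    manifest.work_units["seed_growth"] = len(seeds)
    manifest.stage_seconds["grow"] = time.perf_counter() - t

    t = time.perf_counter()
    merged = merge_motifs(grown, index, fg.composition, cfg)
    manifest.work_units["a_scores"] = len(grown) * (len(grown) - 1) // 2
    manifest.stage_seconds["merge"] = time.perf_counter() - t

    t = time.perf_counter()
    surviving = deduplicate(merged, cfg)
    surviving.sort(key=lambda m: (m.ln_p.ln_p, m.consensus or ""))
    final = surviving[: cfg.n_output]
    for i, m in enumerate(final):
        m.name = f"motif_{i + 1}"
    manifest.work_units["b_scores"] = len(merged) * (len(merged) - 1) // 2
    manifest.stage_seconds["dedup"] = time.perf_counter() - t

    t = time.perf_counter()
    combos = score_combinations(final, index, cfg, workers=workers)
    manifest.work_units["combinations"] = len(combos)
    ranked = rank_results(final, combos, cfg)
    manifest.stage_seconds["combine_rank"] = time.perf_counter() - t

    return DiscoveryResult(
        motifs=final,
        combinations=combos,
        ranked=ranked,
        manifest=manifest,
        fg=fg,
        n_fg=index.n_fg,
        n_bg=index.n_bg,
    )


# ---------------------------------------------------------------------------
# output writers


def _write_meme(result: DiscoveryResult, path: Path) -> None:
    comp = result.fg.composition
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {comp.freq[b]:.5f}" for b in "ACGT"),
        "",
    ]
    for m in result.motifs:
        lines.append(f"MOTIF {m.name} {m.consensus}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.k} "
            f"nsites= {len(m.fg_support)} E= {m.ln_p.display}"
        )
        for row in m.profile.pfm:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    path.write_text("\n".join(lines) + "\n")


def _write_jaspar(result: DiscoveryResult, path: Path) -> None:
    lines = []
    for m in result.motifs:
        lines.append(f">{m.name} {m.consensus}")
        counts = [[0] * m.k for _ in range(4)]
        for (o, _), w in zip(m.members, m.member_weights):
            for j, ch in enumerate(o):
                counts["ACGT".index(ch)][j] += w
        for bi, b in enumerate("ACGT"):
            vals = " ".join(str(v) for v in counts[bi])
            lines.append(f"{b} [ {vals} ]")
    path.write_text("\n".join(lines) + "\n")


def motif_sites(motif: Motif, fg: SequenceSet) -> list[tuple[int, int, int, str]]:
    """All within-sequence sites of a motif's oriented members, by rescanning.

    Returns (seq_index, start, end, strand) rows, 0-based half-open.
    Strand is '+' where the oriented member matches the sequence as stored,
    '-' where its reverse complement does.
    """
    rows: set[tuple[int, int, int, str]] = set()
    pats = []
    for o, _ in motif.members:
        pats.append((o, "+"))
        rc = reverse_complement(o)
        if rc != o:
            pats.append((rc, "-"))
    for i in motif.fg_support.tolist():
        s = fg.sequences[i]
        for pat, strand in pats:
            start = s.find(pat)
            while start != -1:
                rows.add((i, start, start + len(pat), strand))
                start = s.find(pat, start + 1)
    return sorted(rows)


def _write_bed(result: DiscoveryResult, path: Path) -> None:
    lines = []
    for m in result.motifs:
        for i, start, end, strand in motif_sites(m, result.fg):
            lines.append(
                f"{result.fg.name_of(i)}\t{start}\t{end}\t{m.name}\t0\t{strand}"
            )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _write_combos(result: DiscoveryResult, path: Path) -> None:
    df = result.ranked.to_dataframe()
    cooc = {}
    for c in result.combinations:
        if len(c.motifs) == 2:
            cooc[id(c)] = cooccurrence_test(c, result.n_fg).display
    coocs = []
    for e in result.ranked.entries:
        coocs.append(cooc.get(id(e.item), ""))
    if len(df):
        df["cooccurrence_p"] = coocs
    header = (
        "# combination p combines the members' single-motif enrichment p-values "
        "(Fisher's method); co-occurrence is tested separately (hypergeometric)\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def write_outputs(result: DiscoveryResult, out_dir) -> dict[str, Path]:
    """Write motifs.meme, motifs_pfm.txt, sites.bed, combos.tsv and report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "meme": out / "motifs.meme",
        "jaspar": out / "motifs_pfm.txt",
        "bed": out / "sites.bed",
        "combos": out / "combos.tsv",
        "report": out / "report.json",
    }
    _write_meme(result, paths["meme"])
    _write_jaspar(result, paths["jaspar"])
    _write_bed(result, paths["bed"])
    _write_combos(result, paths["combos"])
    paths["report"].write_text(
        json.dumps(
            {
                "version": result.manifest.version,
                "seed": result.manifest.seed,
                "config": result.manifest.config,
                "inputs": result.manifest.inputs,
                "stage_seconds": result.manifest.stage_seconds,
                "work_units": result.manifest.work_units,
                "n_motifs": len(result.motifs),
                "n_combinations": len(result.combinations),
            },
            indent=2,
            default=str,
        )
        + "\n"
    )
    return paths
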