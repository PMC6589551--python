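"""Synthetic implant benchmark and motif-recovery evaluation statistics.

The benchmark emulates the standard peak-simulation protocol: background
sequences are drawn from a (third-order by default) Markov chain, and one
site sampled column-wise from a reference PFM is implanted per sequence at
a uniform random position and strand, replacing the background bases so
sequence lengths stay fixed. Ground truth is recorded per sequence.

Evaluation statistics, all against reference profiles via the B-score:

* PA (prediction accuracy): the fraction of datasets whose top predicted
  motif matches some reference profile of the dataset's TF above gamma.
* ARR (average recovered rate): sum over datasets of the number of the
  TF's reference motifs recovered by the top-10 predictions, normalised by
  sum_i d_i * k_i (d_i datasets and k_i references per TF).
* ROC/AUC over prediction rank, treating rank as the sweep score: at each
  rank cutoff r, TPR is the fraction of datasets whose implanted truth is
  matched by a prediction of rank <= r, and FPR is the fraction of all
  non-matching predictions already emitted at rank <= r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from .kmer_index import reverse_complement
from .motif_core import MotifProfile
from .motif_similarity import b_score
from .sequence_io import DNA, MarkovModel, SequenceSet, sample_markov

_LUT = np.frombuffer(DNA.encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# reference-profile plumbing


def profile_from_counts(counts: np.ndarray, pseudocount: float = 1.0) -> MotifProfile:
    """Build a MotifProfile from a (k, 4) count matrix against a uniform background."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be (k, 4) over A,C,G,T")
    c = counts + pseudocount
    pfm = c / c.sum(axis=1, keepdims=True)
    pwm = np.log2(pfm / 0.25)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    pic = np.clip(2.0 + plogp.sum(axis=1), 0.0, 2.0)
    return MotifProfile(pfm=pfm, pwm=pwm, pic=pic)


def read_jaspar_pfms(path) -> dict[str, MotifProfile]:
    """Read a JASPAR-format PFM collection into profiles (uniform background)."""
    out: dict[str, MotifProfile] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in DNA], dtype=float).T
            name = m.matrix_id or m.name
            out[str(name)] = profile_from_counts(counts)
    if not out:
        raise ValueError("no PFM records found")
    return out


def random_markov_model(
    order: int = 3, seed: int = 0, concentration: float = 10.0
) -> MarkovModel:
    """A seeded random order-``r`` chain with mildly non-uniform transitions.

    Emulates the compositional structure of genomic peak background where no
    real training sequences are supplied: Dirichlet(concentration) rows give
    conditional probabilities deviating ~25-30% from uniform at the default,
    about the magnitude of genomic di-/tri-nucleotide odds outside CpG.
    Larger ``concentration`` = closer to uniform.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    n_ctx = 4**order
    trans = rng.dirichlet(np.full(4, concentration), size=n_ctx)
    initial = rng.dirichlet(np.full(n_ctx, concentration))
    return MarkovModel(order=order, transition_matrix=trans, initial=initial)


def random_strong_pfm(
    length: int, rng: np.random.Generator, dominance: float = 0.9
) -> np.ndarray:
    """A (length, 4) PFM with one dominant base per column (frequency `dominance`)."""
    if not (0.25 < dominance <= 1.0):
        raise ValueError("dominance must exceed 0.25")
    pfm = np.full((length, 4), (1.0 - dominance) / 3.0)
    dom = rng.integers(0, 4, size=length)
    pfm[np.arange(length), dom] = dominance
    return pfm


def sample_site(pfm: np.ndarray, rng: np.random.Generator) -> str:
    """Draw one site column-wise from a PFM."""
    bases = [rng.choice(4, p=row / row.sum()) for row in pfm]
    return _LUT[np.array(bases)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# implant benchmark


@dataclass
class ImplantRecord:
    """Ground truth of one synthetic dataset: exactly one implant per sequence."""

    dataset_id: int
    source_pfm_id: str
    sites: list[str]  # implanted oriented strings, as written into the sequence
    positions: list[int]  # 0-based start of the implant
    strands: list[str]  # "+" | "-"


def implant_benchmark(
    pfm: np.ndarray,
    model: MarkovModel,
    n_seqs: int,
    length: int,
    seed: int,
    dataset_id: int = 0,
    pfm_id: str = "truth",
) -> tuple[SequenceSet, ImplantRecord]:
    """Markov background + one PFM-sampled site per sequence (bases replaced)."""
    pfm = np.asarray(pfm, dtype=float)
    w = pfm.shape[0]
    if w >= length:
        raise ValueError("pfm longer than the sequence length")
    background = sample_markov(model, n_seqs, length, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_000_003]))
    sites, positions, strands = [], [], []
    seqs = []
    for s in background.sequences:
        site = sample_site(pfm, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        ins = site if strand == "+" else reverse_complement(site)
        pos = int(rng.integers(0, length - w + 1))
        seqs.append(s[:pos] + ins + s[pos + w :])
        sites.append(ins)
        positions.append(pos)
        strands.append(strand)
    record = ImplantRecord(
        dataset_id=dataset_id,
        source_pfm_id=pfm_id,
        sites=sites,
        positions=positions,
        strands=strands,
    )
    return SequenceSet(sequences=seqs, label="synthetic"), record


# ---------------------------------------------------------------------------
# similarity-threshold calibration helpers (synthetic analogue of the
# JASPAR sub-motif split used to pick the 0.7/0.6 defaults)


def random_informative_profile(
    length: int, rng: np.random.Generator, concentration: float = 0.3
) -> np.ndarray:
    """A random informative PFM: Dirichlet columns sharpened toward one base."""
    pfm = rng.dirichlet(np.full(4, concentration), size=length)
    return pfm


def split_profile_sites(
    parent_pfm: np.ndarray, n_sites: int, rng: np.random.Generator
) -> tuple[MotifProfile, MotifProfile]:
    """Two sub-motifs of one parent: the parent's sites split into two halves.

    Each half estimates the same underlying motif from disjoint site samples,
    so the two sub-profiles should score high against each other while
    sub-profiles of different parents should score near zero.
    """
    parent_pfm = np.asarray(parent_pfm, dtype=float)
    sites = [sample_site(parent_pfm, rng) for _ in range(n_sites)]
    half = n_sites // 2
    return (
        _profile_from_sites(sites[:half]),
        _profile_from_sites(sites[half:]),
    )


def _profile_from_sites(sites: list[str]) -> MotifProfile:
    k = len(sites[0])
    counts = np.zeros((k, 4))
    idx = {b: i for i, b in enumerate(DNA)}
    for s in sites:
        for j, ch in enumerate(s):
            counts[j, idx[ch]] += 1
    return profile_from_counts(counts)


def similarity_calibration(
    n_parents: int = 100,
    length_range: tuple[int, int] = (12, 20),
    n_sites: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Median same-parent vs cross-parent B-scores over random split profiles."""
    rng = np.random.default_rng(seed)
    halves = []
    for _ in range(n_parents):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        parent = random_informative_profile(L, rng)
        halves.append(split_profile_sites(parent, n_sites, rng))
    same = [b_score(a, b).value for a, b in halves]
    cross = [
        b_score(halves[i][0], halves[(i + 1) % n_parents][1]).value
        for i in range(n_parents)
    ]
    return {
        "median_same_parent": float(np.median(same)),
        "median_cross_parent": float(np.median(cross)),
        "median_difference": float(np.median(same) - np.median(cross)),
    }


# ---------------------------------------------------------------------------
# evaluation statistics


def _best_ref_score(pred: MotifProfile, refs: list[MotifProfile]) -> float:
    return max(b_score(pred, r).value for r in refs)


def prediction_accuracy(
    predictions: list[tuple[str, MotifProfile | None]],
    references: dict[str, list[MotifProfile]],
    gamma: float,
) -> float:
    """Fraction of datasets whose top prediction matches a reference above gamma.

    ``predictions`` holds one (tf, top-profile) pair per dataset; a dataset
    with no prediction contributes 0. Every dataset's TF must have at least
    one reference profile.
    """
    if not predictions:
        raise ValueError("no datasets")
    hits = 0
    for tf, pred in predictions:
        refs = references.get(tf)
        if not refs:
            raise ValueError(f"no reference profiles for TF {tf!r}")
        if pred is not None and _best_ref_score(pred, refs) > gamma:
            hits += 1
    return hits / len(predictions)


def average_recovered_rate(
    top10: list[tuple[str, list[MotifProfile]]],
    kk_refs: dict[str, list[MotifProfile]],
    gamma: float,
) -> float:
    """Recovered reference motifs in top-10 output, normalised by sum d_i * k_i."""
    if not top10:
        raise ValueError("no datasets")
    recovered = 0
    denom = 0
    for tf, preds in top10:
        refs = kk_refs.get(tf)
        if not refs:
            raise ValueError(f"no reference profiles for TF {tf!r}")
        denom += len(refs)
        for ref in refs:
            if any(b_score(p, ref).value > gamma for p in preds[:10]):
                recovered += 1
    return recovered / denom


def roc_auc(
    ranked_predictions: list[list[MotifProfile]],
    truths: list[MotifProfile],
    gamma: float,
    max_rank: int = 20,
) -> tuple[list[tuple[float, float]], float]:
    """ROC over prediction rank; AUC by trapezoid with (0,0) and (1,.) closure.

    Rank plays the role of the classifier score: sweeping the cutoff r emits
    predictions in rank order, true positives being datasets whose truth has
    been matched and false positives the non-matching predictions emitted so
    far (out of all non-matching predictions the finder produced).
    """
    if len(ranked_predictions) != len(truths):
        raise ValueError("one truth per dataset required")
    n_ds = len(truths)
    match: list[list[bool]] = []
    for preds, truth in zip(ranked_predictions, truths):
        match.append([b_score(p, truth).value > gamma for p in preds[:max_rank]])
    total_fp = sum(sum(1 for v in row if not v) for row in match)
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    last_tpr = 0.0
    for r in range(1, max_rank + 1):
        tp_ds = sum(1 for row in match if any(row[:r]))
        tpr = tp_ds / n_ds
        fp = sum(sum(1 for v in row[:r] if not v) for row in match)
        fpr = fp / total_fp if total_fp else 0.0
        points.append((fpr, tpr))
        last_tpr = tpr
    points.append((1.0, last_tpr))
    points = sorted(set(points))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


@dataclass
class EvalReport:
    gamma: float
    pa: float
    arr: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float = math.nan
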