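import math

import numpy as np
import pytest

from combimotif import (
    LogPValue,
    Motif,
    MotifProfile,
    NoSignificantKmers,
    PipelineConfig,
    SequenceSet,
    build_index,
    build_profile,
    canonical,
    finalize_motif,
    grow_primitive_motif,
    motif_pvalue,
    render_consensus,
    seed_array,
)
from combimotif.sequence_io import BaseComposition


def lp(p):
    return LogPValue(math.log(p))


UNIFORM_COMP = BaseComposition.from_sequences(["ACGT"])


class TestSeedArray:
    def test_all_insignificant_raises(self):
        with pytest.raises(NoSignificantKmers):
            seed_array({"AAAAA": lp(1.0), "CCCCC": lp(0.9)}, PipelineConfig())

    def test_filter_at_cutoff(self):
        pvals = {"AAAAA": lp(1e-9), "CCCCC": lp(1e-5), "GGGGG": lp(0.2)}
        A, seeds = seed_array(pvals, PipelineConfig())
        assert A == ["AAAAA", "CCCCC"]
        assert seeds == A

    def test_top_m_truncation_mixed_list(self, rng):
        from combimotif.kmer_index import codes_to_kmers

        codes = np.arange(150, dtype=np.int64)
        kmers = codes_to_kmers(codes, 6)
        pvals = {km: lp(1e-6 * (i + 1)) for i, km in enumerate(kmers)}
        A, seeds = seed_array(pvals, PipelineConfig(m=100, seeds_per_length=False))
        assert len(A) == 150
        assert len(seeds) == 100

    def test_per_length_seed_lists(self, rng):
        from combimotif.kmer_index import codes_to_kmers

        pvals = {}
        for k in (5, 6):
            codes = np.arange(80, dtype=np.int64)
            for i, km in enumerate(codes_to_kmers(codes, k)):
                # every 6-mer more significant than every 5-mer
                scale = 1e-20 if k == 6 else 1e-6
                pvals[km] = lp(scale * (i + 1))
        cfg = PipelineConfig(m=50, k_min=5, k_max=10)
        A, seeds = seed_array(pvals, cfg)
        # a strongly enriched length cannot crowd the other out of the seeds
        assert len([s for s in seeds if len(s) == 5]) == 50
        assert len([s for s in seeds if len(s) == 6]) == 50
        _, mixed = seed_array(pvals, PipelineConfig(m=50, seeds_per_length=False))
        assert all(len(s) == 6 for s in mixed)

    def test_ascending_with_lexicographic_ties(self):
        pvals = {"TTTTT": lp(0.01), "AAAAA": lp(0.01), "CCCCC": lp(0.001)}
        A, _ = seed_array(pvals, PipelineConfig())
        assert A == ["CCCCC", "AAAAA", "TTTTT"]


def _index_for(fg_seqs, bg_seqs, k):
    fg = SequenceSet(fg_seqs)
    bg = SequenceSet(bg_seqs, label="background")
    return build_index(fg, bg, k, k), fg, bg


class TestGrow:
    def test_seed_with_no_neighbours_is_fixed_point(self):
        # foreground dominated by one exact word; nothing within Hamming-1 in A
        fg_seqs = ["CCAAAAACC" for _ in range(6)]
        bg_seqs = ["CGCGCGCGC" for _ in range(6)]
        idx, fg, bg = _index_for(fg_seqs, bg_seqs, 5)
        A = ["AAAAA", "CCCCC"]  # CCCCC not even present; irrelevant
        m = grow_primitive_motif("AAAAA", A, idx, PipelineConfig(k_min=5, k_max=5))
        assert m.u == 1
        assert m.members == [("AAAAA", "AAAAA")]
        assert m.ln_p.ln_p == motif_pvalue(m, idx).ln_p

    def test_hamming1_admission_and_conservation_budget(self):
        # Sequences carry AAAAA, AAAAT and AATAA; with alpha=0.3 and k=5 the
        # budget is floor(1.5)=1 non-conserved position: AAAAT joins the seed
        # but AATAA would raise the count to 2 and must be rejected.
        fg_seqs = ["CCAAAAACC", "GGAAAATGG", "CCAATAACC"] * 6
        bg_seqs = ["CGCGCGCGC"] * 18
        idx, *_ = _index_for(fg_seqs, bg_seqs, 5)
        A = ["AAAAA", canonical("AAAAT")[0], canonical("AATAA")[0]]
        m = grow_primitive_motif("AAAAA", A, idx, PipelineConfig(k_min=5, k_max=5))
        oriented = [o for o, _ in m.members]
        assert "AAAAA" in oriented
        assert "AAAAT" in oriented
        assert all(o != "AATAA" for o in oriented)

    def test_support_union_matches_bruteforce(self):
        fg_seqs = ["TTAAAAATT", "GGAAAATGG", "CCAAAAACC", "GGGCGCGGG"]
        bg_seqs = ["CGCGCGCGC"] * 4
        idx, fg, _ = _index_for(fg_seqs, bg_seqs, 5)
        A = ["AAAAA", canonical("AAAAT")[0]]
        m = grow_primitive_motif("AAAAA", A, idx, PipelineConfig(k_min=5, k_max=5))
        expect = set()
        for _, key in m.members:
            expect |= set(idx.fg_support(key).tolist())
        assert set(m.fg_support.tolist()) == expect

    def test_reverse_complement_candidates_admitted(self):
        # ATTTT is Hamming-1 from AAAAA only through its rc AAAAT
        fg_seqs = ["CCAAAAACC", "GGATTTTGG"] * 8
        bg_seqs = ["CGCGCGCGC"] * 16
        idx, *_ = _index_for(fg_seqs, bg_seqs, 5)
        A = ["AAAAA", "AAAAT"]  # canonical form of ATTTT is AAAAT
        m = grow_primitive_motif("AAAAA", A, idx, PipelineConfig(k_min=5, k_max=5))
        assert ("AAAAT", "AAAAT") in m.members


class TestMotifPvalue:
    def test_single_member_equals_kmer_p(self):
        idx, *_ = _index_for(["CCAAAAACC"] * 4, ["CGCGCGCGC"] * 4, 5)
        m = Motif(
            k=5,
            members=[("AAAAA", "AAAAA")],
            member_weights=[4],
            fg_support=idx.fg_support("AAAAA"),
            bg_support=idx.bg_support("AAAAA"),
            ln_p=lp(1.0),
        )
        from combimotif import ContingencyTable, fisher_exact_enrichment

        expect = fisher_exact_enrichment(ContingencyTable(4, 4, 0, 4))
        assert motif_pvalue(m, idx).ln_p == pytest.approx(expect.ln_p, abs=1e-12)

    def test_union_idempotent_for_identical_support(self):
        idx, *_ = _index_for(["AAAAAA"] * 5, ["CGCGCG"] * 5, 5)
        one = Motif(
            k=5, members=[("AAAAA", "AAAAA")], member_weights=[5],
            fg_support=idx.fg_support("AAAAA"), bg_support=idx.bg_support("AAAAA"),
            ln_p=lp(1.0),
        )
        # AAAAA occurs twice per sequence; both "members" share support
        two = Motif(
            k=5, members=[("AAAAA", "AAAAA"), ("TTTTT", "AAAAA")],
            member_weights=[5, 5],
            fg_support=one.fg_support, bg_support=one.bg_support, ln_p=lp(1.0),
        )
        assert motif_pvalue(one, idx).ln_p == motif_pvalue(two, idx).ln_p


class TestBuildProfile:
    def test_single_member_column_formula(self):
        m = Motif(
            k=3, members=[("ACG", "ACG")], member_weights=[7],
            fg_support=np.arange(7), bg_support=np.arange(0), ln_p=lp(0.01),
        )
        prof = build_profile(m, UNIFORM_COMP, PipelineConfig())
        # column for base A at position 0: (7+1)/(7+4); others 1/11
        assert prof.pfm[0, 0] == pytest.approx(8 / 11)
        assert prof.pfm[0, 1] == pytest.approx(1 / 11)
        assert np.allclose(prof.pfm.sum(axis=1), 1.0)

    def test_uniform_column_zero_information(self):
        prof = MotifProfile(
            pfm=np.full((1, 4), 0.25),
            pwm=np.zeros((1, 4)),
            pic=np.zeros(1),
        )
        assert prof.pic[0] == 0.0

    def test_concentrated_column_approaches_two_bits(self):
        m = Motif(
            k=1, members=[("A", "A")], member_weights=[100000],
            fg_support=np.arange(3), bg_support=np.arange(0), ln_p=lp(0.01),
        )
        prof = build_profile(m, UNIFORM_COMP, PipelineConfig(pseudocount=1e-9))
        assert prof.pic[0] == pytest.approx(2.0, abs=1e-3)

    def test_pic_bounds_random_profiles(self, rng):
        for _ in range(20):
            members = []
            k = 6
            from combimotif.kmer_index import codes_to_kmers

            codes = rng.choice(4**k, size=5, replace=False).astype(np.int64)
            for km in codes_to_kmers(np.sort(codes), k):
                members.append((km, km))
            m = Motif(
                k=k, members=members,
                member_weights=[int(w) for w in rng.integers(1, 50, size=5)],
                fg_support=np.arange(5), bg_support=np.arange(0), ln_p=lp(0.01),
            )
            prof = build_profile(m, UNIFORM_COMP, PipelineConfig())
            assert np.all(prof.pic >= 0) and np.all(prof.pic <= 2)
            assert np.allclose(prof.pfm.sum(axis=1), 1.0, atol=1e-12)


class TestRenderConsensus:
    def _profile(self, rows):
        pfm = np.array(rows, dtype=float)
        pfm = pfm / pfm.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(pfm > 0, pfm * np.log2(np.where(pfm > 0, pfm, 1)), 0)
        return MotifProfile(
            pfm=pfm,
            pwm=np.zeros_like(pfm),
            pic=np.clip(2 + plogp.sum(axis=1), 0, 2),
        )

    def test_dominant_base_uppercase(self):
        prof = self._profile([[0.95, 0.03, 0.01, 0.01]])
        assert render_consensus(prof) == "A"

    def test_two_way_split_lowercase(self):
        prof = self._profile([[0.45, 0.0, 0.5, 0.05]])
        assert render_consensus(prof) == "(g/a)"

    def test_no_base_reaches_threshold_renders_n(self):
        prof = self._profile([[0.19, 0.19, 0.19, 0.43]])
        # T at 0.43 is below 0.7 but above 0.2: listed alone
        assert render_consensus(prof) == "(t)"
        prof2 = self._profile([[0.25, 0.25, 0.25, 0.25]])
        # a perfectly uniform column: every base above 0.2 -> all four listed
        assert render_consensus(prof2) == "(a/c/g/t)"

    def test_ctcf_like_shape(self):
        rows = [
            [0.9, 0.02, 0.06, 0.02],   # A
            [0.02, 0.02, 0.9, 0.06],   # G
            [0.3, 0.05, 0.6, 0.05],    # (g/a)
            [0.25, 0.05, 0.4, 0.3],    # (g/t/a)
            [0.02, 0.02, 0.9, 0.06],   # G
            [0.02, 0.02, 0.9, 0.06],   # G
            [0.02, 0.9, 0.02, 0.06],   # C
        ]
        assert render_consensus(self._profile(rows)) == "AG(g/a)(g/t/a)GGC"


def test_finalize_attaches_profile_and_consensus():
    m = Motif(
        k=5, members=[("AAAAA", "AAAAA")], member_weights=[10],
        fg_support=np.arange(10), bg_support=np.arange(0), ln_p=lp(0.001),
    )
    finalize_motif(m, UNIFORM_COMP, PipelineConfig())
    assert m.profile is not None
    assert m.consensus == "AAAAA"
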