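import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replitime.fixtures import make_sequence_fixture, write_fasta
from replitime.genome_io import BinnedTrack, GenomeIndex, IntervalSet
from replitime.ipls import (
    build_ipls,
    cpg_ipls,
    fuse_translocation,
    g4_ipls,
    g4_pattern,
    gc_ipls,
    subsample,
    subtract_overlap,
    subtract_random,
    tss_ipls,
)


def track_of(values, bin_width=500):
    g = GenomeIndex(("chrT",), (len(values) * bin_width,), bin_width)
    return BinnedTrack(g, {"chrT": np.asarray(values, float)})


class TestBuildIpls:
    def test_linear_scaling_and_floor(self):
        lm = build_ipls(track_of([2, 4, 0]), "linear", 1e-4)
        assert np.allclose(lm.values("chrT"), [0.5, 1.0, 1e-4])

    def test_constant_map_zero_background(self):
        lm = build_ipls(track_of([2, 4, 0]), "constant", 0.0)
        assert np.allclose(lm.values("chrT"), [1.0, 1.0, 0.0])

    def test_square_map(self):
        lm = build_ipls(track_of([1, 4]), "square", 0.0)
        assert np.allclose(lm.values("chrT"), [0.0625, 1.0])

    def test_sqrt_map(self):
        lm = build_ipls(track_of([1, 4]), "sqrt", 0.0)
        assert np.allclose(lm.values("chrT"), [0.5, 1.0])

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="empty landscape"):
            build_ipls(track_of([0, 0, 0]))

    @settings(derandomize=True, max_examples=30)
    @given(
        raw=st.lists(st.floats(0, 100), min_size=2, max_size=20),
        scale=st.floats(0.01, 1000),
    )
    def test_scale_invariance(self, raw, scale):
        raw = np.asarray(raw)
        if raw.max() <= 0:
            return
        a = build_ipls(track_of(raw)).values("chrT")
        b = build_ipls(track_of(raw * scale)).values("chrT")
        assert np.allclose(a, b)

    def test_missing_treated_as_zero(self):
        lm = build_ipls(track_of([np.nan, 4.0]))
        assert np.allclose(lm.values("chrT"), [1e-4, 1.0])


class TestTssIpls:
    def test_single_tss(self):
        g = GenomeIndex(("chrT",), (2000,), 500)
        tss = IntervalSet.from_records([("chrT", 750, 751, 0.0)])
        lm = tss_ipls(tss, g)
        assert np.allclose(lm.values("chrT"), [1e-4, 1.0, 1e-4, 1e-4])

    def test_zero_tss_raises(self):
        g = GenomeIndex(("chrT",), (2000,), 500)
        empty = IntervalSet.from_records([("chrX", 0, 1, 0.0)])
        with pytest.raises(ValueError, match="empty landscape"):
            tss_ipls(empty, g)

    def test_idempotent_for_cobinned_tss(self):
        g = GenomeIndex(("chrT",), (2000,), 500)
        tss = IntervalSet.from_records([("chrT", 700, 701, 0.0), ("chrT", 900, 901, 0.0)])
        assert tss_ipls(tss, g).values("chrT")[1] == 1.0


class TestSequenceLandscapes:
    def test_g4_planted_motif_is_unique_maximum(self):
        seqs, g = make_sequence_fixture(n_bins=8, g4_plus_bins=(2,), seed=0, chrom="chrT")
        lm = g4_ipls(seqs, g)
        v = lm.values("chrT")
        assert v[2] == 1.0
        assert np.all(v[np.arange(8) != 2] == 1e-4)
        # regex oracle on the literal string: motif length 15
        m = g4_pattern().search(seqs["chrT"])
        assert m is not None and m.end() - m.start() == 15

    def test_g4_strand_symmetry(self):
        seqs, g = make_sequence_fixture(n_bins=8, g4_plus_bins=(1,), g4_minus_bins=(5,), seed=0, chrom="chrT")
        v = g4_ipls(seqs, g).values("chrT")
        assert v[1] == 1.0 and v[5] == 1.0

    def test_g4_no_motif_raises(self):
        g = GenomeIndex(("chrT",), (1000,), 500)
        with pytest.raises(ValueError, match="empty landscape"):
            g4_ipls({"chrT": "A" * 1000}, g)

    def test_g4_reads_fasta_file(self, tmp_path):
        seqs, g = make_sequence_fixture(n_bins=8, g4_plus_bins=(2,), seed=0, chrom="chrT")
        fa = tmp_path / "seq.fa"
        write_fasta(seqs, fa)
        assert np.allclose(g4_ipls(fa, g).values("chrT"), g4_ipls(seqs, g).values("chrT"))

    def test_missing_chromosome_raises(self):
        g = GenomeIndex(("chrT", "chrU"), (1000, 1000), 500)
        with pytest.raises(KeyError, match="chrU"):
            gc_ipls({"chrT": "A" * 1000}, g)

    def test_gc_fraction(self):
        g = GenomeIndex(("chrT",), (1000,), 500)
        seq = "GC" * 250 + "A" * 500
        v = gc_ipls({"chrT": seq}, g).values("chrT")
        assert v[0] == 1.0 and v[1] == 1e-4

    def test_cpg_obs_exp_oracle(self):
        # same base composition, different CpG dinucleotide counts
        g = GenomeIndex(("chrT",), (1000,), 500)
        cgcg, ccgg = "CG" * 250, "CCGG" * 125
        v = cpg_ipls({"chrT": cgcg + ccgg}, g).values("chrT")

        def obs_exp(s):
            return s.count("CG") * len(s) / (s.count("C") * s.count("G"))

        assert obs_exp(cgcg) > obs_exp(ccgg)
        assert v[0] == 1.0
        assert np.isclose(v[1], obs_exp(ccgg) / obs_exp(cgcg))


class TestSetReductions:
    @pytest.fixture()
    def a(self):
        return IntervalSet.from_records(
            [("chrT", 0, 500, 1.0), ("chrT", 1000, 1500, 1.0)]
        )

    def test_subtract_overlap(self, a):
        b = IntervalSet.from_records([("chrT", 400, 600, 1.0)])
        out = subtract_overlap(a, b)
        assert len(out) == 1 and out.df.loc[0, "start"] == 1000

    def test_subtract_overlap_disjoint_identity(self, a):
        b = IntervalSet.from_records([("chrT", 600, 900, 1.0)])
        assert len(subtract_overlap(a, b)) == len(a)

    def test_subtract_overlap_self_empties(self, a):
        assert len(subtract_overlap(a, a)) == 0

    def test_subtract_random_size_matches_overlap_contract(self, a):
        b = IntervalSet.from_records([("chrT", 400, 600, 1.0)])
        n_removed = len(a) - len(subtract_overlap(a, b))
        assert len(subtract_random(a, n_removed, seed=0)) == len(subtract_overlap(a, b))

    def test_subtract_random_too_many(self, a):
        with pytest.raises(ValueError):
            subtract_random(a, 3, seed=0)

    def test_subsample(self, a):
        big = IntervalSet.from_records([("chrT", i * 10, i * 10 + 5, 1.0) for i in range(1000)])
        assert len(subsample(big, 1.0, seed=0)) == 1000
        assert len(subsample(big, 0.25, seed=0)) == 250
        s1 = subsample(big, 0.5, seed=3)
        s2 = subsample(big, 0.5, seed=3)
        assert s1.df.equals(s2.df)


class TestFuseTranslocation:
    @pytest.fixture()
    def pair(self):
        a = build_ipls(track_of([2, 4, 1, 3]), background=1e-4)
        b = build_ipls(track_of([1, 2, 3, 4]), background=1e-4)
        return a, b

    def test_bin_boundary_fusion_concatenates(self, pair):
        a, b = pair
        fused, mapping = fuse_translocation(a, b, 1000, 1000)
        expected = np.concatenate([a.values("chrT")[:2], b.values("chrT")[2:]])
        assert np.allclose(fused.values("der"), expected)
        assert list(mapping["source_bin"]) == [0, 1, 2, 3]

    def test_length_conservation(self, pair):
        a, b = pair
        fused, _ = fuse_translocation(a, b, 700, 300)
        assert fused.genome.lengths[0] == 700 + (2000 - 300)

    def test_reciprocal_lengths_sum(self, pair):
        a, b = pair
        ab, _ = fuse_translocation(a, b, 700, 300)
        ba, _ = fuse_translocation(a, b, 700, 300, orientation="BA")
        assert ab.genome.lengths[0] + ba.genome.lengths[0] == 2000 + 2000

    def test_majority_rule_at_breakpoint_bin(self, pair):
        a, b = pair
        # breakpoint at 700: fused bin 1 has 200 bases of A, 300 of B -> B
        fused, mapping = fuse_translocation(a, b, 700, 0)
        assert mapping.loc[1, "source_chrom"] == "chrT" and mapping.loc[1, "source_bin"] == 0
        assert fused.values("der")[0] == a.values("chrT")[0]
        assert fused.values("der")[1] == b.values("chrT")[0]

    def test_breakpoint_beyond_end(self, pair):
        a, b = pair
        with pytest.raises(ValueError, match="breakpoint"):
            fuse_translocation(a, b, 99999, 0)
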