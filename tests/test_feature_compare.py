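import itertools
import math

import numpy as np
import pytest

from cycflex import feature_compare as fc, sequence_io as sio
from cycflex.predictor import LinearDinucModel
from tests.conftest import random_seq


def make_window(chrom, start, seq):
    return sio.SequenceWindow(chrom, start, start + len(seq), "+", seq)


class TestClassifyVariantWindows:
    def test_no_variants(self):
        w = make_window("c", 100, "A" * 50)
        assert fc.classify_variant_windows([w], []) == ["none"]

    def test_snp_and_del(self):
        w = make_window("c", 100, "A" * 50)
        vs = [fc.VariantRecord("c", 120, "SNP"),
              fc.VariantRecord("c", 130, "DEL", ref_span=2)]
        assert fc.classify_variant_windows([w], vs) == ["snp_and_indel"]

    def test_del_starting_before_window(self):
        w = make_window("c", 100, "A" * 50)
        v = fc.VariantRecord("c", 95, "DEL", ref_span=10)
        assert fc.classify_variant_windows([w], [v]) == ["indel_only"]

    def test_del_ending_at_window_start_misses(self):
        w = make_window("c", 100, "A" * 50)
        v = fc.VariantRecord("c", 90, "DEL", ref_span=10)  # [90,100)
        assert fc.classify_variant_windows([w], [v]) == ["none"]

    def test_brute_force_agreement(self, rng):
        windows = [make_window("c", int(s), "A" * 50)
                   for s in rng.integers(0, 3000, 100)]
        variants = []
        for _ in range(80):
            vtype = ["SNP", "INS", "DEL"][int(rng.integers(3))]
            span = 1 if vtype != "DEL" else int(rng.integers(1, 12))
            variants.append(fc.VariantRecord("c", int(rng.integers(0, 3000)),
                                             vtype, ref_span=span))
        labels = fc.classify_variant_windows(windows, variants)
        for w, lab in zip(windows, labels):
            snp = any(v.vtype == "SNP" and v.pos < w.end and v.end > w.start
                      for v in variants)
            ind = any(v.vtype != "SNP" and v.pos < w.end and v.end > w.start
                      for v in variants)
            expect = ("snp_and_indel" if snp and ind else
                      "snp_only" if snp else
                      "indel_only" if ind else "none")
            assert lab == expect


class TestCompareFeatureWindows:
    def test_identical_sets_d_zero(self, toy_genome, truth_model):
        wins = [make_window("chr1", s, toy_genome["chr1"][s:s + 50])
                for s in range(0, 500, 50)]
        rep = fc.compare_feature_windows(toy_genome, wins, wins, truth_model)
        assert rep.d == 0.0

    def test_hand_pairs(self, toy_genome):
        class Stub:
            kind = "stub"
            table = {}

            def score_raw(self, seq):
                return self.table[seq]

            def score_raw_batch(self, seqs):
                return np.array([self.score_raw(s) for s in seqs])

        # palindromic windows so rc-averaging is the identity
        w1 = "AT" * 25
        w2 = "GC" * 25
        w3 = "TA" * 25
        w4 = "CG" * 25
        stub = Stub()
        stub.table = {w1: 2.0, w2: 4.0, w3: 0.0, w4: 2.0}
        from cycflex.sequence_io import revcomp
        for s in list(stub.table):
            stub.table[revcomp(s)] = stub.table[s]
        a = [make_window("chr1", 0, w1), make_window("chr1", 50, w2)]
        b = [make_window("chr1", 100, w3), make_window("chr1", 150, w4)]
        rep = fc.compare_feature_windows(toy_genome, a, b, stub)
        assert rep.d == pytest.approx(math.sqrt(2))

    def test_small_set_error(self, toy_genome, truth_model):
        w = [make_window("chr1", 0, toy_genome["chr1"][:50])]
        with pytest.raises(ValueError):
            fc.compare_feature_windows(toy_genome, w, w * 2, truth_model)


class TestContexts:
    def test_rule_application(self):
        assert fc.classify_context("CGT") == "CG"
        assert fc.classify_context("CAG") == "CHG"
        assert fc.classify_context("CCT") == "CHH"

    def test_total_and_consistent(self):
        for b2, b3 in itertools.product("ACGT", repeat=2):
            ctx = "C" + b2 + b3
            cls = fc.classify_context(ctx)
            if b2 == "G":
                assert cls == "CG"
            elif b3 == "G":
                assert cls == "CHG"
            else:
                assert cls == "CHH"

    def test_find_contexts_small(self):
        g = sio.GenomeStore({"c": "ACGTT"})
        sites = fc.find_cytosine_contexts(g, "c")
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert plus[0].pos == 1 and plus[0].context3 == "CGT"
        assert plus[0].context_class == "CG"
        # G at pos 2 -> minus-strand C, context revcomp("ACG") = "CGT"
        minus = [s for s in sites if s.strand == "-"]
        assert len(minus) == 1
        assert minus[0].pos == 2 and minus[0].context3 == "CGT"

    def test_no_cg_sequence(self):
        g = sio.GenomeStore({"c": "ATATAT"})
        assert fc.find_cytosine_contexts(g, "c") == []

    def test_edge_cytosines_skipped(self):
        g = sio.GenomeStore({"c": "AAAAC"})  # C at last position: no context
        assert fc.find_cytosine_contexts(g, "c") == []


class TestMethylationComparison:
    def test_identical_sequences_d_zero(self, truth_model):
        g = sio.GenomeStore({"c": ("A" * 30 + "CAT" + "A" * 30) * 20})
        sites = fc.find_cytosine_contexts(g, "c")
        sites = [fc.MethylationSiteRecord(
            chrom=s.chrom, pos=s.pos, strand=s.strand, context3=s.context3,
            context_class=s.context_class, methylated=(i % 2 == 0))
            for i, s in enumerate(sites)]
        out = fc.methylation_comparison(g, sites, [("c", 0, 10_000)],
                                        truth_model)
        assert out["CHH"].d == 0.0

    def test_missing_flags_rejected(self, toy_genome, truth_model):
        sites = fc.find_cytosine_contexts(toy_genome, "chr1")[:10]
        with pytest.raises(ValueError, match="flags"):
            fc.methylation_comparison(toy_genome, sites,
                                      [("chr1", 0, 5000)], truth_model)

    def test_small_context_group_skipped(self, toy_genome, truth_model):
        sites = [s for s in fc.find_cytosine_contexts(toy_genome, "chr1")
                 if s.context_class == "CG"][:30]
        flagged = [fc.MethylationSiteRecord(
            chrom=s.chrom, pos=s.pos, strand=s.strand, context3=s.context3,
            context_class=s.context_class,
            methylated=(i == 0))  # only one methylated site
            for i, s in enumerate(sites)]
        with pytest.warns(UserWarning, match="skipped"):
            out = fc.methylation_comparison(toy_genome, flagged,
                                            [("chr1", 0, 5000)], truth_model)
        assert out == {}

    def test_null_flags_small_d(self, toy_genome, truth_model):
        rng = np.random.default_rng(0)
        sites = fc.find_cytosine_contexts(toy_genome, "chr1")
        flagged = [fc.MethylationSiteRecord(
            chrom=s.chrom, pos=s.pos, strand=s.strand, context3=s.context3,
            context_class=s.context_class,
            methylated=bool(rng.random() < 0.5)) for s in sites]
        out = fc.methylation_comparison(toy_genome, flagged,
                                        [("chr1", 0, 5000)], truth_model)
        assert set(out) <= {"CG", "CHG", "CHH"}
        for rep in out.values():
            # desk-scale null: |d| bounded by ~3/sqrt(n_min)
            n_min = min(rep.n1, rep.n2)
            assert abs(rep.d) < 4 / math.sqrt(n_min)


class TestTfBoundVsUnbound:
    def sites(self, toy_genome, n=12, bound_every=2):
        out = []
        for k in range(n):
            start = 400 + 300 * k
            out.append(("chr1", start, start + 10,
                        "1" if k % bound_every == 0 else "0"))
        return out

    def test_bound_equals_all(self, toy_genome, truth_model):
        sites = [(c, s, e, "1") for c, s, e, _ in self.sites(toy_genome, 8)]
        with pytest.warns(UserWarning, match="instances"):
            bound, allp = fc.tf_bound_vs_unbound(toy_genome, sites,
                                                 truth_model, flank=100,
                                                 min_sites=100)
        np.testing.assert_allclose(bound.mean, allp.mean)

    def test_constant_predictor_flat_equal(self, toy_genome, constant_model):
        sites = self.sites(toy_genome)
        with pytest.warns(UserWarning):
            bound, allp = fc.tf_bound_vs_unbound(toy_genome, sites,
                                                 constant_model, flank=100)
        np.testing.assert_allclose(bound.mean, 0.7)
        np.testing.assert_allclose(allp.mean, 0.7)

    def test_offsets_cover_flank(self, toy_genome, truth_model):
        sites = self.sites(toy_genome)
        bound, _ = fc.tf_bound_vs_unbound(toy_genome, sites, truth_model,
                                          flank=200, min_sites=5)
        assert bound.offsets[0] == -176
        assert bound.offsets[-1] == 175

    def test_no_bound_sites_error(self, toy_genome, truth_model):
        sites = [("chr1", 500, 510, "0")]
        with pytest.raises(ValueError, match="bound"):
            fc.tf_bound_vs_unbound(toy_genome, sites, truth_model)


class TestPositionwiseCorrelation:
    def test_track_equals_predictions(self, toy_genome, truth_model):
        from cycflex.profiles import predict_track
        pos, scores = predict_track(toy_genome, "chr1", 0, 2000, truth_model,
                                    step=7)
        track = {"chr1": (pos, scores)}
        r = fc.positionwise_correlation(track, toy_genome, truth_model)
        assert r == pytest.approx(1.0)

    def test_negated_track(self, toy_genome, truth_model):
        from cycflex.profiles import predict_track
        pos, scores = predict_track(toy_genome, "chr1", 0, 2000, truth_model,
                                    step=7)
        track = {"chr1": (pos, -scores)}
        r = fc.positionwise_correlation(track, toy_genome, truth_model)
        assert r == pytest.approx(-1.0)

    def test_noise_track_null_bound(self, toy_genome, truth_model):
        rng = np.random.default_rng(12)
        pos = np.arange(30, 4900)
        vals = rng.normal(size=len(pos))
        vals[vals == 0] = 1.0
        r = fc.positionwise_correlation({"chr1": (pos, vals)}, toy_genome,
                                        truth_model)
        assert abs(r) < 3 / math.sqrt(len(pos))

    def test_exclusion_intervals(self, toy_genome, truth_model):
        pos = np.arange(100, 200)
        vals = np.ones(len(pos))
        with pytest.raises(ValueError, match="usable"):
            fc.positionwise_correlation({"chr1": (pos, vals)}, toy_genome,
                                        truth_model,
                                        exclude=[("chr1", 0, 5000)])

    def test_zero_values_skipped(self, toy_genome, truth_model):
        pos = np.arange(100, 104)
        vals = np.array([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="usable"):
            fc.positionwise_correlation({"chr1": (pos, vals)}, toy_genome,
                                        truth_model)


class TestReadVariantsVcf:
    VCF = (
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t101\t.\tA\tG\t.\t.\t.\n"
        "chr1\t201\t.\tACGT\tA\t.\t.\t.\n"
        "chr1\t301\t.\tA\tATT\t.\t.\t.\n"
        "chr1\t401\t.\tC\tG,T\t.\t.\t.\n"
    )

    def test_typing_and_coordinates(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(self.VCF)
        recs = fc.read_variants_vcf(p)
        assert [(v.chrom, v.pos, v.vtype, v.ref_span) for v in recs] == [
            ("chr1", 100, "SNP", 1),
            ("chr1", 200, "DEL", 4),
            ("chr1", 300, "INS", 1),
            ("chr1", 400, "SNP", 1),
            ("chr1", 400, "SNP", 1),
        ]

    def test_malformed_line(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("chr1\t101\t.\n")
        with pytest.raises(ValueError, match="columns"):
            fc.read_variants_vcf(p)
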