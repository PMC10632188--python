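import numpy as np
import pytest

from cycflex import profiles, sequence_io as sio
from cycflex.predictor import (
    LinearDinucModel,
    rc_averaged_predict,
)
from tests.conftest import random_seq


def brute_force_profile(genome, anchors, model, flank):
    """Independent double-loop oracle for anchored_mean_profile."""
    offsets = list(range(-(flank - 24), flank - 25 + 1))
    per_offset = {o: [] for o in offsets}
    for a in anchors:
        L = genome.length(a.chrom)
        if a.pos - flank < 0 or a.pos + flank + 1 > L:
            continue
        region = genome[a.chrom][a.pos - flank:a.pos + flank + 1]
        if a.strand == "-":
            region = sio.revcomp(region, allow_iupac=True)
        for o in offsets:
            i = o + flank
            win = region[i - 24:i + 26]
            if set(win) <= set("ACGT"):
                per_offset[o].append(rc_averaged_predict(model, win))
    mean = np.array([np.mean(per_offset[o]) if per_offset[o] else np.nan
                     for o in offsets])
    n = np.array([len(per_offset[o]) for o in offsets])
    return np.array(offsets), mean, n


class TestAnchoredMeanProfile:
    def test_constant_predictor_flat(self, toy_genome, constant_model):
        anchors = [sio.TSSRecord("g1", "chr1", 1000, "+"),
                   sio.TSSRecord("g2", "chr1", 3000, "-")]
        prof = profiles.anchored_mean_profile(toy_genome, anchors,
                                              constant_model, flank=100)
        np.testing.assert_allclose(prof.mean, 0.7)
        assert (prof.n == 2).all()

    def test_offset_domain(self, toy_genome, constant_model):
        anchors = [sio.TSSRecord("g1", "chr1", 1000, "+")]
        prof = profiles.anchored_mean_profile(toy_genome, anchors,
                                              constant_model, flank=525)
        assert prof.offsets[0] == -501
        assert prof.offsets[-1] == 500

    def test_matches_brute_force_bitwise(self, toy_genome, truth_model):
        anchors = [sio.TSSRecord("g1", "chr1", 500, "+"),
                   sio.TSSRecord("g2", "chr2", 900, "-"),
                   sio.TSSRecord("g3", "chr1", 4000, "+")]
        prof = profiles.anchored_mean_profile(toy_genome, anchors,
                                              truth_model, flank=60)
        offs, mean, n = brute_force_profile(toy_genome, anchors, truth_model,
                                            60)
        np.testing.assert_array_equal(prof.offsets, offs)
        np.testing.assert_array_equal(prof.n, n)
        np.testing.assert_allclose(prof.mean, mean, rtol=0, atol=0)

    def test_single_anchor_offset_zero_window(self, toy_genome, truth_model):
        a = sio.TSSRecord("g1", "chr1", 800, "+")
        prof = profiles.anchored_mean_profile(toy_genome, [a], truth_model,
                                              flank=60)
        win = toy_genome["chr1"][800 - 24:800 + 26]
        expected = rc_averaged_predict(truth_model, win)
        j = list(prof.offsets).index(0)
        assert prof.mean[j] == pytest.approx(expected, abs=0)

    def test_edge_anchors_skipped(self, toy_genome, constant_model):
        anchors = [sio.TSSRecord("g1", "chr1", 5, "+"),
                   sio.TSSRecord("g2", "chr1", 1000, "+")]
        with pytest.warns(UserWarning):
            prof = profiles.anchored_mean_profile(toy_genome, anchors,
                                                  constant_model, flank=100)
        assert (prof.n == 1).all()

    def test_no_usable_anchors_error(self, toy_genome, constant_model):
        anchors = [sio.TSSRecord("g1", "chr1", 5, "+")]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero usable"):
                profiles.anchored_mean_profile(toy_genome, anchors,
                                               constant_model, flank=100)

    def test_tsv_roundtrip(self, toy_genome, truth_model, tmp_path):
        anchors = [sio.TSSRecord("g1", "chr1", 500, "+")]
        prof = profiles.anchored_mean_profile(toy_genome, anchors,
                                              truth_model, flank=50)
        p = tmp_path / "prof.tsv"
        prof.to_tsv(p)
        back = profiles.PositionalProfile.from_tsv(p)
        np.testing.assert_allclose(back.mean, prof.mean)


class TestRandomizedProfile:
    @pytest.mark.parametrize("mode", ["mono_h", "dinuc_h", "mono_v",
                                      "dinuc_v"])
    def test_constant_predictor_flat(self, toy_genome, constant_model, rng,
                                     mode):
        anchors = [sio.TSSRecord("g1", "chr1", 1000, "+"),
                   sio.TSSRecord("g2", "chr1", 2000, "+")]
        prof = profiles.randomized_profile(toy_genome, anchors,
                                           constant_model, 60, mode, 1, rng)
        np.testing.assert_allclose(prof.mean, 0.7)

    def test_dinuc_h_preserves_scores_exactly(self, toy_genome, truth_model,
                                              rng):
        # dinucleotide counts are preserved, so a linear dinucleotide model
        # assigns identical scores to every shuffled window
        anchors = [sio.TSSRecord("g1", "chr1", 1000, "+"),
                   sio.TSSRecord("g2", "chr2", 1500, "-")]
        actual = profiles.anchored_mean_profile(toy_genome, anchors,
                                                truth_model, 60)
        shuffled = profiles.randomized_profile(toy_genome, anchors,
                                               truth_model, 60, "dinuc_h", 1,
                                               rng)
        np.testing.assert_allclose(shuffled.mean, actual.mean, atol=1e-12)

    def test_mono_h_flattens_planted_structure(self, planted_sim, rng):
        # the planted structure is purely dinucleotide-arranged (uniform base
        # marginals), so single-base shuffling flattens the profile
        spec, sim = planted_sim
        ta = LinearDinucModel.from_dict({"TA": 0.5, "AT": 0.5})
        anchors = list(sim.tss)[:60]
        actual = profiles.anchored_mean_profile(sim.genome, anchors, ta, 100)
        shuffled = profiles.randomized_profile(sim.genome, anchors, ta, 100,
                                               "mono_h", 2, rng)
        assert np.var(shuffled.mean) < 0.3 * np.var(actual.mean)

    def test_matched_pair_returns_differences(self, toy_genome, truth_model,
                                              rng):
        anchors = [sio.TSSRecord("g1", "chr1", 1000, "+")]
        prof, pairs = profiles.randomized_profile(
            toy_genome, anchors, truth_model, 40, "matched_pair", 1, rng)
        assert len(pairs.diff_dinuc) == len(pairs.diff_mono)
        # dinuc shuffling preserves linear scores exactly
        np.testing.assert_allclose(pairs.diff_dinuc, 0.0, atol=1e-12)
        assert np.abs(pairs.diff_mono).max() > 0

    def test_bad_mode(self, toy_genome, constant_model, rng):
        anchors = [sio.TSSRecord("g1", "chr1", 1000, "+")]
        with pytest.raises(ValueError, match="mode"):
            profiles.randomized_profile(toy_genome, anchors, constant_model,
                                        60, "tetra_h", 1, rng)


class TestDinucLogratioProfile:
    def test_observed_equals_expected(self):
        # user-supplied expected equal to the observed composition -> zeros
        seqs = ["".join(p) for p in
                __import__("itertools").product("ACGT", repeat=2)]
        prof = profiles.dinuc_logratio_profile(
            seqs, expected=np.full(16, 1.0 / 16))
        np.testing.assert_allclose(prof.values[prof.defined], 0.0, atol=1e-12)

    def test_atat_hand_case(self):
        seqs = ["ATAT"] * 5
        prof = profiles.dinuc_logratio_profile(seqs)
        # pooled base freqs: A=0.5, T=0.5 -> e_AT = 0.25
        assert prof.value("AT", 0) == pytest.approx(np.log(1 / 0.25))
        assert prof.value("TA", 1) == pytest.approx(np.log(1 / 0.25))
        # unobserved cells are flagged undefined
        assert np.isnan(prof.value("AA", 0))

    def test_uniform_iid_null_bound(self):
        rng = np.random.default_rng(5)
        n, L = 8000, 6
        seqs = [random_seq(rng, L) for _ in range(n)]
        prof = profiles.dinuc_logratio_profile(
            seqs, expected=np.full(16, 1.0 / 16))
        # 3-sigma multinomial bound on log-ratio around 0
        sigma = np.sqrt((1 - 1 / 16) / (n / 16))
        assert np.nanmax(np.abs(prof.values)) < 3 * sigma

    def test_pooled_dinucleotide_expected(self):
        seqs = ["ATAT"] * 3
        prof = profiles.dinuc_logratio_profile(seqs,
                                               expected="pooled_dinucleotide")
        # pooled dinuc: AT 2/3, TA 1/3; at offset 0 only AT observed
        assert prof.value("AT", 0) == pytest.approx(np.log(1 / (2 / 3)))


class TestPredictTrack:
    def test_minimal_region(self, toy_genome, constant_model):
        pos, scores = profiles.predict_track(toy_genome, "chr1", 0, 50,
                                             constant_model)
        assert pos.tolist() == [24]
        np.testing.assert_allclose(scores, 0.7)

    def test_length_60_step_1(self, toy_genome, truth_model):
        pos, scores = profiles.predict_track(toy_genome, "chr1", 100, 160,
                                             truth_model)
        assert pos.tolist() == list(range(124, 135))
        win = toy_genome["chr1"][100:150]
        assert scores[0] == pytest.approx(
            rc_averaged_predict(truth_model, win))

    def test_too_short_region(self, toy_genome, constant_model):
        with pytest.raises(ValueError):
            profiles.predict_track(toy_genome, "chr1", 0, 49, constant_model)

    def test_ambiguous_positions_absent(self, constant_model):
        g = sio.GenomeStore({"c": "A" * 60 + "N" + "A" * 60})
        pos, _ = profiles.predict_track(g, "c", 0, 121, constant_model)
        # windows overlapping the N at index 60 are dropped
        assert 60 not in ((pos - 24).tolist())
        expected = [s + 24 for s in range(0, 72)
                    if not (s <= 60 < s + 50)]
        assert pos.tolist() == expected


class TestAcf:
    def test_lag_zero_is_one(self, rng):
        x = rng.normal(size=100)
        assert profiles.acf(x, 10)[0] == pytest.approx(1.0)

    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 500)
        vals = profiles.acf(x, 1)
        assert vals[1] == pytest.approx(-1.0, abs=2e-3)

    def test_white_noise_bound(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10_000)
        vals = profiles.acf(x, 50)
        assert np.abs(vals[1:]).max() < 3 / np.sqrt(len(x))

    def test_matches_fft_implementation(self, rng):
        x = rng.normal(size=512)
        direct = profiles.acf(x, 64)
        xc = x - x.mean()
        f = np.fft.rfft(np.concatenate([xc, np.zeros_like(xc)]))
        fft_acov = np.fft.irfft(f * np.conj(f))[:65]
        fft_acf = fft_acov / fft_acov[0]
        np.testing.assert_allclose(direct, fft_acf, atol=1e-8)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            profiles.acf(np.ones(100), 5)

    def test_max_lag_too_large(self, rng):
        with pytest.raises(ValueError):
            profiles.acf(rng.normal(size=10), 10)
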