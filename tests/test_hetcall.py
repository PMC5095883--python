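"""Likelihood model, LLR statistic, strand filter, calling and comparison."""

import numpy as np
import pytest

from cfmito import hetcall, simdata
from cfmito.hetcall import (
    SitePileup,
    call_plasma,
    call_wbc,
    classify_shared,
    consensus_sequences,
    likelihood,
    llr,
    llr_counts,
    loglik_counts,
    reconstruct_pileup,
    strand_test,
)


def grid_oracle(eps, major, minor, step=1e-4):
    """Brute-force grid maximisation of the site likelihood."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    values = loglik_counts(grid, eps, np.asarray(major), np.asarray(minor))
    f_best = grid[values.argmax()]
    llr_value = (values.max() - max(values[0], values[-1])) / np.log(10)
    return f_best, llr_value


def uniform_pileup(l, k, qual=30, position=100):
    """l major (A) and k minor (G) bases at one quality, strand-balanced."""
    return SitePileup.from_counts(
        position, {"A": (l - l // 2, l // 2), "G": (k - k // 2, k // 2)}, qual=qual
    )


class TestLikelihood:
    def test_perfect_homoplasmy_peaks_at_one(self):
        pile = uniform_pileup(50, 0, qual=90)
        assert likelihood(pile, 1.0) == pytest.approx(0.0, abs=1e-6)
        f_het, value = llr(pile)
        assert f_het == pytest.approx(1.0, abs=1e-6)
        assert value == 0.0

    def test_symmetry_when_alleles_balance(self):
        pile = uniform_pileup(20, 20)
        for f in (0.1, 0.3, 0.5):
            assert likelihood(pile, f) == pytest.approx(likelihood(pile, 1 - f))

    def test_f_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            likelihood(uniform_pileup(5, 1), 1.5)

    def test_mle_matches_grid_search(self):
        pile = uniform_pileup(52, 4)
        eps, major, minor = pile.quality_count_matrix()
        f_grid, llr_grid = grid_oracle(eps, major, minor)
        f_het, value = llr(pile)
        assert abs(f_het - f_grid) < 1e-3
        assert abs(value - llr_grid) < 1e-3
        assert value > 5

    def test_mle_approaches_count_fraction_as_error_vanishes(self):
        pile = uniform_pileup(90, 10, qual=90)
        f_het, _ = llr(pile)
        assert f_het == pytest.approx(0.9, abs=1e-4)


class TestLLR:
    def test_no_minor_bases_means_zero_llr(self):
        _f, value = llr(uniform_pileup(100, 0))
        assert value == 0.0

    def test_single_low_quality_minor_base_insufficient(self):
        pile = SitePileup.from_counts(100, {"A": (50, 50), "G": (1, 0)}, qual=10)
        _f, value = llr(pile)
        assert value < 5

    def test_llr_never_negative_and_zero_depth_errors(self):
        with pytest.raises(ValueError):
            llr(SitePileup(position=5))

    def test_monotone_in_minor_count_at_fixed_depth(self):
        values = []
        for k in range(0, 8):
            values.append(llr(uniform_pileup(100 - k, k))[1])
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_invariant_to_strand_relabelling(self):
        p1 = SitePileup.from_counts(100, {"A": (30, 22), "G": (4, 1)})
        p2 = SitePileup.from_counts(100, {"A": (22, 30), "G": (1, 4)})
        assert llr(p1) == llr(p2)


class TestStrandTest:
    def test_balanced_strands_pass_with_p_one(self):
        ok, p = strand_test(SitePileup.from_counts(1, {"A": (50, 50), "G": (5, 5)}))
        assert ok and p == pytest.approx(1.0)

    def test_minor_on_one_strand_only_fails(self):
        ok, _ = strand_test(SitePileup.from_counts(1, {"A": (250, 250), "G": (6, 0)}))
        assert not ok

    def test_chi_square_matches_textbook_formula(self):
        pile = SitePileup.from_counts(1, {"A": (500, 500), "G": (30, 5)})
        _ok, p = strand_test(pile)
        # 2x2 chi-square without continuity correction:
        # X^2 = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]
        a, b, c, d = 500, 30, 500, 5
        n = a + b + c + d
        x2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        from scipy.stats import chi2

        assert p == pytest.approx(1 - chi2.cdf(x2, df=1))
        assert not _ok  # imbalanced minor allele is rejected

    def test_zero_depth_strand_fails(self):
        ok, _ = strand_test(SitePileup.from_counts(1, {"A": (50, 0), "G": (5, 0)}))
        assert not ok


class TestCallWbc:
    def test_sub_percent_minor_frequency_rejected(self):
        # depth 3714, minor 0.46%: fails the 1% frequency criterion
        pile = reconstruct_pileup(11836, 3714, "A", 99.54, "G", 0.46)
        call = call_wbc(pile)
        assert not call.is_heteroplasmic
        assert not call.flags["maf"]
        assert call.flags["coverage"]

    def test_coverage_threshold_is_strict(self):
        pile = uniform_pileup(380, 20)  # depth 400 exactly
        call = call_wbc(pile)
        assert pile.depth == 400
        assert not call.flags["coverage"]
        assert not call.is_heteroplasmic

    def test_planted_five_percent_heteroplasmy_recovered(self, rng):
        major, minor = simdata.simulate_heteroplasmic_counts(1, 1000, 0.05, 30, rng)
        pile = uniform_pileup(int(major[0]), int(minor[0]))
        call = call_wbc(pile)
        assert call.is_heteroplasmic
        se = 100 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(call.minor_freq - 5.0) < 3 * se


class TestCallPlasma:
    def test_published_single_site_examples(self):
        call56 = call_plasma(uniform_pileup(52, 4))
        assert call56.is_heteroplasmic
        assert round(call56.minor_freq, 1) == 7.1
        call58 = call_plasma(uniform_pileup(54, 4))
        assert call58.is_heteroplasmic
        assert round(call58.minor_freq, 2) == 6.90

    def test_minor_on_single_strand_not_called(self):
        pile = SitePileup.from_counts(100, {"A": (26, 26), "G": (4, 0)})
        call = call_plasma(pile)
        assert not call.flags["both_strands"]
        assert not call.is_heteroplasmic

    def test_coverage_threshold_strict(self):
        pile = uniform_pileup(46, 4)  # depth 50 exactly
        assert not call_plasma(pile).flags["coverage"]


class TestClassifyShared:
    def test_minor_absent_from_plasma_is_wbc_only(self):
        wbc = reconstruct_pileup(477, 942, "T", 96.1, "C", 3.9)
        plasma = reconstruct_pileup(477, 452, "T", 100.0, "C", 0.0)
        result = classify_shared(wbc, plasma)
        assert result.klass == "wbc_only"

    def test_minor_absent_from_wbc_is_plasma_only(self):
        wbc = reconstruct_pileup(72, 2325, "T", 100.0, "C", 0.0)
        plasma = reconstruct_pileup(72, 1199, "T", 84.8, "C", 15.1)
        assert classify_shared(wbc, plasma).klass == "plasma_only"

    def test_weak_but_present_wbc_signal_is_shared(self):
        wbc = reconstruct_pileup(186, 2325, "G", 99.87, "T", 0.13)
        plasma = reconstruct_pileup(186, 481, "G", 97.9, "T", 2.1)
        result = classify_shared(wbc, plasma)
        assert result.klass == "both"
        assert result.criteria["llr"]

    def test_flipped_major_alleles_can_still_be_shared(self):
        wbc = reconstruct_pileup(207, 2040, "A", 96.8, "G", 3.2)
        plasma = reconstruct_pileup(207, 335, "A", 1.8, "G", 98.2)
        assert classify_shared(wbc, plasma).klass == "both"

    def test_called_in_neither_compartment_errors(self):
        wbc = reconstruct_pileup(100, 500, "A", 100.0, "G", 0.0)
        plasma = reconstruct_pileup(100, 100, "A", 100.0, "G", 0.0)
        with pytest.raises(ValueError, match="neither"):
            classify_shared(wbc, plasma)


class TestConsensus:
    def _call(self, position, major, minor):
        return hetcall.HeteroplasmyCall(
            position, "plasma", major, minor, 100, 90.0, 10.0,
            0.9, 1.0, 20.0, {}, True,
        )

    def test_no_heteroplasmy_gives_identical_sequences(self):
        ref = "ACGT" * 10
        major, minor = consensus_sequences([], ref)
        assert major == minor == ref

    def test_single_site_differs_at_exactly_that_position(self):
        ref = "A" * 100
        major, minor = consensus_sequences([self._call(10, "G", "A")], ref)
        diffs = [i for i, (x, y) in enumerate(zip(major, minor)) if x != y]
        assert diffs == [9]
        assert major[9] == "G" and minor[9] == "A"

    def test_conflicting_calls_error(self):
        ref = "A" * 100
        with pytest.raises(ValueError, match="conflicting"):
            consensus_sequences(
                [self._call(10, "G", "A"), self._call(10, "C", "A")], ref
            )

    def test_roundtrip_minor_consensus_recovers_alleles_as_major(self, reference):
        # simulate reads from the minor-allele consensus and re-call
        call = self._call(5000, reference.mito[4999], "T")
        assert reference.mito[4999] != "T"
        _, minor_seq = consensus_sequences([call], reference.mito)
        from cfmito.reference import ReferenceSet

        minor_ref = ReferenceSet(mito=minor_seq, nuclear=reference.nuclear)
        config = simdata.SimConfig(
            n_fragments=500, mito_fraction=1.0, mito_region=(4950, 5050),
            base_quality_model=simdata.QualityModel((60,), (1.0,)), seed=31,
        )
        frags, _ = simdata.simulate_fragments(config, minor_ref)
        import tempfile, os

        with tempfile.TemporaryDirectory() as d:
            sam = os.path.join(d, "m.sam")
            simdata.write_sam(frags, config, minor_ref, sam)
            piles = hetcall.pileups_from_alignments(sam)
        assert piles[5000].major_allele == "T"


class TestPileupConstruction:
    def test_quality_filter_drops_everything_below_q20(self):
        pile = SitePileup.from_bases(10, [("A", 19, False)] * 10)
        assert pile.depth == 0

    def test_position_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            SitePileup(position=16570)
        with pytest.raises(ValueError):
            SitePileup(position=0)

    def test_overlapping_mates_count_once_with_higher_quality(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrM", "LN": 16569}]}
        sam = tmp_path / "overlap.sam"
        with pysam.AlignmentFile(str(sam), "wh", header=header) as af:
            for first, qual, flag in ((True, 30, 0x63), (False, 35, 0x93)):
                seg = pysam.AlignedSegment(af.header)
                seg.query_name = "frag1"
                seg.query_sequence = "A" * 42
                seg.flag = flag
                seg.reference_id = 0
                seg.reference_start = 99
                seg.mapping_quality = 60
                seg.cigarstring = "42M"
                seg.query_qualities = pysam.qualitystring_to_array(
                    chr(qual + 33) * 42
                )
                af.write(seg)
        piles = hetcall.pileups_from_alignments(str(sam))
        pile = piles[100]
        assert pile.depth == 1
        assert pile.quals["A"] == [35]

    def test_simulated_error_free_counts_match_truth(self, reference, tmp_path):
        site = simdata.HetSite(5000, "C", 0.3)
        assert reference.mito[4999] != "C"
        config = simdata.SimConfig(
            n_fragments=400, mito_fraction=1.0, het_sites=(site,),
            mito_region=(4950, 5050),
            base_quality_model=simdata.QualityModel((60,), (1.0,)), seed=37,
        )
        frags, _ = simdata.simulate_fragments(config, reference)
        sam = tmp_path / "t.sam"
        simdata.write_sam(frags, config, reference, str(sam))
        piles = hetcall.pileups_from_alignments(str(sam))
        covers = (frags.start <= 4999) & (4999 < frags.start + frags.length)
        carriers = int(frags.minor_carrier[:, 0].sum())
        pile = piles[5000]
        assert pile.depth == int(covers.sum())
        assert pile.allele_count("C") == carriers


class TestVectorisedAgreement:
    def test_llr_counts_agrees_with_scalar_path(self, rng):
        eps, major, minor = simdata.simulate_homoplasmic_quality_counts(
            20, 200, np.arange(20, 41), rng
        )
        f_vec, _homo, llr_vec = llr_counts(eps, major, minor)
        quals = np.arange(20, 41)
        for i in range(20):
            pile = SitePileup(position=50)
            for q, n_maj, n_min in zip(quals, major[i], minor[i]):
                for _ in range(int(n_maj)):
                    pile.add("A", int(q), False)
                for _ in range(int(n_min)):
                    pile.add("G", int(q), False)
            f_s, llr_s = llr(pile)
            assert f_s == pytest.approx(f_vec[i], abs=1e-5)
            assert llr_s == pytest.approx(llr_vec[i], abs=1e-6)
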