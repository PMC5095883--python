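"""Pair filtering, fragment inference, deduplication, NUMT screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfmito import readproc, simdata
from cfmito.readproc import (
    AlignedPair,
    FragmentRecord,
    MateAlignment,
    dedupe,
    filter_pair,
    infer_fragment,
    numt_filter,
)
from cfmito.reference import MITO_NAME
from cfmito.simdata import QualityModel, SimConfig


def _mate(ref=MITO_NAME, start=100, end=250, mapq=60, nm=0, length=150,
          reverse=False, score=0):
    return MateAlignment(ref, start, end, mapq, nm, length, reverse, score)


def _pair(m1=None, m2=None, name="p"):
    return AlignedPair(name, m1 or _mate(), m2 or _mate(start=120, end=270, reverse=True))


class TestFilterPair:
    def test_passing_pair(self):
        ok, reason = filter_pair(_pair(_mate(mapq=21, nm=2), _mate(mapq=30, nm=2, start=120, end=270, reverse=True)))
        assert ok and reason is None

    def test_mapq_threshold_is_strict(self):
        ok, reason = filter_pair(_pair(_mate(mapq=20), None))
        assert not ok and reason == "mapq"
        ok, _ = filter_pair(_pair(_mate(mapq=21), None))
        assert ok

    def test_mismatch_boundary_is_strict(self):
        # 5 mismatches on a 100 bp mate: 5 is not < 5% of 100
        bad = _mate(nm=5, length=100)
        ok, reason = filter_pair(_pair(bad, None))
        assert not ok and reason == "mismatches"
        ok, _ = filter_pair(_pair(_mate(nm=4, length=100), None))
        assert ok

    @pytest.mark.parametrize(
        "m1,m2,reason",
        [
            (_mate(reverse=True), _mate(start=120, end=270), "RF"),
            (_mate(), _mate(start=120, end=270), "tandem"),
        ],
    )
    def test_orientation_required_inward(self, m1, m2, reason):
        pair = AlignedPair("p", m1, m2)
        assert pair.orientation == reason
        ok, why = filter_pair(pair)
        assert not ok and why == "orientation"

    def test_unmapped_mate(self):
        ok, reason = filter_pair(_pair(_mate(ref=None), None))
        assert not ok and reason == "unmapped"

    def test_filtering_is_idempotent(self):
        pair = _pair()
        assert filter_pair(pair) == filter_pair(pair)


class TestInferFragment:
    def test_fully_overlapping_mates(self):
        pair = _pair(_mate(start=100, end=142), _mate(start=100, end=142, reverse=True))
        frag = infer_fragment(pair)
        assert (frag.start, frag.end, frag.length) == (100, 142, 42)
        assert frag.genome_class == "mito"

    def test_outermost_coordinates(self):
        pair = _pair(_mate(start=0, end=150), _mate(start=17, end=167, reverse=True))
        assert infer_fragment(pair).length == 167

    def test_different_references_error(self):
        pair = _pair(_mate(), _mate(ref="nuc1", reverse=True, start=120, end=270))
        with pytest.raises(ValueError, match="different references"):
            infer_fragment(pair)


class TestDedupe:
    @given(k=st.integers(min_value=1, max_value=12))
    @settings(max_examples=20, derandomize=True)
    def test_k_identical_copies_retain_exactly_one(self, k):
        frags = [
            FragmentRecord(MITO_NAME, 100, 142, "mito", name=f"f{i}")
            for i in range(k)
        ]
        dedupe(frags)
        assert sum(not f.duplicate for f in frags) == 1
        assert not frags[0].duplicate  # first-seen wins

    def test_near_duplicates_both_retained(self):
        frags = [
            FragmentRecord(MITO_NAME, 100, 142, "mito"),
            FragmentRecord(MITO_NAME, 101, 142, "mito"),
        ]
        dedupe(frags)
        assert all(not f.duplicate for f in frags)

    def test_dedupe_is_idempotent_and_never_empties_a_locus(self):
        frags = [FragmentRecord(MITO_NAME, 1, 43, "mito") for _ in range(3)]
        once = [f.duplicate for f in dedupe(frags)]
        twice = [f.duplicate for f in dedupe(frags)]
        assert once == twice
        assert sum(not d for d in once) == 1


class TestNumtFilter:
    def test_mito_only_alignment_retained(self):
        frag = FragmentRecord(MITO_NAME, 100, 142, "mito")
        assert numt_filter(frag, [[_mate(score=-6)], [_mate(score=0)]])
        assert not frag.numt_ambiguous

    def test_equal_score_nuclear_alignment_is_ambiguous(self):
        frag = FragmentRecord(MITO_NAME, 100, 142, "mito")
        mito = _mate(score=0)
        nuclear = _mate(ref="nuc1", score=0)
        assert not numt_filter(frag, [[mito, nuclear], [_mate(score=0)]])
        assert frag.numt_ambiguous

    def test_worse_nuclear_alignment_retained(self):
        frag = FragmentRecord(MITO_NAME, 100, 142, "mito")
        assert numt_filter(frag, [[_mate(score=0), _mate(ref="nuc1", score=-12)]])

    def test_missing_scores_fall_back_to_mapq(self, caplog):
        frag = FragmentRecord(MITO_NAME, 100, 142, "mito")
        mito = _mate(score=None, mapq=60)
        nuclear = _mate(ref="nuc1", score=None)
        with caplog.at_level("WARNING"):
            assert numt_filter(frag, [[mito, nuclear]])
        assert "MAPQ proxy" in caplog.text


@pytest.fixture(scope="module")
def sim_run(reference, tmp_path_factory):
    config = SimConfig(
        n_fragments=1500,
        mito_fraction=0.5,
        base_quality_model=QualityModel((60,), (1.0,)),
        seed=17,
    )
    frags, truth = simdata.simulate_fragments(config, reference)
    sam = tmp_path_factory.mktemp("rp") / "sim.sam"
    simdata.write_sam(frags, config, reference, str(sam))
    return frags, truth, readproc.process_sam(str(sam))


class TestSimulatedRoundTrip:
    def test_error_free_data_all_pass_with_exact_lengths(self, sim_run):
        frags, truth, result = sim_run
        assert all(f.pass_filters for f in result.fragments)
        truth_lengths = dict(
            zip(truth.to_frame()["fragment_id"], truth.to_frame()["length"])
        )
        for frag in result.fragments:
            assert frag.length == truth_lengths[frag.name]

    def test_no_decoys_means_no_numt_flags(self, sim_run):
        _frags, _truth, result = sim_run
        assert not any(f.numt_ambiguous for f in result.fragments)

    def test_numt_decoys_are_flagged_against_truth(self, reference, tmp_path):
        config = SimConfig(
            n_fragments=1200,
            mito_fraction=0.3,
            numt_decoys=(simdata.NumtDecoy("nuc1", 10_000, 5_000, 2_000, 0.02),),
            numt_fraction=0.3,
            seed=29,
        )
        frags, _ = simdata.simulate_fragments(config, reference)
        sam = tmp_path / "numt.sam"
        simdata.write_sam(frags, config, reference, str(sam))
        result = readproc.process_sam(str(sam))
        flagged = {f.name for f in result.fragments if f.numt_ambiguous}
        truth_numt = {
            f"frag{i:07d}"
            for i in np.flatnonzero(frags.origin == "numt")
        }
        assert len(truth_numt) > 100
        sensitivity = len(flagged & truth_numt) / len(truth_numt)
        assert sensitivity >= 0.90
        # genuine mito fragments are never flagged
        truth_mito = {
            f"frag{i:07d}" for i in np.flatnonzero(frags.origin == "mito")
        }
        assert not (flagged & truth_mito)
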