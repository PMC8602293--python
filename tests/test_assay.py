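"""Splice-assay quantification, fragment arithmetic, normalization and
severity classification."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from irdsolve.assay import (
    AssayConfig,
    classify_allele_severity,
    interpret_assay,
    normalized_wt_percent,
    predict_fragment_length,
    quantify_fragments,
)
from irdsolve.model import Lane, SpliceEvent, SpliceEventKind


def _lanes(*pairs):
    return tuple(Lane(fragment_length_nt=l, intensity=i) for l, i in pairs)


class TestQuantifyFragments:
    def test_published_ush2a_percentages(self):
        out = quantify_fragments(_lanes((332, 78.9), (225, 21.1)))
        assert out == [(332, pytest.approx(78.9)), (225, pytest.approx(21.1))]

    def test_simple_ratio(self):
        assert quantify_fragments(_lanes((300, 3.0), (200, 1.0))) == \
            [(300, 75.0), (200, 25.0)]

    def test_single_lane_is_all_of_the_product(self):
        assert quantify_fragments(_lanes((378, 12.3))) == [(378, 100.0)]

    def test_all_zero_intensities_rejected(self):
        with pytest.raises(ValueError):
            quantify_fragments(_lanes((300, 0.0)))

    def test_ignored_lanes_are_excluded(self):
        lanes = (Lane(492, 42.0), Lane(620, 99.0, ignore=True), Lane(359, 58.0))
        pct = dict(quantify_fragments(lanes))
        assert pct[492] == pytest.approx(42.0)
        assert 620 not in pct

    @given(
        weights=st.lists(st.floats(0.01, 1e6), min_size=1, max_size=6),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_and_sums_to_100(self, weights, scale):
        lanes = _lanes(*[(100 + i, w) for i, w in enumerate(weights)])
        scaled = _lanes(*[(100 + i, w * scale) for i, w in enumerate(weights)])
        base = quantify_fragments(lanes)
        assert sum(p for _, p in base) == pytest.approx(100.0, abs=1e-9)
        for (_, p1), (_, p2) in zip(base, quantify_fragments(scaled)):
            assert p1 == pytest.approx(p2, rel=1e-9)


class TestPredictFragmentLength:
    @pytest.mark.parametrize("wt,kind,size,expected", [
        (225, SpliceEventKind.exon_elongation, 107, 332),
        (274, SpliceEventKind.pseudoexon_insertion, 104, 378),
        (492, SpliceEventKind.pseudoexon_insertion, 75, 567),
        (500, SpliceEventKind.exon_skipping, 130, 370),
    ])
    def test_published_fragment_arithmetic(self, wt, kind, size, expected):
        assert predict_fragment_length(wt, SpliceEvent(kind, size)) == expected

    def test_removal_larger_than_fragment_rejected(self):
        with pytest.raises(ValueError):
            predict_fragment_length(
                100, SpliceEvent(SpliceEventKind.exon_skipping, 100))

    @given(wt=st.integers(50, 2000), size=st.integers(1, 49))
    def test_insertion_then_skipping_is_identity(self, wt, size):
        longer = predict_fragment_length(
            wt, SpliceEvent(SpliceEventKind.pseudoexon_insertion, size))
        assert predict_fragment_length(
            longer, SpliceEvent(SpliceEventKind.exon_skipping, size)) == wt

    def test_frame_derived_from_size(self):
        assert SpliceEvent(SpliceEventKind.pseudoexon_insertion, 75).frame == "in_frame"
        assert SpliceEvent(SpliceEventKind.pseudoexon_insertion, 104).frame == "frameshift"


class TestNormalization:
    def test_published_grm6_normalization(self):
        assert normalized_wt_percent(42.0, 46.0) == 91.0

    def test_densitometry_rounding_of_inputs(self):
        # the wild-type construct's 45.6% is rounded to 46 before the ratio
        assert normalized_wt_percent(42.0, 45.6) == 91.0

    def test_plain_ratio(self):
        assert normalized_wt_percent(50.0, 100.0) == 50.0

    def test_no_remaining_wild_type(self):
        assert normalized_wt_percent(0.0, 76.0) == 0.0

    def test_capped_at_100(self):
        assert normalized_wt_percent(80.0, 60.0) == 100.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            normalized_wt_percent(10.0, 0.0)


class TestSeverity:
    @pytest.mark.parametrize("pct,expected", [
        (21.1, "severe"), (91.0, "mild"), (50.0, "moderate"),
        (0.0, "severe"), (24.9, "severe"), (25.0, "moderate"),
        (74.9, "moderate"), (75.0, "mild"), (100.0, "mild"),
    ])
    def test_boundaries(self, pct, expected):
        assert classify_allele_severity(pct) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_allele_severity(101.0)

    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    def test_monotone_severity_never_worsens_with_more_wild_type(self, a, b):
        order = {"severe": 0, "moderate": 1, "mild": 2}
        lo, hi = sorted((a, b))
        assert order[classify_allele_severity(lo)] <= \
            order[classify_allele_severity(hi)]


class TestInterpretAssay:
    def test_eys_minigene_mutant_loses_all_wild_type(self, cases_by_id):
        (assay,) = cases_by_id["Pt-9"].assays
        it = interpret_assay(assay)
        assert it.defect_present and it.severity == "severe"
        assert it.pct_wt_raw == pytest.approx(0.0)

    def test_no_defect_when_profiles_match(self, cases_by_id):
        (assay,) = cases_by_id["Pt-27"].assays
        it = interpret_assay(assay)
        assert not it.defect_present and it.severity == "no_defect"

    def test_grm6_novel_fragment_and_mild_call(self, cases_by_id):
        (assay,) = cases_by_id["Pt-14"].assays
        it = interpret_assay(assay)
        assert it.defect_present
        assert it.pct_wt_normalized == 91.0
        assert it.severity == "mild"

    def test_predicted_lengths_match_recorded_lanes(self, bundle):
        for case in bundle.cases:
            for assay in case.assays:
                if assay.event is None:
                    continue
                predicted = predict_fragment_length(
                    assay.wt_fragment_length, assay.event)
                mut_lengths = {l.fragment_length_nt
                               for l in assay.mut_construct_lanes if not l.ignore}
                assert predicted in mut_lengths
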