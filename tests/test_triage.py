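"""Frequency gating, missense rule, effect ordering, ROH scan and the
two-branch prioritization protocol."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from irdsolve.model import Consequence, InSilicoScores, PopulationFrequencies
from irdsolve.triage import (
    TriageConfig,
    effect_rank,
    frequency_pass,
    missense_causative,
    prioritize_case,
    roh_scan,
)

CFG = TriageConfig()


class TestFrequencyGate:
    @pytest.mark.parametrize("freqs,expected", [
        (PopulationFrequencies(gnomad=0.003052), True),   # rare CDHR1-like allele
        (PopulationFrequencies(gnomad=0.02), False),      # above the 1% gate
        (PopulationFrequencies(), True),                  # unreported everywhere
        (PopulationFrequencies(gnomad=0.01), True),       # boundary inclusive
        (PopulationFrequencies(gnomad=0.005, dbsnp=0.06), False),
        (PopulationFrequencies(inhouse_asian=0.02), True),
    ])
    def test_examples(self, freqs, expected):
        assert frequency_pass(freqs, Consequence.missense, CFG) is expected

    @given(
        gnomad=st.one_of(st.none(), st.floats(0, 1)),
        dbsnp=st.one_of(st.none(), st.floats(0, 1)),
        shrink=st.floats(0.0, 1.0),
    )
    def test_lowering_any_frequency_never_fails_a_passing_gate(
        self, gnomad, dbsnp, shrink
    ):
        freqs = PopulationFrequencies(gnomad=gnomad, dbsnp=dbsnp)
        lowered = PopulationFrequencies(
            gnomad=None if gnomad is None else gnomad * shrink,
            dbsnp=None if dbsnp is None else dbsnp * shrink,
        )
        if frequency_pass(freqs, Consequence.missense, CFG):
            assert frequency_pass(lowered, Consequence.missense, CFG)


class TestMissenseRule:
    def test_all_scores_absent_is_an_error(self):
        with pytest.raises(ValueError):
            missense_causative(InSilicoScores(), CFG)

    # exhaustive small-domain check around the three inclusive thresholds
    @pytest.mark.parametrize("phylop", [2.6, 2.7, None])
    @pytest.mark.parametrize("cadd", [14.9, 15.0, None])
    @pytest.mark.parametrize("grantham", [79.0, 80.0, None])
    def test_two_of_three_rule_exhaustive_at_boundaries(self, phylop, cadd, grantham):
        if phylop is None and cadd is None and grantham is None:
            return
        scores = InSilicoScores(phylop=phylop, cadd_phred=cadd, grantham=grantham)
        n_pass = sum([
            phylop is not None and phylop >= 2.7,
            cadd is not None and cadd >= 15.0,
            grantham is not None and grantham >= 80.0,
        ])
        assert missense_causative(scores, CFG) is (n_pass >= 2)

    @given(
        phylop=st.floats(-14.1, 6.4),
        cadd=st.floats(1, 99),
        grantham=st.floats(0, 215),
        bump=st.floats(0, 5),
    )
    def test_monotone_nondecreasing_in_each_score(self, phylop, cadd, grantham, bump):
        base = InSilicoScores(phylop=phylop, cadd_phred=cadd, grantham=grantham)
        bumped = InSilicoScores(
            phylop=min(phylop + bump, 6.4),
            cadd_phred=min(cadd + bump, 99),
            grantham=min(grantham + bump, 215),
        )
        if missense_causative(base, CFG):
            assert missense_causative(bumped, CFG)


class TestEffectRank:
    def test_printed_order(self):
        order = ["nonsense", "frameshift", "canonical_splice", "ncss",
                 "inframe_indel", "missense", "synonymous"]
        assert [effect_rank(Consequence(c)) for c in order] == list(range(1, 8))
        shuffled = order[::-1]
        assert sorted(shuffled, key=lambda c: effect_rank(Consequence(c))) == order

    def test_noncoding_classes_rank_after_synonymous(self):
        for c in (Consequence.deep_intronic, Consequence.utr, Consequence.other):
            assert effect_rank(c) > effect_rank(Consequence.synonymous)

    def test_unknown_consequence_rejected(self):
        with pytest.raises(ValueError):
            effect_rank("stopgain")


def _brute_force_roh(track, cfg):
    """Independent oracle: enumerate all qualifying subintervals, keep the
    inclusion-maximal ones."""
    n = len(track)
    het = [1 if h else 0 for _, h in track]
    prefix = [0]
    for h in het:
        prefix.append(prefix[-1] + h)
    w = cfg.roh_min_snps
    qualifying = []
    for i in range(n):
        for j in range(i, n):
            if j - i + 1 < cfg.roh_min_snps:
                continue
            if track[j][0] - track[i][0] + 1 < cfg.roh_min_kb * 1000:
                continue
            if all(prefix[k + w] - prefix[k] <= cfg.roh_window_het
                   for k in range(i, j - w + 2)):
                qualifying.append((i, j))
    maximal = [
        (i, j) for (i, j) in qualifying
        if not any(a <= i and j <= b and (a, b) != (i, j) for a, b in qualifying)
    ]
    return [(track[i][0], track[j][0]) for i, j in maximal]


SMALL_ROH_CFG = TriageConfig(roh_window_het=1, roh_min_snps=5, roh_min_kb=0.05)


class TestRohScan:
    def test_pure_hom_track_is_one_run(self):
        track = [(1 + k * 7_000, False) for k in range(60)]  # spans ~413 kb
        (run,) = roh_scan(track, CFG)
        assert (run.start_pos, run.end_pos, run.n_sites) == (1, 413_001, 60)

    def test_span_below_300kb_yields_nothing(self):
        track = [(1 + k * 3_000, False) for k in range(60)]  # ~177 kb
        assert roh_scan(track, CFG) == []

    def test_unsorted_track_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            roh_scan([(100, False), (50, False)], CFG)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_tracks(self, seed):
        rnd = random.Random(seed)
        n = rnd.randint(0, 60)
        pos = 0
        track = []
        for _ in range(n):
            pos += rnd.randint(1, 40)
            track.append((pos, rnd.random() < 0.25))
        got = [(r.start_pos, r.end_pos) for r in roh_scan(track, SMALL_ROH_CFG)]
        assert got == _brute_force_roh(track, SMALL_ROH_CFG)


class TestPrioritizeCase:
    def test_monoallelic_branch_interrogates_prior_gene_intronically(
        self, cases_by_id, bundle
    ):
        result = prioritize_case(cases_by_id["Pt-14"], bundle.panel, CFG,
                                 bundle.repeat_ranges)
        assert result.branch_taken == "monoallelic"
        assert "GRM6" in result.genes_interrogated_intronically
        labels = [item.label for item, _ in result.candidate_alleles]
        assert "GRM6:c.1355-587dup" in labels

    def test_common_nonsense_yields_no_candidates(self, bundle):
        from irdsolve.model import AnnotatedSmallVariant, CaseRecord, Zygosity

        case = CaseRecord("X-1", "Retinitis pigmentosa", "WES")
        case.small_variants.append(AnnotatedSmallVariant(
            case_id="X-1", gene="USH2A", hgvs_c="c.1A>T", chrom="chr1",
            pos=3_000_100, ref="A", alt="T", consequence=Consequence.nonsense,
            zygosity=Zygosity.het,
            freqs=PopulationFrequencies(gnomad=0.02),
        ))
        result = prioritize_case(case, bundle.panel, CFG)
        assert result.candidate_alleles == []

    def test_frameshift_beats_single_threshold_missense(self, bundle):
        from irdsolve.model import AnnotatedSmallVariant, CaseRecord, Zygosity

        case = CaseRecord("X-2", "Retinitis pigmentosa", "WES")
        mk = lambda hgvs, cons, scores: AnnotatedSmallVariant(
            case_id="X-2", gene="EYS", hgvs_c=hgvs, chrom="chr6",
            pos=1_000_100 + len(hgvs), ref="A", alt="T",
            consequence=cons, zygosity=Zygosity.hom, scores=scores,
            freqs=PopulationFrequencies(gnomad=1e-4),
        )
        case.small_variants = [
            mk("c.10del", Consequence.frameshift, InSilicoScores()),
            mk("c.20A>T", Consequence.missense,
               InSilicoScores(phylop=3.0, cadd_phred=10.0, grantham=50.0)),
        ]
        result = prioritize_case(case, bundle.panel, CFG)
        coding = [item.label for item, tag in result.candidate_alleles
                  if tag == "coding"]
        assert coding == ["EYS:c.10del"]

    def test_order_invariant_under_input_permutation(self, cases_by_id, bundle):
        import copy

        case = copy.deepcopy(cases_by_id["Pt-24"])
        base = prioritize_case(case, bundle.panel, CFG, bundle.repeat_ranges)
        case.small_variants.reverse()
        case.assays.reverse()
        permuted = prioritize_case(case, bundle.panel, CFG, bundle.repeat_ranges)
        assert [(i.label, t) for i, t in base.candidate_alleles] == \
               [(i.label, t) for i, t in permuted.candidate_alleles]

    def test_repeat_expansion_screened_without_prior(self, cases_by_id, bundle):
        result = prioritize_case(cases_by_id["Pt-4"], bundle.panel, CFG,
                                 bundle.repeat_ranges)
        assert result.branch_taken == "no_prior_candidate"
        assert [(i.label, t) for i, t in result.candidate_alleles] == \
               [("STR:ATXN7[10/70]", "repeat_expansion")]

    def test_roh_flags_gene_inside_homozygous_run(self, cases_by_id, bundle):
        result = prioritize_case(cases_by_id["Pt-15"], bundle.panel, CFG,
                                 bundle.repeat_ranges)
        assert "HGSNAT" in result.roh_genes
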