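"""Case-resolution rules and cohort accounting."""

import copy

import pytest

from irdsolve.model import (
    AnnotatedSmallVariant,
    CaseRecord,
    Classification,
    Consequence,
    InSilicoScores,
    PopulationFrequencies,
    Zygosity,
)
from irdsolve.resolve import resolve_case, summarize_cohort


class TestWorkedCases:
    def test_hom_sv_solves_recessive_gene(self, bundle, cases_by_id):
        r = resolve_case(cases_by_id["Pt-22"], bundle.panel, bundle.repeat_ranges)
        assert r.status == "solved"
        assert r.causal_gene == "RPGRIP1"
        assert "biallelic_lof" in r.rationale_tags

    def test_het_whole_gene_sv_solves_dominant_gene(self, bundle, cases_by_id):
        r = resolve_case(cases_by_id["Pt-23"], bundle.panel, bundle.repeat_ranges)
        assert r.status == "solved"
        assert r.causal_gene == "PRPF31"
        assert "dominant_lof_sv" in r.rationale_tags

    def test_no_defect_partner_leaves_case_unsolved(self, bundle, cases_by_id):
        r = resolve_case(cases_by_id["Pt-27"], bundle.panel, bundle.repeat_ranges)
        assert r.status == "unsolved"
        assert r.causal_gene is None

    def test_repeat_expansion_solves_dominant_locus(self, bundle, cases_by_id):
        r = resolve_case(cases_by_id["Pt-4"], bundle.panel, bundle.repeat_ranges)
        assert r.status == "solved"
        assert r.causal_gene == "ATXN7"
        assert r.rationale_tags == {"repeat_expansion"}

    def test_unanimous_in_silico_vus_gives_likely_solved(self, bundle, cases_by_id):
        r = resolve_case(cases_by_id["Pt-12"], bundle.panel, bundle.repeat_ranges)
        assert r.status == "likely_solved"
        assert r.rationale_tags == {"vus_supported"}
        assert ("EYS:c.5044G>T", "vus_supported") in r.causal_alleles

    def test_hom_hypomorphic_allele_solves(self, bundle, cases_by_id):
        r = resolve_case(cases_by_id["Pt-15"], bundle.panel, bundle.repeat_ranges)
        assert r.status == "solved"
        assert "hom_hypomorphic" in r.rationale_tags

    def test_mild_assay_allele_needs_a_qualifying_partner(
        self, bundle, cases_by_id
    ):
        case = copy.deepcopy(cases_by_id["Pt-14"])
        # with the prior pathogenic missense the mild allele completes the
        # genotype; without it the mild allele alone must not solve
        assert resolve_case(case, bundle.panel,
                            bundle.repeat_ranges).status == "solved"
        case.small_variants = [v for v in case.small_variants
                               if v.hgvs_c != "c.1732C>T"]
        assert resolve_case(case, bundle.panel,
                            bundle.repeat_ranges).status == "unsolved"

    def test_gene_absent_from_panel_is_an_error(self, bundle):
        case = CaseRecord("X-9", "Retinitis pigmentosa", "WES")
        case.small_variants.append(AnnotatedSmallVariant(
            case_id="X-9", gene="NOTAGENE", hgvs_c="c.1A>G", chrom="chr1",
            pos=10, ref="A", alt="G", consequence=Consequence.missense,
            zygosity=Zygosity.het,
        ))
        with pytest.raises(ValueError, match="NOTAGENE"):
            resolve_case(case, bundle.panel, bundle.repeat_ranges)


class TestEvidenceMonotonicity:
    def test_adding_evidence_never_demotes(self, bundle, cases_by_id):
        # start from the solved USH2A case, add an unrelated benign variant
        # and a no-defect assay for an extra candidate: still solved
        case = copy.deepcopy(cases_by_id["Pt-24"])
        base = resolve_case(case, bundle.panel, bundle.repeat_ranges)
        assert base.status == "solved"
        case.small_variants.append(AnnotatedSmallVariant(
            case_id="Pt-24", gene="USH2A", hgvs_c="c.999+5000A>G", chrom="chr1",
            pos=3_010_000, ref="A", alt="G",
            consequence=Consequence.deep_intronic, zygosity=Zygosity.het,
            freqs=PopulationFrequencies(gnomad=1e-4),
        ))
        again = resolve_case(case, bundle.panel, bundle.repeat_ranges)
        assert again.status == "solved"
        assert again.causal_gene == base.causal_gene

    def test_biallelic_requires_two_alleles(self, bundle):
        case = CaseRecord("X-1", "Retinitis pigmentosa", "WES")
        allele = AnnotatedSmallVariant(
            case_id="X-1", gene="EYS", hgvs_c="c.100C>T", chrom="chr6",
            pos=1_000_200, ref="C", alt="T", consequence=Consequence.nonsense,
            zygosity=Zygosity.het, classification=Classification.pathogenic,
        )
        case.small_variants.append(allele)
        assert resolve_case(case, bundle.panel,
                            bundle.repeat_ranges).status == "unsolved"
        # the same allele homozygous counts twice
        case.small_variants = [
            AnnotatedSmallVariant(**{**allele.__dict__, "zygosity": Zygosity.hom})
        ]
        assert resolve_case(case, bundle.panel,
                            bundle.repeat_ranges).status == "solved"


class TestCohortSummary:
    def test_fixture_totals(self, fixture_result, bundle):
        s = fixture_result.summary
        assert s.n_cases == 100
        assert s.n_solved == 24
        assert s.solved_pct == 24.0
        assert sum(s.per_phenotype.values()) == s.n_cases

    def test_summary_invariant_to_case_order(self, bundle, fixture_result):
        rev_cases = list(reversed(bundle.cases))
        rev_res = list(reversed(fixture_result.resolutions))
        s1 = summarize_cohort(fixture_result.resolutions, bundle.cases)
        s2 = summarize_cohort(rev_res, rev_cases)
        assert s1 == s2

    def test_duplicate_case_id_rejected(self, bundle, fixture_result):
        cases = bundle.cases + [bundle.cases[0]]
        res = fixture_result.resolutions + [fixture_result.resolutions[0]]
        with pytest.raises(ValueError, match="duplicate"):
            summarize_cohort(res, cases)

    def test_all_unsolved_cohort_has_zero_pct(self):
        cases = [CaseRecord(f"U-{i}", "Retinitis pigmentosa", "WES")
                 for i in range(4)]
        from irdsolve.resolve import ResolutionResult

        res = [ResolutionResult(case_id=c.case_id) for c in cases]
        assert summarize_cohort(res, cases).solved_pct == 0.0
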