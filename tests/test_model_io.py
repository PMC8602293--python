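"""Domain-type invariants and format round-trips."""

import pytest

from irdsolve import io as irdio
from irdsolve.model import (
    AnnotatedSmallVariant,
    Consequence,
    GenePanelEntry,
    InSilicoScores,
    PopulationFrequencies,
    RepeatLocusRange,
    StructuralVariantCall,
    Zygosity,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=case_id,Number=1,Type=String,Description="case">
##INFO=<ID=gene,Number=1,Type=String,Description="gene">
##INFO=<ID=hgvs_c,Number=1,Type=String,Description="hgvs">
##INFO=<ID=consequence,Number=1,Type=String,Description="effect">
##INFO=<ID=zygosity,Number=1,Type=String,Description="zygosity">
##INFO=<ID=gnomad_af,Number=1,Type=Float,Description="gnomAD AF">
##contig=<ID=chr10>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr10\t1000037\t.\tG\tA\t.\t.\tcase_id=Pt-7;gene=CDHR1;hgvs_c=c.783G>A;consequence=ncss;zygosity=hom;gnomad_af=0.003052
"""


class TestVariantReaders:
    def test_vcf_dialect_maps_info_keys(self, tmp_path):
        path = tmp_path / "one.vcf"
        path.write_text(VCF_TEXT)
        dialect = irdio.VariantDialect(keys={"gnomad": "gnomad_af"})
        (v,) = irdio.read_variants(path, dialect)
        assert v.gene == "CDHR1"
        assert v.freqs.gnomad == pytest.approx(0.003052)
        assert v.consequence is Consequence.ncss
        assert v.zygosity is Zygosity.hom
        # missing sources stay absent, never zero
        assert v.freqs.dbsnp is None and v.scores.phylop is None

    def test_vcf_with_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text("\n".join(VCF_TEXT.splitlines()[:-1]) + "\n")
        assert irdio.read_variants(path) == []

    def test_unknown_consequence_names_accepted_vocabulary(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(VCF_TEXT.replace("consequence=ncss", "consequence=stopgain"))
        with pytest.raises(ValueError, match="nonsense.*deep_intronic"):
            irdio.read_variants(path)

    def test_tsv_round_trip_is_lossless(self, tmp_path, bundle):
        variants = [v for c in bundle.cases for v in c.small_variants]
        path = tmp_path / "variants.tsv"
        irdio.write_variants_tsv(variants, path)
        assert irdio.read_variants(path) == variants

    def test_tsv_missing_field_error_names_line_and_field(self, tmp_path):
        path = tmp_path / "broken.tsv"
        path.write_text(
            "case_id\tgene\thgvs_c\tchrom\tpos\tref\talt\tconsequence\tzygosity\n"
            "Pt-1\tABCA4\tc.1A>G\tchr1\t100\tA\t\tmissense\thet\n"
        )
        with pytest.raises(ValueError, match="line 2.*alt"):
            irdio.read_variants(path)


class TestPanelIO:
    def test_bed_coordinates_convert_to_one_based_inclusive(self, tmp_path):
        path = tmp_path / "panel.bed"
        path.write_text("chr19\t54106453\t54133135\tPRPF31\n")
        (entry,) = irdio.read_panel(path)
        assert (entry.start, entry.end) == (54_106_454, 54_133_135)

    def test_panel_round_trip_bijective(self, tmp_path, bundle):
        path = tmp_path / "panel.bed"
        irdio.write_panel(bundle.panel, path)
        assert irdio.read_panel(path) == bundle.panel

    def test_zero_length_interval_rejected(self, tmp_path):
        path = tmp_path / "panel.bed"
        path.write_text("chr1\t100\t100\tGENE\n")
        with pytest.raises(ValueError, match="zero-length"):
            irdio.read_panel(path)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "panel.bed"
        path.write_text("chr1\t100\t200\tGENE\nchr1\t150\t300\tGENE\n")
        with pytest.raises(ValueError, match="duplicate gene"):
            irdio.read_panel(path)

    def test_two_panels_concatenate_with_panel_field_preserved(self, tmp_path):
        path = tmp_path / "panel.bed"
        path.write_text(
            "chr1\t100\t200\tGENE1\tird\tAR\n"
            "chr2\t100\t200\tGENE2\tciliopathy\tAR\n"
        )
        entries = irdio.read_panel(path)
        assert [e.panel.value for e in entries] == ["ird", "ciliopathy"]


class TestCohortBundleIO:
    def test_cohort_round_trip(self, tmp_path, bundle):
        irdio.write_cohort(tmp_path / "cohort", bundle.cases, bundle.panel,
                           bundle.repeat_ranges)
        cases, panel, ranges = irdio.load_cohort(tmp_path / "cohort")
        assert panel == bundle.panel
        assert ranges == bundle.repeat_ranges
        assert cases == bundle.cases

    def test_case_report_names_causal_gene(self, tmp_path, bundle,
                                           cases_by_id, resolutions_by_id):
        import json

        path = tmp_path / "Pt-23.json"
        irdio.write_case_report(cases_by_id["Pt-23"], resolutions_by_id["Pt-23"], path)
        doc = json.loads(path.read_text())
        assert doc["status"] == "solved"
        assert doc["causal_gene"] == "PRPF31"
        assert any("54106454-54133135" in a[0] for a in doc["causal_alleles"])

    def test_unsolved_report_has_empty_causal_fields(self, tmp_path, bundle,
                                                     cases_by_id, resolutions_by_id):
        import json

        path = tmp_path / "Pt-27.json"
        irdio.write_case_report(cases_by_id["Pt-27"], resolutions_by_id["Pt-27"], path)
        doc = json.loads(path.read_text())
        assert doc["status"] == "unsolved"
        assert doc["causal_gene"] is None and doc["causal_alleles"] == []
        # rejected evidence is retained in the chain
        assert any(not e["qualifies"] for e in doc["evidence"])


class TestTypeInvariants:
    def test_prior_allele_requires_classification(self):
        with pytest.raises(ValueError, match="prior_allele"):
            AnnotatedSmallVariant(
                case_id="x", gene="G", hgvs_c="c.1A>G", chrom="chr1", pos=1,
                ref="A", alt="G", consequence=Consequence.missense,
                zygosity=Zygosity.het, prior_allele=True,
            )

    @pytest.mark.parametrize("field,value", [
        ("gnomad", -0.1), ("gnomad", 1.5), ("dbsnp", 2.0),
    ])
    def test_frequencies_must_be_fractions(self, field, value):
        with pytest.raises(ValueError):
            PopulationFrequencies(**{field: value})

    def test_scores_outside_documented_ranges_rejected(self):
        with pytest.raises(ValueError):
            InSilicoScores(phylop=7.0)
        with pytest.raises(ValueError):
            InSilicoScores(grantham=230.0)

    def test_sv_flanks_restricted_to_dna_alphabet(self):
        with pytest.raises(ValueError, match="non-DNA"):
            StructuralVariantCall(
                case_id="x", chrom="chr1", start=1, end=10, svtype="del",
                zygosity=Zygosity.het, left_flank_seq="ACGU",
            )

    def test_repeat_range_normal_below_pathogenic(self):
        with pytest.raises(ValueError):
            RepeatLocusRange("L", 3, 40, 37, 460)

    def test_exons_must_lie_within_gene_span(self):
        with pytest.raises(ValueError):
            GenePanelEntry(gene="G", chrom="chr1", start=100, end=200,
                           exons=((90, 150),))
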