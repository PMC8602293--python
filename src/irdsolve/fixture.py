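"""Deterministic reference cohort: 100 cases built from published evidence.

The bundle transcribes, as raw evidence only (no solved-status labels), the
genotypes of the 24 genetically solved cases, the splice-candidate variants
with their SpliceAI/Alamut triggers, the splice-assay band tables (printed
quantification percentages used as lane intensities), both structural
variants with their breakpoints, the ATXN7 repeat expansion, and the
hypomorphic-allele annotations. The remaining 69 cases carry non-resolving
background evidence, each constructed to fail exactly one gate (frequency,
missense score count, SpliceAI delta, missing second allele, intronic-only
SV, or normal repeat count), so every rejection path of the protocol is
exercised. Phenotype counts match the published cohort table.

Gene coordinates are a self-consistent miniature annotation invented for
this bundle — except the PRPF31-cluster deletion breakpoints, which are the
published ones. Junction flank sequences are synthetic, constructed to carry
the reported 12-bp microhomology. The bundle is byte-identical across
builds (no randomness is involved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    AnnotatedSmallVariant,
    CaseRecord,
    Classification,
    Consequence,
    GenePanelEntry,
    Inheritance,
    InSilicoScores,
    Lane,
    PanelName,
    PopulationFrequencies,
    RepeatGenotype,
    RepeatLocusRange,
    SpliceAIDeltas,
    AlgorithmScorePair,
    SpliceAlgorithm,
    SiteKind,
    SpliceAssayResult,
    SpliceEvent,
    SpliceEventKind,
    SpliceScores,
    StructuralVariantCall,
    Zygosity,
)

__all__ = ["FixtureBundle", "build_reference_fixture"]


@dataclass
class FixtureBundle:
    cases: list[CaseRecord]
    panel: list[GenePanelEntry]
    repeat_ranges: list[RepeatLocusRange]


# --------------------------------------------------------------------------
# Miniature panel annotation

_GENERIC_EXONS = 8
_EXON_LEN = 150
_INTRON_LEN = 4_000


def _generic_gene(gene, chrom, start, inheritance=Inheritance.AR,
                  panel=PanelName.ird, n_exons=_GENERIC_EXONS) -> GenePanelEntry:
    exons = tuple(
        (start + k * (_EXON_LEN + _INTRON_LEN),
         start + k * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN - 1)
        for k in range(n_exons)
    )
    return GenePanelEntry(
        gene=gene, chrom=chrom, start=start, end=exons[-1][1],
        exons=exons, promoter=(start - 1_000, start - 1),
        panel=panel, inheritance=inheritance,
    )


def _build_panel() -> list[GenePanelEntry]:
    g = _generic_gene
    panel = [
        g("ABCA4", "chr1", 1_000_000),
        g("USH2A", "chr1", 3_000_000),
        g("RPE65", "chr1", 5_000_000),
        g("CRB1", "chr1", 7_000_000),
        g("FAM161A", "chr2", 1_000_000),
        g("PCARE", "chr2", 3_000_000),
        g("CERKL", "chr2", 5_000_000),
        g("MERTK", "chr2", 7_000_000),
        g("NPHP1", "chr2", 9_000_000, panel=PanelName.ciliopathy),
        g("ATXN7", "chr3", 1_000_000, inheritance=Inheritance.AD),
        g("IQCB1", "chr3", 3_000_000, panel=PanelName.ciliopathy),
        g("CYP4V2", "chr4", 1_000_000),
        g("PDE6B", "chr4", 3_000_000),
        g("GRM6", "chr5", 1_000_000),
        g("PDE6A", "chr5", 3_000_000),
        g("EYS", "chr6", 1_000_000),
        g("HGSNAT", "chr8", 1_000_000),
        g("RP1", "chr8", 3_000_000),
        g("CNGB3", "chr8", 5_000_000),
        g("CEP78", "chr9", 1_000_000),
        g("CDHR1", "chr10", 1_000_000),
        g("USH1C", "chr11", 1_000_000),
        g("CEP290", "chr12", 1_000_000),
        g("RLBP1", "chr15", 1_000_000),
        g("RGS9BP", "chr19", 1_000_000),
        g("C21ORF2", "chr21", 1_000_000),
    ]
    # RPGRIP1: custom exon layout around the published 3.5-kb exon-20 deletion
    panel.append(GenePanelEntry(
        gene="RPGRIP1", chrom="chr14", start=4_990_000, end=5_010_000,
        exons=(
            (4_995_000, 4_995_149),
            (4_999_851, 5_000_000),        # exon 19
            (5_004_194, 5_004_294),        # exon 20: 101 coding nt
            (5_006_000, 5_006_149),
        ),
        promoter=(4_989_000, 4_989_999),
    ))
    # PRPF31 cluster on chr19q13: the published deletion removes PRPF31 and
    # TFPT entirely and the NDUFA3 promoter
    panel.append(_generic_gene("PRPF31", "chr19", 54_110_000,
                               inheritance=Inheritance.AD_incomplete_penetrance,
                               n_exons=4))
    panel.append(GenePanelEntry(
        gene="TFPT", chrom="chr19", start=54_128_000, end=54_131_000,
        exons=((54_128_000, 54_128_149), (54_130_851, 54_131_000)),
        promoter=(54_127_000, 54_127_999),
    ))
    panel.append(GenePanelEntry(
        gene="NDUFA3", chrom="chr19", start=54_134_000, end=54_140_000,
        exons=((54_134_000, 54_134_149), (54_139_851, 54_140_000)),
        promoter=(54_133_000, 54_133_999),
    ))
    return panel


_REPEAT_RANGES = [
    # ATXN7 CAG repeat: wild-type 3-19 units, pathogenic 37-460
    RepeatLocusRange("ATXN7", 3, 19, 37, 460),
]


# --------------------------------------------------------------------------
# Evidence constructors

_PASSING = InSilicoScores(phylop=4.2, cadd_phred=26.0, grantham=110.0)
_SOFT = InSilicoScores(phylop=1.2, cadd_phred=13.5, grantham=58.0)  # p.Ala615Thr
_ONE_OF_THREE = InSilicoScores(phylop=3.1, cadd_phred=9.0, grantham=30.0)

_P = Classification.pathogenic
_LP = Classification.likely_pathogenic
_VUS = Classification.vus


class _Builder:
    def __init__(self, panel):
        self.by_gene = {e.gene: e for e in panel}
        self._offsets: dict[str, int] = {}

    def pos(self, gene: str) -> int:
        off = self._offsets.get(gene, 0) + 37
        self._offsets[gene] = off
        return self.by_gene[gene].start + off

    def v(self, case_id, gene, hgvs, consequence, zygosity, *,
          ref="C", alt="T", freqs=None, scores=None, splice=None,
          prior=False, classification=None, hypomorphic=False,
          splice_event=None) -> AnnotatedSmallVariant:
        entry = self.by_gene[gene]
        return AnnotatedSmallVariant(
            case_id=case_id, gene=gene, hgvs_c=hgvs, chrom=entry.chrom,
            pos=self.pos(gene), ref=ref, alt=alt,
            consequence=Consequence(consequence), zygosity=Zygosity(zygosity),
            freqs=freqs or PopulationFrequencies(gnomad=2e-4),
            scores=scores or InSilicoScores(),
            splice=splice, prior_allele=prior,
            classification=classification, hypomorphic=hypomorphic,
            splice_event=splice_event,
        )


def _sai(**kw) -> SpliceScores:
    return SpliceScores(spliceai=SpliceAIDeltas(**kw))


def _alamut(*pairs) -> SpliceScores:
    out = []
    for algo, site, wt, mut, scale in pairs:
        out.append(AlgorithmScorePair(
            algorithm=SpliceAlgorithm(algo), site_kind=SiteKind(site),
            wt_score=wt, mut_score=mut, scale_max=scale))
    return SpliceScores(spliceai=None, alamut=tuple(out))


def _assay(case_id, gene, hgvs, wt_lanes, mut_lanes, wt_len,
           event: Optional[SpliceEvent] = None) -> SpliceAssayResult:
    mk = lambda lanes: tuple(
        Lane(fragment_length_nt=l, intensity=i, ignore=bool(ig))
        for l, i, ig in lanes
    )
    return SpliceAssayResult(
        case_id=case_id, gene=gene, hgvs_c=hgvs,
        wt_construct_lanes=mk(wt_lanes), mut_construct_lanes=mk(mut_lanes),
        wt_fragment_length=wt_len, event=event,
    )


def _no_defect_assay(case_id, gene, hgvs, wt_len) -> SpliceAssayResult:
    return _assay(case_id, gene, hgvs,
                  [(wt_len, 100.0, 0)], [(wt_len, 100.0, 0)], wt_len)


_EVENT = SpliceEventKind


# phenotype labels (cohort-table rows, ASCII-normalized)
RP = "Retinitis pigmentosa"
CD = "Cone dystrophy"
RCD = "Rod-cone dystrophy"
CRD = "Cone-rod dystrophy"
ALSTROM = "Alstrom syndrome"
BBS = "Bardet-Biedl syndrome"
LCA = "Leber congenital amaurosis"
MD = "Macular dystrophy"
OGUCHI = "Oguchi disease"
CACD = "Central areolar choroidal dystrophy"
FAP = "Fundus albipunctatus"
USH3 = "Usher syndrome type III"
SLS = "Senior-Loken syndrome"
NYSTAGMUS = "Nystagmus"
STGD1 = "Stargardt disease"
CPRD = "Clumped pigmentary retinal dystrophy"
CRD_NEURO = "Cone-rod dystrophy with progressive neurodegeneration"
RP_HYPOGONADISM = "Retinitis pigmentosa with hypogonadism"
BIETTI = "Bietti crystalline corneoretinal dystrophy"
CSNB = "Congenital stationary night blindness"
ACHM = "Achromatopsia"

# WGS-column counts of the cohort table
PHENOTYPE_WGS_COUNTS = {
    RP: 53, CD: 3, RCD: 3, CRD: 9, ALSTROM: 1, BBS: 1, LCA: 2, MD: 9,
    OGUCHI: 1, CACD: 1, FAP: 1, USH3: 1, SLS: 1, NYSTAGMUS: 1, STGD1: 7,
    CPRD: 1, CRD_NEURO: 1, RP_HYPOGONADISM: 1, BIETTI: 1, CSNB: 1, ACHM: 1,
}


def _solved_cases(b: _Builder) -> list[CaseRecord]:
    C = CaseRecord
    cases = []

    # --- STGD1 trio: ABCA4 prior missense + known deep-intronic allele
    c = C("Pt-1", STGD1, "TCS")
    c.small_variants += [
        b.v("Pt-1", "ABCA4", "c.6079C>T", "missense", "het", prior=True,
            classification=_P,
            scores=InSilicoScores(phylop=4.1, cadd_phred=27.0, grantham=22.0)),
        b.v("Pt-1", "ABCA4", "c.5196+1137G>A", "deep_intronic", "het",
            ref="G", alt="A", classification=_P,
            splice=_sai(donor_gain=0.20), splice_event="pseudoexon_insertion"),
    ]
    cases.append(c)

    c = C("Pt-2", STGD1, "TCS")
    c.small_variants += [
        b.v("Pt-2", "ABCA4", "c.6743T>C", "missense", "het", ref="T", alt="C",
            prior=True, classification=_P,
            scores=InSilicoScores(phylop=4.4, cadd_phred=28.0, grantham=155.0)),
        b.v("Pt-2", "ABCA4", "c.4539+2028C>T", "deep_intronic", "het",
            classification=_P, splice=_sai(donor_gain=0.18),
            splice_event="pseudoexon_insertion"),
    ]
    cases.append(c)

    c = C("Pt-3", STGD1, "TCS")
    c.small_variants += [
        # p.(Asn1868Ile): hypomorphic, above the 1% gate yet qualifying
        b.v("Pt-3", "ABCA4", "c.5603A>T", "missense", "het", ref="A", alt="T",
            prior=True, classification=_VUS, hypomorphic=True,
            freqs=PopulationFrequencies(gnomad=0.04),
            scores=InSilicoScores(phylop=2.1, cadd_phred=16.0, grantham=149.0)),
        b.v("Pt-3", "ABCA4", "c.286A>C", "missense", "het", ref="A", alt="C",
            classification=_LP,
            scores=InSilicoScores(phylop=3.2, cadd_phred=24.0, grantham=68.0)),
    ]
    cases.append(c)

    # --- ATXN7 CAG repeat expansion, dominant
    c = C("Pt-4", CRD_NEURO, "WES")
    c.repeats.append(RepeatGenotype("Pt-4", "ATXN7", (10, 70)))
    cases.append(c)

    # --- C21ORF2 biallelic missense
    c = C("Pt-5", RP, "TCS")
    c.small_variants += [
        b.v("Pt-5", "C21ORF2", "c.218G>C", "missense", "het", ref="G", alt="C",
            classification=_P,
            scores=InSilicoScores(phylop=4.0, cadd_phred=24.0, grantham=103.0)),
        b.v("Pt-5", "C21ORF2", "c.76T>C", "missense", "het", ref="T", alt="C",
            classification=_P,
            scores=InSilicoScores(phylop=3.8, cadd_phred=25.0, grantham=101.0)),
    ]
    cases.append(c)

    c = C("Pt-6", RP, "TCS")
    c.small_variants.append(
        b.v("Pt-6", "C21ORF2", "c.218G>C", "missense", "hom", ref="G", alt="C",
            classification=_P,
            scores=InSilicoScores(phylop=4.0, cadd_phred=24.0, grantham=103.0)))
    cases.append(c)

    # --- CDHR1: homozygous last-exonic-nucleotide variant (NCSS class);
    # splice defect (in-frame exon 8 skipping) established previously
    c = C("Pt-7", RP, "TCS")
    c.small_variants.append(
        b.v("Pt-7", "CDHR1", "c.783G>A", "ncss", "hom", ref="G", alt="A",
            classification=_P,
            freqs=PopulationFrequencies(gnomad=0.003052),
            splice=_sai(donor_loss=0.30), splice_event="exon_skipping"))
    cases.append(c)

    c = C("Pt-8", ALSTROM, "TCS")
    c.small_variants.append(
        b.v("Pt-8", "CEP78", "c.1033G>T", "nonsense", "hom", ref="G", alt="T",
            classification=_P))
    cases.append(c)

    # --- EYS: prior complex allele + deep-intronic variant, assay severe
    c = C("Pt-9", RP, "WES")
    c.small_variants += [
        b.v("Pt-9", "EYS", "c.[3906C>A;9468T>A]", "nonsense", "het",
            prior=True, classification=_P),
        b.v("Pt-9", "EYS", "c.5644+70912A>G", "deep_intronic", "het",
            ref="A", alt="G", splice=_sai(acceptor_gain=0.30, donor_gain=0.22),
            splice_event="pseudoexon_insertion"),
    ]
    c.assays.append(_assay(
        "Pt-9", "EYS", "c.5644+70912A>G",
        # wild-type minigene: 274-nt wild-type fragment (76.0%) and a 378-nt
        # baseline pseudoexon fragment (24.0%); mutant: 378 nt only
        [(274, 76.0, 0), (378, 24.0, 0)],
        [(378, 100.0, 0)],
        274, SpliceEvent(_EVENT.pseudoexon_insertion, 104)))
    cases.append(c)

    c = C("Pt-10", RP, "TCS")
    c.small_variants += [
        b.v("Pt-10", "EYS", "c.403_423delinsCTTTT", "frameshift", "het",
            ref="CAGGTCAGGTCAGGTCAGGTC", alt="CTTTT", prior=True,
            classification=_P),
        b.v("Pt-10", "EYS", "c.539C>A", "nonsense", "het", ref="C", alt="A",
            classification=_P),
    ]
    cases.append(c)

    c = C("Pt-11", CRD, "WES")
    c.small_variants.append(
        b.v("Pt-11", "EYS", "c.9468T>A", "nonsense", "hom", ref="T", alt="A",
            classification=_P))
    cases.append(c)

    # --- EYS VUS with unanimous in silico support: likely solved
    c = C("Pt-12", RCD, "WES")
    c.small_variants += [
        b.v("Pt-12", "EYS", "c.1660T>A", "missense", "het", ref="T", alt="A",
            prior=True, classification=_P,
            scores=InSilicoScores(phylop=4.3, cadd_phred=25.0, grantham=112.0)),
        b.v("Pt-12", "EYS", "c.5044G>T", "missense", "het", ref="G", alt="T",
            classification=_VUS,
            scores=InSilicoScores(phylop=5.0, cadd_phred=29.0, grantham=160.0)),
    ]
    cases.append(c)

    c = C("Pt-13", RP, "TCS")
    c.small_variants.append(
        b.v("Pt-13", "FAM161A", "c.1753_1756del", "frameshift", "hom",
            ref="CAAAG", alt="C", classification=_P))
    cases.append(c)

    # --- GRM6: prior missense + deep-intronic dup; assay mild (91.0%)
    c = C("Pt-14", OGUCHI, "WES")
    c.small_variants += [
        b.v("Pt-14", "GRM6", "c.1732C>T", "missense", "het", prior=True,
            classification=_P,
            scores=InSilicoScores(phylop=4.6, cadd_phred=28.0, grantham=180.0)),
        b.v("Pt-14", "GRM6", "c.1355-587dup", "deep_intronic", "het",
            ref="A", alt="AA", splice=_sai(donor_gain=0.15),
            splice_event="pseudoexon_insertion"),
    ]
    c.assays.append(_assay(
        "Pt-14", "GRM6", "c.1355-587dup",
        # both constructs show a 97-nt partial exon-6 deletion product; the
        # 567-nt pseudoexon fragment is mutant-only; heteroduplex band ignored
        [(492, 45.6, 0), (359, 54.4, 0)],
        [(492, 42.0, 0), (359, 37.0, 0), (567, 21.0, 0), (620, 12.0, 1)],
        492, SpliceEvent(_EVENT.pseudoexon_insertion, 75)))
    cases.append(c)

    # --- HGSNAT cluster around the hypomorphic p.Ala615Thr allele
    def hgsnat_hypo(case_id, zyg, prior=False):
        return b.v(case_id, "HGSNAT", "c.1843G>A", "missense", zyg,
                   ref="G", alt="A", prior=prior, classification=_VUS,
                   hypomorphic=True,
                   freqs=PopulationFrequencies(gnomad=0.004), scores=_SOFT)

    c = C("Pt-15", RP, "WES")
    c.small_variants.append(hgsnat_hypo("Pt-15", "hom"))
    hg = b.by_gene["HGSNAT"]
    c.genotype_track = [(hg.start - 200_000 + k * 7_000, False) for k in range(60)]
    c.genotype_track_chrom = hg.chrom
    cases.append(c)

    c = C("Pt-16", RP, "WES")
    c.small_variants += [
        b.v("Pt-16", "HGSNAT", "c.1030C>T", "missense", "het",
            classification=_P,
            scores=InSilicoScores(phylop=4.2, cadd_phred=26.0, grantham=180.0)),
        hgsnat_hypo("Pt-16", "het"),
    ]
    cases.append(c)

    c = C("Pt-17", RP, "WES")
    c.small_variants += [
        hgsnat_hypo("Pt-17", "het", prior=True),
        b.v("Pt-17", "HGSNAT", "c.493+5G>A", "ncss", "het", ref="G", alt="A",
            splice=_sai(donor_loss=0.45), splice_event="exon_skipping"),
    ]
    c.assays.append(_assay(
        "Pt-17", "HGSNAT", "c.493+5G>A",
        # exon 4 skipping with no remaining wild-type mRNA
        [(500, 100.0, 0)], [(370, 100.0, 0)],
        500, SpliceEvent(_EVENT.exon_skipping, 130)))
    cases.append(c)

    c = C("Pt-18", RP, "WES")
    c.small_variants.append(hgsnat_hypo("Pt-18", "hom"))
    cases.append(c)

    c = C("Pt-19", RP, "TCS")
    c.small_variants += [
        b.v("Pt-19", "HGSNAT", "c.1622C>T", "missense", "het",
            classification=_P,
            scores=InSilicoScores(phylop=3.9, cadd_phred=24.0, grantham=145.0)),
        hgsnat_hypo("Pt-19", "het"),
    ]
    cases.append(c)

    c = C("Pt-20", RP, "TCS")
    c.small_variants += [
        b.v("Pt-20", "PCARE", "c.3604C>T", "nonsense", "het", prior=True,
            classification=_P),
        b.v("Pt-20", "PCARE", "c.3099_3100insCAGG", "frameshift", "het",
            ref="A", alt="ACAGG", classification=_P),
    ]
    cases.append(c)

    c = C("Pt-21", CRD, "WES")
    c.small_variants.append(
        b.v("Pt-21", "RGS9BP", "c.583T>G", "missense", "hom", ref="T", alt="G",
            classification=_P,
            scores=InSilicoScores(phylop=3.5, cadd_phred=22.0, grantham=99.0)))
    cases.append(c)

    # --- RPGRIP1: homozygous 3.5-kb exon-20 deletion, 12-bp junction
    # microhomology (flank sequences synthetic; length is the published one)
    c = C("Pt-22", LCA, "WES")
    for gene, hgvs, protein_scores in (
        ("CEP290", "c.1079G>A", InSilicoScores(phylop=3.0, cadd_phred=22.0,
                                               grantham=43.0)),
        ("PDE6A", "c.2053G>A", InSilicoScores(phylop=2.9, cadd_phred=21.0,
                                              grantham=21.0)),
        ("RPE65", "c.676G>A", InSilicoScores(phylop=3.1, cadd_phred=23.0,
                                             grantham=29.0)),
    ):
        c.small_variants.append(
            b.v("Pt-22", gene, hgvs, "missense", "het", ref="G", alt="A",
                prior=True, classification=_VUS, scores=protein_scores))
    c.svs.append(StructuralVariantCall(
        case_id="Pt-22", chrom="chr14", start=5_001_118, end=5_004_617,
        svtype="del", zygosity=Zygosity.hom,
        left_flank_seq="ATCGGATTCTAGGCCTGGAGCTGA",
        right_flank_seq="GCCTGGAGCTGATTACCGGTTAAC",
    ))
    cases.append(c)

    # --- PRPF31: heterozygous 26.68-kb whole-gene deletion, dominant with
    # incomplete penetrance (published breakpoints)
    c = C("Pt-23", RP, "TCS")
    c.svs.append(StructuralVariantCall(
        case_id="Pt-23", chrom="chr19", start=54_106_454, end=54_133_135,
        svtype="del", zygosity=Zygosity.het,
    ))
    cases.append(c)

    # --- USH2A: NCSS + deep-intronic allele, both assay-severe; the prior
    # PCARE frameshift never found a partner
    c = C("Pt-24", RP, "TCS")
    c.small_variants += [
        b.v("Pt-24", "PCARE", "c.2756del", "frameshift", "het", ref="CA",
            alt="C", prior=True, classification=_P),
        b.v("Pt-24", "USH2A", "c.4758+3A>G", "ncss", "het", ref="A", alt="G",
            splice=_sai(donor_loss=0.35, donor_gain=0.10),
            splice_event="exon_elongation"),
        b.v("Pt-24", "USH2A", "c.784+14389G>T", "deep_intronic", "het",
            ref="G", alt="T", splice=_sai(donor_gain=0.25),
            splice_event="pseudoexon_insertion"),
    ]
    c.assays += [
        _assay("Pt-24", "USH2A", "c.4758+3A>G",
               # 107-nt exon 22 elongation: 78.9% mutant vs 21.1% wild type
               [(225, 100.0, 0)], [(332, 78.9, 0), (225, 21.1, 0)],
               225, SpliceEvent(_EVENT.exon_elongation, 107)),
        _assay("Pt-24", "USH2A", "c.784+14389G>T",
               # 97-nt pseudoexon: 77.1% mutant fragment vs 22.9% wild type;
               # artifact product in the wild-type construct is ignored
               [(274, 100.0, 0), (305, 8.0, 1)],
               [(371, 77.1, 0), (274, 22.9, 0)],
               274, SpliceEvent(_EVENT.pseudoexon_insertion, 97)),
    ]
    cases.append(c)
    return cases


def _no_defect_cases(b: _Builder) -> list[CaseRecord]:
    """Monoallelic cases whose candidate showed no splice defect in vitro."""
    cases = []

    c = CaseRecord("Pt-27", STGD1, "TCS")
    c.small_variants += [
        b.v("Pt-27", "ABCA4", "c.5714+5G>A", "ncss", "het", ref="G", alt="A",
            prior=True, classification=_P),
        b.v("Pt-27", "ABCA4", "c.6148-89G>A", "deep_intronic", "het",
            ref="G", alt="A", splice=_sai(donor_gain=0.12),
            splice_event="cryptic_site_gain"),
    ]
    c.assays.append(_no_defect_assay("Pt-27", "ABCA4", "c.6148-89G>A", 410))
    cases.append(c)

    # the delins carried by three cases: no SpliceAI scores for indels,
    # selected on Alamut predictions alone (two algorithms gain a donor site)
    delins_scores = _alamut(
        ("SSFL", "donor", None, 78.2, 100.0),
        ("HSF", "donor", None, 81.0, 100.0),
    )
    for pid in ("Pt-28", "Pt-29", "Pt-30"):
        c = CaseRecord(pid, STGD1, "TCS")
        c.small_variants += [
            b.v(pid, "ABCA4", "c.3113C>T", "missense", "het", prior=True,
                classification=_P,
                scores=InSilicoScores(phylop=3.6, cadd_phred=23.0, grantham=64.0)),
            b.v(pid, "ABCA4", "c.5460+1315_5460+1317delinsTA", "deep_intronic",
                "het", ref="CAT", alt="TA", splice=delins_scores,
                splice_event="cryptic_site_gain"),
        ]
        c.assays.append(_no_defect_assay(
            pid, "ABCA4", "c.5460+1315_5460+1317delinsTA", 380))
        cases.append(c)

    c = CaseRecord("Pt-52", BIETTI, "TCS")
    c.small_variants += [
        b.v("Pt-52", "CYP4V2", "c.802-8_810delinsGC", "frameshift", "het",
            ref="TTTTTCAGATGGCCCAGAG", alt="GC", prior=True, classification=_P),
        b.v("Pt-52", "CYP4V2", "c.214+879_214+882delinsG", "deep_intronic",
            "het", ref="CTAG", alt="G",
            splice=_alamut(("SSFL", "donor", None, 74.5, 100.0),
                           ("MaxEntScan", "donor", 2.1, 8.9, 12.0)),
            splice_event="cryptic_site_gain"),
    ]
    c.assays.append(_no_defect_assay(
        "Pt-52", "CYP4V2", "c.214+879_214+882delinsG", 295))
    cases.append(c)

    c = CaseRecord("Pt-61", RP, "WES")
    c.small_variants += [
        b.v("Pt-61", "PDE6B", "c.892C>T", "nonsense", "het", prior=True,
            classification=_P),
        b.v("Pt-61", "PDE6B", "c.469-776C>G", "deep_intronic", "het",
            ref="C", alt="G", splice=_sai(acceptor_gain=0.08),
            splice_event="cryptic_site_gain"),
    ]
    c.assays.append(_no_defect_assay("Pt-61", "PDE6B", "c.469-776C>G", 350))
    cases.append(c)

    c = CaseRecord("Pt-65", FAP, "WES")
    c.small_variants += [
        b.v("Pt-65", "RLBP1", "c.700C>T", "missense", "het", prior=True,
            classification=_P,
            scores=InSilicoScores(phylop=4.0, cadd_phred=25.0, grantham=101.0)),
        b.v("Pt-65", "RLBP1", "c.525+425_525+433delinsATA", "deep_intronic",
            "het", ref="GTCAGTCAG", alt="ATA",
            splice=_alamut(("SSFL", "donor", None, 70.3, 100.0),
                           ("HSF", "donor", None, 79.8, 100.0)),
            splice_event="cryptic_site_gain"),
    ]
    c.assays.append(_no_defect_assay(
        "Pt-65", "RLBP1", "c.525+425_525+433delinsATA", 310))
    cases.append(c)
    return cases


_FILLER_GENE_POOL = [
    "CRB1", "CERKL", "MERTK", "USH1C", "CNGB3", "RP1", "NPHP1", "IQCB1",
    "USH2A", "EYS", "ABCA4", "CEP290", "PDE6A", "RPE65",
]


def _filler_cases(b: _Builder, case_ids: list[str],
                  phenotypes: list[str]) -> list[CaseRecord]:
    """Background cases, each failing exactly one prioritization gate."""
    cases = []
    for i, (cid, phen) in enumerate(zip(case_ids, phenotypes)):
        gene = _FILLER_GENE_POOL[i % len(_FILLER_GENE_POOL)]
        entry = b.by_gene[gene]
        method = "WES" if i % 2 == 0 else "TCS"
        c = CaseRecord(cid, phen, method)
        mode = i % 5
        if mode == 0:
            # too common: fails the 1% gnomAD gate
            c.small_variants.append(
                b.v(cid, gene, f"c.{1200 + i}G>A", "nonsense", "het",
                    ref="G", alt="A",
                    freqs=PopulationFrequencies(gnomad=0.02 + (i % 7) * 0.003)))
        elif mode == 1:
            # rare missense passing only one threshold
            c.small_variants.append(
                b.v(cid, gene, f"c.{900 + i}A>G", "missense", "het",
                    ref="A", alt="G", scores=_ONE_OF_THREE))
        elif mode == 2:
            # rare deep-intronic with sub-threshold deltas, plus an
            # intronic-only SV in a second gene
            c.small_variants.append(
                b.v(cid, gene, f"c.300+{4000 + i}C>T", "deep_intronic", "het",
                    splice=_sai(donor_gain=0.01)))
            other = b.by_gene[_FILLER_GENE_POOL[(i + 3) % len(_FILLER_GENE_POOL)]]
            c.svs.append(StructuralVariantCall(
                case_id=cid, chrom=other.chrom,
                start=other.exons[1][1] + 200, end=other.exons[2][0] - 200,
                svtype="del", zygosity=Zygosity.het))
        elif mode == 3:
            # monoallelic: one pathogenic allele, no partner found
            c.small_variants.append(
                b.v(cid, gene, f"c.{700 + i}C>T", "nonsense", "het",
                    prior=True, classification=_P))
        else:
            # normal-range repeat plus an unclassified rare synonymous variant
            c.repeats.append(RepeatGenotype(cid, "ATXN7", (10, 15)))
            c.small_variants.append(
                b.v(cid, gene, f"c.{600 + i}G>A", "synonymous", "het",
                    ref="G", alt="A"))
        cases.append(c)
    return cases


def build_reference_fixture() -> FixtureBundle:
    """Build the deterministic 100-case reference cohort (evidence only)."""
    panel = _build_panel()
    b = _Builder(panel)
    solved = _solved_cases(b)
    no_defect = _no_defect_cases(b)
    used_pheno: dict[str, int] = {}
    for c in solved + no_defect:
        used_pheno[c.phenotype] = used_pheno.get(c.phenotype, 0) + 1

    filler_slots: list[str] = []
    for phen, total in PHENOTYPE_WGS_COUNTS.items():
        remaining = total - used_pheno.get(phen, 0)
        if remaining < 0:
            raise AssertionError(f"phenotype {phen} over-allocated")
        filler_slots.extend([phen] * remaining)

    used_ids = {c.case_id for c in solved + no_defect}
    filler_ids = [f"Pt-{i}" for i in range(25, 101) if f"Pt-{i}" not in used_ids]
    if len(filler_ids) != len(filler_slots):
        raise AssertionError("filler count does not reconcile with phenotype table")
    filler = _filler_cases(b, filler_ids, filler_slots)

    cases = sorted(solved + no_defect + filler,
                   key=lambda c: int(c.case_id.split("-")[1]))
    return FixtureBundle(cases=cases, panel=panel,
                         repeat_ranges=list(_REPEAT_RANGES))
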