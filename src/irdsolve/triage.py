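"""Frequency gating, the missense rule, effect-class ordering, ROH scanning
and the two-branch manual prioritization protocol.

The protocol restricts attention to the gene panel, gates every small variant
on population allele frequency, requires missense variants to pass at least
two of three in silico thresholds (PhyloP >= 2.7, CADD-PHRED >= 15,
Grantham >= 80), orders coding/near-splice candidates by predicted severity
(nonsense < frameshift < canonical splice < NCSS < in-frame indel < missense
< synonymous), and only interrogates rare intronic variants of a gene once
that gene already holds a candidate allele. The branch taken depends on
whether a first candidate allele was carried over from the earlier TCS/WES
screen. Repeat expansions are screened for every case. ROH detection is
advisory: it flags genes inside long homozygous runs but changes no gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .model import (
    AnnotatedSmallVariant,
    CaseRecord,
    Consequence,
    GenePanelEntry,
    InSilicoScores,
    PopulationFrequencies,
    RepeatGenotype,
    RepeatLocusRange,
    StructuralVariantCall,
    Zygosity,
)

__all__ = [
    "TriageConfig",
    "PrioritizationResult",
    "RohInterval",
    "frequency_pass",
    "missense_causative",
    "effect_rank",
    "roh_scan",
    "prioritize_case",
    "small_variant_passes_gates",
]


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the prioritization protocol (all overridable).

    Frequency maxima are fractions; the gnomAD 1% gate is the binding rule at
    the WGS stage, the dbSNP/in-house gates apply when those sources are
    annotated (they stem from the earlier screening stage). ``intronic_max``
    gates the rare-intronic interrogation of a gene of interest. The three
    ROH parameters mirror plink's homozyg-window-het / homozyg-snp /
    homozyg-kb.
    """

    gnomad_max: float = 0.01
    dbsnp_max: float = 0.05
    inhouse_eur_max: float = 0.01
    inhouse_asian_max: float = 0.02
    intronic_max: float = 0.01
    phylop_min: float = 2.7
    cadd_min: float = 15.0
    grantham_min: float = 80.0
    min_passed_scores: int = 2
    roh_window_het: int = 3
    roh_min_snps: int = 50
    roh_min_kb: float = 300.0

    def __post_init__(self) -> None:
        for name in ("gnomad_max", "dbsnp_max", "inhouse_eur_max",
                     "inhouse_asian_max", "intronic_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        if self.min_passed_scores not in (1, 2, 3):
            raise ValueError("min_passed_scores must be 1, 2 or 3")

    @classmethod
    def from_yaml(cls, path) -> "TriageConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class PrioritizationResult:
    """Ordered candidate alleles of one case plus the branch taken."""

    case_id: str
    candidate_alleles: list[tuple[object, str]] = field(default_factory=list)
    branch_taken: str = "no_prior_candidate"  # or "monoallelic"
    genes_interrogated_intronically: list[str] = field(default_factory=list)
    roh_genes: list[str] = field(default_factory=list)


def frequency_pass(
    freqs: PopulationFrequencies, consequence: Consequence, cfg: TriageConfig
) -> bool:
    """True iff every *present* source frequency is within its maximum.

    A variant unreported in all sources passes: absence of a population
    record is evidence of rarity, never grounds for exclusion.
    """
    maxima = {
        "gnomad": cfg.gnomad_max,
        "dbsnp": cfg.dbsnp_max,
        "inhouse_eur": cfg.inhouse_eur_max,
        "inhouse_asian": cfg.inhouse_asian_max,
    }
    return all(v <= maxima[src] for src, v in freqs.present().items())


def missense_causative(scores: InSilicoScores, cfg: TriageConfig) -> bool:
    """Two-of-three rule: a missense variant passing only one threshold is
    not considered causative.

    Thresholds are inclusive (``predicted pathogenic >= threshold``). Raises
    if no score is present — the rule is uninterpretable without evidence.
    """
    present = scores.present()
    if not present:
        raise ValueError("missense rule needs at least one in silico score")
    thresholds = {
        "phylop": cfg.phylop_min,
        "cadd_phred": cfg.cadd_min,
        "grantham": cfg.grantham_min,
    }
    passed = sum(1 for name, v in present.items() if v >= thresholds[name])
    return passed >= cfg.min_passed_scores


_EFFECT_ORDER = {
    Consequence.nonsense: 1,
    Consequence.frameshift: 2,
    Consequence.canonical_splice: 3,
    Consequence.ncss: 4,
    Consequence.inframe_indel: 5,
    Consequence.missense: 6,
    Consequence.synonymous: 7,
    Consequence.deep_intronic: 8,
    Consequence.utr: 9,
    Consequence.other: 10,
}


def effect_rank(consequence: Consequence) -> int:
    """Severity order of predicted effects; lower rank = assessed first."""
    try:
        return _EFFECT_ORDER[Consequence(consequence)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown consequence {consequence!r}")


@dataclass(frozen=True)
class RohInterval:
    start_pos: int
    end_pos: int
    n_sites: int

    @property
    def span_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


def roh_scan(
    genotype_track: Sequence[tuple[int, bool]], cfg: Optional[TriageConfig] = None
) -> list[RohInterval]:
    """Find maximal runs of homozygosity on one chromosome's site track.

    A qualifying run holds >= ``roh_min_snps`` sites, spans >=
    ``roh_min_kb`` kilobases, and every window of ``roh_min_snps``
    consecutive sites inside it carries at most ``roh_window_het``
    heterozygous calls. Returned runs are inclusion-maximal.
    """
    cfg = cfg or TriageConfig()
    n = len(genotype_track)
    positions = [p for p, _ in genotype_track]
    if any(positions[i] > positions[i + 1] for i in range(n - 1)):
        raise ValueError("genotype track must be sorted by position")
    if n == 0:
        return []
    het = [1 if h else 0 for _, h in genotype_track]
    prefix = [0]
    for h in het:
        prefix.append(prefix[-1] + h)
    w = cfg.roh_min_snps
    h_max = cfg.roh_window_het

    def window_ok(k: int) -> bool:
        # het count in sites [k, k+w-1]
        return prefix[k + w] - prefix[k] <= h_max

    # two-pointer: j_max[i] = furthest j with all windows inside [i, j] ok
    results: list[RohInterval] = []
    j = -1
    prev_j = -2
    for i in range(n):
        if j < i - 1:
            j = i - 1
        while j + 1 < n:
            length = j + 2 - i
            if length >= w and not window_ok(j + 2 - w):
                break
            j += 1
        if j == prev_j:  # contained in the previous maximal interval
            continue
        prev_j = j
        n_sites = j - i + 1
        span = positions[j] - positions[i] + 1
        if n_sites >= cfg.roh_min_snps and span >= cfg.roh_min_kb * 1000:
            results.append(RohInterval(positions[i], positions[j], n_sites))
    return results


def small_variant_passes_gates(
    v: AnnotatedSmallVariant, cfg: TriageConfig
) -> tuple[bool, str]:
    """Apply the frequency gate and (for missense) the two-of-three rule.

    Returns (passed, reason). Hypomorphic-flagged alleles bypass both gates:
    the protocol treats them as qualifying in specific genotypes despite
    frequency or score softness. Retained reasons feed the report's evidence
    chain.
    """
    if v.hypomorphic:
        return True, "hypomorphic_bypass"
    if not frequency_pass(v.freqs, v.consequence, cfg):
        return False, "frequency_fail"
    if v.consequence is Consequence.missense:
        if not v.scores.present():
            return False, "missense_no_scores"
        if not missense_causative(v.scores, cfg):
            return False, "missense_threshold_fail"
    return True, "pass"


def _variant_sort_key(v: AnnotatedSmallVariant) -> tuple:
    return (effect_rank(v.consequence), v.gene, v.chrom, v.pos, v.hgvs_c)


def _is_rare_intronic(v: AnnotatedSmallVariant, cfg: TriageConfig) -> bool:
    if v.consequence not in (Consequence.deep_intronic, Consequence.utr,
                             Consequence.other):
        return False
    present = v.freqs.present()
    return all(f <= cfg.intronic_max for f in present.values())


def _sv_hits(sv: StructuralVariantCall, panel: Sequence[GenePanelEntry]):
    # imported lazily to keep triage importable without the SV module
    from .svrepeat import genes_disrupted

    return genes_disrupted(sv, panel)


def prioritize_case(
    case: CaseRecord,
    panel: Sequence[GenePanelEntry],
    cfg: Optional[TriageConfig] = None,
    repeat_ranges: Sequence[RepeatLocusRange] = (),
) -> PrioritizationResult:
    """Run the two-branch manual prioritization protocol on one case.

    Monoallelic branch (a prior candidate allele exists): assess SVs/CNVs and
    rare intronic variants of the prior gene first, then fall back to the
    general search. No-prior branch: SVs/CNVs first, then SNVs ordered by
    predicted effect. Once a gene holds a candidate, its rare intronic
    variants are added and the gene is recorded as interrogated
    intronically. Repeat expansions are screened for every case. Output is
    deterministic and independent of input variant order.
    """
    from .svrepeat import classify_repeat

    cfg = cfg or TriageConfig()
    panel_genes = {e.gene for e in panel}
    result = PrioritizationResult(case_id=case.case_id)

    in_panel = [v for v in case.small_variants if v.gene in panel_genes]
    passed = [v for v in in_panel if small_variant_passes_gates(v, cfg)[0]]
    coding = sorted(
        (v for v in passed if effect_rank(v.consequence) <= 7),
        key=_variant_sort_key,
    )
    intronic = sorted(
        (v for v in passed if _is_rare_intronic(v, cfg)),
        key=_variant_sort_key,
    )

    prior_genes = sorted({v.gene for v in in_panel if v.prior_allele})
    result.branch_taken = "monoallelic" if prior_genes else "no_prior_candidate"

    svs = sorted(case.svs, key=lambda s: (s.chrom, s.start, s.end, s.svtype))
    sv_candidates: list[tuple[StructuralVariantCall, list[str]]] = []
    for sv in svs:
        hit_genes = [g for g, cons in _sv_hits(sv, panel) if cons != "intronic_only"]
        if hit_genes:
            sv_candidates.append((sv, hit_genes))

    interrogated: list[str] = []
    ordered: list[tuple[object, str]] = []
    seen: set = set()

    def add(item, tag) -> None:
        key = (id(item),)
        if key not in seen:
            seen.add(key)
            ordered.append((item, tag))

    def add_intronic_for(gene: str) -> None:
        if gene not in interrogated:
            interrogated.append(gene)
        for v in intronic:
            if v.gene == gene:
                add(v, "intronic")

    if prior_genes:
        # search the prior gene first: its SVs, then its rare intronic SNVs
        for gene in prior_genes:
            for sv, hit_genes in sv_candidates:
                if gene in hit_genes:
                    add(sv, "sv")
            add_intronic_for(gene)
    # general search: SVs/CNVs first, then SNVs by predicted effect
    for sv, _ in sv_candidates:
        add(sv, "sv")
    for v in coding:
        add(v, "coding")
        add_intronic_for(v.gene)
    # repeat expansions are screened for every case
    range_by_locus = {r.locus: r for r in repeat_ranges}
    for rep in sorted(case.repeats, key=lambda r: r.locus):
        rng = range_by_locus.get(rep.locus)
        if rng is None:
            continue
        call = classify_repeat(rep, rng)
        if "pathogenic_expansion" in call.allele_classes:
            add(rep, "repeat_expansion")

    result.candidate_alleles = ordered
    result.genes_interrogated_intronically = interrogated

    if case.genotype_track:
        rohs = roh_scan(case.genotype_track, cfg)
        # advisory only: flag panel genes whose span lies inside an ROH
        track_chrom = case.genotype_track_chrom
        for e in panel:
            if track_chrom is not None and e.chrom != track_chrom:
                continue
            for roh in rohs:
                if roh.start_pos <= e.start and e.end <= roh.end_pos:
                    result.roh_genes.append(e.gene)
                    break
    return result
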