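"""Case-level decision logic: solved / likely_solved / unsolved.

An allele qualifies as causal when any positive evidence route supports it:
a pathogenic / likely-pathogenic classification, a hypomorphic-allele flag
(pathogenic in specific genotypes despite frequency or score softness), a
splice-assay severity of severe or moderate, a gene-disrupting structural
variant, or a pathogenic repeat expansion. An assay-derived *mild* allele
counts only alongside an independently qualifying partner allele; an assay
showing no splice defect blocks the assay route (but never a
classification-based route, keeping resolution monotone in evidence).

Autosomal recessive genes need two qualifying alleles (a homozygous allele
counts twice; compound-heterozygous alleles are assumed in trans). Dominant
genes — including dominant with incomplete penetrance — are solved by a
single qualifying loss-of-function SV, repeat expansion or pathogenic coding
allele. A case is likely solved when a recessive gene pairs one pathogenic
allele with a VUS missense that passes all three in silico thresholds.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .assay import AssayConfig, interpret_assay
from .model import (
    AnnotatedSmallVariant,
    CaseRecord,
    Classification,
    Consequence,
    GenePanelEntry,
    Inheritance,
    RepeatLocusRange,
    Zygosity,
)
from .svrepeat import EXONIC_CONSEQUENCES, classify_repeat, interpret_sv
from .triage import TriageConfig, missense_causative, small_variant_passes_gates

__all__ = ["ResolutionResult", "CohortSummary", "resolve_case", "summarize_cohort"]

RATIONALE_TAGS = (
    "biallelic_lof",
    "hom_hypomorphic",
    "assay_severe",
    "dominant_lof_sv",
    "repeat_expansion",
    "vus_supported",
)

_DOMINANT = (Inheritance.AD, Inheritance.AD_incomplete_penetrance)


@dataclass
class ResolutionResult:
    case_id: str
    status: str = "unsolved"  # solved | likely_solved | unsolved
    causal_gene: Optional[str] = None
    causal_alleles: list[tuple[str, str]] = field(default_factory=list)
    rationale_tags: set[str] = field(default_factory=set)
    evidence: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class _Allele:
    label: str
    gene: str
    kind: str        # coding | ncss | deep_intronic | sv | repeat
    quality: str     # pathogenic | likely_pathogenic | hypomorphic | severe |
                     # moderate | mild | sv_lof | repeat_expansion | vus_supported
    count: int       # 2 for homozygous
    tag: Optional[str] = None


def _variant_kind(v: AnnotatedSmallVariant) -> str:
    if v.consequence is Consequence.ncss:
        return "ncss"
    if v.consequence in (Consequence.deep_intronic, Consequence.utr,
                         Consequence.other):
        return "deep_intronic"
    return "coding"


def resolve_case(
    case: CaseRecord,
    panel: Sequence[GenePanelEntry],
    repeat_ranges: Sequence[RepeatLocusRange] = (),
    cfg: Optional[TriageConfig] = None,
    assay_cfg: Optional[AssayConfig] = None,
) -> ResolutionResult:
    """Combine per-allele evidence of one case into a resolution."""
    cfg = cfg or TriageConfig()
    assay_cfg = assay_cfg or AssayConfig()
    by_gene = {e.gene: e for e in panel}
    result = ResolutionResult(case_id=case.case_id)

    assay_by_variant = {}
    for a in case.assays:
        assay_by_variant[a.variant_label] = interpret_assay(a, assay_cfg)

    qualifying: dict[str, list[_Allele]] = defaultdict(list)
    mild: dict[str, list[_Allele]] = defaultdict(list)
    vus: dict[str, list[_Allele]] = defaultdict(list)

    for v in sorted(case.small_variants, key=lambda v: (v.gene, v.chrom, v.pos, v.hgvs_c)):
        if v.gene not in by_gene:
            raise ValueError(
                f"{case.case_id}: variant {v.label} references gene "
                f"{v.gene!r} absent from the panel"
            )
        passed, reason = small_variant_passes_gates(v, cfg)
        interp = assay_by_variant.get(v.label)
        ev = {
            "allele": v.label, "type": "small_variant",
            "consequence": v.consequence.value, "zygosity": v.zygosity.value,
            "gate": reason,
            "classification": v.classification.value if v.classification else None,
            "assay_severity": interp.severity if interp else None,
            "qualifies": False,
        }
        result.evidence.append(ev)
        if not passed:
            continue
        count = 2 if v.zygosity is Zygosity.hom else 1
        kind = _variant_kind(v)
        if v.classification in (Classification.pathogenic,
                                Classification.likely_pathogenic):
            ev["qualifies"] = True
            qualifying[v.gene].append(
                _Allele(v.label, v.gene, kind, v.classification.value, count)
            )
            continue
        if v.hypomorphic:
            ev["qualifies"] = True
            qualifying[v.gene].append(
                _Allele(v.label, v.gene, kind, "hypomorphic", count,
                        tag="hom_hypomorphic" if count == 2 else None)
            )
            continue
        if interp is not None and interp.defect_present:
            if interp.severity in ("severe", "moderate"):
                ev["qualifies"] = True
                qualifying[v.gene].append(
                    _Allele(v.label, v.gene, kind, interp.severity, count,
                            tag="assay_severe" if interp.severity == "severe" else None)
                )
                continue
            if interp.severity == "mild":
                mild[v.gene].append(_Allele(v.label, v.gene, kind, "mild", count))
                continue
        if (
            v.classification is Classification.vus
            and v.consequence is Consequence.missense
            and len(v.scores.present()) == 3
            and missense_causative(v.scores, TriageConfig(
                phylop_min=cfg.phylop_min, cadd_min=cfg.cadd_min,
                grantham_min=cfg.grantham_min, min_passed_scores=3))
        ):
            vus[v.gene].append(_Allele(v.label, v.gene, kind, "vus_supported", count))

    for sv in sorted(case.svs, key=lambda s: (s.chrom, s.start, s.end)):
        interp = interpret_sv(sv, panel)
        count = 2 if sv.zygosity is Zygosity.hom else 1
        hit_exonic = [g for g, c in interp.genes_hit if c in EXONIC_CONSEQUENCES]
        result.evidence.append({
            "allele": sv.label, "type": "sv",
            "length_bp": interp.length_bp,
            "genes_hit": [list(h) for h in interp.genes_hit],
            "microhomology_len": interp.microhomology_len,
            "frame_effect": interp.frame_effect,
            "qualifies": bool(hit_exonic),
        })
        for gene in hit_exonic:
            qualifying[gene].append(
                _Allele(sv.label, gene, "sv", "sv_lof", count)
            )

    range_by_locus = {r.locus: r for r in repeat_ranges}
    for rep in sorted(case.repeats, key=lambda r: r.locus):
        rng = range_by_locus.get(rep.locus)
        if rng is None:
            raise ValueError(f"{case.case_id}: no range table entry for "
                             f"locus {rep.locus!r}")
        call = classify_repeat(rep, rng)
        expanded = "pathogenic_expansion" in call.allele_classes
        result.evidence.append({
            "allele": rep.label, "type": "repeat",
            "allele_classes": list(call.allele_classes),
            "qualifies": expanded,
        })
        if expanded:
            if rep.locus not in by_gene:
                raise ValueError(
                    f"{case.case_id}: repeat locus {rep.locus!r} absent from panel"
                )
            count = sum(1 for c in call.allele_classes if c == "pathogenic_expansion")
            qualifying[rep.locus].append(
                _Allele(rep.label, rep.locus, "repeat", "repeat_expansion", count)
            )

    # decide per gene, take the best outcome (solved beats likely_solved),
    # ties broken by gene name for determinism
    best: Optional[tuple[int, str, list[_Allele], set[str]]] = None
    for gene in sorted(set(qualifying) | set(vus)):
        entry = by_gene[gene]
        base = qualifying.get(gene, [])
        tags: set[str] = set()
        alleles: list[_Allele] = []
        status_rank = 0
        if entry.inheritance in _DOMINANT:
            if base:
                status_rank, alleles = 2, list(base)
        else:  # AR (and XL, resolved with the biallelic rule)
            extra = mild.get(gene, []) if base else []
            total = sum(a.count for a in base) + sum(a.count for a in extra)
            if total >= 2 and base:
                status_rank, alleles = 2, list(base) + list(extra)
            elif sum(a.count for a in base) == 1 and vus.get(gene):
                partner = base[0]
                if partner.quality in ("pathogenic", "likely_pathogenic"):
                    status_rank = 1
                    alleles = [partner, vus[gene][0]]
                    tags.add("vus_supported")
        if status_rank == 0:
            continue
        for a in alleles:
            if a.tag:
                tags.add(a.tag)
            if a.quality == "sv_lof":
                tags.add("dominant_lof_sv" if entry.inheritance in _DOMINANT
                         else "biallelic_lof")
            if a.quality == "repeat_expansion":
                tags.add("repeat_expansion")
        if status_rank == 2 and entry.inheritance not in _DOMINANT:
            if all(a.quality == "hypomorphic" for a in alleles):
                tags.add("hom_hypomorphic")
            elif not tags & {"assay_severe", "hom_hypomorphic", "biallelic_lof"}:
                tags.add("biallelic_lof")
        cand = (status_rank, gene, alleles, tags)
        if best is None or cand[0] > best[0]:
            best = cand

    if best is not None:
        status_rank, gene, alleles, tags = best
        result.status = "solved" if status_rank == 2 else "likely_solved"
        result.causal_gene = gene
        result.causal_alleles = [(a.label, a.quality) for a in alleles]
        result.rationale_tags = tags
    return result


@dataclass
class CohortSummary:
    n_cases: int
    n_solved: int  # solved + likely_solved
    solved_pct: float
    per_phenotype: dict[str, int]
    per_phenotype_solved: dict[str, int]
    per_variant_type: dict[str, int]  # causal-allele kinds across solved cases


def summarize_cohort(
    resolutions: Sequence[ResolutionResult], cases: Sequence[CaseRecord]
) -> CohortSummary:
    """Cohort accounting: diagnostic yield and phenotype/variant-type counts."""
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case_id in cohort")
    res_ids = [r.case_id for r in resolutions]
    if len(set(res_ids)) != len(res_ids):
        raise ValueError("duplicate case_id in resolutions")
    if set(res_ids) != set(ids):
        raise ValueError("resolutions and cases do not cover the same case IDs")
    by_id = {r.case_id: r for r in resolutions}
    per_phenotype: dict[str, int] = defaultdict(int)
    per_phenotype_solved: dict[str, int] = defaultdict(int)
    per_variant_type: dict[str, int] = defaultdict(int)
    n_solved = 0
    kind_by_label: dict[str, str] = {}
    for c in cases:
        per_phenotype[c.phenotype] += 1
        r = by_id[c.case_id]
        solved = r.status in ("solved", "likely_solved")
        if solved:
            n_solved += 1
            per_phenotype_solved[c.phenotype] += 1
            kinds = {}
            for v in c.small_variants:
                kinds[v.label] = _variant_kind(v)
            for label, _quality in r.causal_alleles:
                if label.startswith("SV:"):
                    kind = "sv"
                elif label.startswith("STR:"):
                    kind = "repeat"
                else:
                    kind = kinds.get(label, "coding")
                per_variant_type[kind] += 1
    n = len(cases)
    return CohortSummary(
        n_cases=n,
        n_solved=n_solved,
        solved_pct=round(100.0 * n_solved / n, 1) if n else 0.0,
        per_phenotype=dict(sorted(per_phenotype.items())),
        per_phenotype_solved=dict(sorted(per_phenotype_solved.items())),
        per_variant_type=dict(sorted(per_variant_type.items())),
    )
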