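"""End-to-end orchestration: triage → splice-candidate selection → assay
interpretation → SV/repeat interpretation → case resolution → cohort
summary."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import CaseRecord, GenePanelEntry, RepeatLocusRange
from .assay import AssayConfig
from .resolve import CohortSummary, ResolutionResult, resolve_case, summarize_cohort
from .splice import SpliceCandidate, SpliceSelectionConfig, select_splice_candidates
from .triage import PrioritizationResult, TriageConfig, prioritize_case, \
    small_variant_passes_gates

__all__ = ["PipelineResult", "run_pipeline", "splice_candidates_for_cases"]


@dataclass
class PipelineResult:
    prioritizations: list[PrioritizationResult]
    splice_candidates: list[SpliceCandidate]
    resolutions: list[ResolutionResult]
    summary: CohortSummary
    stage_counts: dict[str, int] = field(default_factory=dict)


def splice_candidates_for_cases(
    cases: Sequence[CaseRecord],
    panel: Sequence[GenePanelEntry],
    triage_cfg: Optional[TriageConfig] = None,
    splice_cfg: Optional[SpliceSelectionConfig] = None,
) -> list[SpliceCandidate]:
    """Select splice-assay candidates across a cohort.

    Only variants inside the panel that survive the frequency/missense gates
    are offered to the selector, mirroring the protocol's order of
    operations.
    """
    triage_cfg = triage_cfg or TriageConfig()
    panel_genes = {e.gene for e in panel}
    eligible = [
        v
        for c in cases
        for v in c.small_variants
        if v.gene in panel_genes and small_variant_passes_gates(v, triage_cfg)[0]
    ]
    return select_splice_candidates(eligible, splice_cfg)


def run_pipeline(
    cases: Sequence[CaseRecord],
    panel: Sequence[GenePanelEntry],
    repeat_ranges: Sequence[RepeatLocusRange] = (),
    triage_cfg: Optional[TriageConfig] = None,
    splice_cfg: Optional[SpliceSelectionConfig] = None,
    assay_cfg: Optional[AssayConfig] = None,
) -> PipelineResult:
    triage_cfg = triage_cfg or TriageConfig()
    prioritizations = [
        prioritize_case(c, panel, triage_cfg, repeat_ranges) for c in cases
    ]
    candidates = splice_candidates_for_cases(cases, panel, triage_cfg, splice_cfg)
    resolutions = [
        resolve_case(c, panel, repeat_ranges, triage_cfg, assay_cfg) for c in cases
    ]
    summary = summarize_cohort(resolutions, cases)
    stage_counts = {
        "cases": len(cases),
        "small_variants": sum(len(c.small_variants) for c in cases),
        "svs": sum(len(c.svs) for c in cases),
        "repeats": sum(len(c.repeats) for c in cases),
        "assays": sum(len(c.assays) for c in cases),
        "candidate_alleles": sum(len(p.candidate_alleles) for p in prioritizations),
        "splice_candidates": len(candidates),
        "solved_or_likely": summary.n_solved,
    }
    return PipelineResult(
        prioritizations=prioritizations,
        splice_candidates=candidates,
        resolutions=resolutions,
        summary=summary,
        stage_counts=stage_counts,
    )
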