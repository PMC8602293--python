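"""Interpretation of midigene/minigene splice-assay band tables.

RT-PCR products of the wild-type and mutant constructs are quantified as
intensity fractions per fragment. A splice defect is called when the mutant
construct produces a fragment the wild-type construct does not. The share of
correctly spliced (wild-type-length) product in the mutant construct is
normalized to the wild-type construct and mapped to an allele-severity
class: below 25% remaining wild-type fragment is a severe allele, 75% or
more is mild, in between is moderate. Only the 25% cut is biologically
anchored (it defines "severe"); the 75% mild boundary completes the scale
consistently with a 91%-remaining allele being labeled mild, and both are
config-overridable.

Percentages follow gel-densitometry reporting conventions: both input
percentages and the normalized ratio are rounded to the nearest integer and
formatted at one decimal (so 42 of 46 percent remaining prints as 91.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import Lane, SpliceAssayResult, SpliceEvent, SpliceEventKind

__all__ = [
    "AssayConfig",
    "AssayInterpretation",
    "quantify_fragments",
    "predict_fragment_length",
    "normalized_wt_percent",
    "classify_allele_severity",
    "interpret_assay",
]


@dataclass(frozen=True)
class AssayConfig:
    """Severity boundaries (percent remaining wild-type fragment) and the
    minimum intensity fraction for a mutant-only fragment to count as a
    defect rather than gel noise."""

    severe_below_pct: float = 25.0
    mild_at_least_pct: float = 75.0
    novel_fragment_min_pct: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.severe_below_pct < self.mild_at_least_pct <= 100):
            raise ValueError("severity boundaries must satisfy 0 < severe < mild <= 100")


def quantify_fragments(lanes: Sequence[Lane]) -> list[tuple[int, float]]:
    """Percent of total product per fragment (ignored lanes excluded).

    percent_i = 100 × intensity_i / Σ intensity; the output sums to 100.
    """
    used = [l for l in lanes if not l.ignore]
    total = sum(l.intensity for l in used)
    if total <= 0:
        raise ValueError("total lane intensity must be positive")
    # clamp against float rounding (a lone lane can print 100.0000…01)
    return [
        (l.fragment_length_nt, min(100.0, 100.0 * l.intensity / total))
        for l in used
    ]


def predict_fragment_length(wt_len: int, event: SpliceEvent) -> int:
    """Expected RT-PCR fragment length under a hypothesized splice event."""
    if wt_len <= 0:
        raise ValueError("wild-type fragment length must be positive")
    if event.kind in (SpliceEventKind.pseudoexon_insertion,
                      SpliceEventKind.exon_elongation):
        return wt_len + event.size_nt
    if event.size_nt >= wt_len:
        raise ValueError(
            f"removed size {event.size_nt} nt must be smaller than the "
            f"{wt_len}-nt wild-type fragment"
        )
    return wt_len - event.size_nt


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def normalized_wt_percent(mut_wt_pct: float, wtconstruct_wt_pct: float) -> float:
    """Wild-type-fragment share of the mutant construct, normalized to the
    wild-type construct.

    Both percentages are rounded to the nearest integer before the ratio
    (the densitometry convention: 42.0 over 45.6 is computed as 42/46), the
    ratio is capped at 100 and rounded to the nearest integer, and returned
    on a one-decimal scale.
    """
    if not (0 <= mut_wt_pct <= 100) or not (0 <= wtconstruct_wt_pct <= 100):
        raise ValueError("percentages must be in [0, 100]")
    denom = _round_half_up(wtconstruct_wt_pct)
    if denom <= 0:
        raise ValueError("wild-type construct must contain wild-type fragment")
    num = _round_half_up(mut_wt_pct)
    ratio = min(100.0, 100.0 * num / denom)
    return float(_round_half_up(ratio))


def classify_allele_severity(
    pct_wt: float, cfg: Optional[AssayConfig] = None
) -> str:
    """Map percent remaining wild-type fragment to an allele severity class."""
    cfg = cfg or AssayConfig()
    if not (0 <= pct_wt <= 100):
        raise ValueError(f"percent must be in [0, 100], got {pct_wt!r}")
    if pct_wt < cfg.severe_below_pct:
        return "severe"
    if pct_wt >= cfg.mild_at_least_pct:
        return "mild"
    return "moderate"


@dataclass(frozen=True)
class AssayInterpretation:
    pct_wt_raw: float
    pct_wt_normalized: float
    severity: str  # severe | moderate | mild | no_defect
    defect_present: bool


def interpret_assay(
    assay: SpliceAssayResult, cfg: Optional[AssayConfig] = None
) -> AssayInterpretation:
    """Interpret one band table into a defect call and allele severity.

    No defect is called when the mutant construct's lane profile matches the
    wild-type construct's within tolerance: no mutant-only fragment above
    the intensity-fraction tolerance and no comparable loss of the
    wild-type-length fragment's share (a baseline aberrant product both
    constructs produce is not, by itself, a defect of the variant).
    """
    cfg = cfg or AssayConfig()
    wt_profile = quantify_fragments(assay.wt_construct_lanes)
    mut_profile = quantify_fragments(assay.mut_construct_lanes)
    wt_lengths = {length for length, _ in wt_profile}
    novel = [
        (length, pct)
        for length, pct in mut_profile
        if length not in wt_lengths and pct >= cfg.novel_fragment_min_pct
    ]
    wt_share_wt = sum(p for l, p in wt_profile if l == assay.wt_fragment_length)
    wt_share_mut = sum(p for l, p in mut_profile if l == assay.wt_fragment_length)
    wt_fragment_lost = (wt_share_wt - wt_share_mut) >= cfg.novel_fragment_min_pct
    if not novel and not wt_fragment_lost:
        return AssayInterpretation(
            pct_wt_raw=100.0, pct_wt_normalized=100.0,
            severity="no_defect", defect_present=False,
        )
    raw = sum(pct for length, pct in mut_profile
              if length == assay.wt_fragment_length)
    wt_construct_pct = sum(pct for length, pct in wt_profile
                           if length == assay.wt_fragment_length)
    normalized = normalized_wt_percent(raw, wt_construct_pct)
    return AssayInterpretation(
        pct_wt_raw=raw,
        pct_wt_normalized=normalized,
        severity=classify_allele_severity(normalized, cfg),
        defect_present=True,
    )
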