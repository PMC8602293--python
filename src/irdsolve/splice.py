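"""Selection of noncanonical splice-site and deep-intronic variants for
in vitro splice assays.

Two prediction signals are consumed (never computed): SpliceAI delta scores
— the predicted change in acceptor/donor gain/loss probability — and
Alamut-embedded algorithm score pairs (SSFL, MaxEntScan, GeneSplicer, HSF,
NNSPLICE). A variant is a candidate when any SpliceAI delta reaches the
0.02 threshold, or — for variant types SpliceAI does not score, such as the
delins indels — when at least two Alamut algorithms show a gained or
strengthened splice site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import AlgorithmScorePair, AnnotatedSmallVariant, SpliceScores

__all__ = [
    "SpliceSelectionConfig",
    "SpliceCandidate",
    "spliceai_candidate",
    "alamut_candidate",
    "select_splice_candidates",
]

PREDICTED_EVENTS = (
    "pseudoexon_insertion",
    "exon_elongation",
    "exon_skipping",
    "cryptic_site_gain",
    "unknown",
)


@dataclass(frozen=True)
class SpliceSelectionConfig:
    """Candidate-selection thresholds.

    ``spliceai_delta_min`` is compared inclusively by default (a delta of
    exactly 0.02 selects); set ``spliceai_strict`` for a strict comparison.
    ``spliceai_context_bp`` is metadata only — scores arrive precomputed with
    that much flanking sequence. The Alamut rule requires
    ``alamut_min_algorithms`` score pairs each gaining at least
    ``alamut_min_rel_increase`` of the algorithm's scale.
    """

    spliceai_delta_min: float = 0.02
    spliceai_strict: bool = False
    spliceai_context_bp: int = 500
    alamut_min_algorithms: int = 2
    alamut_min_rel_increase: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.spliceai_delta_min < 1.0):
            raise ValueError("spliceai_delta_min must be in (0, 1)")
        if self.alamut_min_algorithms not in range(1, 6):
            raise ValueError("alamut_min_algorithms must be in 1..5")


@dataclass(frozen=True)
class SpliceCandidate:
    variant: AnnotatedSmallVariant
    trigger: str  # "spliceai" | "alamut_only"
    predicted_event: str = "unknown"

    def __post_init__(self) -> None:
        if self.trigger not in ("spliceai", "alamut_only"):
            raise ValueError(f"unknown trigger {self.trigger!r}")
        if self.predicted_event not in PREDICTED_EVENTS:
            raise ValueError(f"unknown predicted event {self.predicted_event!r}")


def spliceai_candidate(
    splice: SpliceScores, cfg: Optional[SpliceSelectionConfig] = None
) -> bool:
    """True iff the maximum of the four delta scores reaches the threshold."""
    cfg = cfg or SpliceSelectionConfig()
    if splice.spliceai is None:
        raise ValueError(
            "SpliceAI deltas absent for this variant; use the Alamut-only path"
        )
    m = splice.spliceai.max_delta()
    return m > cfg.spliceai_delta_min if cfg.spliceai_strict else m >= cfg.spliceai_delta_min


def _pair_gained(pair: AlgorithmScorePair, cfg: SpliceSelectionConfig) -> bool:
    if pair.wt_score is None or pair.wt_score == 0:
        return pair.mut_score > 0  # de novo site
    return (pair.mut_score - pair.wt_score) >= cfg.alamut_min_rel_increase * pair.scale_max


def alamut_candidate(
    pairs: Sequence[AlgorithmScorePair], cfg: Optional[SpliceSelectionConfig] = None
) -> bool:
    """True iff enough algorithms report a gained or strengthened site."""
    cfg = cfg or SpliceSelectionConfig()
    if not pairs:
        raise ValueError("Alamut rule needs at least one algorithm score pair")
    return sum(1 for p in pairs if _pair_gained(p, cfg)) >= cfg.alamut_min_algorithms


def select_splice_candidates(
    variants: Sequence[AnnotatedSmallVariant],
    cfg: Optional[SpliceSelectionConfig] = None,
) -> list[SpliceCandidate]:
    """Select assay candidates from already frequency-passed variants.

    A variant is selected iff its SpliceAI deltas reach the threshold, or the
    SpliceAI block is absent (unsupported variant type) and the Alamut rule
    fires — then flagged ``alamut_only``. Selection is order-independent; the
    output is sorted by (gene, position, case).
    """
    cfg = cfg or SpliceSelectionConfig()
    selected = []
    for v in variants:
        if v.splice is None:
            continue
        trigger = None
        if v.splice.spliceai is not None:
            if spliceai_candidate(v.splice, cfg):
                trigger = "spliceai"
        elif v.splice.alamut and alamut_candidate(v.splice.alamut, cfg):
            trigger = "alamut_only"
        if trigger:
            event = v.splice_event if v.splice_event in PREDICTED_EVENTS else "unknown"
            selected.append(SpliceCandidate(variant=v, trigger=trigger,
                                            predicted_event=event))
    selected.sort(key=lambda c: (c.variant.gene, c.variant.chrom, c.variant.pos,
                                 c.variant.case_id, c.variant.hgvs_c))
    return selected


def candidates_tsv_rows(candidates: Sequence[SpliceCandidate]) -> list[list[str]]:
    """Rows for the exported candidate table (with header)."""
    rows = [["case_id", "gene", "hgvs_c", "trigger", "predicted_event"]]
    for c in candidates:
        rows.append([c.variant.case_id, c.variant.gene, c.variant.hgvs_c,
                     c.trigger, c.predicted_event])
    return rows
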