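"""Structural-variant and repeat-expansion interpretation.

Structural variants are sized with 1-based inclusive arithmetic, mapped onto
the gene panel (whole gene / multi-exon / single-exon / promoter-only /
intronic-only), and their junctions assessed for microhomology — a short
identical sequence shared by both breakpoint boundaries, a signature of the
repair mechanism. Repeat genotypes are classified against per-locus normal
and pathogenic count ranges; counts falling between the two ranges are
indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    DNA_ALPHABET,
    GenePanelEntry,
    RepeatGenotype,
    RepeatLocusRange,
    StructuralVariantCall,
)

__all__ = [
    "SvInterpretation",
    "RepeatCall",
    "sv_length",
    "microhomology",
    "genes_disrupted",
    "interpret_sv",
    "classify_repeat",
]

# consequence classes a deletion can have on a panel gene
EXONIC_CONSEQUENCES = ("whole_gene", "multi_exon", "single_exon")


@dataclass(frozen=True)
class SvInterpretation:
    sv: StructuralVariantCall
    length_bp: int
    genes_hit: tuple[tuple[str, str], ...]  # (gene, consequence)
    microhomology_len: Optional[int] = None
    microhomology_seq: Optional[str] = None
    frame_effect: str = "unknown"  # frameshift | in_frame | regulatory | unknown


@dataclass(frozen=True)
class RepeatCall:
    genotype: RepeatGenotype
    allele_classes: tuple[str, str]  # normal | indeterminate | pathogenic_expansion


def sv_length(sv: StructuralVariantCall) -> int:
    """Affected span in bp, 1-based inclusive: end − start + 1."""
    return sv.end - sv.start + 1


def microhomology(left_flank_seq: str, right_flank_seq: str) -> tuple[int, str]:
    """Longest junction microhomology between inner-edge anchored flanks.

    Returns the largest k for which the k-suffix of the left flank equals the
    k-prefix of the right flank, with the shared sequence; (0, "") when none.
    ``N`` never matches anything, including another ``N``.
    """
    if not left_flank_seq or not right_flank_seq:
        raise ValueError("both flank sequences must be nonempty")
    for name, seq in (("left", left_flank_seq), ("right", right_flank_seq)):
        extra = set(seq) - DNA_ALPHABET
        if extra:
            raise ValueError(f"{name} flank contains non-DNA characters {sorted(extra)}")
    for k in range(min(len(left_flank_seq), len(right_flank_seq)), 0, -1):
        candidate = left_flank_seq[-k:]
        if "N" not in candidate and candidate == right_flank_seq[:k]:
            return k, candidate
    return 0, ""


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def genes_disrupted(
    sv: StructuralVariantCall, panel: Sequence[GenePanelEntry]
) -> list[tuple[str, str]]:
    """Map an SV onto panel genes.

    whole_gene when the SV covers the full gene span; otherwise single_exon /
    multi_exon by the number of exons overlapped; promoter_only when only the
    promoter interval is touched; intronic_only for any other overlap of the
    gene span.
    """
    hits: list[tuple[str, str]] = []
    for entry in panel:
        if entry.chrom != sv.chrom:
            continue
        gene_overlap = _overlap(sv.start, sv.end, entry.start, entry.end)
        promoter_overlap = (
            _overlap(sv.start, sv.end, *entry.promoter) if entry.promoter else 0
        )
        if gene_overlap == 0 and promoter_overlap == 0:
            continue
        if sv.start <= entry.start and entry.end <= sv.end:
            hits.append((entry.gene, "whole_gene"))
            continue
        n_exons = sum(
            1 for s, e in entry.exons if _overlap(sv.start, sv.end, s, e) > 0
        )
        if n_exons > 1:
            hits.append((entry.gene, "multi_exon"))
        elif n_exons == 1:
            hits.append((entry.gene, "single_exon"))
        elif gene_overlap == 0 and promoter_overlap > 0:
            hits.append((entry.gene, "promoter_only"))
        else:
            hits.append((entry.gene, "intronic_only"))
    return hits


def _frame_effect(
    sv: StructuralVariantCall, panel: Sequence[GenePanelEntry],
    hits: Sequence[tuple[str, str]],
) -> str:
    """Reading-frame effect of a deletion from summed deleted coding length.

    Exon intervals are treated as coding; for partial-exon deletions only the
    overlapped part counts. A whole-gene loss has no reading frame (unknown);
    promoter-only events are regulatory; non-deletion SV types are left
    unknown.
    """
    by_gene = {e.gene: e for e in panel}
    exonic = [(g, c) for g, c in hits if c in ("multi_exon", "single_exon")]
    if any(c == "whole_gene" for _, c in hits):
        return "unknown"
    if exonic:
        if sv.svtype != "del":
            return "unknown"
        gene = exonic[0][0]
        entry = by_gene[gene]
        deleted = sum(_overlap(sv.start, sv.end, s, e) for s, e in entry.exons)
        return "in_frame" if deleted % 3 == 0 else "frameshift"
    if any(c == "promoter_only" for _, c in hits):
        return "regulatory"
    return "unknown"


def interpret_sv(
    sv: StructuralVariantCall, panel: Sequence[GenePanelEntry]
) -> SvInterpretation:
    """Full interpretation: size, gene consequences, junction microhomology
    (when flank sequences were captured) and reading-frame effect."""
    hits = tuple(genes_disrupted(sv, panel))
    mh_len: Optional[int] = None
    mh_seq: Optional[str] = None
    if sv.left_flank_seq and sv.right_flank_seq:
        mh_len, mh_seq = microhomology(sv.left_flank_seq, sv.right_flank_seq)
    return SvInterpretation(
        sv=sv,
        length_bp=sv_length(sv),
        genes_hit=hits,
        microhomology_len=mh_len,
        microhomology_seq=mh_seq,
        frame_effect=_frame_effect(sv, panel, hits),
    )


def classify_repeat(
    genotype: RepeatGenotype, locus_range: RepeatLocusRange
) -> RepeatCall:
    """Classify each allele count against the locus's published ranges."""
    if locus_range.locus != genotype.locus:
        raise ValueError(
            f"range table entry is for {locus_range.locus!r}, "
            f"genotype is at {genotype.locus!r}"
        )

    def classify(count: int) -> str:
        if locus_range.normal_min <= count <= locus_range.normal_max:
            return "normal"
        if locus_range.pathogenic_min <= count <= locus_range.pathogenic_max:
            return "pathogenic_expansion"
        return "indeterminate"

    return RepeatCall(
        genotype=genotype,
        allele_classes=tuple(classify(c) for c in genotype.allele_counts),
    )
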