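"""Domain types for IRD cohort variant evidence.

Every piece of evidence the pipeline reasons about — annotated small
variants, structural variant calls, repeat-expansion genotypes, splice-assay
band tables and the gene panel — is represented by a small validated
dataclass. HGVS ``c.`` strings are carried as opaque labels; all computation
uses explicit genomic fields. Internal coordinates are 1-based inclusive
(matching ``g.`` notation); BED files on disk are 0-based half-open and are
converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Consequence",
    "Zygosity",
    "Classification",
    "Inheritance",
    "PanelName",
    "SpliceAlgorithm",
    "SiteKind",
    "PopulationFrequencies",
    "InSilicoScores",
    "SpliceAIDeltas",
    "AlgorithmScorePair",
    "SpliceScores",
    "AnnotatedSmallVariant",
    "StructuralVariantCall",
    "RepeatGenotype",
    "RepeatLocusRange",
    "GenePanelEntry",
    "Lane",
    "SpliceEvent",
    "SpliceAssayResult",
    "CaseRecord",
    "DNA_ALPHABET",
]

DNA_ALPHABET = frozenset("ACGTN")


class Consequence(str, Enum):
    """Predicted molecular consequence of a small variant."""

    nonsense = "nonsense"
    frameshift = "frameshift"
    canonical_splice = "canonical_splice"
    ncss = "ncss"
    inframe_indel = "inframe_indel"
    missense = "missense"
    synonymous = "synonymous"
    deep_intronic = "deep_intronic"
    utr = "utr"
    other = "other"


class Zygosity(str, Enum):
    het = "het"
    hom = "hom"


class Classification(str, Enum):
    """Five-class clinical label, consumed as an input annotation."""

    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    vus = "vus"
    likely_benign = "likely_benign"
    benign = "benign"


class Inheritance(str, Enum):
    AR = "AR"
    AD = "AD"
    AD_incomplete_penetrance = "AD_incomplete_penetrance"
    XL = "XL"


class PanelName(str, Enum):
    ird = "ird"
    ciliopathy = "ciliopathy"


class SpliceAlgorithm(str, Enum):
    SSFL = "SSFL"
    MaxEntScan = "MaxEntScan"
    GeneSplicer = "GeneSplicer"
    HSF = "HSF"
    NNSPLICE = "NNSPLICE"


class SiteKind(str, Enum):
    donor = "donor"
    acceptor = "acceptor"


def _check_fraction(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class PopulationFrequencies:
    """Per-source allele frequencies; a missing source is ``None``, never 0."""

    gnomad: Optional[float] = None
    dbsnp: Optional[float] = None
    inhouse_eur: Optional[float] = None
    inhouse_asian: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("gnomad", "dbsnp", "inhouse_eur", "inhouse_asian"):
            _check_fraction(name, getattr(self, name))

    def present(self) -> dict[str, float]:
        return {
            name: v
            for name in ("gnomad", "dbsnp", "inhouse_eur", "inhouse_asian")
            if (v := getattr(self, name)) is not None
        }


# Documented input ranges for the in silico scores. PhyloP is printed by some
# sources without its sign; the conventional signed range is used here.
PHYLOP_RANGE = (-14.1, 6.4)
CADD_RANGE = (1.0, 99.0)
GRANTHAM_RANGE = (0.0, 215.0)


@dataclass(frozen=True)
class InSilicoScores:
    """Conservation/deleteriousness scores used by the missense rule.

    phylop: per-base conservation, range −14.1..6.4, pathogenic ≥ 2.7.
    cadd_phred: scaled CADD, range 1..99, pathogenic ≥ 15.
    grantham: amino-acid substitution distance, range 0..215, pathogenic ≥ 80.
    """

    phylop: Optional[float] = None
    cadd_phred: Optional[float] = None
    grantham: Optional[float] = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("phylop", PHYLOP_RANGE),
            ("cadd_phred", CADD_RANGE),
            ("grantham", GRANTHAM_RANGE),
        ):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValueError(f"{name}={v!r} outside documented range [{lo}, {hi}]")

    def present(self) -> dict[str, float]:
        return {
            name: v
            for name in ("phylop", "cadd_phred", "grantham")
            if (v := getattr(self, name)) is not None
        }


@dataclass(frozen=True)
class SpliceAIDeltas:
    """SpliceAI delta scores: predicted change in splice-site probability."""

    acceptor_gain: float = 0.0
    acceptor_loss: float = 0.0
    donor_gain: float = 0.0
    donor_loss: float = 0.0

    def __post_init__(self) -> None:
        for name in ("acceptor_gain", "acceptor_loss", "donor_gain", "donor_loss"):
            _check_fraction(name, getattr(self, name))

    def max_delta(self) -> float:
        return max(
            self.acceptor_gain, self.acceptor_loss, self.donor_gain, self.donor_loss
        )


@dataclass(frozen=True)
class AlgorithmScorePair:
    """One Alamut-embedded algorithm's wild-type vs mutant site score.

    ``scale_max`` is the algorithm's documented score ceiling (100 for
    SSFL/HSF, 1 for NNSPLICE); wt and mut scores share that scale. A
    wild-type score of ``None`` means no site was predicted in the reference.
    """

    algorithm: SpliceAlgorithm
    site_kind: SiteKind
    wt_score: Optional[float]
    mut_score: float
    scale_max: float

    def __post_init__(self) -> None:
        if self.wt_score is not None and self.wt_score < 0:
            raise ValueError("wt_score must be >= 0")
        if self.mut_score < 0:
            raise ValueError("mut_score must be >= 0")
        if self.scale_max <= 0:
            raise ValueError("scale_max must be positive")


@dataclass(frozen=True)
class SpliceScores:
    """Splice predictions attached to a variant.

    ``spliceai`` is absent as a block for variant types the score provider
    does not support (the delins indels of the study); ``alamut`` may be
    empty.
    """

    spliceai: Optional[SpliceAIDeltas] = None
    alamut: tuple[AlgorithmScorePair, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "alamut", tuple(self.alamut))


@dataclass(frozen=True)
class AnnotatedSmallVariant:
    """One SNV/indel, one record per ALT allele."""

    case_id: str
    gene: str
    hgvs_c: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    zygosity: Zygosity
    freqs: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    scores: InSilicoScores = field(default_factory=InSilicoScores)
    splice: Optional[SpliceScores] = None
    prior_allele: bool = False
    classification: Optional[Classification] = None
    hypomorphic: bool = False
    splice_event: Optional[str] = None  # site-geometry annotation, if supplied

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty")
        if self.prior_allele and self.classification is None:
            raise ValueError(
                "prior_allele implies a classification from the earlier screen"
            )

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.hgvs_c}"


@dataclass(frozen=True)
class StructuralVariantCall:
    """A deletion/duplication/inversion with 1-based inclusive breakpoints.

    Flank sequences, when present, are inner-edge anchored: ``left_flank_seq``
    ends at the left breakpoint and ``right_flank_seq`` begins at the right
    breakpoint, so junction microhomology is a suffix/prefix match.
    """

    case_id: str
    chrom: str
    start: int
    end: int
    svtype: str  # "del" | "dup" | "inv"
    zygosity: Zygosity
    left_flank_seq: Optional[str] = None
    right_flank_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if self.svtype not in ("del", "dup", "inv"):
            raise ValueError(f"unknown svtype {self.svtype!r}")
        for name in ("left_flank_seq", "right_flank_seq"):
            seq = getattr(self, name)
            if seq is not None and not set(seq) <= DNA_ALPHABET:
                bad = sorted(set(seq) - DNA_ALPHABET)
                raise ValueError(f"{name} contains non-DNA characters {bad}")

    @property
    def label(self) -> str:
        return f"SV:{self.chrom}:{self.start}-{self.end}{self.svtype}"


@dataclass(frozen=True)
class RepeatGenotype:
    """Per-allele repeat-unit counts at a short-tandem-repeat locus."""

    case_id: str
    locus: str
    allele_counts: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele_counts", tuple(self.allele_counts))
        if any(c < 1 for c in self.allele_counts):
            raise ValueError("repeat counts must be >= 1")

    @property
    def label(self) -> str:
        return f"STR:{self.locus}[{self.allele_counts[0]}/{self.allele_counts[1]}]"


@dataclass(frozen=True)
class RepeatLocusRange:
    """Normal and pathogenic repeat-count ranges for one locus."""

    locus: str
    normal_min: int
    normal_max: int
    pathogenic_min: int
    pathogenic_max: int

    def __post_init__(self) -> None:
        if not (self.normal_min <= self.normal_max):
            raise ValueError("normal range inverted")
        if not (self.pathogenic_min <= self.pathogenic_max):
            raise ValueError("pathogenic range inverted")
        if self.normal_max >= self.pathogenic_min:
            raise ValueError("normal_max must be < pathogenic_min")


@dataclass(frozen=True)
class GenePanelEntry:
    """One panel gene: span, exons, optional promoter, inheritance mode."""

    gene: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    promoter: Optional[tuple[int, int]] = None
    panel: PanelName = PanelName.ird
    inheritance: Inheritance = Inheritance.AR

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.end < self.start:
            raise ValueError("gene span inverted")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"exon interval inverted: ({s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"exon ({s}, {e}) outside gene span")
        if self.promoter is not None:
            object.__setattr__(self, "promoter", tuple(self.promoter))
            ps, pe = self.promoter
            if pe < ps:
                raise ValueError("promoter interval inverted")


@dataclass(frozen=True)
class Lane:
    """One gel lane fragment: RT-PCR product length and band intensity.

    ``ignore`` marks heteroduplex/artifact bands excluded from
    quantification by the band-table author.
    """

    fragment_length_nt: int
    intensity: float
    ignore: bool = False

    def __post_init__(self) -> None:
        if self.fragment_length_nt <= 0:
            raise ValueError("fragment length must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


class SpliceEventKind(str, Enum):
    pseudoexon_insertion = "pseudoexon_insertion"
    exon_elongation = "exon_elongation"
    exon_skipping = "exon_skipping"
    partial_exon_deletion = "partial_exon_deletion"


@dataclass(frozen=True)
class SpliceEvent:
    """A hypothesized aberrant splicing outcome of known size."""

    kind: SpliceEventKind
    size_nt: int

    def __post_init__(self) -> None:
        if self.size_nt <= 0:
            raise ValueError("event size must be positive")

    @property
    def frame(self) -> str:
        return "in_frame" if self.size_nt % 3 == 0 else "frameshift"


@dataclass(frozen=True)
class SpliceAssayResult:
    """Band table of one midigene/minigene assay: wild-type and mutant lanes."""

    case_id: str
    gene: str
    hgvs_c: str
    wt_construct_lanes: tuple[Lane, ...]
    mut_construct_lanes: tuple[Lane, ...]
    wt_fragment_length: int
    event: Optional[SpliceEvent] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt_construct_lanes", tuple(self.wt_construct_lanes))
        object.__setattr__(self, "mut_construct_lanes", tuple(self.mut_construct_lanes))
        if not self.wt_construct_lanes or not self.mut_construct_lanes:
            raise ValueError("each construct needs at least one lane")
        if self.wt_fragment_length <= 0:
            raise ValueError("wt_fragment_length must be positive")

    @property
    def variant_label(self) -> str:
        return f"{self.gene}:{self.hgvs_c}"


@dataclass
class CaseRecord:
    """One proband with all attached evidence."""

    case_id: str
    phenotype: str
    prior_method: str  # "TCS" | "WES"
    small_variants: list[AnnotatedSmallVariant] = field(default_factory=list)
    svs: list[StructuralVariantCall] = field(default_factory=list)
    repeats: list[RepeatGenotype] = field(default_factory=list)
    assays: list[SpliceAssayResult] = field(default_factory=list)
    genotype_track: Optional[list[tuple[int, bool]]] = None  # (pos, is_het)
    genotype_track_chrom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.prior_method not in ("TCS", "WES"):
            raise ValueError(f"unknown prior method {self.prior_method!r}")
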