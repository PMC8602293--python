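# Methods

## Scope and assumptions

`irdsolve` operates strictly downstream of sequencing and annotation: reads
are assumed aligned, variants called, and every record already annotated
with population frequencies, conservation/deleteriousness scores and splice
predictions. The pipeline never computes a SpliceAI or Alamut score; it
consumes them as inputs, which is why the `SpliceScores` block is optional
per variant (absent for the indel types SpliceAI does not support) and why
an absent annotation is represented as a missing field — a reader that
imputed 0 for a missing allele frequency would silently convert "unreported,
therefore probably rare" into "common", inverting the gate's meaning.

Cases are assumed to be probands with suspected autosomal recessive disease
drawn from a prescreened cohort; each may carry at most one prior candidate
allele per gene from earlier TCS/WES testing. Compound-heterozygous alleles
are assumed in trans unless segregation evidence says otherwise — the
protocol's own working assumption, encoded here as a fixed convention.

## Coordinates and identifiers

Internal coordinates are 1-based inclusive throughout, matching genomic
(`g.`) notation; BED input/output is 0-based half-open and converted
losslessly at the boundary. This makes deletion length exactly
`end − start + 1`, which is the only arithmetic that reconciles a
`g.54106454-54133135` deletion with its reported 26.68-kb size. HGVS `c.`
strings are opaque labels used for joining evidence (assay ↔ variant) and
for reporting; no computation parses them.

## Triage parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `gnomad_max` | 0.01 | fraction | WGS-stage frequency gate |
| `dbsnp_max` | 0.05 | fraction | applied when annotated |
| `inhouse_eur_max` | 0.01 | fraction | applied when annotated |
| `inhouse_asian_max` | 0.02 | fraction | applied when annotated |
| `intronic_max` | 0.01 | fraction | rare-intronic interrogation gate |
| `phylop_min` | 2.7 | — | conservation threshold (range −14.1..6.4) |
| `cadd_min` | 15 | — | CADD-PHRED threshold (range 1..99) |
| `grantham_min` | 80 | — | substitution-distance threshold (0..215) |
| `min_passed_scores` | 2 | count | missense variants passing fewer are dropped |
| `roh_window_het` | 3 | count | max het calls per window |
| `roh_min_snps` | 50 | count | min sites per run (also the window size) |
| `roh_min_kb` | 300 | kb | min physical span per run |

All thresholds are inclusive (`≥`, and `≤` for frequency maxima) and
overridable from YAML. Missing frequency sources never fail the gate;
a missense variant with no scores at all cannot be evaluated and is
excluded from candidacy (the two-of-three rule is uninterpretable without
evidence). Hypomorphic-flagged alleles — partial-loss-of-function variants
pathogenic only in sensitized genotypes, such as HGSNAT p.Ala615Thr — bypass
the frequency and score gates, because their population frequency and score
profile are exactly what the gates would reject.

### ROH contract

A run of homozygosity is an inclusion-maximal interval of the genotype
track holding at least `roh_min_snps` sites, spanning at least `roh_min_kb`,
in which every window of `roh_min_snps` consecutive sites contains at most
`roh_window_het` heterozygous calls. The window size is deliberately tied to
`roh_min_snps`: the protocol names only the three parameters above, and this
is the testable reading (verified against a brute-force enumeration of all
subintervals). Because the window condition is hereditary under shrinking,
maximal runs are found with a two-pointer sweep in O(n). ROH output is
advisory — it flags panel genes wholly inside a run but changes no gate; no
decision rule is tied to it.

## Splice-candidate selection

SpliceAI route: a variant is a candidate when the maximum of its four delta
scores reaches `spliceai_delta_min` (0.02). The comparison is inclusive by
default with a strict (`>`) toggle, since the boundary case is unobservable
from any worked example. Alamut route (only when the SpliceAI block is
absent): at least `alamut_min_algorithms` (2) score pairs must show a gained
site — a mutant-vs-wild-type increase of at least 5% of that algorithm's
scale, or a de novo site (no wild-type score, positive mutant score).
Measuring the gain relative to each algorithm's scale ceiling (100 for
SSFL/HSF, 1 for NNSPLICE) keeps one rule meaningful across heterogeneous
score ranges. The exact published Alamut criteria are not restated in the
protocol's source; this concrete default reproduces every reference
selection and is config-overridable.

## Assay quantification and severity

Fragment percentages are intensity fractions of the non-ignored lanes
(`ignore` marks heteroduplex/artifact bands excluded by the band-table
author). A splice defect is called when the mutant construct's profile
departs from the wild-type construct's: a mutant-only fragment above
`novel_fragment_min_pct` (5 percentage points), or a drop of the
wild-type-length fragment's share by at least the same tolerance. The
profile comparison matters: a minigene whose wild-type construct already
produces a baseline pseudoexon fragment shows a defect through the *loss*
of wild-type product, not through a novel band.

Normalization follows gel-densitometry reporting: both percentages are
rounded to the nearest integer before the ratio (42.0% against 45.6% is
computed as 42/46), the ratio is capped at 100, rounded to the nearest
integer, and reported at one decimal — reproducing 91.0 for that example.
Rounding half away from zero is used for predictability.

Severity: below 25% remaining wild-type fragment is **severe** — the one
biologically anchored cut, defined on mRNA from HEK293T cells. The scale is
completed with **mild** at ≥ 75% (consistent with a 91%-remaining allele
labeled mild) and **moderate** between; both boundaries are
config-overridable, and a total function over [0, 100] is required for the
resolver. The severity describes the mRNA defect in this cell system only;
retina-specific splicing factors can strengthen a defect that HEK293T cells
understate, which is why a no-defect result downgrades a candidate to
likely benign rather than benign.

## SV and repeat interpretation

Gene consequences are computed from interval overlap against the panel's
exon and promoter annotations. Reading-frame effect of an exonic deletion
is the summed deleted coding length modulo 3, treating panel exon intervals
as coding; a whole-gene loss has no frame (unknown) and a promoter-only hit
is regulatory. Junction microhomology is the longest k-suffix of the left
flank equal to the k-prefix of the right flank, both inner-edge anchored;
`N` never matches. Repeat-family (Alu) annotation at breakpoints is out of
scope. Repeat genotypes partition every positive count into
normal / indeterminate / pathogenic-expansion; the indeterminate band is the
literal gap between the published ranges (e.g. 20–36 units at the ATXN7 CAG
locus, normal 3–19, pathogenic 37–460).

## Resolution

Qualification routes per allele: pathogenic / likely-pathogenic
classification; hypomorphic flag; assay severity severe or moderate;
exon-disrupting or whole-gene SV; pathogenic repeat expansion. An
assay-mild allele counts only beside an independently qualifying partner —
a mild splice defect alone is not accepted as a second hit. A no-defect
assay blocks the assay route but never a classification route, which keeps
resolution monotone: adding evidence can promote a case, never demote it.
Recessive genes need summed allele count ≥ 2 (homozygous = 2); dominant and
dominant-with-incomplete-penetrance genes need one qualifying allele.
"Likely solved" is deliberately strict: one pathogenic partner plus a VUS
missense passing **all three** in silico thresholds. X-linked panel entries
are accepted but resolved with the recessive rule (no sex field exists;
hemizygous screening such as RPGR ORF15 is a known gap, not a feature).
When several genes qualify, solved beats likely-solved and ties break
alphabetically for determinism.

## Synthetic cohorts and the reference fixture

The generator (`simulate.generate_cohort`) emulates the evidence structure
the rules consume: causal allele frequencies log-uniform on 1e-6..5e-3;
background frequencies straddling the 1% gate; in silico scores drawn from
benign distributions (PhyloP ≈ 0.5, CADD ≈ 8, Grantham ≈ 40) shifted by
`score_separation` × (4, 20, 90) for causal alleles; SpliceAI deltas below
0.02 for background and 0.1–0.8 above it for causal intronic alleles; assay
band intensities with 5% lognormal noise; planted genotypes spanning the
five solved-case archetypes (biallelic coding 50%, coding + assay-severe
intronic 25%, homozygous exon-deleting SV 8%, dominant whole-gene SV 9%,
repeat expansion 8%). Defaults are 100 cases, causal fraction 0.24,
monoallelic fraction 0.56 — the study conditions the pipeline targets. At
`score_separation = 0`, planted labels degrade to VUS, deltas fall below
threshold, assays show no defect, SVs land in introns and repeats stay in
the normal range, so the solved fraction collapses to zero; both limits are
tested. Property tests use 200-case cohorts; that size separates recall
estimates cleanly while keeping the whole suite around a second.

What the generator does **not** emulate: linkage between sites, realistic
per-gene mutation spectra, annotation errors, caller false positives, or
pedigree structure. Passing recovery tests therefore demonstrates that the
decision logic is faithful to its rules, not that the rules themselves have
a particular sensitivity on real WGS data.

The reference fixture (`fixture.build_paper_fixture`) is fully
deterministic and carries evidence only — resolution labels are never part
of the inputs, so recovering the 24 resolved cases is a genuine end-to-end
computation. Its gene coordinates are a self-consistent miniature
annotation; only the PRPF31-cluster deletion breakpoints are real published
coordinates. The RPGRIP1 junction flank sequences are synthetic,
constructed to carry the reported 12-bp microhomology. The 69 background
cases each fail exactly one gate so that every rejection path is exercised.

## Numerical conventions and degenerate inputs

- Frequency/score thresholds: inclusive comparisons everywhere.
- Lane percentages are clamped to [0, 100] against float rounding.
- All-zero lane intensities, empty Alamut lists, unsorted genotype tracks,
  unknown repeat loci, genes absent from the panel, and duplicate case IDs
  are errors, not silent defaults.
- Candidate ordering ties break by (effect rank, gene, chromosome,
  position, HGVS label); outputs are independent of input record order.

## Known limitations

- Inheritance handling is genotype-only: no sex, no pedigree, no
  segregation modeling; incomplete penetrance is a panel annotation, not a
  model.
- The assay model reads band tables; densitometry from gel images and
  transfection-efficiency correction via control lanes are out of scope.
- ROH flagging assumes a single-chromosome genotype track per case.
- Digenic and regulatory-region mechanisms are not modeled; unresolved in
  this pipeline does not mean unresolvable.
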