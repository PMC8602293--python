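# irdsolve

Variant prioritization, splice-assay interpretation and case resolution for
inherited retinal disease (IRD) whole-genome sequencing cohorts.

## The problem

IRDs are Mendelian disorders of the retina with more than 270 associated
genes. After targeted-capture (TCS) or whole-exome (WES) screening, 30–40%
of cases remain genetically unexplained — frequently because the causal
allele is a deep-intronic splice variant, a structural variant (SV) whose
breakpoints lie in noncoding sequence, or a repeat expansion, none of which
exome-focused assays see reliably. Re-sequencing such cases by WGS produces
annotated variant call sets that still need a disciplined, auditable
decision protocol to turn evidence into diagnoses.

`irdsolve` implements that protocol as a tested, reusable pipeline for
clinical-genetics analysts. It consumes *annotated* evidence (variant calls
with population frequencies, in silico scores and splice predictions; SV and
repeat calls; splice-assay band tables) — it does not call variants or
compute annotation scores.

## The decision rules

**Triage.** Small variants in a gene panel (IRD + ciliopathy genes) are
gated on population allele frequency (gnomAD AF ≤ 1% at the WGS stage;
dbSNP ≤ 5% and in-house database gates apply when annotated). Missense
variants must pass at least two of three in silico thresholds:

    PhyloP ≥ 2.7,  CADD-PHRED ≥ 15,  Grantham ≥ 80

Candidates are ranked by predicted effect: nonsense < frameshift <
canonical splice < noncanonical splice-site (NCSS) < in-frame indel <
missense < synonymous. The search is two-branch: monoallelic cases (one
prior candidate allele from TCS/WES) have SVs and rare intronic variants
(AF < 1%) of the prior gene assessed first; cases without a prior candidate
start from SVs, then SNVs by effect rank. Repeat expansions are screened
for every case. Runs of homozygosity (plink-style: window-het 3, 50 SNPs,
300 kb) are advisory flags.

**Splice candidates.** A noncoding variant is selected for in vitro testing
when any SpliceAI delta score (acceptor/donor gain/loss) reaches 0.02, or —
for indels, which SpliceAI does not score — when at least two
Alamut-embedded algorithms (SSFL, MaxEntScan, GeneSplicer, HSF, NNSPLICE)
show a gained or strengthened splice site.

**Assay interpretation.** RT-PCR band tables from midigene/minigene assays
are quantified (percent of total product per fragment), the wild-type
fragment share of the mutant construct is normalized to the wild-type
construct, and the allele classified: `< 25%` remaining wild-type product is
*severe*, `≥ 75%` *mild*, in between *moderate*; a mutant profile matching
the wild-type construct is *no defect* (allele likely benign).

**SV / repeat interpretation.** Deletion length is `end − start + 1`
(1-based inclusive); gene consequences are whole-gene / multi-exon /
single-exon / promoter-only / intronic-only; junction microhomology is the
longest shared sequence between the inner-edge-anchored breakpoint flanks;
repeat counts are classified against per-locus normal and pathogenic
ranges.

**Resolution.** Autosomal recessive genes need two qualifying alleles
(homozygous counts twice; assay-*mild* alleles count only beside an
independently qualifying partner); dominant genes — including dominant with
incomplete penetrance — are solved by one disrupting SV, repeat expansion
or pathogenic allele; a recessive gene pairing a pathogenic allele with a
VUS missense passing all three thresholds is *likely solved*; everything
else, including candidates whose assay showed no defect, stays unsolved.

## Worked example

The package ships a deterministic 100-case reference cohort containing raw
evidence only (no outcome labels):

```sh
$ ird-solve fixture --out demo/cohort
wrote 100 cases to demo/cohort
$ ird-solve run --cohort demo/cohort --out demo/results
solved_or_likely=24 of 100 (24.0%)
```

24 of the 100 cases resolve — a 24% diagnostic yield. Individual stages can
be inspected; for instance the splice-assay interpretations:

```sh
$ ird-solve assay --cohort demo/cohort
case_id	variant	pct_wt_raw	pct_wt_normalized	severity
Pt-9	EYS:c.5644+70912A>G	0.0	0.0	severe
Pt-14	GRM6:c.1355-587dup	42.0	91.0	mild
Pt-17	HGSNAT:c.493+5G>A	0.0	0.0	severe
Pt-24	USH2A:c.4758+3A>G	21.1	21.0	severe
Pt-24	USH2A:c.784+14389G>T	22.9	23.0	severe
...
```

The GRM6 mutant construct retains 42% wild-type product against 46% in the
wild-type construct, i.e. 91% after normalization: a mild allele. Combined
with the case's prior pathogenic missense allele it completes a biallelic
recessive genotype, so the per-case report
(`demo/results/reports/Pt-14.json`) reads:

```json
{
  "case_id": "Pt-14",
  "status": "solved",
  "causal_gene": "GRM6",
  "causal_alleles": [["GRM6:c.1732C>T", "pathogenic"],
                     ["GRM6:c.1355-587dup", "mild"]],
  "rationale_tags": ["biallelic_lof"]
}
```

Structural variants are interpreted with sizes, gene consequences and
junction microhomology:

```sh
$ ird-solve sv --cohort demo/cohort
case_id	sv	length_bp	genes_hit	microhomology	frame_effect
Pt-22	SV:chr14:5001118-5004617del	3500	RPGRIP1:single_exon	12	frameshift
Pt-23	SV:chr19:54106454-54133135del	26682	PRPF31:whole_gene;TFPT:whole_gene;NDUFA3:promoter_only	.	unknown
```

The 26,682-bp (26.68 kb) heterozygous deletion removes PRPF31 entirely;
because PRPF31 disease is dominant with incomplete penetrance, that single
SV solves the case.

Synthetic cohorts with planted causal genotypes support end-to-end
validation against known truth:

```sh
ird-solve simulate --n 200 --seed 1 --out demo/sim   # truth.json kept separate
ird-solve run --cohort demo/sim --out demo/sim-results
```

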