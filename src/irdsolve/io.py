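"""Readers and writers for the formats the pipeline touches.

Variants travel as annotated VCF 4.2 (annotation INFO keys mapped through a
config-driven dialect, since different annotation pipelines name them
differently) or as an equivalent TSV. Panels are BED4+ (0-based half-open on
disk, converted to the package's 1-based inclusive coordinates). SVs, repeat
genotypes, repeat-range tables and assay band tables are TSV; per-case
reports are JSON; configs are YAML.

Missing annotations are read as absent fields — never imputed as zeros.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .model import (
    AlgorithmScorePair,
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
    SiteKind,
    SpliceAIDeltas,
    SpliceAlgorithm,
    SpliceAssayResult,
    SpliceEvent,
    SpliceEventKind,
    SpliceScores,
    StructuralVariantCall,
    Zygosity,
)

__all__ = [
    "VariantDialect",
    "read_variants",
    "write_variants_tsv",
    "read_panel",
    "write_panel",
    "read_svs_tsv",
    "write_svs_tsv",
    "read_repeats_tsv",
    "write_repeats_tsv",
    "read_repeat_ranges_tsv",
    "write_repeat_ranges_tsv",
    "read_assays_tsv",
    "write_assays_tsv",
    "read_cases_tsv",
    "write_cases_tsv",
    "write_case_report",
    "write_cohort",
    "load_cohort",
]

# Canonical scalar fields of a variant record, in TSV column order.
_VARIANT_COLUMNS = [
    "case_id", "gene", "hgvs_c", "chrom", "pos", "ref", "alt",
    "consequence", "zygosity",
    "gnomad", "dbsnp", "inhouse_eur", "inhouse_asian",
    "phylop", "cadd_phred", "grantham",
    "spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl",
    "alamut", "prior_allele", "classification", "hypomorphic", "splice_event",
]

_FLOAT_FIELDS = {
    "gnomad", "dbsnp", "inhouse_eur", "inhouse_asian",
    "phylop", "cadd_phred", "grantham",
    "spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl",
}


@dataclass(frozen=True)
class VariantDialect:
    """Maps canonical annotation fields to the INFO/column keys of a source.

    The default dialect uses the canonical names themselves. Override
    individual entries (e.g. ``{"gnomad": "gnomad_af"}``) to ingest VCFs
    annotated by a different pipeline.
    """

    keys: dict = field(default_factory=dict)

    def key(self, canonical: str) -> str:
        return self.keys.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "VariantDialect":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"dialect config {path} must be a mapping")
        return cls(keys={str(k): str(v) for k, v in data.items()})


def _parse_alamut(text: str) -> tuple[AlgorithmScorePair, ...]:
    """Decode ``ALGO:site:wt:mut:scale`` entries joined by ``;`` (wt ``.`` = absent)."""
    pairs = []
    for chunk in text.split(";"):
        if not chunk:
            continue
        algo, site, wt, mut, scale = chunk.split(":")
        pairs.append(
            AlgorithmScorePair(
                algorithm=SpliceAlgorithm(algo),
                site_kind=SiteKind(site),
                wt_score=None if wt == "." else float(wt),
                mut_score=float(mut),
                scale_max=float(scale),
            )
        )
    return tuple(pairs)


def _format_alamut(pairs: Sequence[AlgorithmScorePair]) -> str:
    return ";".join(
        ":".join([
            p.algorithm.value, p.site_kind.value,
            "." if p.wt_score is None else repr(p.wt_score),
            repr(p.mut_score), repr(p.scale_max),
        ])
        for p in pairs
    )


def _variant_from_fields(fields: dict, where: str) -> AnnotatedSmallVariant:
    """Build a variant record from canonical-field strings/values.

    ``where`` names the source location (file + line) for error messages.
    """

    def need(name: str) -> str:
        v = fields.get(name)
        if v is None or v == "":
            raise ValueError(f"{where}: missing required field {name!r}")
        return str(v)

    def opt_float(name: str) -> Optional[float]:
        v = fields.get(name)
        if v is None or v == "":
            return None
        try:
            return float(v)
        except (TypeError, ValueError):
            raise ValueError(f"{where}: field {name!r} is not a number: {v!r}")

    cons_text = need("consequence")
    try:
        consequence = Consequence(cons_text)
    except ValueError:
        accepted = ", ".join(c.value for c in Consequence)
        raise ValueError(
            f"{where}: unknown consequence {cons_text!r}; accepted terms: {accepted}"
        )
    try:
        zygosity = Zygosity(need("zygosity"))
    except ValueError:
        raise ValueError(f"{where}: zygosity must be 'het' or 'hom'")

    deltas = {
        "acceptor_gain": opt_float("spliceai_ag"),
        "acceptor_loss": opt_float("spliceai_al"),
        "donor_gain": opt_float("spliceai_dg"),
        "donor_loss": opt_float("spliceai_dl"),
    }
    spliceai = None
    if any(v is not None for v in deltas.values()):
        spliceai = SpliceAIDeltas(**{k: (v or 0.0) for k, v in deltas.items()})
    alamut_text = fields.get("alamut") or ""
    alamut = _parse_alamut(str(alamut_text)) if alamut_text else ()
    splice = None
    if spliceai is not None or alamut:
        splice = SpliceScores(spliceai=spliceai, alamut=alamut)

    cls_text = fields.get("classification") or ""
    classification = Classification(cls_text) if cls_text else None
    event = fields.get("splice_event") or None

    try:
        return AnnotatedSmallVariant(
            case_id=need("case_id"),
            gene=need("gene"),
            hgvs_c=need("hgvs_c"),
            chrom=need("chrom"),
            pos=int(need("pos")),
            ref=need("ref"),
            alt=need("alt"),
            consequence=consequence,
            zygosity=zygosity,
            freqs=PopulationFrequencies(
                gnomad=opt_float("gnomad"),
                dbsnp=opt_float("dbsnp"),
                inhouse_eur=opt_float("inhouse_eur"),
                inhouse_asian=opt_float("inhouse_asian"),
            ),
            scores=InSilicoScores(
                phylop=opt_float("phylop"),
                cadd_phred=opt_float("cadd_phred"),
                grantham=opt_float("grantham"),
            ),
            splice=splice,
            prior_allele=str(fields.get("prior_allele") or "0") in ("1", "true", "True"),
            classification=classification,
            hypomorphic=str(fields.get("hypomorphic") or "0") in ("1", "true", "True"),
            splice_event=str(event) if event else None,
        )
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def read_variants(
    path: str | os.PathLike, dialect: Optional[VariantDialect] = None
) -> list[AnnotatedSmallVariant]:
    """Read annotated small variants from VCF (by extension) or TSV.

    One record per ALT allele; missing annotations become absent fields.
    """
    dialect = dialect or VariantDialect()
    path = Path(path)
    if path.suffix.lower() == ".vcf" or str(path).endswith(".vcf.gz"):
        return _read_variants_vcf(path, dialect)
    return _read_variants_tsv(path, dialect)


def _read_variants_vcf(path: Path, dialect: VariantDialect) -> list[AnnotatedSmallVariant]:
    from cyvcf2 import VCF

    out = []
    vcf = VCF(str(path))
    try:
        for i, rec in enumerate(vcf, start=1):
            alts = rec.ALT or []
            for alt_idx, alt in enumerate(alts):
                fields: dict = {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                }
                for canonical in _VARIANT_COLUMNS:
                    if canonical in fields:
                        continue
                    raw = rec.INFO.get(dialect.key(canonical))
                    if raw is None:
                        continue
                    if isinstance(raw, tuple):  # per-ALT Number=A annotation
                        raw = raw[alt_idx]
                    if isinstance(raw, bytes):
                        raw = raw.decode()
                    fields[canonical] = raw
                where = f"{path.name} record {i} ({rec.CHROM}:{rec.POS})"
                out.append(_variant_from_fields(fields, where))
    finally:
        vcf.close()
    return out


def _read_variants_tsv(path: Path, dialect: VariantDialect) -> list[AnnotatedSmallVariant]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        for lineno, row in enumerate(reader, start=2):
            fields = {c: row.get(dialect.key(c), "") for c in _VARIANT_COLUMNS}
            out.append(_variant_from_fields(fields, f"{path.name} line {lineno}"))
    return out


def write_variants_tsv(
    variants: Iterable[AnnotatedSmallVariant], path: str | os.PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VARIANT_COLUMNS)
        for v in variants:
            sai = v.splice.spliceai if v.splice else None
            alamut = _format_alamut(v.splice.alamut) if v.splice else ""
            row = {
                "case_id": v.case_id,
                "gene": v.gene,
                "hgvs_c": v.hgvs_c,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "consequence": v.consequence.value,
                "zygosity": v.zygosity.value,
                "gnomad": v.freqs.gnomad,
                "dbsnp": v.freqs.dbsnp,
                "inhouse_eur": v.freqs.inhouse_eur,
                "inhouse_asian": v.freqs.inhouse_asian,
                "phylop": v.scores.phylop,
                "cadd_phred": v.scores.cadd_phred,
                "grantham": v.scores.grantham,
                "spliceai_ag": sai.acceptor_gain if sai else None,
                "spliceai_al": sai.acceptor_loss if sai else None,
                "spliceai_dg": sai.donor_gain if sai else None,
                "spliceai_dl": sai.donor_loss if sai else None,
                "alamut": alamut,
                "prior_allele": int(v.prior_allele),
                "classification": v.classification.value if v.classification else "",
                "hypomorphic": int(v.hypomorphic),
                "splice_event": v.splice_event or "",
            }
            w.writerow(
                ["" if row[c] is None else (repr(row[c]) if c in _FLOAT_FIELDS else row[c])
                 for c in _VARIANT_COLUMNS]
            )


def _interval_to_disk(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def _interval_from_disk(start0: int, end0: int, where: str) -> tuple[int, int]:
    if end0 <= start0:
        raise ValueError(f"{where}: zero-length or inverted interval [{start0}, {end0})")
    return start0 + 1, end0


def read_panel(path: str | os.PathLike) -> list[GenePanelEntry]:
    """Read a gene panel from BED4+ (0-based half-open on disk).

    Columns: chrom, start, end, gene, panel, inheritance, exons, promoter.
    ``exons`` encodes half-open intervals as ``s:e`` joined by ``,``;
    ``promoter`` is one such interval or ``.``.
    """
    path = Path(path)
    entries: list[GenePanelEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path.name} line {lineno}: need >= 4 BED columns")
            where = f"{path.name} line {lineno}"
            chrom, start0, end0, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            start, end = _interval_from_disk(start0, end0, where)
            if gene in seen:
                raise ValueError(f"{where}: duplicate gene name {gene!r}")
            seen.add(gene)
            panel = PanelName(parts[4]) if len(parts) > 4 and parts[4] else PanelName.ird
            inheritance = (
                Inheritance(parts[5]) if len(parts) > 5 and parts[5] else Inheritance.AR
            )
            exons: list[tuple[int, int]] = []
            if len(parts) > 6 and parts[6] not in ("", "."):
                for chunk in parts[6].split(","):
                    s0, e0 = chunk.split(":")
                    exons.append(_interval_from_disk(int(s0), int(e0), where))
            promoter = None
            if len(parts) > 7 and parts[7] not in ("", "."):
                s0, e0 = parts[7].split(":")
                promoter = _interval_from_disk(int(s0), int(e0), where)
            entries.append(
                GenePanelEntry(
                    gene=gene, chrom=chrom, start=start, end=end,
                    exons=tuple(exons), promoter=promoter,
                    panel=panel, inheritance=inheritance,
                )
            )
    return entries


def write_panel(entries: Iterable[GenePanelEntry], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for e in entries:
            s0, e0 = _interval_to_disk(e.start, e.end)
            exons = ",".join(
                "{}:{}".format(*_interval_to_disk(s, en)) for s, en in e.exons
            ) or "."
            promoter = (
                "{}:{}".format(*_interval_to_disk(*e.promoter)) if e.promoter else "."
            )
            fh.write(
                "\t".join(
                    [e.chrom, str(s0), str(e0), e.gene, e.panel.value,
                     e.inheritance.value, exons, promoter]
                )
                + "\n"
            )


_SV_COLUMNS = ["case_id", "chrom", "start", "end", "svtype", "zygosity",
               "left_flank_seq", "right_flank_seq"]


def read_svs_tsv(path: str | os.PathLike) -> list[StructuralVariantCall]:
    out = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                out.append(
                    StructuralVariantCall(
                        case_id=row["case_id"],
                        chrom=row["chrom"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        svtype=row["svtype"],
                        zygosity=Zygosity(row["zygosity"]),
                        left_flank_seq=row.get("left_flank_seq") or None,
                        right_flank_seq=row.get("right_flank_seq") or None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{Path(path).name} line {lineno}: {exc}") from exc
    return out


def write_svs_tsv(svs: Iterable[StructuralVariantCall], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SV_COLUMNS)
        for s in svs:
            w.writerow([s.case_id, s.chrom, s.start, s.end, s.svtype,
                        s.zygosity.value, s.left_flank_seq or "", s.right_flank_seq or ""])


def read_repeats_tsv(path: str | os.PathLike) -> list[RepeatGenotype]:
    out = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                out.append(
                    RepeatGenotype(
                        case_id=row["case_id"],
                        locus=row["locus"],
                        allele_counts=(int(row["allele1"]), int(row["allele2"])),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{Path(path).name} line {lineno}: {exc}") from exc
    return out


def write_repeats_tsv(repeats: Iterable[RepeatGenotype], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["case_id", "locus", "allele1", "allele2"])
        for r in repeats:
            w.writerow([r.case_id, r.locus, r.allele_counts[0], r.allele_counts[1]])


def read_repeat_ranges_tsv(path: str | os.PathLike) -> list[RepeatLocusRange]:
    out = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                out.append(
                    RepeatLocusRange(
                        locus=row["locus"],
                        normal_min=int(row["normal_min"]),
                        normal_max=int(row["normal_max"]),
                        pathogenic_min=int(row["pathogenic_min"]),
                        pathogenic_max=int(row["pathogenic_max"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{Path(path).name} line {lineno}: {exc}") from exc
    return out


def write_repeat_ranges_tsv(
    ranges: Iterable[RepeatLocusRange], path: str | os.PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["locus", "normal_min", "normal_max", "pathogenic_min", "pathogenic_max"])
        for r in ranges:
            w.writerow([r.locus, r.normal_min, r.normal_max,
                        r.pathogenic_min, r.pathogenic_max])


def read_assays_tsv(path: str | os.PathLike) -> list[SpliceAssayResult]:
    """Read band tables: one row per lane, grouped by (case, gene, variant)."""
    groups: dict[tuple, dict] = {}
    order: list[tuple] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                key = (row["case_id"], row["gene"], row["hgvs_c"])
                if key not in groups:
                    order.append(key)
                    event = None
                    if row.get("event_kind"):
                        event = SpliceEvent(
                            kind=SpliceEventKind(row["event_kind"]),
                            size_nt=int(row["event_size"]),
                        )
                    groups[key] = {
                        "wt": [], "mut": [],
                        "wt_fragment_length": int(row["wt_fragment_length"]),
                        "event": event,
                    }
                lane = Lane(
                    fragment_length_nt=int(row["fragment_length_nt"]),
                    intensity=float(row["intensity"]),
                    ignore=row.get("ignore", "0") in ("1", "true", "True"),
                )
                construct = row["construct"]
                if construct not in ("wt", "mut"):
                    raise ValueError(f"construct must be wt or mut, got {construct!r}")
                groups[key][construct].append(lane)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{Path(path).name} line {lineno}: {exc}") from exc
    out = []
    for key in order:
        g = groups[key]
        out.append(
            SpliceAssayResult(
                case_id=key[0], gene=key[1], hgvs_c=key[2],
                wt_construct_lanes=tuple(g["wt"]),
                mut_construct_lanes=tuple(g["mut"]),
                wt_fragment_length=g["wt_fragment_length"],
                event=g["event"],
            )
        )
    return out


def write_assays_tsv(assays: Iterable[SpliceAssayResult], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["case_id", "gene", "hgvs_c", "construct", "fragment_length_nt",
                    "intensity", "ignore", "wt_fragment_length", "event_kind", "event_size"])
        for a in assays:
            for construct, lanes in (("wt", a.wt_construct_lanes),
                                     ("mut", a.mut_construct_lanes)):
                for lane in lanes:
                    w.writerow([
                        a.case_id, a.gene, a.hgvs_c, construct,
                        lane.fragment_length_nt, repr(lane.intensity), int(lane.ignore),
                        a.wt_fragment_length,
                        a.event.kind.value if a.event else "",
                        a.event.size_nt if a.event else "",
                    ])


def read_cases_tsv(path: str | os.PathLike) -> list[CaseRecord]:
    out = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                out.append(
                    CaseRecord(
                        case_id=row["case_id"],
                        phenotype=row["phenotype"],
                        prior_method=row["prior_method"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{Path(path).name} line {lineno}: {exc}") from exc
    return out


def write_cases_tsv(cases: Iterable[CaseRecord], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["case_id", "phenotype", "prior_method"])
        for c in cases:
            w.writerow([c.case_id, c.phenotype, c.prior_method])


def _write_tracks_tsv(cases: Sequence[CaseRecord], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["case_id", "chrom", "pos", "is_het"])
        for c in cases:
            for pos, is_het in c.genotype_track or []:
                w.writerow([c.case_id, c.genotype_track_chrom or "", pos, int(is_het)])


def _read_tracks_tsv(
    path: str | os.PathLike,
) -> dict[str, tuple[Optional[str], list[tuple[int, bool]]]]:
    tracks: dict[str, tuple[Optional[str], list[tuple[int, bool]]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            chrom = row.get("chrom") or None
            if row["case_id"] not in tracks:
                tracks[row["case_id"]] = (chrom, [])
            tracks[row["case_id"]][1].append((int(row["pos"]), row["is_het"] == "1"))
    return tracks


def write_case_report(case: CaseRecord, resolution, path: str | os.PathLike) -> None:
    """Write one machine-readable per-case report (JSON)."""
    doc = {
        "case_id": case.case_id,
        "phenotype": case.phenotype,
        "prior_method": case.prior_method,
        "status": resolution.status,
        "causal_gene": resolution.causal_gene,
        "causal_alleles": [list(a) for a in resolution.causal_alleles],
        "rationale_tags": sorted(resolution.rationale_tags),
        "evidence": resolution.evidence,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Cohort directory bundle


def write_cohort(
    out_dir: str | os.PathLike,
    cases: Sequence[CaseRecord],
    panel: Sequence[GenePanelEntry],
    repeat_ranges: Sequence[RepeatLocusRange],
) -> None:
    """Write a cohort as the file set ``cmd_run`` consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cases_tsv(cases, out / "cases.tsv")
    write_variants_tsv(
        [v for c in cases for v in c.small_variants], out / "variants.tsv"
    )
    write_svs_tsv([s for c in cases for s in c.svs], out / "svs.tsv")
    write_repeats_tsv([r for c in cases for r in c.repeats], out / "repeats.tsv")
    write_assays_tsv([a for c in cases for a in c.assays], out / "assays.tsv")
    write_panel(panel, out / "panel.bed")
    write_repeat_ranges_tsv(repeat_ranges, out / "repeat_ranges.tsv")
    _write_tracks_tsv(cases, out / "roh_tracks.tsv")


def load_cohort(
    in_dir: str | os.PathLike, dialect: Optional[VariantDialect] = None
) -> tuple[list[CaseRecord], list[GenePanelEntry], list[RepeatLocusRange]]:
    """Load a cohort directory and re-attach evidence to its cases."""
    d = Path(in_dir)
    cases = read_cases_tsv(d / "cases.tsv")
    by_id = {c.case_id: c for c in cases}
    if len(by_id) != len(cases):
        raise ValueError("duplicate case_id in cases.tsv")
    for v in read_variants(d / "variants.tsv", dialect):
        by_id[v.case_id].small_variants.append(v)
    for s in read_svs_tsv(d / "svs.tsv"):
        by_id[s.case_id].svs.append(s)
    for r in read_repeats_tsv(d / "repeats.tsv"):
        by_id[r.case_id].repeats.append(r)
    for a in read_assays_tsv(d / "assays.tsv"):
        by_id[a.case_id].assays.append(a)
    tracks_path = d / "roh_tracks.tsv"
    if tracks_path.exists():
        for case_id, (chrom, track) in _read_tracks_tsv(tracks_path).items():
            by_id[case_id].genotype_track = track
            by_id[case_id].genotype_track_chrom = chrom
    panel = read_panel(d / "panel.bed")
    ranges = read_repeat_ranges_tsv(d / "repeat_ranges.tsv")
    return cases, panel, ranges
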