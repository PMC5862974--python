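"""Readers/writers for external formats and the pre-analysis SNV filters.

All point positions are 1-based (VCF convention); all intervals are 0-based
half-open (BED convention). Every conversion between the two happens here.

Variant calls pass through two filters before any analysis:

* :func:`filter_variant_calls` keeps calls with more than ``min_support``
  variant-supporting tags and a variant frequency above ``min_vaf``
  (both strictly).
* :func:`apply_blacklist` removes known germline variants keyed by
  (chrom, pos, ref, alt), e.g. a dbSNP-derived list.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .records import (
    HETEROZYGOUS,
    HOMOZYGOUS,
    UNKNOWN,
    AlleleCount,
    Blacklist,
    GenomicInterval,
    Haplotype,
    ImbalanceCall,
    LongReadObservation,
    MoleculeObservation,
    PhaseBlock,
    RegulatoryCandidate,
    RegulatoryPeak,
    RegulatorySNV,
    SNVRecord,
    TSSCluster,
)

logger = logging.getLogger(__name__)

#: heterozygosity proxy window used when the VCF carries no usable genotype
HET_VAF_WINDOW = (0.2, 0.8)


def sort_key(record) -> tuple[str, int]:
    """Total, stable ordering: chromosome lexicographic, position numeric."""
    return (record.chrom, record.pos)


def classify_genotype(gt_type: Optional[int], vaf: Optional[float]) -> str:
    """Genotype class from a cyvcf2 gt_type, falling back to a VAF window.

    The VAF window (0.2 <= vaf <= 0.8 -> heterozygous) is a proxy used only
    when the genotype field is absent or uninformative.
    """
    if gt_type == 1:  # HET
        return HETEROZYGOUS
    if gt_type in (0, 2):  # HOM_REF / HOM_ALT
        return HOMOZYGOUS
    if vaf is not None:
        lo, hi = HET_VAF_WINDOW
        return HETEROZYGOUS if lo <= vaf <= hi else HOMOZYGOUS
    return UNKNOWN


def read_vcf(path) -> list[SNVRecord]:
    """Read SNVs/indels from a VCF 4.x file.

    Multi-allelic rows are split into one record per ALT allele. Support and
    VAF come from AD-style depths when present, else from an INFO ``VAF``
    tag, else they are left unset. Malformed rows raise with the body line
    number.
    """
    records: list[SNVRecord] = []
    vcf = VCF(str(path))
    for lineno, var in enumerate(vcf, start=1):
        try:
            ad = None
            try:
                fmt_ad = var.format("AD")
                if fmt_ad is not None:
                    ad = [int(x) for x in fmt_ad[0]]
            except KeyError:
                ad = None
            gt_type = var.gt_types[0] if len(var.gt_types) else None
            depth = sum(a for a in ad if a >= 0) if ad else None
            for i, alt in enumerate(var.ALT):
                support = vaf = None
                if ad is not None and len(ad) > i + 1:
                    support = ad[i + 1]
                    if depth:
                        vaf = support / depth
                if vaf is None:
                    info_vaf = var.INFO.get("VAF")
                    if info_vaf is not None:
                        vaf = float(info_vaf)
                records.append(
                    SNVRecord(
                        chrom=var.CHROM,
                        pos=var.POS,
                        ref=var.REF,
                        alt=alt,
                        support=support,
                        vaf=vaf,
                        qual=var.QUAL,
                        genotype_class=classify_genotype(gt_type, vaf),
                    )
                )
        except Exception as exc:  # noqa: BLE001 - re-raise with location
            raise ValueError(f"{path}: malformed VCF body row {lineno}: {exc}") from exc
    records.sort(key=sort_key)
    return records


def write_vcf(path, records: Sequence[SNVRecord], sample: str = "SAMPLE") -> None:
    """Write records as a minimal single-sample VCF 4.2 file."""
    chroms = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for r in sorted(records, key=sort_key):
            gt = {HETEROZYGOUS: "0/1", HOMOZYGOUS: "1/1"}.get(r.genotype_class, "./.")
            support = r.support if r.support is not None else 0
            if r.vaf:
                dp = max(round(support / r.vaf), support)
            else:
                dp = support
            ad = f"{dp - support},{support}"
            qual = f"{r.qual:g}" if r.qual is not None else "."
            info = f"VAF={r.vaf!r}" if r.vaf is not None else "."
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t{info}\tGT:AD\t{gt}:{ad}\n"
            )


def filter_variant_calls(
    records: Iterable[SNVRecord], min_support: int = 5, min_vaf: float = 0.05
) -> list[SNVRecord]:
    """Keep calls with support > min_support AND vaf > min_vaf (both strict).

    Records lacking support or VAF are excluded and counted in a log line.
    """
    kept, missing = [], 0
    for r in records:
        if r.support is None or r.vaf is None:
            missing += 1
            continue
        if r.support > min_support and r.vaf > min_vaf:
            kept.append(r)
    if missing:
        logger.info("filter_variant_calls: %d records lacked support/vaf", missing)
    return kept


def apply_blacklist(records: Iterable[SNVRecord], blacklist: Blacklist) -> list[SNVRecord]:
    """Drop records whose (chrom, pos, ref, alt) key is blacklisted."""
    return [r for r in records if r.key not in blacklist]


def read_blacklist(path) -> Blacklist:
    """Read a germline-variant blacklist TSV: chrom, pos, ref, alt."""
    keys = set()
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            keys.add((row[0], int(row[1]), row[2], row[3]))
    return keys


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals (0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                iv = GenomicInterval(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    label=parts[3] if len(parts) > 3 else "",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# Allele-count table
# ---------------------------------------------------------------------------

_COUNT_COLS = [
    "sample_id", "assay", "chrom", "pos", "ref", "alt",
    "ref_tags", "alt_tags", "library_total",
]


def read_allele_counts(path) -> list[AlleleCount]:
    """Read the per-assay allele tag count TSV."""
    out = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _COUNT_COLS:
            raise ValueError(f"{path}:1: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_COUNT_COLS):
                raise ValueError(f"{path}:{lineno}: expected {len(_COUNT_COLS)} columns")
            try:
                out.append(
                    AlleleCount(
                        sample_id=row[0], assay=row[1], chrom=row[2],
                        pos=int(row[3]), ref=row[4], alt=row[5],
                        ref_tags=int(row[6]), alt_tags=int(row[7]),
                        library_total=int(row[8]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_allele_counts(path, counts: Iterable[AlleleCount]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_COUNT_COLS)
        for c in counts:
            w.writerow([c.sample_id, c.assay, c.chrom, c.pos, c.ref, c.alt,
                        c.ref_tags, c.alt_tags, c.library_total])


# ---------------------------------------------------------------------------
# Molecule / long-read observation tables
# ---------------------------------------------------------------------------

_MOL_COLS = ["molecule_id", "chrom", "pos", "base", "base_qual", "read_qual"]
_LR_COLS = ["read_id", "chrom", "pos", "base", "base_qual", "mapq"]


def read_molecule_table(path) -> list[MoleculeObservation]:
    """Read the linked-read molecule observation TSV.

    A molecule observing the same position twice with conflicting bases is a
    hard error (it violates the one-molecule-one-haplotype premise).
    """
    rows = _read_obs_rows(path, _MOL_COLS)
    out = []
    for (mid, chrom), obs in rows.items():
        quals = {q2 for (_, _, q2) in obs.values()}
        out.append(
            MoleculeObservation(
                molecule_id=mid, chrom=chrom,
                observations={p: (b, q) for p, (b, q, _) in obs.items()},
                read_quality=max(quals),
            )
        )
    out.sort(key=lambda m: (min(m.observations), m.molecule_id))
    return out


def write_molecule_table(path, molecules: Iterable[MoleculeObservation]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_MOL_COLS)
        for m in molecules:
            for pos in sorted(m.observations):
                base, bq = m.observations[pos]
                w.writerow([m.molecule_id, m.chrom, pos, base, f"{bq:g}", f"{m.read_quality:g}"])


def read_long_read_table(path) -> list[LongReadObservation]:
    rows = _read_obs_rows(path, _LR_COLS)
    out = []
    for (rid, chrom), obs in rows.items():
        mapqs = {q2 for (_, _, q2) in obs.values()}
        out.append(
            LongReadObservation(
                read_id=rid, chrom=chrom,
                mapping_quality=max(mapqs),
                observations={p: (b, q) for p, (b, q, _) in obs.items()},
            )
        )
    out.sort(key=lambda r: (min(r.observations), r.read_id))
    return out


def write_long_read_table(path, reads: Iterable[LongReadObservation]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_LR_COLS)
        for r in reads:
            for pos in sorted(r.observations):
                base, bq = r.observations[pos]
                w.writerow([r.read_id, r.chrom, pos, base, f"{bq:g}", f"{r.mapping_quality:g}"])


def _read_obs_rows(path, cols) -> dict[tuple[str, str], dict[int, tuple[str, float, float]]]:
    rows: dict[tuple[str, str], dict[int, tuple[str, float, float]]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != cols:
            raise ValueError(f"{path}:1: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(cols):
                raise ValueError(f"{path}:{lineno}: expected {len(cols)} columns")
            try:
                rid, chrom, pos = row[0], row[1], int(row[2])
                base, bq, rq = row[3], float(row[4]), float(row[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            obs = rows.setdefault((rid, chrom), {})
            if pos in obs and obs[pos][0] != base:
                raise ValueError(
                    f"{path}:{lineno}: conflicting duplicate observation "
                    f"for ({rid}, {pos}): {obs[pos][0]} vs {base}"
                )
            obs[pos] = (base, bq, rq)
    return rows


# ---------------------------------------------------------------------------
# Phase-block table
# ---------------------------------------------------------------------------

_BLOCK_COLS = ["block_id", "chrom", "positions", "hap_index", "alleles", "provenance"]


def write_phase_blocks(path, blocks: Iterable[PhaseBlock]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_BLOCK_COLS)
        for b in blocks:
            pos_s = ",".join(str(p) for p in b.positions)
            for i, hap in enumerate(b.haplotypes):
                alleles = ",".join(hap.alleles[p] for p in b.positions)
                prov = ",".join(hap.provenance.get(p, "direct") for p in b.positions)
                w.writerow([b.block_id, b.chrom, pos_s, i, alleles, prov])


def read_phase_blocks(path) -> list[PhaseBlock]:
    by_block: dict[str, PhaseBlock] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _BLOCK_COLS:
            raise ValueError(f"{path}:1: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_BLOCK_COLS):
                raise ValueError(f"{path}:{lineno}: expected {len(_BLOCK_COLS)} columns")
            bid, chrom = row[0], row[1]
            positions = tuple(int(p) for p in row[2].split(","))
            alleles = row[4].split(",")
            prov = row[5].split(",")
            if bid not in by_block:
                by_block[bid] = PhaseBlock(block_id=bid, chrom=chrom, positions=positions)
            by_block[bid].haplotypes.append(
                Haplotype(
                    alleles=dict(zip(positions, alleles)),
                    provenance=dict(zip(positions, prov)),
                )
            )
    return list(by_block.values())


# ---------------------------------------------------------------------------
# Candidate table
# ---------------------------------------------------------------------------

_CAND_COLS = [
    "sample_id", "block_id", "chrom", "pos", "ref", "alt", "support", "vaf",
    "qual", "genotype_class", "marker", "peak_start", "peak_end", "peak_label",
    "tss_start", "tss_end", "tss_rep", "tss_strand", "tss_tag_count",
    "tss_tags", "tss_transcript", "peak_tss_distance", "target_transcript",
    "chip_calls", "rna_calls", "transcript_snvs", "allele_linkage",
    "direction_concordant", "cpg_overlap", "tad_concordant",
]


def _fmt_opt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(float(x))
    return str(x)


def _parse_opt(s: str, typ):
    return None if s == "" else typ(s)


def _fmt_call(c: ImbalanceCall) -> str:
    return "|".join([
        c.assay, c.chrom, str(c.pos), c.ref, c.alt, repr(float(c.fold_ratio)),
        c.favored_allele, repr(float(c.p_value)), "1" if c.biased else "0",
        "1" if c.is_chrX else "0", c.transcript_id or "",
        "1" if c.indel_warning else "0",
    ])


def _parse_call(s: str, sample_id: str) -> ImbalanceCall:
    f = s.split("|")
    return ImbalanceCall(
        sample_id=sample_id, assay=f[0], chrom=f[1], pos=int(f[2]), ref=f[3],
        alt=f[4], fold_ratio=float(f[5]), favored_allele=f[6],
        p_value=float(f[7]), biased=f[8] == "1", is_chrX=f[9] == "1",
        transcript_id=f[10] or None, indel_warning=f[11] == "1",
    )


def write_candidates(path, candidates: Iterable[RegulatoryCandidate]) -> None:
    """Write regulatory candidates as a TSV (full fidelity round trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_CAND_COLS)
        for c in candidates:
            snv = c.regulatory_snv.snv
            peak = c.regulatory_snv.peak
            tss = peak.assigned_tss
            tags = ";".join(f"{p}:{n}" for p, n in sorted(tss.tags.items())) if tss else ""
            w.writerow([
                c.sample_id, c.block_id, snv.chrom, snv.pos, snv.ref, snv.alt,
                _fmt_opt(snv.support), _fmt_opt(snv.vaf), _fmt_opt(snv.qual),
                snv.genotype_class, peak.marker, peak.peak.start, peak.peak.end,
                peak.peak.label,
                _fmt_opt(tss.start if tss else None),
                _fmt_opt(tss.end if tss else None),
                _fmt_opt(tss.representative_tss if tss else None),
                tss.strand if tss else "",
                _fmt_opt(tss.tag_count if tss else None),
                tags,
                (tss.transcript_id or "") if tss else "",
                _fmt_opt(peak.distance),
                c.regulatory_snv.target_transcript_id or "",
                ";".join(_fmt_call(x) for x in c.chip_calls),
                ";".join(_fmt_call(x) for x in c.rna_calls),
                ";".join(f"{k[0]}|{k[1]}|{k[2]}|{k[3]}" for k in c.transcript_snvs),
                ";".join(f"{a}>{b}" for a, b in sorted(c.allele_linkage.items())),
                "1" if c.direction_concordant else "0",
                _fmt_opt(None if c.cpg_overlap is None else int(c.cpg_overlap)),
                _fmt_opt(None if c.tad_concordant is None else int(c.tad_concordant)),
            ])


def read_candidates(path) -> list[RegulatoryCandidate]:
    out = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _CAND_COLS:
            raise ValueError(f"{path}:1: bad header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_CAND_COLS):
                raise ValueError(f"{path}:{lineno}: expected {len(_CAND_COLS)} columns")
            r = dict(zip(_CAND_COLS, row))
            snv = SNVRecord(
                chrom=r["chrom"], pos=int(r["pos"]), ref=r["ref"], alt=r["alt"],
                support=_parse_opt(r["support"], int),
                vaf=_parse_opt(r["vaf"], float), qual=_parse_opt(r["qual"], float),
                genotype_class=r["genotype_class"],
            )
            tss = None
            if r["tss_start"] != "":
                tags = {}
                if r["tss_tags"]:
                    for item in r["tss_tags"].split(";"):
                        p, n = item.split(":")
                        tags[int(p)] = int(n)
                tss = TSSCluster(
                    chrom=r["chrom"], start=int(r["tss_start"]), end=int(r["tss_end"]),
                    representative_tss=int(r["tss_rep"]), strand=r["tss_strand"],
                    tag_count=int(r["tss_tag_count"]), tags=tags,
                    transcript_id=r["tss_transcript"] or None,
                )
            peak = RegulatoryPeak(
                peak=GenomicInterval(r["chrom"], int(r["peak_start"]),
                                     int(r["peak_end"]), r["peak_label"]),
                marker=r["marker"], assigned_tss=tss,
                distance=_parse_opt(r["peak_tss_distance"], int),
            )
            tr_snvs = []
            if r["transcript_snvs"]:
                for item in r["transcript_snvs"].split(";"):
                    f = item.split("|")
                    tr_snvs.append((f[0], int(f[1]), f[2], f[3]))
            linkage = {}
            if r["allele_linkage"]:
                for item in r["allele_linkage"].split(";"):
                    a, b = item.split(">")
                    linkage[a] = b
            out.append(
                RegulatoryCandidate(
                    sample_id=r["sample_id"],
                    regulatory_snv=RegulatorySNV(
                        snv=snv, peak=peak,
                        target_transcript_id=r["target_transcript"] or None,
                    ),
                    chip_calls=[_parse_call(s, r["sample_id"])
                                for s in r["chip_calls"].split(";") if s],
                    rna_calls=[_parse_call(s, r["sample_id"])
                               for s in r["rna_calls"].split(";") if s],
                    transcript_snvs=tr_snvs,
                    block_id=r["block_id"],
                    allele_linkage=linkage,
                    direction_concordant=r["direction_concordant"] == "1",
                    cpg_overlap=None if r["cpg_overlap"] == "" else r["cpg_overlap"] == "1",
                    tad_concordant=None if r["tad_concordant"] == "" else r["tad_concordant"] == "1",
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def tss_clusters_to_bed(clusters: Iterable[TSSCluster]) -> list[GenomicInterval]:
    """TSS cluster windows as labelled BED intervals."""
    return [
        GenomicInterval(c.chrom, c.start, c.end,
                        label=f"{c.transcript_id or 'TSC'}:{c.representative_tss}:{c.strand}")
        for c in clusters
    ]
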