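"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the structure of the study system: an aneuploid
cancer cell line region carrying ``ploidy`` haplotypes (1-5) over a region
with heterozygous SNVs/indels, sampled by

* barcoded linked-read *molecules* (each molecule derives from exactly one
  haplotype, covers an exponential-length contiguous span and reports the
  haplotype base at each covered het site, with substitution errors),
* error-bearing physical *long reads* (same one-haplotype sampling,
  nanopore-scale spans of ~8 kb by default, per-base identity as in
  nanopore 2D/1D chemistry), and
* per-assay *allele tag counts* (WGS counts follow haplotype copy numbers;
  ChIP/RNA counts optionally silence one haplotype inside a regulatory
  peak and its target transcript by ``effect_fold``).

Region layout (fractions of ``region_length``): a ChIP peak at 10-13%, a
second peak at 20-22%, the target transcript TX1 spanning 40-70% with its
TSS at 40%, and a second transcript TX2 at 72-95% (used as the
imprinted-like transcript in cohort simulations). One TAD spans the whole
region. Everything is deterministic under ``seed``.

What this generator does *not* emulate: GC/mappability bias, PCR
duplicates, read-level sequence content, copy-number heterogeneity along
the region, and partially observed indel alleles (indel markers are
observed all-or-nothing, matching the biallelic-marker assumption of the
phaser).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_core
from .records import (
    HETEROZYGOUS,
    AlleleCount,
    GenomicInterval,
    LongReadObservation,
    MoleculeObservation,
    SNVRecord,
)

BASES = "ACGT"

#: quality score assigned to passing / failing observations (threshold 20)
HIGH_QUAL, LOW_QUAL = 60.0, 10.0
#: mapping qualities for long reads (threshold 10)
HIGH_MAPQ, LOW_MAPQ = 60.0, 5.0

CHIP_MARKERS = ("H3K27ac", "PolII")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study system; defaults mirror its conditions.

    ``ploidy`` defaults to 3 (the average haplotype count per cell line in
    the system emulated); molecule spans are exponential with mean
    ``molecule_length_mean`` capped at 5x the mean.
    """

    seed: int = 0
    ploidy: int = 3
    region_length: int = 60_000
    n_het_sites: int = 12
    indel_fraction: float = 0.1
    molecule_length_mean: int = 30_000
    molecules_per_haplotype: int = 20
    base_error_rate: float = 0.0
    low_quality_fraction: float = 0.0
    long_read_identity: float = 0.9
    long_reads_per_haplotype: int = 10
    long_read_length_mean: int = 8_000
    assay_depth: int = 100
    wgs_depth: int = 60
    effect_haplotype: Optional[int] = None
    effect_fold: float = 10.0
    n_peaks: int = 2
    n_tss: int = 2
    n_samples: int = 1
    chrom: str = "chr1"
    library_total: int = 1_000_000
    ensure_adjacent_coverage: bool = False

    def __post_init__(self) -> None:
        for name in ("indel_fraction", "base_error_rate", "low_quality_fraction",
                     "long_read_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 1 <= self.ploidy <= 5:
            raise ValueError("ploidy must be in 1..5")
        if self.effect_fold < 1.0:
            raise ValueError("effect_fold must be >= 1")
        if self.effect_haplotype is not None and not (
            0 <= self.effect_haplotype < self.ploidy
        ):
            raise ValueError("effect_haplotype out of range")

    def rng(self, *stream) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


@dataclass
class GroundTruth:
    """Everything the generators know and the pipeline must recover."""

    config: SimulationConfig
    reference: str
    haplotypes: list[dict[int, str]]
    snvs: list[SNVRecord]
    peaks: list[GenomicInterval]
    transcripts: list[GenomicInterval]
    tss_positions: dict[str, int]  # transcript id -> 1-based TSS
    tss_tags: list[tuple[str, int, str, int]]
    tads: list[GenomicInterval]
    regulatory_effects: dict[int, tuple[GenomicInterval, str, float]] = field(
        default_factory=dict
    )  # haplotype -> (peak, target transcript, fold)
    imprinted_transcripts: set[str] = field(default_factory=set)

    @property
    def het_positions(self) -> tuple[int, ...]:
        return tuple(sorted(s.pos for s in self.snvs))

    def transcript_of(self, key: tuple) -> Optional[str]:
        chrom, pos = key[0], key[1]
        for t in self.transcripts:
            if t.chrom == chrom and t.contains_point(pos):
                return t.label
        return None

    def haplotype_allele_sets(self, positions: Sequence[int]) -> set[tuple]:
        """Deduplicated truth haplotypes restricted to the given positions."""
        out = set()
        for hap in self.haplotypes:
            out.add(tuple(sorted((p, hap[p]) for p in positions if p in hap)))
        return out


# ---------------------------------------------------------------------------
# Region and variants
# ---------------------------------------------------------------------------

def _sample_positions(rng, lo: int, hi: int, n: int, taken: set[int]) -> list[int]:
    """n positions (1-based) in [lo, hi], pairwise spacing >= 2 incl. taken."""
    if n == 0:
        return []
    if (hi - lo + 1) < 2 * n:
        raise ValueError(
            f"cannot place {n} het sites with 2 bp spacing in [{lo},{hi}]"
        )
    out: list[int] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 10_000 * n:
            raise ValueError("het sites too dense for region")
        p = int(rng.integers(lo, hi + 1))
        if all(abs(p - q) >= 2 for q in out) and all(abs(p - q) >= 2 for q in taken):
            out.append(p)
    return sorted(out)


def simulate_region(config: SimulationConfig) -> GroundTruth:
    """Build the region: reference, haplotypes, variants, annotation."""
    rng = config.rng(0)
    L = config.region_length
    reference = "".join(rng.choice(list(BASES), size=L))

    peak1 = GenomicInterval(config.chrom, int(0.10 * L), int(0.10 * L) + max(2000, L // 30), CHIP_MARKERS[0])
    peak2 = GenomicInterval(config.chrom, int(0.20 * L), int(0.20 * L) + max(1500, L // 40), CHIP_MARKERS[1])
    peaks = [peak1, peak2][: config.n_peaks]
    tss1 = int(0.40 * L) + 1
    tss2 = int(0.72 * L) + 1
    tx1 = GenomicInterval(config.chrom, tss1 - 1, int(0.70 * L), "TX1")
    tx2 = GenomicInterval(config.chrom, tss2 - 1, int(0.95 * L), "TX2")
    transcripts = [tx1, tx2][: config.n_tss]
    tss_positions = {t.label: t.start + 1 for t in transcripts}
    tads = [GenomicInterval(config.chrom, 0, L, "TAD1")]

    if config.ploidy == 1:
        n_peak = n_tx1 = n_tx2 = n_free = 0
    else:
        n = config.n_het_sites
        n_peak = min(max(1, n // 6), n)
        n_tx1 = min(max(2, n // 3), n - n_peak)
        n_tx2 = min(2, max(0, n - n_peak - n_tx1))
        n_free = max(0, n - n_peak - n_tx1 - n_tx2)

    taken: set[int] = set()
    pos_peak = _sample_positions(rng, peak1.start + 1, peak1.end, n_peak, taken)
    taken.update(pos_peak)
    pos_tx1 = _sample_positions(rng, tx1.start + 1, tx1.end, n_tx1, taken)
    taken.update(pos_tx1)
    pos_tx2 = _sample_positions(rng, tx2.start + 1, tx2.end, n_tx2, taken) if len(transcripts) > 1 else []
    taken.update(pos_tx2)
    pos_free = _sample_positions(rng, 1, L - 2, n_free, taken)
    positions = sorted(pos_peak + pos_tx1 + pos_tx2 + pos_free)

    haplotypes: list[dict[int, str]] = [dict() for _ in range(config.ploidy)]
    snvs = []
    for pos in positions:
        ref = reference[pos - 1]
        if rng.random() < config.indel_fraction:
            if rng.random() < 0.5 and pos < L - 1:  # 1-bp deletion, anchored
                ref_allele = reference[pos - 1 : pos + 1]
                alt_allele = reference[pos - 1]
            else:  # 1-2 bp insertion
                ins = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 3))))
                ref_allele, alt_allele = ref, ref + ins
        else:
            ref_allele = ref
            alt_allele = str(rng.choice([b for b in BASES if b != ref]))
        while True:  # het: at least one copy of each allele
            carrier = rng.random(config.ploidy) < 0.5
            if carrier.any() and not carrier.all():
                break
        for h, is_alt in enumerate(carrier):
            haplotypes[h][pos] = alt_allele if is_alt else ref_allele
        alt_copies = int(carrier.sum())
        vaf = alt_copies / config.ploidy
        snvs.append(
            SNVRecord(
                chrom=config.chrom, pos=pos, ref=ref_allele, alt=alt_allele,
                support=round(config.wgs_depth * vaf), vaf=vaf, qual=60.0,
                genotype_class=HETEROZYGOUS,
            )
        )

    tss_tags = []
    tag_rng = config.rng(4)
    for tid, tpos in tss_positions.items():
        tss_tags.append((config.chrom, tpos, "+", 30))
        tss_tags.append((config.chrom, tpos + int(tag_rng.integers(1, 5)), "+", 5))
        tss_tags.append((config.chrom, max(1, tpos - int(tag_rng.integers(1, 5))), "+", 3))

    truth = GroundTruth(
        config=config, reference=reference, haplotypes=haplotypes, snvs=snvs,
        peaks=peaks, transcripts=transcripts, tss_positions=tss_positions,
        tss_tags=tss_tags, tads=tads,
    )
    if config.effect_haplotype is not None and peaks and transcripts:
        truth.regulatory_effects[config.effect_haplotype] = (
            peak1, tx1.label, config.effect_fold
        )
    return truth


# ---------------------------------------------------------------------------
# Linked reads and long reads
# ---------------------------------------------------------------------------

def _observe(rng, truth_base: str, is_indel_site: bool, other_allele: str,
             error_rate: float) -> str:
    if error_rate > 0 and rng.random() < error_rate:
        if is_indel_site:
            return other_allele  # all-or-nothing indel observation
        return str(rng.choice([b for b in BASES if b != truth_base]))
    return truth_base


def _site_info(truth: GroundTruth) -> dict[int, tuple[bool, dict[str, str]]]:
    """pos -> (is_indel, allele -> other allele)."""
    info = {}
    for s in truth.snvs:
        info[s.pos] = (s.is_indel, {s.ref: s.alt, s.alt: s.ref})
    return info


def simulate_linked_reads(truth: GroundTruth, config: SimulationConfig) -> list[MoleculeObservation]:
    """Barcoded molecules sampling one haplotype each over contiguous spans."""
    if config.molecules_per_haplotype < 1:
        raise ValueError("molecules_per_haplotype must be >= 1")
    rng = config.rng(1)
    info = _site_info(truth)
    positions = truth.het_positions
    molecules = []
    counter = 0
    cap = 5.0 * config.molecule_length_mean
    covered_pairs: dict[int, set[tuple[int, int]]] = {
        h: set() for h in range(config.ploidy)
    }
    for h, hap in enumerate(truth.haplotypes):
        for _ in range(config.molecules_per_haplotype):
            length = min(rng.exponential(config.molecule_length_mean), cap)
            start = rng.uniform(-length, config.region_length)
            mol = _molecule_from_span(
                rng, config, hap, info, positions, start, start + length, h,
                counter, covered_pairs,
            )
            counter += 1
            if mol is not None:
                molecules.append(mol)
    if config.ensure_adjacent_coverage:
        for h, hap in enumerate(truth.haplotypes):
            for a, b in zip(positions, positions[1:]):
                if (a, b) in covered_pairs[h]:
                    continue
                mol = _molecule_from_span(
                    rng, config, hap, info, positions, a - 1, b, h, counter,
                    covered_pairs,
                )
                counter += 1
                if mol is not None:
                    molecules.append(mol)
    molecules.sort(key=lambda m: (min(m.observations), m.molecule_id))
    return molecules


def _molecule_from_span(rng, config, hap, info, positions, start, end, hap_idx,
                        counter, covered_pairs) -> Optional[MoleculeObservation]:
    covered = [p for p in positions if start <= p - 1 < end]
    if not covered:
        return None
    obs = {}
    for p in covered:
        is_indel, other = info[p]
        base = _observe(rng, hap[p], is_indel, other[hap[p]], config.base_error_rate)
        bq = LOW_QUAL if rng.random() < config.low_quality_fraction else HIGH_QUAL
        obs[p] = (base, bq)
    rq = LOW_QUAL if rng.random() < config.low_quality_fraction else HIGH_QUAL
    for a, b in zip(covered, covered[1:]):
        covered_pairs[hap_idx].add((a, b))
    return MoleculeObservation(
        molecule_id=f"MI{counter:06d}", chrom=config.chrom,
        observations=obs, read_quality=rq,
    )


def simulate_long_reads(truth: GroundTruth, config: SimulationConfig) -> list[LongReadObservation]:
    """Physical long reads with per-covered-site error = 1 - identity."""
    rng = config.rng(2)
    info = _site_info(truth)
    positions = truth.het_positions
    mean = config.long_read_length_mean
    error_rate = 1.0 - config.long_read_identity
    reads = []
    counter = 0
    for h, hap in enumerate(truth.haplotypes):
        for _ in range(config.long_reads_per_haplotype):
            length = min(rng.exponential(mean), 5.0 * mean)
            start = rng.uniform(-length, config.region_length)
            covered = [p for p in positions if start <= p - 1 < start + length]
            counter += 1
            if not covered:
                continue
            obs = {}
            for p in covered:
                is_indel, other = info[p]
                base = _observe(rng, hap[p], is_indel, other[hap[p]], error_rate)
                bq = LOW_QUAL if rng.random() < config.low_quality_fraction else 30.0
                obs[p] = (base, bq)
            mapq = LOW_MAPQ if rng.random() < config.low_quality_fraction else HIGH_MAPQ
            reads.append(
                LongReadObservation(
                    read_id=f"LR{counter:06d}", chrom=config.chrom,
                    mapping_quality=mapq, observations=obs,
                )
            )
    reads.sort(key=lambda r: (min(r.observations), r.read_id))
    return reads


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

def _weighted_alt_fraction(truth: GroundTruth, pos: int, alt: str,
                           silenced: dict[int, float]) -> float:
    weights = alt_w = 0.0
    for h, hap in enumerate(truth.haplotypes):
        w = silenced.get(h, 1.0)
        weights += w
        if hap[pos] == alt:
            alt_w += w
    return alt_w / weights if weights > 0 else 0.0


def simulate_allele_counts(
    truth: GroundTruth,
    config: SimulationConfig,
    sample_id: str = "S1",
    rng: Optional[np.random.Generator] = None,
    extra_rna_silencing: Optional[dict[str, dict[int, float]]] = None,
) -> list[AlleleCount]:
    """Per-assay ref/alt tag counts for every het site.

    WGS counts are binomial in the haplotype copy-number fraction; ChIP
    counts down-weight the effect haplotype by ``effect_fold`` inside its
    peak; RNA counts do the same inside the target transcript.
    ``extra_rna_silencing`` maps transcript id -> {haplotype: weight} and
    is used by the cohort generator to inject imprinting-like silencing.
    """
    if config.assay_depth < 1:
        raise ValueError("assay_depth must be >= 1")
    rng = rng if rng is not None else config.rng(3)
    counts: list[AlleleCount] = []

    def draw(assay: str, snv: SNVRecord, depth: int, p_alt: float) -> AlleleCount:
        alt = int(rng.binomial(depth, min(max(p_alt, 0.0), 1.0)))
        return AlleleCount(
            sample_id=sample_id, assay=assay, chrom=snv.chrom, pos=snv.pos,
            ref=snv.ref, alt=snv.alt, ref_tags=depth - alt, alt_tags=alt,
            library_total=config.library_total,
        )

    for snv in truth.snvs:
        p_wgs = _weighted_alt_fraction(truth, snv.pos, snv.alt, {})
        counts.append(draw("WGS", snv, config.wgs_depth, p_wgs))

        for peak in truth.peaks:
            if not peak.contains_point(snv.pos):
                continue
            silenced = {
                h: (0.0 if math.isinf(fold) else 1.0 / fold)
                for h, (epeak, _, fold) in truth.regulatory_effects.items()
                if epeak == peak
            }
            p = _weighted_alt_fraction(truth, snv.pos, snv.alt, silenced)
            counts.append(draw(f"ChIP:{peak.label}", snv, config.assay_depth, p))

        tid = truth.transcript_of((snv.chrom, snv.pos))
        if tid is not None:
            silenced = {
                h: (0.0 if math.isinf(fold) else 1.0 / fold)
                for h, (_, target, fold) in truth.regulatory_effects.items()
                if target == tid
            }
            if extra_rna_silencing and tid in extra_rna_silencing:
                for h, w in extra_rna_silencing[tid].items():
                    silenced[h] = min(silenced.get(h, 1.0), w)
            p = _weighted_alt_fraction(truth, snv.pos, snv.alt, silenced)
            counts.append(draw("RNA", snv, config.assay_depth, p))
    return counts


# ---------------------------------------------------------------------------
# Cohorts (for the imprinting filter)
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    truth: GroundTruth
    counts: list[AlleleCount]
    imprinted_transcripts: set[str]
    sample_ids: list[str]


def simulate_cohort(
    config: SimulationConfig, imprinted_sample_fraction: float = 0.4
) -> CohortResult:
    """Shared region, per-sample allele counts, one imprinted-like transcript.

    TX2 has one fixed haplotype silenced in ``imprinted_sample_fraction`` of
    the samples regardless of genotype, exercising the >1/3 imprinting
    filter downstream.
    """
    truth = simulate_region(config)
    imprinted = {"TX2"} if len(truth.transcripts) > 1 else set()
    n_impr = round(imprinted_sample_fraction * config.n_samples)
    counts: list[AlleleCount] = []
    sample_ids = []
    for s in range(config.n_samples):
        sid = f"S{s + 1:02d}"
        sample_ids.append(sid)
        extra = (
            {tid: {0: 0.0} for tid in imprinted} if s < n_impr else None
        )
        counts.extend(
            simulate_allele_counts(
                truth, config, sample_id=sid, rng=config.rng(3, s),
                extra_rna_silencing=extra,
            )
        )
    truth.imprinted_transcripts = imprinted
    return CohortResult(
        truth=truth, counts=counts, imprinted_transcripts=imprinted,
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# Fixture emission (files round-trip through io_core readers)
# ---------------------------------------------------------------------------

def emit_fixture(outdir, config: SimulationConfig) -> dict[str, Path]:
    """Generate a full on-disk fixture for the CLI/pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_region(config)
    molecules = simulate_linked_reads(truth, config)
    long_reads = simulate_long_reads(truth, config)
    counts = simulate_allele_counts(truth, config)

    paths = {
        "vcf": outdir / "variants.vcf",
        "molecules": outdir / "molecules.tsv",
        "long_reads": outdir / "long_reads.tsv",
        "counts": outdir / "allele_counts.tsv",
        "peaks": outdir / "peaks.bed",
        "tads": outdir / "tads.bed",
        "transcripts": outdir / "transcripts.bed",
        "tss_tags": outdir / "tss_tags.tsv",
        "reference": outdir / "reference.fa",
    }
    io_core.write_vcf(paths["vcf"], truth.snvs)
    io_core.write_molecule_table(paths["molecules"], molecules)
    io_core.write_long_read_table(paths["long_reads"], long_reads)
    io_core.write_allele_counts(paths["counts"], counts)
    io_core.write_bed(paths["peaks"], truth.peaks)
    io_core.write_bed(paths["tads"], truth.tads)
    io_core.write_bed(paths["transcripts"], truth.transcripts)
    with open(paths["tss_tags"], "w") as fh:
        fh.write("chrom\tpos\tstrand\tcount\n")
        for chrom, pos, strand, count in truth.tss_tags:
            fh.write(f"{chrom}\t{pos}\t{strand}\t{count}\n")
    io_core.write_fasta(paths["reference"], {config.chrom: truth.reference})
    return paths


def read_tss_tags(path) -> list[tuple[str, int, str, int]]:
    """Read the TSS tag TSV written by :func:`emit_fixture`."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "pos", "strand", "count"]:
            raise ValueError(f"{path}:1: bad header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            out.append((parts[0], int(parts[1]), parts[2], int(parts[3])))
    return out
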