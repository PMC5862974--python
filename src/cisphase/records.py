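"""Shared record types for the cis-regulatory phasing pipeline.

Coordinate conventions (enforced everywhere):

* VCF-style point positions (SNVs, TSSs, molecule observations) are 1-based.
* Intervals (peaks, TADs, transcripts, TSS windows) are BED-style 0-based
  half-open ``[start, end)``.

Conversions between the two live in :mod:`cisphase.io_core`; record types
only validate their own invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

#: genotype classes for called variants
HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
UNKNOWN = "unknown"

#: provenance labels for completed haplotype positions
PROV_DIRECT = "direct"
PROV_GAP_FILLED = "gap_filled"


@dataclass(frozen=True)
class SNVRecord:
    """A called small variant (SNV or anchored indel).

    ``support`` is the number of variant-supporting tags and ``vaf`` the
    variant allele frequency; both may be ``None`` when the caller did not
    provide AD/DP-style fields.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    support: Optional[int] = None
    vaf: Optional[float] = None
    qual: Optional[float] = None
    genotype_class: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNV position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf outside [0,1]: {self.vaf}")
        if self.support is not None and self.support < 0:
            raise ValueError(f"negative support: {self.support}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenomicInterval:
    """A BED-convention interval: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def contains_point(self, pos_1based: int) -> bool:
        """Whether a 1-based point position lies inside the interval."""
        return self.start <= pos_1based - 1 < self.end

    def __len__(self) -> int:
        return self.end - self.start


# A blacklist of known germline variants is just a set of SNV keys.
Blacklist = set


@dataclass
class MoleculeObservation:
    """Bases observed at SNV positions by one barcoded molecule (MI).

    ``observations`` maps 1-based position -> (base, base_quality); the base
    is the full allele string so indel markers stay biallelic.
    """

    molecule_id: str
    chrom: str
    observations: dict[int, tuple[str, float]]
    read_quality: float = 60.0

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"molecule {self.molecule_id} has no observations")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.observations))

    def base_at(self, pos: int) -> str:
        return self.observations[pos][0]


@dataclass
class LongReadObservation:
    """Bases observed at SNV positions by one physical long read."""

    read_id: str
    chrom: str
    mapping_quality: float
    observations: dict[int, tuple[str, float]]

    def __post_init__(self) -> None:
        if self.mapping_quality < 0:
            raise ValueError("mapping_quality must be >= 0")


@dataclass
class PreliminaryHaplotype:
    """A partial allele string formed by merging compatible molecules."""

    alleles: dict[int, str]
    member_mis: frozenset[str]
    block_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.member_mis:
            raise ValueError("preliminary haplotype with no member molecules")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.alleles))

    @property
    def start(self) -> int:
        return min(self.alleles)


@dataclass
class Haplotype:
    """A completed haplotype over all positions of its phase block."""

    alleles: dict[int, str]
    provenance: dict[int, str] = field(default_factory=dict)

    def allele_string(self, positions) -> str:
        return "-".join(self.alleles[p] for p in positions)


@dataclass
class PhaseBlock:
    """A contiguous set of jointly phased heterozygous positions."""

    block_id: str
    chrom: str
    positions: tuple[int, ...]
    haplotypes: list[Haplotype] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.positions), max(self.positions))

    @property
    def span_length(self) -> int:
        lo, hi = self.span
        return hi - lo + 1


SUPPORTED = "supported"
UNSUPPORTED = "unsupported"
UNCOVERED = "uncovered"


@dataclass
class BlockSupport:
    """Long-read validation tally for one phase block."""

    block_id: str
    supportive: int
    unsupportive: int
    uninformative: int
    status: str

    def __post_init__(self) -> None:
        covered = self.supportive + self.unsupportive > 0
        if (self.status == UNCOVERED) == covered:
            raise ValueError("status 'uncovered' iff no informative reads")


@dataclass(frozen=True)
class AlleleCount:
    """Ref/alt tag counts for one SNV in one assay of one sample.

    ``assay`` is ``WGS``, ``RNA`` or ``ChIP:<marker>`` with marker one of
    the eight chromatin marks (H3K4me1, H3K4me3, H3K9me3, H3K9/14ac,
    H3K27ac, H3K27me3, H3K36me3, PolII).
    """

    sample_id: str
    assay: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_tags: int
    alt_tags: int
    library_total: int

    def __post_init__(self) -> None:
        if self.ref_tags < 0 or self.alt_tags < 0:
            raise ValueError("negative tag counts")
        if self.library_total < self.ref_tags + self.alt_tags:
            raise ValueError("library_total smaller than site tag count")

    @property
    def total(self) -> int:
        return self.ref_tags + self.alt_tags

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ImbalanceCall:
    """Allele-bias call for one SNV in one assay, anchored to WGS ratios."""

    sample_id: str
    assay: str
    chrom: str
    pos: int
    ref: str
    alt: str
    fold_ratio: float
    favored_allele: str  # "ref" | "alt"
    p_value: float
    biased: bool
    is_chrX: bool = False
    transcript_id: Optional[str] = None
    indel_warning: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TSSCluster:
    """A 500-bp window of TSS-Seq tags with a representative start site."""

    chrom: str
    start: int  # window, 0-based half-open
    end: int
    representative_tss: int  # 1-based
    strand: str
    tag_count: int
    tags: dict[int, int] = field(default_factory=dict)  # pos -> tag count
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start <= self.representative_tss - 1 < self.end:
            raise ValueError("representative TSS outside cluster window")
        if self.tag_count < 1:
            raise ValueError("empty TSS cluster")


@dataclass
class RegulatoryPeak:
    """A ChIP peak assigned (or not) to its closest TSS cluster."""

    peak: GenomicInterval
    marker: str
    assigned_tss: Optional[TSSCluster] = None
    distance: Optional[int] = None


@dataclass
class RegulatorySNV:
    """An SNV inside an assigned regulatory peak, one record per peak."""

    snv: SNVRecord
    peak: RegulatoryPeak
    target_transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.peak.peak.contains_point(self.snv.pos):
            raise ValueError("regulatory SNV outside its peak")


@dataclass
class Linkage:
    """A phased (regulatory SNV, transcript SNV) pair within one block.

    ``allele_pairs`` holds (regulatory allele, transcript allele) tuples,
    one per completed haplotype of the block.
    """

    reg_snv: RegulatorySNV
    transcript_snv: SNVRecord
    transcript_id: str
    block_id: str
    allele_pairs: list[tuple[str, str]]


@dataclass
class RegulatoryCandidate:
    """A regulatory SNV with concordant evidence across assays."""

    sample_id: str
    regulatory_snv: RegulatorySNV
    chip_calls: list[ImbalanceCall]
    rna_calls: list[ImbalanceCall]
    transcript_snvs: list[tuple[str, int, str, str]]
    block_id: str
    allele_linkage: dict[str, str]  # regulatory allele -> transcript allele
    direction_concordant: bool
    cpg_overlap: Optional[bool] = None
    tad_concordant: Optional[bool] = None
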