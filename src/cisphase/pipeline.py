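"""Single-config orchestration: simulate -> phase -> validate -> imbalance
-> regulatory map -> integrate -> motifs.

The pipeline is a pure function of (inputs, config): no stage mutates
another stage's outputs, every threshold lives in :class:`PipelineConfig`
(defaults are the analysis' canonical rule set), and the manifest records
the seed, config and SHA-256 of every input and output so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import (
    allelic_imbalance,
    integration,
    io_core,
    longread_support,
    motif_annotation,
    phasing,
    regulatory_map,
    synthetic_data,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or malformed stage input (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """All thresholds and paths; defaults are the canonical rule set."""

    outdir: str = "cisphase_run"
    seed: int = 0

    # stage inputs; when simulate=True they are generated into outdir/inputs
    simulate: bool = True
    vcf: Optional[str] = None
    molecules: Optional[str] = None
    long_reads: Optional[str] = None
    allele_counts: Optional[str] = None
    peaks: Optional[str] = None
    tads: Optional[str] = None
    transcripts: Optional[str] = None
    tss_tags: Optional[str] = None
    reference: Optional[str] = None
    blacklist: Optional[str] = None
    pwm_library: Optional[str] = None

    # thresholds (canonical defaults)
    min_support: int = 5
    min_vaf: float = 0.05
    score: float = 20.0
    min_total_tags: int = 4
    fold: float = 5.0
    alpha: float = 0.01
    imprint_fraction: float = 1.0 / 3.0
    max_dist: int = 150_000
    tss_window: int = 500
    mapq: float = 10.0
    baseq: float = 15.0
    mss: float = 0.95
    flank: int = 10

    # mode flags
    longread_mode: str = "2d"
    require_concordance: bool = False
    exclude_chrX: bool = True

    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in (0,1], got {self.alpha}")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ConfigError(f"min_vaf must be in [0,1], got {self.min_vaf}")
        if not 0.0 < self.imprint_fraction <= 1.0:
            raise ConfigError("imprint_fraction must be in (0,1]")
        if self.fold < 1.0:
            raise ConfigError("fold must be >= 1")
        if self.longread_mode not in ("1d", "2d"):
            raise ConfigError(f"longread_mode must be 1d or 2d, got {self.longread_mode!r}")
        if isinstance(self.simulation, dict):
            self.simulation = synthetic_data.SimulationConfig(**self.simulation)

    @classmethod
    def from_yaml(cls, path, overrides: Optional[dict] = None) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides or {})
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Optional[str], stage: str, what: str) -> Path:
    if path is None:
        raise DataError(f"stage {stage}: no path configured for {what}")
    p = Path(path)
    if not p.exists():
        raise DataError(f"stage {stage}: missing input {what}: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim = dataclasses.replace(config.simulation, seed=config.seed)
    if config.simulate:
        inputs = synthetic_data.emit_fixture(outdir / "inputs", sim)
        key_map = {"counts": "allele_counts"}
        for key, p in inputs.items():
            attr = key_map.get(key, key)
            if getattr(config, attr, None) is None and hasattr(config, attr):
                setattr(config, attr, str(p))

    # --- variants -----------------------------------------------------
    vcf_path = _require(config.vcf, "variants", "VCF")
    snvs = io_core.read_vcf(vcf_path)
    snvs = io_core.filter_variant_calls(snvs, config.min_support, config.min_vaf)
    if config.blacklist:
        snvs = io_core.apply_blacklist(
            snvs, io_core.read_blacklist(_require(config.blacklist, "variants", "blacklist"))
        )

    # --- phasing ------------------------------------------------------
    molecules = io_core.read_molecule_table(_require(config.molecules, "phase", "molecule table"))
    result = phasing.phase(snvs, molecules, min_score=config.score)
    io_core.write_phase_blocks(outdir / "phase_blocks.tsv", result.blocks)
    stats = phasing.phase_statistics(result.blocks, result.n_eligible_het)
    _write_json(outdir / "phase_stats.json", stats)

    # --- long-read validation ----------------------------------------
    support_summary = None
    if config.long_reads:
        reads = io_core.read_long_read_table(_require(config.long_reads, "validate", "long reads"))
        supports = longread_support.validate_blocks(
            result.blocks, reads, mode=config.longread_mode, min_mapq=config.mapq
        )
        with open(outdir / "block_support.tsv", "w") as fh:
            fh.write("block_id\tsupportive\tunsupportive\tuninformative\tstatus\n")
            for s in supports:
                fh.write(f"{s.block_id}\t{s.supportive}\t{s.unsupportive}\t"
                         f"{s.uninformative}\t{s.status}\n")
        support_summary = longread_support.support_summary(supports)
        _write_json(outdir / "block_support_summary.json", support_summary)

    # --- regulatory map ----------------------------------------------
    peaks = io_core.read_bed(_require(config.peaks, "regmap", "peaks BED"))
    transcripts = io_core.read_bed(_require(config.transcripts, "regmap", "transcripts BED"))
    tss_tags = synthetic_data.read_tss_tags(_require(config.tss_tags, "regmap", "TSS tags"))
    clusters = regulatory_map.cluster_tss(tss_tags, window=config.tss_window)
    regulatory_map.label_clusters_with_transcripts(clusters, transcripts)
    reg_peaks = regulatory_map.assign_peaks_to_tss(peaks, clusters, max_dist=config.max_dist)
    reg_snvs = regulatory_map.identify_regulatory_snvs(snvs, reg_peaks)

    # --- allelic imbalance -------------------------------------------
    counts = io_core.read_allele_counts(_require(config.allele_counts, "imbalance", "allele counts"))
    transcript_of = {}
    for s in snvs:
        for t in transcripts:
            if t.chrom == s.chrom and t.contains_point(s.pos):
                transcript_of[s.key] = t.label
                break
    calls = allelic_imbalance.call_assay_imbalance(
        counts, fold=config.fold, alpha=config.alpha,
        min_total=config.min_total_tags, transcript_of=transcript_of,
    )
    n_samples = len({c.sample_id for c in counts})
    calls, imprinted = allelic_imbalance.filter_imprinted(
        calls, n_samples, fraction=config.imprint_fraction
    )
    calls = allelic_imbalance.flag_sex_chromosome(calls)

    # --- integration --------------------------------------------------
    transcript_snvs = [
        (s, transcript_of[s.key]) for s in snvs if s.key in transcript_of
    ]
    linkages = integration.link_regulatory_to_transcript(
        result.blocks, reg_snvs, transcript_snvs
    )
    candidates = integration.call_candidates(
        linkages, calls,
        require_concordance=config.require_concordance,
        exclude_chrX=config.exclude_chrX,
    )

    # annotate CpG and TAD concordance when reference/TADs are available
    reference = (
        io_core.read_fasta(config.reference) if config.reference else None
    )
    tads = io_core.read_bed(config.tads) if config.tads else None
    for cand in candidates:
        snv = cand.regulatory_snv.snv
        if reference and snv.chrom in reference:
            seq = reference[snv.chrom]
            if 2 <= snv.pos <= len(seq) - 1:
                cand.cpg_overlap = regulatory_map.cpg_overlap(
                    seq[snv.pos - 2 : snv.pos + 1]
                )
        if tads is not None and cand.regulatory_snv.peak.assigned_tss is not None:
            cand.tad_concordant = regulatory_map.check_tad_concordance(
                snv.pos,
                cand.regulatory_snv.peak.assigned_tss.representative_tss,
                tads, snv.chrom,
            )
    io_core.write_candidates(outdir / "candidates.tsv", candidates)
    summary = integration.summarize_candidates(candidates)
    summary["imprinted_transcripts"] = sorted(imprinted)
    _write_json(outdir / "candidate_summary.json", summary)

    # --- motif annotation --------------------------------------------
    if reference:
        pwms = (
            motif_annotation.read_transfac(config.pwm_library)
            if config.pwm_library
            else motif_annotation.bundled_toy_pwms()
        )
        with open(outdir / "motif_changes.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tgained\tlost\n")
            seen = set()
            for cand in candidates:
                snv = cand.regulatory_snv.snv
                if snv.key in seen or snv.chrom not in reference:
                    continue
                seen.add(snv.key)
                ref_ctx, var_ctx = motif_annotation.build_contexts(
                    reference[snv.chrom], snv.pos, snv.ref, snv.alt,
                    flank=config.flank,
                )
                change = motif_annotation.motif_gain_loss(
                    ref_ctx, var_ctx, pwms, threshold=config.mss,
                    variant_key=snv.key,
                )
                fh.write(
                    f"{snv.chrom}\t{snv.pos}\t{snv.ref}\t{snv.alt}\t"
                    f"{_fmt_set(change.gained)}\t{_fmt_set(change.lost)}\n"
                )

    # --- manifest ------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "inputs": {
            k: _sha256(Path(v))
            for k, v in (
                ("vcf", config.vcf), ("molecules", config.molecules),
                ("long_reads", config.long_reads),
                ("allele_counts", config.allele_counts),
                ("peaks", config.peaks), ("tads", config.tads),
                ("transcripts", config.transcripts),
                ("tss_tags", config.tss_tags), ("reference", config.reference),
            )
            if v and Path(v).exists()
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json"))
            if p.name != "manifest.json"
        },
        "n_candidates": len(candidates),
        "phase_stats": stats,
        "block_support": support_summary,
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def _fmt_set(s) -> str:
    return ";".join(f"{m}:{strand}" for m, strand in sorted(s))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(path, data) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
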