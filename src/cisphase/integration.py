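"""Join phasing, regulatory mapping and imbalance calls into candidates.

A regulatory candidate is a phased (regulatory SNV, transcript SNV) pair
in which the regulatory SNV shows at least one biased ChIP call and a
linked transcript SNV shows a biased RNA call. The phased allele linkage
additionally says whether the chromatin-favored allele rides the same
haplotype as the expression-favored allele (direction concordance); that
flag is reported, and optionally required. chrX candidates are excluded
by default (possible X inactivation rather than somatic regulation).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional, Sequence

from .records import (
    ImbalanceCall,
    Linkage,
    PhaseBlock,
    RegulatoryCandidate,
    RegulatorySNV,
    SNVRecord,
)

#: substitution classes collapsed onto the pyrimidine reference base
_PYRIMIDINE_COLLAPSE = str.maketrans("ACGT", "TGCA")


def link_regulatory_to_transcript(
    blocks: Sequence[PhaseBlock],
    reg_snvs: Sequence[RegulatorySNV],
    transcript_snvs: Sequence[tuple[SNVRecord, str]],
) -> list[Linkage]:
    """Phased pairs of (regulatory SNV, transcript SNV) in the same block.

    ``transcript_snvs`` rows are (snv, transcript_id). Only pairs where the
    transcript is the regulatory peak's assigned target are linked; the
    per-haplotype allele pairing comes from completed haplotypes only.
    """
    pos_to_block: dict[tuple[str, int], PhaseBlock] = {}
    for b in blocks:
        for p in b.positions:
            pos_to_block[(b.chrom, p)] = b
    linkages = []
    for reg in reg_snvs:
        block = pos_to_block.get((reg.snv.chrom, reg.snv.pos))
        if block is None:
            continue
        for snv, tid in transcript_snvs:
            if tid != reg.target_transcript_id:
                continue
            other = pos_to_block.get((snv.chrom, snv.pos))
            if other is None or other.block_id != block.block_id:
                continue
            pairs = [
                (h.alleles[reg.snv.pos], h.alleles[snv.pos])
                for h in block.haplotypes
            ]
            linkages.append(
                Linkage(
                    reg_snv=reg, transcript_snv=snv, transcript_id=tid,
                    block_id=block.block_id, allele_pairs=pairs,
                )
            )
    return linkages


def _favored_base(call: ImbalanceCall) -> str:
    return call.alt if call.favored_allele == "alt" else call.ref


def call_candidates(
    linkages: Sequence[Linkage],
    imbalance_calls: Sequence[ImbalanceCall],
    require_concordance: bool = False,
    exclude_chrX: bool = True,
) -> list[RegulatoryCandidate]:
    """Emit candidates from linkages with biased ChIP and biased RNA calls.

    The imprinting filter must already have been applied to the RNA calls.
    Direction concordance holds when some completed haplotype carries both
    the chromatin-favored regulatory allele and the expression-favored
    transcript allele.
    """
    chip_by_key: dict[tuple, list[ImbalanceCall]] = {}
    rna_by_key: dict[tuple, list[ImbalanceCall]] = {}
    for c in imbalance_calls:
        if not c.biased:
            continue
        bucket = chip_by_key if c.assay.startswith("ChIP") else (
            rna_by_key if c.assay == "RNA" else None
        )
        if bucket is not None:
            bucket.setdefault((c.sample_id,) + c.key, []).append(c)

    samples = sorted({c.sample_id for c in imbalance_calls})
    # group linkages by (regulatory SNV, target transcript)
    grouped: dict[tuple, list[Linkage]] = {}
    for lk in linkages:
        grouped.setdefault(
            (lk.reg_snv.snv.key, lk.transcript_id, lk.reg_snv.peak.marker), []
        ).append(lk)

    candidates = []
    for (reg_key, tid, _marker), lks in sorted(grouped.items()):
        reg = lks[0].reg_snv
        if exclude_chrX and reg.snv.chrom in ("chrX", "X"):
            continue
        for sample in samples:
            chip = chip_by_key.get((sample,) + reg_key, [])
            if not chip:
                continue
            rna, tr_keys, concordant = [], [], False
            linkage_map: dict[str, str] = {}
            for lk in lks:
                tr_calls = rna_by_key.get((sample,) + lk.transcript_snv.key, [])
                if not tr_calls:
                    continue
                rna.extend(tr_calls)
                tr_keys.append(lk.transcript_snv.key)
                for reg_allele, tr_allele in lk.allele_pairs:
                    linkage_map[reg_allele] = tr_allele
                    for cc in chip:
                        for rc in tr_calls:
                            if (
                                _favored_base(cc) == reg_allele
                                and _favored_base(rc) == tr_allele
                            ):
                                concordant = True
            if not rna:
                continue
            if require_concordance and not concordant:
                continue
            candidates.append(
                RegulatoryCandidate(
                    sample_id=sample,
                    regulatory_snv=reg,
                    chip_calls=chip,
                    rna_calls=rna,
                    transcript_snvs=tr_keys,
                    block_id=lks[0].block_id,
                    allele_linkage=linkage_map,
                    direction_concordant=concordant,
                )
            )
    return candidates


def summarize_candidates(candidates: Sequence[RegulatoryCandidate]) -> dict:
    """Per-sample counts, substitution spectrum, indel/CpG/TAD fractions.

    Substitution classes are collapsed onto the pyrimidine reference base
    (G>A counts as C>T, etc.); fractions are over unique regulatory SNVs.
    """
    if not candidates:
        return {
            "n_candidates": 0, "n_unique_regulatory_snvs": 0,
            "per_sample": {}, "substitution_spectrum": {},
            "insertion_fraction": 0.0, "deletion_fraction": 0.0,
            "cpg_fraction": None, "tad_concordant_fraction": None,
        }
    per_sample = Counter(c.sample_id for c in candidates)
    unique: dict[tuple, RegulatoryCandidate] = {}
    for c in candidates:
        unique.setdefault(c.regulatory_snv.snv.key, c)
    spectrum: Counter = Counter()
    n_ins = n_del = 0
    for key, c in unique.items():
        snv = c.regulatory_snv.snv
        if len(snv.alt) > len(snv.ref):
            n_ins += 1
        elif len(snv.alt) < len(snv.ref):
            n_del += 1
        else:
            ref, alt = snv.ref, snv.alt
            if ref in "GA":  # collapse purine-ref classes onto pyrimidines
                ref = ref.translate(_PYRIMIDINE_COLLAPSE)
                alt = alt.translate(_PYRIMIDINE_COLLAPSE)
            spectrum[f"{ref}>{alt}"] += 1
    n_unique = len(unique)
    cpg = [c.cpg_overlap for c in unique.values() if c.cpg_overlap is not None]
    tad = [c.tad_concordant for c in unique.values() if c.tad_concordant is not None]
    return {
        "n_candidates": len(candidates),
        "n_unique_regulatory_snvs": n_unique,
        "per_sample": dict(sorted(per_sample.items())),
        "substitution_spectrum": dict(sorted(spectrum.items())),
        "insertion_fraction": n_ins / n_unique,
        "deletion_fraction": n_del / n_unique,
        "cpg_fraction": (sum(cpg) / len(cpg)) if cpg else None,
        "tad_concordant_fraction": (sum(tad) / len(tad)) if tad else None,
    }
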