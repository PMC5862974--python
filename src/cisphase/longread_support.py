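"""Validation of phase blocks against physical long reads.

A long read is *supportive* of a block when the bases it observes at two or
more block positions match at least one of the block's completed haplotypes
at every observed position; it is *unsupportive* when it contradicts every
haplotype; reads that are low quality or cover at most one block position
are *uninformative*. A block is *supported* when supportive reads outnumber
unsupportive reads by strictly more than a factor of two (and at least one
supportive read exists); a block with no informative reads is *uncovered*.

Two run modes mirror nanopore chemistry: 2D reads (~90% identity) use no
base-quality filter; noisier 1D/1D^2 reads (~80% identity) additionally
drop base calls with quality not exceeding 15.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .records import (
    SUPPORTED,
    UNCOVERED,
    UNSUPPORTED,
    BlockSupport,
    LongReadObservation,
    PhaseBlock,
)

SUPPORTIVE = "supportive"
UNSUPPORTIVE = "unsupportive"
UNINFORMATIVE = "uninformative"

DEFAULT_MIN_MAPQ = 10.0
BASEQ_1D = 15.0

#: strict factor by which supportive reads must exceed unsupportive ones
SUPPORT_RATIO = 2.0


def classify_read(
    read: LongReadObservation,
    block: PhaseBlock,
    min_mapq: float = DEFAULT_MIN_MAPQ,
    min_baseq: Optional[float] = None,
) -> str:
    """Classify one long read against a phase block's haplotypes."""
    if read.mapping_quality <= min_mapq:
        return UNINFORMATIVE
    block_positions = set(block.positions)
    obs = {
        pos: base
        for pos, (base, bq) in read.observations.items()
        if pos in block_positions and (min_baseq is None or bq > min_baseq)
    }
    if len(obs) <= 1:
        return UNINFORMATIVE
    for hap in block.haplotypes:
        if all(hap.alleles.get(p) == b for p, b in obs.items()):
            return SUPPORTIVE
    return UNSUPPORTIVE


def assess_block_support(
    block: PhaseBlock,
    reads: Iterable[LongReadObservation],
    min_mapq: float = DEFAULT_MIN_MAPQ,
    min_baseq: Optional[float] = None,
) -> BlockSupport:
    """Tally read classes and apply the >2x support rule."""
    counts = {SUPPORTIVE: 0, UNSUPPORTIVE: 0, UNINFORMATIVE: 0}
    for read in reads:
        counts[classify_read(read, block, min_mapq=min_mapq, min_baseq=min_baseq)] += 1
    sup, unsup = counts[SUPPORTIVE], counts[UNSUPPORTIVE]
    if sup + unsup == 0:
        status = UNCOVERED
    elif sup >= 1 and sup > SUPPORT_RATIO * unsup:
        status = SUPPORTED
    else:
        status = UNSUPPORTED
    return BlockSupport(
        block_id=block.block_id,
        supportive=sup,
        unsupportive=unsup,
        uninformative=counts[UNINFORMATIVE],
        status=status,
    )


def validate_blocks(
    blocks: Sequence[PhaseBlock],
    reads: Sequence[LongReadObservation],
    mode: str = "2d",
    min_mapq: float = DEFAULT_MIN_MAPQ,
) -> list[BlockSupport]:
    """Validate every block; ``mode`` is '2d' (no base filter) or '1d'."""
    if mode not in ("1d", "2d"):
        raise ValueError(f"mode must be '1d' or '2d', got {mode!r}")
    min_baseq = BASEQ_1D if mode == "1d" else None
    return [
        assess_block_support(b, reads, min_mapq=min_mapq, min_baseq=min_baseq)
        for b in blocks
    ]


def support_summary(supports: Sequence[BlockSupport]) -> dict:
    """Aggregate fraction of covered blocks that are supported."""
    covered = [s for s in supports if s.status != UNCOVERED]
    supported = sum(1 for s in covered if s.status == SUPPORTED)
    return {
        "n_blocks": len(supports),
        "n_covered": len(covered),
        "n_supported": supported,
        "fraction_supported": (supported / len(covered)) if covered else 0.0,
    }
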