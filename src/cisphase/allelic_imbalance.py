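"""Allele-biased representation of SNVs in RNA-Seq and ChIP-Seq tag counts.

Each assay's allele ratio is anchored to the whole-genome-sequencing (WGS)
allele ratio of the same site, so copy-number skew present in the genome
itself does not masquerade as a regulatory effect. A site is called biased
when both hold:

* the assay allele ratio differs from the WGS ratio by more than
  ``fold`` (default 5), measured on reads-per-million normalized counts
  with a pseudocount of 0.5, oriented so the fold ratio is >= 1; and
* a two-sided exact binomial test of the assay's alt tags against the WGS
  alt fraction gives p < ``alpha`` (default 0.01).

Transcripts allele-biased in more than a third of samples are treated as
imprinted (parent-of-origin or lineage effects, not somatic regulation)
and removed; chrX calls are flagged for possible X inactivation and are
excluded from candidate calling downstream by default.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

from scipy.stats import binomtest

from .records import AlleleCount, ImbalanceCall

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 4
DEFAULT_FOLD = 5.0
DEFAULT_ALPHA = 0.01
DEFAULT_IMPRINT_FRACTION = 1.0 / 3.0
PSEUDOCOUNT = 0.5


def validate_site(count: AlleleCount, min_total: int = DEFAULT_MIN_TOTAL) -> bool:
    """A site is usable when ref + alt tags strictly exceed ``min_total``."""
    return count.total > min_total


def normalize_per_million(tags: float, library_total: int) -> float:
    """Tags per million mapped tags in the sample/assay library."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return tags * 1e6 / library_total


def log10_plus1(x: float) -> float:
    """Presentation-only transform used for plotting normalized counts."""
    return math.log10(x + 1.0)


def call_imbalance(
    wgs: AlleleCount,
    assay: AlleleCount,
    fold: float = DEFAULT_FOLD,
    alpha: float = DEFAULT_ALPHA,
    transcript_id: Optional[str] = None,
) -> ImbalanceCall:
    """Call allele bias of one assay site against its WGS anchor."""
    if wgs.key != assay.key:
        raise ValueError(f"mismatched SNV keys: {wgs.key} vs {assay.key}")
    a_ref = normalize_per_million(assay.ref_tags, assay.library_total)
    a_alt = normalize_per_million(assay.alt_tags, assay.library_total)
    w_ref = normalize_per_million(wgs.ref_tags, wgs.library_total)
    w_alt = normalize_per_million(wgs.alt_tags, wgs.library_total)
    ratio = ((a_alt + PSEUDOCOUNT) / (a_ref + PSEUDOCOUNT)) / (
        (w_alt + PSEUDOCOUNT) / (w_ref + PSEUDOCOUNT)
    )
    fold_ratio = max(ratio, 1.0 / ratio)
    favored = "alt" if ratio > 1.0 else "ref"
    p_value = _binomial_p(assay.alt_tags, assay.total, wgs.alt_tags, wgs.total)
    biased = fold_ratio > fold and p_value < alpha
    is_indel = len(wgs.ref) != len(wgs.alt)
    if is_indel and biased:
        logger.info(
            "biased indel call at %s:%d %s>%s - indel tag counts can reflect "
            "mapping artifacts; inspect alignments",
            wgs.chrom, wgs.pos, wgs.ref, wgs.alt,
        )
    return ImbalanceCall(
        sample_id=assay.sample_id,
        assay=assay.assay,
        chrom=assay.chrom,
        pos=assay.pos,
        ref=assay.ref,
        alt=assay.alt,
        fold_ratio=fold_ratio,
        favored_allele=favored,
        p_value=p_value,
        biased=biased,
        is_chrX=assay.chrom in ("chrX", "X"),
        transcript_id=transcript_id,
        indel_warning=is_indel,
    )


def _binomial_p(alt: int, total: int, wgs_alt: int, wgs_total: int) -> float:
    """Two-sided exact binomial test of assay alt tags vs the WGS fraction.

    Kept in one place so the statistic behind the p < 0.01 rule can be
    swapped. A degenerate WGS fraction (0 or 1) is stabilised with a 0.5
    pseudocount so the test remains defined.
    """
    p0 = wgs_alt / wgs_total
    if p0 <= 0.0 or p0 >= 1.0:
        p0 = (wgs_alt + PSEUDOCOUNT) / (wgs_total + 2 * PSEUDOCOUNT)
    return float(binomtest(alt, total, p0, alternative="two-sided").pvalue)


def call_assay_imbalance(
    counts: Sequence[AlleleCount],
    fold: float = DEFAULT_FOLD,
    alpha: float = DEFAULT_ALPHA,
    min_total: int = DEFAULT_MIN_TOTAL,
    transcript_of: Optional[dict[tuple, str]] = None,
) -> list[ImbalanceCall]:
    """Pair each non-WGS count with its sample's WGS anchor and call bias.

    Sites whose WGS or assay total does not pass :func:`validate_site` are
    skipped. ``transcript_of`` optionally maps SNV keys to transcript ids
    (used by the imprinting filter).
    """
    wgs_by_key: dict[tuple, AlleleCount] = {
        (c.sample_id,) + c.key: c for c in counts if c.assay == "WGS"
    }
    calls = []
    for c in counts:
        if c.assay == "WGS":
            continue
        anchor = wgs_by_key.get((c.sample_id,) + c.key)
        if anchor is None:
            continue
        if not (validate_site(anchor, min_total) and validate_site(c, min_total)):
            continue
        tid = transcript_of.get(c.key) if transcript_of else None
        calls.append(call_imbalance(anchor, c, fold=fold, alpha=alpha, transcript_id=tid))
    return calls


def filter_imprinted(
    calls: Iterable[ImbalanceCall],
    n_samples: int,
    fraction: float = DEFAULT_IMPRINT_FRACTION,
    known_imprinted: Optional[set[str]] = None,
) -> tuple[list[ImbalanceCall], set[str]]:
    """Remove transcripts allele-biased in more than ``fraction`` of samples.

    A transcript is imprinted-like when the number of samples with at least
    one biased RNA call in it strictly exceeds ``n_samples * fraction``;
    all its calls are removed. Membership in ``known_imprinted`` is logged
    but does not itself remove a transcript.
    """
    calls = list(calls)
    if n_samples < 2:  # an imprinting pattern is undefined for one sample
        return calls, set()
    samples_per_transcript: dict[str, set[str]] = {}
    for c in calls:
        if c.assay == "RNA" and c.biased and c.transcript_id:
            samples_per_transcript.setdefault(c.transcript_id, set()).add(c.sample_id)
    threshold = n_samples * fraction
    imprinted = {
        t for t, samples in samples_per_transcript.items() if len(samples) > threshold
    }
    if known_imprinted:
        overlap = imprinted & known_imprinted
        if overlap:
            logger.info("known imprinted transcripts flagged: %s", sorted(overlap))
    retained = [c for c in calls if c.transcript_id not in imprinted]
    return retained, imprinted


def flag_sex_chromosome(calls: Iterable[ImbalanceCall]) -> list[ImbalanceCall]:
    """Annotate chrX calls (possible X inactivation); nothing is removed."""
    out = []
    for c in calls:
        c.is_chrX = c.chrom in ("chrX", "X")
        out.append(c)
    return out
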