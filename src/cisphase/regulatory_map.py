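"""TSS clustering, peak-to-TSS assignment and regulatory-SNV mapping.

Transcription start sites measured by TSS-Seq are clustered into fixed
500-bp windows per chromosome and strand; clusters from multiple samples
are merged when their windows overlap. ChIP peaks within 150 kb of a
representative TSS become regulatory regions assigned to their closest
TSS; SNVs inside assigned peaks are regulatory SNVs, counted once per
peak. A regulatory SNV and its target TSS are TAD-concordant when one
topologically associated domain contains both.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .records import (
    GenomicInterval,
    RegulatoryPeak,
    RegulatorySNV,
    SNVRecord,
    TSSCluster,
)

DEFAULT_TSS_WINDOW = 500
DEFAULT_MAX_DIST = 150_000


def cluster_tss(
    tags: Sequence[tuple[str, int, str, int]],
    window: int = DEFAULT_TSS_WINDOW,
) -> list[TSSCluster]:
    """Cluster TSS-Seq tags into fixed-width windows.

    ``tags`` rows are (chrom, pos [1-based], strand, count). Windows are
    opened greedily left to right per chromosome/strand: a tag beyond the
    current window's end opens a new window. The representative TSS is the
    modal tag position (ties -> smallest position).
    """
    grouped: dict[tuple[str, str], Counter] = {}
    for chrom, pos, strand, count in tags:
        grouped.setdefault((chrom, strand), Counter())[pos] += count
    clusters = []
    for (chrom, strand), counter in sorted(grouped.items()):
        positions = sorted(counter)
        current: list[int] = []
        win_start = None
        for pos in positions:
            if win_start is None or pos - 1 >= win_start + window:
                if current:
                    clusters.append(_make_cluster(chrom, strand, win_start, window, counter, current))
                win_start = pos - 1
                current = [pos]
            else:
                current.append(pos)
        if current:
            clusters.append(_make_cluster(chrom, strand, win_start, window, counter, current))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def _make_cluster(chrom, strand, win_start, window, counter, members) -> TSSCluster:
    tags = {p: counter[p] for p in members}
    rep = _modal_position(tags)
    return TSSCluster(
        chrom=chrom, start=win_start, end=win_start + window,
        representative_tss=rep, strand=strand,
        tag_count=sum(tags.values()), tags=tags,
    )


def _modal_position(tags: dict[int, int]) -> int:
    best = max(tags.values())
    return min(p for p, n in tags.items() if n == best)


def merge_tss_across_samples(cluster_lists: Iterable[Sequence[TSSCluster]]) -> list[TSSCluster]:
    """Union overlapping same-strand cluster windows across samples.

    Merged windows are connected components of the window-overlap graph;
    the representative TSS is recomputed from the pooled tags.
    """
    all_clusters = [c for lst in cluster_lists for c in lst]
    grouped: dict[tuple[str, str], list[TSSCluster]] = {}
    for c in all_clusters:
        grouped.setdefault((c.chrom, c.strand), []).append(c)
    merged: list[TSSCluster] = []
    for (chrom, strand), clusters in sorted(grouped.items()):
        clusters.sort(key=lambda c: c.start)
        run: list[TSSCluster] = []
        run_end = None
        for c in clusters:
            if run and c.start >= run_end:
                merged.append(_pool(chrom, strand, run))
                run = []
            run.append(c)
            run_end = c.end if run_end is None or len(run) == 1 else max(run_end, c.end)
        if run:
            merged.append(_pool(chrom, strand, run))
    merged.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return merged


def _pool(chrom: str, strand: str, run: Sequence[TSSCluster]) -> TSSCluster:
    if len(run) == 1:
        return run[0]
    tags: Counter = Counter()
    for c in run:
        tags.update(c.tags)
    tids = sorted({c.transcript_id for c in run if c.transcript_id})
    return TSSCluster(
        chrom=chrom,
        start=min(c.start for c in run),
        end=max(c.end for c in run),
        representative_tss=_modal_position(dict(tags)),
        strand=strand,
        tag_count=sum(tags.values()),
        tags=dict(tags),
        transcript_id=tids[0] if tids else None,
    )


def label_clusters_with_transcripts(
    clusters: Sequence[TSSCluster], transcripts: Sequence[GenomicInterval]
) -> None:
    """Attach a transcript id to each cluster whose representative TSS is
    the transcript's annotated start (interval start, label = id)."""
    starts = {(t.chrom, t.start): t.label for t in transcripts}
    for c in clusters:
        tid = starts.get((c.chrom, c.representative_tss - 1))
        if tid is None:
            # fall back: closest transcript start within the cluster window
            for t in transcripts:
                if t.chrom == c.chrom and c.start <= t.start < c.end:
                    tid = t.label
                    break
        if tid is not None:
            c.transcript_id = tid


def assign_peaks_to_tss(
    peaks: Sequence[GenomicInterval],
    clusters: Sequence[TSSCluster],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[RegulatoryPeak]:
    """Assign each peak to its closest representative TSS within max_dist.

    Distance is 0 when the TSS lies inside the peak, else the gap from the
    nearer peak boundary. Ties go to the smaller TSS position. Peaks with
    no TSS in range stay unassigned (and are not regulatory).
    """
    out = []
    for peak in peaks:
        best: Optional[TSSCluster] = None
        best_dist = None
        for c in clusters:
            if c.chrom != peak.chrom:
                continue
            p0 = c.representative_tss - 1  # 0-based
            if peak.start <= p0 < peak.end:
                dist = 0
            elif p0 < peak.start:
                dist = peak.start - p0
            else:
                dist = p0 - (peak.end - 1)
            if dist > max_dist:
                continue
            if (
                best_dist is None
                or dist < best_dist
                or (dist == best_dist and c.representative_tss < best.representative_tss)
            ):
                best, best_dist = c, dist
        out.append(
            RegulatoryPeak(
                peak=peak, marker=peak.label, assigned_tss=best, distance=best_dist
            )
        )
    return out


def identify_regulatory_snvs(
    snvs: Sequence[SNVRecord], regulatory_peaks: Sequence[RegulatoryPeak]
) -> list[RegulatorySNV]:
    """One record per (SNV, assigned peak) pair.

    An SNV inside several assigned peaks is deliberately counted once per
    peak; SNVs in unassigned peaks or outside all peaks are excluded.
    """
    out = []
    for snv in snvs:
        for rp in regulatory_peaks:
            if rp.assigned_tss is None:
                continue
            if rp.peak.chrom == snv.chrom and rp.peak.contains_point(snv.pos):
                out.append(
                    RegulatorySNV(
                        snv=snv, peak=rp,
                        target_transcript_id=rp.assigned_tss.transcript_id,
                    )
                )
    return out


def check_tad_concordance(
    snv_pos: int, tss_pos: int, tads: Sequence[GenomicInterval], chrom: str
) -> Optional[bool]:
    """True iff one TAD contains both the SNV and the TSS (1-based points).

    TADs must not overlap within a chromosome. Returns None ("unassigned")
    when the SNV falls in no TAD.
    """
    tree = IntervalTree()
    for t in tads:
        if t.chrom != chrom:
            continue
        if tree.overlap(t.start, t.end):
            raise ValueError(f"overlapping TADs on {chrom} at {t.start}-{t.end}")
        tree.addi(t.start, t.end, t)
    snv_hits = tree.at(snv_pos - 1)
    if not snv_hits:
        return None
    tad = next(iter(snv_hits)).data
    return tad.contains_point(tss_pos)


def cpg_overlap(context: str, center_index: Optional[int] = None) -> bool:
    """Whether the reference base at ``center_index`` sits in a CpG.

    ``context`` is a reference window covering the SNV and both immediate
    neighbours; the centre defaults to ``len(context) // 2``.
    """
    i = len(context) // 2 if center_index is None else center_index
    up = context[i - 1 : i + 1] if i >= 1 else ""
    down = context[i : i + 2]
    return up.upper() == "CG" or down.upper() == "CG"
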