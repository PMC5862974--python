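"""Match-style PWM scanning and motif gain/loss annotation of variants.

Position weight matrices (TRANSFAC-like flat files, parsed with
Biopython's ``Bio.motifs``) are scored against every window of a variant's
sequence context with the information-weighted matrix similarity score

    I(i)   = sum_b f(i,b) * ln(4 f(i,b))          (0 ln 0 := 0)
    MSS    = (Current - Min) / (Max - Min)

where Current sums ``I(i) * f(i, base_i)`` over positions, and Max/Min use
the per-position maximum/minimum of ``I(i) * f(i, .)``. The consensus
scores exactly 1, the anti-consensus exactly 0. Hits with MSS strictly
above the threshold (default 0.95) on either strand are reported; motif
gain/loss compares the (matrix, strand) hit sets of the reference and
variant contexts, so indel-induced coordinate shifts do not create
spurious pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import motifs as bio_motifs

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_THRESHOLD = 0.95
DEFAULT_FLANK = 10
#: pseudocount added to each count cell before normalization
PSEUDOCOUNT = 0.01


@dataclass
class PWM:
    """A normalized position frequency matrix with Match-style weights."""

    matrix_id: str
    freqs: np.ndarray  # shape (L, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("frequency matrix must be L x 4")
        if np.any(self.freqs < 0):
            raise ValueError("negative frequencies")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows must sum to 1")
        self._info = information_vector(self.freqs)
        weighted = self.freqs * self._info[:, None]
        self._col_max = weighted.max(axis=1)
        self._col_min = weighted.min(axis=1)

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def information(self) -> np.ndarray:
        return self._info

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    @property
    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmin(axis=1))


@dataclass(frozen=True)
class MotifHit:
    matrix_id: str
    offset: int
    strand: str  # "+" | "-"
    mss: float


@dataclass
class MotifChange:
    """Motifs gained/lost by a variant, as (matrix_id, strand) sets."""

    variant_key: tuple
    gained: set[tuple[str, str]]
    lost: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.gained & self.lost:
            raise ValueError("a motif cannot be both gained and lost")


def information_vector(freqs: np.ndarray) -> np.ndarray:
    """Per-position information weights I(i) = sum_b f ln(4f), 0 ln 0 := 0."""
    freqs = np.asarray(freqs, dtype=float)
    if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must be normalized")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(4.0 * freqs), 0.0)
    return terms.sum(axis=1)


def normalize_counts(counts: np.ndarray, pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    """Counts -> frequencies with a small pseudocount per cell."""
    counts = np.asarray(counts, dtype=float) + pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def read_transfac(path) -> list[PWM]:
    """Parse a TRANSFAC-like flat matrix file into PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "transfac")
    pwms = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        pwms.append(PWM(matrix_id=m.get("ID") or m.get("AC") or "PWM", freqs=normalize_counts(counts)))
    return pwms


def bundled_toy_pwms() -> list[PWM]:
    """The small PWM library shipped with the package (ETS and AP-4 style)."""
    ref = resources.files("cisphase.data") / "toy_pwms.dat"
    with resources.as_file(ref) as path:
        return read_transfac(path)


def mss_score(pwm: PWM, window: str) -> float:
    """Matrix similarity score of one window (must equal the PWM length)."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    idx = [BASE_INDEX[b] for b in window.upper()]
    current = float(
        (pwm.information * pwm.freqs[np.arange(pwm.length), idx]).sum()
    )
    max_s = float(pwm._col_max.sum())
    min_s = float(pwm._col_min.sum())
    if max_s == min_s:
        return 1.0
    return (current - min_s) / (max_s - min_s)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def scan_context(
    pwm_library: Sequence[PWM],
    context: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MotifHit]:
    """Score every window of the context on both strands.

    Windows containing non-ACGT characters are skipped. Hits require
    MSS strictly above ``threshold``. Minus-strand offsets refer to the
    plus-strand coordinate of the window start.
    """
    hits = []
    context = context.upper()
    for pwm in pwm_library:
        L = pwm.length
        for strand, seq in (("+", context), ("-", reverse_complement(context))):
            for off in range(len(seq) - L + 1):
                window = seq[off : off + L]
                if any(b not in BASE_INDEX for b in window):
                    continue
                score = mss_score(pwm, window)
                if score > threshold:
                    plus_off = off if strand == "+" else len(context) - L - off
                    hits.append(MotifHit(pwm.matrix_id, plus_off, strand, score))
    hits.sort(key=lambda h: (h.matrix_id, h.offset, h.strand))
    return hits


def build_contexts(
    reference: str, pos: int, ref: str, alt: str, flank: int = DEFAULT_FLANK,
    offset: int = 0,
) -> tuple[str, str]:
    """Reference and variant ±flank contexts around a variant.

    ``reference`` is the chromosome/region sequence, ``pos`` the 1-based
    variant position (minus ``offset`` for region-local sequences). The
    variant context substitutes the alt allele for the ref allele, so
    indels change the context length.
    """
    i = pos - 1 - offset
    if reference[i : i + len(ref)].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at {pos}: expected {ref}, "
            f"found {reference[i:i + len(ref)]}"
        )
    left = reference[max(0, i - flank) : i]
    right = reference[i + len(ref) : i + len(ref) + flank]
    return left + ref + right, left + alt + right


def motif_gain_loss(
    ref_context: str,
    var_context: str,
    pwm_library: Sequence[PWM],
    threshold: float = DEFAULT_THRESHOLD,
    variant_key: tuple = (),
) -> MotifChange:
    """Compare (matrix, strand) hit sets of reference vs variant context."""
    ref_hits = {(h.matrix_id, h.strand) for h in scan_context(pwm_library, ref_context, threshold)}
    var_hits = {(h.matrix_id, h.strand) for h in scan_context(pwm_library, var_context, threshold)}
    return MotifChange(
        variant_key=variant_key,
        gained=var_hits - ref_hits,
        lost=ref_hits - var_hits,
    )
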