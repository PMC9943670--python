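"""PWM scanning with palindrome-aware single-strand counting.

Palindromic motifs (a sequence equal to its reverse complement, like the
CpGpal element ATGCGCAT or the MORE ATGCATATGCAT) score identically on both
strands; scanning both would report every genomic site twice. Palindromic
PWMs are therefore scanned on the plus strand only, mirroring the standard
practice of disabling opposite-strand scanning for such motifs; asymmetric
PWMs are scanned on both strands with the strand reported.

Coordinates are BED-style throughout: 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Pwm",
    "GenomicInterval",
    "MotifHit",
    "MotifOccupancySummary",
    "reverse_complement",
    "is_palindrome",
    "pwm_from_consensus",
    "scan_sequence",
    "fraction_of_peaks_with_motif",
    "motif_cooccurrence",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: Consensus reconstructions of the three POU motifs used throughout:
#: the methylation-prone palindrome, the longer MORE palindrome, and the
#: asymmetric monomeric Octamer site.
CONSENSUS = {
    "CpGpal": "ATGCGCAT",
    "MORE": "ATGCATATGCAT",
    "Octamer": "ATGCAAAT",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; invalid bases raise."""
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid bases: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def is_palindrome(seq: str) -> bool:
    """True iff the sequence equals its reverse complement."""
    s = seq.upper()
    return s == reverse_complement(s)


@dataclass(frozen=True)
class GenomicInterval:
    """BED-style interval: 0-based half-open, strand in {+, -, .}."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in "+-.":
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    score: float
    matched_sequence: str


@dataclass(frozen=True)
class MotifOccupancySummary:
    motif_name: str
    has_motif: tuple[bool, ...]
    n_peaks: int
    fraction_with_motif: float


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix with background and palindromy flag.

    ``matrix`` is (length, 4) over A/C/G/T; rows sum to 1. ``is_palindromic``
    defaults to the palindromy of the consensus (argmax base per position)
    and can be overridden at construction.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    is_palindromic: bool | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 4:
            raise ValueError("PWM must be (length>=4, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1 (tolerance 1e-6)")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any():
            raise ValueError("background must be 4 strictly positive frequencies")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)
        if self.is_palindromic is None:
            object.__setattr__(self, "is_palindromic", is_palindrome(self.consensus))

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    @property
    def log_odds(self) -> np.ndarray:
        # small floor keeps zero-probability cells finite yet prohibitive
        p = np.maximum(self.matrix, 1e-9)
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score(self, window: str) -> float:
        """Log-odds score of one window; NaN if the window contains N."""
        if len(window) != len(self):
            raise ValueError("window length must equal PWM length")
        lo = self.log_odds
        total = 0.0
        for i, base in enumerate(window.upper()):
            j = _BASE_INDEX.get(base)
            if j is None:
                return float("nan")
            total += lo[i, j]
        return total


def pwm_from_consensus(
    name: str, consensus: str, match_prob: float = 0.997
) -> Pwm:
    """Build a near-deterministic PWM from a consensus string.

    The consensus base gets ``match_prob`` at each position, the rest is
    split evenly. These are reconstructions, not measured matrices.
    """
    cons = consensus.upper()
    off = (1.0 - match_prob) / 3.0
    m = np.full((len(cons), 4), off)
    for i, base in enumerate(cons):
        m[i, _BASE_INDEX[base]] = match_prob
    return Pwm(name=name, matrix=m)


def scan_sequence(
    seq: str,
    pwm: Pwm,
    threshold_fraction: float = 0.85,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Sliding-window log-odds scan; hits where score >= fraction of maximum.

    Palindromic PWMs scan the plus strand only (each genomic site reported
    once); asymmetric PWMs scan both strands. Windows containing N are
    skipped. Hits come back sorted by start. ``offset`` shifts reported
    coordinates (for scanning a subsequence of a larger contig).
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError(f"threshold_fraction must be in (0, 1], got {threshold_fraction}")
    s = seq.upper()
    L, W = len(s), len(pwm)
    if L < W:
        return []
    # score all windows vectorized: encode bases, N -> -1 poisons the window
    codes = np.full(L, -1, dtype=np.int8)
    for base, j in _BASE_INDEX.items():
        codes[np.frombuffer(s.encode(), dtype=np.uint8) == ord(base)] = j

    lo = pwm.log_odds
    cutoff = threshold_fraction * pwm.max_score
    n_win = L - W + 1
    win_codes = np.lib.stride_tricks.sliding_window_view(codes, W)
    valid = (win_codes >= 0).all(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("%s: skipped %d windows containing N", pwm.name, n_skipped)

    hits: list[MotifHit] = []

    def collect(strand_lo: np.ndarray, strand: str) -> None:
        scores = np.zeros(n_win)
        cols = np.arange(W)
        safe = np.where(win_codes >= 0, win_codes, 0)
        scores = strand_lo[cols, safe].sum(axis=1)
        for i in np.nonzero(valid & (scores >= cutoff - 1e-9))[0]:
            start = offset + int(i)
            hits.append(
                MotifHit(
                    interval=GenomicInterval(chrom, start, start + W, strand),
                    score=float(scores[i]),
                    matched_sequence=s[i : i + W],
                )
            )

    collect(lo, "+")
    if not pwm.is_palindromic:
        # scoring the window's reverse complement == scoring with the
        # reversed, base-complemented matrix
        collect(lo[::-1, [3, 2, 1, 0]], "-")

    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def _center(iv: GenomicInterval, summit: int | None = None) -> float:
    return float(iv.start + summit) if summit is not None else iv.center


def fraction_of_peaks_with_motif(
    peaks: Sequence[GenomicInterval],
    hits: Sequence[MotifHit],
    window_bp: int = 100,
    motif_name: str = "motif",
    summits: Sequence[int | None] | None = None,
) -> MotifOccupancySummary:
    """Fraction of peaks with a motif hit near the peak center.

    A peak carries the motif if at least one hit center lies within
    ``window_bp / 2`` of the peak center (summit offset if provided, else
    the interval midpoint). Default window 100 bp, matching the standard
    peak-annotation window.
    """
    if not peaks:
        raise ValueError("empty peak set")
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if summits is None:
        summits = [None] * len(peaks)

    by_chrom: dict[str, np.ndarray] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h.interval.center)  # type: ignore[attr-defined]
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}

    half = window_bp / 2.0
    flags = []
    for peak, summit in zip(peaks, summits):
        centers = by_chrom.get(peak.chrom)
        if centers is None or centers.size == 0:
            flags.append(False)
            continue
        c = _center(peak, summit)
        lo = np.searchsorted(centers, c - half, side="left")
        hi = np.searchsorted(centers, c + half, side="right")
        flags.append(hi > lo)
    return MotifOccupancySummary(
        motif_name=motif_name,
        has_motif=tuple(flags),
        n_peaks=len(peaks),
        fraction_with_motif=sum(flags) / len(peaks),
    )


def motif_cooccurrence(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    window_bp: int = 200,
) -> tuple[float, float]:
    """How often an a-site has a b-site nearby.

    Returns ``(fraction_within_window, fraction_direct_overlap)`` over the
    a-hits: the first counts a b-hit center within ``window_bp`` of the
    a-hit center, the second counts actual coordinate intersection. The
    200 bp default matches the window used to ask whether two motif
    repertoires share genomic neighborhoods. For the symmetric statistic,
    call twice with the arguments swapped and combine.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if not hits_a:
        return 0.0, 0.0

    centers: dict[str, np.ndarray] = {}
    spans: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for h in hits_b:
        centers.setdefault(h.interval.chrom, []).append(h.interval.center)  # type: ignore[attr-defined]
    for c in list(centers):
        centers[c] = np.sort(np.asarray(centers[c]))
    for h in hits_b:
        spans.setdefault(h.interval.chrom, ([], []))
        spans[h.interval.chrom][0].append(h.interval.start)  # type: ignore[attr-defined]
        spans[h.interval.chrom][1].append(h.interval.end)  # type: ignore[attr-defined]
    spans = {
        c: (np.asarray(s), np.asarray(e)) for c, (s, e) in spans.items()
    }

    near = overlap = 0
    for h in hits_a:
        iv = h.interval
        cb = centers.get(iv.chrom)
        if cb is not None and cb.size:
            lo = np.searchsorted(cb, iv.center - window_bp, side="left")
            hi = np.searchsorted(cb, iv.center + window_bp, side="right")
            if hi > lo:
                near += 1
        sp = spans.get(iv.chrom)
        if sp is not None and ((sp[0] < iv.end) & (sp[1] > iv.start)).any():
            overlap += 1
    n = len(hits_a)
    return near / n, overlap / n
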