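"""PWM scanning with exact p-values under a zero-order background.

Scores are log2 likelihood ratios against the background.  P-values are
exact tail probabilities of the total score under the background model,
computed by dynamic programming over score bins of 1/1000 bit (column
score distributions convolved position by position).  Both strands are
scanned; windows containing N score those positions as background
(log-odds 0); hits overlapping the blacklist by >= 1 bp are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import GenomicInterval, PWM, PeakSet, sequence_to_codes

DEFAULT_BIN = 1e-3  # bits per score bin


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    interval: GenomicInterval
    score: float  # log2 likelihood ratio
    pvalue: float

    @property
    def strand(self) -> str:
        return self.interval.strand


def log_odds(pwm: PWM) -> np.ndarray:
    """5 x width score table: log2(probs / background), with row 4 (N) = 0."""
    if np.any(pwm.background <= 0):
        raise ValueError("background frequencies must be strictly positive")
    table = np.zeros((5, pwm.width))
    with np.errstate(divide="ignore"):
        table[:4] = np.log2(pwm.probs / pwm.background[:, None])
    if not np.all(np.isfinite(table[:4])):
        raise ValueError(
            f"PWM {pwm.motif_id} has zero probabilities; apply a pseudocount"
        )
    return table


class ScoreDistribution:
    """Exact binned distribution of total window scores under the background."""

    def __init__(self, offset: int, probs: np.ndarray, bin_width: float):
        self.offset = offset  # integer bin index of probs[0]
        self.probs = probs
        self.bin_width = bin_width
        # survival[i] = P(binned score >= offset + i)
        self.survival = np.cumsum(probs[::-1])[::-1]

    def pvalue_binned(self, b: int) -> float:
        """P(binned total score >= b) for an integer bin index."""
        i = b - self.offset
        if i <= 0:
            return 1.0
        if i >= len(self.probs):
            return 0.0
        return float(self.survival[i])

    def pvalue(self, score: float) -> float:
        """P(total score >= score), exact up to one bin of discretization."""
        return self.pvalue_binned(int(np.rint(score / self.bin_width)))

    def bin_threshold(self, p_threshold: float) -> int:
        """Smallest integer bin whose tail probability is <= p_threshold."""
        idx = int(np.searchsorted(-self.survival, -p_threshold, side="left"))
        if idx >= len(self.probs):
            return self.offset + len(self.probs)  # unattainable
        return self.offset + idx

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest binned score whose tail probability is <= p_threshold."""
        b = self.bin_threshold(p_threshold)
        if b >= self.offset + len(self.probs):
            return np.inf
        return b * self.bin_width


def exact_score_distribution(score_table: np.ndarray, background: np.ndarray,
                             bin_width: float = DEFAULT_BIN) -> ScoreDistribution:
    """DP convolution of per-column score distributions under the background.

    Scores are discretized to integer multiples of *bin_width* (rounded to
    nearest); the resulting tail P(score >= s) is exact up to binning.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    width = score_table.shape[1]
    bins = binned_table(score_table[:4], bin_width)  # 4 x width
    lo = int(bins.min(axis=0).sum())
    hi = int(bins.max(axis=0).sum())
    dist = np.zeros(hi - lo + 1)
    # start as a point mass at 0, tracked relative to running minimum
    cur = np.array([1.0])
    cur_off = 0
    for j in range(width):
        col = bins[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(cur) + cmax - cmin)
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift:shift + len(cur)] += background[b] * cur
        cur = new
        cur_off += cmin
    dist[cur_off - lo: cur_off - lo + len(cur)] = cur
    return ScoreDistribution(lo, dist, bin_width)


def _window_scores(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Total score at every window start, vectorized over positions.

    Works for float score tables and integer bin tables alike; the caller
    chooses the dtype of *table*.
    """
    L, w = len(codes), table.shape[1]
    n = L - w + 1
    if n <= 0:
        return np.zeros(0, dtype=table.dtype)
    scores = np.zeros(n, dtype=table.dtype)
    for j in range(w):
        scores += table[codes[j:j + n], j]
    return scores


def binned_table(table: np.ndarray, bin_width: float) -> np.ndarray:
    """Integer per-column score bins: the discretization shared by the DP
    and the scanner, so scan p-values are exactly the DP tail."""
    return np.rint(table / bin_width).astype(np.int64)


def reverse_complement_table(table: np.ndarray) -> np.ndarray:
    """Score table for the reverse strand read on forward coordinates."""
    rc = np.empty_like(table)
    rc[:4] = table[[3, 2, 1, 0], ::-1]
    rc[4] = table[4, ::-1]
    return rc


def scan(genome: Dict[str, str], pwm: PWM, p_threshold: float = 1e-4,
         blacklist: Optional[PeakSet] = None,
         bin_width: float = DEFAULT_BIN) -> List[MotifOccurrence]:
    """Scan both strands of every chromosome for PWM hits with exact p-values.

    Occurrences with p <= p_threshold (inclusive) are kept; those
    overlapping the blacklist by >= 1 bp are removed.  Output is sorted by
    (chrom, start, end) with '+' before '-' at identical coordinates.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    table = log_odds(pwm)
    rc_table = reverse_complement_table(table)
    dists = {
        "+": exact_score_distribution(table, pwm.background, bin_width),
        "-": exact_score_distribution(rc_table, pwm.background, bin_width),
    }
    w = pwm.width
    hits: List[MotifOccurrence] = []
    any_fits = False
    for chrom in sorted(genome):
        seq = genome[chrom]
        if len(seq) < w:
            continue
        any_fits = True
        codes = sequence_to_codes(seq)
        for strand, tab in (("+", table), ("-", rc_table)):
            dist = dists[strand]
            bmin = dist.bin_threshold(p_threshold)
            ibins = binned_table(tab, bin_width)
            bins = _window_scores(codes, ibins)
            raw = _window_scores(codes, tab)
            for i in np.nonzero(bins >= bmin)[0]:
                iv = GenomicInterval(chrom, int(i), int(i) + w, strand)
                hits.append(MotifOccurrence(pwm.motif_id, iv, float(raw[i]),
                                            dist.pvalue_binned(int(bins[i]))))
    if not any_fits:
        warnings.warn(f"motif {pwm.motif_id} is wider than every chromosome")
        return []
    if blacklist is not None and len(blacklist):
        hits = [h for h in hits if not blacklist.overlaps_interval(h.interval)]
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start,
                             h.interval.end, h.interval.strand))
    return hits


def occurrences_to_peakset(hits: Sequence[MotifOccurrence],
                           sample: str = "") -> PeakSet:
    ivs = [h.interval for h in hits]
    scores = [-np.log10(max(h.pvalue, 1e-300)) for h in hits]
    return PeakSet(ivs, sample=sample, scores=scores)
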