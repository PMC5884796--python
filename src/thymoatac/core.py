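"""Core domain containers shared across the pipeline.

All coordinates held in memory are 0-based half-open (BED convention).
Conversion to and from 1-based display coordinates happens only at format
boundaries, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class PeakSet:
    """A coordinate-sorted set of intervals for one sample.

    The constructor sorts its input by (chrom, start, end).  ``merged()``
    returns a new PeakSet in which overlapping and bookended intervals have
    been unioned; many query helpers (containment, overlap) operate on the
    merged representation, which is equivalent for set-membership questions.
    """

    def __init__(
        self,
        intervals: Sequence[GenomicInterval],
        sample: str = "",
        scores: Optional[Sequence[float]] = None,
    ):
        order = sorted(range(len(intervals)), key=lambda i: intervals[i].sort_key())
        self.intervals: List[GenomicInterval] = [intervals[i] for i in order]
        self.sample = sample
        self.scores: Optional[List[float]] = (
            None if scores is None else [float(scores[i]) for i in order]
        )
        if self.scores is not None and len(self.scores) != len(self.intervals):
            raise ValueError("scores length must match intervals length")
        self._index: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def merged(self, sample: Optional[str] = None) -> "PeakSet":
        """Union of intervals, merging overlaps and bookended neighbours."""
        out: List[GenomicInterval] = []
        for iv in self.intervals:
            if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
                if iv.end > out[-1].end:
                    out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
            else:
                out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return PeakSet(out, sample=self.sample if sample is None else sample)

    def _merged_index(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        if self._index is None:
            idx: Dict[str, List[List[int]]] = {}
            for iv in self.merged().intervals:
                idx.setdefault(iv.chrom, [[], []])
                idx[iv.chrom][0].append(iv.start)
                idx[iv.chrom][1].append(iv.end)
            self._index = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in idx.items()
            }
        return self._index

    def contains_interval(self, iv: GenomicInterval) -> bool:
        """True if *iv* is entirely contained in the union of the peaks."""
        idx = self._merged_index()
        if iv.chrom not in idx:
            return False
        starts, ends = idx[iv.chrom]
        i = int(np.searchsorted(starts, iv.start, side="right")) - 1
        return i >= 0 and ends[i] >= iv.end

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        """True if *iv* overlaps the union of the peaks by >= 1 bp."""
        idx = self._merged_index()
        if iv.chrom not in idx:
            return False
        starts, ends = idx[iv.chrom]
        i = int(np.searchsorted(starts, iv.end, side="left")) - 1
        return i >= 0 and ends[i] > iv.start


class CutSiteTrack:
    """Per-base, per-strand Tn5 insertion counts for one sample.

    Counts are stored sparsely as sorted position/count arrays per
    (chrom, strand).  ``total`` is the sum of all insertion events.
    """

    def __init__(self, sample: str = ""):
        self.sample = sample
        self._data: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
        self.total: int = 0

    @classmethod
    def from_sparse(
        cls,
        sample: str,
        data: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]],
    ) -> "CutSiteTrack":
        track = cls(sample)
        for key, (pos, val) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=np.int64)
            if np.any(val < 0):
                raise ValueError("insertion counts must be non-negative")
            order = np.argsort(pos, kind="stable")
            pos, val = pos[order], val[order]
            keep = val > 0
            track._data[key] = (pos[keep], val[keep])
        track.total = int(sum(v.sum() for _, v in track._data.values()))
        return track

    @classmethod
    def from_dense(
        cls, sample: str, dense: Dict[str, Tuple[np.ndarray, np.ndarray]]
    ) -> "CutSiteTrack":
        """Build from per-chromosome dense (plus, minus) count arrays."""
        sparse: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (plus, minus) in dense.items():
            for strand, arr in (("+", plus), ("-", minus)):
                arr = np.asarray(arr)
                pos = np.nonzero(arr)[0]
                sparse[(chrom, strand)] = (pos, arr[pos])
        return cls.from_sparse(sample, sparse)

    def chroms(self) -> List[str]:
        return sorted({c for c, _ in self._data})

    def items(self):
        for key in sorted(self._data):
            yield key, self._data[key]

    def window_counts(
        self, chrom: str, strand: str, start: int, end: int
    ) -> np.ndarray:
        """Dense per-base counts over [start, end) for one strand."""
        out = np.zeros(end - start, dtype=np.int64)
        key = (chrom, strand)
        if key not in self._data:
            return out
        pos, val = self._data[key]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        out[pos[lo:hi] - start] = val[lo:hi]
        return out

    def window_counts_both(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.window_counts(chrom, "+", start, end) + self.window_counts(
            chrom, "-", start, end
        )


@dataclass
class PWM:
    """Position weight matrix: per-column base probabilities over A,C,G,T."""

    motif_id: str
    probs: np.ndarray  # shape (4, width), columns sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # length 4, sums to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.width < 1:
            raise ValueError("probs must be a 4 x width matrix with width >= 1")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        background: Optional[np.ndarray] = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        reg = counts + pseudocount
        probs = reg / reg.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else background
        return cls(motif_id, probs, bg)

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1].copy(), self.background)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


def gc_background(gc: float) -> np.ndarray:
    """Zero-order background base frequencies from a G+C fraction.

    gc=0.417 gives (0.2915, 0.2085, 0.2085, 0.2915) over A,C,G,T.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


@dataclass
class FragmentSet:
    """Sequenced fragments (read pairs) for one library."""

    sample: str
    fragments: List[Tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.fragments:
            if start >= end:
                raise ValueError(f"fragment {chrom}:{start}-{end} has start >= end")

    @property
    def depth(self) -> int:
        return len(self.fragments)

    def chrom_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (sorted starts, sorted ends) arrays for counting."""
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in self.fragments:
            by_chrom.setdefault(chrom, []).append((start, end))
        out = {}
        for chrom, pairs in by_chrom.items():
            starts = np.sort(np.array([p[0] for p in pairs], dtype=np.int64))
            ends = np.sort(np.array([p[1] for p in pairs], dtype=np.int64))
            out[chrom] = (starts, ends)
        return out


def sequence_to_codes(seq: str) -> np.ndarray:
    """Map an ACGTN string to integer codes A=0 C=1 G=2 T=3 N=4."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    table[ord("N")] = 4
    table[ord("n")] = 4
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"non-IUPAC base {bad!r} in sequence")
    return codes.astype(np.int64)


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]
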