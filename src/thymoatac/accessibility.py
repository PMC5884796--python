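"""Master-peak signal matrix construction and the normalization chain.

The chain is: FPKM per master peak -> divide each sample by its TSS
enrichment -> robust IQR scaling per sample, (x - median(X)) / IQR(X) with
type-7 quantiles -> row-wise division by the row maximum.  State is tracked
on the matrix and transitions are only allowed in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import io as tio
from .core import CutSiteTrack, FragmentSet, GenomicInterval, PeakSet

STATES = ("raw_fpkm", "tss_normalized", "iqr_scaled", "row_max_normalized")


@dataclass
class AccessibilityMatrix:
    """Master peaks x samples signal matrix with a recorded state."""

    regions: List[GenomicInterval]
    samples: List[str]
    values: np.ndarray
    state: str = "raw_fpkm"
    flagged: np.ndarray = field(default=None)  # all-zero rows excluded downstream

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError("values shape must be (n_regions, n_samples)")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.flagged is None:
            self.flagged = np.zeros(len(self.regions), dtype=bool)

    def _require_state(self, state: str) -> None:
        if self.state != state:
            raise ValueError(f"matrix must be in state {state!r}, is {self.state!r}")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({
            "chrom": [r.chrom for r in self.regions],
            "start": [r.start for r in self.regions],
            "end": [r.end for r in self.regions],
        })
        for j, s in enumerate(self.samples):
            df[s] = self.values[:, j]
        df["flagged"] = self.flagged.astype(int)
        tio.write_tsv(path, df, comment=f"state={self.state}")

    @classmethod
    def from_tsv(cls, path) -> "AccessibilityMatrix":
        comment = tio.read_tsv_comment(path) or ""
        state = comment.split("state=")[-1] if "state=" in comment else "raw_fpkm"
        df = tio.read_tsv(path)
        samples = [c for c in df.columns if c not in ("chrom", "start", "end", "flagged")]
        regions = [GenomicInterval(c, int(s), int(e))
                   for c, s, e in zip(df["chrom"], df["start"], df["end"])]
        flagged = df["flagged"].to_numpy(bool) if "flagged" in df else None
        return cls(regions, samples, df[samples].to_numpy(float), state, flagged)


def downsample_fragments(libs: Sequence[FragmentSet], seed: int) -> List[FragmentSet]:
    """Down-sample every library to the median input depth.

    Sampling is without replacement at the fragment (read-pair) level, so
    mates are never split; libraries already at or below the median are
    returned unchanged.  The target is floor(median) when the median falls
    between depths.
    """
    if not libs:
        raise ValueError("need at least one library")
    depths = [lib.depth for lib in libs]
    target = int(np.median(depths))
    rng = np.random.default_rng(seed)
    out = []
    for lib in libs:
        if lib.depth <= target:
            out.append(lib)
        else:
            keep = rng.choice(lib.depth, size=target, replace=False)
            keep.sort()
            out.append(FragmentSet(lib.sample, [lib.fragments[i] for i in keep]))
    return out


def make_master_peaks(peak_sets: Sequence[PeakSet]) -> PeakSet:
    """Union of all peak calls with overlapping/bookended intervals merged."""
    if not peak_sets:
        raise ValueError("need at least one PeakSet")
    all_ivs = [iv for ps in peak_sets for iv in ps.intervals]
    return PeakSet(all_ivs, sample="master").merged()


def count_overlapping_fragments(master: PeakSet, lib: FragmentSet) -> np.ndarray:
    """Fragments of *lib* overlapping each master region by >= 1 bp."""
    arrays = lib.chrom_arrays()
    counts = np.zeros(len(master), dtype=np.int64)
    for i, region in enumerate(master.intervals):
        if region.chrom not in arrays:
            continue
        starts, ends = arrays[region.chrom]
        # overlap <=> fragment.start < region.end and fragment.end > region.start
        n_start_ok = np.searchsorted(starts, region.end, side="left")
        n_end_bad = np.searchsorted(ends, region.start, side="right")
        counts[i] = n_start_ok - n_end_bad
    return counts


def fpkm_matrix(master: PeakSet, libs: Sequence[FragmentSet]) -> AccessibilityMatrix:
    """FPKM per master peak: C / (len/1e3 * depth/1e6), any-overlap counting."""
    if not libs:
        raise ValueError("need at least one library")
    lengths = np.array([iv.length for iv in master.intervals], dtype=float)
    values = np.zeros((len(master), len(libs)))
    for j, lib in enumerate(libs):
        if lib.depth == 0:
            raise ValueError(f"library {lib.sample!r} has zero depth")
        counts = count_overlapping_fragments(master, lib)
        values[:, j] = counts / (lengths / 1e3) / (lib.depth / 1e6)
    return AccessibilityMatrix(list(master.intervals), [l.sample for l in libs],
                               values, state="raw_fpkm")


def tss_enrichment(track: CutSiteTrack, tss: Sequence[GenomicInterval],
                   halfwidth: int = 1000, core: int = 250,
                   flank: int = 100) -> float:
    """Signal-to-noise score: TSS-proximal insertion rate over distal flanks.

    Aggregates the per-base insertion profile (both strands) over
    TSS +/- halfwidth, oriented by TSS strand, then divides the mean signal
    within +/- core of the TSS by the mean over the two outermost *flank*
    bp.  A flank total of zero is floored at one pseudo-insertion so the
    score stays finite.
    """
    if not tss:
        raise ValueError("need at least one TSS")
    if halfwidth <= 0 or core <= 0 or flank <= 0 or core + flank > halfwidth:
        raise ValueError("require 0 < core, flank and core + flank <= halfwidth")
    profile = np.zeros(2 * halfwidth + 1, dtype=float)
    for t in tss:
        window = track.window_counts_both(t.chrom, t.start - halfwidth,
                                          t.start + halfwidth + 1)
        profile += window[::-1] if t.strand == "-" else window
    center = halfwidth
    core_mean = profile[center - core:center + core + 1].mean()
    flank_total = profile[:flank].sum() + profile[-flank:].sum()
    flank_mean = max(flank_total, 1.0) / (2 * flank)
    return float(core_mean / flank_mean)


def divide_by_enrichment(m: AccessibilityMatrix,
                         enrichments: Dict[str, float]) -> AccessibilityMatrix:
    m._require_state("raw_fpkm")
    scale = np.array([enrichments[s] for s in m.samples], dtype=float)
    if np.any(scale <= 0):
        raise ValueError("TSS enrichments must be positive")
    return AccessibilityMatrix(m.regions, m.samples, m.values / scale,
                               "tss_normalized", m.flagged.copy())


def iqr_scale(m: AccessibilityMatrix) -> AccessibilityMatrix:
    """Per-column robust scaling (x - median) / IQR with type-7 quantiles."""
    m._require_state("tss_normalized")
    values = m.values.copy()
    for j, sample in enumerate(m.samples):
        col = values[:, j]
        q1, med, q3 = np.quantile(col, [0.25, 0.5, 0.75], method="linear")
        iqr = q3 - q1
        if iqr == 0:
            raise ValueError(f"sample {sample!r} has zero IQR (degenerate signal)")
        values[:, j] = (col - med) / iqr
    return AccessibilityMatrix(m.regions, m.samples, values, "iqr_scaled",
                               m.flagged.copy())


def row_max_normalize(m: AccessibilityMatrix) -> AccessibilityMatrix:
    """Divide each row by its maximum across samples; degenerate rows flagged.

    Rows whose maximum is <= 0 or whose values are all equal carry no
    relative stage information; they are zeroed and flagged so clustering
    can exclude them.
    """
    m._require_state("iqr_scaled")
    values = m.values.copy()
    row_max = values.max(axis=1)
    all_equal = np.all(values == values[:, :1], axis=1)
    bad = (row_max <= 0) | all_equal
    flagged = m.flagged | bad
    values[bad] = 0.0
    good = ~bad
    values[good] = values[good] / row_max[good, None]
    return AccessibilityMatrix(m.regions, m.samples, values,
                               "row_max_normalized", flagged)


def normalize_matrix(m: AccessibilityMatrix,
                     enrichments: Dict[str, float]) -> AccessibilityMatrix:
    """Full chain: TSS-enrichment division -> IQR scaling -> row-max."""
    return row_max_normalize(iqr_scale(divide_by_enrichment(m, enrichments)))


def replicate_correlation(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman and Pearson correlations between replicate columns.

    Input is a regions x replicates fragment-count table.  Constant columns
    make the correlation undefined; such pairs are reported as NaN.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two replicates")
    rows = []
    for a, b in combinations(counts.columns, 2):
        x, y = counts[a].to_numpy(float), counts[b].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            pear = spear = np.nan
        else:
            pear = stats.pearsonr(x, y).statistic
            spear = stats.spearmanr(x, y).statistic
        rows.append({"rep_a": a, "rep_b": b, "pearson": pear, "spearman": spear})
    return pd.DataFrame(rows)
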