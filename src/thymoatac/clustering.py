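"""k-means clustering of the normalized accessibility matrix and the
cluster-level descriptive analyses: territory fractions, TSS-distance
distributions with pairwise KS tests, and promoter/exon/distal annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .accessibility import AccessibilityMatrix
from .core import GenomicInterval, PeakSet

CATEGORIES = ("promoter", "exonic", "distal")


@dataclass
class ClusterModel:
    k: int
    centers: np.ndarray  # k x samples
    assignment: np.ndarray  # cluster id per region; -1 for flagged rows
    seed: int
    n_starts: int
    wcss: float
    wcss_by_k: Optional[Dict[int, float]] = None

    def regions_in_cluster(self, regions: Sequence[GenomicInterval],
                           cluster: int) -> List[GenomicInterval]:
        return [r for r, a in zip(regions, self.assignment) if a == cluster]


def _best_kmeans(x: np.ndarray, k: int, n_starts: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_starts, init="k-means++",
                algorithm="lloyd", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence chatter on tiny data
        km.fit(x)
    return km


def run_kmeans(m: AccessibilityMatrix, k: int = 6, n_starts: int = 1000,
               seed: int = 0) -> ClusterModel:
    """Lloyd k-means from *n_starts* k-means++ initializations; best WCSS wins.

    Flagged (all-zero) rows are excluded and receive assignment -1.
    Deterministic given the seed; Euclidean distance on rows.
    """
    m._require_state("row_max_normalized")
    good = ~m.flagged
    x = m.values[good]
    if k < 1 or k > x.shape[0]:
        raise ValueError(f"k={k} out of range for {x.shape[0]} usable regions")
    km = _best_kmeans(x, k, n_starts, seed)
    assignment = np.full(len(m.regions), -1, dtype=int)
    assignment[good] = km.labels_
    return ClusterModel(k=k, centers=km.cluster_centers_.copy(),
                        assignment=assignment, seed=seed, n_starts=n_starts,
                        wcss=float(km.inertia_))


def scan_k(m: AccessibilityMatrix, k_range: Sequence[int] = range(1, 16),
           n_starts: int = 1000, seed: int = 0) -> Dict[int, float]:
    """Best within-cluster sum of squares for each k; non-increasing in k.

    Best-of-starts WCSS is guaranteed monotone here by additionally seeding
    each k with the previous solution's centers plus the point farthest
    from its center, then keeping the better fit.
    """
    m._require_state("row_max_normalized")
    x = m.values[~m.flagged]
    wcss: Dict[int, float] = {}
    prev: Optional[KMeans] = None
    for k in sorted(k_range):
        km = _best_kmeans(x, k, n_starts, seed)
        if prev is not None:
            dists = ((x - prev.cluster_centers_[prev.labels_]) ** 2).sum(axis=1)
            init = np.vstack([prev.cluster_centers_, x[np.argmax(dists)]])
            if init.shape[0] == k and len(np.unique(init, axis=0)) == k:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    km_warm = KMeans(n_clusters=k, n_init=1, init=init,
                                     algorithm="lloyd", random_state=seed).fit(x)
                if km_warm.inertia_ < km.inertia_:
                    km = km_warm
        wcss[k] = float(km.inertia_)
        prev = km
    return wcss


def territory_fraction(model: ClusterModel,
                       regions: Sequence[GenomicInterval]) -> Dict[int, float]:
    """Fraction of total clustered-peak territory (bp) covered per cluster."""
    lengths = np.array([r.length for r in regions], dtype=float)
    used = model.assignment >= 0
    total = lengths[used].sum()
    return {c: float(lengths[(model.assignment == c)].sum() / total)
            for c in range(model.k)}


def tss_distances(regions: Sequence[GenomicInterval],
                  tss: Sequence[GenomicInterval]) -> np.ndarray:
    """bp from each region midpoint to the nearest TSS; 0 if a TSS is inside."""
    if not tss:
        raise ValueError("need at least one TSS")
    by_chrom: Dict[str, List[int]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t.start)
    pos = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}
    out = np.empty(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        if r.chrom not in pos:
            out[i] = np.iinfo(np.int64).max // 2
            continue
        p = pos[r.chrom]
        inside = p[(p >= r.start) & (p < r.end)]
        if inside.size:
            out[i] = 0
            continue
        mid = r.midpoint
        j = np.searchsorted(p, mid)
        cands = [abs(int(p[idx]) - mid) for idx in (j - 1, j) if 0 <= idx < len(p)]
        out[i] = min(cands)
    return out


def tss_distance_tests(model: ClusterModel, regions: Sequence[GenomicInterval],
                       tss: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Pairwise two-sample KS tests between clusters on log10(distance + 1).

    Asymptotic KS p-values with a Bonferroni multiplier equal to the number
    of tested pairs; per-cluster medians are reported alongside.  Clusters
    with fewer than two regions are skipped and flagged.
    """
    d = tss_distances(regions, tss)
    logd = np.log10(d + 1.0)
    groups = {c: logd[model.assignment == c] for c in range(model.k)}
    testable = [c for c, g in groups.items() if g.size >= 2]
    skipped = [c for c in range(model.k) if c not in testable]
    pairs = list(combinations(testable, 2))
    rows = []
    for a, b in pairs:
        res = stats.ks_2samp(groups[a], groups[b], method="asymp")
        rows.append({
            "cluster_a": a, "cluster_b": b,
            "median_a": float(np.median(10 ** groups[a] - 1)),
            "median_b": float(np.median(10 ** groups[b] - 1)),
            "ks_D": float(res.statistic),
            "p": float(res.pvalue),
            "p_bonferroni": float(min(1.0, res.pvalue * len(pairs))),
        })
    df = pd.DataFrame(rows)
    df.attrs["skipped_clusters"] = skipped
    return df


@dataclass
class PeakAnnotation:
    """Mutually exclusive region categories with precedence
    promoter > exonic > distal, plus midpoint-to-TSS distances."""

    categories: List[str]
    tss_distance: np.ndarray

    def fractions(self, mask: Optional[np.ndarray] = None) -> Dict[str, float]:
        cats = np.asarray(self.categories)
        if mask is not None:
            cats = cats[mask]
        n = max(len(cats), 1)
        return {c: float((cats == c).sum() / n) for c in CATEGORIES}


def promoter_windows(tss: Sequence[GenomicInterval],
                     upstream: int = 200) -> List[GenomicInterval]:
    """Strictly-upstream promoter windows: [t-200, t) on '+', mirrored on '-'."""
    out = []
    for t in tss:
        if t.strand == "+":
            start, end = t.start - upstream, t.start
        elif t.strand == "-":
            start, end = t.start + 1, t.start + 1 + upstream
        else:
            raise ValueError(f"TSS at {t.chrom}:{t.start} has strand '.'; "
                             "upstream is undefined")
        if end > 0:
            out.append(GenomicInterval(t.chrom, max(start, 0), end, t.strand))
    return out


def annotate_peaks(master: PeakSet, tss: Sequence[GenomicInterval],
                   exons: Sequence[GenomicInterval],
                   upstream: int = 200) -> PeakAnnotation:
    """Classify each master peak as promoter, exonic or distal.

    A peak overlapping a promoter window (200 bp upstream of a TSS) is a
    promoter peak regardless of exon overlap; otherwise exon overlap makes
    it exonic; otherwise distal.
    """
    prom = PeakSet(promoter_windows(tss, upstream)).merged()
    exon_set = PeakSet(list(exons)).merged()
    cats = []
    for region in master.intervals:
        if prom.overlaps_interval(region):
            cats.append("promoter")
        elif exon_set.overlaps_interval(region):
            cats.append("exonic")
        else:
            cats.append("distal")
    return PeakAnnotation(cats, tss_distances(master.intervals, tss))


# Archetype template patterns in row-max-normalized space, used to attach a
# human-readable label to each cluster center.  This reports the nearest
# archetype, not a claim about any particular dataset's manual labels.
def archetype_templates(samples: Sequence[str],
                        shared_level: float = 0.5) -> Dict[str, np.ndarray]:
    n = len(samples)
    templates: Dict[str, np.ndarray] = {}
    for i, s in enumerate(samples):
        v = np.full(n, 0.0)
        v[i] = 1.0
        templates[s] = v
    templates["ubiquitous"] = np.ones(n)
    dn_ub = np.full(n, shared_level)
    dn_ub[list(samples).index("DN") if "DN" in samples else 0] = 1.0
    templates["DN_ubiquitous"] = dn_ub
    return templates


def label_clusters(model: ClusterModel, samples: Sequence[str]) -> Dict[int, str]:
    """Map each cluster to the archetype template nearest its center."""
    templates = archetype_templates(samples)
    labels = {}
    for c in range(model.k):
        center = model.centers[c]
        best = min(templates, key=lambda a: float(((center - templates[a]) ** 2).sum()))
        labels[c] = best
    return labels
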