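"""Workspace-restricted permutation enrichment of interval overlap.

Observed overlap (in nucleotides) between segments and an annotation,
compared with a null in which every segment is independently re-placed
uniformly at random within the workspace: a segment of length l lands in
workspace interval w with probability proportional to max(len(w) - l + 1, 0)
and a uniform start therein.  Empirical p-values use the +1/(n+1) estimator
so they are never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, PeakSet

STAGE_CLUSTERS = ("DN", "DP", "SP4", "SP8")


@dataclass
class WorkspaceSpec:
    """GAT's three interval sets: where randomization is allowed (workspace),
    what is randomized (segments), what overlap is scored against
    (annotations, labelled)."""

    workspace: PeakSet
    segments: PeakSet
    annotations: Dict[str, PeakSet]


@dataclass
class EnrichmentResult:
    motif_id: str
    sample: str
    annotation_label: str
    observed_overlap: float  # bp
    expected_overlap: float  # null mean, bp
    fold: float
    p_enrich: float
    p_deplete: float
    n_samples: int
    q: float = np.nan


class _CoverageIndex:
    """Prefix-coverage queries over a merged, sorted interval set."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        merged = PeakSet(list(intervals)).merged()
        self.by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chroms: Dict[str, List[GenomicInterval]] = {}
        for iv in merged.intervals:
            chroms.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in chroms.items():
            starts = np.array([i.start for i in ivs], dtype=np.int64)
            ends = np.array([i.end for i in ivs], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self.by_chrom[chrom] = (starts, ends, cum)

    def coverage_before(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Total annotated bp in (-inf, x) per query position."""
        if chrom not in self.by_chrom:
            return np.zeros(len(x), dtype=np.int64)
        starts, ends, cum = self.by_chrom[chrom]
        idx = np.searchsorted(starts, x, side="right") - 1
        out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0).astype(np.int64)
        partial = np.clip(x - starts[np.maximum(idx, 0)], 0, None)
        lengths = ends[np.maximum(idx, 0)] - starts[np.maximum(idx, 0)]
        out = out + np.where(idx >= 0, np.minimum(partial, lengths), 0)
        return out

    def overlap(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return self.coverage_before(chrom, ends) - self.coverage_before(chrom, starts)


def _clip_segments_to_workspace(segments: PeakSet, workspace: PeakSet) -> List[GenomicInterval]:
    ws = workspace.merged()
    idx = ws._merged_index()
    max_ws_len = max((iv.length for iv in ws.intervals), default=0)
    out: List[GenomicInterval] = []
    clipped = 0
    for seg in segments.intervals:
        if seg.length > max_ws_len:
            raise ValueError(
                f"segment of length {seg.length} is longer than every workspace interval"
            )
        if seg.chrom not in idx:
            clipped += 1
            continue
        starts, ends = idx[seg.chrom]
        i = int(np.searchsorted(starts, seg.start, side="right")) - 1
        # clip to the workspace interval overlapping the segment start (or next)
        placed = False
        for j in (i, i + 1):
            if 0 <= j < len(starts):
                lo = max(seg.start, int(starts[j]))
                hi = min(seg.end, int(ends[j]))
                if lo < hi:
                    if (lo, hi) != (seg.start, seg.end):
                        clipped += 1
                    out.append(GenomicInterval(seg.chrom, lo, hi, seg.strand))
                    placed = True
                    break
        if not placed:
            clipped += 1
    if clipped:
        warnings.warn(f"{clipped} segments extended outside the workspace and were clipped/dropped")
    return out


def gat_test(spec: WorkspaceSpec, n_samples: int = 1000, seed: int = 0,
             motif_id: str = "", sample: str = "") -> List[EnrichmentResult]:
    """One workspace-restricted permutation test per annotation label.

    All annotations share the same null placements, mirroring how a single
    randomization run is scored against multiple annotation tracks.  The
    fold denominator is floored at 1 bp only when the expected overlap is
    zero, so folds stay finite without biasing the ordinary case.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    workspace = spec.workspace.merged()
    if not len(workspace):
        raise ValueError("workspace is empty")
    segments = _clip_segments_to_workspace(spec.segments, workspace)
    ann_index = {label: _CoverageIndex([iv for iv in ann.intervals
                                        if workspace.overlaps_interval(iv)])
                 for label, ann in spec.annotations.items()}
    labels = list(spec.annotations)
    if not segments:
        return [EnrichmentResult(motif_id, sample, lab, 0.0, 0.0, 0.0, 1.0, 1.0,
                                 n_samples) for lab in labels]

    ws_chroms = [iv.chrom for iv in workspace.intervals]
    chrom_names = sorted(set(ws_chroms))
    chrom_code = {c: i for i, c in enumerate(chrom_names)}
    ws_chrom_id = np.array([chrom_code[c] for c in ws_chroms], dtype=np.int64)
    ws_starts = np.array([iv.start for iv in workspace.intervals], dtype=np.int64)
    ws_ends = np.array([iv.end for iv in workspace.intervals], dtype=np.int64)
    ws_lengths = ws_ends - ws_starts

    observed = {}
    for label in labels:
        cov = ann_index[label]
        obs = 0
        for seg in segments:
            obs += int(cov.overlap(seg.chrom, np.array([seg.start]),
                                   np.array([seg.end]))[0])
        observed[label] = float(obs)

    rng = np.random.default_rng(seed)
    null = {label: np.zeros(n_samples) for label in labels}
    for seg in segments:
        l = seg.length
        weights = np.maximum(ws_lengths - l + 1, 0).astype(float)
        if weights.sum() == 0:
            raise ValueError(f"segment of length {l} is longer than every workspace interval")
        probs = weights / weights.sum()
        widx = rng.choice(len(ws_lengths), size=n_samples, p=probs)
        offsets = rng.random(n_samples)
        starts = ws_starts[widx] + np.floor(offsets * (ws_lengths[widx] - l + 1)).astype(np.int64)
        ends = starts + l
        cids = ws_chrom_id[widx]
        for label in labels:
            cov = ann_index[label]
            for cid in np.unique(cids):
                mask = cids == cid
                null[label][mask] += cov.overlap(chrom_names[cid], starts[mask], ends[mask])

    results = []
    for label in labels:
        obs = observed[label]
        nul = null[label]
        expected = float(nul.mean())
        # floor the denominator at 1 bp only to keep folds finite at expected 0
        fold = obs / (expected if expected > 0 else 1.0)
        p_enrich = (1.0 + float((nul >= obs).sum())) / (n_samples + 1.0)
        p_deplete = (1.0 + float((nul <= obs).sum())) / (n_samples + 1.0)
        results.append(EnrichmentResult(motif_id, sample, label, obs, expected,
                                        fold, p_enrich, p_deplete, n_samples))
    return results


def footprint_cluster_enrichment(
    calls_by_motif_sample: Dict[Tuple[str, str], Sequence[GenomicInterval]],
    hits_by_motif: Dict[str, Sequence[GenomicInterval]],
    master: PeakSet,
    clusters: Dict[str, Sequence[GenomicInterval]],
    n_samples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per (motif, sample) GAT test of footprints against cluster regions.

    Workspace: the motif's occurrences contained in master peaks.
    Segments: that motif's footprint calls in that sample.  Annotations:
    the cluster regions.  BH q-values are computed across motifs within
    each (sample, cluster) family.
    """
    master_merged = master.merged()
    annotations = {lab: PeakSet(list(regs)) for lab, regs in clusters.items()}
    rows: List[EnrichmentResult] = []
    for mi, (motif_id, hits) in enumerate(sorted(hits_by_motif.items())):
        ws_ivs = [iv for iv in hits if master_merged.contains_interval(iv)]
        if not ws_ivs:
            warnings.warn(f"motif {motif_id}: no occurrences within master peaks; skipped")
            continue
        workspace = PeakSet(ws_ivs)
        for si, smp in enumerate(sorted({s for _, s in calls_by_motif_sample})):
            segs = PeakSet(list(calls_by_motif_sample.get((motif_id, smp), [])))
            spec = WorkspaceSpec(workspace, segs, annotations)
            rows.extend(gat_test(spec, n_samples=n_samples,
                                 seed=seed + 1009 * mi + 31 * si,
                                 motif_id=motif_id, sample=smp))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return df
    df["q"] = np.nan
    for (smp, lab), grp in df.groupby(["sample", "annotation_label"]):
        _, qvals, _, _ = multipletests(grp["p_enrich"].to_numpy(), method="fdr_bh")
        df.loc[grp.index, "q"] = qvals
    return df


def median_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Median fold across motifs per (sample, cluster); empty cells -> NaN."""
    return table.pivot_table(index="sample", columns="annotation_label",
                             values="fold", aggfunc="median")


def top_variance_factors(table: pd.DataFrame, top_n: int = 20,
                         stage_clusters: Sequence[str] = STAGE_CLUSTERS
                         ) -> pd.DataFrame:
    """Rank motifs by variance of fold across the stage-specific clusters.

    Computed per sample; motifs missing any stage-specific cluster value
    are excluded with a warning.  When top_n exceeds the table, the full
    ranking is returned.
    """
    sub = table[table["annotation_label"].isin(stage_clusters)]
    rows = []
    for (smp, motif), grp in sub.groupby(["sample", "motif_id"]):
        folds = grp.set_index("annotation_label")["fold"]
        if not all(c in folds.index for c in stage_clusters):
            warnings.warn(f"motif {motif} in sample {smp}: missing stage-cluster folds; excluded")
            continue
        vec = folds.loc[list(stage_clusters)].to_numpy(float)
        row = {"sample": smp, "motif_id": motif, "fold_variance": float(np.var(vec))}
        row.update({f"fold_{c}": float(v) for c, v in zip(stage_clusters, vec)})
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(["sample", "fold_variance"], ascending=[True, False],
                        kind="stable").reset_index(drop=True)
    return df.groupby("sample", group_keys=False).head(top_n).reset_index(drop=True)
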