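"""End-to-end orchestration: simulate -> matrix -> cluster -> scan ->
footprint -> enrich -> report, with a single config, per-stage seeds and a
manifest recording parameters and output checksums.

Defaults match the analysis parameters the pipeline is built around:
window halfwidth L=100, posterior threshold 0.99, scan p-value 1e-4, k=6
with a 1..15 scan and 1000 random starts, 1000 permutation samples for the
enrichment test, GC background 0.417.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import accessibility as acc
from . import clustering as clu
from . import enrichment as enr
from . import footprinting as fp
from . import io as tio
from . import motif_scan as ms
from . import simulate as sim
from .core import GenomicInterval, PeakSet

log = logging.getLogger("thymoatac")


@dataclass
class PipelineConfig:
    outdir: str = "thymoatac_run"
    seed: int = 0
    L: int = 100
    posterior_threshold: float = 0.99
    p_threshold: float = 1e-4
    k: int = 6
    k_min: int = 1
    k_max: int = 15
    n_starts: int = 1000
    gat_n: int = 1000
    gc: float = 0.417
    simulation: Dict = field(default_factory=dict)  # SimulationParams overrides

    def __post_init__(self) -> None:
        if not 0.0 < self.posterior_threshold < 1.0:
            raise ValueError("posterior_threshold must be in (0, 1)")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.k < 1 or self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid k range")
        if self.n_starts < 1 or self.gat_n < 1 or self.L < 1:
            raise ValueError("n_starts, gat_n and L must be >= 1")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sim_params(self) -> sim.SimulationParams:
        overrides = dict(self.simulation)
        shape = sim.FootprintShape(**overrides.pop("shape", {}))
        cut_rates = sim.CutCountRates(**overrides.pop("cut_rates", {}))
        frag_rates = sim.FragmentRates(**overrides.pop("fragment_rates", {}))
        if "motifs" in overrides:
            overrides["motifs"] = tuple(overrides["motifs"])
        return sim.SimulationParams(gc=self.gc, shape=shape, cut_rates=cut_rates,
                                    fragment_rates=frag_rates, **overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 131 + stage * 7919 + 1) % (2**31 - 1)


def cluster_regions_by_label(model: clu.ClusterModel,
                             regions: Sequence[GenomicInterval],
                             labels: Dict[int, str]) -> Dict[str, List[GenomicInterval]]:
    out: Dict[str, List[GenomicInterval]] = {}
    for c in range(model.k):
        lab = labels[c]
        if lab in out:  # two clusters mapped to one archetype: disambiguate
            lab = f"{lab}_{c}"
        out[lab] = model.regions_in_cluster(regions, c)
    return out


def run_all(config: PipelineConfig) -> Dict:
    """Run every stage on a fresh simulation; returns the manifest dict.

    Re-running with the same config and seed produces byte-identical
    outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    # --- simulate -------------------------------------------------------
    log.info("[simulate] generating synthetic dataset")
    simdir = outdir / "sim"
    ds = sim.simulate_dataset(config.sim_params(), seed=_stage_seed(config.seed, 0),
                              outdir=simdir)
    written.extend(sorted(simdir.iterdir()))
    samples = list(sim.SAMPLES)

    # --- accessibility matrix -------------------------------------------
    log.info("[matrix] master peaks, FPKM and normalization")
    rep_libs = [rep for s in samples for rep in ds.replicates[s]]
    rep_libs = acc.downsample_fragments(rep_libs, seed=_stage_seed(config.seed, 1))
    merged_libs = []
    for s in samples:
        frags = [f for lib in rep_libs if lib.sample.startswith(f"{s}_rep")
                 for f in lib.fragments]
        frags.sort()
        merged_libs.append(acc.FragmentSet(s, frags))
    master = acc.make_master_peaks([ds.peaks_by_sample[s] for s in samples])
    fpkm = acc.fpkm_matrix(master, merged_libs)
    enrichments = {s: acc.tss_enrichment(ds.tracks[s], ds.truth.tss) for s in samples}
    norm = acc.normalize_matrix(fpkm, enrichments)
    fpkm.to_tsv(_w(outdir / "matrix_raw_fpkm.tsv"))
    norm.to_tsv(_w(outdir / "matrix_normalized.tsv"))
    rep_counts = pd.DataFrame({lib.sample: acc.count_overlapping_fragments(master, lib)
                               for lib in rep_libs})
    corr_rows = []
    for s in samples:
        cols = [c for c in rep_counts.columns if c.startswith(f"{s}_rep")]
        tbl = acc.replicate_correlation(rep_counts[cols])
        tbl.insert(0, "sample", s)
        corr_rows.append(tbl)
    tio.write_tsv(_w(outdir / "replicate_correlation.tsv"), pd.concat(corr_rows))
    tio.write_json(_w(outdir / "tss_enrichment.json"), enrichments)

    # --- clustering ------------------------------------------------------
    log.info("[cluster] k-means k=%d with %d starts", config.k, config.n_starts)
    seed_k = _stage_seed(config.seed, 2)
    model = clu.run_kmeans(norm, k=config.k, n_starts=config.n_starts, seed=seed_k)
    model.wcss_by_k = clu.scan_k(norm, range(config.k_min, config.k_max + 1),
                                 n_starts=config.n_starts, seed=seed_k)
    labels = clu.label_clusters(model, samples)
    territory = clu.territory_fraction(model, norm.regions)
    ks_table = clu.tss_distance_tests(model, norm.regions, ds.truth.tss)
    annotation = clu.annotate_peaks(master, ds.truth.tss, ds.truth.exons)

    assign_names = [f"cluster_{a}" if a >= 0 else "flagged"
                    for a in model.assignment]
    tio.write_bed(_w(outdir / "cluster_assignments.bed"), PeakSet(norm.regions),
                  names=[assign_names[i] for i in
                         sorted(range(len(norm.regions)),
                                key=lambda i: norm.regions[i].sort_key())])
    centers = pd.DataFrame(model.centers, columns=samples)
    centers.insert(0, "cluster", range(config.k))
    centers["label"] = [labels[c] for c in range(config.k)]
    centers["territory_fraction"] = [territory[c] for c in range(config.k)]
    tio.write_tsv(_w(outdir / "cluster_centers.tsv"), centers)
    tio.write_tsv(_w(outdir / "wcss_by_k.tsv"),
                  pd.DataFrame({"k": list(model.wcss_by_k),
                                "wcss": list(model.wcss_by_k.values())}))
    tio.write_tsv(_w(outdir / "tss_distance_ks.tsv"), ks_table)
    ann_df = pd.DataFrame({
        "chrom": [r.chrom for r in master.intervals],
        "start": [r.start for r in master.intervals],
        "end": [r.end for r in master.intervals],
        "category": annotation.categories,
        "tss_distance": annotation.tss_distance,
        "cluster": model.assignment,
    })
    tio.write_tsv(_w(outdir / "peak_annotation.tsv"), ann_df)

    # --- motif scan ------------------------------------------------------
    log.info("[scan] PWM scan at p <= %g", config.p_threshold)
    genome = ds.genome
    hits_by_motif: Dict[str, List[ms.MotifOccurrence]] = {}
    for pwm in ds.pwms:
        hits_by_motif[pwm.motif_id] = ms.scan(genome, pwm,
                                              p_threshold=config.p_threshold)
        tio.write_bed(_w(outdir / f"hits_{pwm.motif_id}.bed"),
                      ms.occurrences_to_peakset(hits_by_motif[pwm.motif_id]),
                      names=[pwm.motif_id] * len(hits_by_motif[pwm.motif_id]))

    # --- footprinting ----------------------------------------------------
    log.info("[footprint] mixture-model fits per motif x sample")
    seed_fp = _stage_seed(config.seed, 4)
    calls_by_ms: Dict[Tuple[str, str], List[GenomicInterval]] = {}
    call_rows = []
    occupancy_rows = []
    cluster_regions = cluster_regions_by_label(model, norm.regions, labels)
    for pwm in ds.pwms:
        hits = hits_by_motif[pwm.motif_id]
        if len(hits) < 20:
            log.warning("motif %s: too few hits (%d) for a fit", pwm.motif_id, len(hits))
            continue
        for s_i, s in enumerate(samples):
            matrix = fp.build_cut_matrix(hits, ds.tracks[s], L=config.L)
            fit = fp.fit_centipede(matrix, seed=seed_fp)
            calls = fp.call_footprints(fit, matrix, ds.peaks_by_sample[s],
                                       config.posterior_threshold)
            bound = [c.occurrence.interval for c in calls if c.bound]
            calls_by_ms[(pwm.motif_id, s)] = bound
            for c in calls:
                iv = c.occurrence.interval
                call_rows.append({
                    "motif": pwm.motif_id, "sample": s, "chrom": iv.chrom,
                    "start": iv.start, "end": iv.end, "strand": iv.strand,
                    "posterior": round(c.posterior, 6), "bound": int(c.bound),
                })
            tio.write_json(_w(outdir / f"fit_{pwm.motif_id}_{s}.json"), fit.to_dict())
            prof = fp.occupancy_profile(matrix, fit, ds.peaks_by_sample[s],
                                        seed=seed_fp + s_i, sample=s,
                                        posterior_threshold=config.posterior_threshold)
            for j, v in enumerate(prof.signal):
                occupancy_rows.append({
                    "motif": pwm.motif_id, "sample": s, "cluster": prof.cluster,
                    "column": j, "signal": round(float(v), 6),
                    "n_bound": prof.n_bound, "n_unbound": prof.n_unbound,
                })
    tio.write_tsv(_w(outdir / "footprint_calls.tsv"), pd.DataFrame(call_rows))
    tio.write_tsv(_w(outdir / "occupancy_profiles.tsv"), pd.DataFrame(occupancy_rows))

    # --- enrichment ------------------------------------------------------
    log.info("[enrich] workspace-restricted permutation tests (n=%d)", config.gat_n)
    hit_ivs = {m: [h.interval for h in hits] for m, hits in hits_by_motif.items()}
    table = enr.footprint_cluster_enrichment(
        calls_by_ms, hit_ivs, master, cluster_regions,
        n_samples=config.gat_n, seed=_stage_seed(config.seed, 5))
    tio.write_tsv(_w(outdir / "enrichment_table.tsv"), table)

    # --- report ----------------------------------------------------------
    if not table.empty:
        med = enr.median_enrichment(table).reset_index()
        tio.write_tsv(_w(outdir / "median_enrichment.tsv"), med)
        stage_labels = [l for l in cluster_regions if l in enr.STAGE_CLUSTERS]
        if len(stage_labels) == 4:
            top = enr.top_variance_factors(table)
            tio.write_tsv(_w(outdir / "top_variance_factors.tsv"), top)

    manifest = {
        "config": asdict(config),
        "parameters": {
            "L": config.L, "posterior_threshold": config.posterior_threshold,
            "p_threshold": config.p_threshold, "k": config.k,
            "n_starts": config.n_starts, "gat_n": config.gat_n, "gc": config.gc,
        },
        "seeds": {f"stage_{i}": _stage_seed(config.seed, i) for i in range(6)},
        "cluster_labels": {str(c): labels[c] for c in labels},
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))},
    }
    tio.write_json(outdir / "manifest.json", manifest)
    log.info("done: %d outputs in %s", len(manifest["outputs"]), outdir)
    return manifest
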