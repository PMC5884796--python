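"""Synthetic four-stage thymocyte ATAC-seq dataset generator with ground truth.

Emulates the statistical structure the downstream analysis assumes: four
samples (DN, DP, SP4, SP8), six accessibility archetypes (one per stage,
one ubiquitous, one DN+ubiquitous), motif occurrences planted inside peaks
with footprint-shaped strand-specific insertion profiles at bound sites and
flat profiles at unbound sites, plus TSS/exon annotation in which the
ubiquitous archetype is preferentially TSS-adjacent.  Every random draw
flows from a single integer seed, and regenerating with the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as tio
from .core import (
    BASES,
    CutSiteTrack,
    FragmentSet,
    GenomicInterval,
    PWM,
    PeakSet,
    gc_background,
    reverse_complement,
)

SAMPLES: Tuple[str, ...] = ("DN", "DP", "SP4", "SP8")
ARCHETYPES: Tuple[str, ...] = ("DN", "DP", "SP4", "SP8", "ubiquitous", "DN_ubiquitous")


def archetype_membership(archetype: str) -> Tuple[str, ...]:
    """Samples in which peaks of this archetype are called."""
    if archetype in SAMPLES:
        return (archetype,)
    if archetype in ("ubiquitous", "DN_ubiquitous"):
        return SAMPLES
    raise ValueError(f"unknown archetype {archetype!r}")


def archetype_multiplier(archetype: str, sample: str,
                         closed: float = 0.05, shared: float = 0.5) -> float:
    """Relative accessibility of an archetype's peaks in a given sample.

    Stage-specific archetypes are fully open (1.0) in their own stage and
    nearly closed elsewhere; the ubiquitous archetype is open everywhere;
    DN_ubiquitous is open everywhere with elevated DN signal.
    """
    if archetype in SAMPLES:
        return 1.0 if sample == archetype else closed
    if archetype == "ubiquitous":
        return 1.0
    if archetype == "DN_ubiquitous":
        return 1.0 if sample == "DN" else shared
    raise ValueError(f"unknown archetype {archetype!r}")


@dataclass
class FootprintShape:
    """Spatial shape of the Tn5 insertion profile around a bound motif.

    The per-position profile starts flat at 1, is multiplied by
    ``depletion_depth`` over motif-covered positions (the protein shields
    its motif from the transposase) and by ``flank_boost`` over a band
    immediately flanking the motif (accessible DNA at the footprint edge).
    A small strand asymmetry up-weights upstream positions on the
    motif-forward strand and downstream positions on the opposite strand.
    """

    depletion_depth: float = 0.4
    flank_boost: float = 1.8
    window_halfwidth: int = 100
    flank_width: int = 12
    strand_asymmetry: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.depletion_depth <= 1.0:
            raise ValueError("depletion_depth must be in (0, 1]")
        if self.flank_boost <= 0:
            raise ValueError("flank_boost must be positive")
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")

    def profile(self, motif_width: int) -> np.ndarray:
        """Normalized (2, 2L+1) probability profile in the motif frame.

        Row 0 is the motif-forward strand, row 1 the opposite strand;
        column L is the motif center.  Entries sum to 1.
        """
        L = self.window_halfwidth
        rel = np.arange(-L, L + 1)
        base = np.ones(2 * L + 1)
        lo = -(motif_width // 2)
        hi = motif_width - motif_width // 2 - 1  # inclusive motif span
        in_motif = (rel >= lo) & (rel <= hi)
        in_flank = (~in_motif) & (rel >= lo - self.flank_width) & (rel <= hi + self.flank_width)
        base[in_motif] *= self.depletion_depth
        base[in_flank] *= self.flank_boost
        fwd = base * np.where(rel < 0, 1.0 + self.strand_asymmetry, 1.0)
        rev = base * np.where(rel > 0, 1.0 + self.strand_asymmetry, 1.0)
        prof = np.stack([fwd, rev])
        return prof / prof.sum()


@dataclass
class CutCountRates:
    """Rates for the insertion-count generator (per base, per strand)."""

    background_per_base: float = 0.001
    peak_per_base: float = 0.02
    peak_phi: float = 10.0
    bound_mu: float = 200.0
    bound_phi: float = 10.0
    unbound_mu: float = 20.0
    unbound_phi: float = 10.0

    def __post_init__(self) -> None:
        for name in ("peak_per_base", "peak_phi", "bound_mu", "bound_phi",
                     "unbound_mu", "unbound_phi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_per_base < 0:
            raise ValueError("background_per_base must be non-negative")


@dataclass
class FragmentRates:
    """Rates for the fragment (read-pair) generator used by the FPKM path."""

    background_per_base: float = 2e-4
    fragments_per_open_peak: float = 200.0
    mean_length: float = 150.0
    sd_length: float = 40.0


@dataclass
class SyntheticTruth:
    """Ground-truth labels for everything the generator planted."""

    peaks: List[GenomicInterval] = field(default_factory=list)
    peak_archetype: List[str] = field(default_factory=list)
    occurrences: List[GenomicInterval] = field(default_factory=list)
    occ_motif: List[str] = field(default_factory=list)
    occ_peak_index: List[int] = field(default_factory=list)  # -1 for decoys
    bound: Dict[str, List[bool]] = field(default_factory=dict)
    tss: List[GenomicInterval] = field(default_factory=list)
    exons: List[GenomicInterval] = field(default_factory=list)
    params: Dict = field(default_factory=dict)

    def bound_array(self, sample: str) -> np.ndarray:
        return np.asarray(self.bound.get(sample, []), dtype=bool)

    def archetype_of_region(self, region: GenomicInterval) -> Optional[str]:
        for peak, arch in zip(self.peaks, self.peak_archetype):
            if peak.overlaps(region):
                return arch
        return None

    def to_json(self, path) -> None:
        def ivs(lst):
            return [[iv.chrom, iv.start, iv.end, iv.strand] for iv in lst]

        tio.write_json(path, {
            "peaks": ivs(self.peaks),
            "peak_archetype": self.peak_archetype,
            "occurrences": ivs(self.occurrences),
            "occ_motif": self.occ_motif,
            "occ_peak_index": self.occ_peak_index,
            "bound": self.bound,
            "tss": ivs(self.tss),
            "exons": ivs(self.exons),
            "params": self.params,
        })

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        raw = tio.read_json(path)

        def ivs(lst):
            return [GenomicInterval(c, s, e, st) for c, s, e, st in lst]

        return cls(
            peaks=ivs(raw["peaks"]),
            peak_archetype=raw["peak_archetype"],
            occurrences=ivs(raw["occurrences"]),
            occ_motif=raw["occ_motif"],
            occ_peak_index=raw["occ_peak_index"],
            bound={k: list(map(bool, v)) for k, v in raw["bound"].items()},
            tss=ivs(raw["tss"]),
            exons=ivs(raw["exons"]),
            params=raw["params"],
        )


def generate_genome(n_chroms: int, chrom_length: int, gc: float,
                    seed: int) -> Dict[str, np.ndarray]:
    """Generate i.i.d. background sequence with the given G+C fraction.

    Returns {chrom: array of single characters} so motif planting can edit
    in place.  gc must be strictly inside (0, 1) — a degenerate alphabet
    would make PWM scanning meaningless.
    """
    bg = gc_background(gc)  # validates gc in (0, 1)
    rng = np.random.default_rng(seed)
    genome = {}
    for i in range(n_chroms):
        codes = rng.choice(4, size=chrom_length, p=bg)
        genome[f"chr{i + 1}"] = np.array(list(BASES), dtype="<U1")[codes]
    return genome


def genome_as_strings(genome: Dict[str, np.ndarray]) -> Dict[str, str]:
    return {c: "".join(arr) for c, arr in genome.items()}


def generate_stage_peaks(genome: Dict[str, np.ndarray], n_per_archetype: int,
                         peak_length: int, seed: int, gap: int = 700,
                         margin: int = 1000) -> Tuple[Dict[str, PeakSet], SyntheticTruth]:
    """Place 6 x n disjoint peaks and label each with an archetype.

    Peaks of archetype "SP4" appear in the SP4 sample's PeakSet only;
    "ubiquitous" and "DN_ubiquitous" peaks appear in all four.  Archetype
    labels are shuffled over genomic slots so archetypes interleave.
    """
    rng = np.random.default_rng(seed)
    n_total = n_per_archetype * len(ARCHETYPES)
    slots: List[Tuple[str, int]] = []
    spacing = peak_length + gap
    for chrom in sorted(genome):
        usable = len(genome[chrom]) - 2 * margin
        for k in range(max(usable // spacing, 0)):
            slots.append((chrom, margin + k * spacing))
    if len(slots) < n_total:
        raise ValueError(
            f"genome too small: {len(slots)} peak slots < {n_total} requested peaks"
        )
    chosen = sorted(rng.choice(len(slots), size=n_total, replace=False).tolist())
    labels = np.repeat(np.arange(len(ARCHETYPES)), n_per_archetype)
    labels = labels[rng.permutation(n_total)]

    truth = SyntheticTruth()
    for slot_i, lab in zip(chosen, labels):
        chrom, start = slots[slot_i]
        jitter = int(rng.integers(0, gap // 2))
        iv = GenomicInterval(chrom, start + jitter, start + jitter + peak_length)
        truth.peaks.append(iv)
        truth.peak_archetype.append(ARCHETYPES[lab])

    peaks_by_sample = {}
    for sample in SAMPLES:
        ivs = [p for p, a in zip(truth.peaks, truth.peak_archetype)
               if sample in archetype_membership(a)]
        peaks_by_sample[sample] = PeakSet(ivs, sample=sample)
    return peaks_by_sample, truth


def plant_motifs(genome: Dict[str, np.ndarray], truth: SyntheticTruth, pwm: PWM,
                 per_peak: int = 1, bound_fraction: float = 1.0,
                 decoy_fraction: float = 1.0, seed: int = 0,
                 margin: int = 30) -> None:
    """Plant motif occurrences inside every peak plus decoys outside peaks.

    Each planted sequence is sampled column-wise from the PWM; strand is
    uniform.  An in-peak occurrence is labelled bound, with probability
    ``bound_fraction``, in exactly the samples where its peak is open
    (archetype membership); decoys are unbound everywhere.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound_fraction must be in [0, 1]")
    w = pwm.width
    rng = np.random.default_rng(seed)
    peak_union = PeakSet(truth.peaks).merged()
    occupied: Dict[str, List[Tuple[int, int]]] = {}
    for iv in truth.occurrences:  # never overwrite previously planted sites
        occupied.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def collides(chrom: str, start: int) -> bool:
        return any(start < e and s < start + w for s, e in occupied.get(chrom, []))

    def sample_site() -> str:
        cols = [BASES[rng.choice(4, p=pwm.probs[:, j])] for j in range(w)]
        return "".join(cols)

    def write_site(chrom: str, start: int, strand: str) -> None:
        seq = sample_site()
        if strand == "-":
            seq = reverse_complement(seq)
        genome[chrom][start:start + w] = list(seq)
        occupied.setdefault(chrom, []).append((start, start + w))

    n_planted = 0
    for peak_i, (peak, arch) in enumerate(zip(truth.peaks, truth.peak_archetype)):
        if peak.length < w + 2 * margin:
            raise ValueError("peak too short for motif plus margins")
        lo, hi = peak.start + margin, peak.end - margin - w
        for j in range(per_peak):
            start = None
            for _ in range(100):
                cand = int(rng.integers(lo, hi + 1))
                if not collides(peak.chrom, cand):
                    start = cand
                    break
            if start is None:
                raise ValueError("could not place motif occurrence without overlap")
            strand = "+" if rng.random() < 0.5 else "-"
            write_site(peak.chrom, start, strand)
            truth.occurrences.append(GenomicInterval(peak.chrom, start, start + w, strand))
            truth.occ_motif.append(pwm.motif_id)
            truth.occ_peak_index.append(peak_i)
            for sample in SAMPLES:
                truth.bound.setdefault(sample, [])
                is_open = sample in archetype_membership(arch)
                truth.bound[sample].append(bool(is_open and rng.random() < bound_fraction))
            n_planted += 1

    n_decoys = int(round(decoy_fraction * n_planted))
    placed = 0
    attempts = 0
    L_guard = 150  # keep decoy windows clear of chromosome edges
    chroms = sorted(genome)
    while placed < n_decoys and attempts < 50 * n_decoys + 100:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(L_guard, len(genome[chrom]) - w - L_guard))
        iv = GenomicInterval(chrom, start, start + w)
        if peak_union.overlaps_interval(GenomicInterval(chrom, start - 5, start + w + 5)):
            continue
        if collides(chrom, start):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        write_site(chrom, start, strand)
        truth.occurrences.append(GenomicInterval(chrom, start, start + w, strand))
        truth.occ_motif.append(pwm.motif_id)
        truth.occ_peak_index.append(-1)
        for sample in SAMPLES:
            truth.bound.setdefault(sample, []).append(False)
        placed += 1
    if placed < n_decoys:
        raise ValueError("could not place all decoy occurrences outside peaks")


def generate_annotation(genome: Dict[str, np.ndarray], truth: SyntheticTruth,
                        tss_fraction_ubiquitous: float = 0.9,
                        n_background_tss: int = 20, exon_length: int = 200,
                        exon_fraction: float = 0.15, seed: int = 0) -> None:
    """Synthesize TSS and exon annotation.

    A configurable fraction of ubiquitous-archetype peaks gets a TSS placed
    immediately adjacent (so the ubiquitous accessibility cluster becomes
    the TSS-proximal one, a property the clustering stage must recover);
    background TSSs and exons are scattered elsewhere.
    """
    rng = np.random.default_rng(seed)
    peak_union = PeakSet(truth.peaks).merged()
    for peak, arch in zip(truth.peaks, truth.peak_archetype):
        if arch != "ubiquitous":
            continue
        if rng.random() >= tss_fraction_ubiquitous:
            continue
        if rng.random() < 0.5:
            pos = peak.end + 20  # promoter window [pos-200, pos) reaches into the peak
            truth.tss.append(GenomicInterval(peak.chrom, pos, pos + 1, "+"))
        else:
            pos = peak.start - 21  # on '-', upstream extends right into the peak
            truth.tss.append(GenomicInterval(peak.chrom, pos, pos + 1, "-"))
    chroms = sorted(genome)
    for _ in range(n_background_tss):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(300, len(genome[chrom]) - 300))
        strand = "+" if rng.random() < 0.5 else "-"
        truth.tss.append(GenomicInterval(chrom, pos, pos + 1, strand))
    # exons: overlap a fraction of the non-ubiquitous peaks, plus scatter
    for peak, arch in zip(truth.peaks, truth.peak_archetype):
        if arch == "ubiquitous" or rng.random() >= exon_fraction:
            continue
        start = peak.start + peak.length // 3
        truth.exons.append(GenomicInterval(peak.chrom, start, start + exon_length))
    for _ in range(n_background_tss):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(300, len(genome[chrom]) - exon_length - 300))
        iv = GenomicInterval(chrom, start, start + exon_length)
        if not peak_union.overlaps_interval(iv):
            truth.exons.append(iv)


def _scatter_window(plus: np.ndarray, minus: np.ndarray, counts: np.ndarray,
                    center: int, strand: str, L: int) -> None:
    """Add a motif-frame (2(2L+1),) count vector into genome-frame arrays."""
    fwd, rev = counts[: 2 * L + 1], counts[2 * L + 1:]
    sl = slice(center - L, center + L + 1)
    if strand == "+":
        plus[sl] += fwd
        minus[sl] += rev
    else:
        minus[sl] += fwd[::-1]
        plus[sl] += rev[::-1]


def generate_cut_counts(genome: Dict[str, np.ndarray], truth: SyntheticTruth,
                        shape: FootprintShape, rates: CutCountRates,
                        seed: int) -> Dict[str, CutSiteTrack]:
    """Draw per-base strand-specific Tn5 insertion counts for every sample.

    Poisson background genome-wide; negative-binomial per-base counts
    within peaks scaled by the archetype x sample accessibility multiplier;
    at bound occurrences a NegBin total split multinomially over the
    footprint profile, at unbound occurrences the same machinery with a
    flat profile.
    """
    L = shape.window_halfwidth
    tracks = {}
    widths = {m: iv.length for m, iv in zip(truth.occ_motif, truth.occurrences)}
    profiles = {m: shape.profile(w).ravel() for m, w in widths.items()}
    flat = {m: np.full(2 * (2 * L + 1), 1.0 / (2 * (2 * L + 1))) for m in widths}
    for si, sample in enumerate(SAMPLES):
        rng = np.random.default_rng(seed + 7919 * si)
        dense = {}
        for chrom in sorted(genome):
            n = len(genome[chrom])
            plus = rng.poisson(rates.background_per_base, size=n).astype(np.int64)
            minus = rng.poisson(rates.background_per_base, size=n).astype(np.int64)
            dense[chrom] = (plus, minus)
        for peak, arch in zip(truth.peaks, truth.peak_archetype):
            mean = rates.peak_per_base * archetype_multiplier(arch, sample)
            p_nb = rates.peak_phi / (rates.peak_phi + mean)
            for arr in dense[peak.chrom]:
                arr[peak.start:peak.end] += rng.negative_binomial(
                    rates.peak_phi, p_nb, size=peak.length
                )
        for i, occ in enumerate(truth.occurrences):
            if truth.bound[sample][i]:
                mu, phi = rates.bound_mu, rates.bound_phi
                prof = profiles[truth.occ_motif[i]]
            else:
                mu, phi = rates.unbound_mu, rates.unbound_phi
                prof = flat[truth.occ_motif[i]]
            total = int(rng.negative_binomial(phi, phi / (phi + mu)))
            counts = rng.multinomial(total, prof)
            center = occ.start + occ.length // 2
            plus, minus = dense[occ.chrom]
            if center - L < 0 or center + L + 1 > len(plus):
                continue  # edge occurrence: no window signal
            _scatter_window(plus, minus, counts, center, occ.strand, L)
        tracks[sample] = CutSiteTrack.from_dense(sample, dense)
    return tracks


def generate_fragments(genome: Dict[str, np.ndarray], truth: SyntheticTruth,
                       rates: FragmentRates, seed: int
                       ) -> Tuple[Dict[str, FragmentSet], Dict[str, Tuple[FragmentSet, FragmentSet]]]:
    """Draw sequenced fragments per sample plus a pseudo-replicate split.

    Per-peak fragment counts are Poisson with mean proportional to the
    archetype x sample multiplier; replicates are a Bernoulli(0.5) split of
    the merged library so replicate-correlation code has inputs.
    """
    libs: Dict[str, FragmentSet] = {}
    reps: Dict[str, Tuple[FragmentSet, FragmentSet]] = {}
    chrom_lengths = {c: len(a) for c, a in genome.items()}
    for si, sample in enumerate(SAMPLES):
        rng = np.random.default_rng(seed + 104729 * si)
        frags: List[Tuple[str, int, int]] = []
        for chrom in sorted(genome):
            n_bg = rng.poisson(rates.background_per_base * chrom_lengths[chrom])
            for _ in range(n_bg):
                length = int(np.clip(rng.normal(rates.mean_length, rates.sd_length), 50, 500))
                start = int(rng.integers(0, chrom_lengths[chrom] - length))
                frags.append((chrom, start, start + length))
        for peak, arch in zip(truth.peaks, truth.peak_archetype):
            mean = rates.fragments_per_open_peak * archetype_multiplier(arch, sample)
            for _ in range(rng.poisson(mean)):
                length = int(np.clip(rng.normal(rates.mean_length, rates.sd_length), 50, 500))
                center = int(rng.integers(peak.start, peak.end))
                start = max(center - length // 2, 0)
                frags.append((peak.chrom, start, start + length))
        frags.sort()
        libs[sample] = FragmentSet(sample, frags)
        mask = rng.random(len(frags)) < 0.5
        reps[sample] = (
            FragmentSet(f"{sample}_rep1", [f for f, m in zip(frags, mask) if m]),
            FragmentSet(f"{sample}_rep2", [f for f, m in zip(frags, mask) if not m]),
        )
    return libs, reps


# Built-in high-information motifs used by the default simulation.  Counts
# are 4 x width (A, C, G, T); the dominant base carries nearly all counts so
# planted sites rescan well above the genome-wide significance threshold.
def _sharp_counts(consensus: str, dominant: int = 197, off: int = 1) -> np.ndarray:
    counts = np.full((4, len(consensus)), off, dtype=float)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = dominant
    return counts


BUILTIN_MOTIF_COUNTS: Dict[str, np.ndarray] = {
    "FOOT1": _sharp_counts("TGACGTCATCGAAT"),
    "FOOT2": _sharp_counts("CCAGATAAGGCT"),
}


def builtin_pwms(gc: float = 0.417, pseudocount: float = 0.25) -> List[PWM]:
    bg = gc_background(gc)
    return [PWM.from_counts(mid, cnt, pseudocount, bg)
            for mid, cnt in BUILTIN_MOTIF_COUNTS.items()]


@dataclass
class SimulationParams:
    """Study conditions for the default desk-scale simulation."""

    n_chroms: int = 2
    chrom_length: int = 160_000
    gc: float = 0.417
    n_per_archetype: int = 25
    peak_length: int = 300
    per_peak: int = 1
    bound_fraction: float = 1.0
    decoy_fraction: float = 1.0
    motifs: Tuple[str, ...] = tuple(BUILTIN_MOTIF_COUNTS)
    tss_fraction_ubiquitous: float = 0.9
    shape: FootprintShape = field(default_factory=FootprintShape)
    cut_rates: CutCountRates = field(default_factory=CutCountRates)
    fragment_rates: FragmentRates = field(default_factory=FragmentRates)


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything one simulation produced."""

    genome: Dict[str, str]
    peaks_by_sample: Dict[str, PeakSet]
    tracks: Dict[str, CutSiteTrack]
    fragments: Dict[str, FragmentSet]
    replicates: Dict[str, Tuple[FragmentSet, FragmentSet]]
    pwms: List[PWM]
    truth: SyntheticTruth


def simulate_dataset(params: Optional[SimulationParams] = None, seed: int = 0,
                     outdir: Optional[Path] = None) -> SyntheticDataset:
    """Run the full generator and optionally write every artifact to disk."""
    p = params or SimulationParams()
    genome = generate_genome(p.n_chroms, p.chrom_length, p.gc, seed)
    peaks_by_sample, truth = generate_stage_peaks(
        genome, p.n_per_archetype, p.peak_length, seed + 1
    )
    pwms = [pw for pw in builtin_pwms(p.gc) if pw.motif_id in p.motifs]
    if not pwms:
        raise ValueError(f"no built-in motifs match {p.motifs}")
    for mi, pwm in enumerate(pwms):
        plant_motifs(genome, truth, pwm, per_peak=p.per_peak,
                     bound_fraction=p.bound_fraction,
                     decoy_fraction=p.decoy_fraction, seed=seed + 2 + mi)
    generate_annotation(genome, truth,
                        tss_fraction_ubiquitous=p.tss_fraction_ubiquitous,
                        seed=seed + 11)
    tracks = generate_cut_counts(genome, truth, p.shape, p.cut_rates, seed + 17)
    fragments, replicates = generate_fragments(genome, truth, p.fragment_rates, seed + 23)
    truth.params = {"seed": seed, **_params_dict(p)}

    ds = SyntheticDataset(
        genome=genome_as_strings(genome),
        peaks_by_sample=peaks_by_sample,
        tracks=tracks,
        fragments=fragments,
        replicates=replicates,
        pwms=pwms,
        truth=truth,
    )
    if outdir is not None:
        write_dataset(ds, Path(outdir))
    return ds


def _params_dict(p: SimulationParams) -> Dict:
    d = asdict(p)
    d["motifs"] = list(d["motifs"])
    return d


def write_dataset(ds: SyntheticDataset, outdir: Path) -> List[Path]:
    """Write every simulation artifact under *outdir*; returns paths written."""
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    tio.write_fasta(_w(outdir / "genome.fa"), ds.genome)
    for sample, peaks in ds.peaks_by_sample.items():
        tio.write_narrowpeak(_w(outdir / f"{sample}.narrowPeak"), peaks)
    for sample, track in ds.tracks.items():
        tio.write_cut_track(_w(outdir / f"{sample}.plus.bedGraph"),
                            _w(outdir / f"{sample}.minus.bedGraph"), track)
    for sample, (r1, r2) in ds.replicates.items():
        for rep in (r1, r2):
            with open(_w(outdir / f"{rep.sample}.fragments.bed"), "w") as fh:
                for chrom, start, end in rep.fragments:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
    occ = PeakSet(ds.truth.occurrences)
    tio.write_bed(_w(outdir / "occurrences.bed"), occ,
                  names=[ds.truth.occ_motif[i] for i in
                         sorted(range(len(ds.truth.occurrences)),
                                key=lambda i: ds.truth.occurrences[i].sort_key())])
    tio.write_bed(_w(outdir / "tss.bed"), PeakSet(ds.truth.tss))
    tio.write_bed(_w(outdir / "exons.bed"), PeakSet(ds.truth.exons))
    tio.write_jaspar_pfm(_w(outdir / "motifs.pfm"),
                         [(m, BUILTIN_MOTIF_COUNTS[m]) for m in
                          [pw.motif_id for pw in ds.pwms]])
    ds.truth.to_json(_w(outdir / "truth.json"))
    return written


def simulate_cut_matrix(n_bound: int, n_unbound: int, shape: FootprintShape,
                        mu1: float, phi1: float, mu0: float, phi0: float,
                        seed: int, motif_width: int = 14,
                        score_informative: bool = False):
    """Draw a motif-anchored cut-count matrix straight from the mixture model.

    Returns (counts, is_bound, scores, true_profile).  Bound rows draw a
    NegBin(mu1, phi1) total split multinomially over the footprint profile;
    unbound rows draw NegBin(mu0, phi0) split uniformly.  Scores are
    uninformative by default so recovery tests measure only what the count
    data carry.
    """
    rng = np.random.default_rng(seed)
    L = shape.window_halfwidth
    S = 2 * (2 * L + 1)
    prof = shape.profile(motif_width).ravel()
    flat = np.full(S, 1.0 / S)
    n = n_bound + n_unbound
    is_bound = np.zeros(n, dtype=bool)
    is_bound[:n_bound] = True
    counts = np.zeros((n, S), dtype=np.int64)
    for i in range(n):
        mu, phi = (mu1, phi1) if is_bound[i] else (mu0, phi0)
        total = int(rng.negative_binomial(phi, phi / (phi + mu)))
        counts[i] = rng.multinomial(total, prof if is_bound[i] else flat)
    if score_informative:
        scores = rng.normal(12.0, 2.0, size=n) + 2.0 * is_bound
    else:
        scores = rng.normal(12.0, 2.0, size=n)
    perm = rng.permutation(n)
    return counts[perm], is_bound[perm], scores[perm], prof
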