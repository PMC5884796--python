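"""Readers and writers for every external format the pipeline touches.

Formats: BED3/BED6, ENCODE narrowPeak, per-strand bedGraph pairs for Tn5
insertion counts, FASTA, JASPAR PFM text, TSV tables and JSON.  All files
use 0-based half-open coordinates, matching the in-memory convention.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .core import CutSiteTrack, GenomicInterval, PWM, PeakSet

PathLike = Union[str, Path]

_VALID_FASTA = set("ACGTN")


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _iter_data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coords(path: PathLike, lineno: int, fields: List[str]) -> Tuple[str, int, int]:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(path, lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}")
    if start >= end:
        raise ParseError(path, lineno, f"start >= end ({start} >= {end})")
    if start < 0:
        raise ParseError(path, lineno, f"negative start {start}")
    return chrom, start, end


def read_bed(path: PathLike, sample: str = "") -> PeakSet:
    """Read a BED3/BED6 file into a sorted PeakSet.

    Strand defaults to "." when the file has fewer than six columns; the
    BED score column, when present, is kept as the peak score.
    """
    intervals: List[GenomicInterval] = []
    scores: List[float] = []
    any_score = False
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
        chrom, start, end = _parse_coords(path, lineno, fields)
        strand = fields[5] if len(fields) >= 6 else "."
        if strand not in ("+", "-", "."):
            raise ParseError(path, lineno, f"invalid strand {strand!r}")
        intervals.append(GenomicInterval(chrom, start, end, strand))
        if len(fields) >= 5 and fields[4] not in (".", ""):
            scores.append(float(fields[4]))
            any_score = True
        else:
            scores.append(0.0)
    return PeakSet(intervals, sample=sample, scores=scores if any_score else None)


def read_narrowpeak(path: PathLike, sample: str = "") -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file.

    signalValue (column 7) is stored as the peak score; qValue (column 9,
    -log10) is available for upstream FDR filtering but not re-applied here.
    """
    intervals: List[GenomicInterval] = []
    scores: List[float] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) != 10:
            raise ParseError(path, lineno, f"narrowPeak requires 10 columns, got {len(fields)}")
        chrom, start, end = _parse_coords(path, lineno, fields)
        strand = fields[5] if fields[5] in ("+", "-") else "."
        intervals.append(GenomicInterval(chrom, start, end, strand))
        scores.append(float(fields[6]))
    return PeakSet(intervals, sample=sample, scores=scores)


def write_bed(path: PathLike, peaks: PeakSet, names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            name = names[i] if names is not None else f"{peaks.sample or 'region'}_{i}"
            score = peaks.scores[i] if peaks.scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def write_narrowpeak(path: PathLike, peaks: PeakSet) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            signal = peaks.scores[i] if peaks.scores is not None else 0.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.sample or 'peak'}_{i}\t"
                f"0\t{iv.strand}\t{signal:g}\t-1\t-1\t-1\n"
            )


def _read_bedgraph_strand(path: PathLike, strand: str) -> Dict[Tuple[str, str], Tuple[List[int], List[int]]]:
    spans: Dict[str, List[Tuple[int, int, int]]] = {}
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(path, lineno, f"bedGraph requires 4 columns, got {len(fields)}")
        chrom, start, end = _parse_coords(path, lineno, fields)
        try:
            value = int(fields[3])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer count {fields[3]!r}")
        if value < 0:
            raise ParseError(path, lineno, f"negative count {value}")
        spans.setdefault(chrom, []).append((start, end, value))
    data: Dict[Tuple[str, str], Tuple[List[int], List[int]]] = {}
    for chrom, entries in spans.items():
        entries.sort()
        positions: List[int] = []
        values: List[int] = []
        prev_end = -1
        for start, end, value in entries:
            if start < prev_end:
                raise ParseError(path, 0, f"overlapping bedGraph intervals on {chrom} at {start}")
            prev_end = end
            if value > 0:
                positions.extend(range(start, end))
                values.extend([value] * (end - start))
        data[(chrom, strand)] = (positions, values)
    return data


def read_cut_track(plus_path: PathLike, minus_path: PathLike, sample: str = "") -> CutSiteTrack:
    """Read a strand-specific Tn5 insertion-count track from two bedGraphs.

    Each bedGraph span contributes its (integer) value at every base it
    covers, so a span of length 2 with value 3 adds 6 insertion events to
    the track total.
    """
    data: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        for key, (pos, val) in _read_bedgraph_strand(path, strand).items():
            data[key] = (np.asarray(pos, dtype=np.int64), np.asarray(val, dtype=np.int64))
    return CutSiteTrack.from_sparse(sample, data)


def write_cut_track(plus_path: PathLike, minus_path: PathLike, track: CutSiteTrack) -> None:
    """Write a CutSiteTrack as a per-strand bedGraph pair (run-length merged)."""
    handles = {"+": open(plus_path, "w"), "-": open(minus_path, "w")}
    try:
        for (chrom, strand), (pos, val) in track.items():
            fh = handles[strand]
            i = 0
            while i < len(pos):
                j = i
                while (
                    j + 1 < len(pos)
                    and pos[j + 1] == pos[j] + 1
                    and val[j + 1] == val[i]
                ):
                    j += 1
                fh.write(f"{chrom}\t{pos[i]}\t{pos[j] + 1}\t{val[i]}\n")
                i = j + 1
    finally:
        for fh in handles.values():
            fh.close()


def read_jaspar_pfm(path: PathLike, pseudocount: float = 0.25,
                    background: Optional[np.ndarray] = None) -> List[PWM]:
    """Read JASPAR PFM text (one or more 4-row count records) into PWMs.

    The pseudocount is added to every cell before converting counts to
    column probabilities, which keeps log-odds finite for zero counts.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        records = bio_motifs.parse(StringIO(text), "jaspar")
        parsed = [
            (m.matrix_id or m.name or f"motif_{i}",
             np.array([m.counts[b] for b in "ACGT"], dtype=float))
            for i, m in enumerate(records)
        ]
    except Exception as exc:
        raise ParseError(path, 0, f"invalid JASPAR PFM: {exc}")
    pwms = []
    for motif_id, counts in parsed:
        if counts.ndim != 2 or counts.shape[1] < 1:
            raise ParseError(path, 0, f"motif {motif_id}: rows of unequal width")
        pwms.append(PWM.from_counts(motif_id, counts, pseudocount, background))
    return pwms


def write_jaspar_pfm(path: PathLike, motifs: Sequence[Tuple[str, np.ndarray]]) -> None:
    """Write (motif_id, 4 x width count matrix) records as JASPAR PFM text."""
    with open(path, "w") as fh:
        for motif_id, counts in motifs:
            fh.write(f">{motif_id} {motif_id}\n")
            for base, row in zip("ACGT", np.asarray(counts)):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; alphabet must be ACGTN."""
    genome: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_FASTA
        if bad:
            raise ParseError(path, 0, f"{record.id}: non-IUPAC characters {sorted(bad)}")
        genome[record.id] = seq
    return genome


def write_fasta(path: PathLike, genome: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(path: PathLike, table: pd.DataFrame, comment: Optional[str] = None) -> None:
    """Write a DataFrame as TSV, optionally preceded by a '#' comment header."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_tsv_comment(path: PathLike) -> Optional[str]:
    with open(path) as fh:
        first = fh.readline()
    return first[1:].strip() if first.startswith("#") else None


def write_json(path: PathLike, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: PathLike):
    with open(path) as fh:
        return json.load(fh)
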