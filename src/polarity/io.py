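"""Shared genomic data model and readers/writers for the standard formats.

All internal coordinates are 1-based inclusive; conversion to/from the
0-based half-open bedGraph convention happens only at file boundaries.
Strand is explicit on every record and track: on the minus strand
"upstream" means larger coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "GeneRecord",
    "CoverageTrack",
    "Sample",
    "SampleSheet",
    "ParseError",
    "read_gff",
    "read_bedgraph",
    "write_bedgraph",
    "read_wiggle",
    "read_coverage",
    "normalize_coverage",
    "read_counts",
    "write_results",
    "read_samplesheet",
]

STRANDS = ("+", "-")


class ParseError(ValueError):
    """Malformed input file; message names the offending line/cell."""


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene interval.

    ``start``/``end`` are 1-based inclusive with ``start <= end``
    regardless of strand; the strand determines which end carries the
    start codon (+: ``start``, -: ``end``).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.start > self.end:
            raise ValueError(f"start > end for {self.gene_id}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def start_codon_pos(self) -> int:
        """Genomic coordinate of the first nucleotide of the start codon."""
        return self.start if self.strand == "+" else self.end


@dataclass
class CoverageTrack:
    """Per-nucleotide read depth over ``[start, start + len(values) - 1]``.

    ``library_size`` is the total number of aligned reads of the library
    (supplied, not inferred from coverage mass); ``normalized`` flags
    whether :func:`normalize_coverage` has been applied.
    """

    chrom: str
    strand: str
    values: np.ndarray
    start: int = 1
    library_size: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.values) - 1

    def value_at(self, pos: int) -> float:
        """Depth at 1-based genomic position ``pos`` (0 outside the track)."""
        if pos < self.start or pos > self.end:
            return 0.0
        return float(self.values[pos - self.start])

    def slice(self, lo: int, hi: int) -> np.ndarray:
        """Values over the 1-based inclusive interval [lo, hi], zero-padded."""
        out = np.zeros(hi - lo + 1)
        a, b = max(lo, self.start), min(hi, self.end)
        if a <= b:
            out[a - lo : b - lo + 1] = self.values[a - self.start : b - self.start + 1]
        return out


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    replicate: int
    paths: dict = field(default_factory=dict)


@dataclass
class SampleSheet:
    samples: list[Sample]

    def __post_init__(self) -> None:
        by_cond: dict[str, list[int]] = {}
        for s in self.samples:
            by_cond.setdefault(s.condition, []).append(s.replicate)
        for cond, reps in by_cond.items():
            if len(reps) != len(set(reps)):
                raise ValueError(f"duplicate replicate ids in condition {cond!r}")
        if not by_cond:
            raise ValueError("sample sheet is empty")

    @property
    def conditions(self) -> pd.Series:
        return pd.Series(
            {s.sample_id: s.condition for s in self.samples}, name="condition"
        )


# ---------------------------------------------------------------------------
# GFF3


def read_gff(
    path: str | Path,
    feature_types: Sequence[str] = ("gene",),
    fallback_type: str = "CDS",
    id_attributes: Sequence[str] = ("ID", "locus_tag", "Name", "gene_id"),
) -> list[GeneRecord]:
    """Read gene features from a GFF3 file, sorted by (chrom, start).

    Features whose type is in ``feature_types`` are used; if none are
    present the ``fallback_type`` is used instead.  Records with an
    unknown strand are rejected with a warning; structurally malformed
    lines raise :class:`ParseError` naming the line number.
    """
    primary: list[GeneRecord] = []
    fallback: list[GeneRecord] = []
    wanted = set(feature_types) | {fallback_type}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] not in wanted:
                continue
            try:
                feat = feature_from_line(line)
                start, end = int(fields[3]), int(fields[4])
            except Exception as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if feat.strand not in STRANDS:
                warnings.warn(
                    f"{path}: line {lineno}: unknown strand "
                    f"{feat.strand!r}, record skipped"
                )
                continue
            gene_id = None
            for key in id_attributes:
                if key in feat.attributes:
                    gene_id = feat.attributes[key][0]
                    break
            if gene_id is None:
                gene_id = f"{feat.seqid}:{start}-{end}"
            rec = GeneRecord(gene_id, feat.seqid, feat.strand, start, end)
            (primary if feat.featuretype in feature_types else fallback).append(rec)
    records = primary if primary else fallback
    return sorted(records, key=lambda g: (g.chrom, g.start, g.end))


# ---------------------------------------------------------------------------
# Coverage: bedGraph and wiggle


def read_bedgraph(
    path: str | Path,
    strand: str = "+",
    library_size: int | None = None,
) -> CoverageTrack:
    """Read a single-chromosome bedGraph into a per-nucleotide track.

    bedGraph intervals are 0-based half-open and must be non-overlapping;
    uncovered positions become 0.  The returned track starts at position 1.
    """
    rows = []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(parts)}"
                )
            try:
                c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if v < 0:
                raise ParseError(f"{path}: line {lineno}: negative coverage {v}")
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ParseError(
                    f"{path}: line {lineno}: multiple chromosomes in one track "
                    f"({chrom!r}, {c!r})"
                )
            rows.append((s, e, v))
    if not rows:
        return CoverageTrack(chrom or "", strand, np.zeros(0), 1, library_size)
    rows.sort()
    prev_end = -1
    for s, e, _ in rows:
        if s < prev_end:
            raise ParseError(f"{path}: overlapping intervals at {chrom}:{s}")
        prev_end = e
    values = np.zeros(rows[-1][1])
    for s, e, v in rows:
        values[s:e] = v  # 0-based half-open [s, e) -> 1-based [s+1, e]
    return CoverageTrack(chrom, strand, values, 1, library_size)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging equal-value runs, omitting zeros."""
    with open(path, "w") as fh:
        vals = track.values
        i = 0
        while i < len(vals):
            j = i
            while j < len(vals) and vals[j] == vals[i]:
                j += 1
            if vals[i] != 0:
                # internal 1-based [start+i, start+j-1] -> 0-based half-open
                fh.write(
                    f"{track.chrom}\t{track.start + i - 1}\t{track.start + j - 1}"
                    f"\t{vals[i]:g}\n"
                )
            i = j


def read_wiggle(
    path: str | Path,
    strand: str = "+",
    library_size: int | None = None,
) -> CoverageTrack:
    """Read fixedStep/variableStep wiggle into a per-nucleotide track."""
    cover: dict[int, float] = {}
    chrom = None
    mode = None
    pos = step = span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                kv = dict(p.split("=") for p in line.split()[1:])
                mode = line.split()[0]
                chrom = kv.get("chrom", chrom)
                span = int(kv.get("span", 1))
                if mode == "fixedStep":
                    pos = int(kv["start"])
                    step = int(kv.get("step", 1))
                continue
            parts = line.split()
            try:
                if mode == "fixedStep":
                    (v,) = parts
                    p = pos
                    pos += step
                elif mode == "variableStep":
                    p, v = int(parts[0]), parts[1]
                else:
                    raise ParseError(
                        f"{path}: line {lineno}: data before step declaration"
                    )
                v = float(v)
            except ParseError:
                raise
            except Exception as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if v < 0:
                raise ParseError(f"{path}: line {lineno}: negative coverage {v}")
            for k in range(span):
                cover[p + k] = v
    if not cover:
        return CoverageTrack(chrom or "", strand, np.zeros(0), 1, library_size)
    values = np.zeros(max(cover))
    for p, v in cover.items():
        values[p - 1] = v
    return CoverageTrack(chrom, strand, values, 1, library_size)


def read_coverage(
    path: str | Path,
    strand: str = "+",
    library_size: int | None = None,
) -> CoverageTrack:
    """Read coverage in either bedGraph or wiggle dialect (sniffed)."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                return read_wiggle(path, strand, library_size)
            break
    return read_bedgraph(path, strand, library_size)


def normalize_coverage(
    track: CoverageTrack, all_library_sizes: Iterable[int]
) -> CoverageTrack:
    """Library-size normalization of a coverage track.

    Each value is divided by the track's own total number of aligned reads
    (tnoar) and multiplied by the smallest tnoar among all considered
    libraries, so the most shallowly sequenced library is left unscaled.
    Within-track ratios between positions are preserved exactly.
    """
    sizes = list(all_library_sizes)
    if not sizes:
        raise ValueError("all_library_sizes must be non-empty")
    if track.library_size is None or track.library_size <= 0:
        raise ValueError("track library_size missing or non-positive")
    if any(s <= 0 for s in sizes):
        raise ValueError("library sizes must be positive")
    factor = min(sizes) / track.library_size
    out = replace(track, values=track.values * factor)
    out.normalized = True
    return out


# ---------------------------------------------------------------------------
# Tables


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV count table (first column = feature ids).

    Counts must be numeric and complete; a non-numeric or missing cell
    raises :class:`ParseError` naming the row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if np.allclose(out.values, np.round(out.values)):
        out = out.astype(np.int64)
    return out


def write_results(
    table: pd.DataFrame, path: str | Path, params: dict | None = None
) -> None:
    """Write a result table as TSV with a provenance comment header."""
    from polarity import __version__

    with open(path, "w") as fh:
        extra = "".join(f" {k}={v}" for k, v in (params or {}).items())
        fh.write(f"# polarity v{__version__}{extra}\n")
        table.to_csv(fh, sep="\t")


def read_samplesheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet CSV: sample_id, condition, replicate, then paths."""
    df = pd.read_csv(path)
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    path_cols = [c for c in df.columns if c not in required]
    samples = [
        Sample(
            str(row.sample_id),
            str(row.condition),
            int(row.replicate),
            {c: getattr(row, c) for c in path_cols},
        )
        for row in df.itertuples()
    ]
    return SampleSheet(samples)
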