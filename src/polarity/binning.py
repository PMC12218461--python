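"""TSS-anchored binning and operon polarity summaries.

For each TSS, 25 contiguous bins of 100 nt are laid downstream along the
TSS strand (2,500 nt in total, enough to cover any gene shorter than
2.5 kb).  Bin-level counts feed the same negative-binomial engine as
genes, with an adjusted-p threshold of 0.05 and a separate multiple-
testing family.  Polarity summaries count up/down regulated genes by TSS
class and tabulate fold change against gene position within operons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from polarity import de
from polarity.io import CoverageTrack, GeneRecord
from polarity.tss import DEGLink, PeakRatio, TSSRecord

__all__ = [
    "BinSet",
    "OperonAssignment",
    "PolaritySummary",
    "make_bins",
    "bin_counts",
    "bin_de",
    "assign_operons",
    "polarity_summary",
]


@dataclass
class BinSet:
    """Ordered fixed-width intervals downstream of a TSS (1-based inclusive)."""

    tss: TSSRecord
    intervals: list[tuple[int, int]]
    bin_width: int = 100

    @property
    def n_bins(self) -> int:
        return len(self.intervals)

    @property
    def span_nt(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)


@dataclass
class OperonAssignment:
    """Genes of one transcription unit, promoter-proximal first."""

    operon_id: str
    gene_ids: list[str]
    anchor_gtss: TSSRecord | None = None


@dataclass
class PolaritySummary:
    n_up_with_gtss: int = 0
    n_up_with_itss: int = 0
    n_up_unassigned: int = 0
    n_down_with_gtss: int = 0
    n_down_with_itss: int = 0
    n_down_unassigned: int = 0
    peak_ratio_gt5_count: int = 0
    position_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["operon_id", "gene_id", "gene_index", "log2fc", "deg_status"]
        )
    )

    @property
    def n_up(self) -> int:
        return self.n_up_with_gtss + self.n_up_with_itss + self.n_up_unassigned

    @property
    def n_down(self) -> int:
        return self.n_down_with_gtss + self.n_down_with_itss + self.n_down_unassigned


def make_bins(
    tss: TSSRecord,
    n_bins: int = 25,
    bin_width: int = 100,
    chrom_length: int | None = None,
) -> BinSet:
    """Lay ``n_bins`` bins of ``bin_width`` nt downstream of a TSS.

    Bin 1 starts at the TSS position; bin k covers transcript offsets
    [(k-1)*width, k*width).  On the minus strand bins extend toward
    smaller coordinates.  Bins running off the chromosome are truncated
    with a warning.
    """
    intervals: list[tuple[int, int]] = []
    for k in range(n_bins):
        if tss.strand == "+":
            a = tss.pos + k * bin_width
            b = a + bin_width - 1
        else:
            b = tss.pos - k * bin_width
            a = b - bin_width + 1
        if a < 1 or (chrom_length is not None and b > chrom_length):
            a2 = max(a, 1)
            b2 = min(b, chrom_length) if chrom_length is not None else b
            if a2 > b2:
                warnings.warn(f"bin {k + 1} of TSS {tss.pos} off chromosome; dropped")
                continue
            warnings.warn(f"bin {k + 1} of TSS {tss.pos} truncated to {a2}-{b2}")
            a, b = a2, b2
        intervals.append((a, b))
    return BinSet(tss, intervals, bin_width)


def bin_counts(
    bin_set: BinSet,
    coverage_by_sample: Mapping[str, CoverageTrack],
    read_length: int = 1,
) -> pd.DataFrame:
    """Integer pseudo-counts per bin from raw per-nucleotide coverage.

    The count is the rounded depth sum within the bin divided by
    ``read_length``; the default of 1 keeps depth-sum pseudo-counts,
    which is the faithful desk-scale analogue of counting reads per bin.
    Coverage must be raw (unnormalized): library size differences are the
    size-factor model's job downstream.
    """
    if not coverage_by_sample:
        raise ValueError("no coverage supplied")
    rows = {}
    for sample_id, track in coverage_by_sample.items():
        if track is None:
            raise ValueError(f"coverage missing for sample {sample_id!r}")
        if track.normalized:
            raise ValueError("bin_counts expects raw (unnormalized) coverage")
        rows[sample_id] = [
            int(round(track.slice(a, b).sum() / read_length))
            for a, b in bin_set.intervals
        ]
    index = [f"bin{k + 1}" for k in range(bin_set.n_bins)]
    return pd.DataFrame(rows, index=index)


def bin_de(
    counts: pd.DataFrame,
    conditions: pd.Series,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Differential test per bin (NB Wald, BH within the bin family).

    Bins are a separate multiple-testing family from genes; mixing the
    two in one adjustment is an error by construction here.
    """
    cm = de.CountMatrix(counts, conditions)
    return de.wald_test(cm, alpha=alpha, lfc_threshold=lfc_threshold)


def assign_operons(
    genes: Sequence[GeneRecord],
    tss_list: Sequence[TSSRecord],
    max_gap: int = 200,
    window_nt: int = 200,
) -> list[OperonAssignment]:
    """Group same-strand gene runs into operons.

    Consecutive same-strand genes with intergenic gap <= ``max_gap`` and
    no intervening gTSS form one operon, ordered promoter-proximal first
    (so minus-strand runs are reported right-to-left).  The anchoring
    gTSS is the highest gTSS within ``window_nt`` upstream of the first
    gene.  This is a declared approximation of curated operon maps; user
    supplied operon tables take precedence in the pipeline drivers.
    """
    gtss = [t for t in tss_list if t.tss_class == "gTSS"]
    by_key: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        by_key.setdefault((g.chrom, g.strand), []).append(g)

    def has_gtss_between(chrom: str, strand: str, lo: int, hi: int) -> bool:
        return any(
            t.chrom == chrom and t.strand == strand and lo <= t.pos <= hi
            for t in gtss
        )

    operons: list[OperonAssignment] = []
    for (chrom, strand), run_genes in by_key.items():
        current: list[GeneRecord] = []
        runs: list[list[GeneRecord]] = []
        for g in run_genes:
            if current:
                gap = g.start - current[-1].end - 1
                if gap > max_gap or has_gtss_between(
                    chrom, strand, current[-1].end + 1, g.start - 1
                ):
                    runs.append(current)
                    current = []
            current.append(g)
        if current:
            runs.append(current)
        for run in runs:
            ordered = run if strand == "+" else run[::-1]
            first = ordered[0]
            anchor_candidates = []
            for t in gtss:
                if t.chrom != chrom or t.strand != strand:
                    continue
                d = (
                    first.start_codon_pos - t.pos
                    if strand == "+"
                    else t.pos - first.start_codon_pos
                )
                if 0 <= d <= window_nt:
                    anchor_candidates.append(t)
            anchor = (
                max(anchor_candidates, key=lambda t: t.height)
                if anchor_candidates
                else None
            )
            operons.append(
                OperonAssignment(
                    f"operon_{chrom}_{strand}_{ordered[0].start_codon_pos}",
                    [g.gene_id for g in ordered],
                    anchor,
                )
            )
    return operons


def polarity_summary(
    deg_links: Sequence[DEGLink],
    operons: Sequence[OperonAssignment],
    de_results: pd.DataFrame,
    peak_ratios: Sequence[PeakRatio] = (),
    ratio_cutoff: float = 5.0,
) -> PolaritySummary:
    """Count up/down DEGs by TSS class and tabulate position in operon.

    Produces the proportions behind the polarity picture: how many up-
    and down-regulated genes have a TSS at all, how many of those TSSs
    are internal, the number of strong (> ``ratio_cutoff``) gTSS/iTSS
    peak ratios, and a long table of (operon, gene index from promoter,
    log2 fold change, DEG status).
    """
    s = PolaritySummary()
    for link in deg_links:
        up = link.direction_of_change == "up"
        if link.tss is None:
            if up:
                s.n_up_unassigned += 1
            else:
                s.n_down_unassigned += 1
        elif link.tss.tss_class == "iTSS":
            if up:
                s.n_up_with_itss += 1
            else:
                s.n_down_with_itss += 1
        else:
            if up:
                s.n_up_with_gtss += 1
            else:
                s.n_down_with_gtss += 1
    s.peak_ratio_gt5_count = sum(1 for r in peak_ratios if r.ratio > ratio_cutoff)

    rows = []
    deg_by_gene = {l.gene_id: l for l in deg_links}
    for op in operons:
        for idx, gene_id in enumerate(op.gene_ids, start=1):
            if gene_id not in de_results.index:
                continue
            rec = de_results.loc[gene_id]
            if gene_id in deg_by_gene:
                status = deg_by_gene[gene_id].direction_of_change
            elif bool(rec.get("is_deg", False)):
                status = "up" if rec["log2fc"] > 0 else "down"
            else:
                status = "ns"
            rows.append(
                {
                    "operon_id": op.operon_id,
                    "gene_id": gene_id,
                    "gene_index": idx,
                    "log2fc": float(rec["log2fc"]),
                    "deg_status": status,
                }
            )
    if rows:
        s.position_table = pd.DataFrame(rows)
    return s
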