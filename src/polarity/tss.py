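"""Transcription start site calling and classification.

TSSs are called from paired coverage tracks of 5'-ends in which one
library was treated with terminator exonuclease (TEX).  TEX degrades
processed 5'-monophosphate RNAs, so genuine (5'-triphosphate) starts are
enriched, or at least not diminished, in the treated library, while
processing sites are depleted.  A called TSS is classified as a gene TSS
(gTSS) when it falls in intergenic space, or an internal TSS (iTSS) when
it lies inside an upstream gene transcribed in the same direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from polarity.io import CoverageTrack, GeneRecord

__all__ = [
    "TSSRecord",
    "DEGLink",
    "PeakRatio",
    "TSSCallParams",
    "call_tss",
    "classify_tss",
    "link_deg_to_tss",
    "peak_ratio_table",
    "tss_table",
    "read_tss_table",
]


@dataclass
class TSSRecord:
    """A called 5'-end peak.

    ``height`` is the normalized TEX+ read value at ``pos``; ``tex_ratio``
    is TEX+/TEX- height (``inf`` when TEX- is zero); ``step_factor``
    measures sharpness against the immediate upstream background.
    """

    chrom: str
    strand: str
    pos: int
    height: float
    tex_ratio: float
    step_factor: float
    tss_class: str = "unassigned"

    def __post_init__(self) -> None:
        if self.height < 0 or self.tex_ratio < 0:
            raise ValueError("height and tex_ratio must be non-negative")


@dataclass
class DEGLink:
    """Assignment of a differentially expressed gene to its TSS.

    ``distance_nt`` is measured from the TSS to the first nucleotide of
    the start codon (0 = leaderless); ``tss`` is ``None`` when no TSS lies
    within the assignment window.
    """

    gene_id: str
    tss: TSSRecord | None
    distance_nt: int | None
    direction_of_change: str = "up"


@dataclass
class PeakRatio:
    gene_id: str
    gtss_height: float
    itss_height: float

    @property
    def ratio(self) -> float:
        return self.gtss_height / self.itss_height


@dataclass(frozen=True)
class TSSCallParams:
    """Thresholds for :func:`call_tss`.

    min_height: minimum normalized TEX+ value at the peak.
    min_step: minimum sharpness, peak height over the mean of the
        ``upstream_window`` nt immediately upstream (floored at
        ``pseudocount`` so flat-zero background does not divide by zero).
    min_tex_ratio: minimum TEX+/TEX- height ratio; 1.0 encodes
        "not diminished by TEX treatment".
    merge_window: within this many nt only the highest candidate is kept.
    """

    min_height: float = 10.0
    min_step: float = 3.0
    min_tex_ratio: float = 1.0
    upstream_window: int = 5
    pseudocount: float = 0.25
    merge_window: int = 3


def _upstream_background(track: CoverageTrack, pos: int, strand: str, w: int) -> float:
    if strand == "+":
        vals = track.slice(pos - w, pos - 1)
    else:
        vals = track.slice(pos + 1, pos + w)
    return float(np.mean(vals)) if len(vals) else 0.0


def call_tss(
    tex_plus: CoverageTrack,
    tex_minus: CoverageTrack,
    params: TSSCallParams = TSSCallParams(),
) -> list[TSSRecord]:
    """Call sharp, TEX-resistant 5'-end peaks as TSS candidates.

    Both tracks must have been library-size normalized so their heights
    are comparable.  A position is a candidate when its TEX+ height,
    sharpness (step factor) and TEX+/TEX- ratio all meet the thresholds
    in ``params``; within ``merge_window`` nt only the highest candidate
    survives.
    """
    if tex_plus.chrom != tex_minus.chrom or tex_plus.strand != tex_minus.strand:
        raise ValueError("TEX+ and TEX- tracks must share chrom and strand")
    if not (tex_plus.normalized and tex_minus.normalized):
        raise ValueError("call_tss requires normalized tracks (see normalize_coverage)")
    strand = tex_plus.strand
    p = params
    candidates: list[TSSRecord] = []
    for i, h in enumerate(tex_plus.values):
        if h < p.min_height:
            continue
        pos = tex_plus.start + i
        bg = _upstream_background(tex_plus, pos, strand, p.upstream_window)
        step = h / max(bg, p.pseudocount)
        if step < p.min_step:
            continue
        minus_h = tex_minus.value_at(pos)
        ratio = h / minus_h if minus_h > 0 else float("inf")
        if ratio < p.min_tex_ratio:
            continue
        candidates.append(TSSRecord(tex_plus.chrom, strand, pos, float(h), ratio, step))
    # keep only the highest candidate within each merge window
    kept: list[TSSRecord] = []
    for rec in sorted(candidates, key=lambda r: (-r.height, r.pos)):
        if all(abs(rec.pos - k.pos) > p.merge_window for k in kept):
            kept.append(rec)
    return sorted(kept, key=lambda r: r.pos)


def classify_tss(
    tss: TSSRecord,
    genes: Sequence[GeneRecord],
    exclude_gene_id: str | None = None,
) -> str:
    """Classify a TSS as internal (iTSS) or gene TSS (gTSS).

    A TSS is internal when it lies within the body of a same-strand gene
    other than ``exclude_gene_id`` (the gene the TSS is being assigned
    to), strictly downstream of that gene's own start codon — so a
    leaderless TSS at a gene's first nucleotide remains a gTSS.  TSSs
    inside antisense genes are gTSSs: internal status requires the
    harbouring gene to be transcribed in the same direction.
    """
    for g in genes:
        if g.chrom != tss.chrom or g.strand != tss.strand:
            continue
        if g.gene_id == exclude_gene_id:
            continue
        if g.strand == "+":
            inside = g.start < tss.pos <= g.end
        else:
            inside = g.start <= tss.pos < g.end
        if inside:
            return "iTSS"
    return "gTSS"


def link_deg_to_tss(
    deg_gene: GeneRecord,
    tss_list: Sequence[TSSRecord],
    window_nt: int = 200,
    direction_of_change: str = "up",
) -> DEGLink:
    """Assign a gene the TSS in its upstream window, if any.

    Candidate TSSs lie on the gene's strand with a distance to the first
    start-codon nucleotide in [0, window_nt] (0 = leaderless; distances
    beyond the window leave the gene unassigned).  Among several
    candidates the highest peak wins; ties go to the smaller distance.
    """
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    anchor = deg_gene.start_codon_pos
    best: TSSRecord | None = None
    best_d: int | None = None
    for t in tss_list:
        if t.chrom != deg_gene.chrom or t.strand != deg_gene.strand:
            continue
        d = anchor - t.pos if deg_gene.strand == "+" else t.pos - anchor
        if d < 0 or d > window_nt:
            continue
        if best is None or t.height > best.height or (
            t.height == best.height and d < best_d
        ):
            best, best_d = t, d
    return DEGLink(deg_gene.gene_id, best, best_d, direction_of_change)


def peak_ratio_table(
    deg_links: Sequence[DEGLink],
    tss_list: Sequence[TSSRecord],
    max_operon_span: int = 10_000,
) -> list[PeakRatio]:
    """Ratio of the strongest upstream gTSS to each DEG's internal TSS.

    For every DEG whose assigned TSS is internal, same-strand gTSSs up to
    ``max_operon_span`` nt upstream are searched and the highest peak is
    taken; a large ratio means the internal start is weak relative to the
    operon promoter.  DEGs without an upstream gTSS in range are skipped
    with a warning.
    """
    ratios: list[PeakRatio] = []
    for link in deg_links:
        t = link.tss
        if t is None or t.tss_class != "iTSS":
            continue
        upstream = [
            g
            for g in tss_list
            if g.tss_class == "gTSS"
            and g.chrom == t.chrom
            and g.strand == t.strand
            and 0 < (t.pos - g.pos if t.strand == "+" else g.pos - t.pos)
            <= max_operon_span
        ]
        if not upstream:
            warnings.warn(
                f"no upstream gTSS within {max_operon_span} nt for {link.gene_id}"
            )
            continue
        g = max(upstream, key=lambda r: r.height)
        ratios.append(PeakRatio(link.gene_id, g.height, t.height))
    return ratios


def count_ratios_above(ratios: Sequence[PeakRatio], cutoff: float = 5.0) -> int:
    """Number of gTSS/iTSS peak ratios exceeding ``cutoff``."""
    return sum(1 for r in ratios if r.ratio > cutoff)


def tss_table(tss_list: Sequence[TSSRecord]) -> pd.DataFrame:
    """TSS records as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "strand": t.strand,
                "pos": t.pos,
                "height": t.height,
                "tex_ratio": t.tex_ratio,
                "step_factor": t.step_factor,
                "class": t.tss_class,
            }
            for t in tss_list
        ]
    )


def read_tss_table(path) -> list[TSSRecord]:
    """Read a TSS table (ours or an externally produced one) back to records."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        records.append(
            TSSRecord(
                str(row["chrom"]),
                str(row["strand"]),
                int(row["pos"]),
                float(row["height"]),
                float(row.get("tex_ratio", np.inf)),
                float(row.get("step_factor", np.inf)),
                str(row.get("class", "unassigned")),
            )
        )
    return records
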