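"""ChIP peak filtering, promoter assignment and genomic classification.

Peaks are intervals with antibody-sample and IgG-control read depths.
Filtering keeps peaks whose pseudocounted depth ratio is strictly above a
fold threshold (default 2).  Kept peaks are assigned to genes whose
promoter window (default -5 kb..+0.5 kb around the TSS, strand-aware)
they overlap by at least one base, and classified by precedence
promoter > exon > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

PEAK_COLUMNS = ["contig", "start", "end", "name", "sample_depth", "control_depth"]


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: strand-aware TSS plus exon structure.

    *tss* is the 0-based coordinate of the first transcribed base; exons
    are 0-based half-open, sorted and non-overlapping; *span* is the full
    transcribed interval.
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        prev_end = -1
        for s, e in self.exons:
            if e <= s or s < prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted, non-overlapping")
            prev_end = e
        if self.exons:
            span = self.span
            expected = span[0] if self.strand == "+" else span[1] - 1
            if self.tss != expected:
                raise ValueError(f"{self.gene_id}: tss inconsistent with strand and exons")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1]) if self.exons else (self.tss, self.tss + 1)

    def promoter_window(self, upstream: int = 5000, downstream: int = 500) -> tuple[int, int]:
        """Half-open promoter interval, mirrored on the minus strand."""
        if self.strand == "+":
            return (self.tss - upstream, self.tss + downstream)
        return (self.tss - downstream + 1, self.tss + upstream + 1)


def add_fold(peaks: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Attach ``fold = (sample + c) / (control + c)``."""
    if (peaks["sample_depth"] < 0).any() or (peaks["control_depth"] < 0).any():
        raise ValueError("read depths must be >= 0")
    out = peaks.copy()
    out["fold"] = (out["sample_depth"] + pseudocount) / (out["control_depth"] + pseudocount)
    return out


def filter_peaks_fold(
    peaks: pd.DataFrame, fold_threshold: float = 2.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Keep peaks with fold enrichment strictly above *fold_threshold*."""
    out = add_fold(peaks, pseudocount)
    return out.loc[out["fold"] > fold_threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# interval indexing
# ---------------------------------------------------------------------------

def _build_trees(
    models: Sequence[GeneModel], upstream: int, downstream: int
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree], dict[str, IntervalTree]]:
    """Per-contig interval trees for promoters, exons and gene spans."""
    promoters: dict[str, IntervalTree] = {}
    exons: dict[str, IntervalTree] = {}
    spans: dict[str, IntervalTree] = {}
    for gm in models:
        s, e = gm.promoter_window(upstream, downstream)
        promoters.setdefault(gm.contig, IntervalTree())[max(0, s):e] = gm.gene_id
        for xs, xe in gm.exons:
            exons.setdefault(gm.contig, IntervalTree())[xs:xe] = gm.gene_id
        ss, se = gm.span
        spans.setdefault(gm.contig, IntervalTree())[ss:se] = gm.gene_id
    return promoters, exons, spans


def assign_to_promoters(
    peaks: pd.DataFrame,
    models: Sequence[GeneModel],
    upstream: int = 5000,
    downstream: int = 500,
) -> tuple[set[str], pd.DataFrame]:
    """Genes whose promoter window a peak overlaps by >= 1 base.

    A peak may hit several promoters; the returned gene set is
    de-duplicated.  The per-peak table lists assigned genes
    semicolon-joined (empty string when none).
    """
    trees, _, _ = _build_trees(models, upstream, downstream)
    genes: set[str] = set()
    rows = []
    for row in peaks.itertuples(index=False):
        tree = trees.get(row.contig)
        hit = sorted({iv.data for iv in tree.overlap(row.start, row.end)}) if tree else []
        genes.update(hit)
        rows.append(
            {"name": row.name, "contig": row.contig, "start": row.start,
             "end": row.end, "genes": ";".join(hit)}
        )
    return genes, pd.DataFrame(rows, columns=["name", "contig", "start", "end", "genes"])


def classify_region(
    peak: tuple[str, int, int],
    models: Sequence[GeneModel] | tuple,
    upstream: int = 5000,
    downstream: int = 500,
) -> str:
    """Class of one peak with precedence promoter > exon > intron > intergenic.

    *peak* is ``(contig, start, end)``; intron means inside a gene span but
    not overlapping any exon or promoter window.
    """
    trees = models if isinstance(models, tuple) and models and isinstance(
        models[0], dict
    ) else _build_trees(models, upstream, downstream)
    promoters, exons, spans = trees
    contig, start, end = peak
    if contig in promoters and promoters[contig].overlap(start, end):
        return "promoter"
    if contig in exons and exons[contig].overlap(start, end):
        return "exon"
    if contig in spans and spans[contig].overlap(start, end):
        return "intron"
    return "intergenic"


def classify_peaks(
    peaks: pd.DataFrame,
    models: Sequence[GeneModel],
    upstream: int = 5000,
    downstream: int = 500,
) -> pd.DataFrame:
    """Classify every peak; adds a ``region_class`` column."""
    trees = _build_trees(models, upstream, downstream)
    out = peaks.copy()
    out["region_class"] = [
        classify_region((r.contig, r.start, r.end), trees)
        for r in peaks.itertuples(index=False)
    ]
    return out


def class_fractions(classified: pd.DataFrame) -> dict[str, float]:
    """Fraction of peaks per region class (all four classes present)."""
    counts = classified["region_class"].value_counts()
    n = max(1, len(classified))
    return {c: float(counts.get(c, 0)) / n for c in ("promoter", "exon", "intron", "intergenic")}
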