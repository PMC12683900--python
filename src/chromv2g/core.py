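"""Genomic interval primitives shared by every pipeline stage.

All internal coordinates are 0-based, half-open ``[start, end)``.  Inputs
that arrive 1-based (TSS tables, summary-statistic positions) are converted
on read and never stored in mixed conventions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based point; start inclusive, end exclusive."""
        return chrom == self.chrom and self.start <= pos0 < self.end

    def expanded(self, flank: int) -> "GenomicInterval":
        """Return the interval widened by ``flank`` bp each side (clamped at 0)."""
        if flank < 0:
            raise ValueError("flank must be >= 0")
        return GenomicInterval(self.chrom, max(0, self.start - flank), self.end + flank, self.strand)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open semantics: abutting intervals (``a.end == b.start``) do not
    overlap, and intervals on different chromosomes never do.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True, slots=True)
class Ocr:
    """An open chromatin region (ATAC-seq peak) in one cell type."""

    interval: GenomicInterval
    cell_type: str
    peak_id: str


@dataclass(frozen=True, slots=True)
class Loop:
    """An intra-chromosomal promoter-interaction loop (Capture-C or Hi-C).

    ``anchor1`` holds the bait side for ibed input; for BEDPE the two blocks
    are taken in file order.  Inter-chromosomal records are rejected because
    contact-based gene assignment is cis-only.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    cell_type: str
    loop_id: str
    source: str = "pcc"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(
                f"loop {self.loop_id}: anchors on different chromosomes "
                f"({self.anchor1.chrom} vs {self.anchor2.chrom})"
            )
        if self.source not in {"pcc", "hic"}:
            raise ValueError(f"loop source must be 'pcc' or 'hic', got {self.source!r}")


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """One transcription start site of a gene (1-based TSS position)."""

    gene_id: str
    gene_name: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"gene {self.gene_id}: TSS must be >= 1 (1-based)")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True, slots=True)
class PromoterWindow:
    """The promoter interval of one gene TSS (default -1500/+500 bp)."""

    gene: GeneAnnotation
    interval: GenomicInterval


@dataclass(frozen=True, slots=True)
class SummaryStatRecord:
    """One harmonized GWAS/eQTL association (beta is ln(OR) for case-control)."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float = 1.0
    maf: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.variant_id}: pvalue must be in (0,1]")


def make_promoters(
    genes: Iterable[GeneAnnotation],
    upstream: int = 1500,
    downstream: int = 500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[PromoterWindow]:
    """Build promoter windows of ``-upstream/+downstream`` bp around each TSS.

    The window is strand-aware: "upstream" means 5' of the TSS on the gene's
    own strand.  With the defaults this yields a 2-kb window covering
    [TSS-1500, TSS+500) in transcript orientation.  Windows are clamped to
    ``[0, chrom_size)`` rather than rejected, so genes near a chromosome edge
    keep a (shorter) promoter.

    Parameters
    ----------
    genes
        TSS records (1-based positions).
    upstream, downstream
        Extents in bp; both must be >= 0 and sum to >= 1.
    chrom_sizes
        chrom -> length map used for clamping.  If given, every gene's
        chromosome must be present.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    out: list[PromoterWindow] = []
    for g in genes:
        if chrom_sizes is not None and g.chrom not in chrom_sizes:
            raise KeyError(f"chromosome {g.chrom!r} not in chrom_sizes")
        tss0 = g.tss - 1  # to 0-based
        if g.strand == "+":
            start, end = tss0 - upstream, tss0 + downstream
        else:
            start, end = tss0 - downstream + 1, tss0 + upstream + 1
        start = max(0, start)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g.chrom])
        if end <= start:  # degenerate after clamping; keep the TSS base itself
            start, end = tss0, tss0 + 1
        out.append(PromoterWindow(g, GenomicInterval(g.chrom, start, end, g.strand)))
    return out


class IntervalIndex:
    """Per-chromosome interval tree mapping intervals to arbitrary payloads."""

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for iv, payload in items:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object) -> None:
        self._trees[iv.chrom].addi(iv.start, iv.end, payload)

    def query(self, iv: GenomicInterval) -> list[object]:
        """Payloads of all stored intervals overlapping ``iv`` (>= 1 bp)."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def query_point(self, chrom: str, pos0: int) -> list[object]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos0)]

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (not merely abutting) intervals per chromosome.

    Returns a sorted, pairwise non-overlapping list.  Abutting intervals
    ([a,b) and [b,c)) are kept separate, consistent with half-open overlap.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (0-based half-open) into an interval."""
    try:
        chrom, rng = text.rsplit(":", 1)
        start_s, end_s = rng.replace(",", "").split("-")
        return GenomicInterval(chrom, int(start_s), int(end_s))
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end") from exc
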