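"""cis-Regulatory element definition and S-LDSC annotation export.

A cRE is an ATAC-seq open chromatin region (OCR) that physically contacts a
gene promoter through a chromatin loop: one loop anchor overlaps the OCR and
the *other* anchor overlaps a promoter window (-1500/+500 bp of a TSS).  By
default the contacted promoter must itself be open (overlap an OCR of the
same cell type), restricting V2G to promoters with regulatory potential in
that cell state.

Open chromatin is further partitioned into the five annotation categories
used for stratified LD-score regression: all OCRs, promoter OCRs, cREs,
cREs flanked by 500 bp, and the non-cRE non-promoter negative control.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .core import (
    GenomicInterval,
    IntervalIndex,
    Loop,
    Ocr,
    PromoterWindow,
    merge_intervals,
    overlaps,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CisRegElement:
    """An OCR plus the gene promoters it contacts through loops."""

    ocr: Ocr
    contacted_genes: frozenset[str]
    supporting_loops: frozenset[str]

    def __post_init__(self) -> None:
        if not self.contacted_genes:
            raise ValueError(f"cRE {self.ocr.peak_id}: contacted_genes must be non-empty")

    @property
    def cell_type(self) -> str:
        return self.ocr.cell_type

    @property
    def cre_id(self) -> str:
        return self.ocr.peak_id


class AnnotCategory(str, Enum):
    ALL_OCR = "ALL_OCR"
    PROMOTER_OCR = "PROMOTER_OCR"
    CRE = "CRE"
    CRE_FLANK500 = "CRE_FLANK500"
    NON_CRE_NON_PROM = "NON_CRE_NON_PROM"


@dataclass
class AnnotationPartition:
    """The five S-LDSC input region sets for one cell type.

    Categories are not mutually exclusive (a promoter OCR may also be a cRE);
    the negative control is defined by exclusion from both.
    """

    cell_type: str
    categories: dict[AnnotCategory, list[GenomicInterval]]


def define_cres(
    ocrs: Sequence[Ocr],
    loops: Sequence[Loop],
    promoters: Sequence[PromoterWindow],
    require_open_promoter: bool = True,
) -> list[CisRegElement]:
    """Intersect OCRs with loop anchors and promoter windows to call cREs.

    An OCR becomes a cRE iff some loop has one anchor overlapping the OCR
    and its partner anchor overlapping >=1 promoter window (of an open
    promoter when ``require_open_promoter``).  Contact requires the two
    distinct anchors of a loop: a single anchor covering both the OCR and a
    promoter does not qualify (self-contact excluded).  Anchor overlap is
    >=1 bp.  Duplicate loops are collapsed here on (anchor1, anchor2): each
    distinct contact geometry contributes once, but every supporting loop id
    is retained on the cRE.

    All inputs must share one cell type.
    """
    cell_types = {o.cell_type for o in ocrs} | {l.cell_type for l in loops}
    if len(cell_types) > 1:
        raise ValueError(f"define_cres needs a single cell type, got {sorted(cell_types)}")

    ocr_index = IntervalIndex((o.interval, o) for o in ocrs)
    prom_index = IntervalIndex((p.interval, p) for p in promoters)

    n_dup = 0
    seen_geometries: set[tuple] = set()
    contacts: dict[str, tuple[Ocr, set[str], set[str]]] = {}

    def promoter_is_open(window: PromoterWindow) -> bool:
        return bool(ocr_index.query(window.interval))

    for loop in loops:
        geom = (
            loop.anchor1.chrom, loop.anchor1.start, loop.anchor1.end,
            loop.anchor2.start, loop.anchor2.end,
        )
        if geom in seen_geometries:
            n_dup += 1
        seen_geometries.add(geom)
        for ocr_anchor, prom_anchor in ((loop.anchor1, loop.anchor2), (loop.anchor2, loop.anchor1)):
            proms = [
                p for p in prom_index.query(prom_anchor)
                if not require_open_promoter or promoter_is_open(p)
            ]
            if not proms:
                continue
            for ocr in ocr_index.query(ocr_anchor):
                entry = contacts.setdefault(ocr.peak_id, (ocr, set(), set()))
                entry[1].update(p.gene.gene_id for p in proms)
                entry[2].add(loop.loop_id)
    if n_dup:
        logger.info("define_cres: %d duplicate loop geometries collapsed", n_dup)

    return [
        CisRegElement(ocr, frozenset(genes), frozenset(loop_ids))
        for ocr, genes, loop_ids in (contacts[k] for k in sorted(contacts))
    ]


def partition_annotations(
    ocrs: Sequence[Ocr],
    cres: Sequence[CisRegElement],
    promoters: Sequence[PromoterWindow],
    flank: int = 500,
) -> AnnotationPartition:
    """Partition open chromatin into the five S-LDSC annotation categories."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    cell_types = {o.cell_type for o in ocrs}
    if len(cell_types) != 1:
        raise ValueError("partition_annotations needs exactly one cell type of OCRs")
    cell_type = cell_types.pop()

    prom_index = IntervalIndex((p.interval, p) for p in promoters)
    cre_ids = {c.cre_id for c in cres}

    all_ocr = [o.interval for o in ocrs]
    promoter_ocr = [o.interval for o in ocrs if prom_index.query(o.interval)]
    cre_ivs = [c.ocr.interval for c in cres]
    flanked = merge_intervals([iv.expanded(flank) for iv in cre_ivs]) if cre_ivs else []
    negative = [
        o.interval
        for o in ocrs
        if o.peak_id not in cre_ids and not prom_index.query(o.interval)
    ]
    return AnnotationPartition(
        cell_type,
        {
            AnnotCategory.ALL_OCR: all_ocr,
            AnnotCategory.PROMOTER_OCR: promoter_ocr,
            AnnotCategory.CRE: cre_ivs,
            AnnotCategory.CRE_FLANK500: flanked,
            AnnotCategory.NON_CRE_NON_PROM: negative,
        },
    )


@dataclass(frozen=True, slots=True)
class LdscAnnotationRecord:
    """One row of an LDSC .annot file (1-based BP, 0/1 membership)."""

    chrom: str
    bp: int
    snp_id: str
    cm: float
    annot: int


def export_ldsc_annot(
    partition: AnnotationPartition,
    variant_template: Sequence[tuple[str, int, str, float]],
    category: AnnotCategory,
) -> list[LdscAnnotationRecord]:
    """Mark template variants falling inside a category's intervals.

    ``variant_template`` rows are (chrom, bp [1-based], snp_id, cm) and must
    be sorted by (chrom, bp), matching LDSC's per-chromosome template files.
    Membership converts bp to a 0-based point and applies half-open interval
    semantics.  Output order equals template order, one record per variant.
    """
    prev: Optional[tuple[str, int]] = None
    for chrom, bp, _snp, _cm in variant_template:
        if prev is not None and (chrom, bp) < prev:
            raise ValueError("variant template must be sorted by (chrom, bp)")
        prev = (chrom, bp)
    index = IntervalIndex((iv, True) for iv in partition.categories[category])
    return [
        LdscAnnotationRecord(chrom, bp, snp, cm, 1 if index.query_point(chrom, bp - 1) else 0)
        for chrom, bp, snp, cm in variant_template
    ]


def write_annot_file(
    records: Iterable[LdscAnnotationRecord],
    path: str,
    compress: bool = False,
) -> None:
    """Write records as a tab-separated LDSC .annot(.gz) file."""
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        fh.write("CHR\tBP\tSNP\tCM\tANNOT\n")
        for r in records:
            chrom = r.chrom[3:] if r.chrom.startswith("chr") else r.chrom
            fh.write(f"{chrom}\t{r.bp}\t{r.snp_id}\t{r.cm:g}\t{r.annot}\n")


def write_category_bed(partition: AnnotationPartition, category: AnnotCategory, path: str) -> None:
    with open(path, "w") as fh:
        for iv in sorted(partition.categories[category], key=lambda x: (x.chrom, x.start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
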