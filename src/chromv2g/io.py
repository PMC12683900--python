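"""Readers and writers for the plain-text interchange formats.

Covered formats: BED3/BED4 peak files, BEDPE and CHiCAGO-style ibed loop
files, TSV gene/TSS tables, two-column chrom-sizes files, and schema-mapped
GWAS/eQTL summary-statistic TSVs.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .core import GenomicInterval, GeneAnnotation, Loop, Ocr, SummaryStatRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

IBED_COLUMNS = [
    "bait_chr", "bait_start", "bait_end", "bait_name",
    "otherEnd_chr", "otherEnd_start", "otherEnd_end", "otherEnd_name",
    "N_reads", "score",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def read_bed(path: PathLike, cell_type: str) -> list[Ocr]:
    """Read a BED3/BED4 peak file into ``Ocr`` records.

    BED is 0-based half-open, matching the internal convention, so the
    coordinates are taken verbatim.  ``peak_id`` comes from column 4 when
    present, else ``chrom:start-end``.
    """
    out: list[Ocr] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            peak_id = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            if peak_id in seen_ids:
                raise FormatError(f"{path}: line {lineno}: duplicate peak_id {peak_id!r}")
            seen_ids.add(peak_id)
            out.append(Ocr(GenomicInterval(chrom, start, end), cell_type, peak_id))
    return out


def write_bed(path: PathLike, ocrs: Iterable[Ocr]) -> None:
    with open(path, "w") as fh:
        for ocr in ocrs:
            iv = ocr.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ocr.peak_id}\n")


def read_loops(
    path: PathLike,
    format: str,
    cell_type: str,
    source: str = "pcc",
) -> list[Loop]:
    """Read loops from an ibed (headered) or BEDPE file.

    Inter-chromosomal lines are dropped with a logged count — all downstream
    contact logic is cis-only.  Duplicate lines are retained (with distinct
    loop ids); deduplication, where wanted, is an explicit later step.
    """
    if format not in {"ibed", "bedpe"}:
        raise ValueError(f"format must be 'ibed' or 'bedpe', got {format!r}")
    loops: list[Loop] = []
    n_inter = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    start_at = 0
    if format == "ibed":
        if not lines:
            raise FormatError(f"{path}: empty ibed file (header expected)")
        header = lines[0].split("\t")
        missing = [c for c in IBED_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: ibed header missing columns {missing}")
        col = {c: header.index(c) for c in IBED_COLUMNS}
        start_at = 1
    for idx, line in enumerate(lines[start_at:], start=start_at + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if format == "ibed":
            if len(fields) < len(header):
                raise FormatError(f"{path}: line {idx}: expected {len(header)} columns")
            c1, s1, e1 = fields[col["bait_chr"]], fields[col["bait_start"]], fields[col["bait_end"]]
            c2, s2, e2 = (
                fields[col["otherEnd_chr"]],
                fields[col["otherEnd_start"]],
                fields[col["otherEnd_end"]],
            )
            score: Optional[float] = float(fields[col["score"]])
        else:
            if len(fields) < 6:
                raise FormatError(f"{path}: line {idx}: BEDPE needs >=6 columns")
            c1, s1, e1, c2, s2, e2 = fields[:6]
            score = float(fields[7]) if len(fields) >= 8 and fields[7] not in {".", ""} else None
        if c1 != c2:
            n_inter += 1
            continue
        loop_id = f"{cell_type}_{source}_{len(loops)}"
        loops.append(
            Loop(
                GenomicInterval(c1, int(s1), int(e1)),
                GenomicInterval(c2, int(s2), int(e2)),
                cell_type,
                loop_id,
                source=source,
                score=score,
            )
        )
    if n_inter:
        logger.info("%s: dropped %d inter-chromosomal loop lines", path, n_inter)
    if not loops:
        raise FormatError(f"{path}: no valid intra-chromosomal loop lines")
    return loops


def write_loops_ibed(path: PathLike, loops: Iterable[Loop]) -> None:
    """Write loops as CHiCAGO-style ibed (anchor1 = bait)."""
    with open(path, "w") as fh:
        fh.write("\t".join(IBED_COLUMNS) + "\n")
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            score = lp.score if lp.score is not None else 5.0
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{lp.loop_id}_bait\t"
                f"{b.chrom}\t{b.start}\t{b.end}\t{lp.loop_id}_oe\t"
                f"10\t{score:g}\n"
            )


def read_tss_table(path: PathLike) -> list[GeneAnnotation]:
    """Read a TSV gene table: gene_id, gene_name, chrom, tss (1-based), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "gene_name", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: TSS table missing columns {sorted(missing)}")
    return [
        GeneAnnotation(r.gene_id, r.gene_name, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_tss_table(path: PathLike, genes: Iterable[GeneAnnotation]) -> None:
    rows = [
        {"gene_id": g.gene_id, "gene_name": g.gene_name, "chrom": g.chrom,
         "tss": g.tss, "strand": g.strand}
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


#: Default column mapping for summary-statistic TSVs; override per dataset.
DEFAULT_SUMSTAT_SCHEMA: dict[str, str] = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "maf": "maf",
    "n": "n",
}

_MANDATORY_FIELDS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele", "se")


def read_sumstats(
    path: PathLike,
    schema: Optional[Mapping[str, str]] = None,
) -> list[SummaryStatRecord]:
    """Read a summary-statistic TSV under a declared column mapping.

    ``schema`` maps canonical field names to file column names.  Either a
    ``beta`` or an ``or`` (odds-ratio) column must be mapped; odds ratios are
    converted to log-odds.  Rows with se <= 0 or a missing position are
    dropped with a logged count rather than aborting the read.
    """
    sch = dict(DEFAULT_SUMSTAT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path, sep="\t", dtype={sch["chrom"]: str})
    for fieldname in _MANDATORY_FIELDS:
        if sch.get(fieldname) not in df.columns:
            raise FormatError(
                f"{path}: mandatory field {fieldname!r} not mapped to an existing "
                f"column (looked for {sch.get(fieldname)!r})"
            )
    has_beta = sch.get("beta") in df.columns
    has_or = sch.get("or") in df.columns
    if not (has_beta or has_or):
        raise FormatError(f"{path}: need a 'beta' or 'or' column mapping")

    out: list[SummaryStatRecord] = []
    n_dropped = 0
    for rec in df.to_dict("records"):  # itertuples would mangle names like 'or'
        pos = rec.get(sch["pos"])
        se = rec.get(sch["se"])
        if pos is None or (isinstance(pos, float) and math.isnan(pos)) or se is None or se <= 0:
            n_dropped += 1
            continue
        if has_beta:
            beta = float(rec[sch["beta"]])
        else:
            or_val = float(rec[sch["or"]])
            if or_val <= 0:
                n_dropped += 1
                continue
            beta = math.log(or_val)
        maf = rec.get(sch.get("maf", ""), None)
        if maf is not None and isinstance(maf, float) and math.isnan(maf):
            maf = None
        n_val = rec.get(sch.get("n", ""), None)
        if n_val is not None and isinstance(n_val, float) and math.isnan(n_val):
            n_val = None
        pval = rec.get(sch.get("pvalue", ""), 1.0)
        if pval is None or (isinstance(pval, float) and math.isnan(pval)):
            pval = 1.0
        out.append(
            SummaryStatRecord(
                variant_id=str(rec[sch["variant_id"]]),
                chrom=str(rec[sch["chrom"]]),
                pos=int(pos),
                effect_allele=str(rec[sch["effect_allele"]]),
                other_allele=str(rec[sch["other_allele"]]),
                beta=beta,
                se=float(se),
                pvalue=float(pval),
                maf=float(maf) if maf is not None else None,
                n=int(n_val) if n_val is not None else None,
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d rows (se<=0, missing position, or OR<=0)", path, n_dropped)
    return out


def read_gene_list(path: PathLike) -> set[str]:
    """Read a plain-text gene list (one symbol per line, case-normalized)."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            name = line.strip()
            if name and not name.startswith("#"):
                genes.add(name.upper())
    return genes
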