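"""Variant-to-gene mapping through cRE-promoter contacts.

GWAS sentinels are expanded to their LD proxies (r2 >= 0.8), the extended-LD
MHC region is masked out, and each remaining proxy is placed within the cRE
landscape of every cell type: a proxy falling inside a cRE is assigned to
every gene whose promoter that cRE contacts, yielding the central
(trait, sentinel, proxy, cell type, cRE, gene) pair table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import GenomicInterval, IntervalIndex
from .cre import CisRegElement

logger = logging.getLogger(__name__)

#: Extended-LD MHC mask on GRCh38; co-inherited proxies cannot be confidently
#: resolved here, so the whole window is excluded from mapping.
MHC_GRCH38 = GenomicInterval("chr6", 25_000_000, 34_000_000)

PAIR_COLUMNS = ["trait", "sentinel_id", "proxy_id", "cell_type", "cre_id", "gene_id", "loop_ids"]


@dataclass(frozen=True, slots=True)
class Sentinel:
    """A reported genome-wide-significant GWAS lead variant."""

    trait: str
    variant_id: str
    chrom: str
    pos: int  # 1-based


@dataclass(frozen=True, slots=True)
class Proxy:
    """A variant in LD with a sentinel (the sentinel itself has r2 = 1)."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    r2: float
    sentinel: Sentinel
    provenance: str = "ld"  # "ld", "self", or "credible_set"

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise ValueError(f"proxy {self.variant_id}: r2 must be in [0,1], got {self.r2}")


def filter_proxies(
    raw_proxies: Sequence[Proxy],
    sentinels: Sequence[Sentinel],
    r2_min: float = 0.8,
    mhc: Optional[GenomicInterval] = MHC_GRCH38,
) -> list[Proxy]:
    """Apply the LD threshold and MHC mask; ensure each sentinel self-proxies.

    Keeps proxies with r2 >= ``r2_min`` whose position (and whose sentinel's
    position) lies outside ``mhc``.  A sentinel absent from the proxy table
    is added as its own proxy with r2 = 1.0, since a variant is trivially in
    perfect LD with itself.  Credible-set variants ingested with r2 = 1.0
    pass the threshold by construction.
    """

    def in_mhc(chrom: str, pos: int) -> bool:
        return mhc is not None and mhc.contains_point(chrom, pos - 1)

    kept: list[Proxy] = []
    n_low_r2 = n_mhc = 0
    self_covered: set[tuple[str, str]] = set()
    for p in raw_proxies:
        if p.r2 < r2_min:
            n_low_r2 += 1
            continue
        if in_mhc(p.chrom, p.pos) or in_mhc(p.sentinel.chrom, p.sentinel.pos):
            n_mhc += 1
            continue
        kept.append(p)
        if p.variant_id == p.sentinel.variant_id:
            self_covered.add((p.sentinel.trait, p.sentinel.variant_id))
    for s in sentinels:
        if (s.trait, s.variant_id) in self_covered or in_mhc(s.chrom, s.pos):
            continue
        kept.append(Proxy(s.variant_id, s.chrom, s.pos, 1.0, s, provenance="self"))
    if n_low_r2 or n_mhc:
        logger.info(
            "filter_proxies: dropped %d below r2 %.2f and %d in MHC mask", n_low_r2, r2_min, n_mhc
        )
    return kept


def map_variants_to_genes(
    proxies: Sequence[Proxy],
    cres_by_cell_type: Mapping[str, Sequence[CisRegElement]],
) -> pd.DataFrame:
    """Place proxies in each cell type's cRE landscape and emit variant-gene pairs.

    A proxy positioned inside a cRE (half-open membership of its 0-based
    point) yields one pair per contacted gene.  Pairs are deduplicated on
    (trait, proxy, cell type, gene): when overlapping cREs implicate the
    same gene, one row carries the union of supporting loop ids and the
    lexically first cRE id.  Proxies in no cRE contribute nothing.

    Returns a DataFrame with columns ``PAIR_COLUMNS`` (loop_ids
    comma-joined, sorted).
    """
    # key -> [trait, sentinel, proxy, cell_type, cre_ids, gene, loop_ids]
    acc: dict[tuple[str, str, str, str], dict] = {}
    for cell_type, cres in cres_by_cell_type.items():
        index = IntervalIndex((c.ocr.interval, c) for c in cres)
        for p in proxies:
            for cre in index.query_point(p.chrom, p.pos - 1):
                for gene in cre.contacted_genes:
                    key = (p.sentinel.trait, p.variant_id, cell_type, gene)
                    entry = acc.setdefault(
                        key,
                        {
                            "trait": p.sentinel.trait,
                            "sentinel_id": p.sentinel.variant_id,
                            "proxy_id": p.variant_id,
                            "cell_type": cell_type,
                            "cre_ids": set(),
                            "gene_id": gene,
                            "loop_ids": set(),
                        },
                    )
                    entry["cre_ids"].add(cre.cre_id)
                    entry["loop_ids"].update(cre.supporting_loops)
    rows = []
    for key in sorted(acc):
        e = acc[key]
        rows.append(
            {
                "trait": e["trait"],
                "sentinel_id": e["sentinel_id"],
                "proxy_id": e["proxy_id"],
                "cell_type": e["cell_type"],
                "cre_id": sorted(e["cre_ids"])[0],
                "gene_id": e["gene_id"],
                "loop_ids": ",".join(sorted(e["loop_ids"])),
            }
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def genes_per_variant(pairs: pd.DataFrame) -> tuple[pd.Series, float]:
    """Distinct-gene counts per (proxy, cell type) and their overall mean.

    This is the "genes contacted per accessible variant in a given cell
    type" statistic; the mean is taken over (proxy, cell type) observations.
    """
    if pairs.empty:
        raise ValueError("empty pair table")
    counts = pairs.groupby(["proxy_id", "cell_type"])["gene_id"].nunique()
    return counts, float(counts.mean())


def read_proxy_table(path: str) -> tuple[list[Sentinel], list[Proxy]]:
    """Read a proxy TSV: trait, sentinel, sentinel_chrom, sentinel_pos,
    proxy, chrom, pos, r2 [, provenance]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sentinel_chrom": str})
    required = {"trait", "sentinel", "sentinel_chrom", "sentinel_pos", "proxy", "chrom", "pos", "r2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: proxy table missing columns {sorted(missing)}")
    sentinels: dict[tuple[str, str], Sentinel] = {}
    proxies: list[Proxy] = []
    for row in df.itertuples(index=False):
        key = (row.trait, row.sentinel)
        if key not in sentinels:
            sentinels[key] = Sentinel(row.trait, row.sentinel, row.sentinel_chrom, int(row.sentinel_pos))
        prov = getattr(row, "provenance", "ld")
        proxies.append(
            Proxy(row.proxy, row.chrom, int(row.pos), float(row.r2), sentinels[key], provenance=prov)
        )
    return list(sentinels.values()), proxies


def write_pair_table(pairs: pd.DataFrame, path: str) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pair_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna({"loop_ids": ""})
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pair table missing columns {sorted(missing)}")
    return df[PAIR_COLUMNS]
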