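"""Synthetic multi-cell-type dataset with planted ground truth.

The generator emulates the downstream products of an ATAC-seq +
promoter-interaction study across several cell types, together with a
multi-trait GWAS sentinel/proxy structure and eQTL summary statistics, at a
desk scale where every pipeline stage's expected output is known exactly.

Layout.  Each chromosome is divided into one block per gene.  Within a
block, fixed sub-regions keep the planted features disjoint by
construction:

* the TSS (with its -1500/+500 promoter window) near the block start;
* a promoter OCR inside the window (present per cell type with probability
  ``p_open_promoter``, forced open where a loop targets the promoter);
* one distal candidate-cRE OCR mid-block;
* filler OCRs that never touch promoters or loops (negative controls);
* a "desert" zone holding negative-control loop anchors and non-causal
  proxies, guaranteed free of OCRs.

A planted fraction of blocks receives loops joining the distal OCR to 1-7
open promoters (the contact-degree distribution), in one or several cell
types; GWAS sentinels drop proxies into the distal OCRs (r2 straddling the
0.8 threshold, so the LD filter is exercised) and into the desert.  The
ground truth records exactly which (trait, sentinel, proxy, cell type, cRE,
gene) pairs a correct pipeline must recover.

All randomness flows from one ``numpy.random.default_rng(seed)``; the same
seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomicInterval, Loop, Ocr, make_promoters
from .io import write_bed, write_loops_ibed, write_tss_table
from .v2g import PAIR_COLUMNS, Proxy, Sentinel

# fixed offsets within a gene block (bp from block start)
_TSS_OFFSET = 20_000
_TSS_JITTER = 2_000
_DISTAL_OFFSET = 40_000
_DISTAL_WIDTH = 500
_FILLER_OFFSET = 48_000
_FILLER_SPACING = 1_500
_FILLER_WIDTH = 400
_DESERT_OFFSET = 56_000
_MIN_BLOCK = 64_000


@dataclass
class EqtlConfig:
    """Per-locus colocalization simulation settings."""

    n_snps: int = 200
    n_gwas: int = 10_000
    n_eqtl: int = 10_000
    causal_z: float = 8.0
    ld_rho: float = 0.9
    frac_h4: float = 0.5  # remaining planted loci are H3 (distinct causals)


@dataclass
class SimConfig:
    seed: int = 42
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 300
    n_cell_types: int = 4
    n_ocr_per_cell: int = 2_000
    frac_ocr_looped_to_promoter: float = 0.15
    p_open_promoter: float = 0.9
    n_traits: int = 3
    n_sentinels_per_trait: int = 20
    proxies_per_sentinel: tuple[int, int] = (5, 30)
    frac_causal_proxies_in_cre: float = 0.3
    frac_multi_trait_variants: float = 0.2
    frac_multi_cell_cres: float = 0.5
    eqtl: EqtlConfig = field(default_factory=EqtlConfig)
    mhc_mimic: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.n_genes, self.n_cell_types, self.n_traits) <= 0:
            raise ValueError("all counts must be > 0")
        for frac in (
            self.frac_ocr_looped_to_promoter,
            self.p_open_promoter,
            self.frac_causal_proxies_in_cre,
            self.frac_multi_trait_variants,
            self.frac_multi_cell_cres,
        ):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        block = self.chrom_length // max(1, self.n_genes // self.n_chroms)
        if block < _MIN_BLOCK:
            raise ValueError(
                f"infeasible density: {self.n_genes} genes on {self.n_chroms} x "
                f"{self.chrom_length} bp leaves {block} bp blocks (< {_MIN_BLOCK})"
            )

    @property
    def cell_types(self) -> list[str]:
        return [f"cell{j}" for j in range(self.n_cell_types)]

    @property
    def traits(self) -> list[str]:
        return [f"trait{j}" for j in range(self.n_traits)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{j + 1}": self.chrom_length for j in range(self.n_chroms)}


@dataclass
class GroundTruth:
    """Everything a correct pipeline must recover from the emitted files."""

    genes: list[GeneAnnotation] = field(default_factory=list)
    ocrs_by_cell: dict[str, list[Ocr]] = field(default_factory=dict)
    loops_by_cell: dict[str, list[Loop]] = field(default_factory=dict)
    # cell type -> {peak_id: (contacted gene ids, supporting loop ids)}
    cres_by_cell: dict[str, dict[str, tuple[frozenset, frozenset]]] = field(default_factory=dict)
    sentinels: list[Sentinel] = field(default_factory=list)
    proxies: list[Proxy] = field(default_factory=list)
    pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PAIR_COLUMNS))
    sentinel_ld: dict[frozenset, float] = field(default_factory=dict)  # pairwise r2
    coloc_labels: dict[str, str] = field(default_factory=dict)  # locus label -> h4|h3|null


@dataclass
class _Block:
    chrom: str
    start: int
    gene: GeneAnnotation
    distal_peak: GenomicInterval
    loop_cell_types: list[str] = field(default_factory=list)
    contacted: dict[str, list[str]] = field(default_factory=dict)  # ct -> gene ids
    loop_ids: dict[str, list[str]] = field(default_factory=dict)  # ct -> loop ids


def simulate_genome(config: SimConfig) -> GroundTruth:
    """Generate genes, per-cell-type OCRs and loops, with planted cREs."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    genes_per_chrom = config.n_genes // config.n_chroms
    extras = config.n_genes - genes_per_chrom * config.n_chroms
    blocks: list[_Block] = []

    gene_idx = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n_here = genes_per_chrom + (1 if ci < extras else 0)
        block_size = config.chrom_length // n_here
        for b in range(n_here):
            bstart = b * block_size
            tss = bstart + _TSS_OFFSET + int(rng.integers(0, _TSS_JITTER)) + 1  # 1-based
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneAnnotation(f"GENE{gene_idx:04d}", f"Gene{gene_idx:04d}", chrom, tss, strand)
            distal_start = bstart + _DISTAL_OFFSET + int(rng.integers(0, 500))
            blocks.append(
                _Block(chrom, bstart, gene,
                       GenomicInterval(chrom, distal_start, distal_start + _DISTAL_WIDTH))
            )
            gene_idx += 1
    truth.genes = [b.gene for b in blocks]
    promoters = {
        p.gene.gene_id: p for p in make_promoters(truth.genes, chrom_sizes=config.chrom_sizes)
    }

    # which blocks get loops, in which cell types, contacting which genes
    blocks_by_chrom: dict[str, list[_Block]] = {}
    for blk in blocks:
        blocks_by_chrom.setdefault(blk.chrom, []).append(blk)
    open_promoter: dict[tuple[str, str], bool] = {}  # (ct, gene_id) -> bool
    for blk in blocks:
        for ct in config.cell_types:
            open_promoter[(ct, blk.gene.gene_id)] = bool(rng.random() < config.p_open_promoter)

    for blk in blocks:
        if rng.random() >= config.frac_ocr_looped_to_promoter:
            continue
        if rng.random() < config.frac_multi_cell_cres and config.n_cell_types >= 2:
            k_cells = int(rng.integers(2, config.n_cell_types + 1))
        else:
            k_cells = 1
        cts = list(rng.choice(config.cell_types, size=k_cells, replace=False))
        blk.loop_cell_types = sorted(cts)
        # contact degree 1..7 (mean 4), targets = own gene + same-chrom neighbours
        degree = int(rng.integers(1, 8))
        siblings = blocks_by_chrom[blk.chrom]
        my_idx = siblings.index(blk)
        candidates = [blk] + [
            siblings[j]
            for j in range(max(0, my_idx - 4), min(len(siblings), my_idx + 5))
            if siblings[j] is not blk
        ]
        targets = candidates[:degree]
        for ct in blk.loop_cell_types:
            genes_ct, loops_ct = [], []
            for tgt in targets:
                # force the contacted promoter open so the cRE call is valid
                open_promoter[(ct, tgt.gene.gene_id)] = True
                genes_ct.append(tgt.gene.gene_id)
            blk.contacted[ct] = sorted(set(genes_ct))
            blk.loop_ids[ct] = loops_ct  # filled when loops are materialized

    # materialize OCRs and loops per cell type
    n_blocks = len(blocks)
    per_block_fillers = _filler_allocation(config, blocks, rng)
    for ct in config.cell_types:
        ocrs: list[Ocr] = []
        loops: list[Loop] = []
        neg_loop_count = 0
        for bi, blk in enumerate(blocks):
            prom_iv = promoters[blk.gene.gene_id].interval
            if open_promoter[(ct, blk.gene.gene_id)]:
                jitter = int(rng.integers(0, 100))
                start = max(prom_iv.start, min(prom_iv.start + jitter, prom_iv.end - 200))
                width = min(600, prom_iv.end - start)
                ocrs.append(
                    Ocr(GenomicInterval(blk.chrom, start, start + width), ct,
                        f"{ct}_prom_{blk.gene.gene_id}")
                )
            d = blk.distal_peak
            jitter = int(rng.integers(-50, 51))
            distal_iv = GenomicInterval(blk.chrom, d.start + jitter, d.end + jitter)
            ocrs.append(Ocr(distal_iv, ct, f"{ct}_distal_{blk.gene.gene_id}"))
            for fi in range(per_block_fillers[bi]):
                fstart = blk.start + _FILLER_OFFSET + fi * _FILLER_SPACING + int(rng.integers(0, 100))
                ocrs.append(
                    Ocr(GenomicInterval(blk.chrom, fstart, fstart + _FILLER_WIDTH), ct,
                        f"{ct}_filler_{blk.gene.gene_id}_{fi}")
                )
            if ct in blk.loop_cell_types:
                for tgt_gene in blk.contacted[ct]:
                    tgt_iv = promoters[tgt_gene].interval
                    loop_id = f"{ct}_pcc_{len(loops)}"
                    loops.append(
                        Loop(
                            GenomicInterval(blk.chrom, max(0, tgt_iv.start - 500), tgt_iv.end + 500),
                            GenomicInterval(blk.chrom, max(0, distal_iv.start - 100), distal_iv.end + 100),
                            ct,
                            loop_id,
                            source="pcc",
                            score=float(np.round(5.0 + rng.random() * 5.0, 3)),
                        )
                    )
                    blk.loop_ids[ct].append(loop_id)
            elif rng.random() < 0.1:  # negative-control loop in the desert
                a = blk.start + _DESERT_OFFSET + int(rng.integers(0, 500))
                bpos = blk.start + _DESERT_OFFSET + 3_000 + int(rng.integers(0, 500))
                loops.append(
                    Loop(
                        GenomicInterval(blk.chrom, a, a + 400),
                        GenomicInterval(blk.chrom, bpos, bpos + 400),
                        ct,
                        f"{ct}_pcc_{len(loops)}",
                        source="pcc",
                        score=float(np.round(5.0 + rng.random() * 2.0, 3)),
                    )
                )
                neg_loop_count += 1
        truth.ocrs_by_cell[ct] = ocrs
        truth.loops_by_cell[ct] = loops
        truth.cres_by_cell[ct] = {
            f"{ct}_distal_{blk.gene.gene_id}": (
                frozenset(blk.contacted[ct]),
                frozenset(blk.loop_ids[ct]),
            )
            for blk in blocks
            if ct in blk.loop_cell_types
        }
    truth._blocks = blocks  # type: ignore[attr-defined]  # internal handle for simulate_gwas
    truth._open_promoter = open_promoter  # type: ignore[attr-defined]
    return truth


def _filler_allocation(config: SimConfig, blocks: Sequence[_Block], rng) -> list[int]:
    """Spread the filler-OCR budget over blocks (>=0 each, deterministic)."""
    # budget: total peaks minus ~1 promoter + 1 distal per block
    budget = max(0, config.n_ocr_per_cell - 2 * len(blocks))
    base = budget // len(blocks)
    rem = budget - base * len(blocks)
    max_fillers = (_DESERT_OFFSET - _FILLER_OFFSET) // _FILLER_SPACING - 1
    return [min(max_fillers, base + (1 if i < rem else 0)) for i in range(len(blocks))]


def simulate_gwas(config: SimConfig, truth: GroundTruth) -> GroundTruth:
    """Plant sentinels, LD proxies, and the exact expected V2G pair table."""
    rng = np.random.default_rng(config.seed + 1)
    blocks: list[_Block] = truth._blocks  # type: ignore[attr-defined]
    lo, hi = config.proxies_per_sentinel

    order = rng.permutation(len(blocks))
    sentinel_blocks = [blocks[i] for i in order[: config.n_traits * config.n_sentinels_per_trait]]
    sentinels: list[Sentinel] = []
    proxies: list[Proxy] = []
    causal_proxies: list[tuple[Proxy, _Block]] = []  # in-cRE, r2 >= 0.8
    k = 0
    for trait in config.traits:
        for _ in range(config.n_sentinels_per_trait):
            blk = sentinel_blocks[k]
            k += 1
            spos = blk.start + _DESERT_OFFSET + 1_000 + int(rng.integers(0, 200)) + 1
            sent = Sentinel(trait, f"rs{k:05d}", blk.chrom, spos)
            sentinels.append(sent)
            proxies.append(Proxy(sent.variant_id, sent.chrom, sent.pos, 1.0, sent, "self"))
            n_prox = int(rng.integers(lo, hi + 1))
            n_causal = int(np.floor(n_prox * config.frac_causal_proxies_in_cre))
            d = blk.distal_peak
            # keep planted proxies strictly inside every cell type's jittered
            # copy of the distal peak (jitter is +/-50 bp)
            offsets = rng.choice(np.arange(50, _DISTAL_WIDTH - 60), size=max(n_causal, 0), replace=False)
            for j in range(n_prox):
                if j < n_causal:
                    pos = d.start + int(offsets[j]) + 1  # 1-based, inside the distal OCR
                    r2 = float(np.round(0.70 + 0.30 * rng.random(), 4))
                else:
                    pos = blk.start + _DESERT_OFFSET + 1_500 + j * 11 + 1
                    r2 = float(np.round(0.50 + 0.50 * rng.random(), 4))
                prox = Proxy(f"{sent.variant_id}_p{j}", blk.chrom, pos, r2, sent, "ld")
                proxies.append(prox)
                if j < n_causal and r2 >= 0.8:
                    causal_proxies.append((prox, blk))

    # plant multi-trait sharing: an exact count of causal proxies recur under
    # a sentinel of another trait (same chromosome, as LD demands)
    n_share = int(round(config.frac_multi_trait_variants * len(causal_proxies)))
    share_idx = rng.permutation(len(causal_proxies))[:n_share]
    sent_by_trait_chrom: dict[tuple[str, str], list[Sentinel]] = {}
    for s in sentinels:
        sent_by_trait_chrom.setdefault((s.trait, s.chrom), []).append(s)
    shared_copies: list[tuple[Proxy, _Block]] = []
    high_ld_pairs: set[frozenset] = set()
    for i in share_idx:
        prox, blk = causal_proxies[i]
        other_traits = [t for t in config.traits if t != prox.sentinel.trait
                        and (t, prox.chrom) in sent_by_trait_chrom]
        if not other_traits:
            continue
        t2 = other_traits[int(rng.integers(0, len(other_traits)))]
        cands = sent_by_trait_chrom[(t2, prox.chrom)]
        s2 = cands[int(rng.integers(0, len(cands)))]
        copy = Proxy(prox.variant_id, prox.chrom, prox.pos,
                     float(np.round(0.80 + 0.20 * rng.random(), 4)), s2, "ld")
        proxies.append(copy)
        shared_copies.append((copy, blk))
        if s2.variant_id != prox.sentinel.variant_id:
            high_ld_pairs.add(frozenset({s2.variant_id, prox.sentinel.variant_id}))

    truth.sentinels = sentinels
    truth.proxies = proxies

    # pairwise sentinel LD: sentinels sharing a planted proxy are in high LD
    # (their loci must merge); all other same-chromosome pairs are in low LD
    for i, a in enumerate(sentinels):
        for b in sentinels[i + 1:]:
            if a.chrom != b.chrom or a.variant_id == b.variant_id:
                continue
            key = frozenset({a.variant_id, b.variant_id})
            truth.sentinel_ld[key] = 0.9 if key in high_ld_pairs else 0.1

    # expected pair table, by construction
    rows = []
    mhc = config.mhc_mimic

    def masked(chrom: str, pos: int) -> bool:
        return mhc is not None and mhc.contains_point(chrom, pos - 1)

    for prox, blk in causal_proxies + shared_copies:
        if masked(prox.chrom, prox.pos) or masked(prox.sentinel.chrom, prox.sentinel.pos):
            continue
        for ct in blk.loop_cell_types:
            cre_id = f"{ct}_distal_{blk.gene.gene_id}"
            for gene in blk.contacted[ct]:
                rows.append(
                    {
                        "trait": prox.sentinel.trait,
                        "sentinel_id": prox.sentinel.variant_id,
                        "proxy_id": prox.variant_id,
                        "cell_type": ct,
                        "cre_id": cre_id,
                        "gene_id": gene,
                        "loop_ids": ",".join(sorted(blk.loop_ids[ct])),
                    }
                )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    pairs = (
        pairs.drop_duplicates(subset=["trait", "proxy_id", "cell_type", "gene_id"])
        .sort_values(PAIR_COLUMNS[:6])
        .reset_index(drop=True)
    )
    truth.pairs = pairs
    return truth


def simulate_coloc_pair(
    rng: np.random.Generator,
    scenario: str,
    eqtl: EqtlConfig,
) -> tuple[list, list]:
    """Simulate one locus's GWAS and eQTL summary statistics.

    SNPs sit on an LD block with autoregressive correlation rho^|i-j| in
    rank distance.  Marginal effects follow the standard summary-statistic
    model under LD: beta_i = r_{i,causal} * b_causal + e_i with noise
    correlated through the same LD (z-scores are MVN with covariance R), so
    e is an AR(1) series scaled by se = 1/sqrt(n) and the causal SNP's
    expected z-score equals ``causal_z``.  Scenarios: "h4" shares one causal
    SNP between the two studies, "h3" uses two distant (low-LD) causal SNPs,
    "null" has none.
    """
    from .core import SummaryStatRecord

    if eqtl.n_snps < 2:
        raise ValueError("need at least 2 SNPs per locus")
    if scenario not in {"h4", "h3", "null"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    m = eqtl.n_snps
    rho = eqtl.ld_rho
    ranks = np.arange(m)
    quarter = max(1, m // 4)
    c1 = int(rng.integers(quarter, 2 * quarter))
    c2 = int(rng.integers(3 * quarter, m)) if scenario == "h3" else c1

    out = []
    for causal, n in ((c1, eqtl.n_gwas), (c2, eqtl.n_eqtl)):
        se = 1.0 / np.sqrt(n)
        eta = rng.normal(0.0, 1.0, size=m)
        noise = np.empty(m)
        noise[0] = eta[0]
        for i in range(1, m):
            noise[i] = rho * noise[i - 1] + np.sqrt(1.0 - rho * rho) * eta[i]
        if scenario == "null":
            beta = noise * se
        else:
            corr = rho ** np.abs(ranks - causal)
            beta = corr * (eqtl.causal_z * se) + noise * se
        stats = [
            SummaryStatRecord(
                variant_id=f"snp{i}",
                chrom="chr1",
                pos=1_000_000 + i * 500,
                effect_allele="A",
                other_allele="G",
                beta=float(beta[i]),
                se=float(se),
                maf=0.3,
                n=n,
            )
            for i in range(m)
        ]
        out.append(stats)
    return out[0], out[1]


def simulate_eqtl_tables(
    config: SimConfig,
    truth: GroundTruth,
    loci: Sequence,
    cell_type: str = "cell0",
    dataset: str = "synthetic_eqtl",
) -> pd.DataFrame:
    """Per-locus eQTL association rows for eGene extraction.

    For each locus, genes implicated there by the planted pair table become
    significant eGenes (FDR 0.01) at the locus's in-cRE proxies; one
    same-chromosome decoy gene per locus stays non-significant (FDR 0.5)
    and one off-chromosome gene is significant but trans (excluded under the
    same-chromosome rule).
    """
    rng = np.random.default_rng(config.seed + 2)
    gene_chrom = {g.gene_id: g.chrom for g in truth.genes}
    pairs = truth.pairs
    rows = []
    all_genes = [g.gene_id for g in truth.genes]
    for locus in loci:
        sent_ids = set(locus.member_sentinels)
        sub = pairs[pairs["sentinel_id"].isin(sent_ids)]
        local = [
            p for p in truth.proxies
            if p.sentinel.variant_id in sent_ids
            and locus.interval.contains_point(p.chrom, p.pos - 1)
        ]
        if not local:
            continue
        for gene in sorted(set(sub["gene_id"])):
            for p in local[:3]:
                rows.append(
                    {
                        "variant_id": p.variant_id, "chrom": p.chrom, "pos": p.pos,
                        "gene_id": gene, "gene_chrom": gene_chrom.get(gene, locus.chrom),
                        "beta": float(np.round(rng.normal(0.3, 0.05), 4)),
                        "se": 0.05, "fdr": 0.01,
                        "cell_type": cell_type, "dataset": dataset,
                    }
                )
        p0 = local[0]
        decoy = all_genes[int(rng.integers(0, len(all_genes)))]
        rows.append(
            {
                "variant_id": p0.variant_id, "chrom": p0.chrom, "pos": p0.pos,
                "gene_id": decoy, "gene_chrom": gene_chrom[decoy],
                "beta": 0.01, "se": 0.05, "fdr": 0.5,
                "cell_type": cell_type, "dataset": dataset,
            }
        )
        off_chrom = "chrX_gene"
        rows.append(
            {
                "variant_id": p0.variant_id, "chrom": p0.chrom, "pos": p0.pos,
                "gene_id": off_chrom, "gene_chrom": "chrX",
                "beta": 0.4, "se": 0.05, "fdr": 0.01,
                "cell_type": cell_type, "dataset": dataset,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "gene_id", "gene_chrom",
                 "beta", "se", "fdr", "cell_type", "dataset"],
    )


def write_dataset(config: SimConfig, truth: GroundTruth, outdir: str) -> None:
    """Emit every file the pipeline consumes, plus the ground truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tss_table(out / "genes.tsv", truth.genes)
    with open(out / "chrom.sizes", "w") as fh:
        for chrom, size in config.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    for ct in config.cell_types:
        write_bed(out / f"{ct}.ocr.bed", truth.ocrs_by_cell[ct])
        write_loops_ibed(out / f"{ct}.loops.ibed", truth.loops_by_cell[ct])
    prox_rows = [
        {
            "trait": p.sentinel.trait, "sentinel": p.sentinel.variant_id,
            "sentinel_chrom": p.sentinel.chrom, "sentinel_pos": p.sentinel.pos,
            "proxy": p.variant_id, "chrom": p.chrom, "pos": p.pos,
            "r2": p.r2, "provenance": p.provenance,
        }
        for p in truth.proxies
    ]
    pd.DataFrame(prox_rows).to_csv(out / "proxies.tsv", sep="\t", index=False)
    ld_rows = [
        {"sentinel_a": a, "sentinel_b": b, "r2": r2}
        for (a, b), r2 in sorted(
            ((tuple(sorted(k)), v) for k, v in truth.sentinel_ld.items())
        )
    ]
    pd.DataFrame(ld_rows, columns=["sentinel_a", "sentinel_b", "r2"]).to_csv(
        out / "sentinel_ld.tsv", sep="\t", index=False
    )
    truth.pairs.to_csv(out / "planted_pairs.tsv", sep="\t", index=False)
    with open(out / "ground_truth.jsonl", "w") as fh:
        for ct, cres in truth.cres_by_cell.items():
            for peak_id, (genes, loop_ids) in sorted(cres.items()):
                fh.write(json.dumps({
                    "record": "cre", "cell_type": ct, "peak_id": peak_id,
                    "genes": sorted(genes), "loops": sorted(loop_ids),
                }) + "\n")
        for row in truth.pairs.itertuples(index=False):
            fh.write(json.dumps({"record": "pair", **row._asdict()}) + "\n")


def simulate_all(config: SimConfig) -> GroundTruth:
    """Run genome and GWAS simulation under one config."""
    truth = simulate_genome(config)
    return simulate_gwas(config, truth)
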