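"""LD-merged locus construction and single-causal GWAS-eQTL colocalization.

Loci are built per sentinel from three key intervals — the sentinel
position, the span of its LD proxies, and that span extended by +/-250 kb —
then merged where overlapping.  Merged regions holding several sentinels
stay merged only if all pairwise LD is high (r2 >= 0.8, via connected
components); low-LD groups are split apart at the midpoint between their
proxy spans, so the output is always pairwise non-overlapping.

Colocalization follows the approximate-Bayes-factor model with a single
causal variant per trait: each SNP's association gets a Wakefield log-ABF,
the five hypotheses (no association; trait only; eQTL only; two distinct
causal variants; one shared causal variant) are scored by prior-weighted
sums of ABF products, and posteriors are the softmax of the five log
scores.  All sums run in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import GenomicInterval
from .v2g import Proxy, Sentinel

logger = logging.getLogger(__name__)

HYPOTHESES = ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")


@dataclass(frozen=True)
class Locus:
    """A non-overlapping merged region holding one or more sentinels."""

    locus_id: str
    chrom: str
    interval: GenomicInterval
    member_sentinels: frozenset[str]
    provenance: str = ""


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP priors of the single-causal colocalization model.

    p1/p2: prior that a SNP is causal for trait 1 / trait 2 only;
    p12: prior that it is causal for both.  W_quant / W_cc are the prior
    effect-size variances for quantitative (sd 0.15) and case-control
    (sd 0.2, log-odds scale) traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W_quant: float = 0.15**2
    W_cc: float = 0.2**2

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("need 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 0.1:
            raise ValueError("priors must be small (p1+p2+p12 << 1)")
        if self.W_quant <= 0 or self.W_cc <= 0:
            raise ValueError("prior variances must be > 0")


@dataclass
class ColocResult:
    locus_id: str
    gene_id: str
    trait: str
    eqtl_cell_type: str
    nsnps: int
    pp: dict[str, float]
    per_snp_pp_h4: dict[str, float]

    @property
    def top_snp(self) -> str:
        return max(self.per_snp_pp_h4, key=self.per_snp_pp_h4.get)


def build_loci(
    sentinels: Sequence[Sentinel],
    proxies: Sequence[Proxy],
    flank: int = 250_000,
    ld_r2: Optional[Mapping[frozenset[str], float]] = None,
    r2_merge: float = 0.8,
) -> list[Locus]:
    """Construct non-overlapping loci from sentinel/proxy geometry and LD.

    Steps: (1) per sentinel, the candidate region is the union of its
    position, its proxy span, and the proxy span widened by ``flank``;
    (2) overlapping candidates merge; (3) a merged region with several
    sentinels stays whole only if its sentinels form one connected component
    of the pairwise r2 >= ``r2_merge`` graph — otherwise the components are
    separated at the midpoints between adjacent proxy spans and each part is
    re-clamped so the output never overlaps.

    ``ld_r2`` maps frozenset({sentinel_a, sentinel_b}) -> r2 and must cover
    every pair of sentinels that ends up sharing a merged region.
    """
    by_sent: dict[str, list[Proxy]] = {}
    sent_by_id: dict[str, Sentinel] = {}
    for s in sentinels:
        sent_by_id[s.variant_id] = s
        by_sent.setdefault(s.variant_id, [])
    for p in proxies:
        if p.sentinel.variant_id in by_sent:
            by_sent[p.sentinel.variant_id].append(p)

    candidates: list[tuple[str, str, int, int, int, int]] = []  # sid, chrom, start, end, span_lo, span_hi
    for sid, plist in by_sent.items():
        s = sent_by_id[sid]
        positions = [p.pos for p in plist] + [s.pos]
        span_lo, span_hi = min(positions) - 1, max(positions)  # 0-based half-open proxy span
        start = max(0, span_lo - flank)
        end = span_hi + flank
        candidates.append((sid, s.chrom, start, end, span_lo, span_hi))

    # step 2: merge overlapping candidate windows per chromosome
    loci: list[Locus] = []
    counter = 0
    by_chrom: dict[str, list] = {}
    for cand in candidates:
        by_chrom.setdefault(cand[1], []).append(cand)
    for chrom in sorted(by_chrom):
        cands = sorted(by_chrom[chrom], key=lambda c: (c[2], c[3]))
        groups: list[list] = [[cands[0]]]
        cur_end = cands[0][3]
        for c in cands[1:]:
            if c[2] < cur_end:
                groups[-1].append(c)
            else:
                groups.append([c])
            cur_end = max(cur_end, c[3]) if c[2] < cur_end else c[3]
        for group in groups:
            counter, new = _split_group(group, chrom, ld_r2, r2_merge, counter)
            loci.extend(new)
    _check_non_overlap(loci)
    return loci


def _split_group(group, chrom, ld_r2, r2_merge, counter) -> tuple[int, list[Locus]]:
    """Resolve one merged candidate group into >=1 loci via LD components."""
    region_start = min(c[2] for c in group)
    region_end = max(c[3] for c in group)
    if len(group) == 1:
        sid = group[0][0]
        counter += 1
        return counter, [
            Locus(
                f"locus_{counter}",
                chrom,
                GenomicInterval(chrom, region_start, region_end),
                frozenset({sid}),
                provenance=f"single sentinel {sid}",
            )
        ]
    # connected components of the r2 >= r2_merge graph
    sids = [c[0] for c in group]
    adj: dict[str, set[str]] = {sid: set() for sid in sids}
    for i, a in enumerate(sids):
        for b in sids[i + 1:]:
            key = frozenset({a, b})
            if ld_r2 is None or key not in ld_r2:
                raise KeyError(
                    f"missing pairwise LD for co-resident sentinels {a!r} and {b!r}"
                )
            if ld_r2[key] >= r2_merge:
                adj[a].add(b)
                adj[b].add(a)
    components: list[set[str]] = []
    unvisited = set(sids)
    while unvisited:
        stack = [next(iter(unvisited))]
        comp: set[str] = set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        unvisited -= comp
        components.append(comp)
    if len(components) == 1:
        counter += 1
        return counter, [
            Locus(
                f"locus_{counter}",
                chrom,
                GenomicInterval(chrom, region_start, region_end),
                frozenset(sids),
                provenance=f"merged {len(sids)} sentinels, all pairwise r2>={r2_merge}",
            )
        ]
    # split between the proxy-span boundaries of adjacent low-LD components
    span = {c[0]: (c[4], c[5]) for c in group}
    comp_spans = sorted(
        (
            (min(span[s][0] for s in comp), max(span[s][1] for s in comp), comp)
            for comp in components
        ),
        key=lambda t: t[0],
    )
    out: list[Locus] = []
    prev_bound = region_start
    for i, (lo, hi, comp) in enumerate(comp_spans):
        if i + 1 < len(comp_spans):
            next_lo = comp_spans[i + 1][0]
            bound = (hi + next_lo) // 2  # midpoint rule
            bound = max(bound, prev_bound + 1)
        else:
            bound = region_end
        counter += 1
        out.append(
            Locus(
                f"locus_{counter}",
                chrom,
                GenomicInterval(chrom, prev_bound, bound),
                frozenset(comp),
                provenance=(
                    f"split from {len(group)}-sentinel region at proxy-span midpoints "
                    f"(low LD < {r2_merge})"
                ),
            )
        )
        prev_bound = bound
    return counter, out


def _check_non_overlap(loci: Sequence[Locus]) -> None:
    by_chrom: dict[str, list[Locus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    for chrom, ls in by_chrom.items():
        ls = sorted(ls, key=lambda l: l.interval.start)
        for a, b in zip(ls, ls[1:]):
            if a.interval.end > b.interval.start:
                raise AssertionError(f"loci overlap on {chrom}: {a.locus_id} vs {b.locus_id}")


def assign_egenes(
    loci: Sequence[Locus],
    eqtl: pd.DataFrame,
    fdr_max: float = 0.05,
    require_same_chrom: bool = True,
    require_high_ld_variant: bool = True,
    proxies: Optional[Sequence[Proxy]] = None,
    fdr_greater: bool = False,
) -> pd.DataFrame:
    """Extract the eGenes testable within each locus from an eQTL table.

    ``eqtl`` needs columns: variant_id, chrom, pos (1-based), gene_id,
    gene_chrom, fdr, cell_type, dataset.  An eGene is kept for a locus iff
    at least one of its eQTL variants lies inside the locus, passes the FDR
    cut, is (optionally) one of the locus sentinels' high-LD proxies, and
    the gene sits on the locus chromosome.  ``fdr_greater`` flips the FDR
    comparison for anyone wanting the literal inequality rather than
    significance.
    """
    keep_fdr = (eqtl["fdr"] > fdr_max) if fdr_greater else (eqtl["fdr"] <= fdr_max)
    sig = eqtl[keep_fdr]
    proxy_ids_by_sentinel: dict[str, set[str]] = {}
    if proxies is not None:
        for p in proxies:
            proxy_ids_by_sentinel.setdefault(p.sentinel.variant_id, set()).add(p.variant_id)
    rows = []
    for locus in loci:
        sub = sig[(sig["chrom"] == locus.chrom)]
        inside = sub[
            (sub["pos"] - 1 >= locus.interval.start) & (sub["pos"] - 1 < locus.interval.end)
        ]
        if require_high_ld_variant and proxies is not None:
            allowed: set[str] = set()
            for sid in locus.member_sentinels:
                allowed |= proxy_ids_by_sentinel.get(sid, set())
                allowed.add(sid)
            inside = inside[inside["variant_id"].isin(allowed)]
        if require_same_chrom and "gene_chrom" in inside.columns:
            inside = inside[inside["gene_chrom"] == locus.chrom]
        for (gene, cell_type, dataset), sub2 in inside.groupby(["gene_id", "cell_type", "dataset"]):
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "gene_id": gene,
                    "cell_type": cell_type,
                    "dataset": dataset,
                    "n_supporting_variants": sub2["variant_id"].nunique(),
                    "min_fdr": float(sub2["fdr"].min()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "gene_id", "cell_type", "dataset", "n_supporting_variants", "min_fdr"],
    )


def concordance_summary(
    v2g_genes: set[str],
    egenes: set[str],
) -> dict[str, float]:
    """Overlap between V2G-implicated genes and eQTL eGenes, both directions.

    Returns the intersection size and each side's directional percentage
    (raw, not display-rounded): ``pct_of_egenes`` uses the eGene total as
    denominator, ``pct_of_v2g`` the V2G total.
    """
    common = v2g_genes & egenes
    return {
        "n_common": float(len(common)),
        "n_v2g": float(len(v2g_genes)),
        "n_egenes": float(len(egenes)),
        "pct_of_egenes": 100.0 * len(common) / len(egenes) if egenes else 0.0,
        "pct_of_v2g": 100.0 * len(common) / len(v2g_genes) if v2g_genes else 0.0,
    }


def wakefield_labf(beta: float, se: float, W: float) -> float:
    """Wakefield's log approximate Bayes factor for one association.

    With V = se^2, z = beta/se and shrinkage r = W/(V+W):
    lABF = 0.5 * (ln(1-r) + z^2 * r), the log evidence for a nonzero effect
    with prior variance W against the null.
    """
    if not (math.isfinite(beta) and math.isfinite(se) and math.isfinite(W)):
        raise ValueError("non-finite input to wakefield_labf")
    if se <= 0 or W <= 0:
        raise ValueError("se and W must be > 0")
    V = se * se
    z = beta / se
    r = W / (V + W)
    return 0.5 * (math.log1p(-r) + z * z * r)


def labf_vector(stats: Sequence, W: float) -> np.ndarray:
    return np.array([wakefield_labf(s.beta, s.se, W) for s in stats])


def coloc_abf(
    trait_stats: Sequence,
    eqtl_stats: Sequence,
    priors: ColocPriors = ColocPriors(),
    trait_type: str = "cc",
    eqtl_type: str = "quant",
    locus_id: str = "",
    gene_id: str = "",
    trait: str = "",
    eqtl_cell_type: str = "",
) -> ColocResult:
    """Single-causal colocalization of a trait and an eQTL at one locus-gene.

    Both inputs are SummaryStatRecord-like sequences sharing variant ids
    within one locus; only shared variants are analysed.  The prior effect
    variance is chosen per dataset: W = 0.2^2 for case-control ("cc"),
    0.15^2 for quantitative ("quant").  Hypothesis log scores:

    - H0: 0
    - H1: log(p1) + logsumexp(lABF1)
    - H2: log(p2) + logsumexp(lABF2)
    - H3: log(p1) + log(p2) + log(sum_{i != j} ABF1_i * ABF2_j)
    - H4: log(p12) + logsumexp(lABF1 + lABF2)

    Posteriors are the softmax of the five scores; the per-SNP posterior of
    being the shared causal variant is the softmax of lABF1 + lABF2.
    """
    by_id_1 = {s.variant_id: s for s in trait_stats}
    by_id_2 = {s.variant_id: s for s in eqtl_stats}
    if len(by_id_1) != len(trait_stats) or len(by_id_2) != len(eqtl_stats):
        raise ValueError("duplicated variant ids in coloc input")
    shared = sorted(set(by_id_1) & set(by_id_2))
    if not shared:
        raise ValueError("no shared variants between trait and eQTL statistics")

    W1 = priors.W_cc if trait_type == "cc" else priors.W_quant
    W2 = priors.W_cc if eqtl_type == "cc" else priors.W_quant
    l1 = labf_vector([by_id_1[v] for v in shared], W1)
    l2 = labf_vector([by_id_2[v] for v in shared], W2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)

    lp1, lp2, lp12 = math.log(priors.p1), math.log(priors.p2), math.log(priors.p12)
    s0 = 0.0
    s1 = lp1 + lsum1
    s2 = lp2 + lsum2
    if len(shared) == 1:
        s3 = -np.inf  # the i != j sum is empty
    else:
        # log(sum_i ABF1 * sum_j ABF2 - sum_i ABF1_i*ABF2_i), stable log-difference;
        # when one SNP dominates both studies the difference underflows to zero
        total = lsum1 + lsum2
        delta = min(lsum12 - total, 0.0)
        if delta > -1e-15:
            s3 = -np.inf
        else:
            s3 = lp1 + lp2 + total + math.log1p(-math.exp(delta))
    s4 = lp12 + lsum12

    scores = np.array([s0, s1, s2, s3, s4])
    pp = np.exp(scores - logsumexp(scores))
    snp_pp = np.exp((l1 + l2) - lsum12)
    return ColocResult(
        locus_id=locus_id,
        gene_id=gene_id,
        trait=trait,
        eqtl_cell_type=eqtl_cell_type,
        nsnps=len(shared),
        pp=dict(zip(HYPOTHESES, (float(x) for x in pp))),
        per_snp_pp_h4=dict(zip(shared, (float(x) for x in snp_pp))),
    )


def coloc_results_frame(results: Sequence[ColocResult]) -> pd.DataFrame:
    """Tabulate results as the coloc TSV (locus, gene, trait, cell type, PP.H0-H4)."""
    rows = []
    for r in results:
        row = {
            "locus_id": r.locus_id,
            "gene_id": r.gene_id,
            "trait": r.trait,
            "eqtl_cell_type": r.eqtl_cell_type,
            "nsnps": r.nsnps,
        }
        row.update(r.pp)
        row["top_snp"] = r.top_snp
        row["top_snp_pp_h4"] = r.per_snp_pp_h4[r.top_snp]
        rows.append(row)
    return pd.DataFrame(rows)


def write_locus_bed(loci: Sequence[Locus], path: str) -> None:
    with open(path, "w") as fh:
        for l in sorted(loci, key=lambda x: (x.chrom, x.interval.start)):
            sents = ",".join(sorted(l.member_sentinels))
            fh.write(f"{l.chrom}\t{l.interval.start}\t{l.interval.end}\t{l.locus_id}\t{sents}\n")
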