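# Methods

This note records the models implemented in `chromv2g`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Coordinates and interval semantics

All internal coordinates are 0-based half-open `[start, end)`. BED input is
taken verbatim; 1-based inputs (TSS tables, variant positions in proxy and
summary-statistic tables) are converted on read. Overlap requires at least
one shared base, so abutting intervals do not overlap, and a variant at an
interval's end coordinate is outside it. Promoter windows are strand-aware:
−1,500/+500 bp of the TSS in transcript orientation (a 2-kb window),
clamped to `[0, chromosome length)` rather than rejected so that genes near
a contig edge keep a shortened promoter — synthetic small genomes and
scaffold-level assemblies both need this.

## cRE definition

An open chromatin region (OCR) is called a cis-regulatory element (cRE)
when some loop has one anchor overlapping the OCR and its *other* anchor
overlapping at least one promoter window. Two deliberate choices:

- **Self-contacts are excluded.** A single anchor covering both the OCR and
  a promoter does not qualify; physical contact through a loop requires the
  two distinct anchors. Without this rule every promoter-proximal peak
  under a bait anchor would be annotated as contacting its own promoter.
- **Open-promoter requirement (default on).** The contacted promoter must
  itself overlap an OCR of the same cell type. This restricts V2G to
  promoters with regulatory potential in that cell state; the flag
  `require_open_promoter=False` gives the permissive definition.

Anchor overlap is ≥1 bp with no minimum fraction — the simplest defensible
rule; loop anchors arrive pre-merged at fragment or bin resolution and a
fractional threshold would silently interact with anchor width. Duplicate
loop records are retained by the readers (parsing is lossless) and collapse
naturally during cRE construction, where each distinct contact geometry is
logged once.

## S-LDSC annotations and post-processing

Open chromatin is partitioned into five region sets per cell type: all
OCRs; promoter-overlapping OCRs; cREs; cREs ±500 bp (merged where the
flanked intervals overlap — membership is per-SNP, so merging only affects
bookkeeping); and OCRs that are neither cREs nor promoter-overlapping, the
negative control. The first three sets are not mutually exclusive; the
negative control is disjoint from the other two by construction. Annotation
export marks template variants (1-based BP converted to a 0-based point)
with 0/1 membership, preserving template order.

Post-processing reimplements the two comparison statistics:

- enrichment = (h²_c/h²_g)/(M_c/M), the annotation's share of SNP
  heritability over its share of SNPs; negative values are legitimate and
  preserved.
- τ\* = τ·sd_c·M/h²_g, the per-SNP regression coefficient standardized by
  the annotation's standard deviation across reference SNPs, the reference
  SNP count, and total SNP heritability, making effect sizes comparable
  across annotations and traits. The SE is scaled by the same factor, with
  no covariance terms — the standardization is applied coefficient-wise.
  Liability-scale h²_g is taken from the upstream regression output as-is.

The cross-category comparison is a one-sided Welch (unequal-variance)
t-test of each category's per-trait enrichment vector against the cRE
reference, H1: mean(category) < mean(cRE), pooled across traits within one
cell type. Welch is the robust default when only "t-test" is specified;
the paired variant is a config choice since the same traits underlie every
category.

## V2G mapping

Sentinels expand to LD proxies; proxies with r² < 0.8 are dropped, and any
proxy or sentinel inside the MHC mask (default chr6:25,000,000–34,000,000,
GRCh38) is excluded because extended LD there defeats proxy-based
assignment. A sentinel absent from the proxy table is added as its own
proxy with r² = 1 (a variant is in perfect LD with itself); fine-mapped
credible-set variants ride the same path with r² recorded as 1 and a
provenance tag. A proxy inside a cRE yields one pair per contacted gene;
pairs are deduplicated on (trait, proxy, cell type, gene) with the union of
supporting loop ids kept. Proxies in open chromatin that is not a cRE, or
overlapping only a promoter window, yield nothing by default.

## Sharing analysis

Sharing is computed on distinct label sets: an entity is "shared across
traits" when it occurs with ≥2 distinct traits anywhere in the table,
regardless of row multiplicity, and likewise for cell types. The four-way
pair taxonomy evaluates both axes on the (variant, gene) pair. Display
percentages round half-away-from-zero to integers, matching how such
figures are printed; the raw fractions are always carried alongside because
printed reports sometimes truncate instead. Precision and recall against a
gold-standard list use |P∩T|/|P| and |P∩T|/|T| after case normalization
and optional alias mapping; empty predicted or truth sets are errors, not
zeros.

## Locus construction

Per sentinel, the candidate region is the union of the sentinel position,
its proxy span, and the span widened by ±250 kb. Overlapping candidates
merge; a merged region holding several sentinels stays whole only when its
sentinels form a single connected component of the pairwise r² ≥ 0.8
graph. Otherwise the components are ordered by proxy span and separated at
the midpoint between adjacent spans — the paper-trail for each locus
records which rule produced it. The output is always pairwise
non-overlapping and deterministic for fixed input.

## Colocalization

Single-causal approximate-Bayes-factor colocalization. Each SNP's
association gets a Wakefield log-ABF, ½·[ln(1−r) + z²·r] with r =
W/(V+W), V = se², using prior effect-size variance W = 0.15² for
quantitative traits and 0.2² (log-odds) for case-control — the
conventional defaults, not overridden. Per-SNP causal priors are p1 = p2 =
1e-4 and p12 = 1e-5. The five hypothesis scores are accumulated in log
space with logsumexp; the distinct-causal sum Σ_{i≠j} ABF1_i·ABF2_j is
computed as a stable log-difference `log(Σᵢ·Σⱼ − Σᵢᵢ)`, and underflows to
−∞ (PP.H3 → 0) when a single SNP dominates both studies, where the true
cross-term is negligible anyway. PP.H3 is exactly 0 for a single shared
SNP. Posteriors are the softmax over {0, S1, S2, S3, S4}; the per-SNP
shared-causal posterior is the softmax of lABF1+lABF2. One subtlety worth
stating: the ABF depends on (z, V/W), not on z alone, so jointly rescaling
one study's betas and SEs changes posteriors unless its W rescales with
the variance — the test suite pins down this exact invariance.

eGene extraction keeps a gene for a locus when at least one of its eQTL
variants lies in the locus, passes FDR ≤ 0.05, is one of the locus's
high-LD proxies (optional), and the gene is on the locus chromosome. The
FDR cut is significance-directed; a `fdr_greater` flag provides the
literal reversed inequality for anyone tracing a source that prints it
that way.

## Motif disruption

PFM counts become probabilities with a +0.8/4 pseudocount per cell before
row normalization (avoiding −∞ log-odds); scoring is information-content
log₂(p/background) summed over positions with an even background (¼ per
nucleotide). The p-value of a score is P(S ≥ s) for a random background
sequence, computed by position-wise convolution of the 4-point score
distributions on a discretized grid. Numerical choices: the grid refines
the nominal resolution (10,000 bins) by 16× the motif length, so each
per-position rounding displaces a sequence by at most half a fine bin;
the query admits bins within L/2 fine grid units below it, guaranteeing no
sequence truly scoring ≥ s is missed, while over-counting is confined to
sequences within L fine bins below — for realistic count matrices this
reproduces exhaustive 4^L enumeration exactly, and adversarial matrices
with near-ties at the 1e-5-bit level are bounded by that window. Variant
scanning slides the motif over every placement covering the variant on
both strands (reverse complement for minus), reports placements where
min(p_ref, p_alt) ≤ 5e-4 (a `require_both` flag tightens this), and labels
|Δscore| ≥ 1 bit as strong and ≥ 0.4 as weak, the convention of
allele-disruption scanners; both cutoffs are configurable.

## Synthetic-data generator

The generator emulates the downstream products of a multi-cell-type
chromatin study plus a multi-trait GWAS at desk scale: 2 chromosomes of
10 Mb, 300 genes, 4 cell types with ~2,000 peaks each, 15% of distal peaks
looped to promoters, 3 traits × 20 sentinels with 5–30 proxies each, 30%
of proxies placed inside cREs, proxy r² drawn to straddle the 0.8
threshold so the LD filter is genuinely exercised, 20% of causal proxies
shared across traits, and 50% of planted cREs replicated in ≥2 cell types.
Each gene owns a fixed block with disjoint sub-regions (promoter, distal
peak, filler peaks, desert), which is what makes the planted truth exact:
the expected pair table follows from bookkeeping, not from re-running the
overlap engine. Loop contact degree is uniform on 1–7 (mean 4 genes per
contacting variant). All randomness flows from one seeded generator;
identical seeds give byte-identical files.

For colocalization, each locus has 200 SNPs on an AR(1) LD block
(ρ = 0.9 by rank distance) and two studies of n = 10,000. Marginal effects
follow the standard summary-statistic model under LD: β = r_{·,causal}·b +
ε with the noise itself AR(1)-correlated (z-scores are multivariate normal
with the LD matrix as covariance) and se = 1/√n, causal |z| ≈ 8.
Correlated noise is not a convenience: with independent noise the
marginals are internally inconsistent with the LD structure and
single-causal posteriors are badly calibrated. Shared-causal ("H4") loci
use one causal index for both studies; distinct-causal ("H3") loci use two
indices far enough apart that their LD is below 0.05.

What the generator does **not** emulate: realistic allele frequencies and
LD from population history (the AR(1) block is a caricature), read-level
noise, peak-calling artefacts, fragment-resolution anchors, trans effects,
and overlapping gene bodies. Passing the planted-truth tests therefore
demonstrates pipeline correctness — that the implementation computes the
defined quantities exactly — not biological performance on real data.

## Problem sizes

The test suite and the acceptance script use the generator defaults above;
colocalization calibration uses 100 seeded replicates per scenario, the
coloc oracle 200 random ≤5-SNP instances, locus construction 1,000 random
sentinel configurations, and the annotation-partition check 500 random
fixtures. These sizes make every check exact or tightly calibrated while
keeping a full run in the low seconds.

## Known limitations

- The LD-score regression itself, multi-causal colocalization
  (SuSiE-based), liftover, and loop calling are out of scope; the package
  builds inputs for and consumes outputs of those tools.
- Anchor/OCR intersection treats anchors as whole intervals; restriction-
  fragment boundaries are not modelled.
- The locus split rule (midpoint between adjacent low-LD proxy spans) is
  one defensible reduction of "separated and further reduced"; loci built
  with a different split convention will differ at the boundary bases.
- `assign_egenes` expects per-association FDR/q-values in the eQTL table;
  raw p-values need a correction applied upstream.
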