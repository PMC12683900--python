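"""Post-processing of stratified LD-score regression (S-LDSC) outputs.

The regression itself runs in external LDSC; this module parses its
``.results`` tables and reimplements the two summary statistics used to rank
annotations:

* heritability enrichment = (h2_c / h2_g) / (M_c / M), the share of SNP
  heritability in a category over its share of SNPs;
* the standardized per-SNP effect size tau* = tau * sd_c * M / h2_g, which
  puts the regression coefficient of a binary annotation on a scale
  comparable across annotations and traits.

It also provides the cross-category comparison used to ask whether cRE
annotations capture more heritability than the other open-chromatin
categories: a one-sided (lesser) Welch t-test of each category's per-trait
enrichments against the cRE reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENRICHMENT_CONSISTENCY_RTOL = 0.05


@dataclass(frozen=True)
class LdscResultRecord:
    category: str
    prop_snps: float
    prop_h2: float
    enrichment: float
    enrichment_se: float
    enrichment_p: Optional[float]
    tau: float
    tau_se: float
    is_baseline: bool = False
    cell_type: str = ""
    trait: str = ""


@dataclass(frozen=True)
class TauStarInputs:
    """Reference-panel constants entering the tau* standardization.

    M is the reference SNP count, h2g the total SNP heritability (liability
    or observed scale, as produced by LDSC), and sd_c the standard deviation
    of the annotation indicator across reference SNPs (sqrt(p(1-p)) for a
    binary annotation covering proportion p).
    """

    M: int
    h2g: float
    sd_c: float

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("M must be > 0")
        if self.h2g <= 0:
            raise ValueError("h2g must be > 0")
        if not (0 <= self.sd_c <= 0.5):
            raise ValueError("sd_c of a binary annotation lies in [0, 0.5]")


_RESULTS_COLUMNS = {
    "Category": "category",
    "Prop._SNPs": "prop_snps",
    "Prop._h2": "prop_h2",
    "Enrichment": "enrichment",
    "Enrichment_std_error": "enrichment_se",
    "Enrichment_p": "enrichment_p",
    "Coefficient": "tau",
    "Coefficient_std_error": "tau_se",
}


def parse_ldsc_results(
    path: str,
    cell_type: str = "",
    trait: str = "",
    baseline_prefixes: Sequence[str] = ("base", "baseline"),
) -> list[LdscResultRecord]:
    """Parse an LDSC ``.results`` table into records.

    Rows whose category name starts with a baseline prefix are retained but
    flagged, so downstream summaries can restrict to the custom annotation.
    A mismatch between the printed Enrichment column and Prop._h2/Prop._SNPs
    beyond 5% relative is reported as a warning (LDSC prints rounded values),
    not an error.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if df.empty:
        raise ValueError(f"{path}: empty .results table")
    missing = [c for c in _RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: .results header missing {missing}")
    records = []
    for row in df.itertuples(index=False):
        # index positionally: itertuples mangles '.' in column names
        vals = {ours: row[df.columns.get_loc(theirs)] for theirs, ours in _RESULTS_COLUMNS.items()}
        cat = str(vals["category"])
        prop_snps = float(vals["prop_snps"])
        prop_h2 = float(vals["prop_h2"])
        enr = float(vals["enrichment"])
        if prop_snps > 0 and not np.isclose(
            enr, prop_h2 / prop_snps, rtol=ENRICHMENT_CONSISTENCY_RTOL, atol=1e-6
        ):
            logger.warning(
                "%s: category %s: Enrichment %.4g inconsistent with Prop._h2/Prop._SNPs %.4g",
                path, cat, enr, prop_h2 / prop_snps,
            )
        records.append(
            LdscResultRecord(
                category=cat,
                prop_snps=prop_snps,
                prop_h2=prop_h2,
                enrichment=enr,
                enrichment_se=float(vals["enrichment_se"]),
                enrichment_p=(None if pd.isna(vals["enrichment_p"]) else float(vals["enrichment_p"])),
                tau=float(vals["tau"]),
                tau_se=float(vals["tau_se"]),
                is_baseline=cat.lower().startswith(tuple(p.lower() for p in baseline_prefixes)),
                cell_type=cell_type,
                trait=trait,
            )
        )
    return records


def compute_enrichment(prop_h2: float, prop_snps: float) -> float:
    """Heritability enrichment: share of h2 over share of SNPs.

    Negative values are legitimate (annotations can carry negative estimated
    heritability share).
    """
    if prop_snps <= 0:
        raise ValueError("prop_snps must be > 0")
    return prop_h2 / prop_snps


def compute_tau_star(tau: float, inputs: TauStarInputs) -> float:
    """Standardized annotation effect size tau* = tau * sd_c * M / h2g."""
    return tau * inputs.sd_c * inputs.M / inputs.h2g


def compute_tau_star_se(tau_se: float, inputs: TauStarInputs) -> float:
    """SE of tau*, scaled coefficient-wise by the same standardization factor."""
    if tau_se < 0:
        raise ValueError("tau_se must be >= 0")
    return tau_se * inputs.sd_c * inputs.M / inputs.h2g


def compare_categories(
    enrichments_by_category: Mapping[str, Sequence[float]],
    reference: str = "CRE",
) -> tuple[dict[str, float], int]:
    """One-sided Welch t-tests of each category's enrichments against the reference.

    For each non-reference category, tests H1: mean(category) < mean(reference)
    over paired per-trait enrichment vectors.  Returns the per-category p-values
    and the number of comparisons significant at p < 0.05.
    """
    if reference not in enrichments_by_category:
        raise KeyError(f"reference category {reference!r} absent")
    ref = np.asarray(enrichments_by_category[reference], dtype=float)
    if len(ref) < 2:
        raise ValueError("need >=2 paired observations per category")
    pvals: dict[str, float] = {}
    for cat, values in enrichments_by_category.items():
        if cat == reference:
            continue
        vals = np.asarray(values, dtype=float)
        if len(vals) != len(ref):
            raise ValueError(f"category {cat!r}: length {len(vals)} != reference {len(ref)}")
        if len(vals) < 2:
            raise ValueError("need >=2 paired observations per category")
        res = stats.ttest_ind(vals, ref, equal_var=False, alternative="less")
        pvals[cat] = float(res.pvalue)
    n_significant = sum(1 for p in pvals.values() if p < 0.05)
    return pvals, n_significant


def results_to_frame(records: Sequence[LdscResultRecord]) -> pd.DataFrame:
    """Tabulate records as a (cell_type x trait x category) TSV-ready frame."""
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "trait": r.trait,
                "category": r.category,
                "prop_snps": r.prop_snps,
                "prop_h2": r.prop_h2,
                "enrichment": r.enrichment,
                "enrichment_se": r.enrichment_se,
                "enrichment_p": r.enrichment_p,
                "tau": r.tau,
                "tau_se": r.tau_se,
                "is_baseline": r.is_baseline,
            }
            for r in records
        ]
    )
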