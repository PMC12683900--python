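"""Sharing taxonomy and benchmarking of the variant-gene pair table.

Variants and target genes are classified by whether they recur across
disease traits and across cell types; the four-way pair taxonomy combines
the two axes.  Sharing summaries count distinct entities (not table rows),
and predictions are benchmarked against a gold-standard gene list with
precision and recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

import pandas as pd


class SharingClass(str, Enum):
    SHARED_TRAIT_SHARED_CELL = "SHARED_TRAIT_SHARED_CELL"
    UNIQUE_TRAIT_SHARED_CELL = "UNIQUE_TRAIT_SHARED_CELL"
    SHARED_TRAIT_UNIQUE_CELL = "SHARED_TRAIT_UNIQUE_CELL"
    UNIQUE_TRAIT_UNIQUE_CELL = "UNIQUE_TRAIT_UNIQUE_CELL"


@dataclass(frozen=True)
class SharingSummary:
    n_variants: int
    n_genes: int
    n_pairs: int
    pct_variants_multi_trait: float
    pct_variants_multi_cell: float
    pct_genes_multi_trait: float
    pct_genes_multi_cell: float
    n_pairs_unique_both: int
    # raw fractions (unrounded), for anyone who needs full precision
    frac_variants_multi_trait: float = 0.0
    frac_variants_multi_cell: float = 0.0
    frac_genes_multi_trait: float = 0.0
    frac_genes_multi_cell: float = 0.0


def round_half_away(x: float) -> int:
    """Round half away from zero (5.5 -> 6, -5.5 -> -6), as printed displays do."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def display_percentage(numerator: int, denominator: int) -> float:
    """Integer display percentage of a count ratio, half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return float(round_half_away(100.0 * numerator / denominator))


def _multi(series: pd.core.groupby.SeriesGroupBy) -> pd.Series:
    return series.nunique() >= 2


def classify_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach sharing classes to every pair, variant, and gene.

    An entity is "shared across traits" iff it occurs with >=2 distinct
    traits anywhere in the table, and likewise for cell types; multiplicity
    is ignored.  A pair's class evaluates both axes on the (variant, gene)
    pair itself.  Returns the pair table with a ``pair_class`` column plus
    ``variant_class`` / ``gene_class`` marginal columns.
    """
    df = pairs.copy()
    pair_key = list(zip(df["proxy_id"], df["gene_id"]))
    df["_pair"] = pair_key

    def classes(group_key, frame=None):
        frame = df if frame is None else frame
        traits = frame.groupby(group_key)["trait"].nunique() >= 2
        cells = frame.groupby(group_key)["cell_type"].nunique() >= 2
        return traits, cells

    for key, col in (("_pair", "pair_class"), ("proxy_id", "variant_class"), ("gene_id", "gene_class")):
        multi_trait, multi_cell = classes(key)
        def label(k):
            t, c = multi_trait[k], multi_cell[k]
            if t and c:
                return SharingClass.SHARED_TRAIT_SHARED_CELL.value
            if not t and c:
                return SharingClass.UNIQUE_TRAIT_SHARED_CELL.value
            if t and not c:
                return SharingClass.SHARED_TRAIT_UNIQUE_CELL.value
            return SharingClass.UNIQUE_TRAIT_UNIQUE_CELL.value
        df[col] = [label(k) for k in df[key]]
    return df.drop(columns=["_pair"])


def summarize_sharing(pairs: pd.DataFrame) -> SharingSummary:
    """Count entities shared across >=2 traits / cell types.

    Percentages are display-rounded (half away from zero) with the raw
    fractions retained alongside.
    """
    if pairs.empty:
        raise ValueError("empty pair table")
    n_variants = pairs["proxy_id"].nunique()
    n_genes = pairs["gene_id"].nunique()
    dedup = pairs.drop_duplicates(subset=["trait", "proxy_id", "cell_type", "gene_id"])

    v_trait = int((dedup.groupby("proxy_id")["trait"].nunique() >= 2).sum())
    v_cell = int((dedup.groupby("proxy_id")["cell_type"].nunique() >= 2).sum())
    g_trait = int((dedup.groupby("gene_id")["trait"].nunique() >= 2).sum())
    g_cell = int((dedup.groupby("gene_id")["cell_type"].nunique() >= 2).sum())

    classified = classify_pairs(dedup)
    unique_both = classified.drop_duplicates(subset=["proxy_id", "gene_id"])
    n_pairs = len(unique_both)
    n_unique_both = int(
        (unique_both["pair_class"] == SharingClass.UNIQUE_TRAIT_UNIQUE_CELL.value).sum()
    )

    return SharingSummary(
        n_variants=n_variants,
        n_genes=n_genes,
        n_pairs=n_pairs,
        pct_variants_multi_trait=display_percentage(v_trait, n_variants),
        pct_variants_multi_cell=display_percentage(v_cell, n_variants),
        pct_genes_multi_trait=display_percentage(g_trait, n_genes),
        pct_genes_multi_cell=display_percentage(g_cell, n_genes),
        n_pairs_unique_both=n_unique_both,
        frac_variants_multi_trait=v_trait / n_variants,
        frac_variants_multi_cell=v_cell / n_variants,
        frac_genes_multi_trait=g_trait / n_genes,
        frac_genes_multi_cell=g_cell / n_genes,
    )


def tally_by_group(pairs: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Per-group counts of variants, genes, and group-exclusive genes.

    ``axis`` is ``"trait"`` or ``"cell_type"``.  A gene is exclusive to a
    group when it appears under exactly one group on that axis.  Output is
    sorted descending by exclusive-gene count.
    """
    if axis not in {"trait", "cell_type"}:
        raise ValueError(f"axis must be 'trait' or 'cell_type', got {axis!r}")
    if pairs.empty:
        return pd.DataFrame(columns=[axis, "n_variants", "n_genes", "n_exclusive_genes"])
    gene_groups = pairs.groupby("gene_id")[axis].nunique()
    exclusive_genes = set(gene_groups[gene_groups == 1].index)
    rows = []
    for group, sub in pairs.groupby(axis):
        genes = set(sub["gene_id"])
        rows.append(
            {
                axis: group,
                "n_variants": sub["proxy_id"].nunique(),
                "n_genes": len(genes),
                "n_exclusive_genes": len(genes & exclusive_genes),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["n_exclusive_genes", axis], ascending=[False, True])
        .reset_index(drop=True)
    )


def precision_recall(
    predicted_genes: set[str],
    truth_genes: set[str],
    aliases: Optional[Mapping[str, str]] = None,
) -> tuple[float, float]:
    """Precision and recall of a predicted gene set against a truth set.

    precision = |P & T| / |P|, recall = |P & T| / |T|.  Identifiers are
    compared case-insensitively, after mapping through ``aliases`` when
    provided (alias -> canonical name).
    """
    if not predicted_genes:
        raise ValueError("predicted gene set is empty")
    if not truth_genes:
        raise ValueError("truth gene set is empty")

    def norm(g: str) -> str:
        g = g.upper()
        if aliases:
            g = aliases.get(g, aliases.get(g.upper(), g)).upper()
        return g

    pred = {norm(g) for g in predicted_genes}
    truth = {norm(g) for g in truth_genes}
    hits = len(pred & truth)
    return hits / len(pred), hits / len(truth)


def membership_matrix(pairs: pd.DataFrame, entity: str = "gene_id", axis: str = "trait") -> pd.DataFrame:
    """UpSet-style 0/1 membership matrix of entities across groups."""
    return (
        pairs.assign(flag=1)
        .pivot_table(index=entity, columns=axis, values="flag", aggfunc="max", fill_value=0)
        .astype(int)
    )
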