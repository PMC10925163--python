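"""Guide ranking for a FACS-sorted reporter CRISPR screen.

Cells carrying a fluorescent reporter of the pathway of interest are sorted
into reporter-LOW and reporter-HIGH bins; guides that knock out a coactivator
deplete the reporter and accumulate in the LOW bin. Guides are ranked by the
ratio of counts-per-million normalised abundances, LOW over HIGH, so rank 1
is the most LOW-enriched (strongest coactivator candidate) and the bottom of
the list collects repressor-targeting guides enriched in the HIGH bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["normalize_cpm", "rank_guides", "aggregate_genes"]


def normalize_cpm(table: pd.DataFrame) -> pd.DataFrame:
    """Add counts-per-million columns for every ``count_*`` column.

    cpm = count / population_total * 1e6, per population. Raises if any
    population has zero total counts.
    """
    out = table.copy()
    for col in [c for c in table.columns if c.startswith("count_")]:
        total = table[col].sum()
        if total <= 0:
            raise ValueError(f"population {col} has zero total counts")
        out[col.replace("count_", "cpm_")] = table[col] / total * 1e6
    return out


def rank_guides(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Rank guides by log2((cpm_low + pc) / (cpm_high + pc)), descending.

    Rank 1 is the most LOW-enriched guide. Ties in the ratio are broken by
    guide id (lexicographic) for determinism. CPM columns are computed if
    absent.
    """
    if "cpm_low" not in table.columns or "cpm_high" not in table.columns:
        table = normalize_cpm(table)
    out = table.copy()
    out["log2_ratio"] = np.log2(
        (out["cpm_low"] + pseudocount) / (out["cpm_high"] + pseudocount)
    )
    out = out.sort_values(
        ["log2_ratio", "guide"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def aggregate_genes(ranks: pd.DataFrame) -> pd.DataFrame:
    """Roll guide log2 ratios up to genes: mean ratio across each gene's guides."""
    agg = (
        ranks.groupby("gene", sort=False)
        .agg(score=("log2_ratio", "mean"), n_guides=("log2_ratio", "size"))
        .reset_index()
    )
    agg = agg.sort_values(["score", "gene"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg
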