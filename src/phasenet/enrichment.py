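"""Functional-category enrichment of under-/overexpressed gene sets.

One-sided Fisher's exact (hypergeometric) tests per category and direction,
Benjamini-Hochberg adjustment within the family of all categories x both
directions of one contrast, and per-category alteration profiles (% of a
category's genes called under/over).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "write_gmt",
    "fisher_enrichment",
    "adjust_fdr",
    "enrich_direction_tables",
    "pathway_alteration_profile",
    "stars",
]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT catalog (``name<TAB>description<TAB>gene...`` per line)."""
    catalog: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = {g for g in parts[2:] if g}
            if not genes:
                continue
            if parts[0] in catalog:
                raise ValueError(f"duplicate category {parts[0]!r} in {path}")
            catalog[parts[0]] = genes
    return catalog


def write_gmt(catalog: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def fisher_enrichment(
    called: set[str], category: set[str], universe: set[str]
) -> tuple[float, float]:
    """One-sided (greater) Fisher test of category overrepresentation.

    Returns ``(odds_ratio, p)`` for the 2x2 table of called/not-called vs
    in/out of category over the universe.  The p-value is the hypergeometric
    upper tail; the odds ratio is ad/bc with a 0.5 continuity correction
    applied only when some cell is zero (reported, not used for the test).
    """
    if not universe:
        raise ValueError("empty universe")
    called = called & universe
    category = category & universe
    a = len(called & category)
    b = len(category) - a  # in category, not called
    c = len(called) - a  # called, not in category
    d = len(universe) - a - b - c
    # upper tail P(X >= a) with X ~ Hypergeom(N, K=|category|, n=|called|)
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(category), len(called)))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), min(p, 1.0)


def adjust_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def stars(p_adj: float) -> str:
    if p_adj <= 0.01:
        return "**"
    if p_adj <= 0.05:
        return "*"
    return ""


def enrich_direction_tables(
    de_table: pd.DataFrame, catalog: dict[str, set[str]]
) -> pd.DataFrame:
    """Enrichment of under- and overexpressed genes per category.

    The universe is the set of all genes in the DE table; FDR adjustment is
    over the whole emitted family (all categories x both directions).
    """
    universe = set(de_table.index)
    rows = []
    for direction in ("under", "over"):
        called = set(de_table.index[de_table["call"] == direction])
        for name, genes in catalog.items():
            cat = genes & universe
            if not cat:
                continue
            odds, p = fisher_enrichment(called, cat, universe)
            rows.append(
                {
                    "category": name,
                    "direction": direction,
                    "k": len(called & cat),
                    "K": len(cat),
                    "n": len(called),
                    "N": len(universe),
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = np.maximum(adjust_fdr(table["p"].to_numpy()),
                                    table["p"].to_numpy())
        table["stars"] = [stars(x) for x in table["p_adj"]]
    return table


def pathway_alteration_profile(
    de_table: pd.DataFrame, catalog: dict[str, set[str]]
) -> pd.DataFrame:
    """Percentage of each category's genes called under / over."""
    universe = set(de_table.index)
    under = set(de_table.index[de_table["call"] == "under"])
    over = set(de_table.index[de_table["call"] == "over"])
    rows = []
    for name, genes in catalog.items():
        cat = genes & universe
        if not cat:
            continue
        rows.append(
            {
                "category": name,
                "size": len(cat),
                "pct_under": 100.0 * len(under & cat) / len(cat),
                "pct_over": 100.0 * len(over & cat) / len(cat),
            }
        )
    return pd.DataFrame(rows)
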