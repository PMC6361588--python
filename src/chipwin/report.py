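"""Differential-expression tallies for the summary report.

Model fitting is upstream and out of scope; this module only thresholds a
provided DE table (gene id, log2 fold change, adjusted p-value).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class DEFractions:
    n_total: int
    n_up: int
    n_down: int
    pct_up: int | None
    pct_down: int | None


def report_de_fractions(table: pd.DataFrame, alpha: float = 0.01) -> DEFractions:
    """Count DE genes (adjusted p < alpha) and split them by fold-change sign.

    Percentages are of the up+down total, rounded to the nearest integer to
    match conventional reporting; with zero DE genes they are None
    (undefined).  Genes with missing adjusted p are never DE.
    """
    for col in ("gene_id", "log2fc", "padj"):
        if col not in table.columns:
            raise KeyError(f"DE table missing column {col!r}")
    if len(table) == 0:
        raise ValueError("empty DE table")
    de = table[table["padj"].notna() & (table["padj"] < alpha)]
    n_up = int((de["log2fc"] > 0).sum())
    n_down = int((de["log2fc"] < 0).sum())
    n_total = n_up + n_down
    if n_total == 0:
        return DEFractions(0, 0, 0, None, None)
    return DEFractions(n_total, n_up, n_down,
                       round(100 * n_up / n_total), round(100 * n_down / n_total))
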