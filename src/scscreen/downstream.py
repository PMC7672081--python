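"""Secondary comparisons: mutation burden, resistance-gene overlap,
and MM-vs-MW expression.

These follow the screen and combined-partner analyses: (i) do the
doubly-mutated (MM) lines simply carry more mutations overall, or only in
the partner genes; (ii) are known BRAF/MAPK-inhibitor resistance
alterations enriched in any mutation group; (iii) which partner gene's
expression separates MM from MW lines.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .damaging import CATEGORIES, DamagingMatrix

log = logging.getLogger("scscreen")

#: genes whose alteration is commonly linked to BRAF/MAPK-inhibitor
#: resistance (MEK1/MEK2 under their MAP2K symbols)
DEFAULT_RESISTANCE_GENES = (
    "MAP2K1", "MAP2K2", "PTEN", "RAC1", "CDK4", "AKT1", "NF1", "NRAS",
)


def compare_mutation_burden(subgroup_lines: Sequence[str],
                            all_lines: Sequence[str],
                            matrix: DamagingMatrix,
                            gene_set: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-line mutation-count comparison, subgroup versus full panel.

    For each damaging category (LoF, damaging missense, CNV deletion) the
    per-cell-line count is summed over `gene_set` (all matrix genes when
    None); means +/- SD in the subgroup and the full panel are reported
    with a two-sample Student's t test per category.
    """
    sub = set(subgroup_lines)
    if not sub <= set(all_lines):
        raise ValueError("subgroup_lines must be a subset of all_lines")
    genes = list(gene_set) if gene_set is not None else matrix.genes
    genes = [g for g in genes if g in matrix.status.index]
    rows = []
    for cat in CATEGORIES:
        per_line = matrix.counts[cat].loc[genes].sum(axis=0)
        a = per_line.reindex(subgroup_lines).to_numpy(float)
        b = per_line.reindex(all_lines).to_numpy(float)
        t = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "category": cat,
            "subgroup_mean": float(a.mean()), "subgroup_sd": float(a.std(ddof=1)),
            "all_mean": float(b.mean()), "all_sd": float(b.std(ddof=1)),
            "t": float(t.statistic), "p": float(t.pvalue),
        })
    return pd.DataFrame(rows)


def resistance_status_from_matrix(matrix: DamagingMatrix,
                                  genes: Sequence[str] = DEFAULT_RESISTANCE_GENES,
                                  ) -> pd.Series:
    """Per-line boolean: any damaging alteration in the resistance gene list."""
    present = [g for g in genes if g in matrix.status.index]
    if not present:
        return pd.Series(False, index=matrix.status.columns)
    return matrix.status.loc[present].sum(axis=0) > 0


def resistance_overlap(groups: pd.Series, resistance_status: pd.Series) -> dict:
    """Chi-squared homogeneity of resistance-alteration presence by group.

    `groups` maps cell line / patient -> WWC/WMC/MWC/MMC label. Empty
    groups are dropped with a warning. Returns the overall k x 2 test and
    the focused MMC-vs-MWC 2 x 2 test (NaN when either group is absent).
    """
    status = resistance_status.reindex(groups.index).astype(bool)
    table = pd.crosstab(groups, status)
    table = table.reindex(columns=[False, True], fill_value=0)
    empty = table.sum(axis=1) == 0
    if empty.any():
        log.warning("resistance overlap: empty groups dropped: %s", list(table.index[empty]))
        table = table[~empty]
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    out = {"chi2": float(chi2), "p": float(p), "dof": int(dof), "table": table}
    pairt = table.reindex(["MMC", "MWC"]).dropna()
    if len(pairt) == 2 and (pairt.to_numpy().sum(axis=1) > 0).all():
        # degenerate 2x2 with an all-zero status column: no association testable
        if (pairt.to_numpy().sum(axis=0) == 0).any():
            out["mmc_vs_mwc_chi2"], out["mmc_vs_mwc_p"] = 0.0, 1.0
        else:
            c2, p2, _, _ = stats.chi2_contingency(pairt.to_numpy(), correction=False)
            out["mmc_vs_mwc_chi2"], out["mmc_vs_mwc_p"] = float(c2), float(p2)
    else:
        out["mmc_vs_mwc_chi2"], out["mmc_vs_mwc_p"] = np.nan, np.nan
    return out


def expression_mm_vs_mw(expression: pd.DataFrame,
                        mm_lines: Sequence[str], mw_lines: Sequence[str],
                        gene_set: Sequence[str] | None = None,
                        bh: bool = False) -> pd.DataFrame:
    """Per-gene MM-versus-MW expression comparison (volcano table).

    `expression` is a gene x cell-line matrix. Genes with fewer than two
    non-missing values in either group are excluded with a warning. P
    values are raw by default; `bh` adds a BH-adjusted column.
    """
    mm_lines = [l for l in mm_lines if l in expression.columns]
    mw_lines = [l for l in mw_lines if l in expression.columns]
    if len(mm_lines) < 2 or len(mw_lines) < 2:
        raise ValueError("both groups need >= 2 cell lines with expression data")
    genes = list(gene_set) if gene_set is not None else list(expression.index)
    rows, skipped = [], 0
    for g in genes:
        if g not in expression.index:
            skipped += 1
            continue
        a = expression.loc[g, mm_lines].astype(float).dropna()
        b = expression.loc[g, mw_lines].astype(float).dropna()
        if len(a) < 2 or len(b) < 2:
            skipped += 1
            continue
        t = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"gene": g, "mean_mm": float(a.mean()), "mean_mw": float(b.mean()),
                     "diff": float(a.mean() - b.mean()), "p": float(t.pvalue)})
    if skipped:
        log.warning("expression comparison: %d genes excluded (missing data)", skipped)
    out = pd.DataFrame(rows, columns=["gene", "mean_mm", "mean_mw", "diff", "p"])
    if len(out):
        out["neg_log10_p"] = -np.log10(out["p"].clip(lower=np.finfo(float).tiny))
        if bh:
            from .screen import bh_adjust
            out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
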