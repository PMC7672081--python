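"""Combined-partner grouping and mutation-burden analysis.

After the screen, the partner genes of an anchor gene (e.g. BRAF) are
pooled — per drug (drug-specific) or across a cluster of drugs
(multidrug) — and each cell line is relabelled WWC/WMC/MWC/MMC: first
letter the anchor's damaging status, second whether ANY pooled partner is
damaged. The burden analysis then stratifies anchor-mutated lines by how
many partners are mutated (0 / 1 / 2+, or exact counts) and asks whether
ln IC50 decreases with burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .damaging import DamagingMatrix

log = logging.getLogger("scscreen")

COMBINED_GROUPS = ("WWC", "WMC", "MWC", "MMC")


class EmptyPartnerError(ValueError):
    """The anchor gene appears in no candidate pair within the given scope."""


@dataclass
class CombinedGrouping:
    anchor: str
    partner_set: frozenset[str]
    scope: str  # "drug_specific" or "multidrug"
    labels: pd.Series   # index cell_line, values in COMBINED_GROUPS
    burden: pd.Series   # index cell_line, count of mutated partner genes

    @property
    def sizes(self) -> dict[str, int]:
        counts = self.labels.value_counts()
        return {g: int(counts.get(g, 0)) for g in COMBINED_GROUPS}


def partner_genes(anchor: str, scs_records: pd.DataFrame,
                  drug: str | None = None,
                  drugs: list[str] | None = None) -> frozenset[str]:
    """Partners of `anchor` among candidate pairs, optionally drug-restricted."""
    cand = scs_records[scs_records["candidate"]]
    if drug is not None:
        cand = cand[cand["drug"] == drug]
    elif drugs is not None:
        cand = cand[cand["drug"].isin(drugs)]
    partners = set(cand.loc[cand["gene_a"] == anchor, "gene_b"])
    partners |= set(cand.loc[cand["gene_b"] == anchor, "gene_a"])
    return frozenset(partners)


def build_combined_grouping(anchor: str, scs_records: pd.DataFrame, scope: str,
                            matrix: DamagingMatrix, drug: str | None = None,
                            drugs: list[str] | None = None) -> CombinedGrouping:
    """Relabel all matrix cell lines by anchor + combined-partner status.

    scope="drug_specific" pools partners from candidate pairs of `drug`;
    scope="multidrug" pools across `drugs` (or every drug when omitted).
    """
    if scope not in ("drug_specific", "multidrug"):
        raise ValueError("scope must be 'drug_specific' or 'multidrug'")
    if scope == "drug_specific":
        if drug is None:
            raise ValueError("drug_specific scope requires a drug")
        partners = partner_genes(anchor, scs_records, drug=drug)
    else:
        partners = partner_genes(anchor, scs_records, drugs=drugs)
    if not partners:
        raise EmptyPartnerError(f"no candidate pair involves anchor {anchor!r} in scope")
    present = sorted(partners & set(matrix.status.index))
    if len(present) < len(partners):
        log.warning("%d partner genes absent from damaging matrix", len(partners) - len(present))
    anchor_status = matrix.status.loc[anchor].astype(bool)
    burden = matrix.status.loc[present].sum(axis=0).astype(int)
    lab = np.array(COMBINED_GROUPS)[
        anchor_status.to_numpy(int) * 2 + (burden.to_numpy() > 0).astype(int)
    ]
    labels = pd.Series(lab, index=matrix.status.columns, name="group")
    return CombinedGrouping(anchor, frozenset(partners), scope, labels, burden)


def _drug_values(ic50: pd.DataFrame, drug: str) -> pd.Series:
    v = ic50.loc[ic50["drug"] == drug].set_index("cell_line")["ln_ic50"]
    if v.empty:
        raise KeyError(f"drug {drug!r} absent from IC50 table")
    return v


def compare_combined_groups(grouping: CombinedGrouping, ic50: pd.DataFrame,
                            drug: str) -> dict:
    """Group means and MMC-vs-each-other-group t tests on ln IC50.

    Comparisons against groups with fewer than 2 measured lines are
    skipped with a warning (P reported as NaN).
    """
    values = _drug_values(ic50, drug).reindex(
        grouping.labels.index).dropna()
    labels = grouping.labels.reindex(values.index)
    out = {"drug": drug, "n": {}, "mean": {}, "p_vs_mmc": {}}
    samples = {g: values[labels == g].to_numpy(float) for g in COMBINED_GROUPS}
    for g, v in samples.items():
        out["n"][g] = len(v)
        out["mean"][g] = float(v.mean()) if len(v) else np.nan
    mmc = samples["MMC"]
    for g in ("WWC", "WMC", "MWC"):
        if len(mmc) < 2 or len(samples[g]) < 2:
            log.warning("comparison MMC vs %s skipped (group too small)", g)
            out["p_vs_mmc"][g] = np.nan
        else:
            out["p_vs_mmc"][g] = float(stats.ttest_ind(mmc, samples[g], equal_var=True).pvalue)
    finite_means = {g: m for g, m in out["mean"].items() if np.isfinite(m)}
    out["mmc_lowest"] = bool(finite_means and
                             min(finite_means, key=finite_means.get) == "MMC")
    return out


@dataclass
class BurdenResult:
    """Per-stratum summaries of ln IC50 across partner-mutation burdens."""

    drug: str
    strata: pd.DataFrame          # columns: stratum, n, mean, sd
    pairwise_p: dict[tuple[str, str], float]
    anova_p: float


def burden_analysis(grouping: CombinedGrouping, ic50: pd.DataFrame, drug: str,
                    strata_rule: str = "zero_one_twoplus") -> BurdenResult:
    """Stratify anchor-mutated lines by partner-mutation count.

    strata_rule="zero_one_twoplus" yields MM0 (== MWC), MM1, MM2plus;
    "exact_count" yields MM0, MM1, ..., MMk. Pairwise t tests run for
    every stratum pair with n >= 2 in both, plus a one-way ANOVA when at
    least two strata have n >= 2.
    """
    if strata_rule not in ("zero_one_twoplus", "exact_count"):
        raise ValueError("strata_rule must be 'zero_one_twoplus' or 'exact_count'")
    values = _drug_values(ic50, drug)
    anchor_mut = grouping.labels.isin(["MWC", "MMC"])
    lines = [l for l in grouping.labels.index[anchor_mut] if l in values.index]
    if not lines:
        raise ValueError("no anchor-mutated cell lines with IC50 for this drug")
    burden = grouping.burden.reindex(lines)
    if strata_rule == "zero_one_twoplus":
        name = np.where(burden == 0, "MM0", np.where(burden == 1, "MM1", "MM2plus"))
    else:
        name = np.array([f"MM{b}" for b in burden])
    strata = pd.Series(name, index=lines)
    order = sorted(strata.unique(), key=lambda s: (len(s), s))
    rows, samples = [], {}
    for s in order:
        v = values.reindex(strata.index[strata == s]).to_numpy(float)
        samples[s] = v
        rows.append({"stratum": s, "n": len(v), "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan})
    pairwise = {}
    for s1, s2 in combinations(order, 2):
        if len(samples[s1]) >= 2 and len(samples[s2]) >= 2:
            pairwise[(s1, s2)] = float(
                stats.ttest_ind(samples[s1], samples[s2], equal_var=True).pvalue)
        else:
            log.warning("burden comparison %s vs %s skipped (stratum too small)", s1, s2)
    usable = [v for v in samples.values() if len(v) >= 2]
    anova_p = float(stats.f_oneway(*usable).pvalue) if len(usable) >= 2 else np.nan
    if len(usable) < 2:
        log.warning("burden ANOVA skipped: fewer than two usable strata")
    return BurdenResult(drug=drug, strata=pd.DataFrame(rows),
                        pairwise_p=pairwise, anova_p=anova_p)
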