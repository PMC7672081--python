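"""The synergistic chemo-sensitivity (SCS) screen.

For each drug, cell lines with an IC50 measurement are partitioned by the
damaging-mutation status of a gene pair (A, B) into WW / WM / MW / MM
(first letter = A). The model P value is a two-sided Student's t test of
ln IC50, MM versus the pooled non-MM lines; P values are
Benjamini-Hochberg adjusted per drug over the pairs that pass the
group-size filter. A candidate SCS set additionally requires:

* all four groups of at least ``min_group_size`` lines (default 5);
* mean ln IC50 of MM below the non-MM mean (sensitisation direction);
* max ln IC50 of the MM group below the median of the WW group
  (default; the opposite, literal direction is selectable);
* Q below ``q_threshold`` (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .damaging import DamagingMatrix, enumerate_pairs

log = logging.getLogger("scscreen")

GROUPS = ("WW", "WM", "MW", "MM")

RECORD_COLUMNS = [
    "drug", "gene_a", "gene_b",
    "n_ww", "n_wm", "n_mw", "n_mm",
    "mean_ww", "mean_wm", "mean_mw", "mean_mm", "mean_nonmm",
    "model_p", "q",
    "passed_size", "passed_direction", "passed_mm_ww", "passed_q", "candidate",
]


class DegenerateTestError(ValueError):
    """Both samples have zero variance; the t statistic is undefined."""


@dataclass(frozen=True)
class ScreenConfig:
    min_group_size: int = 5
    q_threshold: float = 0.05
    mm_ww_filter: str = "mm_max_lt_ww_median"  # or "mm_max_gt_ww_median", "off"
    t_variant: str = "pooled"  # or "welch"
    require_mm_lower: bool = True
    commercial_only: bool = True

    def __post_init__(self):
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.mm_ww_filter not in ("mm_max_lt_ww_median", "mm_max_gt_ww_median", "off"):
            raise ValueError(f"unknown mm_ww_filter {self.mm_ww_filter!r}")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError("t_variant must be 'pooled' or 'welch'")


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate measurements to one ln IC50 per (drug, cell line).

    The arithmetic mean on the natural-log scale is taken over available
    sources. More than two replicates is unusual for these panels and is
    logged.
    """
    n_rep = records.groupby(["drug", "cell_line"])["ln_ic50"].size()
    many = n_rep[n_rep >= 3]
    if len(many):
        log.warning("%d (drug, cell line) pairs have >= 3 replicates (e.g. %s)",
                    len(many), many.index[0])
    out = (records.groupby(["drug", "cell_line"], as_index=False)["ln_ic50"].mean())
    return out


@dataclass
class PairGrouping:
    """WW/WM/MW/MM labels for one (drug, gene pair) over measured lines."""

    drug: str
    gene_a: str
    gene_b: str
    labels: pd.Series  # index: cell_line, values in GROUPS

    @property
    def sizes(self) -> dict[str, int]:
        counts = self.labels.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}


def assign_groups(pair: tuple[str, str], matrix: DamagingMatrix,
                  ic50: pd.DataFrame, drug: str) -> PairGrouping:
    """Partition the drug's measured cell lines by pair mutation status."""
    gene_a, gene_b = pair
    for g in (gene_a, gene_b):
        if g not in matrix.status.index:
            raise KeyError(f"gene {g!r} not in damaging matrix")
    lines = ic50.loc[ic50["drug"] == drug, "cell_line"]
    if lines.empty:
        raise KeyError(f"drug {drug!r} has no IC50 measurements")
    lines = [l for l in lines if l in matrix.status.columns]
    a = matrix.status.loc[gene_a, lines].to_numpy(dtype=bool)
    b = matrix.status.loc[gene_b, lines].to_numpy(dtype=bool)
    lab = np.array(["WW", "WM", "MW", "MM"])[a.astype(int) * 2 + b.astype(int)]
    return PairGrouping(drug, gene_a, gene_b, pd.Series(lab, index=lines, name="group"))


def _t_test(mm: np.ndarray, nonmm: np.ndarray, t_variant: str) -> float:
    if mm.std() == 0 and nonmm.std() == 0:
        raise DegenerateTestError("zero variance in both groups; t statistic undefined")
    res = stats.ttest_ind(mm, nonmm, equal_var=(t_variant == "pooled"))
    return float(res.pvalue)


def model_p(grouping: PairGrouping, ic50: pd.DataFrame,
            cfg: ScreenConfig | None = None) -> tuple[float, float, float]:
    """Model P value: MM versus pooled non-MM t test on ln IC50.

    Returns (p, mean_MM, mean_nonMM).
    """
    cfg = cfg or ScreenConfig()
    values = (ic50.loc[ic50["drug"] == grouping.drug]
              .set_index("cell_line")["ln_ic50"]
              .reindex(grouping.labels.index))
    mm = values[grouping.labels == "MM"].to_numpy(float)
    nonmm = values[grouping.labels != "MM"].to_numpy(float)
    if len(mm) < 2 or len(nonmm) < 2:
        raise ValueError("model_p needs >= 2 lines in MM and in pooled non-MM")
    p = _t_test(mm, nonmm, cfg.t_variant)
    return p, float(mm.mean()), float(nonmm.mean())


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up Q values, in the input order, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _screen_drug_arrays(drug: str, status: np.ndarray, genes: list[str],
                        values: np.ndarray, pairs: Iterable[tuple[int, int]],
                        cfg: ScreenConfig) -> pd.DataFrame:
    """Inner loop over gene-index pairs; `status` is genes x measured-lines bool."""
    rows = []
    for ia, ib in pairs:
        a, b = status[ia], status[ib]
        mm_mask = a & b
        groups = {
            "WW": values[~a & ~b], "WM": values[~a & b],
            "MW": values[a & ~b], "MM": values[mm_mask],
        }
        ns = {g: len(v) for g, v in groups.items()}
        passed_size = all(n >= cfg.min_group_size for n in ns.values())
        means = {g: (float(v.mean()) if len(v) else np.nan) for g, v in groups.items()}
        nonmm = values[~mm_mask]
        row = {
            "drug": drug, "gene_a": genes[ia], "gene_b": genes[ib],
            "n_ww": ns["WW"], "n_wm": ns["WM"], "n_mw": ns["MW"], "n_mm": ns["MM"],
            "mean_ww": means["WW"], "mean_wm": means["WM"],
            "mean_mw": means["MW"], "mean_mm": means["MM"],
            "mean_nonmm": float(nonmm.mean()) if len(nonmm) else np.nan,
            "model_p": np.nan, "q": np.nan,
            "passed_size": passed_size, "passed_direction": False,
            "passed_mm_ww": False, "passed_q": False, "candidate": False,
        }
        if passed_size:
            row["model_p"] = _t_test(groups["MM"], nonmm, cfg.t_variant)
            row["passed_direction"] = (not cfg.require_mm_lower
                                       or row["mean_mm"] < row["mean_nonmm"])
            if cfg.mm_ww_filter == "off":
                row["passed_mm_ww"] = True
            else:
                mm_max, ww_med = groups["MM"].max(), float(np.median(groups["WW"]))
                row["passed_mm_ww"] = (mm_max < ww_med
                                       if cfg.mm_ww_filter == "mm_max_lt_ww_median"
                                       else mm_max > ww_med)
        rows.append(row)
    out = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    # BH batch: exactly the size-passing pairs of this drug
    tested = out["passed_size"].to_numpy()
    if tested.any():
        q = bh_adjust(out.loc[tested, "model_p"].to_numpy())
        out.loc[tested, "q"] = q
        out.loc[tested, "passed_q"] = q < cfg.q_threshold
    out["candidate"] = (out["passed_size"] & out["passed_direction"]
                        & out["passed_mm_ww"] & out["passed_q"])
    return out


def screen_drug(drug: str, matrix: DamagingMatrix, ic50: pd.DataFrame,
                cfg: ScreenConfig | None = None,
                pairs: Iterable[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Screen every gene pair against one drug; returns an SCS record table."""
    cfg = cfg or ScreenConfig()
    sub = ic50[ic50["drug"] == drug]
    if sub.empty:
        raise KeyError(f"drug {drug!r} absent from IC50 table")
    lines = [l for l in sub["cell_line"] if l in matrix.status.columns]
    values = (sub.set_index("cell_line")["ln_ic50"].reindex(lines).to_numpy(float))
    genes = matrix.genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    status = matrix.status[lines].to_numpy(dtype=bool)
    if pairs is None:
        idx_pairs = [(gene_idx[a], gene_idx[b]) for a, b in enumerate_pairs(matrix)]
    else:
        idx_pairs = [(gene_idx[a], gene_idx[b]) for a, b in pairs]
    return _screen_drug_arrays(drug, status, genes, values, idx_pairs, cfg)


def screen_all(matrix: DamagingMatrix, ic50: pd.DataFrame, drugs: pd.DataFrame,
               cfg: ScreenConfig | None = None,
               pairs: Iterable[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Run the per-drug screen over a drug-metadata table.

    With ``commercial_only`` (default), non-commercial drugs are excluded
    before screening. Summary counts are logged.
    """
    cfg = cfg or ScreenConfig()
    meta = drugs
    if cfg.commercial_only:
        meta = meta[meta["commercial"].astype(bool)]
    frames = []
    measured = set(ic50["drug"])
    for drug in meta["drug"]:
        if drug not in measured:
            log.warning("drug %r has no IC50 data; skipped", drug)
            continue
        frames.append(screen_drug(drug, matrix, ic50, cfg, pairs))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=RECORD_COLUMNS))
    cand = out[out["candidate"]]
    n_genes = len(set(cand["gene_a"]) | set(cand["gene_b"]))
    log.info("screen: %d candidate SCS sets, %d distinct genes, %d drugs with >= 1 candidate",
             len(cand), n_genes, cand["drug"].nunique())
    return out
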