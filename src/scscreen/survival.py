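"""Cohort classification and survival comparison.

Patients are classified WWC/WMC/MWC/MMC from MAF-like somatic calls: a
gene counts as damaged on any of the four MAF classes missense, nonsense,
splice-site, or translation start site. The first letter is the anchor
gene's status, the second whether any combined partner gene is damaged.
Group survival is compared with Kaplan-Meier curves and the log-rank
test; hazard ratios come from Cox proportional-hazards fits (Efron tie
handling, lifelines). Pairwise HRs are refit on the two groups compared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import logrank_test

log = logging.getLogger("scscreen")

#: MAF Variant_Classification values treated as damaging
DAMAGING_MAF_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Splice_Site", "Translation_Start_Site",
})

#: default BRAF/MAPK inhibitor exposure filter
DEFAULT_INHIBITORS = ("dabrafenib", "sorafenib", "trametinib", "vemurafenib", "selumetinib")

COHORT_GROUPS = ("WWC", "WMC", "MWC", "MMC")


class NoEventsError(ValueError):
    """No deaths observed; survival models are not identifiable."""


def _split_drugs(field) -> set[str]:
    if pd.isna(field) or not str(field).strip():
        return set()
    return {d.strip().lower() for d in str(field).replace(",", ";").split(";") if d.strip()}


def classify_patients(maf: pd.DataFrame, clinical: pd.DataFrame, anchor: str,
                      partner_set: Sequence[str],
                      drug_filter: Sequence[str] | None = DEFAULT_INHIBITORS,
                      melanoma_code: str = "SKCM") -> pd.DataFrame:
    """Build the per-patient cohort table with WWC/WMC/MWC/MMC labels.

    Inclusion requires a patient to appear in both the mutation and the
    clinical table; `drug_filter`, unless None, further restricts to
    patients exposed to at least one named inhibitor (case-insensitive
    match against the clinical drugs field).
    """
    partner_set = set(partner_set)
    damaging = maf[maf["variant_classification"].isin(DAMAGING_MAF_CLASSES)]
    anchor_mut = set(damaging.loc[damaging["gene"] == anchor, "patient"])
    partner_mut = set(damaging.loc[damaging["gene"].isin(partner_set), "patient"])

    cohort = clinical[clinical["patient"].isin(set(maf["patient"]))].copy()
    if drug_filter is not None:
        wanted = {d.lower() for d in drug_filter}
        exposed = cohort["drugs"].map(lambda f: bool(_split_drugs(f) & wanted))
        cohort = cohort[exposed]
    a = cohort["patient"].isin(anchor_mut).to_numpy(int)
    b = cohort["patient"].isin(partner_mut).to_numpy(int)
    cohort["group"] = np.array(COHORT_GROUPS)[a * 2 + b]
    cohort["cancer_type_flag"] = (cohort["cancer_type"] == melanoma_code).astype(int)
    log.info("cohort: %d patients classified (%s)", len(cohort),
             cohort["group"].value_counts().to_dict())
    return cohort.reset_index(drop=True)


@dataclass
class KMResult:
    group_a: str
    group_b: str
    curves: dict[str, pd.DataFrame]     # per-group KM survival function
    medians: dict[str, float]           # median OS, months (NaN if not reached)
    logrank_stat: float
    logrank_p: float
    hr: float                           # group_a relative to group_b
    hr_ci: tuple[float, float]
    hr_p: float


def km_logrank(cohort: pd.DataFrame, group_a: str, group_b: str) -> KMResult:
    """Kaplan-Meier curves, median OS, log-rank test, and pairwise Cox HR."""
    sub = {g: cohort[cohort["group"] == g] for g in (group_a, group_b)}
    for g, df in sub.items():
        if df.empty:
            raise ValueError(f"group {g!r} is empty")
    curves, medians = {}, {}
    for g, df in sub.items():
        kmf = KaplanMeierFitter()
        kmf.fit(df["os_months"], event_observed=df["event"].astype(bool), label=g)
        curves[g] = kmf.survival_function_
        medians[g] = float(kmf.median_survival_time_)
    lr = logrank_test(sub[group_a]["os_months"], sub[group_b]["os_months"],
                      event_observed_A=sub[group_a]["event"].astype(bool),
                      event_observed_B=sub[group_b]["event"].astype(bool))
    both = pd.concat(sub.values())
    if int(both["event"].astype(bool).sum()) == 0:
        raise NoEventsError("no events in the compared groups")
    fit_df = pd.DataFrame({
        "os_months": both["os_months"].to_numpy(float),
        "event": both["event"].astype(bool).to_numpy(),
        "is_a": (both["group"] == group_a).astype(int).to_numpy(),
    })
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cph.fit(fit_df, duration_col="os_months", event_col="event")
    s = cph.summary.loc["is_a"]
    return KMResult(group_a, group_b, curves, medians,
                    float(lr.test_statistic), float(lr.p_value),
                    float(s["exp(coef)"]),
                    (float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
                    float(s["p"]))


@dataclass
class CoxResult:
    univariate: dict[str, pd.DataFrame]   # covariate -> lifelines summary
    multivariate: pd.DataFrame
    flags: list[str]                      # convergence / separation warnings


def _design(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {"os_months": cohort["os_months"].to_numpy(float),
            "event": cohort["event"].astype(bool).to_numpy()}
    for cov in covariates:
        if cov == "group":
            for g in COHORT_GROUPS[1:]:  # WWC is the reference level
                cols[f"group_{g}"] = (cohort["group"] == g).astype(int).to_numpy()
        elif cov == "sex":
            levels = sorted(cohort["sex"].astype(str).unique())
            for lev in levels[1:]:
                cols[f"sex_{lev}"] = (cohort["sex"].astype(str) == lev).astype(int).to_numpy()
        else:
            cols[cov] = pd.to_numeric(cohort[cov]).to_numpy(float)
    df = pd.DataFrame(cols)
    return df.loc[:, df.nunique() > 1]  # drop constant columns (e.g. absent groups)


def cox_models(cohort: pd.DataFrame,
               covariates: Sequence[str] = ("age", "sex", "cancer_type_flag", "group"),
               ) -> CoxResult:
    """Univariate Cox fit per covariate plus one joint multivariate fit.

    The mutation profile enters as the 4-level group factor with WWC as
    the reference. Convergence problems (e.g. complete separation in a
    tiny group) are recorded in ``flags`` rather than silently reported.
    """
    if int(cohort["event"].astype(bool).sum()) == 0:
        raise NoEventsError("no observed events in cohort")
    flags: list[str] = []

    def fit(df: pd.DataFrame, tag: str) -> pd.DataFrame:
        cph = CoxPHFitter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            cph.fit(df, duration_col="os_months", event_col="event")
            for w in caught:
                flags.append(f"{tag}: {w.message}")
        return cph.summary

    univariate = {}
    for cov in covariates:
        univariate[cov] = fit(_design(cohort, [cov]), f"univariate:{cov}")
    multivariate = fit(_design(cohort, covariates), "multivariate")
    return CoxResult(univariate, multivariate, flags)
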