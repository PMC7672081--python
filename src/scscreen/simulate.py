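"""Synthetic pharmacogenomic panels and patient cohorts with planted truth.

The generator emulates the structure of a cell-line drug-sensitivity
resource: a sparse binary damaging-mutation matrix (Bernoulli per gene),
per-drug natural-log IC50 values with Normal baselines, two-level tissue
labels, replicate measurements from a second site, and drug metadata.
Planted (drug, gene pair) effects shift the ln IC50 of doubly-mutated
(MM) lines by a known delta; a planted combined effect shifts
anchor-mutated lines additively per mutated partner. Cohorts carry
exponential survival with group-specific hazard ratios and independent
exponential censoring. Every planted effect is recorded in a truth
manifest so recovery can be checked exactly.

Emitted files pass the data_io validators unmodified, and variant records
carry classifications/scores that guarantee the intended damaging call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import io as sio

#: damaging-category mix for generated hits: LoF / damaging missense /
#: homozygous deletion, matching the roughly 17/68/15 split such panels show
CATEGORY_MIX = (0.17, 0.68, 0.15)

#: (tissue1, tissue2, probability) — coarse anatomical and fine pathological
#: labels; skin/melanoma and large-intestine/colorectal fractions mirror a
#: ~990-line pan-cancer panel
DEFAULT_TISSUES = (
    ("lung", "NSCLC", 0.18), ("lung", "SCLC", 0.07),
    ("skin", "melanoma", 0.06), ("large_intestine", "colorectal_carcinoma", 0.05),
    ("breast", "breast_carcinoma", 0.10), ("blood", "AML", 0.12),
    ("CNS", "glioma", 0.08), ("ovary", "ovarian_carcinoma", 0.06),
    ("pancreas", "pancreatic_carcinoma", 0.05), ("stomach", "gastric_carcinoma", 0.05),
    ("kidney", "renal_carcinoma", 0.05), ("bone", "osteosarcoma", 0.04),
    ("liver", "HCC", 0.04), ("soft_tissue", "sarcoma", 0.05),
)

#: the BRAF synergy partner genes used as default cohort partner set
DEFAULT_PARTNERS = (
    "C10orf112", "COL2A1", "COL4A4", "CSMD1", "GPR112", "LCE3C",
    "NBEA", "NLRP3", "PLG", "TTN", "ZNF234",
)

DEFAULT_INHIBITORS = ("dabrafenib", "sorafenib", "trametinib", "vemurafenib", "selumetinib")


@dataclass(frozen=True)
class DrugSpec:
    drug: str
    name: str = ""
    target_class: str = "unclassified"
    commercial: bool = True
    baseline_mean: float = 2.5   # ln(uM); mid-range potency
    baseline_sd: float = 1.0


@dataclass(frozen=True)
class PlantedPair:
    drug: str
    gene_a: str
    gene_b: str
    delta: float                    # ln-IC50 shift applied to MM lines
    n_mm: int | None = None         # force exact group sizes for the two genes
    n_mw: int | None = None
    n_wm: int | None = None


@dataclass(frozen=True)
class PlantedCombined:
    anchor: str
    partners: tuple[str, ...]
    delta_per_partner: float        # additive ln-IC50 shift per mutated partner
    drugs: tuple[str, ...]


@dataclass
class PanelConfig:
    """Conditions of a synthetic cell-line panel; `seed` is mandatory."""

    seed: int
    n_cell_lines: int = 200
    n_genes: int = 60
    mutation_rate: float | Sequence[float] = 0.08
    drugs: tuple[DrugSpec, ...] | None = None
    n_drugs: int = 3
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_combined: PlantedCombined | None = None
    tissues: tuple[tuple[str, str, float], ...] = DEFAULT_TISSUES
    missing_fraction: float = 0.10   # (drug, line) measurements absent
    replicate_fraction: float = 0.05  # measurements duplicated at a second site
    replicate_sd: float = 0.05       # between-site half-spread of a replicate
    noise_variant_rate: float = 0.01  # benign (non-damaging) coding rows
    #: optional mutation co-occurrence: (gene_a, gene_b, odds_ratio)
    co_occurring: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        rates = np.atleast_1d(np.asarray(self.mutation_rate, float))
        if ((rates < 0) | (rates > 1)).any():
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.drugs is None:
            self.drugs = tuple(
                DrugSpec(drug=f"drug{i + 1:02d}", name=f"compound-{i + 1}")
                for i in range(self.n_drugs)
            )
        drug_ids = {d.drug for d in self.drugs}
        genes = set(self._gene_names())
        for pp in self.planted_pairs:
            if pp.drug not in drug_ids:
                raise ValueError(f"planted pair references unknown drug {pp.drug!r}")
            if pp.gene_a not in genes or pp.gene_b not in genes:
                raise ValueError(f"planted pair references unknown gene in {pp!r}")
            if not np.isfinite(pp.delta):
                raise ValueError("planted delta must be finite")
        if self.planted_combined is not None:
            pc = self.planted_combined
            missing = ({pc.anchor, *pc.partners} - genes) or (set(pc.drugs) - drug_ids)
            if missing:
                raise ValueError(f"planted combined effect references unknown ids: {missing}")

    def _gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def _line_names(self) -> list[str]:
        return [f"CL{i + 1:04d}" for i in range(self.n_cell_lines)]


class PanelData(NamedTuple):
    variants: pd.DataFrame
    copy_number: pd.DataFrame
    dose_response: pd.DataFrame
    drug_meta: pd.DataFrame
    cell_line_meta: pd.DataFrame
    truth: dict


def _joint_bernoulli(rng, pa: float, pb: float, odds_ratio: float, n: int):
    """Sample (A, B) Bernoulli pairs with given marginals and odds ratio."""
    if odds_ratio == 1.0:
        return rng.random(n) < pa, rng.random(n) < pb
    # solve p11 from the OR quadratic: OR = p11*p00 / (p10*p01)
    a = odds_ratio - 1.0
    b = -(1 + (pa + pb) * (odds_ratio - 1.0))
    c = odds_ratio * pa * pb
    disc = b * b - 4 * a * c
    p11 = (-b - np.sqrt(disc)) / (2 * a)
    p11 = float(np.clip(p11, max(0.0, pa + pb - 1.0), min(pa, pb)))
    u = rng.random(n)
    aa = np.zeros(n, bool)
    bb = np.zeros(n, bool)
    aa[u < p11] = bb[u < p11] = True
    aa[(u >= p11) & (u < pa)] = True
    bb[(u >= pa) & (u < pa + pb - p11)] = True
    return aa, bb


def generate_panel(cfg: PanelConfig) -> PanelData:
    """Generate one synthetic panel; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genes, lines = cfg._gene_names(), cfg._line_names()
    n_g, n_l = len(genes), len(lines)
    rates = np.broadcast_to(np.atleast_1d(np.asarray(cfg.mutation_rate, float)), (n_g,))

    status = rng.random((n_g, n_l)) < rates[:, None]
    gi = {g: i for i, g in enumerate(genes)}
    for ga, gb, orr in cfg.co_occurring:
        status[gi[ga]], status[gi[gb]] = _joint_bernoulli(
            rng, float(rates[gi[ga]]), float(rates[gi[gb]]), float(orr), n_l)
    # forced group sizes for planted pairs (exact WW/WM/MW/MM layout)
    for pp in cfg.planted_pairs:
        if pp.n_mm is None:
            continue
        n_mw = pp.n_mw if pp.n_mw is not None else pp.n_mm
        n_wm = pp.n_wm if pp.n_wm is not None else pp.n_mm
        if pp.n_mm + n_mw + n_wm > n_l:
            raise ValueError(f"forced group sizes exceed panel size for {pp!r}")
        perm = rng.permutation(n_l)
        ia, ib = gi[pp.gene_a], gi[pp.gene_b]
        status[ia, :] = False
        status[ib, :] = False
        status[ia, perm[: pp.n_mm + n_mw]] = True
        status[ib, perm[: pp.n_mm]] = True
        status[ib, perm[pp.n_mm + n_mw: pp.n_mm + n_mw + n_wm]] = True

    # per-hit damaging category and the corresponding raw records
    cat = rng.choice(3, size=(n_g, n_l), p=CATEGORY_MIX)
    var_rows, cnv_rows = [], []
    hit_g, hit_l = np.nonzero(status)
    for g, l in zip(hit_g, hit_l):
        if cat[g, l] == 0:   # LoF
            cls = "nonsense" if rng.random() < 0.8 else "stop-loss"
            var_rows.append((genes[g], lines[l], cls, np.nan, np.nan))
        elif cat[g, l] == 1:  # damaging missense
            var_rows.append((genes[g], lines[l], "missense",
                             round(rng.uniform(0.0, 0.049), 4),
                             round(rng.uniform(0.909, 1.0), 4)))
        else:                 # homozygous deletion
            cnv_rows.append((genes[g], lines[l], "homozygous-deletion"))
    # benign coding noise: never passes the damaging filter
    n_noise = rng.binomial(n_g * n_l, cfg.noise_variant_rate)
    for idx in rng.choice(n_g * n_l, size=n_noise, replace=False):
        g, l = divmod(int(idx), n_l)
        if rng.random() < 0.5:
            var_rows.append((genes[g], lines[l], "missense",
                             round(rng.uniform(0.2, 1.0), 4),
                             round(rng.uniform(0.0, 0.5), 4)))
        else:
            var_rows.append((genes[g], lines[l], "other", np.nan, np.nan))
    variants = pd.DataFrame(var_rows, columns=sio.TABLE_COLUMNS["coding_variants"])
    copy_number = pd.DataFrame(cnv_rows, columns=sio.TABLE_COLUMNS["copy_number"])

    # tissue labels
    probs = np.array([t[2] for t in cfg.tissues], float)
    probs = probs / probs.sum()
    t_idx = rng.choice(len(cfg.tissues), size=n_l, p=probs)
    cell_line_meta = pd.DataFrame({
        "cell_line": lines,
        "tissue1": [cfg.tissues[i][0] for i in t_idx],
        "tissue2": [cfg.tissues[i][1] for i in t_idx],
    })

    drug_meta = pd.DataFrame([
        {"drug": d.drug, "name": d.name or d.drug,
         "target_class": d.target_class, "commercial": d.commercial}
        for d in cfg.drugs
    ])

    # true ln IC50 per (drug, line): Normal baseline + planted shifts
    dose_rows = []
    truth_pairs = []
    for d in cfg.drugs:
        value = rng.normal(d.baseline_mean, d.baseline_sd, size=n_l)
        for pp in cfg.planted_pairs:
            if pp.drug != d.drug:
                continue
            mm = status[gi[pp.gene_a]] & status[gi[pp.gene_b]]
            value[mm] += pp.delta
            truth_pairs.append({
                "drug": pp.drug, "gene_a": pp.gene_a, "gene_b": pp.gene_b,
                "delta": pp.delta,
                "mm_lines": ";".join(np.array(lines)[mm]),
            })
        pc = cfg.planted_combined
        if pc is not None and d.drug in pc.drugs:
            anchor_mut = status[gi[pc.anchor]]
            burden = np.zeros(n_l)
            for p in pc.partners:
                burden += status[gi[p]]
            value += pc.delta_per_partner * burden * anchor_mut
        measured = rng.random(n_l) >= cfg.missing_fraction
        replicated = measured & (rng.random(n_l) < cfg.replicate_fraction)
        jitter = rng.normal(0, cfg.replicate_sd, size=n_l)
        for j in range(n_l):
            if not measured[j]:
                continue
            if replicated[j]:
                dose_rows.append((d.drug, lines[j], value[j] + jitter[j], "site1"))
                dose_rows.append((d.drug, lines[j], value[j] - jitter[j], "site2"))
            else:
                dose_rows.append((d.drug, lines[j], value[j], "site1"))
    dose_response = pd.DataFrame(dose_rows, columns=sio.TABLE_COLUMNS["dose_response"])
    dose_response["ln_ic50"] = dose_response["ln_ic50"].round(6)

    truth = {
        "status": pd.DataFrame(status.astype("int8"), index=genes, columns=lines),
        "planted_pairs": pd.DataFrame(
            truth_pairs, columns=["drug", "gene_a", "gene_b", "delta", "mm_lines"]),
        "planted_combined": cfg.planted_combined,
    }
    return PanelData(variants, copy_number, dose_response, drug_meta,
                     cell_line_meta, truth)


@dataclass
class CohortConfig:
    """Conditions of a synthetic treated-patient cohort; `seed` is mandatory.

    Defaults mirror a 65-patient inhibitor-treated pan-cancer cohort with
    group proportions 30/22/2/11 over WWC/WMC/MWC/MMC, a ~27-month median
    OS in the doubly-wild-type group, a 0.44 hazard ratio for the
    doubly-mutated group, and 20% censoring.
    """

    seed: int
    n_patients: int = 65
    proportions: tuple[float, float, float, float] = (30 / 65, 22 / 65, 2 / 65, 11 / 65)
    baseline_median_os: float = 27.13   # months, WWC group
    group_hrs: dict = field(default_factory=lambda: {
        "WWC": 1.0, "WMC": 1.0, "MWC": 1.0, "MMC": 0.44})
    censoring_rate: float = 0.20
    anchor: str = "BRAF"
    partners: tuple[str, ...] = DEFAULT_PARTNERS
    inhibitors: tuple[str, ...] = DEFAULT_INHIBITORS
    age_mean: float = 60.0
    age_sd: float = 12.0
    cancer_types: tuple[tuple[str, float], ...] = (
        ("SKCM", 0.50), ("COAD", 0.15), ("LUSC", 0.10), ("KIRC", 0.10),
        ("GBM", 0.05), ("LIHC", 0.05), ("UCEC", 0.05),
    )

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if self.baseline_median_os <= 0:
            raise ValueError("baseline median OS must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


class CohortData(NamedTuple):
    maf: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame   # patient -> planted group


GROUPS = ("WWC", "WMC", "MWC", "MMC")


def _apportion(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment: exact counts from proportions."""
    raw = np.asarray(proportions, float) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts.tolist()


def generate_cohort(cfg: CohortConfig) -> CohortData:
    """Generate one synthetic cohort; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    counts = _apportion(cfg.n_patients, cfg.proportions)
    patients = [f"TCGA-{i + 1:04d}" for i in range(cfg.n_patients)]
    groups = np.repeat(GROUPS, counts)
    perm = rng.permutation(cfg.n_patients)
    groups = groups[perm]

    h0 = np.log(2) / cfg.baseline_median_os
    maf_rows, clin_rows, truth_rows = [], [], []
    damaging = ("Missense_Mutation", "Nonsense_Mutation",
                "Splice_Site", "Translation_Start_Site")
    ct_names = [c[0] for c in cfg.cancer_types]
    ct_probs = np.array([c[1] for c in cfg.cancer_types], float)
    ct_probs /= ct_probs.sum()
    for pt, grp in zip(patients, groups):
        # mutations: anchor for M**, >=1 partner for *M*; everyone gets at
        # least one neutral row so WW patients still appear in the MAF
        maf_rows.append((pt, "GAPDH", "Silent"))
        if grp[0] == "M":
            maf_rows.append((pt, cfg.anchor, "Missense_Mutation"))
        if grp[1] == "M":
            k = 1 + rng.binomial(min(6, len(cfg.partners) - 1), 0.25)
            chosen = rng.choice(len(cfg.partners), size=k, replace=False)
            for idx in chosen:
                maf_rows.append((pt, cfg.partners[idx],
                                 damaging[rng.choice(4, p=[0.6, 0.2, 0.15, 0.05])]))
        elif rng.random() < 0.2:  # neutral partner-gene row; must stay wild-type
            maf_rows.append((pt, cfg.partners[rng.integers(len(cfg.partners))], "Silent"))

        hazard = h0 * cfg.group_hrs[grp]
        t_event = rng.exponential(1.0 / hazard)
        if cfg.censoring_rate > 0:
            c_rate = hazard * cfg.censoring_rate / (1 - cfg.censoring_rate)
            t_cens = rng.exponential(1.0 / c_rate)
        else:
            t_cens = np.inf
        os_months = round(min(t_event, t_cens), 2)
        clin_rows.append({
            "patient": pt,
            "age": int(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 20, 90)),
            "sex": "male" if rng.random() < 0.5 else "female",
            "cancer_type": ct_names[rng.choice(len(ct_names), p=ct_probs)],
            "drugs": cfg.inhibitors[rng.integers(len(cfg.inhibitors))],
            "os_months": max(os_months, 0.01),
            "event": bool(t_event <= t_cens),
        })
        truth_rows.append({"patient": pt, "group": grp})

    maf = pd.DataFrame(maf_rows, columns=sio.TABLE_COLUMNS["cohort_variants"])
    clinical = pd.DataFrame(clin_rows, columns=sio.TABLE_COLUMNS["clinical"])
    return CohortData(maf, clinical, pd.DataFrame(truth_rows))


def write_panel(panel: PanelData, outdir) -> dict[str, Path]:
    """Write a generated panel (and its truth manifest) as TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "coding_variants": panel.variants, "copy_number": panel.copy_number,
        "dose_response": panel.dose_response, "drug_meta": panel.drug_meta,
        "cell_line_meta": panel.cell_line_meta,
    }
    for name, df in tables.items():
        paths[name] = outdir / f"{name}.tsv"
        sio.write_results(df, paths[name], allow_empty=True)
    paths["truth_status"] = outdir / "truth_status.tsv"
    panel.truth["status"].rename_axis("gene").reset_index().to_csv(
        paths["truth_status"], sep="\t", index=False)
    paths["truth_planted_pairs"] = outdir / "truth_planted_pairs.tsv"
    sio.write_results(panel.truth["planted_pairs"], paths["truth_planted_pairs"],
                      allow_empty=True)
    return paths


def write_cohort(cohort: CohortData, outdir) -> dict[str, Path]:
    """Write a generated cohort (MAF-style variants, clinical, truth) as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"maf": outdir / "cohort_variants.tsv",
             "clinical": outdir / "clinical.tsv",
             "truth": outdir / "truth_groups.tsv"}
    maf = cohort.maf.rename(columns={k: v for k, v in sio.MAF_SCHEMA.items()})
    maf.to_csv(paths["maf"], sep="\t", index=False)
    sio.write_results(cohort.clinical, paths["clinical"])
    sio.write_results(cohort.truth, paths["truth"])
    return paths
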