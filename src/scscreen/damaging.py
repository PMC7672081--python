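"""Damaging-mutation calls and the binary gene x cell-line matrix.

A gene is "significantly damaged" in a cell line if the line carries at
least one of:

* a loss-of-function (LoF) coding variant — stop-loss or nonsense;
* a damaging missense variant — SIFT < 0.05 (deleterious) and
  PolyPhen > 0.908 (probably damaging), both strict;
* a gene-level homozygous copy-number deletion.

Genes damaged in fewer than ``min_mutated_lines`` distinct cell lines
(default 10) are dropped before pair enumeration; a line hit by several
variants of one gene still counts once.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("scscreen")

CAT_LOF = "lof"
CAT_MISSENSE = "missense"
CAT_DELETION = "deletion"
CAT_NONE = "none"
CATEGORIES = (CAT_LOF, CAT_MISSENSE, CAT_DELETION)

LOF_CLASSES = {"stop-loss", "nonsense"}
DELETION_CATEGORIES = {"homozygous-deletion", "homozygous_deletion", "homozygous deletion"}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the damaging-variant filter cascade.

    sift_cut / polyphen_cut are strict bounds (score < sift_cut, score >
    polyphen_cut); `missense_rule` chooses whether a damaging missense call
    needs both predictors ("both") or either one ("either"). Variants with
    a missing predictor score never satisfy that predictor.
    """

    sift_cut: float = 0.05
    polyphen_cut: float = 0.908
    min_mutated_lines: int = 10
    missense_rule: str = "both"
    #: raw classification label -> canonical {stop-loss, nonsense, missense, other}
    class_map: Mapping[str, str] = field(default_factory=dict)
    on_unknown_class: str = "warn"  # or "raise"

    def __post_init__(self):
        if not (0 < self.sift_cut < 1 and 0 < self.polyphen_cut < 1):
            raise ValueError("score cutoffs must lie in (0, 1)")
        if self.min_mutated_lines < 1:
            raise ValueError("min_mutated_lines must be >= 1")
        if self.missense_rule not in ("both", "either"):
            raise ValueError("missense_rule must be 'both' or 'either'")
        if self.on_unknown_class not in ("warn", "raise"):
            raise ValueError("on_unknown_class must be 'warn' or 'raise'")


def _canonical_class(label: str, cfg: FilterConfig) -> str:
    label = cfg.class_map.get(label, label)
    if label not in {"stop-loss", "nonsense", "missense", "other"}:
        if cfg.on_unknown_class == "raise":
            raise ValueError(f"unknown variant classification {label!r} and no mapping")
        log.warning("unknown variant classification %r treated as 'other'", label)
        return "other"
    return label


def classify_variant(record, cfg: FilterConfig | None = None) -> str:
    """Damaging category of one variant or copy-number record.

    `record` is any mapping / namedtuple / pandas row with either a coding
    variant's fields (classification, sift, polyphen) or a copy-number
    record's `category` field. Returns one of ``lof``, ``missense``,
    ``deletion``, ``none``.
    """
    cfg = cfg or FilterConfig()
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)
    if get("category") is not None:
        cat = str(get("category")).strip().lower()
        return CAT_DELETION if cat in DELETION_CATEGORIES else CAT_NONE
    cls = _canonical_class(str(get("classification")), cfg)
    if cls in LOF_CLASSES:
        return CAT_LOF
    if cls == "missense":
        sift, poly = get("sift"), get("polyphen")
        sift_hit = sift is not None and not pd.isna(sift) and float(sift) < cfg.sift_cut
        poly_hit = poly is not None and not pd.isna(poly) and float(poly) > cfg.polyphen_cut
        hit = (sift_hit and poly_hit) if cfg.missense_rule == "both" else (sift_hit or poly_hit)
        return CAT_MISSENSE if hit else CAT_NONE
    return CAT_NONE


@dataclass
class DamagingMatrix:
    """Binary damaging-status indicator plus per-category variant counts.

    ``status`` is a genes x cell-lines int8 DataFrame; ``counts[cat]`` are
    same-shaped variant-count tables for the LoF / damaging-missense /
    CNV-deletion categories. status == 1 iff any category count > 0.
    """

    status: pd.DataFrame
    counts: dict[str, pd.DataFrame]

    @property
    def genes(self) -> list[str]:
        return list(self.status.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.status.columns)

    def damaged_line_counts(self) -> pd.Series:
        """Distinct damaged cell lines per gene."""
        return self.status.sum(axis=1)

    def counts_table(self) -> pd.DataFrame:
        """Long-form per-(gene, cell line) category counts, for TSV export."""
        out = pd.DataFrame({
            "gene": np.repeat(self.genes, len(self.cell_lines)),
            "cell_line": np.tile(self.cell_lines, len(self.genes)),
        })
        for cat in CATEGORIES:
            out[cat] = self.counts[cat].to_numpy().ravel()
        out["any"] = self.status.to_numpy().ravel()
        return out[out[list(CATEGORIES)].sum(axis=1) > 0].reset_index(drop=True)


def build_damaging_matrix(variants: pd.DataFrame | None,
                          cnvs: pd.DataFrame | None,
                          cfg: FilterConfig | None = None,
                          cell_lines: Iterable[str] | None = None) -> DamagingMatrix:
    """Build the damaging matrix and apply the minimum-line gene filter.

    Parameters
    ----------
    variants, cnvs : canonical coding_variants / copy_number tables (either
        may be None or empty).
    cfg : FilterConfig
    cell_lines : full cell-line universe. Required so that lines without
        any damaging call appear as all-zero columns; defaults to the lines
        observed in the inputs.
    """
    cfg = cfg or FilterConfig()
    frames = []
    if variants is not None and len(variants):
        v = variants.copy()
        v["_cat"] = [
            classify_variant(row, cfg)
            for row in v[["classification", "sift", "polyphen"]].to_dict("records")
        ]
        frames.append(v.loc[v["_cat"] != CAT_NONE, ["gene", "cell_line", "_cat"]])
    if cnvs is not None and len(cnvs):
        c = cnvs.copy()
        c["_cat"] = [classify_variant(row, cfg) for row in c[["category"]].to_dict("records")]
        frames.append(c.loc[c["_cat"] != CAT_NONE, ["gene", "cell_line", "_cat"]])

    hits = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["gene", "cell_line", "_cat"]))

    if cell_lines is None:
        universe = sorted(set(hits["cell_line"]))
        if variants is not None and len(variants):
            universe = sorted(set(universe) | set(variants["cell_line"]))
        if cnvs is not None and len(cnvs):
            universe = sorted(set(universe) | set(cnvs["cell_line"]))
    else:
        universe = list(dict.fromkeys(cell_lines))
    if not universe:
        raise ValueError("empty cell-line universe")

    genes = sorted(set(hits["gene"]))
    counts = {}
    for cat in CATEGORIES:
        sub = hits[hits["_cat"] == cat]
        tab = (sub.groupby(["gene", "cell_line"]).size().unstack(fill_value=0)
               .reindex(index=genes, columns=universe, fill_value=0).astype(int))
        counts[cat] = tab
    status = ((counts[CAT_LOF] + counts[CAT_MISSENSE] + counts[CAT_DELETION]) > 0).astype("int8")

    keep = status.sum(axis=1) >= cfg.min_mutated_lines
    dropped = int((~keep).sum())
    status = status.loc[keep]
    counts = {cat: tab.loc[keep] for cat, tab in counts.items()}
    log.info("damaging matrix: %d genes retained (%d dropped by <%d-line filter), %d cell lines",
             len(status), dropped, cfg.min_mutated_lines, len(universe))
    return DamagingMatrix(status=status, counts=counts)


def pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs: n(n-1)/2."""
    return n_genes * (n_genes - 1) // 2


def enumerate_pairs(matrix: DamagingMatrix | Iterable[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs over the retained genes, lexicographic order."""
    genes = matrix.genes if isinstance(matrix, DamagingMatrix) else list(matrix)
    return list(itertools.combinations(sorted(set(genes)), 2))
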