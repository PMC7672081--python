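"""Drug/gene and drug/tissue matrices, hierarchical clustering, enrichment.

The drug/gene matrix is binary (gene appears in >= 1 candidate pair for
the drug), restricted to genes appearing at least twice across all
candidate pairs. The drug/tissue matrix counts doubly-mutated (MM) cell
lines per drug and tissue of origin, min-max normalised within each drug
row to [0, 1]. Both are clustered with complete linkage on Euclidean
distance. Tissue enrichment of MM lines against the full panel uses a
chi-squared test of homogeneity on the tissue x {MM, background} table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

log = logging.getLogger("scscreen")


@dataclass
class ClusterMatrix:
    df: pd.DataFrame
    kind: str                 # "drug_gene" or "drug_tissue"
    normalization: str = "none"


def build_drug_gene_matrix(scs_records: pd.DataFrame) -> ClusterMatrix:
    """Binary gene (rows) x drug (columns) candidate-membership table.

    A gene's appearance count is per candidate pair (a gene paired with
    two partners for one drug counts twice); genes with fewer than two
    total appearances are dropped.
    """
    cand = scs_records[scs_records["candidate"]]
    if cand.empty:
        return ClusterMatrix(pd.DataFrame(), "drug_gene")
    long = pd.concat([
        cand[["drug", "gene_a"]].rename(columns={"gene_a": "gene"}),
        cand[["drug", "gene_b"]].rename(columns={"gene_b": "gene"}),
    ])
    appearances = long.groupby("gene").size()
    keep = appearances[appearances >= 2].index
    long = long[long["gene"].isin(keep)]
    mat = (long.assign(v=1).pivot_table(index="gene", columns="drug", values="v",
                                        aggfunc="max", fill_value=0).astype(int))
    return ClusterMatrix(mat, "drug_gene")


def min_max_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise min-max scaling to [0, 1]; constant rows map to 0."""
    lo = df.min(axis=1)
    span = df.max(axis=1) - lo
    out = df.sub(lo, axis=0).div(span.replace(0, np.nan), axis=0).fillna(0.0)
    const = span == 0
    if const.any():
        log.info("min-max: %d constant rows mapped to 0", int(const.sum()))
    return out


def build_drug_tissue_matrix(scs_records: pd.DataFrame,
                             mm_lines: Mapping[str, Sequence[str]],
                             meta: pd.DataFrame,
                             descriptor: str = "tissue1",
                             normalize: str = "drug_wise_minmax") -> ClusterMatrix:
    """Drug (rows) x tissue (columns) MM-line count table.

    Parameters
    ----------
    scs_records : screen output; fixes the drug universe (drugs with >= 1
        candidate).
    mm_lines : mapping drug -> MM cell lines for that drug's candidate sets.
    meta : canonical cell_line_meta table.
    descriptor : "tissue1" (coarse anatomical) or "tissue2" (fine
        pathological) origin labels.
    normalize : "drug_wise_minmax" (default) or "none".
    """
    if descriptor not in ("tissue1", "tissue2"):
        raise ValueError("descriptor must be 'tissue1' or 'tissue2'")
    if normalize not in ("drug_wise_minmax", "none"):
        raise ValueError("normalize must be 'drug_wise_minmax' or 'none'")
    tissue = meta.set_index("cell_line")[descriptor]
    tissues = sorted(tissue.unique())
    drugs = sorted(set(scs_records.loc[scs_records["candidate"], "drug"]) & set(mm_lines))
    counts = pd.DataFrame(0, index=drugs, columns=tissues, dtype=float)
    for drug in drugs:
        t = tissue.reindex(mm_lines[drug]).dropna().value_counts()
        counts.loc[drug, t.index] = t.to_numpy(float)
    if normalize == "drug_wise_minmax":
        counts = min_max_rows(counts)
    return ClusterMatrix(counts, "drug_tissue", normalization=normalize)


@dataclass
class LinkageResult:
    linkage: np.ndarray       # scipy linkage matrix
    labels: list[str]         # row labels, input order
    leaf_order: list[str]     # dendrogram leaf order

    def flat_clusters(self, n_clusters: int) -> pd.Series:
        assignments = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(assignments, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            return (f"({render(node.left, node.dist)},{render(node.right, node.dist)})"
                    f":{length:.6g}")

        return render(tree, tree.dist) + ";"


def hierarchical_cluster(matrix: ClusterMatrix | pd.DataFrame) -> LinkageResult:
    """Complete-linkage, Euclidean-distance hierarchical clustering of rows."""
    df = matrix.df if isinstance(matrix, ClusterMatrix) else matrix
    if len(df) < 2:
        raise ValueError("clustering needs at least 2 rows")
    Z = hierarchy.linkage(df.to_numpy(float), method="complete", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    labels = list(df.index)
    return LinkageResult(Z, labels, [labels[i] for i in order])


def tissue_enrichment(mm_counts: pd.Series, background: pd.Series) -> dict:
    """Chi-squared homogeneity test of MM-line vs panel tissue composition.

    Both inputs are tissue-indexed count histograms over the same
    categories (missing categories are filled with 0). Returns the
    statistic, P, degrees of freedom, and the expected-count table; a
    warning is logged when any expected cell is below 5.
    """
    cats = sorted(set(mm_counts.index) | set(background.index))
    table = np.column_stack([
        mm_counts.reindex(cats, fill_value=0).to_numpy(float),
        background.reindex(cats, fill_value=0).to_numpy(float),
    ])
    table = table[table.sum(axis=1) > 0]
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        log.warning("tissue enrichment: %d expected cells < 5; chi-squared approximation "
                    "may be poor", int((expected < 5).sum()))
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof), "expected": expected}
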