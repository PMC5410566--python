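"""Tissue expression profiling: log transform, pattern calls, clustering.

The expression matrix is genes x tissues of non-negative RPKM values
(treated as a generic abundance). Pattern calls follow three archetypes —
barely expressed anywhere, constitutively expressed in every tissue, or
expressed in only a few tissues — with explicit, configurable thresholds,
since the archetypes themselves do not pin numbers down. Gene ordering for
heat maps comes from average-linkage hierarchical clustering on Euclidean
distances; rows are pre-sorted by gene name so the tree is invariant to
input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class PatternThresholds:
    expr_min: float = 1.0      # RPKM at or above which a tissue counts as expressed
    specific_max: int = 2      # at most this many tissues for "tissue_specific"


@dataclass(frozen=True)
class PatternCall:
    gene: str
    pattern: str  # barely_expressed | constitutive | tissue_specific | other
    expressed_in: tuple[str, ...]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x tissues matrix from TSV (first column = gene names).

    Accepts both a plain header line and the package's '#'-prefixed header.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#"):
            cols = first[1:].split("\t")
            df = pd.read_csv(fh, sep="\t", header=None, names=cols, index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("negative abundance values")
    return df


def log_transform(m: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Cell-wise log2(value + pseudocount); monotone, rank-preserving."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(m + pseudocount)


def classify_pattern(
    m: pd.DataFrame, thresholds: PatternThresholds = PatternThresholds()
) -> list[PatternCall]:
    """One pattern call per gene from the raw abundance matrix."""
    calls = []
    tissues = list(m.columns)
    for gene, row in m.iterrows():
        expressed = tuple(t for t in tissues if row[t] >= thresholds.expr_min)
        if not expressed:
            pattern = "barely_expressed"
        elif len(expressed) == len(tissues):
            pattern = "constitutive"
        elif len(expressed) <= thresholds.specific_max:
            pattern = "tissue_specific"
        else:
            pattern = "other"
        calls.append(PatternCall(gene=gene, pattern=pattern, expressed_in=expressed))
    return calls


def cluster_genes(m_log: pd.DataFrame):
    """Average-linkage clustering of gene rows on Euclidean distance.

    Rows are sorted by gene name before linkage so the merge sequence is a
    deterministic function of the data, not of input order. Returns
    (linkage matrix, leaf-order gene names, Newick string). A single gene
    yields a trivial one-leaf tree.
    """
    if len(m_log) == 0:
        raise ValueError("empty matrix")
    m_sorted = m_log.sort_index()
    names = list(m_sorted.index)
    if len(names) == 1:
        return None, names, f"{names[0]};"
    Z = hierarchy.linkage(pdist(m_sorted.values, metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(Z)
    leaf_names = [names[i] for i in leaves]
    tree = hierarchy.to_tree(Z)

    def newick(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        return (
            f"({newick(left)}:{node.dist - left.dist:.6g},"
            f"{newick(right)}:{node.dist - right.dist:.6g})"
        )

    return Z, leaf_names, newick(tree) + ";"


def render_heatmap(
    m_log: pd.DataFrame,
    leaf_order: Sequence[str],
    path: str | Path,
) -> None:
    """Render the clustered matrix as a heat map (SVG or PNG by extension).

    Purely presentational; output is deterministic for identical inputs
    (SVG hash salt pinned, no date metadata).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if m_log.empty:
        raise ValueError("empty matrix")
    data = m_log.loc[list(leaf_order)]
    with plt.rc_context({"svg.hashsalt": "dnajsurvey"}):
        fig, ax = plt.subplots(
            figsize=(max(4, 0.4 * data.shape[1]), max(3, 0.25 * data.shape[0]))
        )
        im = ax.imshow(data.values, aspect="auto", cmap="RdYlGn_r")
        ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(data.shape[0]), data.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="log2 abundance")
        fig.tight_layout()
        metadata = {"Date": None} if str(path).endswith(".svg") else None
        fig.savefig(path, metadata=metadata)
        plt.close(fig)
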