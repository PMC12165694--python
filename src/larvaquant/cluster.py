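"""Phenotype-matrix embedding, clustering, and connectivity correlation.

The phenotype matrix holds one row per genotype and seven columns of percent
change from control: four co-activation metrics (peak %CT, cumulative %CT,
average % area change, CT duration) and three silencing metrics (cumulative
%CT, average % area change, CT duration). Columns are z-scored by default
(the matrix mixes seconds and percentages), then embedded with t-SNE and cut
into k groups by Euclidean/complete agglomerative clustering. A separate
analysis relates each neuron's percent synaptic input from the CIII cold
nociceptors (from an EM-derived adjacency table) to the cold-evoked %CT that
remains when the neuron is silenced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.manifold import TSNE

__all__ = [
    "PercentChange",
    "percent_change_from_control",
    "ClusterResult",
    "embed_tsne",
    "cluster_hierarchical",
    "connectivity_behavior_correlation",
]


class PercentChange(NamedTuple):
    value: float
    absolute: bool  # True when the control was 0 and the difference is in points


def percent_change_from_control(metric: float, control: float) -> PercentChange:
    """100 * (metric - control) / |control|.

    When the control value is 0 (e.g. baseline %CT of a non-responding
    control) the relative change is undefined; the absolute difference in
    percentage points is returned instead, flagged via ``absolute=True``.
    """
    if control == 0:
        return PercentChange(float(metric), metric != 0)
    return PercentChange(100.0 * (metric - control) / abs(control), False)


def _standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (matrix - matrix.mean(axis=0)) / sd


@dataclass
class ClusterResult:
    labels: pd.Series              # cluster id in 1..k per genotype
    k: int
    linkage_method: str
    metric: str
    linkage_matrix: np.ndarray
    summary: pd.DataFrame          # per-cluster mean percent change per column

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with genotype names as leaves."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        names = list(self.labels.index)

        def rec(node) -> str:
            if node.is_leaf():
                return f"'{names[node.id]}'"  # quoted: underscores stay literal
            return (f"({rec(node.left)}:{node.dist - node.left.dist:.6g},"
                    f"{rec(node.right)}:{node.dist - node.right.dist:.6g})")

        return rec(tree) + ";"


def embed_tsne(
    matrix: pd.DataFrame,
    perplexity: float = 5.0,
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Deterministic 2-D t-SNE of the (z-scored) phenotype matrix."""
    if len(matrix) < 4:
        raise ValueError("t-SNE needs at least 4 genotypes")
    if perplexity >= (len(matrix) - 1) / 3:
        raise ValueError("perplexity must be below (n_rows - 1) / 3")
    x = _standardize(matrix) if standardize else matrix
    emb = TSNE(n_components=2, perplexity=perplexity, init="pca",
               random_state=seed).fit_transform(x.to_numpy(float))
    return pd.DataFrame(emb, index=matrix.index, columns=["tsne1", "tsne2"])


def cluster_hierarchical(
    matrix: pd.DataFrame,
    k: int = 5,
    linkage: str = "complete",
    metric: str = "euclidean",
    standardize: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of genotypes, tree cut at k clusters.

    Euclidean distance with complete linkage on z-scored columns by default.
    Merge-height ties are resolved by scipy's deterministic pair ordering,
    i.e. lexicographic in row order. Cluster ids are renumbered 1..k in
    order of first appearance down the genotype list. The summary table
    gives each cluster's mean value per matrix column (the per-cluster
    percent-change readout).
    """
    if k > len(matrix):
        raise ValueError("k cannot exceed the number of genotypes")
    x = _standardize(matrix) if standardize else matrix
    z = hierarchy.linkage(x.to_numpy(float), method=linkage, metric=metric)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # renumber in order of first appearance for reproducible labels
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    ser = pd.Series(labels, index=matrix.index, name="cluster")
    summary = matrix.groupby(ser).mean()
    summary.index.name = "cluster"
    return ClusterResult(labels=ser, k=int(ser.max()), linkage_method=linkage,
                         metric=metric, linkage_matrix=z, summary=summary)


@dataclass
class ConnectivityCorrelation:
    scatter: pd.DataFrame      # genotype, pct_input, pct_ct
    rho: float
    p_value: float
    excluded: list[str]


def connectivity_behavior_correlation(
    connectivity: pd.DataFrame,
    silencing_ct: Mapping[str, float],
    presynaptic: str = "CIII",
    method: str = "spearman",
) -> ConnectivityCorrelation:
    """Percent synaptic input from CIII vs cold-evoked %CT under silencing.

    ``connectivity`` is an edge list with columns ``pre_neuron``,
    ``post_neuron``, ``synapse_count``. A neuron's percent input is 100 x
    (synapses it receives from ``presynaptic``) / (its total input synapse
    count). Neurons without a matching silencing %CT entry — and vice
    versa — are excluded and listed. The association is reported as a
    Spearman rank correlation by default; ``method="pearson"`` is available.
    """
    need = {"pre_neuron", "post_neuron", "synapse_count"}
    if not need.issubset(connectivity.columns):
        raise ValueError(f"connectivity table must have columns {sorted(need)}")
    total_in = connectivity.groupby("post_neuron")["synapse_count"].sum()
    from_pre = (connectivity[connectivity["pre_neuron"] == presynaptic]
                .groupby("post_neuron")["synapse_count"].sum())
    pct_input = 100.0 * from_pre.reindex(total_in.index, fill_value=0) / total_in

    matched = sorted(set(pct_input.index) & set(silencing_ct))
    excluded = sorted((set(pct_input.index) | set(silencing_ct)) - set(matched))
    if len(matched) < 3:
        raise ValueError("need at least 3 matched neurons for a correlation")
    scatter = pd.DataFrame({
        "genotype": matched,
        "pct_input": [float(pct_input[g]) for g in matched],
        "pct_ct": [float(silencing_ct[g]) for g in matched],
    })
    if method == "spearman":
        rho, p = stats.spearmanr(scatter["pct_input"], scatter["pct_ct"])
    elif method == "pearson":
        rho, p = stats.pearsonr(scatter["pct_input"], scatter["pct_ct"])
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return ConnectivityCorrelation(scatter=scatter, rho=float(rho),
                                   p_value=float(p), excluded=excluded)
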