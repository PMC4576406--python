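"""Lineage-priming structure within the stem-cell compartment.

Cell-cycle signal dominates overall heterogeneity, so lineage structure is
resolved on a hematopoietic gene compilation from which cycle-annotated
genes have been removed.  Cells are embedded by PCA on that filtered list,
partitioned into subgroups H1..Hk (H1 anchored to the most quiescent /
self-renewal-like corner by a deterministic relabelling), and candidate
regulators are clustered by Spearman co-expression with complete linkage,
which exposes mutually exclusive programs (e.g. Gfi1 vs Gfi1b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .cellcycle import Embedding, _zscore_log, pca_embed
from .data import DataError

#: transcription factors named across the analysis; overridable per call
DEFAULT_REGULATORS = (
    "Bcl11a", "Egr1", "Fos", "Mecom", "Meis1", "Hlf", "Nr4a1", "Hes1",
    "Tcf7l2", "Id1", "Id3", "Gfi1", "Gfi1b", "Cebpa", "Gata1", "Klf1",
)

#: markers anchoring the quiescent / self-renewing subgroup (H1)
QUIESCENCE_ANCHORS = ("Cdkn1c", "Txnip", "Hlf", "Mecom")


def lineage_embed(
    norm: pd.DataFrame,
    hematopoietic_genes,
    cycle_genes,
    n_components: int = 2,
) -> Embedding:
    """PCA on hematopoietic genes minus cycle-annotated genes."""
    cyc = set(cycle_genes)
    filtered = [g for g in dict.fromkeys(hematopoietic_genes) if g not in cyc]
    present = [g for g in filtered if g in norm.index]
    if len(present) < 2:
        raise DataError(
            "hematopoietic gene list minus cycle genes leaves fewer than 2 "
            "genes in the matrix"
        )
    return pca_embed(norm, filtered, n_components=n_components, anchor_genes=None)


@dataclass
class SubgroupAssignment:
    """Per-cell subgroup with embedding scores, group and inherited stage."""

    table: pd.DataFrame  # index cell_id: subgroup, PC*, group, stage

    def composition(self, by: str = "group") -> pd.DataFrame:
        return (
            self.table.groupby("subgroup", observed=True)[by]
            .value_counts()
            .unstack(fill_value=0)
        )


def subgroup_cells(
    emb: Embedding,
    norm: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    anchor_panel=QUIESCENCE_ANCHORS,
    groups: pd.Series | None = None,
    stages: pd.Series | None = None,
    n_starts: int = 25,
) -> SubgroupAssignment:
    """Seeded k-means into H1..Hk on the lineage embedding.

    Subgroups are relabelled deterministically by descending mean z-scored
    expression of the quiescence anchor panel, so H1 is the most
    quiescent/self-renewal-like subgroup regardless of k-means label order.
    """
    X = emb.scores.to_numpy()
    n = X.shape[0]
    if k > n:
        raise DataError(f"k={k} exceeds number of cells ({n})")
    if np.allclose(X.var(axis=0), 0):
        warnings.warn("all cells identical in embedding; clusters are degenerate")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    raw = km.fit_predict(X)
    anchors = [g for g in anchor_panel if g in norm.index]
    if anchors:
        z = _zscore_log(norm[emb.scores.index], anchors)
        cell_anchor = z.mean(axis=0).to_numpy()
        cluster_score = np.array(
            [cell_anchor[raw == c].mean() if (raw == c).any() else -np.inf for c in range(k)]
        )
    else:
        warnings.warn("no anchor-panel genes present; ordering subgroups by size")
        cluster_score = np.bincount(raw, minlength=k).astype(float)
    order = np.argsort(-cluster_score, kind="stable")
    remap = {old: f"H{i + 1}" for i, old in enumerate(order)}
    table = pd.DataFrame(
        {"subgroup": [remap[r] for r in raw]}, index=emb.scores.index
    )
    for c in emb.scores.columns:
        table[c] = emb.scores[c]
    table["group"] = groups.reindex(table.index) if groups is not None else "all"
    table["stage"] = stages.reindex(table.index) if stages is not None else pd.NA
    return SubgroupAssignment(table=table)


@dataclass
class CorrelationClusters:
    """Regulator co-expression: Spearman matrix, dendrogram, cluster cut."""

    correlation: pd.DataFrame
    memberships: pd.Series  # gene -> cluster id (1..n_clusters)
    linkage_matrix: np.ndarray
    within_mean: dict[int, float]
    between_mean: float

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)
        names = list(self.correlation.index)

        def rec(node):
            if node.is_leaf():
                return names[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def regulator_correlation_clusters(
    norm: pd.DataFrame,
    regulators,
    n_clusters: int = 2,
) -> CorrelationClusters:
    """Spearman correlation of regulators over cells, complete-linkage cut.

    Constant (zero-variance) regulators are dropped with a warning; fewer
    than 3 usable regulators is an error.  Reported alongside the cut are
    the mean within-cluster and between-cluster correlations.
    """
    present = [g for g in dict.fromkeys(regulators) if g in norm.index]
    dropped_absent = len(list(dict.fromkeys(regulators))) - len(present)
    if dropped_absent:
        warnings.warn(f"{dropped_absent} regulators absent from matrix; dropped")
    X = norm.loc[present].to_numpy(dtype=float)
    nonconst = X.std(axis=1) > 0
    if (~nonconst).any():
        const = [g for g, keep in zip(present, nonconst) if not keep]
        warnings.warn(f"constant regulators excluded: {const}")
    usable = [g for g, keep in zip(present, nonconst) if keep]
    if len(usable) < 3:
        raise DataError("fewer than 3 usable (non-constant) regulators")
    Xu = norm.loc[usable].to_numpy(dtype=float)
    rho, _ = stats.spearmanr(Xu, axis=1)
    rho = np.atleast_2d(rho)
    corr = pd.DataFrame(rho, index=usable, columns=usable)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="complete")
    member = fcluster(Z, t=n_clusters, criterion="maxclust")
    memberships = pd.Series(member, index=usable, name="cluster")
    within: dict[int, float] = {}
    off_diag = ~np.eye(len(usable), dtype=bool)
    for c in sorted(set(member)):
        mask = member == c
        block = rho[np.ix_(mask, mask)]
        off = off_diag[np.ix_(mask, mask)]
        within[c] = float(block[off].mean()) if off.any() else 1.0
    between_mask = member[:, None] != member[None, :]
    between = float(rho[between_mask].mean()) if between_mask.any() else float("nan")
    return CorrelationClusters(
        correlation=corr,
        memberships=memberships,
        linkage_matrix=Z,
        within_mean=within,
        between_mean=between,
    )
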