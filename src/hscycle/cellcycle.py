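"""Transcriptomic reconstruction of cell-cycle progression.

The workflow: PCA of log2(normalized count + 1) over a curated cell-cycle
gene list, k-means partition of the first two components into clusters
(C1..Ck), marker-panel scoring that labels each cluster with a cell-cycle
stage, and projection of a perturbed (e.g. knockout) population onto the
reference embedding with nearest-centroid stage inheritance.  Occupancy
shifts between groups are tested with Fisher's exact test and per-cell
transcriptional activity (total biological counts on the spike-in scale)
with rank-sum tests.

Stage semantics: quiescent/early cells express Cdkn1c (p57) and Txnip and
lack Uhrf1; late G1 turns on cyclin D/E with Cdk2; S phase is dominated by
Rrm2, the Mcm replication-licensing factors and cyclin A; G2/M by cyclin B,
Cdk1 and division genes such as Prc1, Plk1 and Mki67.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .data import DataError
from .normalize import SizeFactors

#: cycle order used for tie-breaking and occupancy binning
STAGE_ORDER = ("G0/early-G1", "late-G1", "S", "G2/M")
UNDETERMINED = "undetermined"

#: marker panels assembled from cyclin oscillation and quiescence literature;
#: "low" members contribute with negated z-score
STAGE_PANELS: dict[str, dict[str, list[str]]] = {
    "G0/early-G1": {"high": ["Cdkn1c", "Txnip"], "low": ["Uhrf1"]},
    "late-G1": {"high": ["Ccnd2", "Ccne2", "Cdk2"], "low": []},
    "S": {"high": ["Rrm2", "Mcm2", "Mcm5", "Mcm7", "Ccna2", "Uhrf1"], "low": []},
    "G2/M": {"high": ["Ccnb2", "Cdk1", "Ccnf", "Prc1", "Plk1", "Mki67"], "low": []},
}

#: genes anchoring the PCA sign convention (proliferation side positive)
S_G2M_ANCHORS = tuple(STAGE_PANELS["S"]["high"] + STAGE_PANELS["G2/M"]["high"])

PROLIFERATIVE_STAGES = ("S", "G2/M")
QUIESCENT_STAGES = ("G0/early-G1", "late-G1")


# ---------------------------------------------------------------------------
# Embedding


@dataclass
class Embedding:
    """A fitted PCA over a gene list, reusable for projecting new cells."""

    gene_ids: np.ndarray
    center: np.ndarray
    loadings: np.ndarray  # genes x n_components, orthonormal columns
    scores: pd.DataFrame  # training cells x components
    var_explained: np.ndarray
    anchor_genes: tuple[str, ...]
    log_data: pd.DataFrame | None = None  # centered training data (cells x genes)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, norm: pd.DataFrame, min_overlap: float = 0.8) -> pd.DataFrame:
        """Project new cells (genes x cells normalized matrix) onto the PCs.

        Requires at least ``min_overlap`` of the embedding's gene list to be
        present; missing genes are imputed at the reference center (zero
        contribution after centering).
        """
        present = [g for g in self.gene_ids if g in norm.index]
        frac = len(present) / len(self.gene_ids)
        if frac < min_overlap:
            raise DataError(
                f"only {frac:.0%} of the embedding gene list present "
                f"(minimum {min_overlap:.0%})"
            )
        X = np.tile(self.center, (norm.shape[1], 1))  # cells x genes, at center
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in present]
        X[:, cols] = np.log2(norm.loc[present].to_numpy().T + 1.0)
        Xc = X - self.center
        return pd.DataFrame(
            Xc @ self.loadings,
            index=norm.columns,
            columns=self.scores.columns,
        )


def pca_embed(
    norm: pd.DataFrame,
    genes: list[str] | np.ndarray,
    n_components: int = 2,
    anchor_genes: tuple[str, ...] | None = S_G2M_ANCHORS,
) -> Embedding:
    """PCA of log2(normalized count + 1) restricted to a gene list.

    Genes are centered but not scaled to unit variance.  Each component's
    sign is fixed deterministically: the summed loading of the anchor panel
    is made non-negative (falling back to a positive largest-magnitude
    loading when no anchor is usable).
    """
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in norm.index]
    missing = len(genes) - len(present)
    if missing:
        warnings.warn(f"{missing} listed genes absent from matrix; dropped")
    if len(present) < 2:
        raise DataError("fewer than 2 usable genes for PCA")
    if norm.shape[1] < 2:
        raise DataError("PCA requires at least 2 cells")
    X = np.log2(norm.loc[present].to_numpy().T + 1.0)  # cells x genes
    center = X.mean(axis=0)
    Xc = X - center
    n_components = min(n_components, min(Xc.shape) - 0 if min(Xc.shape) else 1)
    n_components = min(n_components, Xc.shape[0] - 1, Xc.shape[1])
    n_components = max(n_components, 1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:n_components].T.copy()
    total_var = np.sum(Xc**2)
    var_explained = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(
        n_components
    )
    anchor_idx = (
        [present.index(g) for g in anchor_genes if g in present]
        if anchor_genes
        else []
    )
    for j in range(n_components):
        a = loadings[anchor_idx, j].sum() if anchor_idx else 0.0
        if a == 0.0:
            a = loadings[np.argmax(np.abs(loadings[:, j])), j]
        if a < 0:
            loadings[:, j] *= -1
    scores = pd.DataFrame(
        Xc @ loadings,
        index=norm.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return Embedding(
        gene_ids=np.asarray(present, dtype=object),
        center=center,
        loadings=loadings,
        scores=scores,
        var_explained=var_explained,
        anchor_genes=tuple(anchor_genes) if anchor_genes else (),
        log_data=pd.DataFrame(Xc, index=norm.columns, columns=present),
    )


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class ClusterResult:
    """k-means partition of embedding scores with a hierarchical cross-check."""

    labels: pd.Series  # cell id -> "C1".."Ck"
    centroids: pd.DataFrame  # cluster -> component coordinates
    inertia: float
    ari_hierarchical: float | None = None

    def cluster_ids(self) -> list[str]:
        return list(self.centroids.index)


def cluster_embedding(
    emb: Embedding, k: int = 5, seed: int = 0, n_starts: int = 25
) -> ClusterResult:
    """Seeded k-means (multi-start, best inertia) on the retained components.

    Clusters are relabelled C1..Ck by decreasing size (ties by PC1 centroid)
    so labels are deterministic.  As a cross-check, complete-linkage
    hierarchical clustering on (1 - Pearson correlation) between cells is cut
    at k and the adjusted Rand index with the k-means partition is reported
    (not enforced).
    """
    X = emb.scores.to_numpy()
    n = X.shape[0]
    if k > n:
        raise DataError(f"k={k} exceeds number of cells ({n})")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], km.cluster_centers_[c, 0]))
    remap = {old: f"C{i + 1}" for i, old in enumerate(order)}
    labels = pd.Series([remap[r] for r in raw], index=emb.scores.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order],
        index=[f"C{i + 1}" for i in range(k)],
        columns=emb.scores.columns,
    )
    ari = None
    if emb.log_data is not None and n > k >= 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(emb.log_data.to_numpy())
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        dist = 1.0 - corr
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        hier = fcluster(linkage(squareform(dist, checks=False), "complete"), k, "maxclust")
        ari = float(adjusted_rand_score(raw, hier))
    return ClusterResult(labels=labels, centroids=centroids, inertia=float(km.inertia_), ari_hierarchical=ari)


# ---------------------------------------------------------------------------
# Stage assignment


@dataclass
class StageModel:
    """Cluster centroids plus the cluster -> stage map and the marker panels."""

    centroids: pd.DataFrame
    cluster_stage: dict[str, str]
    panels: dict[str, dict[str, list[str]]]
    min_cells_for_label: int = 5
    panel_scores: pd.DataFrame | None = None


@dataclass
class StageAssignment:
    """Per-cell cluster/stage labels with embedding scores and group."""

    table: pd.DataFrame  # index cell_id: cluster, stage, PC*, group

    def occupancy(self) -> pd.DataFrame:
        """Per-group fraction of cells in each stage label (rows sum to 1)."""
        t = self.table
        occ = (
            t.groupby("group", observed=True)["stage"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        cols = [s for s in (*STAGE_ORDER, UNDETERMINED) if s in occ.columns]
        return occ[cols]

    def stage_fraction(self, stages) -> pd.Series:
        t = self.table
        return t.groupby("group", observed=True)["stage"].apply(
            lambda s: float(np.mean(s.isin(list(stages))))
        )


def _zscore_log(norm: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    X = np.log2(norm.loc[genes].to_numpy() + 1.0)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((X - mu) / sd, index=genes, columns=norm.columns)


def assign_cluster_stages(
    clusters: ClusterResult,
    norm: pd.DataFrame,
    panels: dict[str, dict[str, list[str]]] | None = None,
    min_cells_for_label: int = 5,
    groups: pd.Series | None = None,
) -> tuple[StageModel, StageAssignment]:
    """Label each cluster with the stage whose marker panel it scores highest on.

    A cluster's score for a stage is the mean (over panel genes) of the
    cluster-mean z-score of log expression, with "low" markers negated.
    Clusters smaller than ``min_cells_for_label`` are labelled undetermined;
    ties break toward the earlier stage in cycle order with a warning.
    """
    panels = panels or STAGE_PANELS
    labels = clusters.labels
    counts = labels.value_counts()
    if (counts == 0).any() or set(clusters.cluster_ids()) - set(counts.index):
        raise DataError("empty cluster")
    usable_panels: dict[str, dict[str, list[str]]] = {}
    needed: list[str] = []
    for stage, panel in panels.items():
        high = [g for g in panel.get("high", []) if g in norm.index]
        low = [g for g in panel.get("low", []) if g in norm.index]
        dropped = (len(panel.get("high", [])) - len(high)) + (
            len(panel.get("low", [])) - len(low)
        )
        if dropped:
            warnings.warn(f"stage panel {stage!r}: {dropped} marker genes absent")
        if not high and not low:
            raise DataError(f"stage panel {stage!r} lost all genes")
        usable_panels[stage] = {"high": high, "low": low}
        needed.extend(high + low)
    z = _zscore_log(norm, list(dict.fromkeys(needed)))
    stage_names = [s for s in STAGE_ORDER if s in usable_panels] + [
        s for s in usable_panels if s not in STAGE_ORDER
    ]
    rows = {}
    for cid in clusters.cluster_ids():
        cells = labels.index[labels == cid]
        zc = z[cells].mean(axis=1)
        rows[cid] = {
            stage: float(
                np.mean(
                    [zc[g] for g in usable_panels[stage]["high"]]
                    + [-zc[g] for g in usable_panels[stage]["low"]]
                )
            )
            for stage in stage_names
        }
    panel_scores = pd.DataFrame(rows).T[stage_names]
    cluster_stage: dict[str, str] = {}
    for cid in clusters.cluster_ids():
        if counts[cid] < min_cells_for_label:
            cluster_stage[cid] = UNDETERMINED
            continue
        s = panel_scores.loc[cid]
        best = s.max()
        winners = [st for st in stage_names if s[st] == best]
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cid}: stage tie {winners}; choosing earliest in cycle order"
            )
        cluster_stage[cid] = winners[0]
    table = pd.DataFrame(
        {
            "cluster": labels,
            "stage": labels.map(cluster_stage),
        }
    )
    table["group"] = (
        groups.reindex(table.index) if groups is not None else "reference"
    )
    model = StageModel(
        centroids=clusters.centroids,
        cluster_stage=cluster_stage,
        panels=usable_panels,
        min_cells_for_label=min_cells_for_label,
        panel_scores=panel_scores,
    )
    return model, StageAssignment(table=table)


def project_and_classify(
    emb: Embedding,
    model: StageModel,
    norm_new: pd.DataFrame,
    groups: pd.Series | None = None,
    min_overlap: float = 0.8,
) -> StageAssignment:
    """Project new cells on a reference embedding and inherit cluster stages.

    Cells are centered with the reference gene means, projected on the
    reference loadings and assigned to the nearest cluster centroid
    (Euclidean distance in the retained components).
    """
    scores = emb.transform(norm_new, min_overlap=min_overlap)
    C = model.centroids.to_numpy()
    d2 = ((scores.to_numpy()[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    cluster_ids = list(model.centroids.index)
    cluster = pd.Series([cluster_ids[i] for i in nearest], index=scores.index)
    table = pd.DataFrame(
        {
            "cluster": cluster,
            "stage": cluster.map(model.cluster_stage),
        }
    )
    for c in scores.columns:
        table[c] = scores[c]
    table["group"] = groups.reindex(table.index) if groups is not None else "projected"
    return StageAssignment(table=table)


def attach_scores(assignment: StageAssignment, emb: Embedding) -> StageAssignment:
    """Join training-cell embedding scores onto an assignment table."""
    t = assignment.table.copy()
    for c in emb.scores.columns:
        t[c] = emb.scores[c].reindex(t.index)
    return StageAssignment(table=t)


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass
class OccupancyComparison:
    fraction_a: float
    fraction_b: float
    difference: float
    odds_ratio: float
    p_value: float
    table: np.ndarray  # 2x2: rows (a, b), cols (in-subset, out)


def compare_occupancy(
    a: StageAssignment,
    b: StageAssignment,
    stages=PROLIFERATIVE_STAGES,
) -> OccupancyComparison:
    """Two-sided Fisher exact test on membership of a stage subset in a vs b."""
    in_a = int(a.table["stage"].isin(list(stages)).sum())
    in_b = int(b.table["stage"].isin(list(stages)).sum())
    n_a, n_b = len(a.table), len(b.table)
    if n_a == 0 or n_b == 0:
        raise DataError("empty group in occupancy comparison")
    table = np.array([[in_a, n_a - in_a], [in_b, n_b - in_b]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return OccupancyComparison(
        fraction_a=in_a / n_a,
        fraction_b=in_b / n_b,
        difference=in_a / n_a - in_b / n_b,
        odds_ratio=float(odds),
        p_value=float(p),
        table=table,
    )


def transcriptional_activity(
    m,
    sf: SizeFactors,
    assignment: StageAssignment,
    min_cells: int = 3,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-cell total biological counts on the spike-in scale, with rank-sum tests.

    activity_j = (sum of non-spike-in counts of cell j) / s_ercc_j.  Cells are
    binned into quiescent (G0/early-G1, late-G1) vs proliferative (S, G2/M)
    stages; two-sided Wilcoxon rank-sum comparisons are run between bins
    within each group and between groups within each bin.  Comparisons with
    fewer than ``min_cells`` cells on either side are skipped with a warning.
    """
    ercc = sf.ercc_series()
    totals = pd.Series(
        m.counts[~m.is_spikein].sum(axis=0), index=m.cell_ids, dtype=float
    )
    cells = assignment.table.index
    activity = (totals.reindex(cells) / ercc.reindex(cells)).rename("activity")
    t = assignment.table.assign(activity=activity)
    t["bin"] = np.where(
        t["stage"].isin(list(PROLIFERATIVE_STAGES)),
        "S/G2/M",
        np.where(t["stage"].isin(list(QUIESCENT_STAGES)), "G0/G1", UNDETERMINED),
    )
    rows = []

    def _compare(label, x, y):
        if len(x) < min_cells or len(y) < min_cells:
            warnings.warn(f"activity comparison {label}: fewer than {min_cells} cells; skipped")
            return
        stat, p = stats.ranksums(x, y)
        rows.append(
            {
                "comparison": label,
                "n_1": len(x),
                "n_2": len(y),
                "median_1": float(np.median(x)),
                "median_2": float(np.median(y)),
                "statistic": float(stat),
                "p_value": float(p),
            }
        )

    groups = list(dict.fromkeys(t["group"]))
    for g in groups:
        sub = t[t["group"] == g]
        _compare(
            f"{g}: S/G2/M vs G0/G1",
            sub.loc[sub["bin"] == "S/G2/M", "activity"].dropna(),
            sub.loc[sub["bin"] == "G0/G1", "activity"].dropna(),
        )
    for bin_label in ("G0/G1", "S/G2/M"):
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i], groups[j]
                _compare(
                    f"{bin_label}: {gi} vs {gj}",
                    t.loc[(t["group"] == gi) & (t["bin"] == bin_label), "activity"].dropna(),
                    t.loc[(t["group"] == gj) & (t["bin"] == bin_label), "activity"].dropna(),
                )
    return activity, pd.DataFrame(rows)
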