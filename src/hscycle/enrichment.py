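"""Gene-set enrichment: weighted Kolmogorov-Smirnov GSEA and hypergeometric ORA.

GSEA ranks genes by the signal-to-noise statistic between two phenotype
classes, walks the ranked list accumulating |metric|^p weight at gene-set
hits and a constant penalty at misses, and reports the signed maximum
deviation of that running sum (the enrichment score, ES).  Significance
comes from phenotype-label permutations: the nominal p compares |ES| with
same-sign permuted scores (add-one smoothed), the normalized score NES
divides ES by the mean same-sign permuted |ES|, and the FDR q uses the
pooled-NES procedure across all sets and permutations.  Over-representation
analysis (ORA) is the exact hypergeometric upper tail with
Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import DataError, GeneSetCollection

MIN_CELLS_PER_CLASS = 3
MIN_PERMUTATIONS = 100


# ---------------------------------------------------------------------------
# Ranking


@dataclass
class RankedList:
    """Genes in strictly decreasing metric order (ties broken by gene id)."""

    genes: np.ndarray
    metric: np.ndarray
    metric_name: str = "signal-to-noise"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise DataError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


def _s2n_matrix(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Signal-to-noise per row of genes x cells data for class A (mask) vs B."""
    A, B = X[:, mask_a], X[:, ~mask_a]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    sd_a, sd_b = A.std(axis=1, ddof=1), B.std(axis=1, ddof=1)
    # the conventional GSEA floor: sd >= 0.2 * |mean|, absolute 0.2 at mean 0
    floor_a = np.where(mean_a != 0, 0.2 * np.abs(mean_a), 0.2)
    floor_b = np.where(mean_b != 0, 0.2 * np.abs(mean_b), 0.2)
    sd_a = np.maximum(sd_a, floor_a)
    sd_b = np.maximum(sd_b, floor_b)
    return (mean_a - mean_b) / (sd_a + sd_b)


def _rank_order(genes: np.ndarray, metric: np.ndarray) -> np.ndarray:
    # descending metric, ascending gene id on ties
    return np.lexsort((genes.astype(str), -metric))


def rank_genes_s2n(
    norm: pd.DataFrame, labels: pd.Series, classes: tuple[str, str] | None = None
) -> RankedList:
    """Rank genes by signal-to-noise of the first-listed class vs the second."""
    labels = labels.reindex(norm.columns)
    if labels.isna().any():
        raise DataError("labels missing for some cells")
    uniq = list(dict.fromkeys(labels))
    if classes is None:
        if len(uniq) != 2:
            raise DataError(f"need exactly two classes, found {uniq}")
        classes = (uniq[0], uniq[1])
    mask_a = (labels == classes[0]).to_numpy()
    mask_b = (labels == classes[1]).to_numpy()
    if not (mask_a | mask_b).all():
        raise DataError("labels contain values outside the two classes")
    if mask_a.sum() < MIN_CELLS_PER_CLASS or mask_b.sum() < MIN_CELLS_PER_CLASS:
        raise DataError(f"each class needs >= {MIN_CELLS_PER_CLASS} cells")
    metric = _s2n_matrix(norm.to_numpy(dtype=float), mask_a)
    genes = norm.index.to_numpy(dtype=object)
    order = _rank_order(genes, metric)
    return RankedList(genes=genes[order], metric=metric[order])


# ---------------------------------------------------------------------------
# Enrichment score


def _es_from_hits(metric: np.ndarray, hits: np.ndarray, weight_p: float):
    """Running-sum ES for one ordered metric vector and boolean hit vector."""
    N = len(metric)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise DataError("gene set does not intersect the ranked list")
    if n_hits == N:
        raise DataError("gene set covers the entire ranked list")
    w = np.abs(metric) ** weight_p
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit metrics zero: fall back to unweighted steps
        hit_w = hits.astype(float)
        total = hit_w.sum()
    inc = hit_w / total
    inc -= (~hits) / (N - n_hits)
    running = np.cumsum(inc)
    i = int(np.argmax(np.abs(running)))
    es = float(running[i])
    return es, running, i


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, running-sum profile and leading-edge genes for one set."""
    members = set(gene_set)
    hits = np.array([g in members for g in ranked.genes])
    es, running, i = _es_from_hits(ranked.metric, hits, weight_p)
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[: i + 1], hits[: i + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[i:], hits[i:]) if h]
    return es, running, leading


def _es_batch(metric_sorted: np.ndarray, hit_matrix: np.ndarray, weight_p: float) -> np.ndarray:
    """ES for many sets at once; hit_matrix is sets x genes in rank order."""
    N = metric_sorted.shape[0]
    w = np.abs(metric_sorted) ** weight_p
    hw = hit_matrix * w[None, :]
    totals = hw.sum(axis=1)
    zero = totals == 0
    if zero.any():
        hw[zero] = hit_matrix[zero].astype(float)
        totals = hw.sum(axis=1)
    n_hits = hit_matrix.sum(axis=1)
    inc = hw / totals[:, None] - (~hit_matrix) / (N - n_hits)[:, None]
    running = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


# ---------------------------------------------------------------------------
# GSEA with phenotype permutation


def gsea(
    norm: pd.DataFrame,
    labels: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    classes: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Full GSEA: per-set ES, NES, nominal p (add-one smoothed) and FDR q.

    Positive NES means enrichment toward the first-listed class.  The FDR is
    the pooled-NES estimate: the same-sign tail fraction of all permuted NES
    values divided by the same-sign tail fraction of observed NES values,
    capped at 1.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise DataError(f"n_perm must be >= {MIN_PERMUTATIONS}")
    ranked = rank_genes_s2n(norm, labels, classes)  # validates classes/sizes
    genes = norm.index.to_numpy(dtype=object)
    X = norm.to_numpy(dtype=float)
    labels = labels.reindex(norm.columns)
    uniq = list(dict.fromkeys(labels)) if classes is None else list(classes)
    mask_a = (labels == uniq[0]).to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    set_names = sets.names()
    member_matrix = np.zeros((len(set_names), len(genes)), dtype=bool)
    for si, name in enumerate(set_names):
        idx = [gene_pos[g] for g in sets[name] if g in gene_pos]
        if not idx:
            raise DataError(f"gene set {name!r} does not intersect the data")
        if len(idx) == len(genes):
            raise DataError(f"gene set {name!r} covers every gene")
        member_matrix[si, idx] = True

    def ranked_hits(mask: np.ndarray):
        metric = _s2n_matrix(X, mask)
        order = _rank_order(genes, metric)
        return metric[order], member_matrix[:, order]

    metric_obs, hits_obs = ranked_hits(mask_a)
    es_obs = _es_batch(metric_obs, hits_obs, weight_p)

    rng = np.random.default_rng(seed)
    n_cells = X.shape[1]
    es_perm = np.empty((n_perm, len(set_names)))
    for b in range(n_perm):
        perm = rng.permutation(n_cells)
        es_perm[b] = _es_batch(*ranked_hits(mask_a[perm]), weight_p)

    pos_mean = np.where(es_perm > 0, es_perm, np.nan)
    neg_mean = np.where(es_perm < 0, -es_perm, np.nan)
    with np.errstate(invalid="ignore"):
        mean_pos = np.nanmean(pos_mean, axis=0)
        mean_neg = np.nanmean(neg_mean, axis=0)
    nes = np.empty_like(es_obs)
    p_nom = np.empty_like(es_obs)
    for si, es in enumerate(es_obs):
        if es >= 0:
            same = es_perm[:, si][es_perm[:, si] > 0]
            denom = mean_pos[si]
        else:
            same = -es_perm[:, si][es_perm[:, si] < 0]
            denom = mean_neg[si]
        nes[si] = es / denom if np.isfinite(denom) and denom > 0 else np.nan
        p_nom[si] = (1.0 + np.sum(same >= abs(es))) / (1.0 + len(same))

    # pooled-NES FDR
    with np.errstate(invalid="ignore"):
        nes_perm = np.where(
            es_perm >= 0, es_perm / mean_pos[None, :], es_perm / mean_neg[None, :]
        )
    pooled = nes_perm[np.isfinite(nes_perm)]
    q = np.empty_like(nes)
    for si, val in enumerate(nes):
        if not np.isfinite(val):
            q[si] = np.nan
            continue
        if val >= 0:
            num_tail = np.mean(pooled >= val) if (pooled >= 0).any() else 0.0
            num_all = max(np.mean(pooled >= 0), 1e-12)
            den_tail = np.mean(nes[np.isfinite(nes)] >= val)
            den_all = max(np.mean(nes[np.isfinite(nes)] >= 0), 1e-12)
        else:
            num_tail = np.mean(pooled <= val)
            num_all = max(np.mean(pooled < 0), 1e-12)
            den_tail = np.mean(nes[np.isfinite(nes)] <= val)
            den_all = max(np.mean(nes[np.isfinite(nes)] < 0), 1e-12)
        ratio_num = num_tail / num_all
        ratio_den = max(den_tail / den_all, 1e-12)
        q[si] = min(1.0, ratio_num / ratio_den)

    leading = []
    for si, name in enumerate(set_names):
        _, _, le = enrichment_score(ranked, sets[name], weight_p)
        leading.append(",".join(le))
    return pd.DataFrame(
        {
            "set": set_names,
            "size": member_matrix.sum(axis=1),
            "es": es_obs,
            "nes": nes,
            "p_value": p_nom,
            "fdr_q": q,
            "n_permutations": n_perm,
            "leading_edge": leading,
        }
    ).set_index("set")


# ---------------------------------------------------------------------------
# Over-representation analysis


def ora_hypergeometric(
    selected, universe, sets: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each set's overlap with a selection.

    ``selected`` must be a subset of ``universe``; every set is intersected
    with the universe first.  p-values are BH-adjusted across sets.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    selected = list(dict.fromkeys(selected))
    if not set(selected) <= uni:
        raise DataError("selected genes must be a subset of the universe")
    sel = set(selected)
    M, n = len(universe), len(selected)
    rows = []
    for name, members in sets.items():
        in_uni = [g for g in dict.fromkeys(members) if g in uni]
        K = len(in_uni)
        k = len(sel.intersection(in_uni))
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "selected_size": n,
                "universe_size": M,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
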