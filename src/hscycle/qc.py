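"""Cell-level quality control.

Filters follow the conventions of deep-coverage microfluidic single-cell
RNA-seq: cells with too few total counts in annotated (non-spike-in) genes,
too few detected genes, a high fraction of mitochondrially encoded counts,
residual reads in a genomic deletion region (applied only to the groups
under a deletion screen), or a bad capture flag are removed.  All
inequalities are strict: a cell fails on fewer than ``min_total_counts``
counts, fewer than ``min_genes_detected`` genes, or a mitochondrial
fraction greater than ``max_mito_fraction``.

The whole-transcriptome PCA outlier step is deterministic here: a cell is
flagged when its PC1 or PC2 score deviates from the per-component median by
more than ``k_mad`` times the (raw) median absolute deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellcycle import pca_embed
from .data import CellMetadata, CountMatrix, DataError

#: capture flags that disqualify a cell outright
BAD_CAPTURE_FLAGS = ("empty", "multiplet", "anomalous")

FILTER_COLUMNS = (
    "pass_total_counts",
    "pass_genes_detected",
    "pass_mito_fraction",
    "pass_deletion_screen",
    "pass_capture_flag",
)


@dataclass
class QCThresholds:
    min_total_counts: int = 500_000
    min_genes_detected: int = 3000
    max_mito_fraction: float = 0.10
    deletion_region_max: int = 0
    outlier_mad_k: float = 6.0

    def __post_init__(self) -> None:
        if self.min_total_counts < 0 or self.min_genes_detected < 0:
            raise DataError("count thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise DataError("max_mito_fraction must lie in [0, 1]")
        if self.deletion_region_max < 0:
            raise DataError("deletion_region_max must be >= 0")
        if self.outlier_mad_k < 0:
            raise DataError("outlier_mad_k must be >= 0")


@dataclass
class QCReport:
    """Per-cell QC metrics, filter outcomes and failure reasons."""

    table: pd.DataFrame

    def kept_ids(self) -> list[str]:
        if "keep" not in self.table.columns:
            raise DataError("filters not yet applied to this report")
        return list(self.table.index[self.table["keep"]])


def compute_qc_metrics(m: CountMatrix, meta: CellMetadata) -> QCReport:
    """Per-cell totals, detected genes and mitochondrial fraction.

    All metrics are computed over non-spike-in genes only; the mitochondrial
    fraction is mito counts / total non-spike-in counts (0 for an all-zero
    cell).  ``genes_detected`` counts genes with raw count > 0.
    """
    bio = ~m.is_spikein
    counts = m.counts[bio]
    total = counts.sum(axis=0)
    genes_detected = (counts > 0).sum(axis=0)
    if m.is_mito is not None:
        mito = m.counts[m.is_mito & bio].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_fraction = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    else:
        mito_fraction = np.full(m.n_cells, np.nan)
    md = meta.for_cells(m.cell_ids)
    table = pd.DataFrame(
        {
            "total_counts": total,
            "genes_detected": genes_detected,
            "mito_fraction": mito_fraction,
            "deletion_region_count": md["deletion_region_count"].to_numpy(),
            "capture_flag": md["capture_flag"].to_numpy(),
            "group": md["group"].to_numpy(),
        },
        index=pd.Index(m.cell_ids, name="cell_id"),
    )
    return QCReport(table=table)


def apply_qc_filters(
    report: QCReport,
    thr: QCThresholds,
    groups_with_deletion_screen: set[str] | frozenset[str] = frozenset(),
) -> list[str]:
    """Evaluate every filter, set the keep flag and return kept cell ids.

    The keep decision is the pure conjunction of the individual filters, so
    evaluation order is irrelevant.  The deletion-region screen applies only
    to cells whose group is listed in ``groups_with_deletion_screen``.
    """
    t = report.table
    if thr.max_mito_fraction < 1.0 and t["mito_fraction"].isna().all():
        raise DataError(
            "mitochondrial filter enabled but the matrix carries no mito flags"
        )
    t = t.copy()
    t["pass_total_counts"] = t["total_counts"] >= thr.min_total_counts
    t["pass_genes_detected"] = t["genes_detected"] >= thr.min_genes_detected
    t["pass_mito_fraction"] = ~(t["mito_fraction"] > thr.max_mito_fraction)
    screened = t["group"].isin(list(groups_with_deletion_screen))
    del_counts = pd.array(t["deletion_region_count"], dtype="Int64").fillna(0)
    over = np.asarray(del_counts.astype(int)) > thr.deletion_region_max
    t["pass_deletion_screen"] = ~(screened & over)
    t["pass_capture_flag"] = ~t["capture_flag"].isin(BAD_CAPTURE_FLAGS)
    t["keep"] = t[list(FILTER_COLUMNS)].all(axis=1)
    reasons = []
    for _, row in t.iterrows():
        failed = [c.removeprefix("pass_") for c in FILTER_COLUMNS if not row[c]]
        reasons.append(",".join(failed))
    t["failure_reasons"] = reasons
    report.table = t
    return list(t.index[t["keep"]])


def pca_outlier_screen(
    m: CountMatrix,
    kept: list[str] | None = None,
    k_mad: float = 6.0,
) -> list[str]:
    """Flag whole-transcriptome PCA outliers among kept cells.

    PCA is run on log2(count + 1) of the non-spike-in genes; a cell is
    flagged when its PC1 or PC2 score lies more than ``k_mad``
    normal-consistent MADs (1.4826 x raw MAD) from that component's median.
    """
    sub = m if kept is None else m.subset_cells(kept)
    if sub.n_cells < 5:
        raise DataError("PCA outlier screen requires at least 5 cells")
    bio = sub.biological()
    norm = bio.to_frame().astype(float)  # raw counts: screen precedes normalization
    emb = pca_embed(norm, list(bio.gene_ids), n_components=2, anchor_genes=None)
    scores = emb.scores.to_numpy()
    med = np.median(scores, axis=0)
    # normal-consistent MAD (the R mad() convention used by scater's isOutlier)
    mad = 1.4826 * np.median(np.abs(scores - med), axis=0)
    mad[mad == 0] = np.finfo(float).tiny
    flagged = np.any(np.abs(scores - med) > k_mad * mad, axis=1)
    return list(emb.scores.index[flagged])
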