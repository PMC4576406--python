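"""Core data types and I/O: count matrices, cell metadata, gene sets, result tables.

The canonical orientation everywhere in this package is genes as rows and
cells as columns.  Spike-in (ERCC) rows are recognised by an id prefix and
mitochondrial rows by a gene-annotation sidecar mapping gene ids to
chromosomes, since neither fact is encoded in a bare count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

DEFAULT_SPIKEIN_PREFIX = "ERCC-"
#: chromosome names recognised as the mitochondrial genome
MITO_CHROMOSOMES = frozenset({"MT", "chrM", "chrMT", "M", "mt"})

CAPTURE_FLAGS = ("single", "empty", "multiplet", "anomalous", "unknown")


class DataError(ValueError):
    """Raised for malformed inputs (duplicate ids, negative counts, ...)."""


# ---------------------------------------------------------------------------
# CountMatrix


@dataclass
class CountMatrix:
    """Gene x cell matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        Dense integer array, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique, ordered identifiers for rows and columns.
    is_spikein
        Boolean flag per gene marking external spike-in species.
    is_mito
        Boolean flag per gene marking mitochondrially encoded genes, or
        ``None`` when no chromosome annotation was available.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    is_spikein: np.ndarray
    is_mito: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.is_spikein = np.asarray(self.is_spikein, dtype=bool)
        if self.is_mito is not None:
            self.is_mito = np.asarray(self.is_mito, dtype=bool)
        if self.counts.ndim != 2:
            raise DataError("counts must be a 2-D genes x cells array")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise DataError("id lengths do not match counts shape")
        if n_genes == 0:
            raise DataError("no genes")
        if len(set(self.gene_ids)) != n_genes:
            raise DataError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise DataError("duplicate cell ids")
        if not np.all(np.isfinite(self.counts)):
            raise DataError("counts contain non-finite values")
        bad = np.argwhere((self.counts < 0) | (self.counts != np.floor(self.counts)))
        if bad.size:
            i, j = bad[0]
            raise DataError(
                f"invalid count {self.counts[i, j]!r} at gene "
                f"{self.gene_ids[i]!r}, cell {self.cell_ids[j]!r} "
                "(counts must be non-negative integers)"
            )
        self.counts = self.counts.astype(np.int64)
        if len(self.is_spikein) != n_genes:
            raise DataError("is_spikein length mismatch")
        if np.all(self.is_spikein):
            raise DataError("at least one non-spike-in gene required")
        if self.is_mito is not None:
            if len(self.is_mito) != n_genes:
                raise DataError("is_mito length mismatch")
            if np.any(self.is_mito & self.is_spikein):
                raise DataError("spike-in and mito flags must be disjoint")

    # -- convenience accessors ------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def biological(self) -> "CountMatrix":
        """Submatrix of non-spike-in genes."""
        return self.subset_genes(~self.is_spikein)

    def spikeins(self) -> pd.DataFrame:
        """Spike-in rows as a genes x cells DataFrame."""
        sel = self.is_spikein
        return pd.DataFrame(
            self.counts[sel], index=self.gene_ids[sel], columns=self.cell_ids
        )

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        mask = self._gene_mask(mask_or_ids)
        return CountMatrix(
            counts=self.counts[mask],
            gene_ids=self.gene_ids[mask],
            cell_ids=self.cell_ids,
            is_spikein=self.is_spikein[mask],
            is_mito=None if self.is_mito is None else self.is_mito[mask],
        )

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        pos = {c: j for j, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise DataError(f"unknown cell ids: {missing[:5]}")
        idx = np.array([pos[c] for c in cell_ids], dtype=int)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=np.asarray(list(cell_ids), dtype=object),
            is_spikein=self.is_spikein,
            is_mito=self.is_mito,
        )

    def _gene_mask(self, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            return arr
        wanted = set(arr.tolist())
        return np.array([g in wanted for g in self.gene_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


# ---------------------------------------------------------------------------
# CellMetadata


@dataclass
class CellMetadata:
    """Per-cell annotations: group label, deletion-region evidence, capture flag.

    ``deletion_region_count`` holds the number of reads falling in a genomic
    region expected to be absent after a conditional deletion (missing when
    not assayed); ``capture_flag`` records microscopy triage of the capture
    site.
    """

    table: pd.DataFrame

    REQUIRED = ("cell_id", "group")

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise DataError(f"cell metadata missing column {col!r}")
        if t["cell_id"].duplicated().any():
            raise DataError("duplicate cell ids in metadata")
        if "deletion_region_count" not in t.columns:
            t["deletion_region_count"] = pd.array([pd.NA] * len(t), dtype="Int64")
        else:
            t["deletion_region_count"] = pd.array(
                t["deletion_region_count"], dtype="Int64"
            )
            if (t["deletion_region_count"].dropna() < 0).any():
                raise DataError("deletion_region_count must be >= 0")
        if "capture_flag" not in t.columns:
            t["capture_flag"] = "unknown"
        bad = set(t["capture_flag"]) - set(CAPTURE_FLAGS)
        if bad:
            raise DataError(f"unknown capture flags: {sorted(bad)}")
        self.table = t.set_index("cell_id", drop=False)

    def for_cells(self, cell_ids: Sequence[str]) -> pd.DataFrame:
        missing = [c for c in cell_ids if c not in self.table.index]
        if missing:
            raise DataError(f"metadata missing for cells: {missing[:5]}")
        return self.table.loc[list(cell_ids)]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


# ---------------------------------------------------------------------------
# GeneSetCollection


@dataclass
class GeneSetCollection:
    """Named gene sets with one-line descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, description, *members = fields
            if name in sets:
                raise DataError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            seen: set[str] = set()
            unique = []
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                unique.append(m)
            if len(unique) < len(members):
                warnings.warn(
                    f"GMT set {name!r}: {len(members) - len(unique)} duplicate "
                    "members de-duplicated"
                )
            if not unique:
                raise DataError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = unique
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Count matrix readers


def _flags_from_annotation(
    gene_ids: np.ndarray,
    spikein_prefix: str,
    gene_annotation: Mapping[str, str] | None,
) -> tuple[np.ndarray, np.ndarray | None]:
    is_spike = np.array([str(g).startswith(spikein_prefix) for g in gene_ids])
    if gene_annotation is None:
        return is_spike, None
    is_mito = np.array(
        [str(gene_annotation.get(str(g), "")) in MITO_CHROMOSOMES for g in gene_ids]
    )
    is_mito &= ~is_spike
    return is_spike, is_mito


def read_gene_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV sidecar mapping gene id to chromosome."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "chromosome"])
    return dict(zip(df["gene_id"].astype(str), df["chromosome"].astype(str)))


def read_count_matrix(
    path: str | Path,
    format: str = "tsv",
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
    gene_annotation: Mapping[str, str] | str | Path | None = None,
) -> CountMatrix:
    """Read a genes x cells count matrix.

    ``format='tsv'`` expects a header row of cell ids and a first column of
    gene ids.  ``format='mtx-triplet'`` expects MatrixMarket coordinate format
    with ``<base>.genes.txt`` / ``<base>.cells.txt`` sidecar files next to it.
    Spike-in rows are flagged by id prefix; mitochondrial rows via an optional
    gene-annotation sidecar (gene id -> chromosome).
    """
    path = Path(path)
    if isinstance(gene_annotation, (str, Path)):
        gene_annotation = read_gene_annotation(gene_annotation)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError:
            raise DataError("no genes") from None
        if df.shape[0] == 0:
            raise DataError("no genes")
        gene_ids = df.index.astype(str).to_numpy(dtype=object)
        cell_ids = df.columns.astype(str).to_numpy(dtype=object)
        counts = df.to_numpy()
    elif format == "mtx-triplet":
        base = path.with_suffix("") if path.suffix == ".mtx" else path
        genes_file = base.parent / (base.name + ".genes.txt")
        cells_file = base.parent / (base.name + ".cells.txt")
        for f in (genes_file, cells_file):
            if not f.exists():
                raise DataError(f"missing sidecar file {f}")
        mat = scipy.io.mmread(path)
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        gene_ids = np.array(
            [l.strip() for l in genes_file.read_text().splitlines() if l.strip()],
            dtype=object,
        )
        cell_ids = np.array(
            [l.strip() for l in cells_file.read_text().splitlines() if l.strip()],
            dtype=object,
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    is_spike, is_mito = _flags_from_annotation(gene_ids, spikein_prefix, gene_annotation)
    return CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        is_spikein=is_spike,
        is_mito=is_mito,
    )


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as a TSV with a header row of cell ids."""
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# ResultTable


@dataclass
class ResultTable:
    """Keyed result table with provenance, serialised as TSV.

    Floats are written with 6 significant digits and NaN as "NA"; a write
    followed by a read is lossless at that precision.
    """

    table: pd.DataFrame
    key: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.key not in self.table.columns:
            raise DataError(f"key column {self.key!r} missing")
        if self.table[self.key].duplicated().any():
            raise DataError("key column not unique")


def write_results(table: ResultTable, path: str | Path, sig_digits: int = 6) -> None:
    df = table.table
    with open(path, "w") as fh:
        if table.provenance:
            fh.write(f"# {table.provenance}\n")
        df.to_csv(
            fh,
            sep="\t",
            index=False,
            na_rep="NA",
            float_format=f"%.{sig_digits}g",
        )


def read_results(path: str | Path, key: str) -> ResultTable:
    prov = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            prov = first.lstrip("# ").rstrip("\n")
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"], keep_default_na=False)
    return ResultTable(table=df, key=key, provenance=prov)
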