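"""Core data containers and on-disk interchange (MatrixMarket + TSV sidecars).

The exchange object between all pipeline stages is :class:`CountMatrix`
(sparse cell x gene raw counts with aligned identifiers) together with a
:class:`GeneTable` carrying the genomic annotation needed for QC and CNV
smoothing (chromosome, start coordinate, mitochondrial flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneTable",
    "NormalizedMatrix",
    "read_dataset",
    "write_dataset",
]


@dataclass
class CountMatrix:
    """Sparse non-negative integer count matrix, cells x genes."""

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicated cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicated gene ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=self.gene_ids,
        )


@dataclass
class GeneTable:
    """Per-gene annotation: chromosome, 1-based start, mito and marker flags."""

    table: pd.DataFrame  # columns: gene_id, chromosome, start, mito[, marker]

    REQUIRED = ("gene_id", "chromosome", "start", "mito")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"gene table missing column {col!r}")
        if "marker" not in self.table.columns:
            self.table = self.table.assign(marker=False)
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicated gene_ids in gene table")
        if (self.table["start"] <= 0).any():
            raise ValueError("gene start coordinates must be positive (1-based)")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    @property
    def mito(self) -> np.ndarray:
        return self.table["mito"].to_numpy(dtype=bool)

    def aligned_to(self, gene_ids: list[str]) -> "GeneTable":
        """Reorder rows to match ``gene_ids``; error if any id is missing."""
        indexed = self.table.set_index("gene_id")
        missing = [g for g in gene_ids if g not in indexed.index]
        if missing:
            raise ValueError(f"gene table missing {len(missing)} ids, e.g. {missing[:3]}")
        return GeneTable(indexed.loc[gene_ids].reset_index())


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with per-stage metadata.

    ``values`` holds ln(1 + scale_factor * count / cell_total), sparse.
    ``column_gain`` records any multiplicative input gain applied per gene
    (1.0 everywhere until :func:`raregain.gain.apply_input_gain` runs);
    scaling uses it to standardize gained columns by their pre-gain spread.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    scale_factor: float = 1e4
    column_gain: np.ndarray | None = None
    forced_hvg: np.ndarray | None = None
    hvg_mask: np.ndarray | None = None
    scaled_values: np.ndarray | None = None
    stages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_genes = self.values.shape[1]
        if self.column_gain is None:
            self.column_gain = np.ones(n_genes)
        if self.forced_hvg is None:
            self.forced_hvg = np.zeros(n_genes, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_cells(self, mask_or_index) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=self.gene_ids,
            scale_factor=self.scale_factor,
            column_gain=self.column_gain.copy(),
            forced_hvg=self.forced_hvg.copy(),
            hvg_mask=None if self.hvg_mask is None else self.hvg_mask.copy(),
            scaled_values=None,
            stages=list(self.stages),
        )


# ---------------------------------------------------------------------------
# MTX + TSV sidecar interchange
# ---------------------------------------------------------------------------

_MTX = "matrix.mtx"
_BARCODES = "barcodes.tsv"
_GENES = "genes.tsv"
_LABELS = "labels.tsv"


def write_dataset(
    counts: CountMatrix,
    gene_table: GeneTable,
    directory,
    truth_labels: list[str] | None = None,
) -> dict[str, str]:
    """Write counts as MatrixMarket with TSV sidecars; returns a file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gt = gene_table.aligned_to(counts.gene_ids)

    scipy.io.mmwrite(
        directory / _MTX, sp.coo_matrix(counts.values), field="integer"
    )
    pd.Series(counts.cell_ids).to_csv(
        directory / _BARCODES, sep="\t", index=False, header=False
    )
    gt.table[["gene_id", "chromosome", "start", "mito"]].assign(
        mito=gt.table["mito"].astype(int)
    ).to_csv(directory / _GENES, sep="\t", index=False, header=False)

    manifest = {
        "matrix": str(directory / _MTX),
        "barcodes": str(directory / _BARCODES),
        "genes": str(directory / _GENES),
    }
    if truth_labels is not None:
        if len(truth_labels) != counts.n_cells:
            raise ValueError("truth labels must align with cells")
        pd.DataFrame({"barcode": counts.cell_ids, "truth_label": truth_labels}).to_csv(
            directory / _LABELS, sep="\t", index=False, header=False
        )
        manifest["labels"] = str(directory / _LABELS)
    return manifest


def read_dataset(directory) -> tuple[CountMatrix, GeneTable, list[str] | None]:
    """Read the MTX + TSV layout written by :func:`write_dataset`."""
    directory = Path(directory)
    mat = scipy.io.mmread(directory / _MTX)
    mat = sp.csr_matrix(mat, dtype=np.int64)
    barcodes_path = directory / _BARCODES
    if barcodes_path.stat().st_size == 0:
        cell_ids: list[str] = []
    else:
        cell_ids = (
            pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
        )
    genes = pd.read_csv(
        directory / _GENES,
        sep="\t",
        header=None,
        names=["gene_id", "chromosome", "start", "mito"],
    )
    gene_table = GeneTable(
        genes.assign(mito=genes["mito"].astype(bool), gene_id=genes["gene_id"].astype(str))
    )
    counts = CountMatrix(mat, cell_ids, gene_table.gene_ids)

    labels = None
    labels_path = directory / _LABELS
    if labels_path.exists():
        if labels_path.stat().st_size == 0:
            labels = []
        else:
            lab = pd.read_csv(labels_path, sep="\t", header=None,
                              names=["barcode", "truth_label"])
            order = {b: i for i, b in enumerate(cell_ids)}
            lab = lab.sort_values("barcode", key=lambda s: s.map(order))
            labels = lab["truth_label"].astype(str).tolist()
    return counts, gene_table, labels
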