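"""Cell QC filtering, log-normalization, HVG selection and feature scaling.

The stage order is fixed: filter -> lognormalize -> (optional input gain) ->
select_hvg -> scale_features; each operation appends its name to the
``stages`` metadata of its output so downstream code can assert ordering.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, GeneTable, NormalizedMatrix

__all__ = ["filter_cells", "lognormalize", "select_hvg", "scale_features"]


def filter_cells(
    counts: CountMatrix,
    gene_table: GeneTable,
    min_genes: int = 200,
    max_mito: float = 0.05,
) -> CountMatrix:
    """Drop low-complexity and high-mitochondrial cells.

    A cell is retained iff it has at least ``min_genes`` detected genes
    (nonzero counts) and a mitochondrial count fraction of at most
    ``max_mito``. The thresholds are the complements of the exclusion rule
    "fewer than 200 genes, or more than 5% mitochondrial counts". Cells with
    zero total counts have mito fraction defined as 0 and fall to the gene
    filter. Cell order is preserved; the operation is idempotent.
    """
    gt = gene_table.aligned_to(counts.gene_ids)
    mat = counts.values
    detected = mat.getnnz(axis=1)
    total = np.asarray(mat.sum(axis=1)).ravel()
    mito_counts = np.asarray(mat[:, gt.mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    keep = (detected >= min_genes) & (mito_frac <= max_mito)
    return counts.subset_cells(keep)


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """ln(1 + scale_factor * count / cell_total), sparsity preserved."""
    total = np.asarray(counts.values.sum(axis=1)).ravel().astype(np.float64)
    if (total == 0).any():
        raise ValueError(
            "cells with zero total counts present; run filter_cells first"
        )
    mat = counts.values.tocsr().astype(np.float64)
    row_scale = scale_factor / total
    mat = sp.diags(row_scale) @ mat
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        values=mat.tocsr(),
        cell_ids=counts.cell_ids,
        gene_ids=counts.gene_ids,
        scale_factor=scale_factor,
        stages=["filter", "lognormalize"],
    )


def _gene_moments(mat: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = mat.shape[0]
    mean = np.asarray(mat.mean(axis=0)).ravel()
    sq = np.asarray(mat.multiply(mat).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
    return mean, var


def select_hvg(norm: NormalizedMatrix, n_top: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Mark the ``n_top`` most variable genes by binned dispersion.

    Per-gene variance of the log-normalized values is z-standardized within
    equal-frequency bins of the gene mean (the classic dispersion method);
    genes are ranked by the standardized dispersion, ties broken by
    lexicographic gene id. Genes flagged ``forced_hvg`` (gained markers) are
    always included. Returns the boolean mask and stores it on ``norm``.
    """
    if n_top > norm.n_genes:
        raise ValueError("n_top exceeds the number of genes")
    mean, var = _gene_moments(norm.values)

    # equal-frequency mean bins; degenerate bins get z = 0
    order = np.argsort(mean, kind="stable")
    bin_id = np.empty(norm.n_genes, dtype=int)
    bin_id[order] = np.minimum(
        (np.arange(norm.n_genes) * n_bins) // max(norm.n_genes, 1), n_bins - 1
    )
    z = np.zeros(norm.n_genes)
    for b in range(n_bins):
        in_bin = bin_id == b
        if not in_bin.any():
            continue
        mu, sd = var[in_bin].mean(), var[in_bin].std(ddof=1) if in_bin.sum() > 1 else 0.0
        z[in_bin] = (var[in_bin] - mu) / sd if sd > 0 else 0.0

    gene_ids = np.asarray(norm.gene_ids)
    # sort by (-z, gene_id): highest dispersion first, lexicographic tie-break
    rank = np.lexsort((gene_ids, -z))
    mask = np.zeros(norm.n_genes, dtype=bool)
    mask[norm.forced_hvg] = True
    for g in rank:
        if mask.sum() >= n_top:
            break
        mask[g] = True
    norm.hvg_mask = mask
    norm.stages.append("select_hvg")
    return mask


def scale_features(norm: NormalizedMatrix, clip: float = 10.0) -> np.ndarray:
    """Per-HVG z-score across cells (sample SD), clipped, gain-exempt markers.

    Zero-variance genes map to all-zero columns. Columns carrying an input
    gain g are standardized by their *pre-gain* mean and SD and clipped in
    pre-gain z units before the gain is re-applied, so a g-fold amplification
    survives standardization (the scaled column is g times the ungained
    z-scores); see :func:`raregain.gain.apply_input_gain`.
    """
    if norm.hvg_mask is None:
        raise ValueError("run select_hvg before scale_features")
    idx = np.flatnonzero(norm.hvg_mask)
    sub = norm.values[:, idx].toarray().astype(np.float64)
    gains = norm.column_gain[idx]
    sub /= gains[None, :]  # back to pre-gain values (no-op where gain == 1)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else np.zeros(sub.shape[1])
    scaled = np.zeros_like(sub)
    nz = sd > 0
    scaled[:, nz] = (sub[:, nz] - mean[nz]) / sd[nz]
    np.clip(scaled, -clip, clip, out=scaled)
    scaled *= gains[None, :]
    norm.scaled_values = scaled
    norm.stages.append("scale_features")
    return scaled
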