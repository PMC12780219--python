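"""Expression-smoothing CNV inference and the CNV-positivity gate.

A deliberately simple, deterministic expression-based copy-number signal:
per-gene residuals against a diploid reference, clamped, averaged along the
genome within each chromosome, re-centered per cell, and offset to a
baseline of 1 (diploid). The per-cell score is the mean squared modified
expression; a diploid cell scores ~1 and CNV-bearing cells score above it,
so a gate slightly above 1 (default 1.009) separates tumor from reference.
No HMM, no subclustering — the aim is the gate, not integer copy calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneTable, NormalizedMatrix

__all__ = [
    "CnvResult",
    "smooth_relative_expression",
    "cnv_score",
    "select_cnv_positive",
    "genome_order",
]

DEFAULT_THRESHOLD = 1.009


@dataclass
class CnvResult:
    modified_expression: np.ndarray  # cells x genes (genome order), baseline 1
    gene_order: np.ndarray  # column order applied to the input genes
    cell_ids: list[str]
    cell_score: np.ndarray | None = None
    cnv_positive: np.ndarray | None = None


def _chrom_sort_key(chrom: str):
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def genome_order(gene_table: GeneTable) -> np.ndarray:
    """Indices sorting genes by (chromosome, start); numeric chromosomes first."""
    tbl = gene_table.table
    keys = sorted(
        range(len(tbl)),
        key=lambda i: (_chrom_sort_key(tbl["chromosome"].iat[i]), tbl["start"].iat[i], i),
    )
    return np.asarray(keys, dtype=int)


def _moving_average_shrunk(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with edge-shrunk windows."""
    half = window // 2
    n = block.shape[1]
    csum = np.cumsum(block, axis=1, dtype=np.float64)
    csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def smooth_relative_expression(
    norm: NormalizedMatrix,
    gene_table: GeneTable,
    reference_cells: set[str] | list[str],
    window: int = 101,
    clamp: float = 3.0,
    center_reference: bool = True,
    denoise_sd: float = 1.0,
    segment_mask_mads: float = 5.0,
) -> CnvResult:
    """Position-smoothed expression relative to a diploid reference.

    Per gene: residual = log-normalized expression minus the reference-cell
    mean, clamped to +/- ``clamp`` reference SDs; residuals are averaged over
    a centered ``window`` of genomically adjacent genes within each
    chromosome (windows shrink at chromosome edges); each cell is then
    re-centered by its median smoothed residual.

    Three refinements, each individually defeatable, sharpen the diploid
    baseline (they stand in for the reference re-centering, denoising and
    HMM segmentation steps of full CNV-inference tools):

    - ``center_reference``: subtract the per-gene mean smoothed residual of
      the reference cells, removing positional bias such as clamp skew;
    - ``denoise_sd`` > 0: soft-threshold residuals toward zero by
      ``denoise_sd`` times the SD of the reference cells' smoothed
      residuals, so diploid cells sit almost exactly at baseline;
    - ``segment_mask_mads`` > 0: keep only genomic positions where the
      pseudo-bulk of the *test* (non-reference) cells deviates from its
      median by more than this many MADs — the cohort-level evidence of
      where CNV segments actually are; per-cell scores then reflect only
      candidate CNV regions instead of genome-wide smoothing noise.

    Output is offset to the diploid baseline: m = 1 + smoothed residual.
    Set ``center_reference=False, denoise_sd=0, segment_mask_mads=0`` for
    the bare residual-smoothing skeleton.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    ref_set = set(reference_cells)
    if not ref_set:
        raise ValueError("reference cell set is empty")
    ref_mask = np.array([c in ref_set for c in norm.cell_ids])
    if not ref_mask.any():
        raise ValueError("no reference cells present in the matrix")

    gt = gene_table.aligned_to(norm.gene_ids)
    order = genome_order(gt)
    dense = norm.values.toarray().astype(np.float64)[:, order]
    chroms = gt.table["chromosome"].to_numpy()[order]

    ref = dense[ref_mask]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1) if ref.shape[0] > 1 else np.zeros(dense.shape[1])
    resid = dense - mu
    lim = clamp * sd
    np.clip(resid, -lim, lim, out=resid)

    smoothed = np.empty_like(resid)
    start = 0
    for chrom in pd.unique(chroms):
        block = resid[:, chroms == chrom]
        stop = start + block.shape[1]
        if block.shape[1] < 3:
            warnings.warn(
                f"chromosome {chrom} has fewer than 3 genes; passed through unsmoothed"
            )
            smoothed[:, start:stop] = block
        else:
            smoothed[:, start:stop] = _moving_average_shrunk(block, window)
        start = stop

    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    if center_reference:
        smoothed -= smoothed[ref_mask].mean(axis=0)
    if segment_mask_mads > 0 and (~ref_mask).any():
        bulk = smoothed[~ref_mask].mean(axis=0)
        med = np.median(bulk)
        mad = 1.4826 * np.median(np.abs(bulk - med))
        keep = np.abs(bulk - med) > segment_mask_mads * mad
    else:
        keep = np.ones(smoothed.shape[1], dtype=bool)
    if denoise_sd > 0:
        noise_floor = denoise_sd * smoothed[ref_mask].std()
        smoothed = np.sign(smoothed) * np.maximum(np.abs(smoothed) - noise_floor, 0.0)
    smoothed *= keep[None, :]
    return CnvResult(
        modified_expression=smoothed + 1.0,
        gene_order=order,
        cell_ids=list(norm.cell_ids),
    )


def cnv_score(modified_expression: np.ndarray) -> np.ndarray:
    """Per-cell score S_c = mean over genes of m_cg^2 (diploid baseline 1)."""
    m = np.asarray(modified_expression, dtype=np.float64)
    return (m**2).mean(axis=1)


def select_cnv_positive(
    cell_score: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    level: str = "cell",
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of CNV-positive cells: score strictly greater than threshold.

    ``level='cell'`` gates individual cells; ``level='cluster'`` gates whole
    clusters by their mean score (requires ``labels``), mirroring a workflow
    where the threshold is applied to tumor clusters rather than cells.
    """
    score = np.asarray(cell_score, dtype=np.float64)
    if level == "cell":
        return score > threshold
    if level == "cluster":
        if labels is None:
            raise ValueError("cluster-level gating requires cluster labels")
        labels = np.asarray(labels)
        keep = np.zeros(score.shape[0], dtype=bool)
        for cid in np.unique(labels):
            members = labels == cid
            if score[members].mean() > threshold:
                keep |= members
        return keep
    raise ValueError("level must be 'cell' or 'cluster'")
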