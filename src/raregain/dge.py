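"""Differential expression between cell groups, with BH correction.

Two per-gene tests are provided: a two-sided Wilcoxon rank-sum on
log-normalized values (robust default, exactly verifiable by enumeration at
small group sizes) and a negative-binomial Wald regression on raw counts
with a log library-size offset (the DESeq2-style test family). Fold changes
are log2 ratios of depth-normalized group means with a small stabilizing
epsilon.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, NormalizedMatrix

__all__ = [
    "differential_expression",
    "bh_adjust",
    "marker_positive_fraction",
]

_EPS = 1e-9


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate and are excluded
    from the number of tests."""
    p = np.asarray(p_values, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _group_arrays(values, cells_a, cells_b, cell_ids):
    index = {c: i for i, c in enumerate(cell_ids)}
    ia = np.array([index[c] for c in cells_a], dtype=int)
    ib = np.array([index[c] for c in cells_b], dtype=int)
    if set(cells_a) & set(cells_b):
        raise ValueError("groups must be disjoint")
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("each group needs at least 3 cells")
    return ia, ib


def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    return np.log2((mean_a + _EPS) / (mean_b + _EPS))


def _wilcoxon(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values, one per gene column.

    Small tie-free groups get the exact U distribution (matching direct
    enumeration over arrangements); otherwise the normal approximation with
    tie correction is used.
    """
    if max(xa.shape[0], xb.shape[0]) <= 8:
        out = np.empty(xa.shape[1])
        for g in range(xa.shape[1]):
            out[g] = scipy.stats.mannwhitneyu(
                xa[:, g], xb[:, g], alternative="two-sided", method="auto"
            ).pvalue
        return out
    res = scipy.stats.mannwhitneyu(
        xa, xb, axis=0, alternative="two-sided", method="asymptotic"
    )
    return np.asarray(res.pvalue)


def _nb_wald_gene(y: np.ndarray, design: np.ndarray, offset: np.ndarray):
    """NB2 regression of one gene; returns (coef, p) for the group column."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, design, offset=offset)
            fit = model.fit(disp=0, maxiter=100)
        if not np.isfinite(fit.bse[1]) or fit.bse[1] == 0:
            raise ValueError("degenerate SE")
        return float(fit.params[1]), float(fit.pvalues[1])
    except Exception:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    y, design, family=sm.families.Poisson(), offset=offset
                ).fit()
            return float(fit.params[1]), float(fit.pvalues[1])
        except Exception:
            return np.nan, np.nan


def differential_expression(
    norm: NormalizedMatrix,
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-gene test of group A vs group B.

    Returns a DataFrame indexed by gene with columns log2fc, p_value, adj_p,
    mean_a, mean_b, direction. Means are depth-normalized (counts scaled to
    ``norm.scale_factor`` per cell). Genes with zero variance across both
    groups get p = 1 and log2fc = 0.
    """
    if method not in ("wilcoxon", "nb_wald"):
        raise ValueError("method must be 'wilcoxon' or 'nb_wald'")
    ia, ib = _group_arrays(None, group_a, group_b, norm.cell_ids)

    raw = counts.values
    totals = np.asarray(raw.sum(axis=1)).ravel().astype(np.float64)
    depth_norm = sp.diags(norm.scale_factor / np.maximum(totals, 1)) @ raw
    mean_a = np.asarray(depth_norm[ia].mean(axis=0)).ravel()
    mean_b = np.asarray(depth_norm[ib].mean(axis=0)).ravel()
    log2fc = _log2fc(mean_a, mean_b)

    xa = norm.values[ia].toarray()
    xb = norm.values[ib].toarray()
    flat = (
        (np.ptp(xa, axis=0) == 0)
        & (np.ptp(xb, axis=0) == 0)
        & (xa[0] == xb[0])
    )

    if method == "wilcoxon":
        p = _wilcoxon(xa, xb)
    else:
        design = np.column_stack(
            [np.ones(len(ia) + len(ib)), np.r_[np.ones(len(ia)), np.zeros(len(ib))]]
        )
        offset = np.log(np.r_[totals[ia], totals[ib]])
        y = np.vstack([raw[ia].toarray(), raw[ib].toarray()])
        coefs = np.empty(y.shape[1])
        p = np.empty(y.shape[1])
        for g in range(y.shape[1]):
            if flat[g]:
                coefs[g], p[g] = 0.0, 1.0
            else:
                coefs[g], p[g] = _nb_wald_gene(y[:, g], design, offset)
        log2fc_wald = coefs / np.log(2)
    p = np.where(flat, 1.0, p)
    log2fc = np.where(flat, 0.0, log2fc)

    table = pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": bh_adjust(p),
            "mean_a": mean_a,
            "mean_b": mean_b,
        }
    ).set_index("gene")
    if method == "nb_wald":
        table["wald_log2fc"] = np.where(flat, 0.0, log2fc_wald)
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    table.loc[table["log2fc"] == 0, "direction"] = "none"
    return table


def marker_positive_fraction(
    norm: NormalizedMatrix, cell_set: set[str] | list[str], gene: str
) -> float | None:
    """Fraction of the given cells with normalized expression > 0 for ``gene``.

    Returns None for an empty cell set.
    """
    cells = list(cell_set)
    if not cells:
        return None
    index = {c: i for i, c in enumerate(norm.cell_ids)}
    rows = np.array([index[c] for c in cells], dtype=int)
    j = norm.gene_index([gene])[0]
    col = np.asarray(norm.values[rows, j].todense()).ravel()
    return float((col > 0).mean())
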