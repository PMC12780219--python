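"""Preranked gene-set enrichment with a gene-set permutation null,
hypergeometric overlap testing, and GMT parsing.

The enrichment score is the classic weighted Kolmogorov-Smirnov running-sum
statistic: walking down the ranked gene list, hits increment the sum by
|stat|^p normalized over the set's hits, misses decrement by 1/(N - Nh);
ES is the signed maximum deviation. The null is built from random gene sets
of the same size drawn from the ranked universe (exhaustively enumerated
when the number of possible sets is small), NES divides ES by the mean |ES|
of same-sign permutations, and the permutation p-value uses the standard
add-one estimator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .dge import bh_adjust

__all__ = [
    "EnrichmentResult",
    "OverlapResult",
    "enrichment_score",
    "preranked_gsea",
    "gsea_table",
    "geneset_overlap",
    "read_gmt",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p_perm: float
    adj_p: float | None
    leading_edge: list[str]
    degenerate: bool = False


@dataclass
class OverlapResult:
    n_deg: int
    n_set: int
    n_overlap: int
    n_universe: int
    p_value: float


def enrichment_score(
    ranked_genes: list[str],
    ranked_stats: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> tuple[float, int, np.ndarray]:
    """ES of ``gene_set`` on the ranked list; returns (ES, extremum index, hits).

    ``ranked_genes`` must already be sorted by decreasing statistic. If the
    set covers the whole universe the miss increment is undefined; the
    running sum then consists of hits only and ES is 1 at the end of the
    list (flagged degenerate by the caller).
    """
    n = len(ranked_genes)
    hits = np.fromiter((g in gene_set for g in ranked_genes), dtype=bool, count=n)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has empty intersection with the ranked universe")
    w = np.abs(np.asarray(ranked_stats, dtype=np.float64)) ** weight
    hit_w = np.where(hits, w, 0.0)
    hit_total = hit_w.sum()
    if hit_total == 0:  # all hit stats are zero: fall back to unweighted
        hit_w = hits.astype(np.float64)
        hit_total = hit_w.sum()
    if n_hits == n:
        running = np.cumsum(hit_w / hit_total)
        return 1.0, n - 1, hits
    miss = 1.0 / (n - n_hits)
    running = np.cumsum(hit_w / hit_total - np.where(hits, 0.0, miss))
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i, hits


def _leading_edge(
    ranked_genes: list[str], hits: np.ndarray, es: float, extremum: int
) -> list[str]:
    if es >= 0:
        idx = np.flatnonzero(hits[: extremum + 1])
    else:
        idx = np.flatnonzero(hits[extremum + 1 :]) + extremum + 1
    return [ranked_genes[i] for i in idx]


def preranked_gsea(
    ranked_stats: dict[str, float] | pd.Series,
    gene_set: set[str] | list[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "gene_set",
) -> EnrichmentResult:
    """Enrichment of one gene set against a ranked statistic.

    The null distribution re-scores random same-size gene sets drawn from
    the universe; when C(N, k) <= 10,000 every possible set is enumerated
    instead (exact permutation p). p_perm = (1 + #{same-sign |ES_perm| >=
    |ES|}) / (1 + #same-sign perms); NES = ES / mean |ES_perm, same sign|.
    """
    if isinstance(ranked_stats, dict):
        ranked_stats = pd.Series(ranked_stats)
    if ranked_stats.index.duplicated().any():
        raise ValueError("duplicate genes in the ranking")
    order = np.lexsort((ranked_stats.index.to_numpy(), -ranked_stats.to_numpy()))
    genes = [str(g) for g in ranked_stats.index[order]]
    stats = ranked_stats.to_numpy(dtype=np.float64)[order]
    gene_set = set(map(str, gene_set))

    inter = gene_set & set(genes)
    if len(inter) < 2:
        raise ValueError(
            f"gene set {set_name!r} shares fewer than 2 genes with the ranking"
        )
    es, extremum, hits = enrichment_score(genes, stats, inter, weight)
    k, n = len(inter), len(genes)
    degenerate = k == n
    leading = _leading_edge(genes, hits, es, extremum)

    if degenerate:
        return EnrichmentResult(set_name, es, np.nan, 1.0, None, leading, True)

    if comb(n, k) <= EXHAUSTIVE_LIMIT:
        combos = itertools.combinations(range(n), k)
        perm_es = np.array(
            [
                enrichment_score(genes, stats, {genes[i] for i in c}, weight)[0]
                for c in combos
            ]
        )
    else:
        rng = np.random.default_rng(seed)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            pick = rng.choice(n, size=k, replace=False)
            perm_es[b] = enrichment_score(
                genes, stats, {genes[i] for i in pick}, weight
            )[0]

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes, p = np.nan, 1.0
    else:
        denom = np.abs(perm_es[same_sign]).mean()
        nes = es / denom if denom > 0 else np.nan
        p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(set_name, es, nes, p, None, leading, False)


def gsea_table(
    ranked_stats: dict[str, float] | pd.Series,
    gene_sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run preranked GSEA over a GMT-style collection; BH-adjust across sets."""
    rows = []
    for name, members in gene_sets.items():
        res = preranked_gsea(
            ranked_stats, members, weight=weight, n_perm=n_perm, seed=seed,
            set_name=name,
        )
        rows.append(
            {
                "gene_set": name,
                "es": res.es,
                "nes": res.nes,
                "p_perm": res.p_perm,
                "leading_edge": ";".join(res.leading_edge),
                "degenerate": res.degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_set")
    table["adj_p"] = bh_adjust(table["p_perm"].to_numpy())
    return table


def geneset_overlap(
    deg_genes: set[str] | list[str],
    reference_set: set[str] | list[str],
    universe: set[str] | list[str],
) -> OverlapResult:
    """Overlap of two gene sets with a one-sided hypergeometric upper-tail p."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    deg = set(deg_genes) & universe
    ref = set(reference_set) & universe
    overlap = len(deg & ref)
    m = len(universe)
    p = float(scipy.stats.hypergeom.sf(overlap - 1, m, len(ref), len(deg)))
    return OverlapResult(
        n_deg=len(deg),
        n_set=len(ref),
        n_overlap=overlap,
        n_universe=m,
        p_value=min(p, 1.0),
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered name -> unique gene list mapping."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"GMT parse error at line {lineno}: expected >= 3 tab-separated "
                f"fields (name, description, genes...), got {len(fields)}"
            )
        name = fields[0]
        genes, seen = [], set()
        dupes = 0
        for g in fields[2:]:
            if not g:
                continue
            if g in seen:
                dupes += 1
                continue
            seen.add(g)
            genes.append(g)
        if dupes:
            warnings.warn(f"gene set {name!r}: {dupes} duplicate gene(s) removed")
        sets[name] = genes
    return sets
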