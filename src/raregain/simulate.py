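"""Synthetic scRNA-seq generator with a planted rare double-marker-positive population.

The generator emulates the structure of a dissociated-tumor scRNA-seq cohort:
a large CNV-bearing cancer compartment, a diploid reference compartment
(stroma/immune stand-in), and a very rare (default 0.1%) dormant cancer
subpopulation that is double-positive for two marker genes and has a
suppressed proliferation signature. Counts are negative binomial with
cell-specific log-normal library sizes, so every downstream stage (QC,
normalization, CNV scoring, gain clustering, DGE, GSEA) has known ground
truth to be tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneTable, write_dataset

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_counts", "n_rare_cells"]

LABEL_SRCC = "SRCC"
LABEL_CANCER = "cancer_nonSRCC"
LABEL_REFERENCE = "reference"

# Default marker ids mirror the biology being emulated: a riboflavin
# transporter and a Notch receptor marking the rare resistant population.
DEFAULT_MARKERS = ("SLC52A2", "NOTCH1")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the study regime exercised throughout the test suite:
    20,000 cells, 0.1% planted SRCC, two marker genes, one gained chromosome
    arm (1.5x) in all cancer cells, and a 50-gene dormancy signature
    down-regulated in the rare population.
    """

    n_cells: int = 20_000
    n_genes: int = 2_000
    rare_fraction: float = 0.001
    n_reference: int = 4_000
    marker_genes: tuple[str, ...] = DEFAULT_MARKERS
    marker_mean_fold: float = 8.0
    marker_background_rate: float = 0.01
    #: expected marker count in a background-positive (non-SRCC) cell
    marker_background_mean: float = 1.2
    dispersion: float = 2.0
    libsize_log_mean: float = float(np.log(2_000))
    libsize_log_sd: float = 0.3
    mito_fraction_genes: float = 0.005
    #: share of each cell's expression budget on mitochondrial genes
    mito_budget: float = 0.03
    #: fraction of cells with elevated mitochondrial content (QC casualties)
    stress_fraction: float = 0.02
    stress_multiplier: float = 4.0
    n_chromosomes: int = 10
    #: (chromosome, start_gene_index, end_gene_index, multiplier), global
    #: 0-based gene indices, end exclusive; applied to all cancer cells.
    #: None resolves to a whole-chr1 gain at 1.5x (trisomy-like).
    cnv_segments: list[tuple[str, int, int, float]] | None = None
    n_dormancy_genes: int = 50
    dormancy_fold: float = 0.3
    #: skew of baseline gene-proportion draws (log-normal sigma)
    proportion_log_sd: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if not (0 <= self.rare_fraction < 1):
            raise ValueError("rare_fraction must lie in [0, 1)")
        if self.rare_fraction > 0 and self.marker_mean_fold <= 1:
            raise ValueError(
                "invalid config: rare_fraction > 0 requires marker_mean_fold > 1 "
                "(the planted population would be undetectable by construction)"
            )
        if self.n_reference < 0 or self.n_reference >= self.n_cells:
            raise ValueError("n_reference must lie in [0, n_cells)")
        if not self.marker_genes:
            raise ValueError("at least one marker gene required")
        if not (0 < self.dormancy_fold < 1) and self.n_dormancy_genes:
            raise ValueError("dormancy_fold must lie in (0, 1)")
        for chrom, start, end, mult in self.cnv_segments or []:
            if mult <= 0:
                raise ValueError("CNV multipliers must be positive")
            if not (0 <= start < end <= self.n_genes):
                raise ValueError(f"CNV segment [{start}, {end}) out of gene range")
        n_mito = int(round(self.mito_fraction_genes * self.n_genes))
        if self.n_genes - n_mito < len(self.marker_genes) + self.n_dormancy_genes:
            raise ValueError("not enough nuclear genes for markers + dormancy set")


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    truth_labels: list[str]
    gene_table: GeneTable
    config: SimulationConfig
    cnv_segments: list[tuple[str, int, int, float]] = field(default_factory=list)

    @property
    def dormancy_genes(self) -> list[str]:
        return self.gene_table.table.loc[
            self.gene_table.table["dormancy"], "gene_id"
        ].tolist()

    def write(self, directory) -> dict[str, str]:
        return write_dataset(
            self.counts, self.gene_table, directory, truth_labels=self.truth_labels
        )


def n_rare_cells(n_cells: int, rare_fraction: float) -> int:
    """Planted SRCC count: round-half-up of the expected count, floor 1."""
    if rare_fraction == 0:
        return 0
    return max(1, int(np.floor(rare_fraction * n_cells + 0.5)))


def _build_gene_table(cfg: SimulationConfig, rng: np.random.Generator) -> GeneTable:
    n_mito = int(round(cfg.mito_fraction_genes * cfg.n_genes))
    n_nuclear = cfg.n_genes - n_mito
    per_chrom = np.full(cfg.n_chromosomes, n_nuclear // cfg.n_chromosomes)
    per_chrom[: n_nuclear % cfg.n_chromosomes] += 1

    gene_ids, chroms, starts = [], [], []
    idx = 0
    for c, size in enumerate(per_chrom, start=1):
        for j in range(size):
            gene_ids.append(f"G{idx + 1:05d}")
            chroms.append(f"chr{c}")
            starts.append((j + 1) * 10_000)
            idx += 1
    for j in range(n_mito):
        gene_ids.append(f"MT-G{j + 1:03d}")
        chroms.append("MT")
        starts.append((j + 1) * 1_000)

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chroms,
            "start": starts,
            "mito": [c == "MT" for c in chroms],
            "marker": False,
            "dormancy": False,
        }
    )

    # Markers live on a CNV-free chromosome so the planted signal is not
    # confounded with copy number.
    cnv_chroms = {seg[0] for seg in cfg.cnv_segments} if cfg.cnv_segments else {"chr1"}
    marker_chrom = next(
        (f"chr{c}" for c in range(cfg.n_chromosomes, 0, -1)
         if f"chr{c}" not in cnv_chroms),
        "chr1",
    )
    marker_rows = table.index[table["chromosome"] == marker_chrom][
        : len(cfg.marker_genes)
    ]
    table.loc[marker_rows, "gene_id"] = list(cfg.marker_genes)
    table.loc[marker_rows, "marker"] = True

    # Dormancy (cell-cycle stand-in) genes on another CNV-free chromosome.
    if cfg.n_dormancy_genes:
        dorm_chrom = next(
            f"chr{c}" for c in range(cfg.n_chromosomes, 0, -1)
            if f"chr{c}" not in cnv_chroms and f"chr{c}" != marker_chrom
        )
        dorm_rows = table.index[table["chromosome"] == dorm_chrom][
            : cfg.n_dormancy_genes
        ]
        table.loc[dorm_rows, "gene_id"] = [
            f"CYC-{k + 1:03d}" for k in range(len(dorm_rows))
        ]
        table.loc[dorm_rows, "dormancy"] = True
    return GeneTable(table)


def resolve_cnv_segments(
    cfg: SimulationConfig, gene_table: GeneTable
) -> list[tuple[str, int, int, float]]:
    """Explicit CNV segments; the default is a 1.5x gain of all of chr1."""
    if cfg.cnv_segments is not None:
        return list(cfg.cnv_segments)
    chr1 = np.flatnonzero((gene_table.table["chromosome"] == "chr1").to_numpy())
    return [("chr1", int(chr1.min()), int(chr1.max()) + 1, 1.5)]


def expected_mean_matrix(
    cfg: SimulationConfig,
    gene_table: GeneTable,
    labels: np.ndarray,
    libsizes: np.ndarray,
    background_mask: np.ndarray,
    stress: np.ndarray,
    proportions: np.ndarray,
    cnv_segments: list[tuple[str, int, int, float]] | None = None,
) -> np.ndarray:
    """Dense generative NB mean for every cell/gene: L_c * p_g * m_cg.

    Exposed separately so tests can assert on the exact generative means
    rather than on sampled counts.
    """
    tbl = gene_table.table
    mito = tbl["mito"].to_numpy(bool)
    marker = tbl["marker"].to_numpy(bool)
    dorm = tbl["dormancy"].to_numpy(bool)
    is_srcc = labels == LABEL_SRCC
    is_cancer = is_srcc | (labels == LABEL_CANCER)

    if cnv_segments is None:
        cnv_segments = resolve_cnv_segments(cfg, gene_table)
    mult = np.ones((len(labels), cfg.n_genes), dtype=np.float64)
    for chrom, start, end, m in cnv_segments:
        seg = np.zeros(cfg.n_genes, dtype=bool)
        seg[start:end] = True
        seg &= (tbl["chromosome"] == chrom).to_numpy()
        mult[np.ix_(is_cancer, seg)] *= m
    if marker.any():
        mult[np.ix_(is_srcc, marker)] *= cfg.marker_mean_fold
        # background thinning: a non-SRCC cell expresses each marker
        # independently with probability marker_background_rate
        non_srcc = ~is_srcc
        mult[np.ix_(non_srcc, marker)] *= background_mask[non_srcc, :]
    if dorm.any():
        mult[np.ix_(is_srcc, dorm)] *= cfg.dormancy_fold
    if mito.any():
        mult[:, mito] *= np.where(stress, cfg.stress_multiplier, 1.0)[:, None]
    return libsizes[:, None] * proportions[None, :] * mult


def _baseline_proportions(
    cfg: SimulationConfig, gene_table: GeneTable, rng: np.random.Generator
) -> np.ndarray:
    tbl = gene_table.table
    mito = tbl["mito"].to_numpy(bool)
    marker = tbl["marker"].to_numpy(bool)
    p = np.exp(rng.normal(0.0, cfg.proportion_log_sd, size=cfg.n_genes))
    # marker baseline set so a background-positive cell sees ~marker_background_mean
    # counts at the typical library size
    p[marker] = cfg.marker_background_mean / np.exp(cfg.libsize_log_mean)
    if mito.any():
        p[mito] = cfg.mito_budget * p[~mito].sum() / (1 - cfg.mito_budget) / mito.sum()
    nonmarker = ~marker
    p[nonmarker] *= (1 - p[marker].sum()) / p[nonmarker].sum()
    return p  # sums to 1


def generate_counts(config: SimulationConfig) -> SyntheticDataset:
    """Sample a :class:`SyntheticDataset` from the generative model.

    Counts are NB(mean = L_c * p_g * m_cg, inverse-dispersion theta), sampled
    as a gamma-Poisson mixture; variance = mu + mu^2/theta. The multiplier
    m_cg composes CNV segments (cancer cells), the marker fold (SRCC),
    the dormancy fold (SRCC), the background-expression mask (non-SRCC
    marker columns) and the mitochondrial stress factor.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_table = _build_gene_table(cfg, rng)
    n_srcc = n_rare_cells(cfg.n_cells, cfg.rare_fraction)
    n_cancer = cfg.n_cells - cfg.n_reference - n_srcc
    if n_cancer < 0:
        raise ValueError("n_reference + planted SRCC exceed n_cells")

    labels = np.array(
        [LABEL_SRCC] * n_srcc
        + [LABEL_CANCER] * n_cancer
        + [LABEL_REFERENCE] * cfg.n_reference
    )
    perm = rng.permutation(cfg.n_cells)
    labels = labels[perm]

    libsizes = np.exp(
        rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, size=cfg.n_cells)
    )
    background_mask = (
        rng.random((cfg.n_cells, len(cfg.marker_genes)))
        < cfg.marker_background_rate
    ).astype(np.float64)
    stress = rng.random(cfg.n_cells) < cfg.stress_fraction
    proportions = _baseline_proportions(cfg, gene_table, rng)

    segments = resolve_cnv_segments(cfg, gene_table)
    mean = expected_mean_matrix(
        cfg, gene_table, labels, libsizes, background_mask, stress, proportions,
        cnv_segments=segments,
    )
    theta = float(cfg.dispersion)
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam).astype(np.int64)
    del lam, mean

    matrix = sp.csr_matrix(counts)
    barcodes = [f"CELL-{i + 1:06d}" for i in range(cfg.n_cells)]
    cm = CountMatrix(matrix, barcodes, gene_table.gene_ids)
    return SyntheticDataset(
        counts=cm, truth_labels=labels.tolist(), gene_table=gene_table, config=cfg,
        cnv_segments=segments,
    )
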