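"""Count ingestion, sample/gene quality filters, CPM and quantile normalization.

Quality metrics (mapped reads, unmapped/ERCC fractions, genes detected,
reporter-transgene molecules, cells per well, identity verification) are
consumed from a metadata table — alignment and UMI deduplication happen
upstream and are out of scope. Expression is standardized to counts per
million using each cell's pre-gene-filter total molecule count, then each
gene is quantile-normalized to a standard normal across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import mmread
from scipy.stats import norm

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "REQUIRED_METADATA_COLUMNS",
    "apply_sample_filters",
    "apply_gene_filters",
    "compute_cpm",
    "quantile_normalize",
    "normalize_counts",
    "read_counts",
    "write_counts",
    "read_metadata",
]

REQUIRED_METADATA_COLUMNS = (
    "cell_id",
    "plate_id",
    "individual_id",
    "cells_in_well",
    "egfp_molecules",
    "verified_individual_on_chip",
    "mapped_reads",
    "pct_unmapped",
    "pct_ercc",
    "genes_detected",
)


@dataclass
class CountMatrix:
    """UMI molecule counts, genes x cells, with unique identifiers."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != self.counts.shape[1]:
            raise ValueError("cell_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Per-cell total molecule counts over all genes in this matrix."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset(self, gene_ids=None, cell_ids=None) -> "CountMatrix":
        gi = np.arange(self.n_genes)
        ci = np.arange(self.n_cells)
        if gene_ids is not None:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            gi = np.array([pos[g] for g in gene_ids])
        if cell_ids is not None:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            ci = np.array([pos[c] for c in cell_ids])
        return CountMatrix(
            self.counts[np.ix_(gi, ci)],
            [self.gene_ids[i] for i in gi],
            [self.cell_ids[i] for i in ci],
        )


@dataclass
class QCThresholds:
    """Sample and gene inclusion thresholds.

    Defaults are the study-calibrated cutoffs: samples need >= 1,309,921
    mapped reads, < 44% unmapped, < 18% ERCC, >= 6292 genes detected, at
    least one reporter-transgene (EGFP) molecule, exactly one verified cell
    per well. Genes are dropped when their total molecule count exceeds
    6^4 = 1296 (overexpressed) or their mean CPM is below 2.
    """

    min_mapped_reads: int = 1_309_921
    max_pct_unmapped: float = 0.44
    max_pct_ercc: float = 0.18
    min_genes_detected: int = 6292
    min_egfp_molecules: int = 1
    max_gene_total_molecules: int = 6**4
    min_gene_mean_cpm: float = 2.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"threshold {name} must be nonnegative")


def apply_sample_filters(
    metadata: pd.DataFrame, thresholds: QCThresholds | None = None
) -> list[str]:
    """Return cell_ids passing all sample-level QC criteria, in input order.

    A cell passes iff exactly one cell was observed in its well, at least one
    molecule mapped to the EGFP transgene, its individual assignment was
    verified on-chip, and its mapped reads / unmapped fraction / ERCC
    fraction / genes detected clear the thresholds.
    """
    thresholds = thresholds or QCThresholds()
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise KeyError(
            f"metadata is missing required column(s): {', '.join(missing)}"
        )
    if metadata["cell_id"].duplicated().any():
        raise ValueError("metadata must have one row per cell_id")
    ok = (
        (metadata["cells_in_well"] == 1)
        & (metadata["egfp_molecules"] >= thresholds.min_egfp_molecules)
        & metadata["verified_individual_on_chip"].astype(bool)
        & (metadata["mapped_reads"] >= thresholds.min_mapped_reads)
        & (metadata["pct_unmapped"] < thresholds.max_pct_unmapped)
        & (metadata["pct_ercc"] < thresholds.max_pct_ercc)
        & (metadata["genes_detected"] >= thresholds.min_genes_detected)
    )
    return metadata.loc[ok, "cell_id"].tolist()


def compute_cpm(
    counts: CountMatrix | np.ndarray, per_cell_totals: np.ndarray
) -> np.ndarray:
    """Counts per million using externally supplied per-cell totals.

    The totals are the pre-gene-filter per-cell molecule sums: after genes
    are dropped, the denominator still reflects every molecule the cell
    produced, so CPM values are comparable across filter settings.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    totals = np.asarray(per_cell_totals, dtype=float)
    if totals.size != mat.shape[1]:
        raise ValueError("one total per cell required")
    zero = np.nonzero(totals <= 0)[0]
    if zero.size:
        names = (
            [counts.cell_ids[i] for i in zero[:5]]
            if isinstance(counts, CountMatrix)
            else zero[:5].tolist()
        )
        raise ValueError(f"zero total molecule count for cell(s): {names}")
    return mat / totals * 1e6


def apply_gene_filters(
    counts: CountMatrix,
    thresholds: QCThresholds | None = None,
    per_cell_totals: np.ndarray | None = None,
) -> list[str]:
    """Return gene_ids retained after expression-level filters.

    A gene is excluded iff its total molecules across the retained samples
    exceed ``max_gene_total_molecules`` or its mean CPM is below
    ``min_gene_mean_cpm`` (strictly; a mean CPM exactly at the threshold is
    kept). ``counts`` should contain all pre-filter genes over the retained
    cells; totals default to this matrix's per-cell sums.
    """
    thresholds = thresholds or QCThresholds()
    if per_cell_totals is None:
        per_cell_totals = counts.cell_totals()
    if not np.any(per_cell_totals > 0):
        raise ValueError("all-zero count matrix: CPM undefined")
    cpm = compute_cpm(counts, per_cell_totals)
    totals = counts.counts.sum(axis=1)
    over = totals > thresholds.max_gene_total_molecules
    low = cpm.mean(axis=1) < thresholds.min_gene_mean_cpm
    keep = ~(over | low)
    return [g for g, k in zip(counts.gene_ids, keep) if k]


def quantile_normalize(matrix: np.ndarray, seed: int = 0) -> np.ndarray:
    """Quantile-normalize each gene (row) to a standard normal across cells.

    Values are replaced by ``Phi^{-1}((r - 0.5) / n)`` where ``r`` is the
    within-gene rank (1 = smallest). Ties — including the block of zero
    counts, which thereby receives the lowest expression levels — are broken
    uniformly at random with the supplied seed, so repeated runs with the
    same seed are identical.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = matrix.shape[1]
    if n < 2:
        raise ValueError("need at least 2 cells to quantile-normalize")
    rng = np.random.default_rng(seed)
    quantiles = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    out = np.empty_like(matrix)
    for g in range(matrix.shape[0]):
        shuffle = rng.permutation(n)  # random tie-breaking via pre-shuffle
        order = shuffle[np.argsort(matrix[g, shuffle], kind="stable")]
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        out[g] = quantiles[ranks]
    return out


def normalize_counts(
    counts: CountMatrix,
    per_cell_totals: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """CPM + per-gene standard-normal quantile normalization in one step."""
    if per_cell_totals is None:
        per_cell_totals = counts.cell_totals()
    return quantile_normalize(compute_cpm(counts, per_cell_totals), seed=seed)


def read_counts(path: str, gene_file: str | None = None, cell_file: str | None = None) -> CountMatrix:
    """Read a genes x cells count matrix.

    ``.mtx`` files need gene/cell identifier sidecar files (one id per
    line); anything else is parsed as a dense TSV with genes as rows, the
    first column holding gene ids and the header holding cell ids.
    """
    if str(path).endswith(".mtx"):
        if gene_file is None or cell_file is None:
            raise ValueError("MatrixMarket input requires gene and cell id files")
        mat = mmread(path)
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        mat = np.asarray(mat)
        genes = [line.strip() for line in open(gene_file) if line.strip()]
        cells = [line.strip() for line in open(cell_file) if line.strip()]
        return CountMatrix(mat, genes, cells)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.to_numpy(), df.index.tolist(), df.columns.tolist())


def write_counts(cm: CountMatrix, path: str) -> None:
    """Write counts as dense TSV (genes as rows, header = cell ids)."""
    pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )


def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise KeyError(f"metadata file missing column(s): {', '.join(missing)}")
    return meta
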