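"""Unit conversions, gene-universe intersection, variance filtering and PCA.

Expression tables arrive on heterogeneous scales (RPKM cell-line tables,
TPM tumour tables, x10-scaled single-cell TPM). This module brings them onto
a common log2(TPM+1) scale over the shared gene universe, and provides the
cohort-level views used for a first-pass comparison: the Pearson correlation
of mean expression profiles and a PCA embedding of the most variable genes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel_io import ExpressionMatrix, Unit
from .errors import DegenerateSampleError, UndefinedCorrelationError

__all__ = [
    "PCAEmbedding",
    "rpkm_to_tpm",
    "to_log_tpm",
    "intersect_universe",
    "top_variance_genes",
    "mean_profile_correlation",
    "pca_embed",
]


@dataclass
class PCAEmbedding:
    """Sample coordinates of a principal-component embedding.

    ``coordinates`` is samples x components; ``explained_variance`` holds the
    fraction of total variance captured by each component (non-increasing).
    ``loadings`` is genes x components, with the sign convention that the
    largest-magnitude loading of each component is positive.
    """

    coordinates: pd.DataFrame
    explained_variance: np.ndarray
    loadings: pd.DataFrame

    @property
    def samples(self) -> pd.Index:
        return self.coordinates.index


def rpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale an RPKM matrix so every sample column sums to 10^6 (TPM)."""
    if matrix.unit is not Unit.RPKM:
        raise ValueError(f"expected RPKM input, got {matrix.unit.value}")
    sums = matrix.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise DegenerateSampleError(f"all-zero sample column: {zero.index[0]!r}")
    tpm = matrix.values.div(sums, axis=1) * 1e6
    return matrix.with_values(tpm, Unit.TPM)


def to_log_tpm(matrix: ExpressionMatrix, single_cell_scale: bool = False) -> ExpressionMatrix:
    """log2(TPM/d + 1) with d=10 for single-cell libraries, d=1 otherwise.

    The divisor 10 compensates for the lower complexity of single-cell
    libraries (on the order of 100,000 transcripts), so that pseudo-count 1
    represents a comparable detection floor.
    """
    if matrix.unit is not Unit.TPM:
        raise ValueError(f"expected TPM input, got {matrix.unit.value}")
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative TPM value")
    d = 10.0 if single_cell_scale else 1.0
    return matrix.with_values(np.log2(matrix.values / d + 1.0), Unit.LOG2_TPM1)


def intersect_universe(*matrices: ExpressionMatrix) -> list[ExpressionMatrix]:
    """Restrict all matrices to their shared genes, in a common order.

    Gene matching is exact-string on the identifiers. The output order is the
    first matrix's gene order filtered to the intersection; values are
    untouched.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    shared = matrices[0].genes
    for m in matrices[1:]:
        shared = shared.intersection(m.genes)
    if len(shared) == 0:
        raise ValueError("empty gene intersection")
    order = [g for g in matrices[0].genes if g in set(shared)]
    return [m.subset_genes(order) for m in matrices]


def top_variance_genes(matrix: ExpressionMatrix, k: int) -> list[str]:
    """The k genes with largest sample variance (ddof=1) across all samples.

    Ties are broken by gene identifier (lexicographic) for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix.genes):
        raise ValueError(f"k={k} exceeds {len(matrix.genes)} genes")
    var = matrix.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:k]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc**2).sum())
    ny = np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        raise UndefinedCorrelationError("zero variance in a mean profile")
    return float((xc @ yc) / (nx * ny))


def mean_profile_correlation(group_a: ExpressionMatrix, group_b: ExpressionMatrix) -> float:
    """Pearson r between the per-gene mean profiles of two groups.

    Both matrices must share the same gene universe (use
    :func:`intersect_universe` first) and should already be on the log scale.
    """
    if not group_a.genes.equals(group_b.genes):
        raise ValueError("gene universes differ; intersect first")
    if len(group_a.genes) < 3:
        raise ValueError("need at least 3 genes")
    return _pearson(
        group_a.values.mean(axis=1).to_numpy(), group_b.values.mean(axis=1).to_numpy()
    )


def pca_embed(
    matrix: ExpressionMatrix, genes: list[str] | None = None, n_components: int = 2
) -> PCAEmbedding:
    """PCA of gene-centered expression (genes are centered, not scaled).

    The component sign is fixed so the largest-magnitude gene loading of each
    component is positive; explained variance fractions are computed over the
    full singular spectrum of the centered matrix.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    sub = matrix if genes is None else matrix.subset_genes(genes)
    X = sub.values.to_numpy().T  # samples x genes
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds min(genes, samples)")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    evr = (s**2) / total if total > 0 else np.zeros_like(s)
    coords = U[:, :n_components] * s[:n_components]
    load = Vt[:n_components].T
    for k in range(n_components):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] *= -1.0
            coords[:, k] *= -1.0
    names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAEmbedding(
        coordinates=pd.DataFrame(coords, index=sub.samples, columns=names),
        explained_variance=evr[:n_components],
        loadings=pd.DataFrame(load, index=sub.genes, columns=names),
    )
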