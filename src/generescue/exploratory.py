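"""QC computations: transformed counts, PCA, sample distances, heatmaps.

These back the study's quality-control views: PCA of samples on the most
variable genes, whole-transcriptome Euclidean sample distances, and the
per-sample rescue heatmap (z-scored DEG expression across samples). The
log-like transform is log2(x + 1) of normalized counts — a simple monotone
variance-damping transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform


def transform_counts(norm_counts: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1) of normalized counts."""
    arr = norm_counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("normalized counts must be non-negative")
    return pd.DataFrame(np.log2(arr + 1.0), index=norm_counts.index,
                        columns=norm_counts.columns)


def top_variable_genes(matrix: pd.DataFrame, n: int = 2000) -> list[str]:
    """The n genes with the largest across-sample variance.

    Ties are resolved by gene id order, so the selection is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > matrix.shape[0]:
        raise ValueError(f"n={n} exceeds the {matrix.shape[0]} available genes")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], g))
    return list(order[:n])


@dataclass(frozen=True)
class PcaResult:
    """Sample coordinates and percent variance explained per component."""

    coordinates: pd.DataFrame
    percent_variance: np.ndarray


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Gene-centered SVD with samples as points (genes are not scaled)."""
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(x.shape)
    if n_components is not None:
        k = min(k, n_components)
    coords = u[:, :k] * s[:k]
    total = (s**2).sum()
    pct = 100.0 * s[:k] ** 2 / total if total > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=matrix.columns, columns=cols),
        percent_variance=pct,
    )


def sample_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples over all genes."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(matrix.to_numpy(dtype=float).T))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def per_sample_rescue_matrix(
    norm_counts: pd.DataFrame, deg_genes: Sequence[str]
) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    """Z-scored (per gene, across samples) DEG expression with orderings.

    Returns (z matrix, row order, column order, skipped genes). Orderings are
    average-linkage hierarchical clustering leaves on Euclidean distance;
    they are presentation hints — the matrix itself is the contract. Genes
    absent from the matrix or with zero variance are skipped and reported.
    """
    genes = [g for g in deg_genes]
    if not genes:
        raise ValueError("DEG gene list must be non-empty")
    skipped = [g for g in genes if g not in norm_counts.index]
    present = [g for g in genes if g in norm_counts.index]
    sub = norm_counts.loc[present].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] < 1e-12
    skipped += [g for g, f in zip(present, flat) if f]
    kept = [g for g, f in zip(present, flat) if not f]
    z = (sub[~flat] - mean[~flat]) / sd[~flat]
    zdf = pd.DataFrame(z, index=kept, columns=norm_counts.columns)

    def _order(data: np.ndarray, labels: Sequence[str]) -> list[str]:
        if len(labels) < 3:
            return list(labels)
        lk = linkage(data, method="average", metric="euclidean")
        return [labels[i] for i in leaves_list(lk)]

    row_order = _order(z, kept)
    col_order = _order(z.T, list(norm_counts.columns))
    return zdf, row_order, col_order, skipped
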