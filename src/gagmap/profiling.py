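"""Tissue-level expression profiling: z-scores, correlation, clustering.

Reproduces the two atlas-style analyses: (1) per-reaction z-score
normalization of reaction activities across tissues with hierarchical
clustering of both axes (the reaction-by-tissue heatmap), and (2) the
gene–gene Pearson correlation matrix across tissues.

Row z-scores use the sample standard deviation (ddof=1) by default;
clustering is agglomerative with Euclidean distance and complete linkage —
the common default of R heatmap tooling — both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression_io import ExpressionMatrix

__all__ = [
    "ZScoreMatrix",
    "CorrelationMatrix",
    "ClusterResult",
    "zscore_rows",
    "pearson_matrix",
    "hierarchical_cluster",
]


@dataclass
class ZScoreMatrix:
    """Row-standardized matrix; zero-variance rows are zeroed and flagged."""

    values: pd.DataFrame
    zero_variance_rows: list[str] = field(default_factory=list)


@dataclass
class CorrelationMatrix:
    """Symmetric gene × gene Pearson r matrix with unit diagonal."""

    values: pd.DataFrame
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    """Agglomerative merge tree over row or column items."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    leaf_order: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Assign each item to one of ``k`` flat clusters (1-based ids)."""
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))


def zscore_rows(m: pd.DataFrame, ddof: int = 1) -> ZScoreMatrix:
    """Standardize each row to mean 0, sd 1 (sample sd by default).

    Rows with zero variance cannot be standardized; they map to all zeros
    and are flagged rather than producing NaN.
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 columns")
    arr = m.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat, :] = 0.0
    return ZScoreMatrix(
        values=pd.DataFrame(z, index=m.index, columns=m.columns),
        zero_variance_rows=[str(g) for g in m.index[flat]],
    )


def pearson_matrix(
    m: ExpressionMatrix | pd.DataFrame, genes: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of gene rows across samples.

    Genes observed in fewer than 3 samples or with zero variance are
    dropped (flagged in the result); fewer than 2 usable genes is an error.
    """
    df = m.values if isinstance(m, ExpressionMatrix) else m
    if genes is not None:
        missing = [g for g in genes if g not in df.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        df = df.loc[genes]
    dropped: list[str] = []
    if df.shape[1] < 3:
        raise ValueError("Pearson correlation requires >= 3 samples")
    var = df.to_numpy(dtype=float).var(axis=1)
    dropped = [str(g) for g, v in zip(df.index, var) if v == 0]
    usable = df.loc[[g for g in df.index if str(g) not in dropped]]
    if usable.shape[0] < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    r = np.corrcoef(usable.to_numpy(dtype=float))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        values=pd.DataFrame(r, index=usable.index, columns=usable.index),
        dropped_genes=dropped,
    )


def hierarchical_cluster(
    m: pd.DataFrame,
    axis: str = "cols",
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of rows or columns of a matrix.

    Items are pre-sorted by label so that distance ties resolve identically
    across runs; the reported ``leaf_order`` is the dendrogram leaf sequence.
    """
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    data = m if axis == "rows" else m.T
    if data.shape[0] < 2:
        raise ValueError("clustering requires at least 2 items")
    data = data.loc[sorted(data.index.astype(str))]
    labels = [str(i) for i in data.index]
    z = hierarchy.linkage(pdist(data.to_numpy(dtype=float), metric=metric), method=method)
    leaves = hierarchy.leaves_list(z)
    return ClusterResult(
        linkage=z, labels=labels, leaf_order=[labels[i] for i in leaves]
    )
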