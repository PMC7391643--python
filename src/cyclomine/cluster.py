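"""Hierarchical clustering of TPM expression profiles.

Genes are clustered by the Pearson-correlation distance d(i,j) = 1 - r(i,j)
with complete linkage, the combination used for tissue-expression heatmaps.
Profiles are row-scaled (centered, unit variance) by default; replicate
columns can be averaged per tissue beforehand with :func:`average_replicates`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def average_replicates(m: pd.DataFrame, tissue_of: dict) -> pd.DataFrame:
    """Average replicate columns per tissue (column -> tissue mapping)."""
    groups = {}
    for col in m.columns:
        groups.setdefault(tissue_of.get(col, col), []).append(col)
    return pd.DataFrame(
        {tissue: m[cols].mean(axis=1) for tissue, cols in groups.items()}
    )


def correlation_distance(m: pd.DataFrame, scaled: bool = True):
    """Pearson-correlation distance matrix over gene (row) profiles.

    Returns ``(D, gene_ids)``; zero-variance rows are dropped with a logged
    warning (correlation is undefined for them). D is symmetric with zero
    diagonal and entries in [0, 2].
    """
    if m.shape[1] < 2:
        raise ValueError("need at least two columns to correlate profiles")
    values = m.values.astype(float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(m.index[~keep])
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped)
    values = values[keep]
    ids = list(m.index[keep])
    if len(ids) < 2:
        raise ValueError("fewer than two non-constant gene profiles")
    if scaled:
        values = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, keepdims=True
        )
    r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d, ids


@dataclass
class Dendrogram:
    """Complete-linkage merge tree with optional flat labels."""

    ids: List[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    labels: Optional[np.ndarray] = None  # flat cluster labels (1..k) when cut

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def cluster_complete(d: np.ndarray, ids: Sequence[str], k: Optional[int] = None) -> Dendrogram:
    """Agglomerative complete-linkage clustering of a distance matrix.

    Complete linkage guarantees non-decreasing merge heights. When ``k`` is
    given the tree is cut into ``k`` flat clusters.
    """
    n = d.shape[0]
    if k is not None and (k < 1 or k > n):
        raise ValueError(f"k={k} out of range for {n} observations")
    Z = linkage(squareform(d, checks=False), method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust") if k is not None else None
    return Dendrogram(ids=list(ids), linkage_matrix=Z, labels=labels)


def cluster_expression(
    m: pd.DataFrame, k: Optional[int] = None, scaled: bool = True
) -> Dendrogram:
    """Convenience wrapper: correlation distance + complete linkage."""
    d, ids = correlation_distance(m, scaled=scaled)
    return cluster_complete(d, ids, k=k)
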