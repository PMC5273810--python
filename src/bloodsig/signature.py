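"""Unsupervised disease-state signature: CV filter, two-way
hierarchical clustering and PCA.

The coefficient-of-variation filter retains probes whose sd/mean across
all arrays exceeds a threshold (default 0.12), computed by default on
the linear (anti-logged) scale.  Sample clustering defaults to a
1 - Pearson distance with centroid linkage, probe clustering to
1 - Pearson with average linkage; Euclidean distance is available by
flag.  Ties are broken by lexicographic item id, which also makes the
result invariant to input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SKPCA

from .errors import ConfigurationError, ValidationError
from .io_formats import ExpressionMatrix

__all__ = ["ClusterResult", "PCAResult", "cv_filter",
           "hierarchical_cluster", "pca"]

_LINKAGES = ("centroid", "average", "complete")
_DISTANCES = ("euclidean", "one_minus_pearson")


@dataclass
class ClusterResult:
    """Agglomerative merge tree over one axis of the matrix.

    ``merge_tree`` rows are (left, right, height) where left/right index
    original items (0..n-1) or earlier merges (n..2n-2), scipy linkage
    convention.  ``leaf_order`` is the dendrogram's left-to-right leaf
    ordering as item ids.
    """

    axis: str
    item_ids: list[str]
    merge_tree: np.ndarray
    leaf_order: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Cut the tree into ``k`` flat clusters; id -> cluster label."""
        labels = hierarchy.fcluster(self._scipy_z(), t=k, criterion="maxclust")
        return dict(zip(self.item_ids, (int(x) for x in labels)))

    def _scipy_z(self) -> np.ndarray:
        n = len(self.item_ids)
        z = np.zeros((n - 1, 4))
        z[:, :3] = self.merge_tree
        sizes = {i: 1 for i in range(n)}
        for row in range(n - 1):
            left, right = int(z[row, 0]), int(z[row, 1])
            sizes[n + row] = sizes[left] + sizes[right]
            z[row, 3] = sizes[n + row]
        return z

    def to_dict(self) -> dict:
        return {"axis": self.axis,
                "item_ids": self.item_ids,
                "merges": [[int(a), int(b), float(h)]
                           for a, b, h in self.merge_tree],
                "leaf_order": self.leaf_order}


@dataclass
class PCAResult:
    """Per-sample component scores and the variance captured by each."""

    component_scores: pd.DataFrame      # samples x k
    variance_fraction: np.ndarray       # length k, non-increasing

    @property
    def total_variance_fraction(self) -> float:
        return float(self.variance_fraction.sum())


def cv_filter(matrix: ExpressionMatrix, threshold: float = 0.12,
              scale: str = "linear") -> ExpressionMatrix:
    """Retain probes with coefficient of variation sd/mean > threshold.

    ``scale="linear"`` (default) anti-logs the stored log2 values before
    computing mean and sample sd; ``scale="log"`` uses the stored
    values.  Probe order is preserved; the filter is idempotent.
    """
    if threshold < 0:
        raise ConfigurationError(f"CV threshold must be >= 0 (got {threshold})")
    if scale not in ("linear", "log"):
        raise ConfigurationError(f"unknown CV scale {scale!r}")
    if matrix.n_samples < 2:
        raise ValidationError("CV filter needs >= 2 samples")
    vals = matrix.linear() if scale == "linear" else matrix.values
    arr = vals.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
        cv = np.where(sd == 0, 0.0, cv)   # constant probe: CV 0, excluded
    keep = [p for p, c in zip(matrix.probe_ids, cv) if c > threshold]
    return matrix.subset_probes(keep)


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str,
                         distance: str | None = None,
                         linkage: str | None = None,
                         standardize: bool = True) -> ClusterResult:
    """Agglomerative clustering of samples or probes.

    Defaults follow the two-way signature protocol: samples use
    1 - Pearson distance with centroid linkage, probes 1 - Pearson with
    average linkage.  ``standardize`` z-scores each probe across samples
    before sample clustering (no effect on correlation distances between
    probes).
    """
    if axis not in ("samples", "probes"):
        raise ConfigurationError(f"axis must be samples|probes (got {axis!r})")
    distance = distance or "one_minus_pearson"
    linkage = linkage or ("centroid" if axis == "samples" else "average")
    if distance not in _DISTANCES:
        raise ConfigurationError(f"unknown distance {distance!r}")
    if linkage not in _LINKAGES:
        raise ConfigurationError(f"unknown linkage {linkage!r}")

    df = matrix.values
    if standardize and axis == "samples":
        sd = df.std(axis=1, ddof=1).replace(0.0, 1.0)
        df = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    data = df.T if axis == "samples" else df
    # lexicographic item order: makes ties deterministic and the result
    # independent of input row/column order
    data = data.sort_index()
    ids = [str(i) for i in data.index]
    if len(ids) < 2:
        raise ValidationError(f"need >= 2 items on axis {axis!r}")
    metric = "euclidean" if distance == "euclidean" else "correlation"
    d = pdist(data.to_numpy(dtype=float), metric=metric)
    d = np.clip(d, 0.0, None)            # guard tiny negative rounding
    z = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(z)
    return ClusterResult(axis=axis, item_ids=ids,
                         merge_tree=z[:, :3].copy(),
                         leaf_order=[ids[i] for i in order])


def pca(matrix: ExpressionMatrix, n_components: int = 3,
        standardize: bool = True) -> PCAResult:
    """PCA of samples in probe space.

    Probes are centered (and, by default, scaled to unit variance)
    across samples before the decomposition.  Returns per-sample scores
    for up to ``n_components`` components and the fraction of total
    variance each captures.  A constant matrix yields all-zero variance
    fractions with a warning.
    """
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs >= 2 samples")
    X = matrix.values.to_numpy(dtype=float).T   # samples x probes
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    k = min(n_components, matrix.n_samples - 1, matrix.n_probes)
    if not np.any(X):
        warnings.warn("constant matrix: PCA variance fractions are all zero")
        scores = pd.DataFrame(np.zeros((matrix.n_samples, k)),
                              index=matrix.sample_ids,
                              columns=[f"PC{i + 1}" for i in range(k)])
        return PCAResult(scores, np.zeros(k))
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    frame = pd.DataFrame(scores, index=matrix.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return PCAResult(frame, model.explained_variance_ratio_.copy())
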