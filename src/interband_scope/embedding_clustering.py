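"""Ordinal (non-metric) MDS embedding and agglomerative clustering of
pairwise dissimilarities between binding factors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.manifold import smacof

from .colocalization import SimilarityMatrix, to_dissimilarity


@dataclass(frozen=True)
class Embedding:
    labels: tuple[str, ...]
    coords: np.ndarray  # (n, dims), conditional units
    stress: float  # normalized stress-1


@dataclass(frozen=True)
class Dendrogram:
    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (1..k) from cutting the tree into k groups."""
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return (D + D.T) / 2.0


def classical_mds(D: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centered -D^2/2."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def nonmetric_mds(
    D: np.ndarray,
    labels: tuple[str, ...] | None = None,
    dims: int = 2,
    seed: int = 0,
    max_iter: int = 2000,
    eps: float = 1e-9,
) -> Embedding:
    """Ordinal MDS: only the rank order of the dissimilarities counts.

    SMACOF majorization with isotonic regression, initialized from
    classical scaling; reported stress is normalized Kruskal stress-1.
    """
    D = _check_dissimilarity(D)
    if labels is None:
        labels = tuple(str(i) for i in range(D.shape[0]))
    init = classical_mds(D, dims)
    coords, stress = smacof(
        D,
        metric=False,
        n_components=dims,
        init=init,
        n_init=1,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    return Embedding(tuple(labels), coords, float(stress))


def ahc(
    D: np.ndarray,
    labels: tuple[str, ...] | None = None,
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative hierarchical clustering of a dissimilarity matrix."""
    D = _check_dissimilarity(D)
    if labels is None:
        labels = tuple(str(i) for i in range(D.shape[0]))
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return Dendrogram(tuple(labels), Z)


def groups(D: np.ndarray, k: int = 3, linkage: str = "average") -> np.ndarray:
    """Convenience: cluster labels from cutting the AHC tree at k groups."""
    return ahc(D, linkage=linkage).cut(k)


def cluster_similarity(
    matrix: SimilarityMatrix, k: int = 3, linkage: str = "average"
) -> dict[str, int]:
    """Cluster proteins from a similarity matrix via d = 1 - r."""
    D = to_dissimilarity(matrix)
    lab = ahc(D, labels=matrix.proteins, linkage=linkage).cut(k)
    return dict(zip(matrix.proteins, (int(x) for x in lab)))
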