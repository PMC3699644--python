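"""Hierarchical clustering of samples by expression profile.

Defaults are the sample-distance recipe familiar from count-based
differential-expression workflows: log2(RPM + 1) transform, euclidean
distance on the transformed profiles, and average linkage. Correlation
distance (1 - r) is available but is a poor choice for gene sets
pre-selected for a between-class contrast — a uniformly depleted class
keeps a near-perfect correlation with the class it is depleted against
while the log-scale offset that actually separates them is discarded.
Sample columns are sorted lexicographically before clustering so the result
is invariant to input column order and merge ties resolve toward the
lexicographically smallest member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .expression import ExpressionMatrix, ExpressionError

TRANSFORMS = ("log2p1", "none")
DISTANCES = ("correlation", "euclidean")
LINKAGES = ("average", "complete")


@dataclass
class SampleDendrogram:
    """Binary merge tree over samples.

    ``labels`` are the (sorted) sample identifiers; ``linkage_matrix`` is the
    scipy linkage encoding, whose rows are merges in non-decreasing height
    order; ``distances`` is the condensed pairwise distance matrix re-expanded
    to square form for export.
    """

    labels: list
    linkage_matrix: np.ndarray
    distances: pd.DataFrame

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def merges(self) -> list[frozenset]:
        """Leaf-label sets of each internal node, in merge order."""
        n = len(self.labels)
        clusters = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for row_index, (left, right, _height, _size) in enumerate(self.linkage_matrix):
            merged = clusters[int(left)] | clusters[int(right)]
            clusters[n + row_index] = merged
            out.append(merged)
        return out

    def topology(self):
        """Nested tuples of the rooted tree, children sorted for determinism."""
        n = len(self.labels)
        nodes: dict = {i: self.labels[i] for i in range(n)}
        for row_index, (left, right, _height, _size) in enumerate(self.linkage_matrix):
            children = sorted((nodes[int(left)], nodes[int(right)]), key=str)
            nodes[n + row_index] = tuple(children)
        return nodes[n + len(self.linkage_matrix) - 1]

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            inner = ",".join(sorted((left, right)))
            return f"({inner}):{length:.6g}"

        left = render(tree.left, tree.dist)
        right = render(tree.right, tree.dist)
        return f"({','.join(sorted((left, right)))});"


def cluster_samples(matrix: ExpressionMatrix,
                    transform: str = "log2p1",
                    distance: str = "euclidean",
                    linkage: str = "average") -> SampleDendrogram:
    """Cluster samples of an RPM matrix into a deterministic dendrogram."""
    if transform not in TRANSFORMS:
        raise ExpressionError(f"unknown transform {transform!r}")
    if distance not in DISTANCES:
        raise ExpressionError(f"unknown distance {distance!r}")
    if linkage not in LINKAGES:
        raise ExpressionError(f"unknown linkage {linkage!r}")
    if len(matrix.sample_ids) < 2:
        raise ExpressionError("clustering requires at least 2 samples")

    labels = sorted(matrix.sample_ids)
    data = matrix.values[labels].to_numpy(dtype=float)
    # canonical gene order too, so row order cannot influence anything
    data = data[np.argsort(np.asarray(matrix.gene_ids, dtype=str)), :]
    if transform == "log2p1":
        data = np.log2(data + 1.0)

    nonconstant = (data.std(axis=1) > 0).sum()
    if nonconstant < 2:
        raise ExpressionError(
            "need at least 2 genes with nonzero variance across samples")
    if distance == "correlation" and (data.std(axis=0) == 0).any():
        raise ExpressionError(
            "correlation distance undefined for a constant sample profile")

    condensed = pdist(data.T, metric=distance)
    linkage_matrix = hierarchy.linkage(condensed, method=linkage)
    square = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    return SampleDendrogram(labels=labels, linkage_matrix=linkage_matrix,
                            distances=square)


def write_newick(dendrogram: SampleDendrogram, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(dendrogram.to_newick() + "\n")


def write_distance_matrix(dendrogram: SampleDendrogram, path) -> None:
    out = dendrogram.distances.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
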