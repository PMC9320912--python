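"""Hierarchical classification of genotypes into ordered resistance types.

Genotypes are clustered on their membership-value profiles (rows of U_ij)
with agglomerative clustering — Euclidean distance and Ward linkage by
default — and the tree is cut into ``k`` clusters (default 4).  Clusters
are then ranked by descending mean comprehensive score U_j and labeled with
roman numerals: type I is the strongest cold-resistant group, the last type
the most sensitive.  Ties in cluster mean U_j are broken by the lower first
genotype index, so labels are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DomainError
from .evaluation import MembershipMatrix

LINKAGES = ("ward", "average", "complete", "single")
METRICS = ("euclidean", "cityblock", "correlation")


def _roman(n: int) -> str:
    numerals = (
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    )
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass
class ClassificationResult:
    """Dendrogram, cluster labels and ordered resistance types."""

    linkage: np.ndarray              # scipy merge table
    assignments: pd.DataFrame        # genotype, cluster, type, u_score
    summary: pd.DataFrame            # per type: n, mean/min/max U_j
    k: int
    method: str
    metric: str

    def types(self) -> pd.Series:
        return self.assignments.set_index("genotype")["type"]

    def to_newick(self) -> str:
        """Dendrogram in newick format with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)
        labels = list(self.assignments["genotype"])

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def classify_genotypes(
    mm: MembershipMatrix,
    k: int = 4,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClassificationResult:
    """Cut the U_ij dendrogram into k ordered resistance types."""
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    n = mm.values.shape[0]
    if k > n:
        raise DomainError(f"k={k} exceeds the number of genotypes ({n})")
    if method not in LINKAGES:
        raise DomainError(f"method must be one of {LINKAGES}, got {method!r}")
    if metric not in METRICS:
        raise DomainError(f"metric must be one of {METRICS}, got {metric!r}")
    if method == "ward" and metric != "euclidean":
        raise DomainError("ward linkage requires the euclidean metric")
    if mm.values.isna().any().any():
        raise DomainError("membership matrix contains missing values")

    x = mm.values.to_numpy()
    z = hierarchy.linkage(pdist(x, metric=metric), method=method)
    clusters = hierarchy.fcluster(z, t=k, criterion="maxclust")

    scores = mm.scores
    genotypes = list(mm.values.index)
    # rank clusters: descending mean U_j, ties -> lower first-genotype index
    cluster_ids = sorted(set(clusters))
    keyed = []
    for c in cluster_ids:
        members = [i for i, lab in enumerate(clusters) if lab == c]
        keyed.append((-scores.iloc[members].mean(), members[0], c))
    type_of = {c: _roman(rank + 1) for rank, (_, _, c) in enumerate(sorted(keyed))}

    assignments = pd.DataFrame(
        {
            "genotype": genotypes,
            "cluster": clusters,
            "type": [type_of[c] for c in clusters],
            "u_score": scores.to_numpy(),
        }
    )
    summary = (
        assignments.groupby("type")["u_score"]
        .agg(n="size", mean_u="mean", min_u="min", max_u="max")
        .sort_values("mean_u", ascending=False)
        .reset_index()
    )
    return ClassificationResult(
        linkage=z, assignments=assignments, summary=summary,
        k=k, method=method, metric=metric,
    )
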