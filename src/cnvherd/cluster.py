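"""CNVR presence/absence clustering: Jaccard distances, UPGMA, Newick export.

Each sample is encoded as a binary vector over CNVRs (1 iff the sample is in
the CNVR's supporting set).  Pairwise dissimilarity is one minus the Jaccard
index of the presence sets; samples with two empty profiles are defined as
identical (distance 0).  Trees are built with UPGMA (unweighted pair-group
method with arithmetic mean): repeatedly join the closest pair of clusters,
new inter-cluster distances being the size-weighted average of member
distances, the joined node sitting at half the joining distance.  Ties are
broken deterministically on the lexicographically smallest pair of cluster
representatives (each cluster represented by its smallest sample id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import CnvRegion


def binary_cnvr_matrix(
    cnvrs: list[CnvRegion], samples: list[str]
) -> pd.DataFrame:
    """Samples x CNVRs presence/absence matrix (0/1)."""
    data = {
        r.cnvr_id: [1 if s in r.supporting_samples else 0 for s in samples]
        for r in cnvrs
    }
    return pd.DataFrame(data, index=list(samples), dtype=np.int8)


def jaccard_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between sample presence profiles."""
    if len(matrix) < 2:
        raise ValueError("need >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    inter = x @ x.T
    row_sums = x.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass(frozen=True)
class TreeNode:
    """A rooted ultrametric tree node; ``height`` is distance to its leaves."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaves(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.name,)
        return tuple(l for c in self.children for l in c.leaves)

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self, parent_height: float | None = None) -> str:
        if self.is_leaf:
            label = self.name
        else:
            inner = ",".join(c._newick_inner(self.height) for c in self.children)
            label = f"({inner})"
        if parent_height is None:
            return label
        return f"{label}:{_fmt(parent_height - self.height)}"


def _fmt(x: float) -> str:
    # shortest exact-ish decimal: 0.1 not 0.100000
    return format(round(x, 10), "g")


def upgma(distances: pd.DataFrame) -> TreeNode:
    """UPGMA tree from a symmetric zero-diagonal distance matrix."""
    d = distances.to_numpy(dtype=float)
    labels = [str(l) for l in distances.index]
    if list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix index and columns must match")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if len(labels) == 1:
        return TreeNode(height=0.0, name=labels[0])

    dist: dict[frozenset[str], float] = {}
    clusters: dict[str, TreeNode] = {}  # keyed by smallest leaf (representative)
    sizes: dict[str, int] = {}
    for i, a in enumerate(labels):
        clusters[a] = TreeNode(height=0.0, name=a)
        sizes[a] = 1
        for j in range(i + 1, len(labels)):
            dist[frozenset((a, labels[j]))] = float(d[i, j])

    while len(clusters) > 1:
        # closest pair; ties resolved on the lexicographically smallest
        # (rep_a, rep_b) pair
        best = min(
            dist.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0])))
        )
        pair, d_min = best
        a, b = sorted(pair)
        height = d_min / 2.0
        merged = TreeNode(
            height=height, children=(clusters[a], clusters[b])
        )
        n_a, n_b = sizes[a], sizes[b]
        others = [k for k in clusters if k not in (a, b)]
        for k in others:
            d_new = (
                n_a * dist[frozenset((a, k))] + n_b * dist[frozenset((b, k))]
            ) / (n_a + n_b)
            dist[frozenset((a, k))] = d_new
            del dist[frozenset((b, k))]
        del dist[pair]
        del clusters[b], sizes[b]
        clusters[a] = merged
        sizes[a] = n_a + n_b
    return next(iter(clusters.values()))


def is_ultrametric(node: TreeNode, tol: float = 1e-10) -> bool:
    """Heights non-decreasing toward the root and leaves at height 0, so all
    root-to-leaf path lengths are equal (within tol)."""
    ok = True

    def walk(n: TreeNode) -> None:
        nonlocal ok
        if n.is_leaf:
            if abs(n.height) > tol:
                ok = False
            return
        for c in n.children:
            if n.height - c.height < -tol:
                ok = False
            walk(c)

    walk(node)
    return ok


def root_bipartition(node: TreeNode) -> tuple[frozenset[str], frozenset[str]]:
    """Leaf sets of the two clades below the root (for a binary root)."""
    if node.is_leaf or len(node.children) != 2:
        raise ValueError("root is not a binary internal node")
    return (
        frozenset(node.children[0].leaves),
        frozenset(node.children[1].leaves),
    )
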