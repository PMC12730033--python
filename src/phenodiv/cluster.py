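"""Genotype grouping: Tocher optimization, UPGMA agglomeration, Mojena cutoff.

Tocher's method is a greedy optimization grouping driven by a single
inclusion limit theta — the largest nearest-neighbour distance over all
genotypes. Starting from the globally closest pair, the unassigned genotype
with the smallest mean distance to the open group joins while that mean stays
within theta; otherwise the group closes and the next one is seeded with the
closest remaining pair. The result is a partition in which within-group mean
distances stay small relative to between-group ones.

UPGMA (average linkage) and the cophenetic matrix are delegated to
scipy.cluster.hierarchy, wrapped in a :class:`MergeTree` that adds Mojena's
dendrogram cutoff (mean + c * SD of the fusion heights) and Newick export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .distance import DistanceMatrix

__all__ = [
    "TocherGroups",
    "MergeTree",
    "MojenaCut",
    "tocher",
    "upgma",
    "mojena_cut",
    "cophenetic",
]


@dataclass
class TocherGroups:
    """Partition produced by Tocher's optimization method."""

    groups: list[list[str]]  #: in formation order
    theta: float  #: inclusion limit (max nearest-neighbour distance)
    within_means: list[float]  #: mean intra-group distance per group (0 for singletons)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def membership(self) -> pd.Series:
        """Genotype -> 1-based group number, in formation order."""
        out = {}
        for gi, members in enumerate(self.groups, start=1):
            for m in members:
                out[m] = gi
        return pd.Series(out, name="group")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": gi,
                "members": "-".join(members),
                "size": len(members),
                "mean_within_distance": self.within_means[gi - 1],
            }
            for gi, members in enumerate(self.groups, start=1)
        ]
        return pd.DataFrame(rows).set_index("group")


def _closest_pair(d: np.ndarray, candidates: list[int], labels: list[str]):
    """Smallest-distance pair among candidates; ties by lexicographic labels."""
    best = None
    for ai in range(len(candidates)):
        for bi in range(ai + 1, len(candidates)):
            i, j = candidates[ai], candidates[bi]
            key = (d[i, j], *sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, (i, j))
    return best[1]


def tocher(dist: DistanceMatrix) -> TocherGroups:
    """Tocher's optimization grouping over a dissimilarity matrix.

    The inclusion limit theta is the maximum over genotypes of their minimum
    off-diagonal distance. Each group is seeded with the closest available
    pair and grows greedily: the unassigned genotype with the smallest mean
    distance to the current group joins iff that mean is <= theta. Ties are
    broken by genotype label for reproducibility. A single remaining genotype
    forms a singleton group.
    """
    labels = dist.labels
    d = dist.values
    n = len(labels)
    if n == 1:
        return TocherGroups(groups=[[labels[0]]], theta=0.0, within_means=[0.0])
    offdiag = d + np.diag([np.inf] * n)
    theta = float(offdiag.min(axis=1).max())

    unassigned = list(range(n))
    groups: list[list[int]] = []
    while unassigned:
        if len(unassigned) == 1:
            groups.append([unassigned.pop()])
            break
        i, j = _closest_pair(d, unassigned, labels)
        group = [i, j]
        unassigned.remove(i)
        unassigned.remove(j)
        while unassigned:
            cand_means = [
                (float(d[c, group].mean()), labels[c], c) for c in unassigned
            ]
            mean_d, _, c = min(cand_means)
            if mean_d <= theta:
                group.append(c)
                unassigned.remove(c)
            else:
                break
        groups.append(group)

    named = [sorted((labels[i] for i in grp)) for grp in groups]
    within = []
    for grp in groups:
        if len(grp) < 2:
            within.append(0.0)
        else:
            sub = d[np.ix_(grp, grp)]
            iu = np.triu_indices(len(grp), k=1)
            within.append(float(sub[iu].mean()))
    return TocherGroups(groups=named, theta=theta, within_means=within)


@dataclass
class MergeTree:
    """A UPGMA dendrogram: scipy linkage matrix plus leaf labels."""

    labels: list[str]
    linkage: np.ndarray  #: (n-1, 4) scipy linkage matrix

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows")
        h = self.heights
        if np.any(np.diff(h) < -1e-9):
            raise ValueError("UPGMA fusion heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        """The n-1 fusion heights, in merge order."""
        return self.linkage[:, 2].copy()

    def cut(self, height: float) -> pd.Series:
        """Cluster labels after removing merges above ``height``."""
        assign = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return pd.Series(assign, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string; node depth = fusion height / 2 (ultrametric)."""
        n = len(self.labels)
        depth = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for row_idx, (a, b, h, _) in enumerate(self.linkage):
            node = n + row_idx
            depth[node] = h / 2.0
            children[node] = (int(a), int(b))

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            a, b = children[node]
            la = depth[node] - depth[a]
            lb = depth[node] - depth[b]
            return f"({render(a)}:{la:.6g},{render(b)}:{lb:.6g})"

        return render(2 * n - 2) + ";"


@dataclass
class MojenaCut:
    """Mojena's relative-height dendrogram cutoff and resulting clusters."""

    cutoff: float
    c: float
    mean_height: float
    sd_height: float
    clusters: pd.Series  #: genotype -> cluster id

    @property
    def n_groups(self) -> int:
        return int(self.clusters.nunique())


def upgma(dist: DistanceMatrix) -> MergeTree:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix."""
    if len(dist.labels) < 2:
        raise ValueError("need at least two genotypes to cluster")
    z = hierarchy.linkage(dist.condensed(), method="average")
    return MergeTree(labels=list(dist.labels), linkage=z)


def mojena_cut(tree: MergeTree, c: float = 1.25) -> MojenaCut:
    """Cut a dendrogram at mean + c * SD of its fusion heights.

    The statistics use all n-1 fusion heights with the sample (n-1
    denominator) standard deviation; with a single merge the SD is taken as
    0. The default constant c = 1.25 is the value recommended in the
    follow-up literature on the stopping rule.
    """
    h = tree.heights
    mean_h = float(h.mean())
    sd_h = float(h.std(ddof=1)) if len(h) > 1 else 0.0
    cutoff = mean_h + c * sd_h
    clusters = tree.cut(cutoff)
    return MojenaCut(
        cutoff=cutoff, c=c, mean_height=mean_h, sd_height=sd_h, clusters=clusters
    )


def cophenetic(tree: MergeTree) -> DistanceMatrix:
    """Cophenetic distances (pairwise fusion heights) of a dendrogram."""
    from scipy.spatial.distance import squareform

    coph = hierarchy.cophenet(tree.linkage)
    return DistanceMatrix(
        labels=list(tree.labels), values=squareform(coph), metric="cophenetic"
    )
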