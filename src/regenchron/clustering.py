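"""Correlation-distance clustering of time points with resampling support.

Time points are clustered on ``1 - Pearson's r`` between their
replicate-averaged log2 profiles (correlation taken across probes), with
unweighted average linkage (UPGMA).  Support for the tree's internal
bipartitions comes from two probe-resampling schemes: ordinary bootstrap
proportions on the full-data tree, and a jackknife majority-rule
consensus built from trees on repeated half-subsamples of probes.

Merge ties are broken by the lexicographically smallest pair of cluster
representatives (each cluster represented by its earliest day), making
trees reproducible across platforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tree structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeNode:
    """A node of a rooted cluster tree; leaves carry a day label."""

    height: float
    label: float | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_set(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.label])
        out: set = set()
        for ch in self.children:
            out |= ch.leaf_set()
        return frozenset(out)


@dataclass
class ClusterTree:
    """Rooted merge tree over time points with merge heights."""

    root: TreeNode
    leaves: tuple[float, ...]

    def clades(self) -> dict[frozenset, float]:
        """Internal-node leaf sets (size >= 2, root included) -> merge height."""
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            members = frozenset().union(*(walk(ch) for ch in node.children))
            out[members] = node.height
            return members

        walk(self.root)
        return out

    def to_newick(self, support: dict[frozenset, float] | None = None) -> str:
        """Newick string; internal labels carry support values when given."""

        def fmt_leaf(label: float) -> str:
            return f"{label:g}"

        def walk(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                s = fmt_leaf(node.label)
            else:
                inner = ",".join(walk(ch, node.height) for ch in node.children)
                label = ""
                if support is not None:
                    val = support.get(node.leaf_set())
                    if val is not None:
                        label = f"{val:.3f}"
                s = f"({inner}){label}"
            if parent_height is not None:
                s += f":{max(parent_height - node.height, 0.0):.6g}"
            return s

        return walk(self.root, None) + ";"


@dataclass
class SupportedTree:
    """A cluster tree plus per-internal-bipartition resampling support."""

    tree: ClusterTree
    support: dict[frozenset, float]
    n_iterations: int
    method: str


# ---------------------------------------------------------------------------
# profiles and distances
# ---------------------------------------------------------------------------

def mean_profiles(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged log2 profile per (probe, day), days in order."""
    day_of = samples.set_index("sample_id")["day"]
    missing = set(matrix.columns) - set(day_of.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    grouped = matrix.T.groupby(day_of.loc[matrix.columns]).mean().T
    return grouped[sorted(grouped.columns)]


def _distance_from_profiles(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between day columns, over probe rows.

    Every probe is an observation, including probes constant across
    days (their level still informs the column correlation); a day
    column constant across probes leaves the correlation undefined and
    is an error.
    """
    if values.shape[0] < 2:
        raise ValueError("need >= 2 probes to correlate day columns")
    if (values.std(axis=0) == 0).any():
        raise ValueError("a day column has zero variance across probes; correlation undefined")
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip((dist + dist.T) / 2.0, 0.0, 2.0)


def pearson_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Day x day matrix of ``1 - r`` distances from a profile matrix."""
    dist = _distance_from_profiles(profiles.to_numpy(dtype=float))
    return pd.DataFrame(dist, index=profiles.columns, columns=profiles.columns)


# ---------------------------------------------------------------------------
# average-linkage agglomeration
# ---------------------------------------------------------------------------

def average_linkage_tree(distances: pd.DataFrame) -> ClusterTree:
    """UPGMA agglomeration of the day x day distance matrix.

    At every step the closest cluster pair merges at its current
    distance; the merged cluster's distance to any other is the
    unweighted mean of all cross-pair leaf distances.  Ties are broken
    by the smallest (representative_i, representative_j) day pair.
    """
    labels = list(distances.columns)
    if len(labels) < 2:
        raise ValueError("need >= 2 leaves to cluster")
    D = distances.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in nodes}
    reps = {i: labels[i] for i in nodes}  # earliest day in the cluster
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(len(labels)) for j in range(i + 1, len(labels))
    }
    next_id = len(labels)

    while len(nodes) > 1:
        best: tuple[float, tuple[float, float], tuple[int, int]] | None = None
        for (i, j), d in dist.items():
            key = tuple(sorted((reps[i], reps[j])))
            cand = (d, key, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, _, (i, j) = best
        merged = TreeNode(height=d, children=(nodes[i], nodes[j]))
        new_id = next_id
        next_id += 1
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(new_id, k), max(new_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        del nodes[i], nodes[j]
        sizes[new_id] = sizes.pop(i) + sizes.pop(j)
        reps[new_id] = min(reps.pop(i), reps.pop(j))
        nodes[new_id] = merged

    (root,) = nodes.values()
    return ClusterTree(root=root, leaves=tuple(sorted(labels)))


def first_bifurcation_groups(tree: ClusterTree) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """The two leaf groups separated by the highest (root) split."""
    if tree.root.is_leaf or len(tree.root.children) != 2:
        raise ValueError("tree root is not a bifurcation")
    g1, g2 = (tuple(sorted(ch.leaf_set())) for ch in tree.root.children)
    return (g1, g2) if g1 <= g2 else (g2, g1)


# ---------------------------------------------------------------------------
# resampling support
# ---------------------------------------------------------------------------

def _build_consensus(
    leaves: Sequence[float],
    freq: dict[frozenset, float],
    heights: dict[frozenset, float],
    threshold: float = 0.5,
) -> tuple[ClusterTree, dict[frozenset, float]]:
    """Majority-rule consensus: nest all clades with frequency > threshold."""
    full = frozenset(leaves)
    majority = {c: f for c, f in freq.items() if f > threshold and len(c) >= 2}
    majority.setdefault(full, 1.0)
    top: dict[frozenset, TreeNode] = {
        frozenset([leaf]): TreeNode(height=0.0, label=leaf) for leaf in leaves
    }
    for clade in sorted(majority, key=lambda c: (len(c), sorted(c))):
        inside = {s: n for s, n in top.items() if s <= clade}
        if frozenset().union(*inside) != clade:
            raise ValueError("incompatible majority clades; consensus impossible")
        children = tuple(inside[s] for s in sorted(inside, key=lambda s: sorted(s)))
        node = TreeNode(
            height=heights.get(clade, max(ch.height for ch in children)),
            children=children,
        )
        for s in inside:
            del top[s]
        top[clade] = node
    root = top[full]
    support = {c: majority[c] for c in majority}
    return ClusterTree(root=root, leaves=tuple(sorted(leaves))), support


def jackknife_consensus(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    n_iter: int = 1000,
    keep_fraction: float = 0.5,
    seed: int | None = None,
) -> SupportedTree:
    """Majority-rule consensus over trees from probe half-subsamples.

    Each iteration keeps ``floor(keep_fraction * n_probes)`` probes
    sampled without replacement, rebuilds the day tree, and records its
    bipartitions.  The consensus contains every bipartition appearing in
    more than half of the iteration trees, annotated with its frequency;
    consensus node heights are the mean merge heights over the trees
    containing the bipartition.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    profiles = mean_profiles(matrix, samples)
    values = profiles.to_numpy(dtype=float)
    n_probes = values.shape[0]
    if n_probes < 4:
        raise ValueError("need >= 4 probes to jackknife")
    k = max(2, math.floor(keep_fraction * n_probes))
    rng = np.random.default_rng(seed)
    days = list(profiles.columns)

    counts: dict[frozenset, int] = {}
    height_sums: dict[frozenset, float] = {}
    for _ in range(n_iter):
        idx = rng.choice(n_probes, size=k, replace=False)
        dist = _distance_from_profiles(values[idx])
        tree = average_linkage_tree(pd.DataFrame(dist, index=days, columns=days))
        for clade, h in tree.clades().items():
            counts[clade] = counts.get(clade, 0) + 1
            height_sums[clade] = height_sums.get(clade, 0.0) + h
    freq = {c: n / n_iter for c, n in counts.items()}
    mean_heights = {c: height_sums[c] / counts[c] for c in counts}
    tree, support = _build_consensus(days, freq, mean_heights)
    return SupportedTree(tree=tree, support=support, n_iterations=n_iter, method="jackknife")


def bootstrap_support(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    n_iter: int = 1000,
    seed: int | None = None,
) -> SupportedTree:
    """Ordinary bootstrap support for the full-data tree's bipartitions.

    Probes are resampled with replacement at full size; the support of
    each internal bipartition of the full-data tree is the fraction of
    bootstrap trees containing it.
    """
    profiles = mean_profiles(matrix, samples)
    values = profiles.to_numpy(dtype=float)
    n_probes = values.shape[0]
    days = list(profiles.columns)
    full_tree = average_linkage_tree(pearson_distance_matrix(profiles))
    target = set(full_tree.clades())
    counts = {c: 0 for c in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        idx = rng.integers(0, n_probes, size=n_probes)
        dist = _distance_from_profiles(values[idx])
        tree = average_linkage_tree(pd.DataFrame(dist, index=days, columns=days))
        for clade in tree.clades():
            if clade in counts:
                counts[clade] += 1
    support = {c: counts[c] / n_iter for c in counts}
    return SupportedTree(tree=full_tree, support=support, n_iterations=n_iter, method="bootstrap")
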