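"""Presence/absence profiles, Pearson-correlation distances, UPGMA trees
and bootstrap support.

Family conservation across bacterial phyla is summarized as an occupancy
matrix (fraction of a phylum's species carrying the gene) and categorized
into three verbal classes: *wide* (present in almost all species), *midlow*
(present in roughly half) and *undetected*.  Relationships among families
are drawn from a feature matrix (occupancy fractions or per-position
amino-acid probabilities) via the distance ``d = 1 - r`` (Pearson
correlation of rows), a UPGMA dendrogram, and column-bootstrap clade
support.

UPGMA is implemented directly so merge ties can be broken
lexicographically, making the tree reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "categorize_occupancy",
    "pearson_distance",
    "upgma",
    "UpgmaTree",
    "bootstrap_support",
    "WIDE_MIN",
    "UNDETECTED_MAX",
]

WIDE_MIN = 0.75
UNDETECTED_MAX = 0.25


def categorize_occupancy(
    fraction: float,
    wide_min: float = WIDE_MIN,
    undetected_max: float = UNDETECTED_MAX,
) -> str:
    """Conservation class for one occupancy fraction.

    wide if fraction >= ``wide_min`` (default 0.75); undetected if
    fraction < ``undetected_max`` (default 0.25); midlow otherwise — the
    bands are symmetric around the ~50% occupancy that defines mid-low
    conservation.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"occupancy fraction outside [0, 1]: {fraction}")
    if not 0 <= undetected_max <= wide_min <= 1:
        raise ValueError("thresholds must satisfy 0 <= undetected_max <= wide_min <= 1")
    if fraction >= wide_min:
        return "wide"
    if fraction < undetected_max:
        return "undetected"
    return "midlow"


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise row distances ``d(i, j) = 1 - r(i, j)`` (Pearson).

    Values lie in [0, 2]; the diagonal is exactly 0.  Rows with zero
    variance are rejected by name (their correlation is undefined).
    """
    x = matrix.to_numpy(float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a matrix with >= 2 rows and >= 2 columns")
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values")
    var = x.var(axis=1)
    dead = [str(matrix.index[i]) for i in np.nonzero(var == 0)[0]]
    if dead:
        raise ValueError(f"zero-variance rows: {dead}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class _Node:
    name: str | None  # leaf name, None for internal
    children: tuple  # () for leaves, else (left, right)
    height: float  # root-to-leaf distance below this node

    @property
    def leaves(self) -> frozenset:
        if self.name is not None:
            return frozenset([self.name])
        return self.children[0].leaves | self.children[1].leaves

    def newick(self, parent_height: float | None = None) -> str:
        length = (
            "" if parent_height is None else f":{parent_height - self.height:.6g}"
        )
        if self.name is not None:
            return f"{self.name}{length}"
        inner = ",".join(c.newick(self.height) for c in self.children)
        return f"({inner}){length}"


@dataclass
class UpgmaTree:
    """Rooted ultrametric tree from UPGMA with convenience accessors."""

    root: _Node
    taxa: tuple[str, ...]

    def newick(self) -> str:
        return self.root.newick() + ";"

    def clades(self) -> set[frozenset]:
        """Leaf sets of all internal nodes (excluding root and leaves)."""
        out: set[frozenset] = set()

        def walk(node: _Node):
            if node.name is not None:
                return
            if node is not self.root:
                out.add(node.leaves)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Canonical bipartitions: each clade or its complement, whichever
        contains the alphabetically first taxon is dropped (root-invariant)."""
        all_taxa = frozenset(self.taxa)
        first = min(self.taxa)
        return {
            all_taxa - clade if first in clade else clade
            for clade in self.clades()
        }

    def cophenetic(self) -> pd.DataFrame:
        """Tree-induced distances: twice the height of the lowest common
        ancestor of each leaf pair."""
        taxa = sorted(self.taxa)
        d = pd.DataFrame(0.0, index=taxa, columns=taxa)

        def walk(node: _Node):
            if node.name is not None:
                return
            left, right = node.children
            for a in left.leaves:
                for b in right.leaves:
                    d.loc[a, b] = d.loc[b, a] = 2.0 * node.height
            walk(left)
            walk(right)

        walk(self.root)
        return d


def upgma(distances: pd.DataFrame) -> UpgmaTree:
    """UPGMA (average-linkage) clustering of a symmetric distance matrix.

    The closest pair is merged at each step; the merged cluster's distance
    to the rest is the size-weighted mean over member pairs; branch lengths
    place every leaf at half the merge distance below each internal node.
    Equal-distance merges pick the pair whose sorted member names are
    lexicographically smallest, so the tree is reproducible.
    """
    d = distances.to_numpy(float)
    names = [str(i) for i in distances.index]
    if len(names) != len(set(names)):
        raise ValueError("duplicate taxon names")
    if d.shape[0] != d.shape[1] or list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    n = len(names)
    if n < 2:
        raise ValueError("need at least two taxa")

    clusters: dict[tuple[str, ...], _Node] = {
        (nm,): _Node(name=nm, children=(), height=0.0) for nm in names
    }
    sizes = {(nm,): 1 for nm in names}
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset([(names[i],), (names[j],)])] = d[i, j]

    while len(clusters) > 1:
        best = min(
            (
                (dist[frozenset([a, b])], tuple(sorted((a, b))))
                for a in clusters
                for b in clusters
                if a < b
            ),
            key=lambda t: (t[0], t[1]),
        )
        h, (a, b) = best
        node = _Node(
            name=None,
            children=(clusters[a], clusters[b]),
            height=h / 2.0,
        )
        merged = tuple(sorted(a + b))
        for c in list(clusters):
            if c in (a, b):
                continue
            da = dist.pop(frozenset([a, c]))
            db = dist.pop(frozenset([b, c]))
            dist[frozenset([merged, c])] = (sizes[a] * da + sizes[b] * db) / (
                sizes[a] + sizes[b]
            )
        dist.pop(frozenset([a, b]))
        del clusters[a], clusters[b]
        clusters[merged] = node
        sizes[merged] = sizes.pop(a) + sizes.pop(b)

    (root,) = clusters.values()
    return UpgmaTree(root=root, taxa=tuple(sorted(names)))


def bootstrap_support(
    matrix: pd.DataFrame,
    n_replicates: int = 100,
    seed: int = 0,
) -> Mapping[frozenset, float]:
    """Column-bootstrap support for the clades of the UPGMA tree.

    Columns (characters) are resampled with replacement ``n_replicates``
    times; for each replicate the Pearson-distance UPGMA tree is rebuilt and
    every original clade is scored 1 when its bipartition reappears.
    Deterministic for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if matrix.shape[1] < 2:
        raise ValueError("bootstrap needs >= 2 columns")
    rng = np.random.default_rng(seed)
    base = upgma(pearson_distance(matrix))
    all_taxa = frozenset(base.taxa)
    first = min(base.taxa)

    def canon(clade: frozenset) -> frozenset:
        return all_taxa - clade if first in clade else clade

    counts = {clade: 0 for clade in base.clades()}
    x = matrix.to_numpy(float)
    n_cols = x.shape[1]
    done = 0
    while done < n_replicates:
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = pd.DataFrame(x[:, cols], index=matrix.index)
        try:
            rep = upgma(pearson_distance(resampled))
        except ValueError:  # a replicate can draw constant rows; redraw
            continue
        rep_bips = rep.bipartitions()
        for clade in counts:
            if canon(clade) in rep_bips:
                counts[clade] += 1
        done += 1
    return {clade: c / n_replicates for clade, c in counts.items()}
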