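"""Amino-acid composition vectors, family clustering and groupwise ANOVA.

Families are summarized by their pooled relative amino-acid frequencies
(20-vectors summing to 1).  Two comparisons are made across families:

* hierarchical clustering of the log2-transformed frequency vectors
  (complete linkage, Euclidean distance), which separates RNA MTases from
  enzymes acting on other substrates;
* per-residue one-way ANOVA across substrate groups (16S, 23S, tRNA,
  non-RNA) with Bonferroni correction over the 20 residues, reporting group
  means so the direction of an enrichment (e.g. the elevated K/R content of
  RNA-binding enzymes) is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from mtevol.profiles import AA_ALPHABET

__all__ = [
    "CompositionTable",
    "aa_frequencies",
    "cluster_families",
    "groupwise_anova",
]

GROUPS = ("16S", "23S", "tRNA", "non-RNA")


@dataclass
class CompositionTable:
    """Family x 20-residue relative-frequency table with group labels."""

    frame: pd.DataFrame  # index: family; columns: the 20 residues
    groups: pd.Series  # family -> group label

    def __post_init__(self):
        if list(self.frame.columns) != list(AA_ALPHABET):
            raise ValueError("columns must be the 20 standard residues in order")
        sums = self.frame.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums.index[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
            raise ValueError(f"rows must sum to 1: {bad}")
        if (self.frame.values < 0).any():
            raise ValueError("negative frequencies")
        if not self.groups.index.equals(self.frame.index):
            raise ValueError("group labels must cover exactly the table rows")


def aa_frequencies(sequences: Iterable[str]) -> np.ndarray:
    """Pooled relative amino-acid frequencies over a protein collection.

    Counts are pooled over all members; ambiguity codes and gaps are excluded
    from both numerator and denominator.  The division is done in exact
    rational arithmetic so the returned vector sums to 1 exactly.
    """
    counts = {a: 0 for a in AA_ALPHABET}
    total = 0
    n_seqs = 0
    for seq in sequences:
        n_seqs += 1
        for c in str(seq).upper():
            if c in counts:
                counts[c] += 1
                total += 1
    if n_seqs == 0:
        raise ValueError("empty sequence collection")
    if total == 0:
        raise ValueError("no standard residues in collection")
    fracs = [Fraction(counts[a], total) for a in AA_ALPHABET]
    assert sum(fracs) == 1
    return np.array([float(f) for f in fracs])


def cluster_families(
    table: CompositionTable, floor: float = 1e-4
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Complete-linkage hierarchical clustering of log2 composition vectors.

    Frequencies are transformed to ``log2(max(freq, floor))`` before
    computing Euclidean distances.  Returns the scipy linkage matrix, the
    leaf order (family names, dendrogram order) and the transformed matrix
    reordered to match.  Ties in merge distance are resolved by scipy's
    deterministic ordering of the condensed distance matrix, with rows
    pre-sorted by family name for reproducibility.
    """
    if floor <= 0:
        raise ValueError("floor must be positive (guards log2 of zero)")
    if len(table.frame) < 2:
        raise ValueError("need at least 2 families to cluster")
    frame = table.frame.sort_index()
    logged = np.log2(np.maximum(frame.to_numpy(float), floor))
    linkage = hierarchy.linkage(pdist(logged, metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(linkage)
    leaves = [frame.index[i] for i in order]
    heat = pd.DataFrame(logged[order], index=leaves, columns=list(AA_ALPHABET))
    return linkage, leaves, heat


def root_split(linkage: np.ndarray, families: Sequence[str]) -> tuple[set, set]:
    """The two family sets joined by the final (root) merge of a dendrogram."""
    n = len(families)
    members: dict[int, set] = {i: {families[i]} for i in range(n)}
    for k, (a, b, _, _) in enumerate(linkage):
        members[n + k] = members[int(a)] | members[int(b)]
    a, b = int(linkage[-1, 0]), int(linkage[-1, 1])
    return members[a], members[b]


def linkage_to_newick(linkage: np.ndarray, leaves: Sequence[str]) -> str:
    """Newick string with merge heights encoded as branch lengths."""
    n = len(leaves)
    height = {i: 0.0 for i in range(n)}
    node = {i: str(leaves[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        node[n + k] = (
            f"({node[a]}:{h / 2 - height[a]:.6g},{node[b]}:{h / 2 - height[b]:.6g})"
        )
        height[n + k] = h / 2
    return node[n + len(linkage) - 1] + ";"


def groupwise_anova(
    table: CompositionTable,
    alpha: float = 0.05,
    n_tests: int = 20,
) -> pd.DataFrame:
    """Per-residue one-way ANOVA across groups with Bonferroni correction.

    For each of the 20 residues, a fixed-effects one-way ANOVA compares the
    family frequencies across groups; a residue is flagged significant iff
    ``p < alpha / n_tests``.  Per-group means are included so the direction
    of an effect can be read off.  Groups whose within-variance is zero for
    every residue are reported in the ``degenerate_groups`` attribute of the
    returned frame rather than silently dropped.
    """
    labels = sorted(table.groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = table.groups.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        raise ValueError(f"groups need >= 2 families: {small}")

    degenerate = []
    for g in labels:
        sub = table.frame[table.groups == g]
        if np.allclose(sub.var(axis=0, ddof=1), 0.0):
            degenerate.append(g)

    rows = []
    for aa in AA_ALPHABET:
        samples = [
            table.frame.loc[table.groups == g, aa].to_numpy(float) for g in labels
        ]
        grand = np.concatenate(samples)
        if np.allclose(grand.var(ddof=0), 0.0):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*samples)
        row = {
            "residue": aa,
            "F": float(f_stat),
            "p": float(p),
            "significant": bool(p < alpha / n_tests),
        }
        for g, s in zip(labels, samples):
            row[f"mean_{g}"] = float(s.mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["n_tests"] = n_tests
    out.attrs["degenerate_groups"] = degenerate
    return out
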