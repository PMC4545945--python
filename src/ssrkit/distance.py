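"""Simple-matching dissimilarities and UPGMA dendrograms for marker panels.

The dissimilarity between two accessions is allele-level simple matching:
at each locus typed in both, the two unordered diploid genotypes share 0, 1
or 2 allele copies (counted with multiplicity), scoring 0, 0.5 or 1;
similarity is the mean score over shared loci and distance is
1 - similarity. Allele-level matching is the standard co-dominant
simple-matching coefficient; genotype-level (all-or-nothing) matching is
available via ``level="genotype"``. Missing data are handled by pairwise
deletion.

Trees are built with UPGMA (average linkage with cluster-size-weighted
updates), merge height d/2, so branch lengths sum to the cophenetic
distance. Tie-breaking is deterministic: among minimum-distance pairs the
one whose (smaller label, larger label) pair sorts first is merged, where a
cluster is labelled by its lexicographically smallest leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .markerstats import Call, GenotypeTable


class IncomparablePairError(ValueError):
    """Two accessions share no locus typed in both."""


def _shared_alleles(a: Call, b: Call) -> float:
    """Allele copies shared between two diploid genotypes, with multiplicity."""
    remaining = list(b)
    shared = 0
    for allele in a:
        if allele in remaining:
            remaining.remove(allele)
            shared += 1
    return shared


def simple_matching_distance(
    table: GenotypeTable, acc_i: str, acc_j: str, level: str = "allele"
) -> float:
    ci = table.accession_calls(acc_i)
    cj = table.accession_calls(acc_j)
    scores = []
    for a, b in zip(ci, cj):
        if a is None or b is None:
            continue
        if level == "allele":
            scores.append(_shared_alleles(a, b) / 2.0)
        elif level == "genotype":
            scores.append(1.0 if a == b else 0.0)
        else:
            raise ValueError(f"unknown matching level: {level!r}")
    if not scores:
        raise IncomparablePairError(
            f"accessions {acc_i!r} and {acc_j!r} share no typed locus")
    return 1.0 - float(np.mean(scores))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(l) for l in df.index], df.to_numpy(dtype=float))


def build_distance_matrix(table: GenotypeTable, level: str = "allele") -> DistanceMatrix:
    accs = table.accessions
    if len(accs) < 2:
        raise ValueError("need at least two accessions")
    n = len(accs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = simple_matching_distance(table, accs[i], accs[j], level)
    return DistanceMatrix(list(accs), d)


@dataclass
class TreeNode:
    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]


@dataclass
class UltrametricTree:
    """Rooted binary ultrametric tree; leaf heights 0, root height = half the
    largest cophenetic distance."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self) -> str:
        return _newick(self.root, parent_height=None) + ";"

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise 2 x (height of the lowest common ancestor)."""
        labels = sorted(self.leaf_labels)
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            sides = [walk(c) for c in node.children]
            for ai in range(len(sides)):
                for bi in range(ai + 1, len(sides)):
                    for a in sides[ai]:
                        for b in sides[bi]:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2 * node.height
            return [l for side in sides for l in side]

        walk(self.root)
        return DistanceMatrix(labels, d)


def _quote_label(name: str) -> str:
    if any(c in name for c in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick(node: TreeNode, parent_height: float | None) -> str:
    if node.is_leaf:
        body = _quote_label(node.name)
    else:
        body = "(" + ",".join(_newick(c, node.height) for c in node.children) + ")"
    if parent_height is None:
        return body
    return f"{body}:{parent_height - node.height:.10g}"


def write_newick(tree: UltrametricTree, path=None) -> str:
    text = tree.newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def upgma(D: DistanceMatrix) -> UltrametricTree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Each step merges the pair of clusters at minimum average distance at
    height d/2; distances to the merged cluster are size-weighted means,
    which keeps them equal to the mean of the original pairwise distances.
    Ties are broken by the lexicographically smallest (label, label) pair,
    clusters being labelled by their smallest leaf.
    """
    if len(D.labels) < 2:
        raise ValueError("UPGMA needs at least two leaves")
    if np.isnan(D.values).any():
        raise ValueError("distance matrix contains NaN")

    # cluster state: label (smallest leaf), size, node
    clusters: dict[str, tuple[int, TreeNode]] = {
        lab: (1, TreeNode(height=0.0, name=lab)) for lab in D.labels
    }
    dist: dict[frozenset[str], float] = {}
    labs = list(D.labels)
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            dist[frozenset((labs[i], labs[j]))] = float(D.values[i, j])

    while len(clusters) > 1:
        best = None
        for pair, d in dist.items():
            a, b = sorted(pair)
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        (na, node_a), (nb, node_b) = clusters[a], clusters[b]
        merged_label = min(a, b)
        merged = TreeNode(height=d / 2.0, children=(node_a, node_b))
        for other in list(clusters):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged_label, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        del clusters[a], clusters[b]
        clusters[merged_label] = (na + nb, merged)

    (_, root), = clusters.values()
    return UltrametricTree(root=root)
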