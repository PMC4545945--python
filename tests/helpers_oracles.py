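"""Independent brute-force oracles used to validate ssrkit.

Everything here is deliberately naive and written without reference to the
package internals: a quadratic per-position repeat scanner, a UPGMA that
recomputes average linkage from the original matrix at every step, and a
count-vector search that recovers allele frequencies from a printed gene
diversity value.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

_DNA = "ACGT"


def _primitive(unit: str) -> bool:
    n = len(unit)
    return not any(
        n % d == 0 and unit == unit[:d] * (n // d) for d in range(1, n)
    )


def brute_force_mine(seq: str, min_total: int = 20,
                     unit_lengths=(2, 3, 4, 5, 6),
                     compound_gap: int = 0) -> list[tuple]:
    """Every maximal perfect repeat by testing each (position, unit length).

    Returns tuples (start, end, unit, n_units) with 1-based inclusive
    coordinates, the same filters (leftmost phase, whole units, minimum
    tract length, compound exclusion) applied by exhaustive checking.
    """
    s = seq.upper()
    n = len(s)
    runs = []
    for k in unit_lengths:
        for i in range(n - 2 * k + 1):
            unit = s[i:i + k]
            if any(c not in _DNA for c in unit) or not _primitive(unit):
                continue
            m = 1
            while s[i + m * k:i + (m + 1) * k] == unit:
                m += 1
            if m < 2:
                continue
            # leftmost phase: a run is not maximal if the periodicity
            # continues one base to the left
            if i > 0 and s[i - 1] == s[i - 1 + k] and s[i - 1] in _DNA:
                continue
            if m * k >= min_total:
                runs.append((i + 1, i + m * k, unit, m))
    runs.sort()
    # compound exclusion: drop every run within compound_gap of another
    dropped = set()
    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            if runs[b][0] - runs[a][1] - 1 > compound_gap:
                break
            dropped.add(a)
            dropped.add(b)
    return [r for i, r in enumerate(runs) if i not in dropped]


def upgma_oracle(labels: list[str], matrix) -> dict[frozenset, float]:
    """UPGMA recomputing every cluster distance as the plain mean of the
    ORIGINAL pairwise distances; ties broken by the smallest
    (label, label) pair, clusters labelled by their smallest leaf.

    Returns {frozenset(leaves of clade): merge height} for every internal
    node — a topology-and-heights fingerprint comparable across
    implementations.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters: dict[str, frozenset] = {lab: frozenset([lab]) for lab in labels}
    clades: dict[frozenset, float] = {}

    def avg(A: frozenset, B: frozenset) -> float:
        return sum(matrix[idx[a]][idx[b]] for a in A for b in B) / (len(A) * len(B))

    while len(clusters) > 1:
        best = None
        for a, b in combinations_with_replacement(sorted(clusters), 2):
            if a == b:
                continue
            key = (avg(clusters[a], clusters[b]), a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[min(a, b)] = merged
        clades[merged] = d / 2.0
    return clades


def clades_of(tree) -> dict[frozenset, float]:
    """Same fingerprint extracted from an ssrkit UltrametricTree."""
    out: dict[frozenset, float] = {}

    def walk(node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        leaves = frozenset().union(*(walk(c) for c in node.children))
        out[leaves] = node.height
        return leaves

    walk(tree.root)
    return out


def frequencies_from_printed_he(he_printed: float, n_alleles: int,
                                gene_copies: int) -> tuple[float, ...]:
    """Recover allele frequencies from a printed gene diversity value.

    Gene-counting frequencies are multiples of 1/gene_copies; enumerate
    every composition of gene_copies into n_alleles positive counts and
    return the one whose He = 1 - sum(p^2) is closest to the printed value.
    """
    best = None

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(1, total - parts + 2):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    for comp in compositions(gene_copies, n_alleles):
        p = tuple(c / gene_copies for c in comp)
        he = 1.0 - sum(x * x for x in p)
        err = abs(he - he_printed)
        if best is None or err < best[0]:
            best = (err, tuple(sorted(p)))
    return best[1]
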