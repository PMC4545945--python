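"""Primer-candidate selection and redundancy removal for mined SSR loci.

A mined locus becomes a primer candidate when its repeat tract is long
enough (>= 20 bases by default, i.e. 10 units for di-, 7 for tri-, 5 for
tetra-nucleotide repeats) and both flanks leave room for primer design
(>= 30 bases by default). Because shotgun contigs are redundant, the
candidate source sequences are then clustered greedily: sequences are
visited longest first, and each joins the first cluster whose
representative it matches at >= 90% identity over >= 80% length coverage
(both orientations tried), else founds a new cluster. Cluster
representatives form the non-redundant marker set.

Identity and coverage come from an exact semi-global alignment (end gaps
free) of the shorter sequence against the longer, computed with edlib:
identity is matches over alignment columns; coverage is the aligned span in
the longer sequence over the longer sequence's length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .mining import SSRCatalog, SSRLocus, reverse_complement

_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ClusteringParams:
    identity_threshold: float = 0.90
    coverage_threshold: float = 0.80
    kmer_prefilter: bool = False  # heuristic short-circuit; never changes the partition
    prefilter_k: int = 8

    def __post_init__(self) -> None:
        for v in (self.identity_threshold, self.coverage_threshold):
            if not 0.0 < v <= 1.0:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass
class CandidateLocus:
    """A mined locus with its source sequence and eligibility flags."""

    locus: SSRLocus
    sequence: str | None = None
    length_ok: bool = False
    flanks_ok: bool = False
    non_redundant: bool = True

    @property
    def eligible(self) -> bool:
        return self.length_ok and self.flanks_ok and self.non_redundant


def min_units_required(min_total_length: int, unit_length: int) -> int:
    """Smallest complete-unit count satisfying the tract-length rule.

    ceil(min_total_length / unit_length): 10/7/5/4/4 for unit lengths 2..6
    at the default 20-base minimum.
    """
    return -(-min_total_length // unit_length)


def select_candidates(
    catalog: SSRCatalog,
    min_flank: int = 30,
    min_total_length: int = 20,
    sequences: Mapping[str, str] | None = None,
) -> list[CandidateLocus]:
    """Flag every catalog locus for repeat length and flank room.

    Returns one :class:`CandidateLocus` per input locus with ``length_ok``
    and ``flanks_ok`` set; ``sequences`` (seq_id -> sequence) attaches the
    source record needed for redundancy clustering.
    """
    out = []
    for loc in catalog:
        out.append(CandidateLocus(
            locus=loc,
            sequence=None if sequences is None else sequences.get(loc.seq_id),
            length_ok=loc.total_length >= min_total_length,
            flanks_ok=loc.left_flank >= min_flank and loc.right_flank >= min_flank,
        ))
    return out


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage) of two sequences under end-gap-free alignment.

    The shorter sequence is aligned into the longer (exact edit-distance
    DP, end gaps in the longer free). identity = matches / alignment
    columns; coverage = aligned span in the longer / length of the longer.
    Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    query, target = sorted((a.upper(), b.upper()), key=lambda s: (len(s), s))
    res = edlib.align(query, target, mode="HW", task="path")
    matches = columns = 0
    for num, op in _CIGAR_OP.findall(res["cigar"]):
        columns += int(num)
        if op == "=":
            matches += int(num)
    loc_start, loc_end = res["locations"][0]
    coverage = (loc_end - loc_start + 1) / len(target)
    return matches / columns, coverage


@dataclass
class Cluster:
    cluster_id: int
    representative: str          # member id of the representative (longest)
    members: list[str] = field(default_factory=list)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    params: ClusteringParams | None = None,
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences are sorted by decreasing length (ties by id, then input
    order) and each is compared — in both orientations — against existing
    cluster representatives in cluster-creation order; it joins the first
    cluster meeting both thresholds, else founds its own. Because longer
    sequences are seen first, the founder of every cluster is its longest
    member and serves as representative.
    """
    params = params or ClusteringParams()
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        raise ValueError("greedy_cluster requires at least one sequence")
    order = sorted(range(len(items)),
                   key=lambda i: (-len(items[i][1]), items[i][0], i))

    clusters: list[Cluster] = []
    reps: list[tuple[str, set[str] | None]] = []  # (sequence, prefilter kmers)
    for idx in order:
        sid, seq = items[idx]
        seq_fwd = seq.upper()
        seq_rev = reverse_complement(seq_fwd)
        placed = False
        for cl, (rep_seq, rep_kmers) in zip(clusters, reps):
            if params.kmer_prefilter and rep_kmers is not None:
                qk = _kmers(seq_fwd, params.prefilter_k) | _kmers(seq_rev, params.prefilter_k)
                if not qk & rep_kmers:
                    continue
            for oriented in (seq_fwd, seq_rev):
                ident, cov = pairwise_identity(oriented, rep_seq)
                if ident >= params.identity_threshold and cov >= params.coverage_threshold:
                    cl.members.append(sid)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            clusters.append(Cluster(cluster_id=len(clusters),
                                    representative=sid, members=[sid]))
            reps.append((seq_fwd,
                         _kmers(seq_fwd, params.prefilter_k) if params.kmer_prefilter else None))
    return clusters


def remove_redundancy(
    candidates: Iterable[CandidateLocus],
    params: ClusteringParams | None = None,
) -> list[Cluster]:
    """Cluster the source sequences of length/flank-eligible candidates and
    mark non-representatives redundant (``non_redundant = False``)."""
    cands = [c for c in candidates if c.length_ok and c.flanks_ok]
    seqs: dict[str, str] = {}
    for c in cands:
        if c.sequence is None:
            raise ValueError(f"candidate {c.locus.seq_id} has no source sequence")
        seqs.setdefault(c.locus.seq_id, c.sequence)
    if not seqs:
        return []
    clusters = greedy_cluster(seqs, params)
    rep_ids = {cl.representative for cl in clusters}
    for c in cands:
        c.non_redundant = c.locus.seq_id in rep_ids
    return clusters
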