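"""Detection of maximal perfect microsatellites (SSRs) in nucleotide sequences.

A perfect microsatellite is an uninterrupted tandem repetition of a short
DNA unit; this module mines di- through hexa-nucleotide repeats (unit length
2-6) from assembled sequence, reports each maximal run as an
:class:`SSRLocus`, and summarises the genome-wide distribution by unit
length, canonical motif class and reiteration number.

Conventions
-----------
* Coordinates are 1-based and inclusive in all reported loci and in the TSV
  serialisation; the BED export is 0-based half-open.
* Only whole repeat units count: a trailing or leading partial unit is
  excluded from ``n_units`` and from the coordinates.
* A run is reported once, under its shortest primitive unit: ``(AT)10`` is a
  dinucleotide locus, never a tetranucleotide ``(ATAT)5``.
* Repeat units are normalised to a canonical motif class, the
  lexicographically smallest string among all cyclic rotations of the unit
  and of its reverse complement (so AG, GA, CT and TC all report as AG).
* Two reportable loci separated by at most ``compound_gap`` bases are a
  compound microsatellite; both are dropped (the strictest reading of
  "compound repeats excluded": the default gap of 0 removes adjacent and
  overlapping runs).
* Mononucleotide runs are out of scope by construction: a unit such as
  ``AA`` is not primitive and is never reported.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGT")
# full IUPAC nucleotide alphabet; anything else is a hard error
_IUPAC = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: columns of the locus TSV serialisation, one row per locus
TSV_COLUMNS = [
    "seq_id", "unit", "motif_class", "unit_length", "n_units",
    "start", "end", "total_length", "left_flank", "right_flank",
]


class AlphabetError(ValueError):
    """Sequence or unit contains a character outside the accepted alphabet."""


class InvalidUnitError(ValueError):
    """Repeat unit is not a primitive DNA string of the accepted length."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a whole-number repetition of a shorter string.

    ``AT`` is primitive; ``ACAC`` (= ``AC`` x 2) is not. Primitivity is what
    keeps a dinucleotide run from being double-reported as a tetranucleotide.

    Raises
    ------
    AlphabetError
        If ``unit`` is empty or contains a character outside A/C/G/T.
    """
    if not unit or any(c not in _DNA for c in unit):
        raise AlphabetError(f"not an unambiguous DNA string: {unit!r}")
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonicalize(unit: str) -> str:
    """Canonical motif class of a primitive repeat unit.

    The class representative is the lexicographically smallest string among
    all cyclic rotations of the unit and all cyclic rotations of its reverse
    complement, so strand and phase never split one biological motif into
    several bookkeeping classes (canonicalize("TC") == "AG",
    canonicalize("TA") == "AT"). Idempotent.
    """
    if not is_primitive(unit):
        raise InvalidUnitError(f"unit is not primitive: {unit!r}")
    candidates = _rotations(unit) + _rotations(reverse_complement(unit))
    return min(candidates)


def _rotations(s: str) -> list[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


def enumerate_motif_classes(unit_length: int) -> set[str]:
    """All canonical motif classes for a given unit length, by enumeration.

    The class counts for unit lengths 2..6 are 4, 10, 33, 102 and 350.
    """
    from itertools import product

    classes = set()
    for tup in product("ACGT", repeat=unit_length):
        unit = "".join(tup)
        if is_primitive(unit):
            classes.add(canonicalize(unit))
    return classes


@dataclass(frozen=True)
class MiningConfig:
    """Mining parameters.

    min_total_length
        Minimum repeat tract length in bases (default 20, i.e. 10 units for
        di-, 7 for tri-, 5 for tetra-, 4 for penta- and hexa-nucleotides).
    unit_lengths
        Unit lengths to mine, subset of {2..6}.
    compound_gap
        Maximum gap (bases) between two reportable loci for them to be
        flagged compound and removed; 0 drops adjacent/overlapping runs.
    n_policy
        "break": an ambiguity code (N etc.) terminates any repeat run;
        "reject": raise on any non-ACGT base.
    mask_policy
        "ignore": soft-masked lowercase bases are ordinary bases;
        "break": lowercase bases terminate runs like an N would.
    """

    min_total_length: int = 20
    unit_lengths: frozenset[int] = frozenset({2, 3, 4, 5, 6})
    compound_gap: int = 0
    n_policy: str = "break"
    mask_policy: str = "ignore"

    def __post_init__(self) -> None:
        if not self.unit_lengths or not set(self.unit_lengths) <= {2, 3, 4, 5, 6}:
            raise ValueError("unit_lengths must be a non-empty subset of {2..6}")
        if self.min_total_length < 2 * min(self.unit_lengths):
            raise ValueError("min_total_length must be >= two units")
        if self.n_policy not in ("break", "reject"):
            raise ValueError(f"unknown n_policy: {self.n_policy!r}")
        if self.mask_policy not in ("ignore", "break"):
            raise ValueError(f"unknown mask_policy: {self.mask_policy!r}")


@dataclass(frozen=True, order=True)
class SSRLocus:
    """One maximal perfect repeat: unit as oriented in the sequence,
    canonical motif class, complete-unit count and 1-based inclusive
    coordinates of the complete-unit run."""

    seq_id: str
    start: int
    end: int
    unit: str
    motif_class: str
    n_units: int
    left_flank: int
    right_flank: int

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def total_length(self) -> int:
        return self.end - self.start + 1

    def to_row(self) -> dict:
        return {
            "seq_id": self.seq_id, "unit": self.unit,
            "motif_class": self.motif_class, "unit_length": self.unit_length,
            "n_units": self.n_units, "start": self.start, "end": self.end,
            "total_length": self.total_length,
            "left_flank": self.left_flank, "right_flank": self.right_flank,
        }


def _validate_alphabet(seq: str, config: MiningConfig) -> None:
    bad = set(seq.upper()) - _IUPAC
    if bad:
        raise AlphabetError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    if config.n_policy == "reject" and set(seq.upper()) - _DNA:
        raise AlphabetError("ambiguity codes present and n_policy='reject'")


def mine_sequence(seq_id: str, sequence: str, config: MiningConfig | None = None) -> list[SSRLocus]:
    """All maximal perfect repeats in one sequence, sorted by start.

    A maximal run for unit length k is a maximal k-periodic stretch of the
    sequence; the locus takes the leftmost phase, keeps ``floor(len/k)``
    complete units and must satisfy the minimum tract length. Runs whose
    unit is non-primitive are parses of a shorter-unit run and are skipped.
    Compound loci (pairwise gap <= ``compound_gap``) are removed.
    """
    config = config or MiningConfig()
    if not sequence:
        return []
    _validate_alphabet(sequence, config)

    su = sequence.upper()
    n = len(su)
    if config.mask_policy == "break":
        ok = [su[i] in _DNA and not sequence[i].islower() for i in range(n)]
    else:
        ok = [su[i] in _DNA for i in range(n)]

    raw: list[SSRLocus] = []
    for k in sorted(config.unit_lengths):
        i = 0
        while i + k < n:
            if ok[i] and ok[i + k] and su[i] == su[i + k]:
                j = i
                while j + k < n and ok[j] and ok[j + k] and su[j] == su[j + k]:
                    j += 1
                # k-periodic region [i, j+k-1], leftmost phase starts at i
                region_len = j - i + k
                units = region_len // k
                unit = su[i:i + k]
                if units >= 2 and is_primitive(unit):
                    start0 = i
                    end0 = i + units * k - 1
                    raw.append(SSRLocus(
                        seq_id=seq_id, start=start0 + 1, end=end0 + 1,
                        unit=unit, motif_class=canonicalize(unit),
                        n_units=units,
                        left_flank=start0, right_flank=n - (end0 + 1),
                    ))
                i = j + 1
            else:
                i += 1

    kept = [
        loc for loc in raw
        if loc.total_length >= config.min_total_length
        and loc.unit_length in config.unit_lengths
    ]
    kept.sort(key=lambda l: (l.start, l.end, l.unit))
    return _drop_compound(kept, config.compound_gap)


def _drop_compound(loci: list[SSRLocus], gap: int) -> list[SSRLocus]:
    """Drop every locus within ``gap`` bases of another reportable locus."""
    compound = set()
    for a in range(len(loci)):
        for b in range(a + 1, len(loci)):
            if loci[b].start - loci[a].end - 1 > gap:
                break
            compound.add(a)
            compound.add(b)
    if compound:
        for idx in sorted(compound):
            logger.info("dropping compound locus %s:%d-%d (%s)",
                        loci[idx].seq_id, loci[idx].start, loci[idx].end,
                        loci[idx].unit)
    return [loc for i, loc in enumerate(loci) if i not in compound]


@dataclass
class SSRCatalog:
    """Ordered collection of mined loci with distribution summaries."""

    loci: list[SSRLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.seq_id, l.start))

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def per_class_counts(self) -> Counter:
        return Counter(l.motif_class for l in self.loci)

    def per_unit_length_counts(self) -> Counter:
        return Counter(l.unit_length for l in self.loci)

    def reiteration_histogram(self) -> Counter:
        return Counter(l.n_units for l in self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([l.to_row() for l in self.loci], columns=TSV_COLUMNS)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bed(self, path) -> None:
        """BED export: 0-based half-open, name = unit xN, score = total length."""
        with open(path, "w") as fh:
            for l in self.loci:
                fh.write(f"{l.seq_id}\t{l.start - 1}\t{l.end}\t"
                         f"({l.unit})x{l.n_units}\t{l.total_length}\t+\n")

    @classmethod
    def from_tsv(cls, path) -> "SSRCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "unit": str})
        loci = [
            SSRLocus(seq_id=str(r.seq_id), start=int(r.start), end=int(r.end),
                     unit=r.unit, motif_class=r.motif_class,
                     n_units=int(r.n_units), left_flank=int(r.left_flank),
                     right_flank=int(r.right_flank))
            for r in df.itertuples()
        ]
        return cls(loci)


def mine_fasta(fasta_path, config: MiningConfig | None = None) -> SSRCatalog:
    """Mine every record of a FASTA file into one catalog.

    Duplicate record identifiers are rejected — flank lengths and downstream
    redundancy removal are meaningless if two records share a name.
    """
    config = config or MiningConfig()
    loci: list[SSRLocus] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in FASTA: {rec.id!r}")
        seen.add(rec.id)
        loci.extend(mine_sequence(rec.id, str(rec.seq), config))
    return SSRCatalog(loci)


def summarize_catalog(catalog: SSRCatalog) -> dict:
    """Distribution report: unit-length shares, motif-class shares and the
    reiteration-number histogram.

    Returns a dict with keys ``n_loci``, ``by_unit_length`` (DataFrame:
    count, percent), ``by_motif_class`` (DataFrame: count, percent),
    ``reiteration`` (DataFrame: n_units, count) and ``reiteration_range``
    ((min, max) or None). Percentages of an empty catalog are an empty
    table, never a division by zero.
    """
    n = len(catalog)
    by_k = catalog.per_unit_length_counts()
    by_class = catalog.per_class_counts()
    reiter = catalog.reiteration_histogram()

    def _share_frame(counter: Counter, key: str) -> pd.DataFrame:
        rows = [
            {key: k, "count": c, "percent": 100.0 * c / n}
            for k, c in sorted(counter.items(), key=lambda kv: (-kv[1], str(kv[0])))
        ]
        return pd.DataFrame(rows, columns=[key, "count", "percent"])

    return {
        "n_loci": n,
        "by_unit_length": _share_frame(by_k, "unit_length"),
        "by_motif_class": _share_frame(by_class, "motif_class"),
        "reiteration": pd.DataFrame(
            [{"n_units": k, "count": c} for k, c in sorted(reiter.items())],
            columns=["n_units", "count"],
        ),
        "reiteration_range": (min(reiter), max(reiter)) if reiter else None,
    }
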