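"""Co-dominant marker diversity statistics (Na, Ho, He, PIC).

Input is a diploid genotype table: loci x accessions, each cell an
unordered pair of allele labels (a homozygote repeats its label) or
missing. Allele frequencies are estimated by gene counting over the
2 x n_typed gene copies present at a locus, with n_typed computed per
locus so that loci with missing calls are handled exactly.

Statistics per locus
--------------------
Na   number of distinct alleles observed
Ho   observed heterozygosity, the fraction of typed accessions carrying
     two distinct alleles
He   gene diversity (expected heterozygosity), 1 - sum(p_i^2)
PIC  polymorphism information content,
     1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2
     (always <= He, with equality only for a monomorphic locus; for a
     biallelic locus PIC = He - 2 p^2 q^2 exactly)

No small-sample (2n/(2n-1)) correction is applied to He: the uncorrected
estimator is the convention of the marker-analysis software family these
summaries mirror. Reported values are rounded to 4 decimals by
round-half-even; all arithmetic is double precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_TOKENS = {"-", "NA", "N/A", "", "."}

Call = tuple[str, str] | None


class NoDataError(ValueError):
    """A locus has no non-missing genotype call."""


def _round4(x: float) -> float:
    return round(float(x), 4)


@dataclass
class GenotypeTable:
    """Loci x accessions diploid co-dominant genotype calls.

    ``calls[locus][accession]`` is an unordered pair of allele labels or
    ``None`` for missing. Allele labels are arbitrary strings (fragment
    sizes are fine).
    """

    loci: list[str]
    accessions: list[str]
    calls: dict[str, dict[str, Call]]
    motif_map: dict[str, str] | None = None

    def locus_calls(self, locus: str) -> list[Call]:
        row = self.calls[locus]
        return [row[a] for a in self.accessions]

    def accession_calls(self, accession: str) -> list[Call]:
        return [self.calls[l][accession] for l in self.loci]

    @classmethod
    def from_tsv(cls, path, motif_map_path=None) -> "GenotypeTable":
        """Read the genotype TSV dialect: first column locus ID, one column
        per accession, cells ``A/B`` (``A/A`` homozygote), ``-``/``NA``
        missing."""
        df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
        loci = [str(i) for i in df.index]
        accessions = [str(c) for c in df.columns]
        calls: dict[str, dict[str, Call]] = {}
        for locus, row in zip(loci, df.itertuples(index=False)):
            calls[locus] = {
                acc: parse_call(cell) for acc, cell in zip(accessions, row)
            }
        motif_map = None
        if motif_map_path is not None:
            mm = pd.read_csv(motif_map_path, sep="\t", dtype=str, index_col=0)
            motif_map = {str(k): str(v) for k, v in mm.iloc[:, 0].items()}
        return cls(loci, accessions, calls, motif_map)

    def to_tsv(self, path) -> None:
        rows = {}
        for locus in self.loci:
            rows[locus] = {
                acc: "-" if c is None else f"{c[0]}/{c[1]}"
                for acc, c in self.calls[locus].items()
            }
        df = pd.DataFrame.from_dict(rows, orient="index")[self.accessions]
        df.index.name = "locus"
        df.to_csv(path, sep="\t")


def parse_call(cell) -> Call:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text.upper() in MISSING_TOKENS or text in MISSING_TOKENS:
        return None
    parts = text.split("/")
    if len(parts) != 2 or not all(p.strip() for p in parts):
        raise ValueError(f"malformed genotype call: {cell!r}")
    a, b = (p.strip() for p in parts)
    return tuple(sorted((a, b)))


def allele_frequencies(calls: Iterable[Call]) -> dict[str, float]:
    """Gene-counting allele frequency estimates over 2 x n_typed copies."""
    counts: Counter[str] = Counter()
    n_typed = 0
    for call in calls:
        if call is None:
            continue
        n_typed += 1
        counts[call[0]] += 1
        counts[call[1]] += 1
    if n_typed == 0:
        raise NoDataError("locus has no non-missing calls")
    total = 2 * n_typed
    return {allele: c / total for allele, c in sorted(counts.items())}


def observed_heterozygosity(calls: Iterable[Call]) -> float:
    typed = [c for c in calls if c is not None]
    if not typed:
        raise NoDataError("locus has no non-missing calls")
    return sum(1 for a, b in typed if a != b) / len(typed)


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs,
                   dtype=float)
    if p.size == 0 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    return p


def gene_diversity(freqs) -> float:
    """He = 1 - sum(p_i^2)."""
    p = _check_freqs(freqs)
    return float(1.0 - np.sum(p ** 2))


def pic(freqs) -> float:
    """PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2."""
    p = _check_freqs(freqs)
    sq = p ** 2
    cross = (np.sum(sq) ** 2 - np.sum(sq ** 2))  # 2 * sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(sq) - cross)


@dataclass(frozen=True)
class LocusStats:
    locus: str
    Na: int
    allele_freqs: dict[str, float]
    Ho: float
    He: float
    PIC: float
    n_typed: int


def locus_stats(locus: str, calls: Sequence[Call]) -> LocusStats:
    try:
        freqs = allele_frequencies(calls)
    except NoDataError as e:
        raise NoDataError(f"locus {locus!r}: {e}") from None
    return LocusStats(
        locus=locus,
        Na=len(freqs),
        allele_freqs=freqs,
        Ho=observed_heterozygosity(calls),
        He=gene_diversity(freqs),
        PIC=pic(freqs),
        n_typed=sum(1 for c in calls if c is not None),
    )


@dataclass(frozen=True)
class PanelSummary:
    per_locus: pd.DataFrame       # locus, Na, He, Ho, PIC, n_typed (4 d.p.)
    mean_Na: float
    mean_He: float
    mean_Ho: float
    mean_PIC: float
    total_alleles: int
    n_loci: int
    n_polymorphic: int


def summarize_panel(table: GenotypeTable) -> PanelSummary:
    """Per-locus stats plus unweighted panel means and allele totals.

    Monomorphic loci stay in the per-locus output but are excluded from the
    polymorphic-marker count.
    """
    stats = [locus_stats(l, table.locus_calls(l)) for l in table.loci]
    per_locus = pd.DataFrame({
        "locus": [s.locus for s in stats],
        "Na": [s.Na for s in stats],
        "He": [_round4(s.He) for s in stats],
        "Ho": [_round4(s.Ho) for s in stats],
        "PIC": [_round4(s.PIC) for s in stats],
        "n_typed": [s.n_typed for s in stats],
    })
    return PanelSummary(
        per_locus=per_locus,
        mean_Na=float(np.mean([s.Na for s in stats])),
        mean_He=float(np.mean([s.He for s in stats])),
        mean_Ho=float(np.mean([s.Ho for s in stats])),
        mean_PIC=float(np.mean([s.PIC for s in stats])),
        total_alleles=int(sum(s.Na for s in stats)),
        n_loci=len(stats),
        n_polymorphic=sum(1 for s in stats if s.Na >= 2),
    )


def motif_polymorphism(table: GenotypeTable,
                       motif_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-motif-class polymorphism rates.

    A locus is polymorphic iff it shows Na >= 2 in the panel. Returns a
    DataFrame with columns motif, total, polymorphic, percent (one decimal,
    round-half-even).

    Raises
    ------
    KeyError
        If any locus is missing from the motif map.
    """
    mapping = motif_map if motif_map is not None else table.motif_map
    if mapping is None:
        raise ValueError("no locus -> motif class mapping provided")
    unmapped = [l for l in table.loci if l not in mapping]
    if unmapped:
        raise KeyError(f"loci missing from motif map: {unmapped[:5]}")
    total: Counter[str] = Counter()
    poly: Counter[str] = Counter()
    for locus in table.loci:
        motif = mapping[locus]
        total[motif] += 1
        if len(allele_frequencies(table.locus_calls(locus))) >= 2:
            poly[motif] += 1
    rows = [
        {"motif": m, "total": total[m], "polymorphic": poly[m],
         "percent": round(100.0 * poly[m] / total[m], 1)}
        for m in sorted(total)
    ]
    return pd.DataFrame(rows, columns=["motif", "total", "polymorphic", "percent"])
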