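"""Synthetic inputs with known truth for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* :func:`make_genome` — FASTA-ready sequences with planted perfect SSR loci
  at exactly known coordinates, embedded in repeat-free flanks so a correct
  miner must recover the truth set with recall and precision 1.0;
* :func:`make_panel` — a diploid genotype panel drawn from specified
  allele frequencies under an inbreeding coefficient F (the heterozygote
  probability at a locus is (1 - F) x (1 - sum p_i^2)), mimicking a highly
  self-pollinating crop at high F, with optional missing data;
* :func:`make_amplification_matrix` — Bernoulli amplification outcomes per
  species with specified success probabilities.

Truth accompanying each output is sufficient to score the corresponding
analysis module by direct comparison, without re-deriving anything.

Defaults mirror the study design these fixtures emulate: a genotype panel
of 93 loci x 23 accessions, strongly selfing (F = 0.9), and a
transferability panel of 93 markers x 9 species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .markerstats import GenotypeTable, gene_diversity, pic
from .mining import TSV_COLUMNS, canonicalize, is_primitive
from .transfer import AmplificationMatrix

_BASES = "ACGT"


class SpecError(ValueError):
    """A generator spec is internally inconsistent."""


# ---------------------------------------------------------------------------
# planted genomes


@dataclass(frozen=True)
class PlantedLocus:
    unit: str
    n_units: int

    def __post_init__(self) -> None:
        if not (2 <= len(self.unit) <= 6) or not is_primitive(self.unit):
            raise SpecError(f"planted unit must be primitive, length 2-6: {self.unit!r}")
        if self.n_units < 2:
            raise SpecError("planted loci need at least 2 units")


@dataclass(frozen=True)
class GenomeSpec:
    """Planted loci are distributed round-robin over ``n_sequences``
    sequences; every locus is padded by ``flank`` repeat-free bases on each
    side, one shared segment between neighbours, so consecutive loci on one
    sequence are separated by exactly ``flank`` non-periodic bases (>= 31,
    far above any reasonable compound gap)."""

    plants: tuple[PlantedLocus, ...]
    n_sequences: int = 1
    flank: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise SpecError("n_sequences must be >= 1")
        if self.flank < 31:
            raise SpecError("flank must be >= 31 to guarantee primer room")


def _max_run_length(seq: str) -> int:
    """Longest perfect tandem tract (complete units, unit length 2-6) in
    ``seq``. Small independent scanner used only to certify that generated
    flanks are repeat-free."""
    best = 0
    n = len(seq)
    for k in range(2, 7):
        i = 0
        while i + k < n:
            if seq[i] == seq[i + k]:
                j = i
                while j + k < n and seq[j] == seq[j + k]:
                    j += 1
                units = (j - i + k) // k
                if units >= 2:
                    best = max(best, units * k)
                i = j + 1
            else:
                i += 1
    return best


def _repeat_free_segment(rng: np.random.Generator, length: int,
                         forbid_first: str = "", forbid_last: str = "") -> str:
    """Random segment with no tandem tract of 8+ bases, first/last base
    constrained so the segment can never extend an adjacent planted run."""
    for _ in range(1000):
        seg = "".join(rng.choice(list(_BASES), size=length))
        if forbid_first and seg[0] in forbid_first:
            continue
        if forbid_last and seg[-1] in forbid_last:
            continue
        if _max_run_length(seg) < 8:
            return seg
    raise SpecError("could not generate a repeat-free flank")  # pragma: no cover


def make_genome(spec: GenomeSpec) -> tuple[dict[str, str], pd.DataFrame]:
    """(sequences, truth) for a genome with planted SSRs.

    ``truth`` uses the mining TSV dialect (1-based inclusive coordinates),
    so recall/precision against a mined catalog is a set comparison.
    Deterministic given the spec (which includes the seed).
    """
    rng = np.random.default_rng(spec.seed)
    per_seq: list[list[PlantedLocus]] = [[] for _ in range(spec.n_sequences)]
    for i, plant in enumerate(spec.plants):
        per_seq[i % spec.n_sequences].append(plant)

    sequences: dict[str, str] = {}
    truth_rows = []
    for s, plants in enumerate(per_seq):
        seq_id = f"synth_{s + 1}"
        parts: list[str] = []
        pos = 0  # 0-based length so far
        pending: list[tuple[PlantedLocus, int]] = []
        for p, plant in enumerate(plants):
            tract = plant.unit * plant.n_units
            # left pad: may not end with the unit's last base (no phase shift)
            # nor begin adjacent to the previous tract's first base
            prev_first = plants[p - 1].unit[0] if p else ""
            parts.append(_repeat_free_segment(
                rng, spec.flank, forbid_first=prev_first,
                forbid_last=plant.unit[-1]))
            pos += spec.flank
            pending.append((plant, pos))
            parts.append(tract)
            pos += len(tract)
        last_first = plants[-1].unit[0] if plants else ""
        parts.append(_repeat_free_segment(rng, spec.flank, forbid_first=last_first))
        pos += spec.flank
        seq = "".join(parts)
        sequences[seq_id] = seq
        for plant, start0 in pending:
            total = len(plant.unit) * plant.n_units
            truth_rows.append({
                "seq_id": seq_id, "unit": plant.unit,
                "motif_class": canonicalize(plant.unit),
                "unit_length": len(plant.unit), "n_units": plant.n_units,
                "start": start0 + 1, "end": start0 + total,
                "total_length": total,
                "left_flank": start0, "right_flank": len(seq) - (start0 + total),
            })
    truth = pd.DataFrame(truth_rows, columns=TSV_COLUMNS)
    return sequences, truth


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# genotype panels


@dataclass(frozen=True)
class PanelSpec:
    """Allele-frequency vectors per locus plus an inbreeding coefficient F.

    With probability F an accession's genotype is an identical-by-descent
    homozygote (one allele draw); otherwise two independent allele draws.
    That makes P(het) = (1 - F)(1 - sum p_i^2) per locus, the classical
    inbreeding model. ``freqs`` maps locus -> {allele: frequency}.
    """

    freqs: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]
    n_accessions: int = 23
    F: float = 0.9
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise SpecError("F must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecError("missing_rate must be in [0, 1)")
        for locus, fv in self.freqs:
            p = [f for _, f in fv]
            if not p or any(f < 0 for f in p) or abs(sum(p) - 1.0) > 1e-9:
                raise SpecError(f"invalid frequency vector for locus {locus!r}")

    @classmethod
    def from_dict(cls, freqs: Mapping[str, Mapping[str, float]], **kw) -> "PanelSpec":
        packed = tuple(
            (locus, tuple(sorted(fv.items()))) for locus, fv in freqs.items()
        )
        return cls(freqs=packed, **kw)


def default_panel_spec(n_loci: int = 93, n_accessions: int = 23,
                       F: float = 0.9, missing_rate: float = 0.02,
                       seed: int = 0) -> PanelSpec:
    """A study-shaped panel: biallelic to tetra-allelic loci with Dirichlet
    frequencies, 23 accessions, strong selfing."""
    rng = np.random.default_rng(seed)
    freqs: dict[str, dict[str, float]] = {}
    for i in range(n_loci):
        k = int(rng.choice([2, 2, 2, 3, 4], p=[0.55, 0.1, 0.08, 0.25, 0.02]))
        p = rng.dirichlet(np.ones(k) * 2.0)
        p = p / p.sum()
        freqs[f"L{i + 1:03d}"] = {
            str(150 + 2 * a): float(round(f, 6)) for a, f in enumerate(p)
        }
        # renormalise the rounding drift onto the last allele
        vals = freqs[f"L{i + 1:03d}"]
        last = list(vals)[-1]
        vals[last] = float(vals[last] + (1.0 - sum(vals.values())))
    return PanelSpec.from_dict(freqs, n_accessions=n_accessions, F=F,
                               missing_rate=missing_rate, seed=seed)


def make_panel(spec: PanelSpec) -> tuple[GenotypeTable, pd.DataFrame]:
    """(genotype table, truth) for a synthetic diploid panel.

    Truth rows carry the generating frequencies and the expected He, PIC
    and Ho = (1 - F) He implied by them.
    """
    rng = np.random.default_rng(spec.seed)
    accessions = [f"acc{j + 1:02d}" for j in range(spec.n_accessions)]
    calls: dict[str, dict[str, tuple[str, str] | None]] = {}
    truth_rows = []
    loci = []
    for locus, fv in spec.freqs:
        alleles = [a for a, _ in fv]
        p = np.array([f for _, f in fv])
        row: dict[str, tuple[str, str] | None] = {}
        for acc in accessions:
            if spec.missing_rate and rng.random() < spec.missing_rate:
                row[acc] = None
                continue
            if rng.random() < spec.F:
                a = rng.choice(alleles, p=p)
                row[acc] = (str(a), str(a))
            else:
                g = rng.choice(alleles, p=p, size=2)
                row[acc] = tuple(sorted((str(g[0]), str(g[1]))))
        calls[locus] = row
        loci.append(locus)
        he = gene_diversity(dict(fv))
        truth_rows.append({
            "locus": locus,
            "freqs": ";".join(f"{a}:{f:.6f}" for a, f in fv),
            "expected_He": he, "expected_PIC": pic(dict(fv)),
            "expected_Ho": (1.0 - spec.F) * he,
            "Na_possible": len(alleles),
        })
    table = GenotypeTable(loci=loci, accessions=accessions, calls=calls)
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# amplification matrices


def make_amplification_matrix(
    n_markers: int,
    species_probs: Mapping[str, float],
    seed: int = 0,
    not_tested_rate: float = 0.0,
) -> tuple[AmplificationMatrix, pd.Series]:
    """(matrix, truth) with per-species Bernoulli amplification success.

    ``truth`` is the generating probability vector.
    """
    probs = pd.Series(species_probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise SpecError("species probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    markers = [f"M{i + 1:03d}" for i in range(n_markers)]
    data = {}
    for sp, pr in probs.items():
        col = (rng.random(n_markers) < pr).astype(float)
        if not_tested_rate:
            col[rng.random(n_markers) < not_tested_rate] = np.nan
        data[sp] = col
    df = pd.DataFrame(data, index=markers)
    return AmplificationMatrix(df), probs


# ---------------------------------------------------------------------------
# YAML spec loading (CLI support)


def genome_spec_from_yaml(path, seed: int | None = None) -> GenomeSpec:
    """Schema: {n_sequences: int, flank: int, seed: int,
    plants: [{unit: AT, n_units: 10}, ...]}"""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    plants = tuple(PlantedLocus(p["unit"], int(p["n_units"]))
                   for p in doc.get("plants", []))
    return GenomeSpec(
        plants=plants,
        n_sequences=int(doc.get("n_sequences", 1)),
        flank=int(doc.get("flank", 60)),
        seed=int(doc.get("seed", 0) if seed is None else seed),
    )


def panel_spec_from_yaml(path, seed: int | None = None) -> PanelSpec:
    """Schema: {n_accessions: int, F: float, missing_rate: float, seed: int,
    loci: {locus: {allele: freq, ...}, ...}}"""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PanelSpec.from_dict(
        {str(l): {str(a): float(f) for a, f in fv.items()}
         for l, fv in doc["loci"].items()},
        n_accessions=int(doc.get("n_accessions", 23)),
        F=float(doc.get("F", 0.9)),
        missing_rate=float(doc.get("missing_rate", 0.0)),
        seed=int(doc.get("seed", 0) if seed is None else seed),
    )
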