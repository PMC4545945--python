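"""Mine perfect microsatellites from a small synthetic genome.

Builds two sequences with six planted repeat loci (di- to hexa-nucleotide),
mines them back and prints the catalog plus its distribution summary. Exact
agreement between planted truth and mined coordinates is the expected
outcome: flanks are generated repeat-free.
"""

from ssrkit import (
    GenomeSpec, PlantedLocus, SSRCatalog, make_genome, mine_sequence,
    summarize_catalog,
)

spec = GenomeSpec(
    plants=(PlantedLocus("AT", 12), PlantedLocus("AG", 10),
            PlantedLocus("AAT", 8), PlantedLocus("AAG", 7),
            PlantedLocus("ACAT", 5), PlantedLocus("AACGTC", 4)),
    n_sequences=2, flank=60, seed=42,
)
sequences, truth = make_genome(spec)

catalog = SSRCatalog(
    [locus for sid, seq in sequences.items() for locus in mine_sequence(sid, seq)]
)
print(catalog.to_frame().to_string(index=False))

report = summarize_catalog(catalog)
print(f"\n{report['n_loci']} loci mined; planted: {len(truth)}")
print(report["by_unit_length"].to_string(index=False))
lo, hi = report["reiteration_range"]
print(f"reiteration numbers span {lo}-{hi} complete units")
print("\nEach row is one maximal perfect repeat with 1-based inclusive")
print("coordinates; on genome-survey data the unit-length shares are what")
print("reveals the di-nucleotide dominance typical of plant genomes.")
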