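"""Select primer-ready, non-redundant candidate loci.

Mines a synthetic genome in which one contig is duplicated (as happens
when multi-k assemblies are pooled), applies the repeat-length (>= 20
bases) and flank (>= 30 bases each side) rules, and removes redundancy by
greedy clustering at 90% identity / 80% coverage. The duplicate loses its
non-redundant flag; the original survives.
"""

from ssrkit import (
    ClusteringParams, GenomeSpec, PlantedLocus, SSRCatalog, make_genome,
    mine_sequence, remove_redundancy, select_candidates,
)

spec = GenomeSpec(plants=(PlantedLocus("AG", 11), PlantedLocus("AAT", 7)),
                  n_sequences=2, flank=50, seed=7)
sequences, _ = make_genome(spec)
sequences["synth_1_dup"] = sequences["synth_1"]  # a redundant contig

catalog = SSRCatalog(
    [l for sid, seq in sequences.items() for l in mine_sequence(sid, seq)]
)
candidates = select_candidates(catalog, min_flank=30, min_total_length=20,
                               sequences=sequences)
clusters = remove_redundancy(candidates, ClusteringParams(0.90, 0.80))

for c in candidates:
    print(f"{c.locus.seq_id:>12}  ({c.locus.unit})x{c.locus.n_units:<3}"
          f" length_ok={c.length_ok} flanks_ok={c.flanks_ok}"
          f" non_redundant={c.non_redundant} -> eligible={c.eligible}")
print(f"\n{len(clusters)} sequence clusters; eligible candidates: "
      f"{sum(c.eligible for c in candidates)} of {len(candidates)}")
print("A candidate is primer-ready only when its tract is >= 20 bases,")
print("both flanks >= 30 bases, and its contig is a cluster representative.")
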