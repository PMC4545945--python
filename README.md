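# ssrkit

A toolkit for developing microsatellite (SSR) markers from genome-survey
sequence and analysing the resulting genotype panels. It is aimed at
groups building co-dominant marker sets for non-model crops from shallow
shotgun assemblies: the workflow that turns assembled contigs into a
non-redundant set of primer-ready repeat loci, and a genotyped accession
panel into diversity statistics, dendrograms and cross-species
transferability summaries.

## What it computes

**Repeat mining.** Maximal perfect tandem repeats with primitive units of
length 2–6 (di- to hexa-nucleotide), whole units only, reported once under
the shortest unit with 1-based inclusive coordinates. Repeat units are
normalised to canonical motif classes under cyclic rotation and reverse
complement (AG/GA/CT/TC → AG); there are exactly 4/10/33/102/350 classes
for unit lengths 2–6. Compound (adjacent) repeats are excluded; tract
length < 20 bases is filtered by default.

**Candidate selection.** Primer-ready loci need a tract ≥ 20 bases (10
units for di-, 7 for tri-, 5 for tetra-nucleotides) and ≥ 30 bases of
flank on each side. Redundant source sequences are removed by greedy
incremental clustering (longest first, join the first representative at
≥ 90% identity and ≥ 80% length coverage, both orientations), with exact
alignment underneath.

**Diversity statistics.** For a diploid co-dominant genotype table with
allele frequencies `p_i` estimated by gene counting over `2 × n_typed`
copies per locus:

- gene diversity `He = 1 − Σ p_i²`
- observed heterozygosity `Ho` = fraction of typed accessions with two
  distinct alleles
- polymorphism information content
  `PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²` (always ≤ He; for a biallelic
  locus `PIC = He − 2p²q²` exactly)

plus per-locus `Na`, unweighted panel means and motif-wise polymorphism
rates.

**Clustering of accessions.** Allele-level simple-matching dissimilarity
(each locus scores 0, ½ or 1 shared allele pairs; distance = 1 − mean
score, pairwise deletion for missing data) and a UPGMA dendrogram with
merge height d/2, deterministic tie-breaking and Newick output.

**Transferability.** Per-species transfer percentages, per-marker species
breadth and the fully transferable marker subset from a markers × species
amplification matrix (amplified / not amplified / not tested).

**Synthetic data.** Generators with exact known truth for all of the
above: genomes with planted repeats in repeat-free flanks, genotype panels
drawn at specified allele frequencies under an inbreeding coefficient F,
and Bernoulli amplification matrices.

## Worked example

```python
from ssrkit import default_panel_spec, make_panel, summarize_panel

table, truth = make_panel(default_panel_spec(n_loci=93, n_accessions=23,
                                             F=0.9, missing_rate=0.02, seed=1))
summary = summarize_panel(table)
print(f"loci: {summary.n_loci}  polymorphic: {summary.n_polymorphic}  "
      f"total alleles: {summary.total_alleles}")
print(f"means: Na {summary.mean_Na:.2f}  He {summary.mean_He:.4f}  "
      f"Ho {summary.mean_Ho:.4f}  PIC {summary.mean_PIC:.4f}")
```

prints

```
loci: 93  polymorphic: 93  total alleles: 206
means: Na 2.22  He 0.4223  Ho 0.0469  PIC 0.3439
```

i.e. a 93-locus panel on 23 accessions of a strongly selfing crop: mean
gene diversity ≈ 0.42 but observed heterozygosity only ≈ 0.05, because at
F = 0.9 nine out of ten genotypes are drawn as identical-by-descent
homozygotes. PIC is below He at every locus, as it must be.

The `examples/` directory has one short script per capability
(`mine_repeats.py`, `candidate_selection.py`, `diversity_stats.py`,
`dendrogram.py`, `transferability.py`); each builds a small input, runs the
method and explains the numbers it prints. A thin CLI mirrors the same
stages:

```sh
ssrkit mine genome.fasta --min-length 20 --out loci.tsv
ssrkit select loci.tsv genome.fasta --out candidates.tsv
ssrkit stats genotypes.tsv --out statsdir/
ssrkit tree genotypes.tsv --out tree.nwk
ssrkit transfer amplification.tsv --out transferdir/
ssrkit fixtures genome --spec spec.yaml --out fixturedir/
```

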