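# Methods

## Repeat model and mining algorithm

A microsatellite locus is a maximal perfect tandem repeat: an uninterrupted
run of a primitive DNA unit of length k ∈ {2..6}. "Primitive" means the
unit is not itself a repetition of a shorter string; this single invariant
prevents double-reporting (an (AT)n run has no primitive parse at unit
length 4 or 6) and excludes mononucleotide runs by construction (AA, AAA…
are non-primitive).

The miner scans each unit length for maximal k-periodic regions — maximal
stretches where `s[j] == s[j+k]` — and reports, per region, the leftmost
phase with `floor(length/k)` complete units. Consequences of this
construction:

- **Whole units only.** A trailing or leading partial unit never counts
  toward `n_units` or the coordinates. The alternative (counting partial
  bases in the tract length) is defensible, but integer repeat numbers
  compose more cleanly with unit-count thresholds, so whole-units-only is
  fixed here.
- **Leftmost phase.** Of the k equivalent phases of one run (CACAC could be
  reported as (CA)2 at position 1 or (AC)2 at position 2) exactly one —
  the leftmost — is reported, so no two reported loci of the same motif
  class ever overlap.
- **Maximality.** A region cannot be extended in either direction, so no
  reported run is a sub-run of another with the same unit.

Motif classes are the orbits of primitive units under cyclic rotation and
reverse complement, represented by the lexicographically smallest member.
Exhaustive enumeration gives 4, 10, 33, 102 and 350 classes for unit
lengths 2–6; the test suite verifies these counts and the strand-invariance
of mined (class, n_units, length) multisets.

**Compound exclusion.** Two reportable loci separated by at most
`compound_gap` bases (default 0: adjacent or overlapping) form a compound
microsatellite and both are dropped. The gap threshold is configurable
because field practice varies; 0 is the most conservative reading of
"compound repeats excluded". The rule is applied among loci that already
pass the tract-length filter — a sub-threshold 8-base run next to a
reportable locus does not poison it. Both conventions (threshold-first,
gap 0) are mirrored independently in the brute-force oracle the tests
compare against.

**Ambiguity and masking.** Any non-ACGT IUPAC code breaks a run under the
default `n_policy="break"`; `"reject"` raises instead, for pipelines that
guarantee clean input. Lowercase (soft-masked) bases are ordinary bases by
default; `mask_policy="break"` treats them as run terminators. Non-IUPAC
characters are always a hard error.

Defaults (tract ≥ 20 bases, units 2–6, gap 0) are the standard genome-survey
settings for this marker class; at 20 bases the implied minimum unit counts
are 10/7/5/4/4 for k = 2..6.

## Candidate selection and redundancy removal

Primer-readiness requires tract length ≥ 20 and both flanks ≥ 30 bases —
room for primer design on either side. Redundancy removal re-implements
greedy incremental clustering: sequences sorted by decreasing length (ties
by identifier, then input order), each compared against existing cluster
representatives in creation order and joined to the first that matches,
else founding a new cluster. Since longer sequences are seen first, every
representative is its cluster's longest member. Both orientations are
tried, because shotgun contigs have arbitrary strand.

The match criterion is identity ≥ 0.90 and coverage ≥ 0.80, with:

- **identity** = matches / alignment columns of an exact semi-global
  alignment (edit-distance DP via edlib; end gaps in the longer sequence
  free), shorter sequence aligned into the longer;
- **coverage** = aligned span in the longer sequence / length of the longer
  sequence. An exact 170-base substring of a 200-base sequence scores
  identity 1.0, coverage 0.85.

Defining identity over a minimum-edit-distance alignment (rather than a
match-maximising one) keeps random 200-base pairs far below the 0.90
threshold (empirically ≈ 0.5–0.6) while scoring biologically redundant
pairs correctly; a match-count-maximising alignment would rate unrelated
sequences ≈ 0.65 by construction (the LCS density of random DNA) and make
the threshold meaningless. An optional shared-8-mer prefilter can skip
alignments that cannot plausibly match; it is off by default and tested to
leave the partition unchanged.

## Diversity statistics

Frequencies are gene-counting estimates over `2 × n_typed` copies with
`n_typed` computed per locus, so per-locus missing data are handled exactly
(a panel of 23 with one untyped accession yields Ho values in multiples of
1/22). He = 1 − Σp², PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j², both uncorrected:
no 2n/(2n−1) small-sample factor is applied, matching the estimator
conventions of the classical marker-analysis packages whose outputs these
tables mirror (printed biallelic He/PIC pairs are consistent with the
uncorrected forms). Reported values are rounded to 4 decimals by
round-half-even; comparisons against published tables use ±0.0001 because
some legacy software truncates rather than rounds (0.499055 printed as
0.4990).

Monomorphic loci stay in per-locus output (Na = 1, He = PIC = Ho = 0) but
are excluded from polymorphic-marker counts. Motif-wise polymorphism is
the share of loci per canonical motif class with Na ≥ 2 in the panel.

## Distances and UPGMA

The accession dissimilarity is allele-level simple matching: two diploid
genotypes share 0, 1 or 2 allele copies (multiset intersection), scoring
0, 0.5 or 1; similarity is the mean over loci typed in both accessions
(pairwise deletion — no imputation), distance 1 − similarity. Allele-level
matching is chosen over genotype-level (exact-match) scoring because
half-matches carry real information in co-dominant data; the
genotype-level variant remains available via `level="genotype"`.

UPGMA merges the closest pair at height d/2 and updates distances with
cluster-size weights, which keeps every cluster distance equal to the
plain mean of the original pairwise distances — verified against a
brute-force oracle that recomputes that mean from scratch at every step,
and against scipy's average-linkage implementation. Ties are broken by the
lexicographically smallest (label, label) pair, a cluster being labelled
by its smallest leaf; this makes trees exactly reproducible and
permutation-invariant up to the documented rule. On an ultrametric input
the algorithm reconstructs the input exactly. Newick output uses branch
length = parent height − child height and quotes labels containing
metacharacters; round-tripping through dendropy preserves topology and
patristic distances to 1e-9.

## Transferability

Cells are three-state (amplified / not amplified / not tested) even though
published matrices are usually two-state: real panels distinguish assay
failure from negative amplification, and the two-state case needs no
special handling (plain 1/0 input is valid). Percentages are whole-number
(round-half-even), the granularity such panels are reported at. The
double-counting identity — amplified cells summed by species equal marker
breadths summed by marker — is property-tested.

## Synthetic data

`make_genome` plants specified (unit, n_units) tracts separated by
repeat-free flanks: flank segments are rejection-sampled until they contain
no tandem tract of ≥ 8 bases, and the bases adjoining each planted tract
are constrained (left neighbour ≠ last unit base, right neighbour ≠ first
unit base) so no planted run can extend or shift phase. This guarantees
exact truth coordinates — recall and precision of a correct miner are 1.0
by construction, which is the point: the generator tests coordinate
arithmetic, not detection power on degraded signals. It deliberately does
not emulate imperfect repeats, sequencing error, assembly collapse or
heterozygous assemblies, so passing these fixtures says nothing about
mining behaviour on low-quality assemblies.

`make_panel` draws genotypes under the classical inbreeding model: with
probability F one allele is drawn and duplicated (identical by descent),
else two independent draws, giving P(het) = (1 − F)(1 − Σp²). The default
panel shape is 93 loci × 23 accessions at F = 0.9 with 2% missing data —
the scale and selfing level of the safflower study design this package's
defaults mirror. Truth files carry the generating frequencies and expected
He/PIC/Ho. The generator draws genotypes independently across loci and
accessions: no linkage, population structure or genotyping-error model, so
fixture-based tests validate estimator arithmetic, not robustness to those
effects.

`make_amplification_matrix` draws independent Bernoulli outcomes per
species. All generators are pure functions of (spec, seed) and are tested
for byte-identical reproducibility.

## Problem sizes and numerical choices

The test suite works at desk scale: miner-vs-oracle equivalence on 1,000
random sequences up to 500 bases (AT-biased so repeats actually occur,
minimum tract 10 for statistical power), UPGMA-vs-oracle on 100 random
6-leaf matrices, 10,000 simplex draws for the PIC ≤ He property, panels of
up to 5,000 accessions for frequency-recovery bounds. These sizes give the
properties real exercise while keeping the whole suite around a few
seconds. Genome-scale mining is linear in sequence length per unit length
and handles megabase FASTA without special treatment.

Floating-point policy: statistics in double precision, reported at 4
decimals (round-half-even); frequency vectors validated to sum to 1 within
1e-9; tree heights compared at 1e-9. Degenerate inputs (empty catalog,
all-missing locus, species with no tested marker, NaN distances) raise
typed errors or return explicit empty reports rather than NaN arithmetic.

## Known limitations

- Imperfect and interrupted repeats are out of scope; only perfect,
  whole-unit runs are mined.
- The compound-repeat gap convention (applied post-threshold) is one of
  several defensible readings; both the threshold and the gap are
  configurable.
- Identity/coverage under greedy clustering are one concrete realisation
  of "90% similarity, 80% coverage"; other tools' internal definitions
  differ in detail, so cluster counts can differ at the margin.
- No Hardy–Weinberg testing, F-statistics, linkage disequilibrium,
  bootstrap support or primer thermodynamics — downstream tools own those.
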