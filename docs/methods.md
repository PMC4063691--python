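# Methods and conventions

This note records the models implemented in mlstkit, the conventions
that change digits, and what the synthetic-data validation does and does
not demonstrate.

## Typing model

An MLST scheme is an ordered list of loci, each defined by a primer
pair and an expected amplicon size; the bundled *Leuconostoc lactis*
scheme lists its eight loci alphabetically (carB, groEL, murC, pheS,
pyrG, recA, rpoB, uvrC; amplicons 550–892 bp, 5,325 bp total), and that
order fixes profile-table columns. In-silico trimming locates the
forward primer (fewest mismatches, then leftmost; default budget 1
mismatch, IUPAC-aware) and the reverse-complemented reverse primer
(rightmost after the forward site) in either orientation of the input,
removes both primer sites — sequencing-primer regions are unreliable, a
flag retains them — and checks the fragment length against the scheme
expectation within a configurable tolerance (default 10%, loose because
deposited sequences may or may not include primer regions).

Alleles are exact sequence identities: equal length within a locus
(indels are out of model, matching ungapped site counting), A/C/G/T
only (an IUPAC ambiguity code is a hard error at assignment time, not a
wildcard). Numbering is first-encounter order over the input in open
mode, so identical inputs yield identical numbering, and permuting
isolates permutes only novel numbers, never the partition of isolates
into alleles or STs. Closed mode never mutates the database and signals
novel alleles/STs instead.

## Per-locus statistics

Polymorphic sites are alignment columns with ≥ 2 residues; the SNP
total is their sum over loci; GC% is pooled over all input sequences.

dN/dS uses the Nei–Gojobori (1986) pathway method with Jukes–Cantor
correction d = −(3/4)·ln(1 − (4/3)p). Conventions (each changes the
digits, so they are fixed here):

- synonymous site fraction per codon position = (synonymous changes)/3,
  with changes that create a stop codon counted as nonsynonymous;
- codons differing at 2–3 positions average the step counts over all
  minimal mutational pathways; pathways through a stop codon are
  excluded unless every pathway is blocked (then all are used);
- site counts are averaged over the two sequences; in-frame stop codons
  trigger a warning and the codon pair is skipped;
- locus-level dN, dS are means over unordered pairs of *distinct
  alleles* by default (an allelic-variation summary); `by_isolate`
  weighting averages over all isolate pairs instead — both are exposed
  because published tables rarely state which was used;
- the ratio is reported as 0 when dN = 0 and as "undefined" when
  dS = 0 < dN;
- the reading frame defaults to fragment position 1 with a per-locus
  offset override, since schemes rarely document frames.

A note on tiny comparisons: a pair differing only at a codon with 1/3
synonymous sites has p_S up to 3, outside the Jukes–Cantor domain
(p < 3/4); such comparisons raise a saturation error and should be
inspected uncorrected. The test suite checks the pre-correction
quantities against an exact rational-arithmetic enumeration oracle.

## Linkage disequilibrium

For all n(n−1)/2 isolate pairs, K = number of loci with differing
alleles. V_O is the **population variance** of this mismatch
distribution (denominator = number of pairs): the distribution is
complete, not a sample, and the hand-enumerable 4-isolate perfect-LD
instance then gives exactly V_O = 8/9, V_E = 4/9, I_A = 1. The
expectation under linkage equilibrium is V_E = Σ_j h_j(1 − h_j) with
unbiased per-locus diversity h_j = (n/(n−1))(1 − Σ_i p_ij²); a flag
drops the n/(n−1) factor because published values come from programs
that differ exactly in this estimator, and the two variants can differ
noticeably at small n. I_A = V_O/V_E − 1; I_A^S = I_A/(l − 1).

The permutation null shuffles each locus column independently
(destroying between-locus association, preserving allele frequencies);
p = (1 + #{V_O* ≥ V_O})/(1 + N) never reports an exact zero. Rows are
put in canonical (lexicographic) order before permuting so the p-value
is exactly invariant under isolate relabelling. A seed is mandatory.

## Clonal complexes and MST

Grouping implements the shared-allele threshold rule literally: the
central genotype is the unassigned ST with the most single-locus
variants among unassigned STs (ties: double-locus variants, isolate
frequency, lowest ST number); every unassigned ST sharing ≥ threshold
alleles (default 5 of 8) with it joins; groups whose centres share the
threshold merge. This admits double- and triple-locus variants into a
complex, unlike classic eBURST SLV-chaining (available as
`rule="slv"`). Founders use the same deterministic key computed within
the group. Reported tallies separate multi-ST complexes from
singletons, since "number of clonal complexes" is ambiguous between
the two.

The MST is Prim's algorithm on the complete ST graph weighted by
Hamming profile distance, with deterministic tie-breaking (lower
weight, then higher isolate frequency of the joining ST, then lower ST
number; start = most frequent ST). Edge classes default to 1–2 strong,
3–5 intermediate, ≥ 6 weak; these are a documented convention, not a
reproduction of any particular drawing, and are configurable.

## Trees

UPGMA: size-weighted average linkage, node height = d/2, lexicographic
smallest-label tie-break; output is ultrametric to < 1e−9 and checked
against SciPy average linkage in the tests. The default distance is the
proportion of mismatched loci between ST profiles; concatenated
p-distance is the alternative. Tree cutting removes the k−1 highest
internal nodes (deterministic under ties) — the convention used to
define 2-cut phylogroups. NJ: Saitou–Nei with the standard Q criterion,
deterministic tie-breaks, negative branch lengths clamped to zero with
a warning; it reconstructs additive metrics exactly (validated on
random 6-taxon tree metrics, cross-checked against scikit-bio's nj).

## Split decomposition

Splits are bipartitions A|B with isolation index
α = ½·min over i,j∈A, k,l∈B of [max(d(i,k)+d(j,l), d(i,l)+d(j,k),
d(i,j)+d(k,l)) − d(i,j) − d(k,l)], i = j and k = l allowed. All splits
with α > 0 are enumerated exhaustively up to 12 taxa and by the
incremental taxon-by-taxon construction above that (pruning is safe
because α is monotone non-increasing under taxon addition); both
routes are cross-validated on their overlap. For an additive metric
the splits biject with tree edges, α equals branch length, and the
residual (1 − split-metric sum / distance sum) is 0. Reticulation is
reported when two non-trivial splits are incompatible (all four
intersection cells non-empty). Distances are uncorrected p-distances;
per-locus analyses use distinct alleles as taxa, combined analyses use
distinct STs. A 60-taxon cap keeps the construction tractable —
collapse isolates to STs first.

## Synthetic data

The generator emulates the study conditions the toolkit targets: 8
loci, ~500–700 bp in-frame coding fragments (default 510 bp) at ~45%
GC with no internal stops, synthesized 18–22 bp primer flanks (so
trimming round-trips by construction), 3–8 alleles per locus carrying
3–9 planted segregating sites (one per codon, so a fully synonymous
request yields dN = 0 exactly), a 0.9 synonymous fraction emulating
purifying selection, and 50-isolate populations. Clonal populations
draw founders maximally separated (distinct alleles at every locus)
with geometric(0.5)-depth single-locus-change descendants — the
founder-star pattern; an optional depth cap keeps descendants within
the complex radius for exact-recovery experiments. Panmictic
populations draw each locus independently, giving linkage equilibrium
by construction. Everything is bit-reproducible given a seed.

What passing on synthetic data does not show: real sequences carry
sequencing error, indels, chimeric reads and missing loci, none of
which are modelled; mutation placement is uniform (no hotspots, no
codon-usage bias); clonal descent has no homologous recombination, so
reticulation in clonal simulations reflects homoplasy only. Validation
demonstrates algorithmic correctness and statistical calibration, not
robustness to real-data artefacts.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use: 200 random codon pairs
(≤ 30 codons) for the NG86 oracle; 100 panmictic replicates of n = 500
isolates with 199 permutations each for null calibration; 50 random
≤ 6-ST instances for MST optimality against exhaustive enumeration;
20 seeded founder-star populations for clonal-complex recovery; 100
random matrices for UPGMA ultrametricity; 50 random 6-taxon additive
metrics for NJ; and 5–12-taxon metrics for the split-decomposition
identities. These sizes give tight Monte-Carlo error on every
calibration quantity while a full run stays under a minute.

## Known limitations

- No maximum-likelihood dN/dS, site-specific selection tests, or
  bootstrap support values.
- LIAN's parametric test and its one-per-lineage "burst" subsampling
  are not implemented; the permutation test is the only significance
  machinery.
- eBURST bootstrap founder confidence and the full goeBURST tie-break
  hierarchy are omitted.
- Split networks are emitted as Nexus splits blocks for external
  viewers; no layout or drawing.
- Published I_A vs I_A^S pairs computed by different programs can be
  mutually inconsistent under any single V_E estimator; both estimator
  variants are provided, but reproducing two programs' outputs
  simultaneously may be impossible in principle.
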