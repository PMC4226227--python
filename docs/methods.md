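# Methods

## The model of mappability

A read of length *k* sampled from position *i* of a reference genome can be
placed uniquely iff the length-*k* window at *i* occurs exactly once in the
genome, counting both strands. The package idealises the read set as every
forward-strand window (equivalently: whole fragments are sequenced, read
length = fragment length = *k*; no sampling or error model). Two measures
follow:

* **read fraction**: repeated windows / all N-free windows — what fraction
  of the read *population* is unmappable;
* **region fraction**: bases covered by ≥ 1 repeated window / non-N bases —
  what fraction of the assembled *sequence* is unmappable.

The region fraction is never smaller than what the repeated windows alone
suggest, because each repeated window spreads over *k* bases; the toy
example (15 % of reads vs 50 % of sequence at k = 4) shows how far the two
views can diverge.

At the fragment level the same logic is summarised by three lengths: a
repeat of length *D* is harmless if *D* < *R* (read runs past it), fatal if
*D* > *F* (the whole fragment sits inside it), and ambiguous in between.
The caption-level rule uses strict inequalities for the two certain
classes, so the boundary cases *D* = *R* and *D* = *F* are classed
ambiguous here.

## Counting conventions

These conventions are applied uniformly and matter for exact agreement
with the worked example:

* **Strand collapse.** Multiplicity is counted on canonical k-mers
  (lexicographic min of the k-mer and its reverse complement, A<C<G<T).
  A palindromic k-mer's window counts once — the forward window and its
  reverse-complement reading are one physical locus.
* **N handling.** Windows containing N are excluded from numerator and
  denominator alike; the region fraction divides by non-N bases. Both
  measures therefore describe the assembled portion only.
* **Contig boundaries.** Windows never span contigs; multiplicity is
  genome-wide across contigs.
* **Coordinates.** 0-based half-open everywhere, BED included.

On input, lowercase folds to uppercase and any IUPAC code other than
A/C/G/T folds to N (real reference FASTA files parse; everything outside
the four bases is treated as unassembled).

Counting is vectorised by 2-bit-packing k-mers into unsigned 64-bit keys
for k ≤ 31, with a string-keyed fallback for longer k; both paths are
checked against a naive window-pair oracle in the tests.

## Maximal and independent repeats

A **maximal repeat** is a substring with ≥ 2 occurrences such that neither
the left-extension nor the right-extension by one base preserves all
occurrences. Enumeration uses a suffix array + LCP array over the
concatenation of every contig *and its reverse complement*, each string
terminated by a distinct sentinel:

* construction is prefix doubling (O(n log² n), vectorised); LCP is
  Kasai's algorithm; both are validated against naive suffix sorting;
* right-maximal strings are exactly the branching LCP intervals; left
  maximality is decided on the characters preceding the occurrence set;
* sentinels and every N position carry unique symbols, so no repeat spans
  a contig boundary or a gap, and repeats abutting string ends count as
  extensible-by-nothing (maximal);
* occurrences found on reverse-complement text are mapped back to forward
  coordinates and deduplicated; a unit and its reverse complement are one
  record under the canonical spelling. Copy number C is the number of
  deduplicated forward loci.

The **independence filter** processes records longest-first and keeps a
record iff at least one occurrence is not fully contained (forward
coordinates, strand-agnostic) in an occurrence of an already-kept longer
record. By default it also requires two mutually non-overlapping
occurrences, which removes self-overlapping stutters such as `aa` occurring
only at positions i and i+1; this non-overlap rule is the convention that
reproduces the worked example's dimer list, and it can be switched off.

**Upper bound.** Every repeated (D₀+1)-mer type yields repeated D₀-mer
types, so N<sub>D₀</sub> − N<sub>D₀+1</sub> bounds the number of maximal
repeat types of length exactly D₀ from above. The difference is floored at
zero — impossible for histograms computed here, but it keeps the operation
total for user-supplied spectra. Between sampled lengths, type counts are
interpolated linearly in log-log space (each segment an exact power law
through its endpoints); queries outside the sampled range extrapolate from
the nearest segment.

## Approximate repeats

**Hamming clusters.** For mismatch tolerance M, nodes are the canonical
k-mer types present in the genome and edges join types at strand-aware
distance min(H(x,y), H(x, RC(y))) ≤ M; clusters are connected components,
and a component "repeats" when its summed occurrence count is ≥ 2. At
M = 0 this reduces exactly to the exact-repeat types (asserted in tests).
A strand-blind mode (plain Hamming distance) is available for comparison.
On the toy sequence at k = 5, M = 1 the strand-aware convention yields
three repeating clusters of 4, 3 and 2 pentamer types. All-pairs
comparison limits the method to small k or small genomes by design.

**SegDup tables.** The reader accepts the UCSC genomicSuperDups-style
columns (chrom, start, end, name, otherChrom, otherStart, otherEnd,
fracMatch), with per-line validation. The standard admission filter
(length ≥ 1 kb, identity > 90 %) is provided separately so unfiltered
tables can also be inspected. Duplication length is taken from the primary
interval (each alignment line is listed from the primary fragment's
perspective); a symmetric mode counts both intervals. Copy number per
label is the number of pairwise alignment lines plus one.

**Exponent fitting.** The default estimator is ordinary least squares of
log₁₀(count density) on log₁₀(x) — the estimator that corresponds to
reading a slope off the log-log histogram. Histograms are log-binned (10
bins per decade by default) and converted to densities (count / bin
width) before fitting, since log-bin widths grow with x and raw counts of
an x^(−a) law would decay as x^(−(a−1)). Sparse tail bins carry
log-Poisson noise, so recovery tests fit over the well-populated range. A
discrete maximum-likelihood (Hill-type) estimator is provided as an
alternative but is not the default.

## The synthetic-genome generator

The generator emulates the structural ingredients that control
mappability in real genomes:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 200 000 b | total simulated length |
| `gc_content` | 0.40 | background GC (human genome-wide value) |
| `repeat_length_exponent` | 2.0 | a in P(D) ∝ D^(−a) for family unit lengths |
| `repeat_length_range` | (20, 2000) b | support of D |
| `copy_exponent` | 3.0 | b in P(C) ∝ C^(−b) (the observed copy-number law) |
| `copy_range` | (2, 20) | support of C |
| `n_repeat_families` | 50 | dispersed repeat families |
| `per_copy_mutation_rate` | 0.0 | substitutions/base per placed copy |
| `satellite_specs` | () | (unit, tandem copies) exact arrays |
| `gap_fraction` | 0.076 | N budget (the GRCh37 unassembled fraction) |

Power-law draws use exact normalised cumulative inversion over the integer
support. Placement is uniform with rejection against an interval tree
(1000 retries, largest blocks first); placements never overlap, each copy
lands on a random strand, and mutations are substitution-only so copies
stay Hamming-comparable. The N budget is split into ~1 kb runs. All
randomness flows from one integer seed; output is byte-identical across
runs.

What the generator does **not** emulate: duplication-dynamics evolution
(no common descent between families), GC heterogeneity and isochores,
nested/overlapping repeat structure, indel divergence between copies, and
centromere-scale higher-order satellite structure. Tests passing on
synthetic genomes therefore validate the counting and enumeration
machinery under known ground truth; they do not by themselves certify
genome-scale biological conclusions, for which the same operations can be
run on a real reference FASTA.

## Numerical and scale choices

* Suffix-array enumeration and the brute-force cross-checks run on
  sequences up to a few hundred kilobases in the test suite; the
  simulator fixtures use 5–60 kb genomes, which exercise every code path
  (both strands, mutation, satellites, gaps) while keeping the default
  suite fast.
* Oracle-equivalence tests run 100 seeded random sequences of length
  ≤ 300 across alphabets of 2–4 letters (low-complexity alphabets make
  repeats dense).
* Degenerate inputs: empty genomes are rejected at indexing; k exceeding
  every contig warns and returns empty counts; a genome with zero
  countable windows makes the read fraction an error rather than a silent
  0/0.
* Chromosome classes default to the human convention: acrocentric =
  {13, 14, 15, 21, 22, Y}; chr1/9/16 are kept separable as the large
  heterochromatin carriers, and the report includes both the
  non-acrocentric aggregate and metacentric-excluding-chr1/9/16.
  Unlisted contigs (chrM, unplaced scaffolds) are classed unknown and
  excluded from named aggregates.
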