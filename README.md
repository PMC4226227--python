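# repeatmap

Repeat structure sets a hard ceiling on short-read mappability: a read that
falls entirely inside a repeated stretch of the genome cannot be aligned to
a unique reference position. `repeatmap` quantifies that ceiling for any
genome. It is written for sequencing-method developers and genome analysts
who need to know, for a given read length *k*, which reads and which
reference regions are unmappable, and how the heavy-tailed (power-law)
distributions of repeat length and copy number make longer reads a game of
diminishing returns.

## What it computes

Let a **canonical k-mer** be the lexicographic minimum of a k-mer and its
reverse complement, so both strands count as one repeat type. Writing
*N*<sub>*D*₀,*C*</sub> for the number of canonical types of fixed length
*D*₀ with exactly *C* genomic copies, the toolkit derives:

* **Unmappable read fraction** at read length *k*: the proportion of N-free
  length-*k* windows whose canonical k-mer occurs ≥ 2 times genome-wide
  (the read-population view, Σ<sub>C≥2</sub> C·N<sub>k,C</sub> / Σ<sub>C</sub> C·N<sub>k,C</sub>).
* **Unmappable region fraction**: the proportion of assembled (non-N) bases
  covered by any occurrence of a repeated k-mer (the reference view), with
  BED export of the flagged regions.
* **Maximal repeats** (*D*, *C*): substrings whose occurrence set survives
  no single-base extension left or right, enumerated over a suffix array +
  LCP index built on forward *and* reverse-complement text; an
  **independence filter** then discards units that exist only inside longer
  kept repeats (and, optionally, units lacking two non-overlapping copies).
* The **upper bound** *N*<sub>*D*₀</sub> − *N*<sub>*D*₀+1</sub> on the
  number of maximal repeat types of length exactly *D*₀, and power-law
  (log-log linear) interpolation of type counts between sampled lengths.
* **Approximate repeats**: Hamming-distance clusters of k-mer types at ≤ M
  mismatches, and length/copy-number histograms of segmental-duplication
  (SegDup) tables with power-law exponent fits against the reference
  curves 1/D, 1/D², 1/D³ and 1/C³.
* **Assembly-gap statistics**: N-run content per contig and chromosome
  class (acrocentric vs metacentric), and the D/R/F fragment-mappability
  classification (repeat length vs read and fragment length).
* A **seeded synthetic-genome generator** with power-law repeat lengths and
  copy numbers, per-copy point mutations, satellite tandem arrays, N-gaps,
  and a complete ground-truth catalog.

## Worked example

The 16-base sequence `atcgaaatatccatcc` contains every phenomenon in
miniature:

```python
>>> from repeatmap import *
>>> toy = Genome.from_dict({"t": "atcgaaatatccatcc"})
>>> unmappable_read_fraction(toy, 4)
0.15384615384615385
>>> unmappable_region_fraction(toy, 4)
0.5
```

Of the 13 tetramer windows, two are the copies of `atcc`, so 2/13 ≈ 15 % of
idealised 4-base reads are unmappable — yet those two copies cover 8 of the
16 bases, so half the *sequence* is unmappable. The two views of
mappability differ, and both are computed.

```python
>>> idx = build_index(toy)
>>> for r in independent_repeat_filter(enumerate_maximal_repeats(idx, min_len=2)):
...     print(r.unit, r.D, r.C)
ATCC 4 2
ATC 3 3
AT 2 4
GA 2 4
```

One maximal tetramer (`atcc`, C = 2), one independent trimer (`atc`, C = 3
— its third copy is not inside `atcc`), and two independent dimers (`at`
and `tc`, each C = 4 once the forward `ga` locus is counted as a
reverse-strand occurrence of `tc`; `GA` is the canonical spelling).
`tcc`, `cc` and the self-overlapping `aa` are correctly excluded.

The same operations scale to simulated or real genomes from the command
line:

```bash
repeatmap mappability --fasta genome.fa --k-list 20,25,30,50,100 --bed-out beds/
repeatmap maxrep --fasta genome.fa --min-len 20 --independent
repeatmap simulate --config sim.yaml --out synth.fa --truth truth.tsv
repeatmap gaps --fasta genome.fa
```

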