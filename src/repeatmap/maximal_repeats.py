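"""Maximal-repeat enumeration via a both-strand suffix array.

A *maximal repeat* is a substring with at least two occurrences that cannot
be extended by one base to the left or right without losing an occurrence.
Enumeration runs over the concatenation of every contig and its reverse
complement, each terminated by a distinct sentinel, so repeats whose copies
sit on opposite strands are found, and copy numbers count deduplicated
forward-coordinate loci (a palindromic unit's two strand readings of one
locus count once).

The index is a plain suffix array + LCP array (prefix-doubling construction,
Kasai LCP).  Right-maximal strings are the branching LCP intervals; left
maximality is checked on the preceding characters of the occurrence set,
with sentinels and N positions acting as unique context characters (so
repeats abutting contig ends or assembly gaps are maximal, and no repeat
spans an N).

Two derived analyses accompany enumeration: the difference
``N_k - N_{k+1}`` of repeated fixed-length type counts, which upper-bounds
the number of maximal repeat types of length exactly ``k``; and power-law
(log-log linear) interpolation of type counts between sampled lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome_io import Genome, GenomicInterval, canonical_kmer, reverse_complement
from .kmer_mappability import KmerCopyHistogram, repeated_type_count

__all__ = [
    "SuffixArrayIndex",
    "RepeatRecord",
    "RepeatLengthSpectrum",
    "build_index",
    "enumerate_maximal_repeats",
    "independent_repeat_filter",
    "upper_bound_spectrum",
    "interpolate_counts_loglog",
]


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), fully vectorised)."""
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    if rank.max() == n - 1:
        return np.argsort(rank, kind="stable").astype(np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        boundary = np.ones(n, dtype=bool)
        boundary[1:] = (np.diff(rank[order]) != 0) | (np.diff(second[order]) != 0)
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(boundary) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


def _lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[i] = LCP of sorted suffixes i-1 and i."""
    n = sa.size
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            m = n - max(i, j)
            while h < m and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


@dataclass
class SuffixArrayIndex:
    """Suffix array + LCP over concatenated (both-strand) contig text.

    ``codes`` encodes A/C/G/T as four shared symbols while every sentinel
    and every N receives its own unique symbol smaller than any base, which
    both prevents suffix comparisons from crossing string boundaries and
    keeps N out of repeat units.
    """

    codes: np.ndarray
    sa: np.ndarray
    lcp: np.ndarray
    # per text position: contig index, strand (+1 fwd / -1 rc), in-string offset
    contig_idx: np.ndarray
    strand: np.ndarray
    offset: np.ndarray
    contig_names: list[str]
    contig_lengths: list[int]
    # forward and reverse-complement residue strings for unit decoding
    fwd_seqs: list[str] = field(repr=False)
    rc_seqs: list[str] = field(repr=False)
    include_revcomp: bool = True

    def __len__(self) -> int:
        return int(self.codes.size)

    def decode_at(self, text_pos: int, length: int) -> str:
        ci = int(self.contig_idx[text_pos])
        off = int(self.offset[text_pos])
        seq = self.fwd_seqs[ci] if self.strand[text_pos] > 0 else self.rc_seqs[ci]
        return seq[off : off + length]

    def forward_locus(self, text_pos: int, length: int) -> GenomicInterval:
        """Forward-coordinate interval of the occurrence starting at text_pos."""
        ci = int(self.contig_idx[text_pos])
        off = int(self.offset[text_pos])
        clen = self.contig_lengths[ci]
        if self.strand[text_pos] > 0:
            return GenomicInterval(self.contig_names[ci], off, off + length, "+")
        return GenomicInterval(
            self.contig_names[ci], clen - off - length, clen - off, "-"
        )


def build_index(genome: Genome, include_revcomp: bool = True) -> SuffixArrayIndex:
    """Index forward (and by default reverse-complement) text of every contig."""
    if len(genome) == 0 or genome.total_length == 0:
        raise ValueError("cannot index an empty genome")
    strings: list[tuple[int, int, str]] = []  # (contig idx, strand, residues)
    for i, c in enumerate(genome):
        strings.append((i, +1, c.residues))
        if include_revcomp:
            strings.append((i, -1, reverse_complement(c.residues)))

    total = sum(len(s) + 1 for _, _, s in strings)
    codes = np.empty(total, dtype=np.int64)
    contig_idx = np.empty(total, dtype=np.int32)
    strand = np.empty(total, dtype=np.int8)
    offset = np.empty(total, dtype=np.int64)

    base_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    unique_code = 0  # sentinels and Ns: unique, strictly below every base
    pos = 0
    n_unique = sum(s.count("N") for _, _, s in strings) + len(strings)
    base_offset = n_unique
    for ci, st, s in strings:
        enc = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        n = enc.size
        seg = np.empty(n + 1, dtype=np.int64)
        lut = np.full(256, -1, dtype=np.int64)
        for ch, b in base_of.items():
            lut[ord(ch)] = base_offset + b
        seg[:n] = lut[enc]
        n_pos = np.flatnonzero(seg[:n] == -1)
        seg[n_pos] = unique_code + np.arange(n_pos.size)
        unique_code += n_pos.size
        seg[n] = unique_code  # sentinel
        unique_code += 1
        codes[pos : pos + n + 1] = seg
        contig_idx[pos : pos + n + 1] = ci
        strand[pos : pos + n + 1] = st
        offset[pos : pos + n + 1] = np.arange(n + 1)
        pos += n + 1

    sa = _suffix_array(codes)
    lcp = _lcp_array(codes, sa)
    return SuffixArrayIndex(
        codes=codes,
        sa=sa,
        lcp=lcp,
        contig_idx=contig_idx,
        strand=strand,
        offset=offset,
        contig_names=genome.names,
        contig_lengths=[c.length for c in genome],
        fwd_seqs=[c.residues for c in genome],
        rc_seqs=[reverse_complement(c.residues) for c in genome],
        include_revcomp=include_revcomp,
    )


@dataclass
class RepeatRecord:
    """One repeat unit: canonical sequence, length D, copy number C, loci.

    C counts deduplicated forward-coordinate occurrences over both strands;
    every occurrence spells the unit or its reverse complement.
    """

    unit: str
    D: int
    C: int
    occurrences: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.D != len(self.unit):
            raise ValueError("D must equal unit length")
        if self.C != len(self.occurrences):
            raise ValueError("C must equal number of occurrences")


def _lcp_intervals(lcp: np.ndarray):
    """Yield branching intervals (depth, lb, rb): suffixes sa[lb:rb] share a
    length-``depth`` prefix and the interval is right-maximal."""
    n = lcp.size
    stack: list[tuple[int, int]] = []  # (depth, left boundary)
    for i in range(1, n):
        lb = i - 1
        while stack and lcp[i] < stack[-1][0]:
            depth, lb = stack.pop()
            yield depth, lb, i
        if lcp[i] > 0 and (not stack or lcp[i] > stack[-1][0]):
            stack.append((int(lcp[i]), lb))
    while stack:
        depth, lb = stack.pop()
        yield depth, lb, n


def enumerate_maximal_repeats(
    index: SuffixArrayIndex, min_len: int = 1, min_copies: int = 2
) -> list[RepeatRecord]:
    """All maximal repeats with unit length >= min_len and >= min_copies loci.

    Returns one record per canonical unit (a unit and its reverse complement
    are the same repeat), with complete, sorted occurrence lists.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    codes, sa, lcp = index.codes, index.sa, index.lcp
    by_canonical: dict[str, RepeatRecord] = {}
    for depth, lb, rb in _lcp_intervals(lcp):
        if depth < min_len:
            continue
        pos = sa[lb:rb]
        left = np.where(pos > 0, codes[np.maximum(pos - 1, 0)], -1)
        if np.unique(left).size < 2:
            continue  # all occurrences share the same left extension
        loci: dict[tuple[str, int, int], GenomicInterval] = {}
        for p in pos:
            iv = index.forward_locus(int(p), depth)
            loci.setdefault((iv.contig, iv.start, iv.end), iv)
        if len(loci) < min_copies:
            continue
        unit = canonical_kmer(index.decode_at(int(pos[0]), depth))
        if unit in by_canonical:
            continue  # reverse-complement twin of an already-collected unit
        occ = sorted(loci.values(), key=lambda iv: (iv.contig, iv.start))
        by_canonical[unit] = RepeatRecord(unit=unit, D=depth, C=len(occ), occurrences=occ)
    return sorted(by_canonical.values(), key=lambda r: (-r.D, r.unit))


def _has_two_disjoint(occ: Sequence[GenomicInterval]) -> bool:
    """True iff some two occurrences do not overlap (greedy by end point)."""
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in occ:
        by_contig.setdefault(iv.contig, []).append(iv)
    if len(by_contig) > 1:
        return True
    ivs = sorted(next(iter(by_contig.values())), key=lambda iv: iv.end)
    first_end = ivs[0].end
    return any(iv.start >= first_end for iv in ivs[1:])


def independent_repeat_filter(
    records: Iterable[RepeatRecord], non_overlap: bool = True
) -> list[RepeatRecord]:
    """Keep repeats that are not mere sub-strings of longer kept repeats.

    Processing lengths from longest to shortest, a record survives iff at
    least one of its occurrences is not fully contained in any occurrence of
    an already-kept longer record — i.e. the unit has an "extra copy" of its
    own.  With ``non_overlap`` (the default), a record additionally needs
    two mutually non-overlapping occurrences, so self-overlapping tandem
    stutters (e.g. ``aa`` occurring only as positions i, i+1) do not count
    as independent repeats.
    """
    recs = sorted(records, key=lambda r: (-r.D, r.unit))
    kept: list[RepeatRecord] = []
    for rec in recs:
        longer_occ = [iv for k in kept if k.D > rec.D for iv in k.occurrences]
        free = any(
            not any(big.contains(iv) for big in longer_occ)
            for iv in rec.occurrences
        )
        if not free:
            continue
        if non_overlap and not _has_two_disjoint(rec.occurrences):
            continue
        kept.append(rec)
    return kept


@dataclass
class RepeatLengthSpectrum:
    """Count of repeat types per unit length, tagged with its provenance."""

    counts: dict[int, int]
    flavor: str  # maximal | independent | fixed-length | upper-bound

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("spectrum counts must be >= 0")


def upper_bound_spectrum(
    hists: Sequence[KmerCopyHistogram],
) -> RepeatLengthSpectrum:
    """Upper bound on maximal-repeat type counts from fixed-length spectra.

    Every repeated (k+1)-mer type contains repeated k-mer types, so the
    difference ``N_k - N_{k+1}`` bounds from above the number of maximal
    repeat types of length exactly k.  The input must contain at least one
    consecutive length pair; the bound is floored at zero to stay total
    under arbitrary user-supplied histograms.
    """
    by_k = {h.k: h for h in hists}
    ks = sorted(by_k)
    pairs = [(k, k + 1) for k in ks if k + 1 in by_k]
    if not pairs:
        raise ValueError(
            f"need histograms at consecutive lengths; got lengths {ks}"
        )
    counts = {
        k: max(0, repeated_type_count(by_k[k]) - repeated_type_count(by_k[k1]))
        for k, k1 in pairs
    }
    return RepeatLengthSpectrum(counts=counts, flavor="upper-bound")


def interpolate_counts_loglog(
    points: Sequence[tuple[float, float]], query_lengths: Iterable[float]
) -> dict[float, float]:
    """Piecewise power-law interpolation of (length, count) samples.

    Between neighbouring samples, log(count) is linear in log(length), i.e.
    each segment is an exact power law through its two endpoints.  Queries
    at sampled lengths return the sampled value; queries outside the range
    extrapolate from the nearest segment.
    """
    if len(points) < 2:
        raise ValueError("need at least two points")
    xs = np.asarray([p[0] for p in points], dtype=float)
    ys = np.asarray([p[1] for p in points], dtype=float)
    if np.any(np.diff(xs) <= 0):
        raise ValueError("points must be sorted by strictly increasing length")
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise ValueError("lengths and counts must be positive for log-log fit")
    lx, ly = np.log(xs), np.log(ys)
    out: dict[float, float] = {}
    for q in query_lengths:
        if q <= 0:
            raise ValueError("query lengths must be positive")
        j = int(np.searchsorted(lx, np.log(q), side="left"))
        j = min(max(j, 1), lx.size - 1)  # clamp => end segments extrapolate
        slope = (ly[j] - ly[j - 1]) / (lx[j] - lx[j - 1])
        out[q] = float(np.exp(ly[j - 1] + slope * (np.log(q) - lx[j - 1])))
    return out
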