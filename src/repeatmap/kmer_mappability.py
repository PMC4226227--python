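"""Canonical k-mer multiplicity counting and unmappability measures.

A read of length ``k`` drawn from inside a repeated k-mer cannot be placed
uniquely against the reference, so the multiplicity spectrum of canonical
k-mers determines mappability at that read length.  Two complementary
measures are computed over a genome:

* the **unmappable read fraction** — the proportion of all N-free length-k
  windows whose canonical k-mer occurs at least twice genome-wide (the
  read-population view);
* the **unmappable region fraction** — the proportion of non-N bases covered
  by at least one such repeated window (the reference-coordinate view).

Both strands are collapsed through the canonical form, so a window and its
reverse-complement reading are one repeat type; a palindromic k-mer window
contributes a single count.  Windows containing N are excluded from both
numerator and denominator: the measures describe the assembled portion of
the genome only.

Reads are idealised as every forward-strand window (whole fragments
sequenced, read length = fragment length = k); no sampling model is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .genome_io import Contig, Genome, GenomicInterval, reverse_complement

__all__ = [
    "KmerCopyHistogram",
    "MappabilityMask",
    "count_canonical_kmers",
    "kmer_copy_histogram",
    "repeated_type_count",
    "unmappable_read_fraction",
    "unmappable_mask",
    "unmappable_region_fraction",
    "mappability_profile",
    "mask_to_bed",
]

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _BASE_CODE[ord(_c)] = _i

# 2-bit packing holds k <= 31 in a uint64; longer k falls back to strings.
_MAX_PACKED_K = 31


@dataclass
class KmerCopyHistogram:
    """Number of distinct canonical k-mer types per copy number at fixed k.

    ``counts[C]`` is the number of canonical types occurring exactly ``C``
    times genome-wide; ``total_instances`` is the number of N-free windows,
    so ``sum(C * counts[C]) == total_instances`` always holds.
    """

    k: int
    counts: dict[int, int]
    total_instances: int

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts):
            raise ValueError("copy numbers must be >= 1")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("type counts must be >= 0")
        conserved = sum(c * n for c, n in self.counts.items())
        if conserved != self.total_instances:
            raise ValueError(
                f"histogram inconsistent: sum(C*N_C)={conserved} != "
                f"total_instances={self.total_instances}"
            )

    @property
    def n_types(self) -> int:
        return sum(self.counts.values())


@dataclass
class MappabilityMask:
    """Per-contig boolean vectors; True marks a base in an unmappable region."""

    k: int
    flags: dict[str, np.ndarray]

    def flagged_bases(self) -> int:
        return int(sum(v.sum() for v in self.flags.values()))


def _encode(contig: Contig) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(contig.residues.encode("ascii"), dtype=np.uint8)]


def _packed_window_keys(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical 2-bit-packed keys for every N-free window; returns (starts, keys)."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 4).any(axis=1)
    starts = np.nonzero(valid)[0]
    if starts.size == 0:
        return starts, np.empty(0, dtype=np.uint64)
    w = win[starts].astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = w @ powers
    rev = (np.uint64(3) - w[:, ::-1]) @ powers
    return starts, np.minimum(fwd, rev)


def _string_window_keys(contig: Contig, k: int) -> tuple[np.ndarray, list[str]]:
    seq = contig.residues
    starts, keys = [], []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        rc = reverse_complement(w)
        starts.append(i)
        keys.append(w if w <= rc else rc)
    return np.asarray(starts, dtype=np.int64), keys


def _decode_packed(key: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[key & 3])
        key >>= 2
    return "".join(reversed(out))


def _genome_window_keys(genome: Genome, k: int):
    """Per-contig (starts, keys) plus flat key array for genome-wide counting."""
    per_contig = []
    flat = []
    if k <= _MAX_PACKED_K:
        for c in genome:
            starts, keys = _packed_window_keys(_encode(c), k)
            per_contig.append((c, starts, keys))
            flat.append(keys)
        flat_keys = (
            np.concatenate(flat) if flat else np.empty(0, dtype=np.uint64)
        )
    else:
        for c in genome:
            starts, keys = _string_window_keys(c, k)
            per_contig.append((c, starts, keys))
            flat.extend(keys)
        flat_keys = np.asarray(flat, dtype=object)
    return per_contig, flat_keys


def count_canonical_kmers(genome: Genome, k: int) -> dict[str, int]:
    """Count occurrences of each canonical k-mer over the whole genome.

    Every N-free forward-strand window contributes one count to its
    canonical form; windows never span contigs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if all(c.length < k for c in genome):
        warnings.warn(f"k={k} exceeds every contig length; no windows counted")
        return {}
    _, flat = _genome_window_keys(genome, k)
    uniq, counts = np.unique(flat, return_counts=True)
    if k <= _MAX_PACKED_K:
        return {
            _decode_packed(int(u), k): int(c) for u, c in zip(uniq, counts)
        }
    return {str(u): int(c) for u, c in zip(uniq, counts)}


def kmer_copy_histogram(genome: Genome, k: int) -> KmerCopyHistogram:
    """The copy-number spectrum N_{k,C} of canonical k-mer types."""
    if all(c.length < k for c in genome):
        warnings.warn(f"k={k} exceeds every contig length; empty histogram")
        return KmerCopyHistogram(k=k, counts={}, total_instances=0)
    _, flat = _genome_window_keys(genome, k)
    _, type_counts = np.unique(flat, return_counts=True)
    cvals, ncopies = np.unique(type_counts, return_counts=True)
    return KmerCopyHistogram(
        k=k,
        counts={int(c): int(n) for c, n in zip(cvals, ncopies)},
        total_instances=int(flat.size),
    )


def repeated_type_count(hist: KmerCopyHistogram) -> int:
    """N_k: number of canonical k-mer types with copy number >= 2."""
    return sum(n for c, n in hist.counts.items() if c >= 2)


def _repeated_window_stats(genome: Genome, k: int):
    """(per-contig repeated-window starts, n repeated windows, n windows)."""
    per_contig, flat = _genome_window_keys(genome, k)
    if flat.size == 0:
        return [], 0, 0
    uniq, counts = np.unique(flat, return_counts=True)
    repeated = set(uniq[counts >= 2].tolist())
    out = []
    n_rep = 0
    n_tot = 0
    for contig, starts, keys in per_contig:
        keys_list = keys if isinstance(keys, list) else keys.tolist()
        mask = np.fromiter(
            (key in repeated for key in keys_list), dtype=bool, count=len(keys_list)
        )
        out.append((contig, starts[mask] if starts.size else starts))
        n_rep += int(mask.sum())
        n_tot += len(keys_list)
    return out, n_rep, n_tot


def unmappable_read_fraction(genome: Genome, k: int) -> float:
    """Fraction of N-free windows whose canonical k-mer occurs >= 2 times."""
    _, n_rep, n_tot = _repeated_window_stats(genome, k)
    if n_tot == 0:
        raise ValueError(f"no N-free windows at k={k}; fraction undefined")
    return n_rep / n_tot


def unmappable_mask(genome: Genome, k: int) -> MappabilityMask:
    """Flag every base covered by a window of a repeated canonical k-mer."""
    per_contig, _, _ = _repeated_window_stats(genome, k)
    flags: dict[str, np.ndarray] = {}
    for contig, rep_starts in per_contig:
        cover = np.zeros(contig.length + 1, dtype=np.int32)
        np.add.at(cover, rep_starts, 1)
        np.add.at(cover, rep_starts + k, -1)
        flags[contig.name] = np.cumsum(cover[:-1]) > 0
    for c in genome:
        flags.setdefault(c.name, np.zeros(c.length, dtype=bool))
    return MappabilityMask(k=k, flags=flags)


def unmappable_region_fraction(genome: Genome, k: int) -> float:
    """Fraction of non-N bases lying in an unmappable region at read length k."""
    mask = unmappable_mask(genome, k)
    non_n = sum(
        c.length - c.residues.count("N") for c in genome
    )
    if non_n == 0:
        raise ValueError("genome has no assembled (non-N) bases")
    return mask.flagged_bases() / non_n


def mappability_profile(genome: Genome, ks: Iterable[int]):
    """Tabulate both unmappability fractions and N_k across read lengths.

    Returns a pandas DataFrame with columns ``k``, ``read_unmappable_frac``,
    ``region_unmappable_frac``, ``repeated_types``.  A read length at which
    no window is countable yields NaN fractions with a warning.
    """
    import pandas as pd

    ks = list(ks)
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("read lengths must be strictly increasing")
    rows = []
    for k in ks:
        try:
            rf = unmappable_read_fraction(genome, k)
            gf = unmappable_region_fraction(genome, k)
            nk = repeated_type_count(kmer_copy_histogram(genome, k))
        except ValueError as exc:
            warnings.warn(f"k={k}: {exc}")
            rf = gf = float("nan")
            nk = 0
        rows.append(
            {
                "k": k,
                "read_unmappable_frac": rf,
                "region_unmappable_frac": gf,
                "repeated_types": nk,
            }
        )
    return pd.DataFrame(rows)


def mask_to_bed(mask: MappabilityMask, contig: str) -> list[GenomicInterval]:
    """Maximal runs of flagged bases as sorted 0-based half-open intervals."""
    flags = mask.flags[contig]
    if flags.size == 0 or not flags.any():
        return []
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [GenomicInterval(contig, int(s), int(e)) for s, e in zip(starts, ends)]
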